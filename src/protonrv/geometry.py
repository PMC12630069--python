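"""Synthetic head phantom geometry and water-equivalent path-length tracing.

The phantom is an analytic layer stack traversed by horizontal pencil beams
(beam axis = +x, gantry 270 deg).  In beam's eye view (BEV) y is vertical
(up positive) and z horizontal (left positive); the isocenter sits at the
origin of the room frame.  Layers along the beam axis are

    air | tissue | skull | brain | skull | tissue | air

with the brain filling the space between the bony shells.  The entry surface
is tilted laterally (a linear gradient in y and z) so that the traversed
water-equivalent thickness (WET) varies smoothly across the field and rigid
lateral couch shifts produce non-zero range shifts.

Couch offsets translate the phantom rigidly in the room frame; detectors and
the beam nozzle never move.  Water-equivalent slabs (SPR = 1) can be
inserted upstream of the phantom (inside the beam path, before the entry
surface) or downstream (between the phantom exit and the range-probing
detector).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "Slab",
    "PhantomConfig",
    "PhantomGeometry",
    "build_phantom",
    "RayOutsidePhantomError",
]

#: default SPR of homogeneous brain tissue (dimensionless, water = 1)
SPR_BRAIN_DEFAULT = 1.04


class RayOutsidePhantomError(ValueError):
    """Raised when a ray misses the lateral extent of the phantom."""


@dataclass(frozen=True)
class Slab:
    """Water-equivalent material slab inserted into the beam path.

    ``wet_mm`` is the water-equivalent thickness; with ``spr`` = 1 the
    physical thickness equals the WET.  ``position`` is ``"upstream"``
    (between nozzle and phantom) or ``"downstream"`` (between phantom exit
    and the MLIC detector).
    """

    wet_mm: float
    position: str
    spr: float = 1.0

    def __post_init__(self) -> None:
        if self.wet_mm <= 0:
            raise ValueError(f"slab WET must be positive, got {self.wet_mm}")
        if self.spr <= 0:
            raise ValueError(f"slab SPR must be positive, got {self.spr}")
        if self.position not in ("upstream", "downstream"):
            raise ValueError(f"unknown slab position {self.position!r}")

    @property
    def thickness_mm(self) -> float:
        return self.wet_mm / self.spr


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the analytic layer-stack head phantom.

    Thicknesses are along the beam axis (mm); ``entry_x``/``exit_x`` place
    the skin surfaces in the room frame at (y, z) = (0, 0) with the couch at
    rest.  ``grad_y``/``grad_z`` tilt the entry surface: the entry moves
    upstream by ``grad * lateral offset`` (mm per mm), so a 3 mm lateral
    couch shift changes the traversed WET by order 1 mm with the defaults.
    """

    entry_x: float = -75.0
    exit_x: float = 75.0
    tissue_mm: float = 5.0
    skull_mm: float = 7.0
    spr_tissue: float = 1.0
    spr_skull: float = 1.6
    spr_brain: float = SPR_BRAIN_DEFAULT
    grad_y: float = 0.3
    grad_z: float = 0.3
    lateral_halfwidth_mm: float = 90.0

    def validate(self) -> None:
        if self.tissue_mm <= 0 or self.skull_mm <= 0:
            raise ValueError("layer thicknesses must be positive")
        for name in ("spr_tissue", "spr_skull", "spr_brain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        shell = 2.0 * (self.tissue_mm + self.skull_mm)
        span = self.exit_x - self.entry_x
        if span <= shell:
            raise ValueError(
                "phantom extent too small: layers overlap "
                f"(span {span} mm <= shells {shell} mm)"
            )


@dataclass(frozen=True)
class PhantomGeometry:
    """Phantom layer stack plus inserted slabs and rigid couch offset.

    The couch offset (dx, dy, dz) translates the phantom only; slabs and
    detectors stay fixed in the room frame.
    """

    config: PhantomConfig = field(default_factory=PhantomConfig)
    couch_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    slabs: tuple[Slab, ...] = ()
    #: room-frame x of the beam nozzle (rays start here)
    nozzle_x: float = -500.0
    #: room-frame x of the MLIC entrance window (rays end here for "full" traces)
    mlic_x: float = 220.0
    #: air gap between phantom exit and the first downstream slab face
    downstream_gap_mm: float = 20.0

    # -- construction helpers -------------------------------------------------

    def with_couch_offset(self, dx: float, dy: float, dz: float) -> "PhantomGeometry":
        return replace(self, couch_offset=(dx, dy, dz))

    def with_slab(self, slab: Slab) -> "PhantomGeometry":
        return replace(self, slabs=self.slabs + (slab,))

    @property
    def upstream_slabs(self) -> tuple[Slab, ...]:
        return tuple(s for s in self.slabs if s.position == "upstream")

    @property
    def downstream_slabs(self) -> tuple[Slab, ...]:
        return tuple(s for s in self.slabs if s.position == "downstream")

    # -- geometry queries -----------------------------------------------------

    def entry_x(self, y_mm: float, z_mm: float) -> float:
        """Room-frame x of the tilted entry (skin) surface for a ray at BEV (y, z)."""
        cfg = self.config
        dx, dy, dz = self.couch_offset
        yl = y_mm - dy  # phantom-frame lateral coordinates
        zl = z_mm - dz
        r = math.hypot(yl, zl)
        if r > cfg.lateral_halfwidth_mm:
            raise RayOutsidePhantomError(
                f"ray at BEV ({y_mm}, {z_mm}) misses the phantom "
                f"(lateral radius {r:.1f} > {cfg.lateral_halfwidth_mm} mm)"
            )
        return cfg.entry_x + dx - cfg.grad_y * yl - cfg.grad_z * zl

    def exit_x(self) -> float:
        """Room-frame x of the flat exit surface (independent of y, z)."""
        return self.config.exit_x + self.couch_offset[0]

    def segments(self, y_mm: float, z_mm: float) -> list[tuple[float, float, float]]:
        """Material segments ``(x_start, x_end, spr)`` along the ray, ordered in x.

        Includes upstream slabs (stacked immediately before the entry
        surface) and downstream slabs (stacked after the exit, separated by
        ``downstream_gap_mm`` of air).  Air segments are omitted (SPR 0).
        """
        cfg = self.config
        xe = self.entry_x(y_mm, z_mm)
        xx = self.exit_x()
        brain = (xx - xe) - 2.0 * (cfg.tissue_mm + cfg.skull_mm)
        if brain <= 0:
            raise ValueError("degenerate phantom: no room left for the brain layer")

        segs: list[tuple[float, float, float]] = []
        # upstream slabs stacked so the last one touches the entry surface
        x = xe
        for slab in reversed(self.upstream_slabs):
            segs.insert(0, (x - slab.thickness_mm, x, slab.spr))
            x -= slab.thickness_mm
        # phantom layers
        x = xe
        for thick, spr in (
            (cfg.tissue_mm, cfg.spr_tissue),
            (cfg.skull_mm, cfg.spr_skull),
            (brain, cfg.spr_brain),
            (cfg.skull_mm, cfg.spr_skull),
            (cfg.tissue_mm, cfg.spr_tissue),
        ):
            segs.append((x, x + thick, spr))
            x += thick
        # downstream slabs after an air gap
        x = xx + self.downstream_gap_mm
        for slab in self.downstream_slabs:
            segs.append((x, x + slab.thickness_mm, slab.spr))
            x += slab.thickness_mm
        return segs

    def trace_wet(
        self, y_mm: float, z_mm: float, to_x: float | None = None
    ) -> float:
        """Line integral of SPR along the ray from the nozzle to room-frame ``to_x``.

        ``to_x=None`` traces the full path to the MLIC entrance window, i.e.
        through the phantom and any downstream slabs.  Pure air contributes
        nothing, so a beam-axis couch translation leaves the full-exit WET
        unchanged.
        """
        if to_x is None:
            to_x = self.mlic_x
        wet = 0.0
        for x0, x1, spr in self.segments(y_mm, z_mm):
            lo = max(x0, self.nozzle_x)
            hi = min(x1, to_x)
            if hi > lo:
                wet += spr * (hi - lo)
        return wet

    def cumulative_wet(self, y_mm: float, z_mm: float, xs) -> "list[float]":
        """Cumulative WET from the nozzle at each room-frame position in ``xs``."""
        return [self.trace_wet(y_mm, z_mm, to_x=float(x)) for x in xs]

    def range_position(self, y_mm: float, z_mm: float, wet_mm: float) -> float:
        """Room-frame x at which the cumulative WET first reaches ``wet_mm``.

        Inverts the piecewise-linear WET accumulation over the material
        segments.  If the residual WET is not exhausted inside the material
        stack the position is clamped to the end of the last segment (the
        beam overshoots into air; emission then stops at the exit surface).
        """
        remaining = wet_mm
        segs = self.segments(y_mm, z_mm)
        for x0, x1, spr in segs:
            seg_wet = spr * (x1 - x0)
            if remaining <= seg_wet:
                return x0 + remaining / spr
            remaining -= seg_wet
        return segs[-1][1]


def build_phantom(config: PhantomConfig | dict | None = None) -> PhantomGeometry:
    """Construct the reference phantom geometry (no slabs, couch at rest).

    ``config`` may be a :class:`PhantomConfig`, a mapping of its fields, or
    ``None`` for the defaults.  Non-physical parameters (negative SPR or
    thickness, overlapping layers) are rejected.
    """
    if config is None:
        cfg = PhantomConfig()
    elif isinstance(config, PhantomConfig):
        cfg = config
    else:
        cfg = PhantomConfig(**dict(config))
    cfg.validate()
    return PhantomGeometry(config=cfg)
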