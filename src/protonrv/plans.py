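"""Pencil-beam-scanning spot plans: the treatment field and the probing field.

Two horizontal fields (gantry 270 deg, couch 0 deg) are used:

* a treatment field of 15 energy layers spanning 115-160 MeV delivered
  through a 73.8 mm WET range shifter, monitored with the prompt-gamma
  camera; the clinical spot lattice is replaced by a configurable regular
  lattice covering the target cross-section, with per-spot proton counts
  drawn log-uniformly around the statistical filter threshold;
* a range-probing field of 81 (9 x 9) spots at 5 mm spacing, all 210 MeV,
  each delivered at the machine-minimum 0.04 MU (6.2e6 protons), energetic
  enough to traverse the head and reach the range telescope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spot",
    "SpotPlan",
    "TreatmentPlanConfig",
    "build_rp_plan",
    "build_treatment_plan",
    "plan_to_csv",
    "plan_from_csv",
]

ENERGY_MIN_MEV = 70.0
ENERGY_MAX_MEV = 230.0

#: machine calibration: 0.04 MU delivers 6.2e6 protons
PROTONS_PER_MU = 6.2e6 / 0.04

RP_ENERGY_MEV = 210.0
RP_PROTONS = 6.2e6
RP_GRID_N = 9
RP_PITCH_MM = 5.0

TREATMENT_RANGE_SHIFTER_WET_MM = 73.8


@dataclass(frozen=True)
class Spot:
    """One pencil-beam spot: energy, BEV position, protons, layer index."""

    energy_mev: float
    y_mm: float
    z_mm: float
    protons: float
    layer: int
    kind: str = "treatment"  # "treatment" | "probe"

    def __post_init__(self) -> None:
        if not ENERGY_MIN_MEV <= self.energy_mev <= ENERGY_MAX_MEV:
            raise ValueError(
                f"spot energy {self.energy_mev} MeV outside machine limits "
                f"[{ENERGY_MIN_MEV}, {ENERGY_MAX_MEV}]"
            )
        if self.protons <= 0:
            raise ValueError("spot must deliver a positive number of protons")


@dataclass(frozen=True)
class SpotPlan:
    """Ordered spot list plus field-level delivery parameters."""

    spots: tuple[Spot, ...]
    gantry_deg: float = 270.0
    couch_deg: float = 0.0
    range_shifter_wet_mm: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        kinds = {s.kind for s in self.spots}
        if kinds == {"probe"}:
            if len({s.energy_mev for s in self.spots}) != 1:
                raise ValueError("a probing plan must have exactly one energy layer")
        energies = [s.energy_mev for s in self.spots]
        layer_e: dict[int, float] = {}
        for s in self.spots:
            layer_e.setdefault(s.layer, s.energy_mev)
            if layer_e[s.layer] != s.energy_mev:
                raise ValueError("spots within a layer must share one energy")
        ordered = [layer_e[k] for k in sorted(layer_e)]
        if ordered != sorted(ordered) and ordered != sorted(ordered, reverse=True):
            raise ValueError("energy layers must be monotone in energy")
        del energies

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def layers(self) -> dict[int, list[int]]:
        """Mapping layer index -> spot indices, preserving plan order."""
        out: dict[int, list[int]] = {}
        for i, s in enumerate(self.spots):
            out.setdefault(s.layer, []).append(i)
        return out

    @property
    def energies(self) -> list[float]:
        return sorted({s.energy_mev for s in self.spots})


def build_rp_plan() -> SpotPlan:
    """The 9 x 9 range-probing field: 5 mm pitch, 210 MeV, 6.2e6 protons/spot."""
    half = (RP_GRID_N - 1) / 2.0
    coords = [(i - half) * RP_PITCH_MM for i in range(RP_GRID_N)]
    spots = tuple(
        Spot(RP_ENERGY_MEV, y, z, RP_PROTONS, layer=0, kind="probe")
        for y in coords
        for z in coords
    )
    return SpotPlan(spots, range_shifter_wet_mm=0.0, label="rp-field")


@dataclass(frozen=True)
class TreatmentPlanConfig:
    """Synthetic stand-in for the clinical one-field brain plan.

    ``n_layers`` energy layers span ``[energy_min, energy_max]`` MeV; each
    layer carries an ``ny`` x ``nz`` lattice at ``pitch_mm`` spacing centered
    on the isocenter.  Per-spot proton counts are drawn log-uniformly from
    ``[protons_min, protons_max]``, straddling the 0.5e8 statistics filter
    so the spot filter is exercised.
    """

    n_layers: int = 15
    energy_min_mev: float = 115.0
    energy_max_mev: float = 160.0
    ny: int = 7
    nz: int = 7
    pitch_mm: float = 5.0
    protons_min: float = 2e7
    protons_max: float = 4e8
    range_shifter_wet_mm: float = TREATMENT_RANGE_SHIFTER_WET_MM
    seed: int = 20260921

    def validate(self) -> None:
        if self.n_layers < 1:
            raise ValueError("need at least one energy layer")
        if self.ny < 1 or self.nz < 1:
            raise ValueError("empty target cross-section")
        for e in (self.energy_min_mev, self.energy_max_mev):
            if not ENERGY_MIN_MEV <= e <= ENERGY_MAX_MEV:
                raise ValueError(f"energy {e} MeV outside machine limits")
        if self.energy_min_mev > self.energy_max_mev:
            raise ValueError("energy_min must not exceed energy_max")
        if not 0 < self.protons_min <= self.protons_max:
            raise ValueError("invalid proton-count range")


def build_treatment_plan(config: TreatmentPlanConfig | dict | None = None) -> SpotPlan:
    """Build the synthetic treatment field (deepest layer delivered first)."""
    if config is None:
        cfg = TreatmentPlanConfig()
    elif isinstance(config, TreatmentPlanConfig):
        cfg = config
    else:
        cfg = TreatmentPlanConfig(**dict(config))
    cfg.validate()

    if cfg.n_layers == 1:
        energies = np.array([cfg.energy_max_mev])
    else:
        # descending: highest energy (deepest layer) first, monotone by layer
        energies = np.linspace(cfg.energy_max_mev, cfg.energy_min_mev, cfg.n_layers)
    ys = (np.arange(cfg.ny) - (cfg.ny - 1) / 2.0) * cfg.pitch_mm
    zs = (np.arange(cfg.nz) - (cfg.nz - 1) / 2.0) * cfg.pitch_mm

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    lo, hi = np.log(cfg.protons_min), np.log(cfg.protons_max)
    spots = []
    for li, e in enumerate(energies):
        for y in ys:
            for z in zs:
                protons = float(np.exp(rng.uniform(lo, hi)))
                spots.append(Spot(float(e), float(y), float(z), protons, layer=li))
    return SpotPlan(
        tuple(spots),
        range_shifter_wet_mm=cfg.range_shifter_wet_mm,
        label="treatment-field",
    )


def plan_to_csv(plan: SpotPlan, path: str | Path) -> None:
    """Write a plan as CSV, one row per spot (layer, energy, y, z, protons)."""
    df = pd.DataFrame(
        {
            "layer": [s.layer for s in plan.spots],
            "energy_MeV": [s.energy_mev for s in plan.spots],
            "y_mm": [s.y_mm for s in plan.spots],
            "z_mm": [s.z_mm for s in plan.spots],
            "protons": [s.protons for s in plan.spots],
            "kind": [s.kind for s in plan.spots],
        }
    )
    df.to_csv(path, index=False)


def plan_from_csv(
    path: str | Path,
    gantry_deg: float = 270.0,
    couch_deg: float = 0.0,
    range_shifter_wet_mm: float = 0.0,
    label: str = "",
) -> SpotPlan:
    df = pd.read_csv(path)
    spots = tuple(
        Spot(
            float(r.energy_MeV),
            float(r.y_mm),
            float(r.z_mm),
            float(r.protons),
            int(r.layer),
            str(r.kind),
        )
        for r in df.itertuples()
    )
    return SpotPlan(spots, gantry_deg, couch_deg, range_shifter_wet_mm, label)
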