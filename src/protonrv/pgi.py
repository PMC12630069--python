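"""Prompt-gamma evaluation: reference accumulation, spot filtering, in-layer
aggregation, and least-squares fall-off matching.

Measured profiles are compared spot-by-spot against a high-statistics
reference built by accumulating the ten reference deliveries.  To tame
counting noise, profiles of one energy layer are aggregated with a 2-D
Gaussian kernel (sigma = 7.8 mm) over BEV spot distances; aggregation never
mixes energy layers and is applied identically to reference and
measurement.  The range shift of a spot is the translation that minimizes
the squared difference between reference and measurement inside the distal
fall-off window, found by a coarse 0.1 mm grid search refined parabolically.
Positive shifts mean the fall-off moved distally (range increase).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detectors import PGIProfile, expected_falloff_x
from .geometry import PhantomGeometry
from .plans import SpotPlan

__all__ = [
    "PGIFilterConfig",
    "MatchConfig",
    "MatchResult",
    "accumulate_reference",
    "filter_spots",
    "aggregate_layer",
    "aggregate_plan",
    "match_profile_shift",
]

AGGREGATION_SIGMA_MM = 7.8
MIN_PROTONS_DEFAULT = 0.5e8


@dataclass(frozen=True)
class PGIFilterConfig:
    """Spot-selection rules: enough protons, fall-off safely inside the FOV."""

    fov_mm: tuple[float, float] = (-50.0, 50.0)
    min_protons: float = MIN_PROTONS_DEFAULT
    edge_margin_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.min_protons <= 0:
            raise ValueError("proton threshold must be positive")


@dataclass(frozen=True)
class MatchConfig:
    """Fall-off matcher settings.

    The matching window is frozen on the reference profile between
    ``window_high`` and ``window_low`` fractions of the plateau level.
    Shifts are searched on a coarse grid inside ``+-search_mm`` and refined
    parabolically; ties go to the smallest absolute shift.
    """

    window_high: float = 0.8
    window_low: float = 0.2
    search_mm: float = 15.0
    coarse_step_mm: float = 0.1
    fine_step_mm: float = 0.01
    window_sample_mm: float = 0.5
    background_offset_mm: float = 20.0
    plateau_band_mm: tuple[float, float] = (30.0, 10.0)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of one fall-off match; ``flag`` is None on success."""

    shift_mm: float
    flag: str | None = None
    residual: float = float("nan")
    window_mm: tuple[float, float] = (float("nan"), float("nan"))

    @property
    def ok(self) -> bool:
        return self.flag is None


def accumulate_reference(profile_sets: list[dict[int, PGIProfile]]) -> dict[int, PGIProfile]:
    """Bin-wise sum of the reference deliveries, one accumulated profile per spot."""
    if not profile_sets:
        raise ValueError("no reference deliveries to accumulate")
    spot_ids = sorted(profile_sets[0])
    for k, pset in enumerate(profile_sets[1:], start=2):
        if sorted(pset) != spot_ids:
            raise ValueError(f"reference delivery {k} has a different spot list")
    out: dict[int, PGIProfile] = {}
    for sid in spot_ids:
        first = profile_sets[0][sid]
        counts = np.zeros_like(first.counts, dtype=float)
        protons = 0.0
        for pset in profile_sets:
            p = pset[sid]
            if p.x_mm.shape != first.x_mm.shape or not np.array_equal(p.x_mm, first.x_mm):
                raise ValueError(f"grid mismatch for spot {sid} across deliveries")
            counts += p.counts
            protons += p.protons
        out[sid] = PGIProfile(
            x_mm=first.x_mm, counts=counts, fov_mm=first.fov_mm,
            spot_id=sid, protons=protons, noisy=first.noisy,
        )
    return out


def filter_spots(
    plan: SpotPlan,
    cfg: PGIFilterConfig,
    geom: PhantomGeometry | None = None,
) -> list[int]:
    """Indices of spots passing the statistics and field-of-view filters.

    A spot is kept when it delivers at least ``min_protons`` and, if a
    geometry is given, its expected fall-off lies inside the FOV with an
    edge margin so the matching window fits.  Order-preserving.
    """
    lo = cfg.fov_mm[0] + cfg.edge_margin_mm
    hi = cfg.fov_mm[1] - cfg.edge_margin_mm
    kept = []
    for i, spot in enumerate(plan.spots):
        if spot.protons < cfg.min_protons:
            continue
        if geom is not None:
            xf = expected_falloff_x(geom, spot, plan.range_shifter_wet_mm)
            if not lo <= xf <= hi:
                continue
        kept.append(i)
    return kept


def aggregate_layer(
    profiles: dict[int, PGIProfile],
    positions: dict[int, tuple[float, float]],
    sigma_mm: float = AGGREGATION_SIGMA_MM,
) -> dict[int, PGIProfile]:
    """2-D Gaussian in-layer aggregation over BEV spot distances.

    The aggregated profile of spot i is the kernel-weighted, normalized sum
    of all profiles of its energy layer; spots at distance sigma contribute
    exp(-1/2) of the self-weight.  All spots passed in must belong to one
    layer — the caller is responsible for never mixing layers.
    """
    if not profiles:
        raise ValueError("empty layer")
    ids = sorted(profiles)
    pos = np.array([positions[i] for i in ids], dtype=float)
    stack = np.array([profiles[i].counts for i in ids], dtype=float)
    d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-0.5 * d2 / sigma_mm**2)
    agg = (w @ stack) / w.sum(axis=1, keepdims=True)
    out = {}
    for row, sid in enumerate(ids):
        p = profiles[sid]
        out[sid] = PGIProfile(
            x_mm=p.x_mm, counts=agg[row], fov_mm=p.fov_mm,
            spot_id=sid, protons=p.protons, noisy=p.noisy,
        )
    return out


def aggregate_plan(
    profiles: dict[int, PGIProfile],
    plan: SpotPlan,
    sigma_mm: float = AGGREGATION_SIGMA_MM,
) -> dict[int, PGIProfile]:
    """Apply in-layer aggregation to every energy layer of a plan."""
    out: dict[int, PGIProfile] = {}
    for _, idxs in plan.layers.items():
        idxs = [i for i in idxs if i in profiles]
        if not idxs:
            continue
        layer_profiles = {i: profiles[i] for i in idxs}
        positions = {i: (plan.spots[i].y_mm, plan.spots[i].z_mm) for i in idxs}
        out.update(aggregate_layer(layer_profiles, positions, sigma_mm))
    return out


# -- fall-off matching --------------------------------------------------------

def _falloff_position(x: np.ndarray, y: np.ndarray) -> float | None:
    """Distal 50%-of-amplitude crossing of a profile, or None if absent."""
    bg = float(y.min())
    amp = float(y.max()) - bg
    if amp <= 0:
        return None
    level = bg + 0.5 * amp
    below = y < level
    imax = int(np.argmax(y))
    for i in range(len(y) - 1, imax, -1):
        if below[i] and not below[i - 1]:
            # linear interpolation of the downward crossing
            f = (y[i - 1] - level) / (y[i - 1] - y[i])
            return float(x[i - 1] + f * (x[i] - x[i - 1]))
    return None


def _normalize(x: np.ndarray, y: np.ndarray, x_falloff: float, cfg: MatchConfig) -> np.ndarray:
    """Background-subtract and plateau-normalize a profile.

    Background is the median of bins beyond the fall-off plus an offset;
    the plateau level is the median inside a band proximal to the fall-off.
    Matching should respond to fall-off position, not intensity.
    """
    tail = y[x > x_falloff + cfg.background_offset_mm]
    bg = float(np.median(tail)) if tail.size >= 3 else float(y.min())
    yn = np.clip(y - bg, 0.0, None)
    prox, dist = cfg.plateau_band_mm
    band = yn[(x >= x_falloff - prox) & (x <= x_falloff - dist)]
    plateau = float(np.median(band)) if band.size >= 3 else float(yn.max())
    if plateau <= 0:
        plateau = float(yn.max()) or 1.0
    return yn / plateau


def match_profile_shift(
    ref: PGIProfile, meas: PGIProfile, cfg: MatchConfig | None = None
) -> MatchResult:
    """Least-squares fall-off match of a measured profile against the reference.

    Returns the translation of the measured profile that best overlays the
    reference inside the fall-off window (0.8 to 0.2 of the reference
    plateau, frozen on the reference).  Positive = distal = range increase.
    Failure modes: no detectable fall-off, or optimum pinned at the search
    boundary.
    """
    cfg = cfg or MatchConfig()
    if ref.x_mm.shape != meas.x_mm.shape or not np.array_equal(ref.x_mm, meas.x_mm):
        raise ValueError("reference and measurement must share one grid")
    x = ref.x_mm

    xf = _falloff_position(x, ref.counts)
    xf_meas = _falloff_position(x, meas.counts)
    if xf is None or xf_meas is None:
        return MatchResult(float("nan"), flag="no_falloff")
    # each profile is normalized relative to its own fall-off so an
    # amplitude bias cannot masquerade as a range shift
    ref_n = _normalize(x, ref.counts, xf, cfg)
    meas_n = _normalize(x, meas.counts, xf_meas, cfg)

    # freeze the window on the normalized reference fall-off
    hi_x = _crossing(x, ref_n, xf, cfg.window_high)
    lo_x = _crossing(x, ref_n, xf, cfg.window_low)
    if hi_x is None or lo_x is None or lo_x <= hi_x:
        return MatchResult(float("nan"), flag="no_falloff")
    xw = np.arange(hi_x, lo_x + 1e-9, cfg.window_sample_mm)
    ref_w = np.interp(xw, x, ref_n)

    def ssd_on(shifts: np.ndarray) -> np.ndarray:
        # evaluate all shifted measurements in one interpolation call
        pts = (xw[None, :] + shifts[:, None]).ravel()
        meas_w = np.interp(pts, x, meas_n).reshape(len(shifts), len(xw))
        return ((ref_w[None, :] - meas_w) ** 2).sum(axis=1)

    coarse = np.arange(-cfg.search_mm, cfg.search_mm + 1e-9, cfg.coarse_step_mm)
    ssd = ssd_on(coarse)
    best = int(np.argmin(ssd))
    # tie-break toward the smallest |shift|
    near = np.flatnonzero(ssd <= ssd[best] * (1.0 + 1e-12))
    best = int(near[np.argmin(np.abs(coarse[near]))])
    if best in (0, len(coarse) - 1):
        return MatchResult(float(coarse[best]), flag="window_edge", residual=float(ssd[best]))

    # local fine grid, then a final parabolic sub-grid step
    fine = np.arange(
        coarse[best] - cfg.coarse_step_mm,
        coarse[best] + cfg.coarse_step_mm + 1e-9,
        cfg.fine_step_mm,
    )
    ssd_f = ssd_on(fine)
    i_f = int(np.argmin(ssd_f))
    if 0 < i_f < len(fine) - 1:
        s = _parabolic(fine, ssd_f, i_f)
    else:
        s = float(fine[i_f])
    return MatchResult(s, residual=float(ssd_f[i_f]), window_mm=(hi_x, lo_x))


def _crossing(x: np.ndarray, yn: np.ndarray, xf: float, level: float) -> float | None:
    """Distal downward crossing of a normalized profile through ``level`` near ``xf``."""
    region = x >= xf - 40.0
    xs, ys = x[region], yn[region]
    below = ys < level
    imax = int(np.argmax(ys))
    for i in range(len(ys) - 1, imax, -1):
        if below[i] and not below[i - 1]:
            f = (ys[i - 1] - level) / (ys[i - 1] - ys[i])
            return float(xs[i - 1] + f * (xs[i] - xs[i - 1]))
    return None


def _parabolic(shifts: np.ndarray, ssd: np.ndarray, i: int) -> float:
    """Sub-grid refinement through the three points around the coarse minimum."""
    y0, y1, y2 = ssd[i - 1], ssd[i], ssd[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom <= 0:
        return float(shifts[i])
    delta = 0.5 * (y0 - y2) / denom
    step = shifts[1] - shifts[0]
    return float(shifts[i] + np.clip(delta, -1.0, 1.0) * step)
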