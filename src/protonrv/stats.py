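"""Geometric-to-WET shift conversion and weighted accuracy/precision scores.

The prompt-gamma camera measures geometric range shifts in the patient; the
range telescope measures water-equivalent (WET) shifts.  For anatomical
changes the conversion factor SPR_dR = S_WET,slab / S_geom,calc is formed
once per scenario from the known slab WET and the calculated geometric
shift; for setup errors the shift happens inside homogeneous brain and the
brain stopping-power ratio (1.04) is used directly.

Per scenario and system, each spot contributes the median M_i of its ten
repeat shifts and the inverse of its repeat variance as weight
w_i = 1 / sigma_i^2.  The accuracy is A = mu_hat - G with the weighted mean

    mu_hat = sum(w_i M_i) / sum(w_i)

and the precision is the unbiased weighted variance

    sigma_hat^2 = [sum(w) / ((sum w)^2 - sum(w^2))] * sum(w_i (M_i - mu_hat)^2),

which reduces to the ordinary unbiased sample variance when all weights are
equal.  Zero repeat variances (possible in noise-free runs) are floored so
the weights stay defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SPR_BRAIN",
    "VARIANCE_FLOOR_MM2",
    "SPRFactors",
    "SpotSummary",
    "ScenarioStats",
    "spr_delta_r",
    "geom_to_wet",
    "summarize_spot",
    "weighted_stats",
    "boxplot_stats",
]

SPR_BRAIN = 1.04
VARIANCE_FLOOR_MM2 = 1e-4


@dataclass(frozen=True)
class SPRFactors:
    """Conversion factors between geometric and WET range shifts."""

    spr_delta_r: float = float("nan")
    s_wet_slab_mm: float = float("nan")
    s_geom_calc_mm: float = float("nan")
    spr_brain: float = SPR_BRAIN

    @classmethod
    def from_slab(cls, s_wet_slab_mm: float, s_geom_calc_mm: float) -> "SPRFactors":
        return cls(
            spr_delta_r=spr_delta_r(s_wet_slab_mm, s_geom_calc_mm),
            s_wet_slab_mm=s_wet_slab_mm,
            s_geom_calc_mm=s_geom_calc_mm,
        )


def spr_delta_r(s_wet_slab_mm: float, s_geom_calc_mm: float) -> float:
    """Mean SPR of the tissue traversed by the Bragg-peak displacement.

    The quotient of the known slab WET and the calculated geometric shift;
    both must be non-zero and of the same sign.
    """
    if s_geom_calc_mm == 0:
        raise ValueError("calculated geometric shift is zero; SPR_dR undefined")
    if s_wet_slab_mm * s_geom_calc_mm < 0:
        raise ValueError(
            "slab WET and calculated geometric shift have opposite signs: "
            f"{s_wet_slab_mm} vs {s_geom_calc_mm}"
        )
    return s_wet_slab_mm / s_geom_calc_mm


def geom_to_wet(s_geom_mm: float, factors: SPRFactors, mode: str) -> float:
    """Convert a measured geometric shift to WET.

    ``mode="AC"`` multiplies by the scenario's SPR_dR; ``mode="SE"`` uses
    the brain SPR constant (homogeneous target region).
    """
    if mode == "AC":
        if math.isnan(factors.spr_delta_r):
            raise ValueError("AC conversion requires SPR_dR in the factors")
        return s_geom_mm * factors.spr_delta_r
    if mode == "SE":
        return s_geom_mm * factors.spr_brain
    raise ValueError(f"unknown conversion mode {mode!r}")


@dataclass(frozen=True)
class SpotSummary:
    """Median, repeat variance and inverse-variance weight of one spot."""

    spot_id: int
    median_mm: float
    variance_mm2: float
    weight: float
    n_repeats: int


def summarize_spot(
    shifts_mm,
    spot_id: int = -1,
    variance_floor_mm2: float = VARIANCE_FLOOR_MM2,
    min_valid: int = 2,
) -> SpotSummary | None:
    """Summarize the repeated shift measurements of one spot.

    Flagged repeats enter as NaN and are dropped; fewer than ``min_valid``
    valid repeats flags the whole spot out (returns None).  The weight is
    the inverse of the floored unbiased variance.  ``min_valid=1`` supports
    degenerate single-delivery runs, where the variance is zero by
    convention and every weight hits the floor.
    """
    vals = np.asarray(shifts_mm, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size < max(min_valid, 1):
        return None
    var = float(np.var(vals, ddof=1)) if vals.size > 1 else 0.0
    return SpotSummary(
        spot_id=spot_id,
        median_mm=float(np.median(vals)),
        variance_mm2=var,
        weight=1.0 / max(var, variance_floor_mm2),
        n_repeats=int(vals.size),
    )


@dataclass(frozen=True)
class ScenarioStats:
    """Weighted per-scenario summary of one verification system."""

    scenario_id: str
    system: str
    n_spots: int
    mu_hat_mm: float
    sigma_hat2_mm2: float
    ground_truth_mm: float
    accuracy_mm: float

    @property
    def sigma_hat_mm(self) -> float:
        return math.sqrt(max(self.sigma_hat2_mm2, 0.0))


def weighted_stats(
    summaries: list[SpotSummary],
    ground_truth_mm: float,
    scenario_id: str = "",
    system: str = "",
) -> ScenarioStats:
    """Inverse-variance weighted mean, variance and accuracy of a scenario."""
    summaries = [s for s in summaries if s is not None]
    n = len(summaries)
    if n < 2:
        raise ValueError(f"need at least two spots for weighted statistics, got {n}")
    w = np.array([s.weight for s in summaries])
    m = np.array([s.median_mm for s in summaries])
    sw = float(w.sum())
    mu = float((w * m).sum() / sw)
    denom = sw**2 - float((w**2).sum())
    if denom <= 0:
        sigma2 = 0.0
    else:
        sigma2 = float(sw / denom * (w * (m - mu) ** 2).sum())
    return ScenarioStats(
        scenario_id=scenario_id,
        system=system,
        n_spots=n,
        mu_hat_mm=mu,
        sigma_hat2_mm2=sigma2,
        ground_truth_mm=float(ground_truth_mm),
        accuracy_mm=mu - float(ground_truth_mm),
    )


def boxplot_stats(values_mm) -> dict:
    """Median/quartile/whisker summary with 1.5 x IQR outlier rule."""
    vals = np.sort(np.asarray(values_mm, dtype=float))
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite values to summarize")
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(inliers.min()),
        "whisker_high": float(inliers.max()),
        "outliers": [float(v) for v in vals[(vals < lo_fence) | (vals > hi_fence)]],
        "n": int(vals.size),
    }
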