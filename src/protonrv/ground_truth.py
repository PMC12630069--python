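"""Noise-free ground-truth expectations for every scenario and system.

Stands in for the independent dose recalculations: both forward models are
run without noise for the reference and the modified geometry, and the same
matchers used on measurements extract the expected spot-wise shift.  For
range probing the ray-traced WET difference to the phantom exit is reported
alongside as the purely geometric expectation.

All expected shifts are stored in the "detected" sign convention (positive
= WET added in the patient / range shortened in the room), matching how the
measurement pipelines report scenario results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detectors import NoiseModel, simulate_idd, simulate_pgi_profile
from .geometry import PhantomGeometry
from .pgi import MatchConfig, aggregate_plan, match_profile_shift
from .plans import SpotPlan
from .rp import IDDMatchConfig, match_idd_shift
from .scenarios import (
    RULE_CALC,
    RULE_CLOSE_TO_ZERO,
    RULE_SLAB_WET,
    RULE_ZERO,
    Scenario,
)
from .stats import SPR_BRAIN, SPRFactors

__all__ = ["GroundTruthShift", "expected_shifts", "scenario_ground_truth", "spr_factors_for"]


@dataclass(frozen=True)
class GroundTruthShift:
    """Spot-wise noise-free expected shifts for one scenario and system.

    ``shift_mm`` holds the matcher-derived expectation (geometric mm for
    the prompt-gamma system, WET mm for range probing); ``delta_wet_mm``
    additionally holds the ray-traced WET change for range probing.
    Flagged spots carry NaN.
    """

    scenario_id: str
    system: str
    shift_mm: dict[int, float]
    delta_wet_mm: dict[int, float] = field(default_factory=dict)
    flags: dict[int, str | None] = field(default_factory=dict)

    def median_shift_mm(self) -> float:
        vals = np.array([v for v in self.shift_mm.values()], dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("all expected shifts are flagged")
        return float(np.median(vals))


def expected_shifts(
    ref_geom: PhantomGeometry,
    mod_geom: PhantomGeometry,
    plan: SpotPlan,
    system: str,
    scenario_id: str = "",
    spot_ids: list[int] | None = None,
    match_cfg: MatchConfig | IDDMatchConfig | None = None,
) -> GroundTruthShift:
    """Run the noise-free forward models through the measurement matchers.

    ``spot_ids`` restricts the evaluation (e.g. to the filtered treatment
    spots); default is every spot of the plan.  Matcher failures propagate
    as flags, never as silent omissions.
    """
    quiet = NoiseModel.none()
    ids = list(spot_ids) if spot_ids is not None else list(range(len(plan)))
    shifts: dict[int, float] = {}
    wets: dict[int, float] = {}
    flags: dict[int, str | None] = {}

    if system == "rp":
        cfg = match_cfg if isinstance(match_cfg, IDDMatchConfig) else None
        for i in ids:
            spot = plan.spots[i]
            ref = simulate_idd(ref_geom, spot, quiet,
                               range_shifter_wet_mm=plan.range_shifter_wet_mm)
            mod = simulate_idd(mod_geom, spot, quiet,
                               range_shifter_wet_mm=plan.range_shifter_wet_mm)
            res = match_idd_shift(ref, mod, cfg)
            shifts[i] = res.shift_mm
            flags[i] = res.flag
            wets[i] = mod_geom.trace_wet(spot.y_mm, spot.z_mm) - ref_geom.trace_wet(
                spot.y_mm, spot.z_mm
            )
        return GroundTruthShift(scenario_id, "rp", shifts, wets, flags)

    if system == "pgi":
        cfg = match_cfg if isinstance(match_cfg, MatchConfig) else None
        ref_profiles = {
            i: simulate_pgi_profile(ref_geom, plan.spots[i], quiet,
                                    range_shifter_wet_mm=plan.range_shifter_wet_mm)
            for i in range(len(plan))
        }
        mod_profiles = {
            i: simulate_pgi_profile(mod_geom, plan.spots[i], quiet,
                                    range_shifter_wet_mm=plan.range_shifter_wet_mm)
            for i in range(len(plan))
        }
        ref_agg = aggregate_plan(ref_profiles, plan)
        mod_agg = aggregate_plan(mod_profiles, plan)
        for i in ids:
            res = match_profile_shift(ref_agg[i], mod_agg[i], cfg)
            # detected convention: positive = range shortened in the room
            shifts[i] = -res.shift_mm
            flags[i] = res.flag
        return GroundTruthShift(scenario_id, "pgi", shifts, {}, flags)

    raise ValueError(f"unknown system {system!r}")


def spr_factors_for(scenario: Scenario, gts: GroundTruthShift) -> SPRFactors:
    """Scenario-level SPR_dR from the slab WET and the calculated geometric shift.

    Only meaningful for anatomical-change scenarios seen by the treatment
    field (upstream slabs); computed once per scenario from the median
    calculated shift, not per spot.
    """
    if not scenario.is_anatomical_change:
        raise ValueError("SPR_dR is defined for anatomical-change scenarios only")
    return SPRFactors.from_slab(scenario.slab_wet_mm, gts.median_shift_mm())


def scenario_ground_truth(
    scenario: Scenario, system: str, gts: GroundTruthShift | None
) -> float:
    """The scalar ground truth G (mm WET) entering the accuracy A = mu_hat - G.

    Slab scenarios use the known slab WET (or zero where the system cannot
    see the slab); setup errors use the median of the calculated expected
    shifts, converted to WET with the brain SPR for the prompt-gamma
    system.
    """
    rule = scenario.rule(system)
    if rule == RULE_SLAB_WET:
        return scenario.slab_wet_mm
    if rule in (RULE_ZERO, RULE_CLOSE_TO_ZERO):
        return 0.0
    if rule == RULE_CALC:
        if gts is None:
            raise ValueError("ground-truth calculation required for this scenario")
        med = gts.median_shift_mm()
        return med * SPR_BRAIN if system == "pgi" else med
    raise ValueError(f"unknown ground-truth rule {rule!r}")
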