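"""The ten treatment-deviation scenarios and their expected range shifts.

Four scenarios mimic anatomical changes (AC) with water-equivalent slabs
(SPR = 1): 2/3/5 mm upstream inside the beam path, and 5 mm downstream
beyond the target.  Six scenarios mimic setup errors (SE) by rigid couch
movements of 2 or 3 mm: left in BEV (+z), down in BEV (-y), and upstream
(toward the nozzle, -x).  Each is compared against the undisturbed
reference.

Expected-shift rules per verification system:

* upstream slabs: the slab WET, seen by both systems;
* downstream slab: zero for the prompt-gamma system (protons stop before
  it) but the slab WET for range probing (the probe beam traverses it);
* lateral couch shifts: derived from a noise-free ground-truth calculation
  (the lateral WET gradient makes them non-trivial);
* upstream couch shifts: close to zero for range probing (only the air gap
  changes), but the full geometric magnitude for the prompt-gamma camera,
  which is fixed in the room frame.
"""

from __future__ import annotations

from dataclasses import dataclass

from .geometry import PhantomGeometry, Slab

__all__ = ["Scenario", "REFERENCE_ID", "enumerate_scenarios", "get_scenario", "apply_scenario"]

REFERENCE_ID = "reference"

#: expected-shift rule names
RULE_SLAB_WET = "slab_wet"
RULE_ZERO = "zero"
RULE_CLOSE_TO_ZERO = "close_to_zero"
RULE_CALC = "from_ground_truth_calc"


@dataclass(frozen=True)
class Scenario:
    """One row of the deviation-scenario matrix."""

    ident: str                 # "1".."10" or "reference"
    kind: str                  # "AC_upstream" | "AC_downstream" | "SE_couch" | "reference"
    slab_wet_mm: float = 0.0
    couch_direction: str = ""  # "left_BEV" | "down_BEV" | "upstream"
    couch_mm: float = 0.0
    pgi_rule: str = RULE_ZERO
    rp_rule: str = RULE_ZERO

    def rule(self, system: str) -> str:
        if system == "pgi":
            return self.pgi_rule
        if system == "rp":
            return self.rp_rule
        raise ValueError(f"unknown system {system!r}")

    @property
    def is_anatomical_change(self) -> bool:
        return self.kind.startswith("AC")


_SCENARIOS: tuple[Scenario, ...] = (
    Scenario("1", "AC_upstream", slab_wet_mm=2.0, pgi_rule=RULE_SLAB_WET, rp_rule=RULE_SLAB_WET),
    Scenario("2", "AC_upstream", slab_wet_mm=3.0, pgi_rule=RULE_SLAB_WET, rp_rule=RULE_SLAB_WET),
    Scenario("3", "AC_upstream", slab_wet_mm=5.0, pgi_rule=RULE_SLAB_WET, rp_rule=RULE_SLAB_WET),
    Scenario("4", "AC_downstream", slab_wet_mm=5.0, pgi_rule=RULE_ZERO, rp_rule=RULE_SLAB_WET),
    Scenario("5", "SE_couch", couch_direction="left_BEV", couch_mm=2.0,
             pgi_rule=RULE_CALC, rp_rule=RULE_CALC),
    Scenario("6", "SE_couch", couch_direction="left_BEV", couch_mm=3.0,
             pgi_rule=RULE_CALC, rp_rule=RULE_CALC),
    Scenario("7", "SE_couch", couch_direction="down_BEV", couch_mm=2.0,
             pgi_rule=RULE_CALC, rp_rule=RULE_CALC),
    Scenario("8", "SE_couch", couch_direction="down_BEV", couch_mm=3.0,
             pgi_rule=RULE_CALC, rp_rule=RULE_CALC),
    Scenario("9", "SE_couch", couch_direction="upstream", couch_mm=2.0,
             pgi_rule=RULE_CALC, rp_rule=RULE_CLOSE_TO_ZERO),
    Scenario("10", "SE_couch", couch_direction="upstream", couch_mm=3.0,
             pgi_rule=RULE_CALC, rp_rule=RULE_CLOSE_TO_ZERO),
)

_REFERENCE = Scenario(REFERENCE_ID, "reference")


def enumerate_scenarios() -> tuple[Scenario, ...]:
    """All ten non-reference deviation scenarios, in matrix order."""
    return _SCENARIOS


def get_scenario(ident: str) -> Scenario:
    if ident == REFERENCE_ID:
        return _REFERENCE
    for sc in _SCENARIOS:
        if sc.ident == str(ident):
            return sc
    raise KeyError(f"unknown scenario id {ident!r}")


def apply_scenario(geom: PhantomGeometry, scenario: Scenario | str) -> PhantomGeometry:
    """Apply a deviation scenario to the reference geometry.

    Slabs are inserted into the fixed room frame; couch movements translate
    the phantom rigidly (left in BEV = +z, down in BEV = -y, upstream = -x
    toward the nozzle).  Detectors never move.
    """
    sc = get_scenario(scenario) if isinstance(scenario, str) else scenario
    if sc.ident == REFERENCE_ID:
        return geom
    if sc.kind == "AC_upstream":
        return geom.with_slab(Slab(sc.slab_wet_mm, "upstream"))
    if sc.kind == "AC_downstream":
        return geom.with_slab(Slab(sc.slab_wet_mm, "downstream"))
    if sc.kind == "SE_couch":
        d = sc.couch_mm
        if sc.couch_direction == "left_BEV":
            return geom.with_couch_offset(0.0, 0.0, +d)
        if sc.couch_direction == "down_BEV":
            return geom.with_couch_offset(0.0, -d, 0.0)
        if sc.couch_direction == "upstream":
            return geom.with_couch_offset(-d, 0.0, 0.0)
        raise ValueError(f"unknown couch direction {sc.couch_direction!r}")
    raise ValueError(f"unknown scenario kind {sc.kind!r}")
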