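# Methods

## Scope and model overview

`protonrv` implements a virtual range-verification experiment: a synthetic
head phantom, a pencil-beam-scanning (PBS) treatment field monitored by a
prompt-gamma slit camera, a range-probing field monitored by a multi-layer
ionization chamber (MLIC), ten deviation scenarios, and the spot-wise
matching and weighted statistics used to score both systems.  Everything is
analytic or seeded-stochastic; there is no Monte-Carlo particle transport.
Ground truths are computed by running the identical noise-free forward
models and matchers, plus exact ray-traced WET differences for the probing
beam.

One fixed room frame is shared by all modules: the beam travels along +x
(horizontal field, gantry 270°), beam's-eye-view (BEV) y is vertical (up
positive) and z horizontal (left positive), with the isocenter at the
origin.  Detectors are fixed in this frame; couch moves translate only the
phantom.

## Phantom

An analytic layer stack along the beam axis — air, tissue (5 mm, SPR 1.0),
skull (7 mm, SPR 1.6), homogeneous brain (SPR 1.04), skull, tissue, air —
between an entry surface near x = −75 mm and a flat exit at x = +75 mm.
The entry surface is tilted linearly in y and z (0.3 mm of entry shift per
mm lateral, both axes), so the traversed WET varies smoothly across the
field and a 2–3 mm lateral couch shift produces an order-1 mm WET change;
without this gradient the lateral setup-error scenarios would be
degenerate (zero expected shift).  The brain SPR of 1.04 doubles as the
setup-error conversion constant.  Water-equivalent slabs (SPR 1) can be
stacked directly upstream of the entry surface or downstream of the exit
(20 mm air gap), emulating anatomical change inside and beyond the beam
path respectively.

WET is the line integral of SPR along a spot's ray; for the piecewise-
constant stack this is exact, and its inverse (the room-frame position at
which a given WET is exhausted) is solved segment-by-segment.  Air
contributes nothing, which makes the probing signal exactly invariant
under beam-axis couch translation.

## Fields

* Probing field: 9 × 9 spots, 5 mm pitch centered on the isocenter, all
  210 MeV, 6.2×10⁶ protons per spot (the machine-minimum 0.04 MU), no
  range shifter.
* Treatment field: 15 energy layers spanning 115–160 MeV behind a 73.8 mm
  WET range shifter, highest energy first.  The clinical spot lattice is
  replaced by a configurable regular 7×7 lattice per layer (735 spots
  total); per-spot proton counts are drawn log-uniformly between 2×10⁷ and
  4×10⁸ so that the 0.5×10⁸ statistics filter removes a realistic fraction
  of spots.  The published field's exact spot count and MU distribution
  come from a clinical optimizer that is out of scope; only the layer
  structure, energy span and filter behaviour are contractual.

## Detector forward models

**Bragg curves.**  Range–energy follows the power law R = α·E^p with
α = 0.0022 cm/MeV^p and p = 1.77 (R(210 MeV) ≈ 283.6 mm of water).  The
raw depth-dose uses the stopping-power shape (R − d)^(1/p − 1), regularized
at one fine-grid step (0.1 mm) and convolved with a Gaussian range-
straggling kernel σ = 0.012·R[cm]^0.935 cm.  The water curve is cached per
energy and evaluated at (upstream WET + detector depth), so any upstream
WET change is an exact rigid translation of the curve.  The MLIC samples
180 channels at 2 mm water-equivalent pitch; channels are treated as
water-equivalent depths (the vendor's geometric-to-WET calibration is not
public).  Protons that stop inside the phantom raise a range-out error —
the regime where range probing is physically infeasible.

**Prompt-gamma profiles.**  Gamma emission density along the ray is the
local SPR times a sigmoid termination (steepness 1.5 mm) centred 2 mm
proximal to the geometric range — the gamma fall-off leads the dose
fall-off by a fixed, configurable offset δ.  Since the analysis only ever
uses *differences* of fall-off positions between scenarios, results are
δ-invariant.  The sigmoid is truncated to exactly zero beyond 12 steepness
units so material the protons never reach (e.g. a downstream slab) leaves
no numerical footprint — downstream invisibility holds bit-exactly.  The
density is convolved with a single Gaussian camera PSF (σ = 3 mm, standing
in for slit optics and the 4 mm crystal pitch) and integrated over fixed
1 mm bins inside a ±50 mm field of view about the isocenter.

**Noise.**  PGI counts are Poisson with expectation protons × yield ×
bin + background; defaults (yield 10⁻⁶ per proton per mm, background
5×10⁻⁸ per proton per bin) give a 10⁸-proton spot ≈10⁴ counts near the
fall-off.  RP channels get 1% multiplicative Gaussian noise plus a 10⁻³-
of-peak additive floor.  The published experiment does not parameterize
either detector's noise, so these are free, documented parameters: the
package's precision numbers characterize *this* noise model, not the real
detectors, and real-hardware precision figures are deliberately not
reproduction targets.  A disabled noise
model returns expectation values bit-identically across runs.

## Shift extraction

**PGI.**  The reference is the bin-wise sum of the ten reference
deliveries.  Spots are kept if they deliver ≥ 0.5×10⁸ protons and their
expected fall-off lies ≥ 5 mm inside the FOV.  Profiles of one energy
layer are aggregated with a normalized 2-D Gaussian kernel (σ = 7.8 mm)
over BEV spot distances — never across layers, identically for reference
and measurement.  The matcher freezes a window on the reference between
0.8 and 0.2 of its plateau level, after subtracting a background (median
of bins ≥ 20 mm beyond the fall-off) and normalizing to the plateau
(median 10–30 mm proximal of the fall-off).  Each profile is normalized
relative to its *own* detected fall-off; normalizing the measurement
against the reference fall-off biases large shifts by ~0.03 mm because the
fall-off leaks into the plateau band.  The squared difference between
reference and translated measurement is minimized on a coarse 0.1 mm grid
over ±15 mm, then on a local 0.01 mm grid with a final parabolic step;
ties break toward the smallest |shift|.  Failures (no detectable
fall-off, optimum at the search boundary) are flagged, never silently
dropped.  Matcher sign: positive = distal = range increase.

**RP.**  IDD curves are area-normalized and aligned over a window from the
proximal 25%-of-peak crossing to the distal 10% level, with the same
coarse/fine/parabolic search.  Deliveries are strictly index-paired
(measurement *k* of a scenario vs measurement *k* of the reference),
yielding ten 9×9 range-shift maps per scenario.  The *reported* shift
flips the matcher sign so that added WET in the patient is positive,
matching how range-shift maps are conventionally displayed; the same
"detected" convention is applied to PGI shifts at the scenario level, and
the conversion factor S_WET,slab / S_geom,calc is therefore positive.

## Statistics

Per spot, the median M_i and unbiased variance σ_i² over the (≤10) valid
repeats give weight w_i = 1/σ_i²; zero variances (exact in noise-free
runs) are floored at 10⁻⁴ mm² so weights stay defined — the floor only
matters when all variances vanish, where it reduces to equal weighting.
A spot needs ≥ 2 valid repeats by default; single-delivery runs are
supported explicitly (variance defined as zero).  The scenario score is
the inverse-variance weighted mean μ̂, the unbiased weighted variance σ̂²
(which reduces to the ordinary unbiased sample variance for equal
weights), and the accuracy A = μ̂ − G.  The conversion factor SPR_ΔR is
computed once per slab scenario from the median calculated shift, not per
spot.  G is the slab WET for slab scenarios (zero for the system that
cannot see the slab), and the median of the noise-free calculated shifts
for couch scenarios (times 1.04 for PGI).

## Orchestration and reproducibility

A master seed fans out through counter-based child seeds keyed by
(scenario, system, repeat), so restricting the scenario subset or repeat
count never changes the remaining draws, and identical configs re-run
bit-identically.  The treatment plan's proton-count draws are tied to the
master seed.  Tables are written as versioned CSV with %.17g floats and
read back with round-trip float parsing, so persistence is bit-exact.

## Problem sizes and runtime

Defaults — 735 treatment spots, 81 probing spots, reference + 10
scenarios × 10 deliveries, both systems — run in under a minute on one
core.  Unit and property tests use a reduced 3-layer, 3×3-spot treatment
field; the acceptance recomputations use the full default fields
noise-free with a single delivery, which is exact for deterministic
scenarios.

## Known limitations

* No lateral beam spot size, scatter, nuclear halo, or heterogeneity
  effects; the Bragg model only aims at a realistic distal edge.
* The PGI camera is reduced to one Gaussian PSF; collimator penumbra,
  energy response and dead time are not modelled.
* The phantom's lateral gradient is linear, so lateral-shift ground
  truths are nearly uniform across the field — real anatomy produces the
  heterogeneous maps seen in measured data.
* Detector noise magnitudes are free parameters; precision results are
  statements about the synthetic noise model only.
* Passing tests demonstrate correctness of the pipelines and statistics
  under these models, not detector-hardware fidelity.
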