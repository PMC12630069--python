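"""Forward models of the two verification detectors.

Range probing is modelled with an analytic Bragg curve: the range-energy
relation is the power law R = alpha * E^p (alpha = 0.0022 cm/MeV^p,
p = 1.77), the raw depth-dose follows the stopping-power shape
(R - d)^(1/p - 1) and is convolved with a Gaussian range-straggling kernel
of width sigma = 0.012 * R[cm]^0.935.  The multi-layer ionization chamber
(MLIC) samples the integral depth-dose (IDD) on 180 channels at 2 mm
water-equivalent pitch behind a 120 mm entrance window, so the curve is
evaluated at water depth = (WET traversed upstream) + (channel depth).

The prompt-gamma camera is modelled as a 1-D profile along the beam axis,
fixed in the room frame: gamma emission is proportional to the local
stopping-power ratio wherever the beam is still in matter, terminated by a
sigmoid fall-off slightly proximal to the dose fall-off, convolved with a
Gaussian camera point-spread function, and binned onto a fixed grid inside
the field of view.  Counts are Poisson-distributed around
protons x yield + background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .geometry import PhantomGeometry
from .plans import ENERGY_MAX_MEV, ENERGY_MIN_MEV, Spot

__all__ = [
    "NoiseModel",
    "IDDCurve",
    "PGIProfile",
    "RangeOutError",
    "proton_range_mm",
    "straggling_sigma_mm",
    "bragg_curve",
    "simulate_idd",
    "simulate_pgi_profile",
]

# power-law range-energy relation, R in cm for E in MeV
RANGE_ALPHA_CM = 0.0022
RANGE_EXPONENT = 1.77

MLIC_CHANNELS = 180
MLIC_PITCH_MM = 2.0
MLIC_WINDOW_DIAMETER_MM = 120.0

PGI_BIN_MM = 1.0
PGI_FOV_MM = (-50.0, 50.0)
#: camera resolution (one Gaussian PSF standing in for slit + 4 mm crystals)
PGI_PSF_SIGMA_MM = 3.0
#: the gamma fall-off precedes the dose fall-off by this offset
PGI_FALLOFF_OFFSET_MM = 2.0
PGI_FALLOFF_STEEPNESS_MM = 1.5


class RangeOutError(RuntimeError):
    """Protons stop before reaching the range telescope (no residual range)."""


@dataclass(frozen=True)
class NoiseModel:
    """Detector-noise parameters for both systems.

    PGI: expected counts per bin = protons * pgi_yield_per_proton_mm * bin
    width (along the plateau) + protons * pgi_background_per_proton;
    sampled from a Poisson distribution when enabled.  RP: per-channel
    multiplicative Gaussian of relative width rp_sigma plus an additive
    Gaussian floor expressed as a fraction of the peak.  A disabled model
    returns deterministic expectation values, bit-identical across runs.
    """

    pgi_yield_per_proton_mm: float = 1e-6
    pgi_background_per_proton: float = 5e-8
    rp_sigma: float = 0.01
    rp_additive_floor: float = 1e-3
    enabled: bool = True

    def __post_init__(self) -> None:
        for name in ("pgi_yield_per_proton_mm", "pgi_background_per_proton",
                     "rp_sigma", "rp_additive_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(enabled=False)

    def without_noise(self) -> "NoiseModel":
        return replace(self, enabled=False)


@dataclass(frozen=True)
class IDDCurve:
    """Integral depth-dose on the MLIC channel grid (arbitrary units >= 0)."""

    depth_mm: np.ndarray   # (180,) channel centers, water-equivalent mm
    dose: np.ndarray       # (180,)
    spot_id: int = -1
    seed: int | None = None
    noisy: bool = False


@dataclass(frozen=True)
class PGIProfile:
    """1-D prompt-gamma count profile on the fixed room-frame grid."""

    x_mm: np.ndarray       # bin centers along the beam axis
    counts: np.ndarray     # expected (float) or Poisson-sampled counts
    fov_mm: tuple[float, float] = PGI_FOV_MM
    spot_id: int = -1
    protons: float = 0.0
    seed: int | None = None
    noisy: bool = False


def proton_range_mm(energy_mev: float) -> float:
    """CSDA range in water (mm) from the power-law range-energy relation."""
    if not ENERGY_MIN_MEV <= energy_mev <= ENERGY_MAX_MEV:
        raise ValueError(
            f"energy {energy_mev} MeV outside machine limits "
            f"[{ENERGY_MIN_MEV}, {ENERGY_MAX_MEV}]"
        )
    return 10.0 * RANGE_ALPHA_CM * energy_mev**RANGE_EXPONENT

def straggling_sigma_mm(range_mm: float) -> float:
    """Gaussian range-straggling width (mm) for a given range in water."""
    return 10.0 * 0.012 * (range_mm / 10.0) ** 0.935


_FINE_DW_MM = 0.1


@lru_cache(maxsize=64)
def _water_depth_dose(energy_mev: float) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free depth-dose in water vs cumulative WET, peak-normalized.

    Cached per energy; the singular stopping-power shape (R - d)^(1/p - 1)
    is regularized at one fine-grid step and smoothed by the straggling
    kernel, which keeps the convolved curve finite and single-peaked.
    """
    r = proton_range_mm(energy_mev)
    sigma = straggling_sigma_mm(r)
    w = np.arange(0.0, r + 8.0 * sigma, _FINE_DW_MM)
    residual = np.clip(r - w, _FINE_DW_MM, None)
    raw = np.where(w < r, residual ** (1.0 / RANGE_EXPONENT - 1.0), 0.0)
    dose = gaussian_filter1d(raw, sigma / _FINE_DW_MM, mode="nearest")
    return w, dose / dose.max()


def bragg_curve(
    energy_mev: float, upstream_wet_mm: float, depth_grid_mm: np.ndarray
) -> np.ndarray:
    """Evaluate the Bragg curve on a residual-depth grid behind ``upstream_wet_mm``.

    The returned dose at depth d is the water depth-dose at cumulative WET
    ``upstream_wet_mm + d``, so the peak sits at R - upstream_wet on the
    residual axis and changing the upstream WET translates the curve
    rigidly.
    """
    w, dose = _water_depth_dose(float(energy_mev))
    return np.interp(np.asarray(depth_grid_mm, dtype=float) + upstream_wet_mm,
                     w, dose, left=0.0, right=0.0)


def mlic_depth_grid() -> np.ndarray:
    """Water-equivalent channel-center depths of the MLIC (180 x 2 mm)."""
    return (np.arange(MLIC_CHANNELS) + 0.5) * MLIC_PITCH_MM


def simulate_idd(
    geom: PhantomGeometry,
    spot: Spot,
    noise: NoiseModel,
    rng: np.random.Generator | int | None = None,
    range_shifter_wet_mm: float = 0.0,
) -> IDDCurve:
    """Simulate the MLIC integral depth-dose for one probing spot.

    The upstream WET is the full ray trace through slabs and phantom to the
    detector entrance (plus any range shifter).  Raises
    :class:`RangeOutError` when the residual range is non-positive, i.e.
    the protons stop inside the phantom and range probing is infeasible.
    """
    radius = math.hypot(spot.y_mm, spot.z_mm)
    if radius > MLIC_WINDOW_DIAMETER_MM / 2.0:
        raise ValueError(
            f"spot at BEV radius {radius:.1f} mm misses the "
            f"{MLIC_WINDOW_DIAMETER_MM:.0f} mm MLIC entrance window"
        )
    upstream = range_shifter_wet_mm + geom.trace_wet(spot.y_mm, spot.z_mm)
    residual = proton_range_mm(spot.energy_mev) - upstream
    if residual <= 0:
        raise RangeOutError(
            f"residual range {residual:.1f} mm <= 0: protons stop inside the "
            "phantom and cannot reach the MLIC"
        )
    depths = mlic_depth_grid()
    dose = bragg_curve(spot.energy_mev, upstream, depths)
    if noise.enabled:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        peak = dose.max()
        dose = dose * (1.0 + noise.rp_sigma * gen.standard_normal(dose.shape))
        dose = dose + noise.rp_additive_floor * peak * gen.standard_normal(dose.shape)
        dose = np.clip(dose, 0.0, None)
    return IDDCurve(depth_mm=depths, dose=dose, noisy=noise.enabled)


def pgi_grid(fov_mm: tuple[float, float] = PGI_FOV_MM) -> np.ndarray:
    """Bin centers of the camera profile grid (1 mm pitch, room frame)."""
    lo, hi = fov_mm
    return np.arange(lo + PGI_BIN_MM / 2.0, hi, PGI_BIN_MM)


def simulate_pgi_profile(
    geom: PhantomGeometry,
    spot: Spot,
    noise: NoiseModel,
    rng: np.random.Generator | int | None = None,
    range_shifter_wet_mm: float = 0.0,
    fov_mm: tuple[float, float] = PGI_FOV_MM,
) -> PGIProfile:
    """Simulate the 1-D prompt-gamma profile of one treatment spot.

    Emission density along the room-frame beam axis is SPR(x) times a
    sigmoid termination at the gamma fall-off (2 mm proximal to the
    geometric range), truncated to exactly zero far beyond the fall-off so
    material the protons never reach (e.g. downstream slabs) cannot leave a
    numerical footprint.  The density is convolved with the camera PSF and
    integrated over fixed 1 mm bins.
    """
    if spot.protons <= 0:
        raise ValueError("spot must deliver protons")
    lo, hi = fov_mm
    fine = 0.25
    x = np.arange(lo - 6.0 * PGI_PSF_SIGMA_MM, hi + 6.0 * PGI_PSF_SIGMA_MM, fine)

    wet_goal = proton_range_mm(spot.energy_mev) - range_shifter_wet_mm
    x_range = geom.range_position(spot.y_mm, spot.z_mm, wet_goal)
    x_falloff = x_range - PGI_FALLOFF_OFFSET_MM

    spr = np.zeros_like(x)
    for x0, x1, s in geom.segments(spot.y_mm, spot.z_mm):
        spr[(x >= x0) & (x < x1)] = s
    k = PGI_FALLOFF_STEEPNESS_MM
    arg = (x - x_falloff) / k
    term = np.where(arg < 12.0, 1.0 / (1.0 + np.exp(np.clip(arg, -50.0, 12.0))), 0.0)
    emission = spr * term
    emission = gaussian_filter1d(emission, PGI_PSF_SIGMA_MM / fine, mode="nearest")

    centers = pgi_grid(fov_mm)
    # integrate the fine emission density over each 1 mm bin
    expected = np.interp(centers, x, emission) * PGI_BIN_MM
    expected = spot.protons * noise.pgi_yield_per_proton_mm * expected
    expected = expected + spot.protons * noise.pgi_background_per_proton

    if noise.enabled:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        counts = gen.poisson(expected).astype(float)
    else:
        counts = expected
    return PGIProfile(
        x_mm=centers, counts=counts, fov_mm=fov_mm,
        protons=spot.protons, noisy=noise.enabled,
    )


def expected_falloff_x(
    geom: PhantomGeometry, spot: Spot, range_shifter_wet_mm: float = 0.0
) -> float:
    """Room-frame position of the prompt-gamma fall-off for a spot (noise-free)."""
    wet_goal = proton_range_mm(spot.energy_mev) - range_shifter_wet_mm
    return geom.range_position(spot.y_mm, spot.z_mm, wet_goal) - PGI_FALLOFF_OFFSET_MM
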