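"""Range-probing evaluation: pairwise IDD alignment and range-shift maps.

Each delivery of the probing field yields one IDD curve per spot; shifts
are computed strictly pairwise — the k-th delivery of a modified scenario
against the k-th delivery of the reference — producing ten 9 x 9 range
shift maps per scenario.  The alignment is a least-squares translation of
the modified curve onto the reference over a window anchored on the distal
edge, with sub-channel refinement by interpolation.

Sign convention: material added upstream of the detector (in the patient or
anywhere in the beam path) REDUCES the residual range at the MLIC, i.e.
translates the Bragg peak proximally.  The reported shift flips that sign
so a slab of WET w appears as +w mm — "WET added in the patient" — which is
how range-shift maps are displayed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detectors import IDDCurve, MLIC_PITCH_MM

__all__ = ["IDDMatchConfig", "IDDMatchResult", "RangeShiftMap", "match_idd_shift", "build_rsm"]


@dataclass(frozen=True)
class IDDMatchConfig:
    """IDD alignment settings.

    The window runs from the proximal 25%-of-peak crossing to the distal
    10% dose level, covering the Bragg peak and its fall-off.  Curves are
    area-normalized first; shifts are searched coarsely at 0.1 mm, then on
    a local 0.01 mm grid with a final parabolic refinement.
    """

    proximal_level: float = 0.25
    distal_level: float = 0.10
    search_mm: float = 15.0
    coarse_step_mm: float = 0.1
    fine_step_mm: float = 0.01
    window_sample_mm: float = 0.25
    edge_channels: int = 2


@dataclass(frozen=True)
class IDDMatchResult:
    """Reported WET shift (positive = WET added upstream of the detector)."""

    shift_mm: float
    flag: str | None = None
    residual: float = float("nan")
    window_mm: tuple[float, float] = (float("nan"), float("nan"))

    @property
    def ok(self) -> bool:
        return self.flag is None


@dataclass(frozen=True)
class RangeShiftMap:
    """One 2-D map of WET shifts on the probing lattice (BEV y rows, z columns)."""

    y_mm: np.ndarray        # (9,) lattice rows
    z_mm: np.ndarray        # (9,) lattice columns
    shift_mm: np.ndarray    # (9, 9) reported WET shifts
    repeat: int
    scenario_id: str
    flags: np.ndarray | None = None  # (9, 9) object array of failure flags or None


def _area_normalize(dose: np.ndarray) -> np.ndarray:
    area = float(dose.sum()) * MLIC_PITCH_MM
    if area <= 0:
        raise ValueError("IDD curve carries no dose")
    return dose / area


def _crossing(x: np.ndarray, y: np.ndarray, level: float, side: str, ipeak: int) -> float | None:
    if side == "proximal":
        for i in range(ipeak, 0, -1):
            if y[i - 1] < level <= y[i]:
                f = (level - y[i - 1]) / (y[i] - y[i - 1])
                return float(x[i - 1] + f * (x[i] - x[i - 1]))
        return float(x[0])
    for i in range(ipeak, len(y) - 1):
        if y[i] >= level > y[i + 1]:
            f = (y[i] - level) / (y[i] - y[i + 1])
            return float(x[i] + f * (x[i + 1] - x[i]))
    return None


def match_idd_shift(
    ref: IDDCurve, meas: IDDCurve, cfg: IDDMatchConfig | None = None
) -> IDDMatchResult:
    """Least-squares alignment of a measured IDD curve onto the reference.

    Returns the reported WET shift (positive = WET added in the patient);
    flags ``"clipped"`` when the Bragg peak sits at the detector boundary.
    """
    cfg = cfg or IDDMatchConfig()
    if ref.depth_mm.shape != meas.depth_mm.shape or not np.array_equal(
        ref.depth_mm, meas.depth_mm
    ):
        raise ValueError("reference and measurement must share the channel grid")
    d = ref.depth_mm
    ref_n = _area_normalize(ref.dose)
    meas_n = _area_normalize(meas.dose)

    for curve in (ref_n, meas_n):
        ipk = int(np.argmax(curve))
        if ipk < cfg.edge_channels or ipk >= len(curve) - cfg.edge_channels:
            return IDDMatchResult(float("nan"), flag="clipped")

    ipeak = int(np.argmax(ref_n))
    peak = float(ref_n[ipeak])
    lo = _crossing(d, ref_n, cfg.proximal_level * peak, "proximal", ipeak)
    hi = _crossing(d, ref_n, cfg.distal_level * peak, "distal", ipeak)
    if hi is None:
        return IDDMatchResult(float("nan"), flag="clipped")
    dw = np.arange(lo, hi + 1e-9, cfg.window_sample_mm)
    ref_w = np.interp(dw, d, ref_n)

    def ssd_on(shifts: np.ndarray) -> np.ndarray:
        pts = (dw[None, :] + shifts[:, None]).ravel()
        vals = np.interp(pts, d, meas_n).reshape(len(shifts), len(dw))
        return ((ref_w[None, :] - vals) ** 2).sum(axis=1)

    coarse = np.arange(-cfg.search_mm, cfg.search_mm + 1e-9, cfg.coarse_step_mm)
    ssd_c = ssd_on(coarse)
    ic = int(np.argmin(ssd_c))
    near = np.flatnonzero(ssd_c <= ssd_c[ic] * (1.0 + 1e-12))
    ic = int(near[np.argmin(np.abs(coarse[near]))])
    if ic in (0, len(coarse) - 1):
        return IDDMatchResult(-float(coarse[ic]), flag="window_edge", residual=float(ssd_c[ic]))

    fine = np.arange(
        coarse[ic] - cfg.coarse_step_mm, coarse[ic] + cfg.coarse_step_mm + 1e-9,
        cfg.fine_step_mm,
    )
    ssd_f = ssd_on(fine)
    i_f = int(np.argmin(ssd_f))
    if 0 < i_f < len(fine) - 1:
        y0, y1, y2 = ssd_f[i_f - 1], ssd_f[i_f], ssd_f[i_f + 1]
        denom = y0 - 2.0 * y1 + y2
        s = fine[i_f] + (0.5 * (y0 - y2) / denom) * cfg.fine_step_mm if denom > 0 else fine[i_f]
    else:
        s = fine[i_f]
    # flip sign: proximal peak movement (negative translation) = WET added
    return IDDMatchResult(-float(s), residual=float(ssd_f[i_f]), window_mm=(lo, hi))


def build_rsm(
    ref_runs: list[dict[int, IDDCurve]],
    mod_runs: list[dict[int, IDDCurve]],
    y_mm: np.ndarray,
    z_mm: np.ndarray,
    scenario_id: str = "",
    cfg: IDDMatchConfig | None = None,
) -> list[RangeShiftMap]:
    """Ten pairwise range-shift maps: delivery k of the scenario vs delivery k
    of the reference, never pooled across repeats.

    ``ref_runs``/``mod_runs`` map spot index (row-major over the lattice) to
    the measured IDD of that delivery.
    """
    if len(ref_runs) != len(mod_runs):
        raise ValueError(
            f"got {len(ref_runs)} reference vs {len(mod_runs)} modified deliveries"
        )
    ny, nz = len(y_mm), len(z_mm)
    maps = []
    for k, (ref_set, mod_set) in enumerate(zip(ref_runs, mod_runs)):
        if sorted(ref_set) != sorted(mod_set):
            raise ValueError(f"delivery {k}: spot lattices differ")
        shifts = np.full((ny, nz), np.nan)
        flags = np.full((ny, nz), None, dtype=object)
        for sid in ref_set:
            iy, iz = divmod(sid, nz)
            res = match_idd_shift(ref_set[sid], mod_set[sid], cfg)
            shifts[iy, iz] = res.shift_mm
            flags[iy, iz] = res.flag
        maps.append(
            RangeShiftMap(
                y_mm=np.asarray(y_mm, dtype=float),
                z_mm=np.asarray(z_mm, dtype=float),
                shift_mm=shifts, repeat=k, scenario_id=scenario_id, flags=flags,
            )
        )
    return maps
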