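"""Comparison report: boxplot summaries, accuracy/precision table, BEV maps.

Assembles per-scenario comparisons of the two systems on the level of
spot-median WET shifts: boxplot statistics (median, quartiles, 1.5 x IQR
whiskers, outliers), the weighted accuracy/precision table, and rendered
figures (slab-scenario and couch-scenario boxplots, range-shift color maps
in beam's eye view).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .experiment import ExperimentResult
from .scenarios import get_scenario
from .stats import boxplot_stats

__all__ = ["compare_report", "write_report", "render_figures"]


def compare_report(result: ExperimentResult) -> dict:
    """Bundle boxplot data and weighted statistics for every scenario.

    Scenarios requested but absent from the analysis are listed under
    ``"missing"`` rather than silently skipped.
    """
    bundle: dict = {"scenarios": {}, "missing": [], "table": result.summary_frame().to_dict("records")}
    have = {(s.scenario_id, s.system) for s in result.scenario_stats}
    for sid in result.config.scenario_ids:
        entry: dict = {"kind": get_scenario(sid).kind}
        for system in ("pgi", "rp"):
            if (sid, system) not in have:
                bundle["missing"].append({"scenario": sid, "system": system})
                continue
            medians = [s.median_mm for s in result.spot_summaries[(sid, system)]]
            entry[system] = {
                "boxplot": boxplot_stats(medians),
                "ground_truth_mm": next(
                    s.ground_truth_mm for s in result.scenario_stats
                    if (s.scenario_id, s.system) == (sid, system)
                ),
            }
        bundle["scenarios"][sid] = entry
    return bundle


def write_report(result: ExperimentResult, outdir: str | Path) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = compare_report(result)
    (out / "report.json").write_text(json.dumps(bundle, indent=2))
    return out / "report.json"


def render_figures(result: ExperimentResult, outdir: str | Path) -> list[Path]:
    """Render boxplot and BEV-map figures as PNG; returns the written paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    groups = {
        "anatomical_changes": [s for s in result.config.scenario_ids
                               if get_scenario(s).kind.startswith("AC")],
        "setup_errors": [s for s in result.config.scenario_ids
                         if get_scenario(s).kind == "SE_couch"],
    }
    for name, sids in groups.items():
        if not sids:
            continue
        fig, ax = plt.subplots(figsize=(1.4 * len(sids) + 2, 4))
        for k, sid in enumerate(sids):
            for off, system, color in ((-0.17, "pgi", "tab:blue"), (0.17, "rp", "tab:orange")):
                if (sid, system) not in result.spot_summaries:
                    continue
                vals = [s.median_mm for s in result.spot_summaries[(sid, system)]]
                ax.boxplot(
                    [vals], positions=[k + off], widths=0.3, patch_artist=True,
                    boxprops={"facecolor": color, "alpha": 0.6},
                    medianprops={"color": "black"},
                )
        ax.set_xticks(range(len(sids)))
        ax.set_xticklabels([f"({s})" for s in sids])
        ax.set_ylabel("detected range shift [mm WET]")
        ax.set_title(f"{name.replace('_', ' ')} — PGI (blue) vs RP (orange)")
        ax.axhline(0.0, color="gray", lw=0.5)
        fig.tight_layout()
        p = out / f"boxplots_{name}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    for sid, maps in result.rsms.items():
        med = np.nanmedian(np.stack([m.shift_mm for m in maps]), axis=0)
        fig, ax = plt.subplots(figsize=(4.5, 4))
        m0 = maps[0]
        im = ax.pcolormesh(m0.z_mm, m0.y_mm, med, shading="nearest", cmap="RdBu_r")
        fig.colorbar(im, ax=ax, label="RP shift [mm WET]")
        ax.set_xlabel("z (BEV left) [mm]")
        ax.set_ylabel("y (BEV up) [mm]")
        ax.set_title(f"scenario ({sid}): median range-shift map")
        fig.tight_layout()
        p = out / f"rsm_scenario_{sid}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
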