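"""Figure and table assembly: violin plots, bar +/- SEM plots, summaries.

Plots are written as SVG with a fixed hash salt and no embedded date so a
regenerated report is byte-identical for identical inputs.  The run log
records the config hash, seed and library versions for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from .io import RunConfig
from .stats import GroupStats, t_test_unpaired

__all__ = ["violin_plot", "bar_sem_plot", "summary_table", "make_report"]

_SVG_KW = dict(format="svg", metadata={"Date": None})


def _deterministic_style() -> None:
    plt.rcParams["svg.hashsalt"] = "radmig"


def violin_plot(table: pd.DataFrame, value_col: str, group_col: str,
                path: str | Path, ylabel: str | None = None) -> None:
    """Violin plot of a per-ROI value by condition (reporter readout)."""
    _deterministic_style()
    fig, ax = plt.subplots(figsize=(4, 4))
    sns.violinplot(data=table, x=group_col, y=value_col, ax=ax, cut=0,
                   inner="quartile")
    ax.set_ylabel(ylabel or value_col)
    fig.tight_layout()
    fig.savefig(path, **_SVG_KW)
    plt.close(fig)


def bar_sem_plot(groups: dict[str, np.ndarray], path: str | Path,
                 ylabel: str = "") -> None:
    """Bar plot of group means with SEM error bars."""
    _deterministic_style()
    names = list(groups)
    means = [float(np.mean(groups[k])) for k in names]
    sems = [float(np.std(groups[k], ddof=1) / np.sqrt(len(groups[k])))
            if len(groups[k]) > 1 else 0.0 for k in names]
    fig, ax = plt.subplots(figsize=(3.5, 4))
    ax.bar(names, means, yerr=sems, capsize=4, color="#888888",
           edgecolor="black")
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, **_SVG_KW)
    plt.close(fig)


def summary_table(comparisons: dict[str, GroupStats]) -> pd.DataFrame:
    """One row per requested comparison."""
    rows = []
    for name, gs in comparisons.items():
        rows.append({
            "comparison": name,
            "group_a": gs.names[0], "group_b": gs.names[1],
            "n_a": gs.n[0], "n_b": gs.n[1],
            "mean_a": gs.means[0], "mean_b": gs.means[1],
            "sem_a": gs.sems[0], "sem_b": gs.sems[1],
            "t": gs.t_statistic, "df": gs.degrees_of_freedom,
            "p": gs.p_value, "star": gs.star, "variant": gs.variant,
        })
    return pd.DataFrame(rows)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def make_report(outdir: str | Path, config: RunConfig,
                reporter_table: pd.DataFrame | None = None,
                velocity_groups: dict[str, np.ndarray] | None = None,
                composition: pd.DataFrame | None = None,
                bin_tables: dict[str, pd.DataFrame] | None = None,
                comparisons: dict[str, tuple[np.ndarray, np.ndarray]]
                | None = None) -> pd.DataFrame:
    """Assemble plots, a GroupStats summary CSV and a run log.

    ``comparisons`` maps a name to a pair of sample arrays; each is
    tested with the configured t-test variant and one summary row is
    emitted per comparison.  At least one input table is required.
    """
    inputs = [reporter_table, velocity_groups, composition, bin_tables,
              comparisons]
    if all(x is None for x in inputs):
        raise ValueError("make_report needs at least one upstream table")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if reporter_table is not None:
        sp = reporter_table[reporter_table["in_sp_selection"]]
        violin_plot(sp, "B_star", "condition", outdir / "reporter_violin.svg",
                    ylabel="corrected low-band power (a.u.)")
        reporter_table.to_csv(outdir / "reporter_values.csv", index=False)
    if velocity_groups is not None:
        bar_sem_plot(velocity_groups, outdir / "velocity_bar.svg",
                     ylabel="radial velocity (um/h)")
    if composition is not None:
        composition.to_csv(outdir / "mp_bp_composition.csv", index=False)
        _deterministic_style()
        fig, ax = plt.subplots(figsize=(3.5, 4))
        x = np.arange(len(composition))
        ax.bar(x - 0.2, composition["frac_mp"], width=0.4, label="MP")
        ax.bar(x + 0.2, composition["frac_bp"], width=0.4, label="BP")
        ax.set_xticks(x, composition["timepoint"])
        ax.set_ylabel("fraction of classified cells")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / "mp_bp_bar.svg", **_SVG_KW)
        plt.close(fig)
    if bin_tables is not None:
        frames = [t.assign(condition=name) for name, t in bin_tables.items()]
        pd.concat(frames).to_csv(outdir / "bin_distribution.csv", index=False)

    stats_rows = {}
    if comparisons is not None:
        for name, (a, b) in comparisons.items():
            stats_rows[name] = t_test_unpaired(
                np.asarray(a, float), np.asarray(b, float),
                variant=config.t_test_variant)
    summary = summary_table(stats_rows)
    summary.to_csv(outdir / "group_stats.csv", index=False)

    log = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_comparisons": len(stats_rows),
        "versions": {m.__name__: m.__version__
                     for m in (np, pd, matplotlib, sns)},
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2,
                                                    sort_keys=True) + "\n")
    return summary
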