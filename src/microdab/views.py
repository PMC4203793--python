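"""Diagnostic views of a two-group comparison.

Two plain-table views back the figures: per-taxon -log10 p-values along
the taxon axis (Manhattan data, with 0.05 / 0.01 reference lines) and
the paired change in median relative abundance versus change in
proportion of animals positive (quadrant data).  The tables are the
testable surface; the rendered figures are cosmetic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import TaxonCountTable, prevalence, relative_abundance
from .twopart import TwoPartResult

__all__ = [
    "manhattan_points",
    "delta_effects",
    "plot_manhattan",
    "plot_delta_effects",
    "REFERENCE_LINES",
]

REFERENCE_LINES = {"p05": -np.log10(0.05), "p01": -np.log10(0.01)}


def manhattan_points(results: Sequence[TwoPartResult]) -> pd.DataFrame:
    """(taxon, -log10 p_raw) pairs in input order, with significance flags."""
    if not results:
        raise ValueError("no results to plot")
    for r in results:
        if r.p_raw <= 0:
            raise ValueError(f"non-positive p-value for {r.taxon!r}")
    return pd.DataFrame(
        {
            "taxon": [r.taxon for r in results],
            "p_raw": [r.p_raw for r in results],
            "neglog10_p": [-np.log10(r.p_raw) for r in results],
            "significant_05": [r.significant_05 for r in results],
            "significant_01": [r.significant_01 for r in results],
        }
    )


def delta_effects(
    table: TaxonCountTable,
    group_a: str,
    group_b: str,
    results: Sequence[TwoPartResult],
    label_min_mean: float = 0.01,
) -> pd.DataFrame:
    """Change in median relative abundance and proportion positive, A - B.

    One row per tested taxon: the two deltas, quadrant assignment by the
    sign of each delta, significance flags carried over from the test,
    and a label flag for taxa whose mean relative abundance across both
    groups' samples exceeds ``label_min_mean`` (default 1%).
    """
    rel = relative_abundance(table)
    samples_a = table.group_samples(group_a)
    samples_b = table.group_samples(group_b)
    prev_a = prevalence(table, group_a)
    prev_b = prevalence(table, group_b)
    rows = []
    for r in results:
        if r.taxon not in table.counts.columns:
            raise ValueError(f"taxon {r.taxon!r} not in table")
        med_a = float(rel.loc[samples_a, r.taxon].median())
        med_b = float(rel.loc[samples_b, r.taxon].median())
        d_med = med_a - med_b
        d_prop = float(prev_a[r.taxon] - prev_b[r.taxon])
        mean_overall = float(rel.loc[samples_a + samples_b, r.taxon].mean())
        if d_med > 0 and d_prop >= 0 or d_med >= 0 and d_prop > 0:
            quadrant = f"higher in {group_a}"
        elif d_med < 0 and d_prop <= 0 or d_med <= 0 and d_prop < 0:
            quadrant = f"higher in {group_b}"
        elif d_med == 0 and d_prop == 0:
            quadrant = "no change"
        else:
            quadrant = "mixed"
        rows.append(
            {
                "taxon": r.taxon,
                "delta_median_relabund": d_med,
                "delta_prop_positive": d_prop,
                "quadrant": quadrant,
                "significant_05": r.significant_05,
                "significant_01": r.significant_01,
                "mean_relabund_overall": mean_overall,
                "labelled": mean_overall > label_min_mean,
            }
        )
    return pd.DataFrame.from_records(rows)


def plot_manhattan(points: pd.DataFrame, path: str | Path, title: str = "") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3.5))
    x = np.arange(len(points))
    colors = np.where(points["significant_05"], "crimson", "steelblue")
    ax.vlines(x, 0, points["neglog10_p"], color=colors, lw=2)
    for name, y in REFERENCE_LINES.items():
        ax.axhline(y, color="black", lw=0.8, ls="-")
        ax.annotate(name, (len(points) - 0.5, y), fontsize=7, va="bottom")
    ax.set_xlabel("taxon")
    ax.set_ylabel(r"$-\log_{10}\,p$")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_delta_effects(
    effects: pd.DataFrame, path: str | Path, group_a: str, group_b: str
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    colors = np.where(effects["significant_05"], "black", "grey")
    ax.scatter(
        effects["delta_median_relabund"],
        effects["delta_prop_positive"],
        c=colors,
        s=18,
    )
    for _, row in effects[effects["labelled"]].iterrows():
        ax.annotate(
            row["taxon"].split("/")[-1],
            (row["delta_median_relabund"], row["delta_prop_positive"]),
            fontsize=7,
        )
    ax.axhline(0, color="black", lw=0.6)
    ax.axvline(0, color="black", lw=0.6)
    ax.set_xlabel(f"median relative abundance, {group_a} - {group_b}")
    ax.set_ylabel(f"proportion positive, {group_a} - {group_b}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
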