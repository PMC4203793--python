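"""Two-part presence/abundance testing, Kruskal-Wallis screen, FDR.

Zero-inflated taxon abundances carry signal in two places: whether a
taxon is present in an animal at all, and how abundant it is when
present.  The two-part statistic tests both at once:

* Part 1 (presence): a two-proportion z on the fractions of samples
  with non-zero abundance, ``Zp = (p1 - p2) / sqrt(pbar (1 - pbar)
  (1/n1 + 1/n2))`` with the pooled proportion ``pbar``; Zp is 0 when
  pbar is 0 or 1 (no information in presence).
* Part 2 (abundance): a Wilcoxon rank-sum z on the *non-zero* values
  only, normal approximation with tie correction and no continuity
  correction.
* Combination: when both parts are defined the statistic is
  ``Zp^2 + Zw^2 ~ chi-square(2)``; when every sample is positive in both
  groups presence is uninformative and the rank-sum z on all values is
  referred to chi-square(1); when one group has no positive samples only
  the presence part is used (chi-square(1)).

The across-group screen is the tie-corrected Kruskal-Wallis test;
multiple testing is controlled with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import TaxonCountTable, prevalence_filter, relative_abundance

__all__ = [
    "TwoPartResult",
    "KWResult",
    "two_part_test",
    "run_comparison",
    "kruskal_wallis",
    "kruskal_wallis_screen",
    "bh_fdr",
    "results_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class TwoPartResult:
    """Per-taxon output of the two-part test (one group pair)."""

    taxon: str
    n_a: int
    n_b: int
    prop_a: float
    prop_b: float
    median_a: float
    median_b: float
    zp_sq: float
    zw_sq: float
    statistic: float
    df: int
    p_raw: float
    parts_used: str  # "both", "presence_only", "wilcoxon_only"
    p_adj: float = np.nan

    @property
    def significant_05(self) -> bool:
        return self.p_raw < 0.05

    @property
    def significant_01(self) -> bool:
        return self.p_raw < 0.01


@dataclass
class KWResult:
    """Tie-corrected Kruskal-Wallis result for one taxon across groups."""

    taxon: str
    h: float
    df: int
    p_raw: float
    p_adj: float = np.nan


def _rank_sum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized Wilcoxon rank-sum z (tie-corrected, no continuity).

    W is the rank sum of ``x`` within the pooled sample; under the null
    E[W] = n1 (N+1) / 2 and Var[W] = n1 n2 / 12 * ((N+1) -
    sum(t^3 - t) / (N (N-1))) over tie groups of size t.  A fully tied
    pooled sample has zero variance and carries no signal: z = 0.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    n = n1 + n2
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    return (w - n1 * (n + 1) / 2.0) / np.sqrt(var)


def _exact_rank_sum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-sum z equivalent to the exact two-sided Mann-Whitney p.

    Enumerates the exact null distribution (scipy) and maps the
    two-sided p back to a normal deviate, signed by the direction of
    the rank-sum shift.  Requires tie-free data.
    """
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    p = min(float(res.pvalue), 1.0)
    z = stats.norm.isf(p / 2.0)
    mid = len(x) * len(y) / 2.0
    return float(np.copysign(z, res.statistic - mid)) if z > 0 else 0.0


def two_part_test(
    x: Sequence[float],
    y: Sequence[float],
    taxon: str = "",
    exact_wilcoxon: bool = False,
) -> TwoPartResult:
    """Two-part presence/abundance test of one taxon between two groups.

    ``x`` and ``y`` are the per-sample relative abundances (zeros mark
    absence).  Raises if the taxon is zero in every sample of both
    groups — such taxa should have been removed by the prevalence
    filter.

    ``exact_wilcoxon`` replaces the normal approximation of the
    abundance part by the exact rank-sum enumeration (intended for
    <= 10 non-zero values per group, tie-free data); the exact p is
    mapped back to a z so the chi-square combination is unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("two_part_test needs >= 2 samples per group")
    pos_x = x[x > 0]
    pos_y = y[y > 0]
    k1, k2 = len(pos_x), len(pos_y)
    if k1 == 0 and k2 == 0:
        raise ValueError(
            f"taxon {taxon!r} is absent from every sample in both groups"
        )
    p1, p2 = k1 / n1, k2 / n2
    pbar = (k1 + k2) / (n1 + n2)

    if pbar in (0.0, 1.0):
        zp = 0.0
    else:
        zp = (p1 - p2) / np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))

    rank_z = _exact_rank_sum_z if exact_wilcoxon else _rank_sum_z
    if k1 == n1 and k2 == n2:
        # Every sample positive: presence carries no information, use the
        # rank-sum alone on all values at one degree of freedom.
        zw = rank_z(x, y)
        statistic, df, parts = zw**2, 1, "wilcoxon_only"
        zp_sq, zw_sq = 0.0, zw**2
    elif k1 == 0 or k2 == 0:
        statistic, df, parts = zp**2, 1, "presence_only"
        zp_sq, zw_sq = zp**2, np.nan
    else:
        zw = rank_z(pos_x, pos_y)
        zp_sq, zw_sq = zp**2, zw**2
        statistic, df, parts = zp_sq + zw_sq, 2, "both"

    p_raw = float(stats.chi2.sf(statistic, df))
    return TwoPartResult(
        taxon=taxon,
        n_a=n1,
        n_b=n2,
        prop_a=p1,
        prop_b=p2,
        median_a=float(np.median(x)),
        median_b=float(np.median(y)),
        zp_sq=float(zp_sq),
        zw_sq=float(zw_sq),
        statistic=float(statistic),
        df=df,
        p_raw=p_raw,
        parts_used=parts,
    )


def run_comparison(
    table: TaxonCountTable,
    group_a: str,
    group_b: str,
    min_prop: float = 0.5,
) -> list[TwoPartResult]:
    """Prevalence-filter, test every retained taxon, adjust, sort by p.

    FDR adjustment (Benjamini-Hochberg) is applied across the retained
    set only, matching the per-comparison analyses the method reports.
    """
    samples_a = table.group_samples(group_a)
    samples_b = table.group_samples(group_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    retained = prevalence_filter(table, group_a, group_b, min_prop=min_prop)
    if not retained:
        logger.warning(
            "no taxa pass the %.0f%% prevalence filter for %s vs %s",
            100 * min_prop, group_a, group_b,
        )
        return []
    rel = relative_abundance(table)
    results = [
        two_part_test(rel.loc[samples_a, t], rel.loc[samples_b, t], taxon=t)
        for t in retained
    ]
    adjusted = bh_fdr([r.p_raw for r in results])
    for r, p_adj in zip(results, adjusted):
        r.p_adj = float(p_adj)
    results.sort(key=lambda r: (r.p_raw, r.taxon))
    return results


def kruskal_wallis(
    values_by_group: Mapping[str, Sequence[float]], taxon: str = ""
) -> KWResult:
    """Tie-corrected Kruskal-Wallis H across >= 2 groups.

    A totally tied input (every observation identical) is defined as
    H = 0, p = 1.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs >= 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    df = len(groups) - 1
    pooled = np.concatenate(list(groups.values()))
    if np.all(pooled == pooled[0]):
        return KWResult(taxon=taxon, h=0.0, df=df, p_raw=1.0)
    h, p = stats.kruskal(*groups.values())
    return KWResult(taxon=taxon, h=float(h), df=df, p_raw=float(p))


def kruskal_wallis_screen(table: TaxonCountTable) -> list[KWResult]:
    """Per-taxon KW test across all groups, BH-adjusted over all taxa.

    Run independently of the prevalence filter: every taxon with at
    least one positive count anywhere is screened.
    """
    rel = relative_abundance(table)
    by_group = {g: table.group_samples(g) for g in table.group_names}
    results = []
    for taxon in table.taxa:
        if (table.counts[taxon] == 0).all():
            continue
        values = {g: rel.loc[s, taxon].to_numpy() for g, s in by_group.items()}
        results.append(kruskal_wallis(values, taxon=taxon))
    adjusted = bh_fdr([r.p_raw for r in results])
    for r, p_adj in zip(results, adjusted):
        r.p_adj = float(p_adj)
    results.sort(key=lambda r: (r.p_raw, r.taxon))
    return results


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-aligned."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def results_to_frame(results: Sequence[TwoPartResult]) -> pd.DataFrame:
    """Two-part results as the TSV-ready results table."""
    rows = [
        {
            "taxon": r.taxon,
            "n_a": r.n_a,
            "n_b": r.n_b,
            "prop_a": r.prop_a,
            "prop_b": r.prop_b,
            "median_a": r.median_a,
            "median_b": r.median_b,
            "zp_sq": r.zp_sq,
            "zw_sq": r.zw_sq,
            "statistic": r.statistic,
            "df": r.df,
            "p_raw": r.p_raw,
            "p_adj": r.p_adj,
            "parts_used": r.parts_used,
            "significant_05": r.significant_05,
            "significant_01": r.significant_01,
        }
        for r in results
    ]
    return pd.DataFrame.from_records(rows)
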