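"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive expected values by routes
independent of the package: brute-force BH from its definition, a
vectorized permutation distribution of the two-part p-value, and a
closed-form 2x2 eigensolve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microdab import TaxonCountTable, two_part_test


@pytest.fixture
def toy_table() -> TaxonCountTable:
    """4 + 4 samples, 5 taxa, hand-chosen counts."""
    counts = pd.DataFrame(
        {
            "taxA": [10, 12, 8, 9, 1, 0, 2, 1],
            "taxB": [0, 3, 0, 1, 5, 6, 7, 4],
            "taxC": [5, 5, 5, 5, 5, 5, 5, 5],
            "taxD": [0, 0, 0, 0, 0, 0, 1, 0],
            "taxE": [2, 0, 1, 0, 0, 3, 0, 2],
        },
        index=[f"s{i}" for i in range(8)],
    )
    groups = pd.Series(
        ["A"] * 4 + ["B"] * 4, index=counts.index
    )
    return TaxonCountTable(counts, groups)


def brute_force_bh(p: list[float]) -> np.ndarray:
    """BH step-up from the definition: sort, p*m/rank, cummin from top."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def permutation_two_part_p(
    x: np.ndarray, y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> tuple[float, float]:
    """(chi-square p, Monte-Carlo permutation p) under group relabeling.

    Re-derives the two-part statistic for every relabeling with
    vectorized numpy, independent of the implementation's code path, and
    estimates P(p_perm <= p_obs).
    """
    obs = two_part_test(x, y).p_raw
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(x) + len(y)
    n2 = n - n1
    nz = pooled > 0
    n_nz = int(nz.sum())
    ranks = np.zeros(n)
    if n_nz:
        ranks[nz] = stats.rankdata(pooled[nz])
    if n_nz > 1:
        _, tc = np.unique(pooled[nz], return_counts=True)
        tie_term = (tc**3 - tc).sum() / (n_nz * (n_nz - 1))
    else:
        tie_term = 0.0
    pbar = n_nz / n

    idx = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1]
    mask_a = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(mask_a, idx, True, axis=1)
    k1 = (mask_a & nz).sum(axis=1)
    k2 = n_nz - k1
    if pbar in (0.0, 1.0):
        zp_sq = np.zeros(n_perm)
    else:
        zp = (k1 / n1 - k2 / n2) / np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
        zp_sq = zp**2
    w = (mask_a * ranks).sum(axis=1)
    var = k1 * k2 / 12.0 * ((n_nz + 1) - tie_term)
    with np.errstate(divide="ignore", invalid="ignore"):
        zw = np.where(var > 0, (w - k1 * (n_nz + 1) / 2.0) / np.sqrt(var), 0.0)
    zw_sq = zw**2
    presence_only = (k1 == 0) | (k2 == 0)
    both_full = (k1 == n1) & (k2 == n2)
    statistic = np.where(presence_only, zp_sq, zp_sq + zw_sq)
    statistic = np.where(both_full, zw_sq, statistic)
    df = np.where(presence_only | both_full, 1, 2)
    p_perm = stats.chi2.sf(statistic, df)
    return obs, float((p_perm <= obs + 1e-12).mean())


def eig2x2(cov: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form eigendecomposition of a symmetric 2x2 matrix."""
    a, b, d = cov[0, 0], cov[0, 1], cov[1, 1]
    tr, det = a + d, a * d - b * b
    disc = np.sqrt(tr * tr / 4.0 - det)
    lam = np.array([tr / 2.0 + disc, tr / 2.0 - disc])
    vecs = []
    for l in lam:
        v = np.array([b, l - a]) if abs(b) > 1e-15 else (
            np.array([1.0, 0.0]) if abs(l - a) < abs(l - d) else np.array([0.0, 1.0])
        )
        vecs.append(v / np.linalg.norm(v))
    return lam, np.column_stack(vecs)
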