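"""Centered log-ratio transformation and principal component analysis.

Count compositions live on the simplex; the CLR transform
``clr(x)_t = ln(x_t) - mean_t ln(x_t)`` maps them to unconstrained
coordinates where Euclidean methods (PCA) are meaningful.  Zeros are
handled with a pseudocount of 1/(sample total): each sample's counts are
augmented by its own delta before the logarithm, so deeper samples get a
proportionally smaller offset.  Because CLR is invariant to per-sample
scaling, the augmented counts need no re-closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import TaxonCountTable

__all__ = ["CLRMatrix", "PCAResult", "clr_transform", "pca_fit"]


@dataclass
class CLRMatrix:
    """Samples x taxa CLR values; every row sums to zero."""

    values: pd.DataFrame
    pseudocount_used: pd.Series = field(repr=False)


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x k
    loadings: pd.DataFrame  # taxa x k, unit-norm columns
    explained_variance_ratio: np.ndarray  # length k, non-increasing


def clr_transform(
    table: TaxonCountTable, pseudocount: float | None = None
) -> CLRMatrix:
    """CLR-transform a count table with the 1/total pseudocount.

    By default each sample s gets its own delta = 1/N_s added to its raw
    counts (N_s the sample's read total).  Pass ``pseudocount`` to use a
    single global delta instead.
    """
    totals = table.counts.sum(axis=1)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero)}")
    if pseudocount is None:
        delta = 1.0 / totals
    else:
        delta = pd.Series(float(pseudocount), index=totals.index)
    augmented = table.counts.add(delta, axis=0)
    logs = np.log(augmented)
    clr = logs.sub(logs.mean(axis=1), axis=0)
    return CLRMatrix(values=clr, pseudocount_used=delta)


def pca_fit(clr: CLRMatrix, k: int) -> PCAResult:
    """PCA of the column-centered CLR matrix by SVD.

    Scores are the sample projections, loadings the right singular
    vectors (orthonormal columns), variance ratios the normalized
    squared singular values.  Sign convention: each loading column is
    oriented so that its largest-magnitude entry is positive.
    """
    x = clr.values.to_numpy(dtype=float)
    n_samples, n_taxa = x.shape
    if n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    if not (1 <= k <= min(n_samples - 1, n_taxa)):
        raise ValueError(
            f"k={k} out of range 1..{min(n_samples - 1, n_taxa)}"
        )
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # orient each component so its largest-|loading| entry is positive
    for j in range(len(s)):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    total_var = float((s**2).sum())
    if total_var > 0:
        ratio = (s**2) / total_var
    else:
        ratio = np.zeros_like(s)
    cols = [f"PC{j + 1}" for j in range(k)]
    scores = pd.DataFrame(
        (u[:, :k] * s[:k]), index=clr.values.index, columns=cols
    )
    loadings = pd.DataFrame(vt[:k].T, index=clr.values.columns, columns=cols)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=ratio[:k],
    )
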