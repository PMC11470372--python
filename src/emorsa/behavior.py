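"""Post-scan emotion-categorization analysis.

Builds the group confusion matrix (rows = presented category, columns =
response), converts it to a dissimilarity matrix by subtracting each
off-diagonal count from the largest off-diagonal count, and correlates the
z-scored strict upper triangles of two matrices (for 7 emotions: 21 pairs,
df = 19).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .rdm import as_rdm, upper_triangle

__all__ = [
    "build_confusion",
    "confusion_to_dissimilarity",
    "correlate_upper_triangles",
]


def build_confusion(responses: pd.DataFrame, labels) -> pd.DataFrame:
    """Count matrix from (true label, response label) records.

    ``responses`` needs columns ``true`` and ``response``; every label must
    be one of ``labels`` (the 7 emotion categories).
    """
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, r in zip(responses["true"], responses["response"]):
        if t not in index or r not in index:
            raise ValueError(f"unknown label in responses: {t!r} / {r!r}")
        counts[index[t], index[r]] += 1
    return pd.DataFrame(counts, index=labels, columns=labels)


def confusion_to_dissimilarity(cm: pd.DataFrame, *, symmetrize: bool = False) -> pd.DataFrame:
    """Map confusion counts to dissimilarities: ``d(i,j) = max_offdiag - c(i,j)``.

    Off-diagonal counts are subtracted from the highest off-diagonal count;
    the diagonal is set to 0 and ignored downstream.  The matrix is left
    asymmetric (the upper triangle is what downstream correlation uses)
    unless ``symmetrize`` averages ``(d + d.T) / 2``.

    The transform is invariant to adding a constant to all off-diagonal
    counts.  Note the direction: a pair confused MORE often gets a SMALLER
    dissimilarity here (see docs for discussion).
    """
    c = cm.to_numpy(dtype=float).copy()
    n = c.shape[0]
    off = ~np.eye(n, dtype=bool)
    d = np.zeros_like(c)
    if n > 1:
        d[off] = c[off].max() - c[off]
    if symmetrize:
        d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=cm.index, columns=cm.columns)


def correlate_upper_triangles(a: pd.DataFrame, b: pd.DataFrame):
    """Pearson correlation of the z-scored strict upper triangles.

    Returns ``(r, df, p)`` with ``df = n_pairs - 2`` (19 for 7 labels) and a
    two-sided p value from the t transform of r.  z-scoring is affine, so r
    equals the raw-triangle Pearson correlation; it is applied to mirror the
    published procedure.
    """
    if list(a.index) != list(b.index):
        raise ValueError("matrices must share labels")
    ua, ub = upper_triangle(a), upper_triangle(b)
    if len(ua) < 3:
        raise ValueError("need at least 3 upper-triangle entries")
    if ua.std() == 0 or ub.std() == 0:
        raise ValueError("zero-variance upper triangle: correlation undefined")
    za = (ua - ua.mean()) / ua.std(ddof=1)
    zb = (ub - ub.mean()) / ub.std(ddof=1)
    r, p = stats.pearsonr(za, zb)
    return float(r), len(ua) - 2, float(p)
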