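"""Representational dissimilarity matrices (RDMs) and triangle utilities.

An RDM is carried as a square :class:`pandas.DataFrame` whose index and
columns hold the same condition labels.  For correlation-distance RDMs
(``d = 1 - r``) entries lie in ``[0, 2]``: 0 means identical patterns (up to
an increasing affine map), 1 means uncorrelated, 2 means perfectly
anti-correlated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "as_rdm",
    "check_rdm",
    "pearson_distance",
    "upper_triangle",
    "lower_triangle",
    "rdm_to_csv",
    "rdm_from_csv",
]


def as_rdm(values, labels=None) -> pd.DataFrame:
    """Wrap a square array of dissimilarities as a labeled DataFrame."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"RDM must be square, got shape {values.shape}")
    n = values.shape[0]
    if labels is None:
        labels = [f"cond{i}" for i in range(n)]
    labels = list(labels)
    if len(labels) != n or len(set(labels)) != n:
        raise ValueError("labels must be unique and match matrix size")
    return pd.DataFrame(values, index=labels, columns=labels)


def check_rdm(rdm: pd.DataFrame, *, symmetric: bool = True, atol: float = 1e-8) -> pd.DataFrame:
    """Validate an RDM: square, matching labels, zero diagonal, optional symmetry."""
    if not isinstance(rdm, pd.DataFrame):
        rdm = as_rdm(rdm)
    v = rdm.to_numpy(dtype=float)
    if v.shape[0] != v.shape[1]:
        raise ValueError("RDM must be square")
    if list(rdm.index) != list(rdm.columns):
        raise ValueError("RDM row and column labels differ")
    if not np.all(np.isfinite(v)):
        raise ValueError("RDM contains non-finite entries")
    if np.max(np.abs(np.diag(v))) > atol:
        raise ValueError("RDM diagonal must be zero")
    if symmetric and np.max(np.abs(v - v.T)) > atol:
        raise ValueError("RDM is not symmetric")
    return rdm


def pearson_distance(patterns: np.ndarray, labels=None) -> pd.DataFrame:
    """Pearson correlation distance ``1 - r`` between the rows of ``patterns``.

    Parameters
    ----------
    patterns : ndarray, shape (n_conditions, n_features)
        One pattern vector per condition (ratings over words, betas over
        voxels, feature vectors ...).
    labels : sequence of str, optional
        Condition labels.

    Raises
    ------
    ValueError
        If any row is constant (Pearson correlation undefined); the error
        names the offending condition rather than silently substituting
        ``r = 0``.
    """
    patterns = np.asarray(patterns, dtype=float)
    if patterns.ndim != 2:
        raise ValueError("patterns must be 2-D (conditions x features)")
    n = patterns.shape[0]
    if labels is None:
        labels = [f"cond{i}" for i in range(n)]
    sd = patterns.std(axis=1)
    if np.any(sd == 0):
        bad = [str(labels[i]) for i in np.flatnonzero(sd == 0)]
        raise ValueError(
            "constant pattern vector(s) for condition(s) "
            + ", ".join(bad)
            + ": Pearson correlation is undefined"
        )
    r = np.corrcoef(patterns)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    # exact symmetry despite floating-point corrcoef
    d = (d + d.T) / 2.0
    return as_rdm(d, labels)


def upper_triangle(rdm: pd.DataFrame) -> np.ndarray:
    """Strict upper-triangle entries, row-major over (i < j)."""
    v = np.asarray(rdm, dtype=float)
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def lower_triangle(rdm: pd.DataFrame) -> np.ndarray:
    """Strict lower-triangle entries in the package's frozen (i > j) order.

    For a symmetric RDM this carries the same 21 values (for 7 conditions)
    as :func:`upper_triangle`; the order is fixed once so that downstream
    regressions are bit-reproducible.
    """
    v = np.asarray(rdm, dtype=float)
    il = np.tril_indices(v.shape[0], k=-1)
    return v[il]


def rdm_to_csv(rdm: pd.DataFrame, path) -> None:
    check_rdm(rdm, symmetric=False).to_csv(path)


def rdm_from_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.columns = list(df.columns)
    return df
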