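"""Conceptual-knowledge geometry.

Per-subject conceptual RDMs from emotion-word relatedness ratings (Pearson
correlation distance between the 40-word rating vectors of each pair of
emotion categories), group averaging, Kruskal nonmetric MDS with a
classical-scaling start, and Ward hierarchical clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .rdm import as_rdm, check_rdm, pearson_distance

__all__ = [
    "rdm_from_ratings",
    "average_rdm",
    "NonmetricMDS",
    "nonmetric_mds",
    "ward_clustering",
    "MdsSolution",
]


def rdm_from_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Conceptual dissimilarity ``d(i, j) = 1 - Pearson(row_i, row_j)``.

    ``ratings`` is an emotions-by-words table (7 x 40 in the standard
    design); each row is one emotion's relatedness ratings over the word
    stimuli.  A dissimilarity of 0 indicates perfect conceptual similarity,
    larger values greater conceptual dissimilarity.

    Raises ``ValueError`` naming the emotion if a rating row is constant.
    """
    if isinstance(ratings, pd.DataFrame):
        values = ratings.to_numpy(dtype=float)
        labels = list(ratings.index)
    else:
        values = np.asarray(ratings, dtype=float)
        labels = None
    return pearson_distance(values, labels)


def average_rdm(rdms) -> pd.DataFrame:
    """Elementwise mean of a non-empty list of RDMs with matching labels."""
    rdms = list(rdms)
    if not rdms:
        raise ValueError("need at least one RDM")
    first = check_rdm(rdms[0])
    labels = list(first.index)
    acc = np.zeros_like(first.to_numpy(dtype=float))
    for r in rdms:
        r = check_rdm(r)
        if list(r.index) != labels:
            raise ValueError("RDM labels do not match across subjects")
        acc += r.to_numpy(dtype=float)
    return as_rdm(acc / len(rdms), labels)


# ---------------------------------------------------------------------------
# nonmetric MDS
# ---------------------------------------------------------------------------

@dataclass
class MdsSolution:
    coordinates: np.ndarray
    stress: float
    n_iterations: int
    labels: list


def _classical_scaling(d: np.ndarray, ndim: int) -> np.ndarray:
    """Torgerson classical scaling: eigendecomposition of -J d^2 J / 2."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:ndim]
    w_top = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(w_top)


def _stress1(d: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 with monotone disparities from isotonic regression."""
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    diss = d[iu]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))[iu]
    order = np.argsort(diss, kind="stable")
    disp = np.empty_like(dist)
    disp[order] = IsotonicRegression().fit_transform(diss[order], dist[order])
    denom = float((dist ** 2).sum())
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist - disp) ** 2).sum() / denom))


class NonmetricMDS(BaseEstimator):
    """Kruskal nonmetric multidimensional scaling of an RDM.

    Minimizes stress by iterative majorization (SMACOF) with isotonic
    regression on the dissimilarity ranks, starting from the classical
    (Torgerson) metric-MDS solution rather than a random configuration, so
    the embedding is deterministic.  Ties in the isotonic step are kept
    together (tied dissimilarities share one disparity).

    Parameters
    ----------
    n_components : int, default 2
        Embedding dimensionality; must be < number of items.
    max_iter : int, default 300
    eps : float, default 1e-9
        Stopping criterion of the SMACOF loop (sklearn's normalized-stress
        improvement scale; 1e-9 here realizes stress-1 improvements well
        below 1e-6 on exactly- or monotonically-embeddable inputs).

    Attributes
    ----------
    embedding_ : ndarray (n_items, n_components)
    stress_ : float
        Final Kruskal stress-1.
    n_iter_ : int
    """

    def __init__(self, n_components: int = 2, max_iter: int = 300, eps: float = 1e-9):
        self.n_components = n_components
        self.max_iter = max_iter
        self.eps = eps

    def fit(self, rdm) -> "NonmetricMDS":
        rdm = check_rdm(as_rdm(rdm) if not isinstance(rdm, pd.DataFrame) else rdm)
        d = rdm.to_numpy(dtype=float)
        n = d.shape[0]
        if self.n_components >= n:
            raise ValueError("n_components must be smaller than the number of items")
        init = _classical_scaling(d, self.n_components)
        coords, _, n_iter = smacof(
            d,
            metric=False,
            n_components=self.n_components,
            init=init,
            n_init=1,
            max_iter=self.max_iter,
            eps=self.eps,
            normalized_stress=True,
            return_n_iter=True,
        )
        self.labels_ = list(rdm.index)
        self.embedding_ = coords
        self.stress_ = _stress1(d, coords)
        self.n_iter_ = int(n_iter)
        return self

    def fit_transform(self, rdm) -> np.ndarray:
        return self.fit(rdm).embedding_


def nonmetric_mds(rdm, dims: int = 2, **kwargs) -> MdsSolution:
    """Functional wrapper over :class:`NonmetricMDS`."""
    est = NonmetricMDS(n_components=dims, **kwargs).fit(rdm)
    return MdsSolution(
        coordinates=est.embedding_,
        stress=est.stress_,
        n_iterations=est.n_iter_,
        labels=est.labels_,
    )


# ---------------------------------------------------------------------------
# Ward clustering
# ---------------------------------------------------------------------------

def ward_clustering(rdm) -> dict:
    """Agglomerative clustering of an RDM under Ward's criterion.

    Uses the dissimilarity-input convention ("Ward2" of Murtagh & Legendre):
    the Lance-Williams update runs on squared dissimilarities and merge
    heights are returned on the square-rooted scale, so heights are monotone
    non-decreasing.

    Returns a dict with the scipy linkage matrix (``merges``: one row per
    merge -- cluster a, cluster b, height, size), the item ``labels``, and
    the ``convention`` recorded for provenance.
    """
    rdm = check_rdm(as_rdm(rdm) if not isinstance(rdm, pd.DataFrame) else rdm)
    d = rdm.to_numpy(dtype=float)
    z = linkage(squareform(d, checks=False), method="ward")
    return {"merges": z, "labels": list(rdm.index), "convention": "ward2-sqrt-heights"}
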