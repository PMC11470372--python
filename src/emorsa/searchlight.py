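"""Searchlight representational similarity analysis.

A sphere (default radius 4 mm in world coordinates) is centered on every
in-mask voxel; within each sphere the per-emotion mean beta patterns give a
7 x 7 Pearson-distance neural RDM whose lower triangle is regressed (OLS,
standardized, with intercept) on one or more model RDMs (conceptual
dissimilarity, optionally low-level feature controls).  The standardized
coefficients are Fisher-transformed (atanh) and written back to the sphere
center, producing one coefficient map per model per subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .rdm import check_rdm, lower_triangle, pearson_distance
from .volumes import BetaVolumeSet

__all__ = [
    "Searchlight",
    "build_searchlights",
    "neural_rdm",
    "rsa_regress",
    "SearchlightRsa",
    "run_searchlight",
]

FISHER_CLIP = 1.0 - 1e-7


@dataclass
class Searchlight:
    center: tuple
    members: np.ndarray  # (n_members, 3) voxel indices, center included
    radius_mm: float


def sphere_offsets(affine: np.ndarray, radius_mm: float) -> np.ndarray:
    """Integer voxel offsets within ``radius_mm`` of the origin in world space.

    Distance uses the linear part of the affine only (translation cancels
    between voxels), so anisotropic voxel sizes are honored.
    """
    a = np.asarray(affine, dtype=float)[:3, :3]
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    smin = np.linalg.svd(a, compute_uv=False).min()
    if smin <= 0:
        raise ValueError("affine is singular")
    reach = int(np.ceil(radius_mm / smin))
    rng = np.arange(-reach, reach + 1)
    grid = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    dist = np.linalg.norm(grid @ a.T, axis=1)
    return grid[dist <= radius_mm + 1e-9]


def build_searchlights(
    mask: np.ndarray,
    affine: np.ndarray,
    radius_mm: float = 4.0,
    min_voxels: int = 3,
):
    """One searchlight per in-mask voxel; membership by world distance.

    Centers whose sphere retains fewer than ``min_voxels`` in-mask members
    are dropped and returned separately.

    Returns ``(searchlights, dropped_centers)``.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    offsets = sphere_offsets(affine, radius_mm)
    shape = np.array(mask.shape)
    centers = np.argwhere(mask)
    lights, dropped = [], []
    for c in centers:
        pts = c + offsets
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        pts = pts[mask[pts[:, 0], pts[:, 1], pts[:, 2]]]
        if len(pts) < min_voxels:
            dropped.append(tuple(int(v) for v in c))
            continue
        lights.append(
            Searchlight(center=tuple(int(v) for v in c), members=pts, radius_mm=radius_mm)
        )
    return lights, dropped


def _emotion_means(betas: BetaVolumeSet, labels) -> tuple:
    """Average trial volumes within each emotion -> (emotions, (7, grid) array)."""
    labels = np.asarray(labels)
    emotions = list(pd.unique(pd.Series(labels)))
    means = np.stack([betas.data[labels == e].mean(axis=0) for e in emotions])
    return emotions, means


def neural_rdm(betas: BetaVolumeSet, labels, sl: Searchlight) -> pd.DataFrame:
    """Pearson-distance RDM of per-emotion mean patterns within one sphere.

    Trial betas are averaged within each emotion, the resulting pattern
    vectors over the sphere's voxels are correlated between each pair of
    emotions, and the correlation matrix is subtracted from 1.

    Raises ``ValueError`` if the sphere is too small or a pattern is
    constant (such centers are excluded by :func:`run_searchlight`).
    """
    if len(sl.members) < 3:
        raise ValueError("sphere has fewer than 3 voxels")
    emotions, means = _emotion_means(betas, labels)
    m = sl.members
    patterns = means[:, m[:, 0], m[:, 1], m[:, 2]]
    return pearson_distance(patterns, emotions)


def rsa_regress(
    neural: pd.DataFrame,
    models,
    *,
    standardize: bool = True,
    intercept: bool = True,
) -> np.ndarray:
    """Fisher-transformed standardized OLS coefficients of neural on model RDMs.

    The strict lower triangles of the neural and each model RDM are
    vectorized (frozen order), z-scored, and entered into one OLS fit with
    intercept.  With a single model the standardized coefficient equals the
    Pearson correlation of the two triangles.  Coefficients are clipped to
    ``+/-(1 - 1e-7)`` before atanh so exact fits stay finite.
    """
    models = list(models)
    if not models:
        raise ValueError("need at least one model RDM")
    y = lower_triangle(check_rdm(neural))
    xs = []
    for m in models:
        m = check_rdm(m, symmetric=False)
        if list(m.index) != list(neural.index):
            raise ValueError("model labels do not match neural labels")
        xs.append(lower_triangle(m))
    x = np.column_stack(xs)
    if y.std() == 0 or np.any(x.std(axis=0) == 0):
        raise ValueError("zero-variance triangle vector")
    if standardize:
        y = (y - y.mean()) / y.std(ddof=1)
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    if intercept:
        x = np.column_stack([x, np.ones(len(y))])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("collinear model RDMs")
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    b = coef[: len(models)]
    return np.arctanh(np.clip(b, -FISHER_CLIP, FISHER_CLIP))


class SearchlightRsa(BaseEstimator):
    """Whole-mask searchlight RSA for one subject.

    Parameters
    ----------
    radius_mm : float, default 4.0
    min_voxels : int, default 3
    standardize, intercept : bool
        Passed through to :func:`rsa_regress`.

    Attributes
    ----------
    coef_maps_ : ndarray (n_models, nx, ny, nz)
        Fisher-transformed coefficients at valid centers, NaN elsewhere.
    valid_mask_ : ndarray of bool
        Centers that produced a value.
    dropped_ : list
        Centers dropped for sphere size or degenerate patterns.
    """

    def __init__(
        self,
        radius_mm: float = 4.0,
        min_voxels: int = 3,
        standardize: bool = True,
        intercept: bool = True,
    ):
        self.radius_mm = radius_mm
        self.min_voxels = min_voxels
        self.standardize = standardize
        self.intercept = intercept

    def fit(self, betas: BetaVolumeSet, labels, models, mask=None):
        mask = betas.mask if mask is None else np.asarray(mask).astype(bool)
        models = [check_rdm(m, symmetric=False) for m in models]
        lights, dropped = build_searchlights(
            mask, betas.affine, self.radius_mm, self.min_voxels
        )
        emotions, means = _emotion_means(betas, labels)
        model_tris, model_labels = [], list(models[0].index)
        for m in models:
            if list(m.index) != model_labels:
                raise ValueError("model RDM labels disagree")
            model_tris.append(lower_triangle(m))
        if model_labels != emotions:
            # align model label order to the emotion order found in the data
            models = [m.loc[emotions, emotions] for m in models]
            model_tris = [lower_triangle(m) for m in models]
        x = np.column_stack(model_tris)
        if self.standardize:
            x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        if self.intercept:
            x = np.column_stack([x, np.ones(x.shape[0])])
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError("collinear model RDMs")
        n_models = len(models)

        grid = betas.grid_shape
        out = np.full((n_models,) + grid, np.nan)
        valid = np.zeros(grid, dtype=bool)
        il = np.tril_indices(len(emotions), k=-1)
        pinv = np.linalg.pinv(x)
        for sl in lights:
            m = sl.members
            patterns = means[:, m[:, 0], m[:, 1], m[:, 2]]
            sd = patterns.std(axis=1)
            if np.any(sd == 0):
                dropped.append(sl.center)
                continue
            d = 1.0 - np.corrcoef(patterns)
            y = d[il]
            if y.std() == 0:
                dropped.append(sl.center)
                continue
            if self.standardize:
                y = (y - y.mean()) / y.std(ddof=1)
            b = (pinv @ y)[:n_models]
            out[(slice(None),) + sl.center] = np.arctanh(
                np.clip(b, -FISHER_CLIP, FISHER_CLIP)
            )
            valid[sl.center] = True

        self.coef_maps_ = out
        self.valid_mask_ = valid
        self.dropped_ = dropped
        self.model_labels_ = [f"model{i}" for i in range(n_models)]
        self.affine_ = betas.affine
        return self

    def transform(self, *args, **kwargs) -> np.ndarray:
        return self.coef_maps_


def run_searchlight(
    betas: BetaVolumeSet,
    labels,
    models,
    mask=None,
    radius_mm: float = 4.0,
    **kwargs,
) -> SearchlightRsa:
    """Functional wrapper: fit :class:`SearchlightRsa` and return it."""
    return SearchlightRsa(radius_mm=radius_mm, **kwargs).fit(
        betas, labels, models, mask=mask
    )
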