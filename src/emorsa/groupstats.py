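"""Group-level inference over subject coefficient maps.

One-sided one-sample t maps, threshold-free cluster enhancement (TFCE),
and a sign-permutation test: under the symmetric null each subject's map is
multiplied by a random ±1, the TFCE'd t map is recomputed, and the maximum
statistic over voxels builds the null distribution that yields FWE-corrected
p values (and z maps thresholded at 1.65, i.e., p < .05 one-tailed).

Also provides the simplified univariate path: a voxelwise repeated-measures
F test over the 7 emotion conditions and a minimum-statistic conjunction of
two maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from ._tfce import tfce_fast, tfce_scipy
from .volumes import StatMap

__all__ = [
    "group_tmap",
    "tfce",
    "SignPermutationTest",
    "sign_permutation_test",
    "PermutationResult",
    "voxelwise_emotion_F",
    "conjunction_min",
]

Z_DISPLAY_THRESHOLD = 1.65  # p < .05, one-tailed


def _stack_maps(subject_maps) -> np.ndarray:
    arrs = [m.values if isinstance(m, StatMap) else np.asarray(m, dtype=float) for m in subject_maps]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError("subject maps are not on a shared grid")
    return np.stack(arrs)


def group_tmap(subject_maps) -> StatMap:
    """Voxelwise one-sample t map: ``t = mean / (sd / sqrt(n))``, df = n - 1.

    Zero-variance voxels get t = 0 by convention (a constant map carries no
    evidence against the symmetric null used downstream).
    """
    x = _stack_maps(subject_maps)
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    t = np.zeros_like(mean)
    nz = sd > 0
    t[nz] = mean[nz] / (sd[nz] / np.sqrt(n))
    return StatMap(values=t, kind="t", df=(n - 1,))


def tfce(
    stat,
    E: float = 0.5,
    H: float = 2.0,
    dh: Optional[float] = None,
    connectivity: int = 26,
    backend: str = "fast",
) -> StatMap:
    """Threshold-free cluster enhancement of the positive part of a map.

    ``tfce(v) = sum_h extent(h)^E * h^H * dh`` over thresholds
    ``h = dh, 2dh, ...`` up to the map maximum, where ``extent(h)`` is the
    size of the suprathreshold connected component containing ``v``
    (26-connectivity by default).  ``dh`` defaults to ``max/100``.
    """
    values = stat.values if isinstance(stat, StatMap) else np.asarray(stat, dtype=float)
    if E < 0 or H < 0:
        raise ValueError("E and H must be non-negative")
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    vmax = float(values.max(initial=0.0))
    if dh is None:
        dh = vmax / 100.0 if vmax > 0 else 1.0
    if dh <= 0:
        raise ValueError("dh must be positive")
    fn = tfce_fast if backend == "fast" else tfce_scipy
    out = fn(np.nan_to_num(values, nan=0.0), E, H, dh, connectivity)
    return StatMap(values=out, kind="tfce")


@dataclass
class PermutationResult:
    observed_tfce: StatMap
    null_max: np.ndarray
    p_corrected: StatMap
    z: StatMap
    significant: np.ndarray
    n_perm: int
    seed: Optional[int]
    params: dict = field(default_factory=dict)


class SignPermutationTest(BaseEstimator):
    """One-sided group test with sign-flip permutations and TFCE.

    The observed statistic is the TFCE-enhanced one-sample t map.  Each
    permutation flips each subject's map by an independent fair coin,
    recomputes t and TFCE, and records the maximum over in-mask voxels;
    corrected ``p(v) = (1 + #{perm max >= observed(v)}) / (n_perm + 1)``
    (so min p = 1/(n_perm+1)), converted to a z map capped accordingly and
    thresholded at z >= 1.65 for the significance mask.  When ``2**n_subjects
    <= n_perm`` all sign assignments are enumerated instead of sampled.

    Attributes (after fit): ``result_`` (:class:`PermutationResult`) plus
    ``p_corrected_``, ``z_``, ``significant_`` shortcuts.
    """

    def __init__(
        self,
        n_perm: int = 10000,
        E: float = 0.5,
        H: float = 2.0,
        dh: Optional[float] = None,
        connectivity: int = 26,
        seed: Optional[int] = None,
        z_threshold: float = Z_DISPLAY_THRESHOLD,
    ):
        self.n_perm = n_perm
        self.E = E
        self.H = H
        self.dh = dh
        self.connectivity = connectivity
        self.seed = seed
        self.z_threshold = z_threshold

    def fit(self, subject_maps, mask=None):
        import warnings

        x = _stack_maps(subject_maps)
        n_sub = x.shape[0]
        grid = x.shape[1:]
        if n_sub < 5:
            raise ValueError("need at least 5 subjects for a sign-permutation test")
        if self.n_perm < 100:
            warnings.warn("fewer than 100 permutations: p values will be coarse")
        if mask is None:
            mask = np.ones(grid, dtype=bool)
        mask = np.asarray(mask).astype(bool)
        if mask.shape != grid:
            raise ValueError("mask grid does not match subject maps")

        flat = x.reshape(n_sub, -1)[:, mask.ravel()]
        nvox = flat.shape[1]
        ssq = (flat ** 2).sum(axis=0)

        def tmap_from_signs(signs: np.ndarray) -> np.ndarray:
            mean = signs @ flat / n_sub  # (n_perm_chunk, nvox)
            var = (ssq - n_sub * mean ** 2) / (n_sub - 1)
            var = np.maximum(var, 0.0)
            t = np.zeros_like(mean)
            nz = var > 0
            t[nz] = mean[nz] / np.sqrt(var[nz] / n_sub)
            return t

        obs_t = tmap_from_signs(np.ones((1, n_sub)))[0]
        obs_vol = np.zeros(grid)
        obs_vol[mask] = obs_t
        vmax = float(obs_vol.max(initial=0.0))
        dh = self.dh if self.dh is not None else (vmax / 100.0 if vmax > 0 else 1.0)
        obs_tfce = tfce(obs_vol, self.E, self.H, dh, self.connectivity).values
        obs_tfce[~mask] = 0.0

        if 2 ** n_sub <= self.n_perm:
            signs = np.array(
                [[1 if (i >> j) & 1 else -1 for j in range(n_sub)] for i in range(2 ** n_sub)],
                dtype=float,
            )
        else:
            rng = np.random.default_rng(self.seed)
            signs = rng.choice([-1.0, 1.0], size=(self.n_perm, n_sub))
        n_perm = signs.shape[0]

        null_max = np.empty(n_perm)
        vol = np.zeros(grid)
        chunk = 512
        for start in range(0, n_perm, chunk):
            tchunk = tmap_from_signs(signs[start : start + chunk])
            for i in range(tchunk.shape[0]):
                vol[mask] = tchunk[i]
                enh = tfce_fast(vol, self.E, self.H, dh, self.connectivity)
                null_max[start + i] = enh[mask].max(initial=0.0)

        sorted_null = np.sort(null_max)
        obs_in_mask = obs_tfce[mask]
        # corrected p = (1 + #{null >= obs}) / (n_perm + 1)
        n_ge = n_perm - np.searchsorted(sorted_null, obs_in_mask, side="left")
        p = (1.0 + n_ge) / (n_perm + 1.0)
        p_vol = np.ones(grid)
        p_vol[mask] = p
        z_cap = stats.norm.ppf(1.0 - 1.0 / (n_perm + 1.0))
        z_vals = stats.norm.ppf(1.0 - p)
        z_vol = np.zeros(grid)
        z_vol[mask] = np.minimum(z_vals, z_cap)
        sig = np.zeros(grid, dtype=bool)
        sig[mask] = z_vol[mask] >= self.z_threshold

        self.result_ = PermutationResult(
            observed_tfce=StatMap(values=obs_tfce, kind="tfce"),
            null_max=null_max,
            p_corrected=StatMap(values=p_vol, kind="p_corrected"),
            z=StatMap(values=z_vol, kind="z"),
            significant=sig,
            n_perm=n_perm,
            seed=self.seed,
            params={
                "E": self.E,
                "H": self.H,
                "dh": dh,
                "connectivity": self.connectivity,
                "z_threshold": self.z_threshold,
            },
        )
        self.p_corrected_ = p_vol
        self.z_ = z_vol
        self.significant_ = sig
        return self


def sign_permutation_test(
    subject_maps, n_perm: int = 10000, seed: Optional[int] = None, mask=None, **tfce_params
) -> PermutationResult:
    """Functional wrapper over :class:`SignPermutationTest`."""
    est = SignPermutationTest(n_perm=n_perm, seed=seed, **tfce_params)
    return est.fit(subject_maps, mask=mask).result_


def voxelwise_emotion_F(condition_means) -> StatMap:
    """Voxelwise one-way repeated-measures F over conditions.

    ``condition_means`` is (n_subjects, n_conditions, nx, ny, nz): one mean
    map per condition per subject.  Subjects act as the blocking factor;
    ``F = MS_condition / MS_error`` with df ``(k - 1, (k - 1)(n - 1))``.
    Voxels with constant data across all cells get F = 0 by convention.
    """
    x = np.asarray(condition_means, dtype=float)
    if x.ndim != 5:
        raise ValueError("expected (n_subjects, n_conditions, nx, ny, nz)")
    n, k = x.shape[:2]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    grand = x.mean(axis=(0, 1))
    cond_mean = x.mean(axis=0)
    subj_mean = x.mean(axis=1)
    ss_cond = n * ((cond_mean - grand) ** 2).sum(axis=0)
    ss_subj = k * ((subj_mean - grand) ** 2).sum(axis=0)
    ss_tot = ((x - grand) ** 2).sum(axis=(0, 1))
    ss_err = np.maximum(ss_tot - ss_cond - ss_subj, 0.0)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    f = np.zeros_like(grand)
    nz = ms_err > 0
    f[nz] = ms_cond[nz] / ms_err[nz]
    return StatMap(values=f, kind="F", df=(df1, df2))


def conjunction_min(map_a: StatMap, map_b: StatMap, threshold_a: float, threshold_b: float):
    """Minimum-statistic conjunction of two aligned maps.

    Returns the elementwise minimum map and the conjunction mask: voxels
    whose statistic passes its (already-corrected) threshold in BOTH maps
    (the conjunction null).
    """
    if map_a.kind != map_b.kind:
        raise ValueError(f"map kinds differ: {map_a.kind} vs {map_b.kind}")
    if map_a.values.shape != map_b.values.shape:
        raise ValueError("maps are not on a shared grid")
    mn = np.minimum(map_a.values, map_b.values)
    mask = (map_a.values >= threshold_a) & (map_b.values >= threshold_b)
    return StatMap(values=mn, kind=map_a.kind), mask
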