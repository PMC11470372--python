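"""Least-Squares-Separate (LSS) single-trial beta estimation.

Each trial is modeled by its own GLM: one boxcar regressor for the target
trial and one collapsing all remaining trials, both convolved with the
canonical double-gamma HRF, plus optional nuisance regressors, a
discrete-cosine high-pass set (128-s cutoff by default) and an intercept.
Fitting is ordinary least squares with no prewhitening; iterating over
trials yields one beta volume per trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from sklearn.base import BaseEstimator

from .volumes import BetaVolumeSet

__all__ = [
    "HrfKernel",
    "canonical_hrf",
    "dct_highpass",
    "trial_regressor",
    "LssGlm",
    "fit_lss",
]


@dataclass
class HrfKernel:
    """Sampled hemodynamic response kernel (first sample 0, peak 1)."""

    samples: np.ndarray
    dt: float

    @property
    def length(self) -> float:
        return len(self.samples) * self.dt


def _gamma_pdf(t: np.ndarray, shape: float, scale: float = 1.0) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos] / scale
    out[pos] = np.exp((shape - 1) * np.log(tp) - tp - special.gammaln(shape)) / scale
    return out


def canonical_hrf(
    dt: float,
    *,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 1.0 / 6.0,
    length: float = 32.0,
) -> HrfKernel:
    """Canonical double-gamma HRF sampled at ``dt`` seconds.

    Difference of two gamma densities (response peaking near 5 s, undershoot
    near 15 s, undershoot amplitude 1/6), truncated at 32 s and normalized so
    the peak equals 1.  The value at t = 0 is exactly 0.
    """
    if not 0 < dt <= 1:
        raise ValueError("dt must lie in (0, 1] seconds")
    t = np.arange(0.0, length, dt)
    h = _gamma_pdf(t, peak_delay / peak_disp, peak_disp) - ratio * _gamma_pdf(
        t, undershoot_delay / undershoot_disp, undershoot_disp
    )
    return HrfKernel(samples=h / h.max(), dt=dt)


def dct_highpass(n_scans: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete-cosine high-pass regressors for a ``cutoff``-second filter.

    Returns the ``floor(2 * n_scans * tr / cutoff)`` non-constant cosine
    basis functions with periods longer than the cutoff, mutually
    orthonormal over the scan (columns of shape ``(n_scans, k)``).
    """
    if n_scans < 2:
        raise ValueError("need at least 2 scans")
    if cutoff <= 2 * tr:
        raise ValueError("cutoff must exceed 2 * TR (nothing to remove below Nyquist)")
    k = int(np.floor(2.0 * n_scans * tr / cutoff))
    t = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * (2 * t + 1) * j / (2.0 * n_scans))
        for j in range(1, k + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_scans, 0))


def trial_regressor(
    onsets,
    durations,
    n_scans: int,
    tr: float,
    hrf: HrfKernel,
    *,
    slice_time_ref: float = 0.5,
) -> np.ndarray:
    """HRF-convolved boxcar regressor sampled at the scan times.

    The boxcar is built on the kernel's microtime grid, convolved with the
    kernel, and sampled at ``(i + slice_time_ref) * TR``.  Several events may
    be combined into one regressor by passing multiple onsets.
    """
    dt = hrf.dt
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.broadcast_to(np.asarray(durations, dtype=float), onsets.shape)
    n_fine = int(np.ceil(n_scans * tr / dt)) + len(hrf.samples) + 1
    box = np.zeros(n_fine)
    for on, du in zip(onsets, durations):
        i0 = int(np.round(on / dt))
        i1 = int(np.round((on + du) / dt))
        box[i0:max(i1, i0 + 1)] = 1.0
    conv = np.convolve(box, hrf.samples)[:n_fine] * dt
    sample_idx = np.round((np.arange(n_scans) + slice_time_ref) * tr / dt).astype(int)
    sample_idx = np.clip(sample_idx, 0, n_fine - 1)
    return conv[sample_idx]


def _name_collinear(x: np.ndarray, names) -> list:
    """Identify columns not adding rank, via pivoted QR."""
    r = np.linalg.qr(x, mode="r")
    diag = np.abs(np.diag(r))
    tol = max(x.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    # columns whose residual after preceding columns is ~0
    bad = []
    for j in range(x.shape[1]):
        sub = x[:, : j + 1]
        if np.linalg.matrix_rank(sub, tol=None) <= np.linalg.matrix_rank(x[:, :j], tol=None):
            bad.append(str(names[j]))
    return bad


class LssGlm(BaseEstimator):
    """Least-Squares-Separate single-trial GLM.

    Parameters
    ----------
    tr : float
        Repetition time in seconds.
    highpass : float or None, default 128.0
        DCT high-pass cutoff in seconds; ``None`` disables the filter.
    boxcar_duration : float or None, default None
        Fixed boxcar length for every trial; ``None`` uses each event's own
        ``duration`` column (12 s in the standard block design).
    microtime : int, default 16
        HRF/boxcar oversampling factor (``dt = TR / microtime``).
    slice_time_ref : float, default 0.5
        Where within the TR regressors are sampled.

    Attributes
    ----------
    betas_ : BetaVolumeSet
        One coefficient volume per trial (NaN outside the mask).
    design_names_ : list of str
        Column names of the last per-trial design fitted.
    """

    def __init__(
        self,
        tr: float,
        highpass: float | None = 128.0,
        boxcar_duration: float | None = None,
        microtime: int = 16,
        slice_time_ref: float = 0.5,
    ):
        self.tr = tr
        self.highpass = highpass
        self.boxcar_duration = boxcar_duration
        self.microtime = microtime
        self.slice_time_ref = slice_time_ref

    def fit(self, bold: np.ndarray, events: pd.DataFrame, mask=None, nuisance=None, affine=None):
        """Fit one GLM per trial and collect the target coefficients.

        ``bold`` is (n_scans, nx, ny, nz); ``events`` needs ``onset``,
        ``duration`` and ``trial_type`` columns (rows flagged ``catch`` are
        dropped).  ``nuisance`` is an optional (n_scans, k) table.
        """
        bold = np.asarray(bold, dtype=float)
        if bold.ndim != 4:
            raise ValueError("bold must be 4-D (n_scans, nx, ny, nz)")
        n_scans = bold.shape[0]
        if mask is None:
            mask = np.ones(bold.shape[1:], dtype=bool)
        mask = np.asarray(mask).astype(bool)
        if not mask.any():
            raise ValueError("mask is empty")
        events = events.copy()
        if "catch" in events.columns:
            events = events.loc[~events["catch"].astype(bool)]
        events = events.reset_index(drop=True)
        onsets = events["onset"].to_numpy(dtype=float)
        if self.boxcar_duration is not None:
            durations = np.full(len(events), float(self.boxcar_duration))
        else:
            durations = events["duration"].to_numpy(dtype=float)
        end = (onsets + durations).max()
        if end > n_scans * self.tr:
            raise ValueError("events extend beyond the scan")

        hrf = canonical_hrf(self.tr / self.microtime)
        reg = np.column_stack(
            [
                trial_regressor(
                    onsets[t], durations[t], n_scans, self.tr, hrf,
                    slice_time_ref=self.slice_time_ref,
                )
                for t in range(len(events))
            ]
        )
        fixed_cols, fixed_names = [], []
        if nuisance is not None:
            nuis = np.asarray(nuisance, dtype=float)
            if nuis.ndim == 1:
                nuis = nuis[:, None]
            if nuis.shape[0] != n_scans:
                raise ValueError("nuisance length does not match scan length")
            fixed_cols.append(nuis)
            names = (
                list(nuisance.columns)
                if isinstance(nuisance, pd.DataFrame)
                else [f"nuisance{k}" for k in range(nuis.shape[1])]
            )
            fixed_names += names
        if self.highpass is not None:
            dct = dct_highpass(n_scans, self.tr, self.highpass)
            if dct.shape[1]:
                fixed_cols.append(dct)
                fixed_names += [f"dct{k + 1}" for k in range(dct.shape[1])]
        fixed_cols.append(np.ones((n_scans, 1)))
        fixed_names.append("intercept")
        fixed = np.column_stack(fixed_cols)

        y = bold[:, mask]
        n_trials = len(events)
        betas = np.full((n_trials,) + bold.shape[1:], np.nan)
        for t in range(n_trials):
            cols = [reg[:, t]]
            names = [f"trial{t}"]
            if n_trials > 1:
                cols.append(reg[:, np.arange(n_trials) != t].sum(axis=1))
                names.append("other_trials")
            x = np.column_stack([np.column_stack(cols), fixed])
            names = names + fixed_names
            if np.allclose(x[:, 0], 0):
                raise ValueError(f"all-zero target regressor for trial {t}")
            if np.linalg.matrix_rank(x) < x.shape[1]:
                bad = _name_collinear(x, names)
                raise ValueError("rank-deficient design; collinear columns: " + ", ".join(bad))
            coef, *_ = np.linalg.lstsq(x, y, rcond=None)
            vol = np.full(bold.shape[1:], np.nan)
            vol[mask] = coef[0]
            betas[t] = vol
            self.design_names_ = names

        self.betas_ = BetaVolumeSet(
            data=betas,
            mask=mask,
            affine=affine if affine is not None else np.eye(4),
            trials=events,
        )
        return self

    def transform(self, *args, **kwargs) -> BetaVolumeSet:
        return self.betas_


def fit_lss(bold, events, mask=None, nuisance=None, tr: float = 1.5, **kwargs) -> BetaVolumeSet:
    """Functional wrapper: run :class:`LssGlm` and return the beta volumes."""
    return LssGlm(tr=tr, **kwargs).fit(bold, events, mask=mask, nuisance=nuisance).betas_
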