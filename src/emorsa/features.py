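"""Low-level stimulus feature models for RSA controls.

Pitch (fundamental frequency) extraction by the normalized-autocorrelation
method for voice stimuli, and conversion of any per-stimulus feature table
(e.g., precomputed HMAX C2 activations for faces, or per-frame pitch
vectors) into a per-emotion Pearson-distance RDM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rdm import pearson_distance

__all__ = ["PitchTrack", "autocorr_pitch", "feature_rdm", "resample_track"]


@dataclass
class PitchTrack:
    """Frame-wise f0 estimates; NaN where the frame is unvoiced."""

    f0: np.ndarray
    voiced: np.ndarray
    f0_median: float  # NaN when no frame is voiced

    @property
    def any_voiced(self) -> bool:
        return bool(self.voiced.any())


def autocorr_pitch(
    wave: np.ndarray,
    sr: float,
    fmin: float = 75.0,
    fmax: float = 500.0,
    frame_length: int = 2048,
    hop_length: int = 512,
    voicing_threshold: float = 0.3,
) -> PitchTrack:
    """Fundamental-frequency track via normalized autocorrelation.

    Per frame the signal is mean-centered and its autocorrelation (normalized
    by lag 0) is searched over lags corresponding to ``[fmin, fmax]``; the lag
    of the highest peak gives ``f0 = sr / lag``.  Frames whose peak
    normalized autocorrelation falls below ``voicing_threshold`` are marked
    unvoiced (aperiodic) and excluded from the median.

    The estimate is invariant to amplitude scaling of the waveform.
    """
    wave = np.asarray(wave, dtype=float)
    if not 0 < fmin < fmax < sr / 2:
        raise ValueError("need 0 < fmin < fmax < sr/2")
    if wave.size < frame_length:
        raise ValueError("signal shorter than one analysis frame")
    lag_min = max(1, int(np.floor(sr / fmax)))
    lag_max = int(np.ceil(sr / fmin))
    if lag_max >= frame_length:
        raise ValueError("frame_length too short for fmin")

    starts = range(0, wave.size - frame_length + 1, hop_length)
    f0 = np.full(len(list(starts)), np.nan)
    voiced = np.zeros(len(f0), dtype=bool)
    for i, s in enumerate(range(0, wave.size - frame_length + 1, hop_length)):
        frame = wave[s : s + frame_length]
        frame = frame - frame.mean()
        r0 = float(frame @ frame)
        if r0 == 0:
            continue
        # full autocorrelation over the candidate lag range
        ac = np.array([frame[:-lag] @ frame[lag:] for lag in range(lag_min, lag_max + 1)]) / r0
        k = int(np.argmax(ac))
        if ac[k] >= voicing_threshold:
            voiced[i] = True
            f0[i] = sr / (lag_min + k)
    med = float(np.median(f0[voiced])) if voiced.any() else float("nan")
    return PitchTrack(f0=f0, voiced=voiced, f0_median=med)


def resample_track(track: np.ndarray, n_points: int) -> np.ndarray:
    """Linear time-resampling of a (pitch) track to a fixed length.

    Unvoiced (NaN) frames are filled by interpolation over voiced frames so
    that tracks of differing duration become comparable feature vectors.
    """
    track = np.asarray(track, dtype=float)
    good = np.isfinite(track)
    if not good.any():
        raise ValueError("track has no voiced frames to resample")
    x = np.flatnonzero(good)
    filled = np.interp(np.arange(track.size), x, track[good])
    src = np.linspace(0, track.size - 1, n_points)
    return np.interp(src, np.arange(track.size), filled)


def feature_rdm(features: pd.DataFrame, *, per_stimulus: bool = False) -> pd.DataFrame:
    """Per-emotion Pearson-distance RDM from a stimulus feature table.

    ``features`` has one row per stimulus, an ``emotion`` column, and
    real-valued feature columns.  By default each emotion's stimuli are
    averaged into one feature vector before computing ``1 - r`` between
    emotion pairs; ``per_stimulus=True`` instead averages the pairwise
    stimulus-level distances across each emotion pair.
    """
    if "emotion" not in features.columns:
        raise ValueError("feature table needs an 'emotion' column")
    feat_cols = [c for c in features.columns if c != "emotion"]
    if not feat_cols:
        raise ValueError("no feature columns")
    if features[feat_cols].isna().any().any():
        raise ValueError("feature table contains missing values")
    emotions = list(pd.unique(features["emotion"]))
    if not per_stimulus:
        means = np.vstack(
            [features.loc[features["emotion"] == e, feat_cols].mean(axis=0) for e in emotions]
        )
        return pearson_distance(means, emotions)
    x = features[feat_cols].to_numpy(dtype=float)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant stimulus feature vector")
    r = np.corrcoef(x)
    d = np.zeros((len(emotions), len(emotions)))
    for i, a in enumerate(emotions):
        ia = np.flatnonzero(features["emotion"] == a)
        for j, b in enumerate(emotions):
            if i == j:
                continue
            ib = np.flatnonzero(features["emotion"] == b)
            d[i, j] = float((1 - r[np.ix_(ia, ib)]).mean())
    d = (d + d.T) / 2
    return pd.DataFrame(d, index=emotions, columns=emotions)
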