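"""Synthetic behavioral and imaging data with planted representational structure.

The generators emulate the statistical structure the analysis pipeline
assumes, so every downstream stage can be exercised without any data
download:

* task-design enumerations (280-trial rating task; 114-trial fMRI sessions),
* per-subject 7 x 40 rating matrices whose emotion-row Pearson-distance
  structure follows a group target RDM with between-subject jitter,
* emotion-categorization confusion counts that decrease with conceptual
  dissimilarity,
* per-trial beta volumes in which a designated signal region carries
  emotion patterns whose pairwise correlations follow a subject RDM,
* forward-modeled BOLD series (boxcar * HRF) for testing single-trial
  estimation, and pure tones for testing pitch extraction.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rdm import as_rdm, check_rdm
from .singletrial import HrfKernel, trial_regressor
from .volumes import BetaVolumeSet

__all__ = [
    "EMOTIONS",
    "DesignSpec",
    "PlantedWorld",
    "default_target_rdm",
    "gen_rating_design",
    "gen_session_design",
    "sample_subject_rdm",
    "gen_subject_ratings",
    "gen_confusions",
    "gen_beta_volumes",
    "gen_bold",
    "gen_tone",
]

EMOTIONS = ["angry", "disgusted", "fearful", "happy", "sad", "surprised", "neutral"]

# per-generator stream tags so one world seed yields decoupled streams
_TAG_RDM, _TAG_RATINGS, _TAG_BETAS = 11, 13, 17


@dataclass
class DesignSpec:
    """Constants of the rating and scanner task designs."""

    n_emotions: int = 7
    n_words: int = 40
    rating_min: int = 1
    rating_max: int = 7
    sessions: int = 4
    blocks_per_session: int = 4
    trials_per_block: int = 7
    actors_per_trial: int = 4
    catch_per_session: int = 2
    pre_fix: float = 4.5
    stim: float = 3.0
    post_fix: float = 3.0
    block_rest: float = 12.0

    def __post_init__(self) -> None:
        counts = [
            self.n_emotions, self.n_words, self.sessions, self.blocks_per_session,
            self.trials_per_block, self.actors_per_trial,
        ]
        if any(c <= 0 for c in counts) or self.catch_per_session < 0:
            raise ValueError("design counts must be positive")
        if self.rating_min >= self.rating_max:
            raise ValueError("rating scale bounds must be ordered")
        if min(self.pre_fix, self.stim, self.post_fix, self.block_rest) < 0:
            raise ValueError("timings must be non-negative")


def default_target_rdm() -> pd.DataFrame:
    """Group-prototype conceptual RDM for the seven emotion categories.

    Built from a Gaussian similarity kernel over a two-dimensional
    valence/arousal-style layout (negative high-arousal emotions close
    together, happy opposite, neutral near the origin), which guarantees a
    valid correlation structure (``1 - d`` positive semidefinite) with
    dissimilarities spanning roughly 0.05-0.85.
    """
    coords = np.array(
        [
            [-0.80, 0.80],   # angry
            [-0.70, 0.35],   # disgusted
            [-0.65, 0.75],   # fearful
            [0.85, 0.55],    # happy
            [-0.75, -0.45],  # sad
            [0.35, 0.85],    # surprised
            [0.00, -0.10],   # neutral
        ]
    )
    sq = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    c = np.exp(-sq / 2.0)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    return as_rdm(d, EMOTIONS)


@dataclass
class PlantedWorld:
    """Ground-truth parameters shared by the behavioral and imaging generators."""

    target_rdm: pd.DataFrame = field(default_factory=default_target_rdm)
    idiosyncrasy_sd: float = 0.1
    noise_sd: float = 1.0
    signal_region: np.ndarray | None = None  # (n, 3) voxel indices
    grid_shape: tuple = (10, 10, 10)
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        self.target_rdm = check_rdm(self.target_rdm)
        d = self.target_rdm.to_numpy(dtype=float)
        if d.min() < 0 or d.max() > 2:
            raise ValueError("target RDM entries must lie in [0, 2]")
        if self.idiosyncrasy_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        w = np.linalg.eigvalsh(1.0 - d)
        if w.min() < -1e-8:
            raise ValueError(
                "implied correlation matrix 1 - target_rdm is not positive "
                "semidefinite; rejecting world"
            )
        if any(s <= 0 for s in self.grid_shape) or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3 positive integers")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.signal_region is not None:
            self.signal_region = np.asarray(self.signal_region, dtype=int)
            if self.signal_region.ndim != 2 or self.signal_region.shape[1] != 3:
                raise ValueError("signal_region must be (n, 3) voxel indices")
            shape = np.array(self.grid_shape)
            if np.any(self.signal_region < 0) or np.any(self.signal_region >= shape):
                raise ValueError("signal_region exceeds the grid")

    @property
    def affine(self) -> np.ndarray:
        a = np.eye(4)
        a[0, 0], a[1, 1], a[2, 2] = self.voxel_size_mm
        return a

    @property
    def emotions(self) -> list:
        return list(self.target_rdm.index)


# ---------------------------------------------------------------------------
# task designs
# ---------------------------------------------------------------------------

def gen_rating_design(spec: DesignSpec, seed: int, emotions=None) -> pd.DataFrame:
    """Randomized rating-task sequence: one record per (emotion block, word).

    Emotion blocks appear in random order; the words are re-shuffled within
    each block.  The default design yields 7 x 40 = 280 records.
    """
    rng = np.random.default_rng(seed)
    if emotions is None:
        if spec.n_emotions <= len(EMOTIONS):
            emotions = EMOTIONS[: spec.n_emotions]
        else:
            emotions = [f"emotion{i}" for i in range(spec.n_emotions)]
    words = [f"word{i + 1:02d}" for i in range(spec.n_words)]
    rows = []
    trial = 0
    for b, e in enumerate(rng.permutation(emotions)):
        for w in rng.permutation(words):
            trial += 1
            rows.append({"trial": trial, "block": b + 1, "emotion": e, "word": w})
    return pd.DataFrame(rows)


def gen_session_design(spec: DesignSpec, modality: str, seed: int) -> pd.DataFrame:
    """One scanner session: blocked emotion trials plus catch trials.

    Each block presents the 7 emotions once (order randomized); each trial
    is a 4.5-s fixation, four 3-s actor stimuli of the same emotion, and a
    3-s fixation, producing one record per stimulus.  Two catch trials (a
    single stimulus followed by a sex-judgment prompt) are appended after
    the last trial of two randomly chosen blocks, and blocks are separated
    by a 12-s rest.  Default counts: 4 x 7 x 4 + 2 = 114 records.
    """
    if modality not in ("face", "voice"):
        raise ValueError("modality must be 'face' or 'voice'")
    rng = np.random.default_rng(seed)
    emotions = EMOTIONS[: spec.trials_per_block] if spec.trials_per_block <= 7 else [
        f"emotion{i}" for i in range(spec.trials_per_block)
    ]
    catch_blocks = rng.choice(
        spec.blocks_per_session, size=min(spec.catch_per_session, spec.blocks_per_session),
        replace=False,
    )
    # if more catch trials than blocks, wrap around
    extra = spec.catch_per_session - len(catch_blocks)
    if extra > 0:
        catch_blocks = np.concatenate(
            [catch_blocks, rng.choice(spec.blocks_per_session, size=extra, replace=True)]
        )
    rows = []
    t = 0.0
    trial = 0
    for b in range(spec.blocks_per_session):
        for e in rng.permutation(emotions):
            trial += 1
            stim_onset = t + spec.pre_fix
            for a in range(spec.actors_per_trial):
                rows.append(
                    {
                        "onset": stim_onset + a * spec.stim,
                        "duration": spec.stim,
                        "trial_type": e,
                        "modality": modality,
                        "block": b + 1,
                        "trial": trial,
                        "actor": a + 1,
                        "catch": False,
                    }
                )
            t = stim_onset + spec.actors_per_trial * spec.stim + spec.post_fix
        for _ in range(int((catch_blocks == b).sum())):
            trial += 1
            rows.append(
                {
                    "onset": t + spec.pre_fix,
                    "duration": spec.stim,
                    "trial_type": "catch",
                    "modality": modality,
                    "block": b + 1,
                    "trial": trial,
                    "actor": int(rng.integers(1, spec.actors_per_trial + 1)),
                    "catch": True,
                }
            )
            t = t + spec.pre_fix + spec.stim + spec.post_fix
        t += spec.block_rest
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# planted rating / confusion / beta structure
# ---------------------------------------------------------------------------

def _psd_correlation(c: np.ndarray) -> np.ndarray:
    """Project a jittered matrix back to a valid correlation matrix.

    Eigenvalues are clipped at zero and the result renormalized to a unit
    diagonal (jittered matrices need not remain positive semidefinite).
    """
    c = (c + c.T) / 2.0
    w, v = np.linalg.eigh(c)
    c = (v * np.clip(w, 0.0, None)) @ v.T
    d = np.sqrt(np.clip(np.diag(c), 1e-12, None))
    c = c / np.outer(d, d)
    np.fill_diagonal(c, 1.0)
    return c


def _exact_corr_rows(c: np.ndarray, n_features: int, rng) -> np.ndarray:
    """Rows with EMPIRICAL correlation equal to ``c`` (unit sample variance).

    Draws Gaussian rows, centers and whitens them so their sample covariance
    is the identity, then mixes with a square root of ``c``.  Requires
    ``n_features > n_rows``; below that an approximate (mixed but
    unwhitened) construction is returned.
    """
    n = c.shape[0]
    w, v = np.linalg.eigh(c)
    a = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((n, n_features))
    z -= z.mean(axis=1, keepdims=True)
    if n_features > n:
        cov = z @ z.T / n_features
        ew, ev = np.linalg.eigh(cov)
        whiten = ev @ np.diag(1.0 / np.sqrt(np.clip(ew, 1e-12, None))) @ ev.T
        z = whiten @ z
    else:
        z /= np.clip(z.std(axis=1, keepdims=True), 1e-12, None)
    return a @ z


def sample_subject_rdm(world: PlantedWorld, subject_id: int) -> pd.DataFrame:
    """Subject-specific conceptual RDM: target plus symmetric jitter.

    Off-diagonal entries get independent Gaussian jitter with sd
    ``idiosyncrasy_sd``, are clipped to [0, 2], and the implied correlation
    matrix is projected back to positive semidefiniteness.
    """
    rng = np.random.default_rng([world.seed, _TAG_RDM, subject_id])
    d = world.target_rdm.to_numpy(dtype=float).copy()
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    jit = rng.normal(0.0, world.idiosyncrasy_sd, size=len(iu[0]))
    d[iu] += jit
    d.T[iu] = d[iu]
    d = np.clip(d, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    c = _psd_correlation(1.0 - d)
    d = 1.0 - c
    np.fill_diagonal(d, 0.0)
    return as_rdm(d, world.emotions)


def gen_subject_ratings(
    world: PlantedWorld,
    subject_id: int,
    *,
    n_words: int = 40,
    rating_min: int = 1,
    rating_max: int = 7,
    loc: float = 4.0,
    scale: float = 1.2,
    subject_rdm: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One subject's emotions-by-words integer rating matrix.

    Emotion prototypes over the word stimuli are constructed so their
    pairwise empirical correlations equal ``1 - subject RDM`` (target plus
    idiosyncratic jitter), Gaussian response noise (``world.noise_sd``) is
    added, and values are affine-mapped to the rating scale (mean ``loc``,
    sd ``scale``), rounded half-up and clipped.
    """
    rng = np.random.default_rng([world.seed, _TAG_RATINGS, subject_id])
    if subject_rdm is None:
        subject_rdm = sample_subject_rdm(world, subject_id)
    c = _psd_correlation(1.0 - subject_rdm.to_numpy(dtype=float))
    proto = _exact_corr_rows(c, n_words, rng)
    noisy = proto + rng.normal(0.0, world.noise_sd, size=proto.shape)
    values = loc + scale * noisy
    values = np.floor(values + 0.5)  # round half-up
    values = np.clip(values, rating_min, rating_max).astype(int)
    words = [f"word{i + 1:02d}" for i in range(n_words)]
    return pd.DataFrame(values, index=world.emotions, columns=words)


def gen_confusions(
    conceptual_rdm: pd.DataFrame,
    temperature: float,
    n_trials_per_emotion: int,
    seed: int,
) -> pd.DataFrame:
    """Multinomial confusion counts linked to conceptual dissimilarity.

    Row i draws ``n_trials_per_emotion`` responses with probabilities
    proportional to ``exp(-d(i, j) / temperature)`` (``d(i, i) = 0``), so
    conceptually closer pairs are confused more often; as the temperature
    approaches 0 the counts become purely diagonal.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rdm = check_rdm(conceptual_rdm)
    d = rdm.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    logits = -d / temperature
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(n_trials_per_emotion, p[i]) for i in range(d.shape[0])])
    return pd.DataFrame(counts, index=rdm.index, columns=rdm.columns)


def gen_beta_volumes(
    world: PlantedWorld,
    subject_rdm: pd.DataFrame,
    trials_per_emotion: int,
    subject_id: int = 0,
) -> BetaVolumeSet:
    """Per-trial beta volumes with an emotion code planted in one region.

    Within ``world.signal_region`` the per-emotion mean patterns have
    pairwise empirical correlations ``1 - subject_rdm`` (unit pattern
    variance); every trial volume adds independent Gaussian noise with sd
    ``world.noise_sd`` everywhere, and voxels outside the region carry
    noise only.
    """
    if world.signal_region is None or len(world.signal_region) < 3:
        raise ValueError("signal_region must contain at least 3 voxels")
    subject_rdm = check_rdm(subject_rdm)
    rng = np.random.default_rng([world.seed, _TAG_BETAS, subject_id])
    region = world.signal_region
    n_region = len(region)
    c = _psd_correlation(1.0 - subject_rdm.to_numpy(dtype=float))
    patterns = _exact_corr_rows(c, n_region, rng)  # (7, n_region)
    emotions = list(subject_rdm.index)
    n_emotions = len(emotions)
    n_trials = n_emotions * trials_per_emotion
    data = rng.normal(0.0, world.noise_sd, size=(n_trials,) + tuple(world.grid_shape))
    labels = []
    for t in range(n_trials):
        e = t % n_emotions
        labels.append(emotions[e])
        data[t, region[:, 0], region[:, 1], region[:, 2]] += patterns[e]
    trials = pd.DataFrame({"trial": np.arange(1, n_trials + 1), "trial_type": labels})
    mask = np.ones(world.grid_shape, dtype=bool)
    return BetaVolumeSet(data=data, mask=mask, affine=world.affine, trials=trials)


# ---------------------------------------------------------------------------
# forward BOLD model and audio fixtures
# ---------------------------------------------------------------------------

def gen_bold(
    events: pd.DataFrame,
    amplitudes,
    hrf: HrfKernel,
    tr: float,
    noise_sd: float,
    seed: int,
    grid_shape: tuple = (2, 2, 2),
    n_scans: int | None = None,
) -> np.ndarray:
    """Forward-model BOLD: sum of amplitude-scaled HRF-convolved boxcars.

    Every voxel shares the same noiseless series (per-trial ``amplitudes``
    times the trial's convolved boxcar, built with the same regressor
    construction the single-trial GLM uses); independent Gaussian noise is
    added per voxel.  Returns a (n_scans, nx, ny, nz) array.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    onsets = events["onset"].to_numpy(dtype=float)
    durations = events["duration"].to_numpy(dtype=float)
    if n_scans is None:
        n_scans = int(np.ceil(((onsets + durations).max() + 32.0) / tr))
    if (onsets + durations).max() > n_scans * tr:
        raise ValueError("events extend beyond the scan")
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.shape[0] != len(events):
        raise ValueError("one amplitude per trial required")
    series = np.zeros(n_scans)
    for t in range(len(events)):
        series += amplitudes[t] * trial_regressor(onsets[t], durations[t], n_scans, tr, hrf)
    rng = np.random.default_rng(seed)
    bold = np.broadcast_to(
        series[:, None, None, None], (n_scans,) + tuple(grid_shape)
    ).copy()
    if noise_sd > 0:
        bold += rng.normal(0.0, noise_sd, size=bold.shape)
    return bold


def gen_tone(f0: float, sr: float, duration: float) -> np.ndarray:
    """Unit-amplitude sine at ``f0`` Hz sampled at ``sr`` Hz."""
    if f0 <= 0 or f0 >= sr / 2:
        raise ValueError("f0 must lie strictly between 0 and the Nyquist frequency")
    n = int(round(sr * duration))
    t = np.arange(n) / sr
    return np.sin(2 * np.pi * f0 * t)
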