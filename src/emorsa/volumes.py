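"""Volume containers shared across the imaging stages.

``BetaVolumeSet`` holds per-trial coefficient volumes on a common grid with a
binary mask and a NIfTI affine; ``StatMap`` holds a single 3-D statistic map.
Both round-trip to NIfTI-1 via nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["BetaVolumeSet", "StatMap"]


@dataclass
class BetaVolumeSet:
    """Per-trial 3-D coefficient volumes over a shared grid.

    Attributes
    ----------
    data : ndarray, shape (n_trials, nx, ny, nz)
    mask : ndarray of bool, shape (nx, ny, nz)
    affine : ndarray, shape (4, 4)
    trials : DataFrame
        One row per volume; must include a ``trial_type`` column with the
        condition (emotion) label.
    """

    data: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    trials: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("data must be (n_trials, nx, ny, nz)")
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("mask grid does not match data grid")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if len(self.trials) and len(self.trials) != self.data.shape[0]:
            raise ValueError("trial metadata length does not match volume count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[1:]

    def masked(self) -> np.ndarray:
        """Return (n_trials, n_mask_voxels) matrix of in-mask values."""
        return self.data[:, self.mask]

    def to_nifti(self, path) -> None:
        """Write as a 4-D NIfTI stack (trial axis last, NIfTI convention)."""
        img = nib.Nifti1Image(np.moveaxis(self.data, 0, -1), self.affine)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, mask, trials=None) -> "BetaVolumeSet":
        img = nib.load(str(path))
        data = np.moveaxis(np.asarray(img.get_fdata()), -1, 0)
        if isinstance(mask, (str,)) or hasattr(mask, "__fspath__"):
            mask = np.asarray(nib.load(str(mask)).get_fdata()) > 0
        return cls(
            data=data,
            mask=mask,
            affine=img.affine,
            trials=trials if trials is not None else pd.DataFrame(),
        )


@dataclass
class StatMap:
    """A 3-D statistic map (t, z, F, TFCE, or corrected p) on the mask grid."""

    values: np.ndarray
    kind: str = "t"
    df: Optional[tuple] = None
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("StatMap values must be 3-D")
        if self.kind in ("p", "p_corrected"):
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("p maps must lie in [0, 1]")

    def to_nifti(self, path) -> None:
        affine = self.affine if self.affine is not None else np.eye(4)
        nib.save(nib.Nifti1Image(self.values, affine), str(path))
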