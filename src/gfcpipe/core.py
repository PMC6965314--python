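"""Shared in-memory containers for 4D BOLD data and rigid-body motion traces."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Bold4D:
    """A single subject's 4D BOLD volume.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Voxel intensities in arbitrary units.
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    tr_s : float
        Repetition time (sampling interval between volumes) in seconds.
    """

    data: np.ndarray
    voxel_size_mm: float
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x,y,z,t); got ndim={self.data.ndim}")
        if self.data.shape[3] < 1:
            raise ValueError("BOLD data must contain at least one volume")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")
        if self.voxel_size_mm <= 0:
            raise ValueError(f"voxel_size_mm must be positive; got {self.voxel_size_mm}")
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive; got {self.tr_s}")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion parameters.

    ``params`` is a (T, 6) array: translations x, y, z in millimetres followed
    by rotations about x, y, z in radians.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                f"motion parameters must be a (T, 6) array; got shape {self.params.shape}"
            )
        if not np.all(np.isfinite(self.params)):
            raise ValueError("motion parameters contain non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_rad(self) -> np.ndarray:
        return self.params[:, 3:]
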