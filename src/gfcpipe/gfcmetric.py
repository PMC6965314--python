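"""Global-brain functional connectivity (GFC).

For every gray-matter voxel i, GFC_i is the average Pearson correlation of
its time series with every other gray-matter voxel's series,

    GFC_i = (1 / (V - 1)) * sum_{j != i} r_ij,

subsequently variance-stabilized with the Fisher transform z = atanh(r).
With rows standardized to population SD 1 the whole map reduces to
r_i = ((x_i . S) / T - 1) / (V - 1) with S the column sum of the matrix,
an O(V*T) computation; the literal O(V^2*T) pairwise definition is retained
as an oracle (:func:`gfc_bruteforce`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import Bold4D
from .preproc import CensorMask

logger = logging.getLogger(__name__)

_CLIP = 1.0 - 1e-7


@dataclass
class GrayMask:
    """Gray-matter analysis mask with linear-index bookkeeping."""

    mask: np.ndarray  # 3D bool
    threshold: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("gray-matter mask must be 3D")
        self.indices = np.argwhere(self.mask)  # (V, 3)
        lookup = np.full(self.mask.shape, -1, dtype=np.int64)
        lookup[self.mask] = np.arange(self.indices.shape[0])
        self.lookup = lookup  # voxel (x,y,z) -> position in the masked vector

    @property
    def n_voxels(self) -> int:
        return self.indices.shape[0]

    def extract(self, data4d: np.ndarray) -> np.ndarray:
        """Masked voxel series as a V x T matrix."""
        return np.asarray(data4d)[self.mask]

    def to_volume(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter a length-V vector back into volume space (off-mask = fill)."""
        vol = np.full(self.mask.shape, fill, dtype=np.float64)
        vol[self.mask] = values
        return vol


@dataclass
class GfcMap:
    r: np.ndarray  # per-masked-voxel mean correlation, in [-1, 1]
    z: np.ndarray  # Fisher z of r
    mask: GrayMask
    t_effective: int  # number of time points the correlations were computed on

    def __post_init__(self) -> None:
        V = self.r.size
        if V >= 2:
            # positive-semidefiniteness of a correlation matrix bounds the mean
            bound = -1.0 / (V - 1)
            if self.r.mean() < bound - 1e-8:
                raise ValueError("mean GFC violates the correlation PSD bound")
        if not (np.all(np.isfinite(self.r)) and np.all(np.isfinite(self.z))):
            raise ValueError("GFC map contains non-finite values")

    def z_volume(self) -> np.ndarray:
        return self.mask.to_volume(self.z)

    def r_volume(self) -> np.ndarray:
        return self.mask.to_volume(self.r)


def gray_matter_mask(prob_map: np.ndarray, threshold: float = 0.2) -> GrayMask:
    """Voxels whose gray-matter probability strictly exceeds the threshold."""
    prob_map = np.asarray(prob_map, dtype=np.float64)
    if prob_map.min() < 0 or prob_map.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    mask = prob_map > threshold
    if mask.sum() < 2:
        raise ValueError(
            f"gray-matter mask has {int(mask.sum())} voxels (< 2) at threshold {threshold}"
        )
    return GrayMask(mask=mask, threshold=threshold)


def standardize(ts_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardize to mean 0 and population SD 1 (so row . row = T).

    Zero-variance rows are flagged and left as zeros; callers should drop
    them from the analysis mask.
    """
    ts = np.asarray(ts_matrix, dtype=np.float64)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("need a V x T matrix with T >= 3")
    centered = ts - ts.mean(axis=1, keepdims=True)
    sd = np.sqrt((centered**2).mean(axis=1))
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance series flagged and excluded",
            stacklevel=2,
        )
    safe = np.where(zero_var, 1.0, sd)
    return centered / safe[:, None], zero_var


def gfc_fast(std_matrix: np.ndarray) -> np.ndarray:
    """Mean correlation of each standardized row with all other rows, O(V*T)."""
    std = np.asarray(std_matrix, dtype=np.float64)
    V, T = std.shape
    if V < 2:
        raise ValueError("need at least 2 voxels")
    s = std.sum(axis=0)
    r = ((std @ s) / T - 1.0) / (V - 1)
    return np.clip(r, -1.0, 1.0)


def gfc_bruteforce(std_matrix: np.ndarray) -> np.ndarray:
    """Literal pairwise definition (oracle): r_i = mean_{j != i} Pearson r_ij."""
    std = np.asarray(std_matrix, dtype=np.float64)
    V = std.shape[0]
    if V < 2:
        raise ValueError("need at least 2 voxels")
    corr = np.corrcoef(std)
    return (corr.sum(axis=1) - np.diag(corr)) / (V - 1)


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z transform, atanh(r); |r| = 1 is clipped with a warning."""
    arr = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(arr) > 1):
        raise ValueError("correlations must satisfy |r| <= 1")
    if np.any(np.abs(arr) >= _CLIP):
        warnings.warn("|r| at or above the clip point; clipping before atanh", stacklevel=2)
        arr = np.clip(arr, -_CLIP, _CLIP)
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) else out


def gfc_subject(
    bold: Bold4D,
    mask: GrayMask,
    censor: CensorMask | None = None,
    min_volumes: int = 50,
) -> GfcMap:
    """Per-voxel Fisher-z GFC for one preprocessed subject.

    Correlations are computed over kept time points only. If ``bold`` is
    already censored (its t-dimension equals the censor's kept count), the
    censor is treated as applied.
    """
    if mask.mask.shape != bold.grid_shape:
        raise ValueError(
            f"mask grid {mask.mask.shape} does not match BOLD grid {bold.grid_shape}"
        )
    ts = mask.extract(bold.data)
    if censor is not None and bold.n_volumes != censor.n_kept:
        if censor.kept.max(initial=-1) >= bold.n_volumes:
            raise ValueError("censor mask indices exceed the BOLD time dimension")
        ts = ts[:, censor.kept]
    if ts.shape[1] < min_volumes:
        raise ValueError(
            f"only {ts.shape[1]} surviving volumes (< {min_volumes}); refusing to compute GFC"
        )
    std, zero_var = standardize(ts)
    eff_mask = mask
    if zero_var.any():
        keep_vol = mask.mask.copy()
        keep_vol[tuple(mask.indices[zero_var].T)] = False
        eff_mask = GrayMask(mask=keep_vol, threshold=mask.threshold)
        std = std[~zero_var]
        logger.warning("dropped %d zero-variance voxels from the mask", int(zero_var.sum()))
    r = gfc_fast(std)
    z = fisher_z(r)
    return GfcMap(r=r, z=np.asarray(z), mask=eff_mask, t_effective=std.shape[1])
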