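"""Per-subject preprocessing: discard, smooth, detrend, band-pass, nuisance
regression, motion QC, framewise displacement, and scrubbing.

The chain order is fixed: discard initial volumes -> spatial smoothing ->
linear detrend -> band-pass (0.01-0.08 Hz) -> nuisance regression (Friston-24
motion expansion + white-matter and CSF mean signals; the global signal is
deliberately not removed) -> scrubbing of high-motion frames (FD > 0.2 mm).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import Bold4D, MotionTrace

logger = logging.getLogger(__name__)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PreprocConfig:
    n_discard: int = 10
    fwhm_mm: float = 4.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    fd_threshold_mm: float = 0.2
    head_radius_mm: float = 50.0
    min_volumes: int = 50
    max_trans_mm: float = 2.0
    max_rot_deg: float = 2.0


@dataclass
class FdSeries:
    """Power-style framewise displacement: FD_t = sum|d trans| + r * sum|d rot|."""

    fd: np.ndarray  # mm, first entry 0 by definition
    mean_fd: float
    head_radius_mm: float


@dataclass
class CensorMask:
    kept: np.ndarray  # strictly increasing kept time indices
    threshold_mm: float
    n_total: int
    insufficient: bool = False  # too few surviving volumes

    @property
    def n_kept(self) -> int:
        return self.kept.size


@dataclass
class NuisanceDesign:
    columns: np.ndarray  # (T, p)
    labels: list[str]


@dataclass
class PreprocResult:
    clean: Bold4D | None
    censor: CensorMask | None
    fd: FdSeries | None
    excluded: bool
    qc: dict = field(default_factory=dict)


def discard_initial(bold: Bold4D, n_discard: int = 10) -> Bold4D:
    """Drop the first ``n_discard`` volumes (steady-state settling)."""
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if bold.n_volumes <= n_discard:
        raise ValueError(
            f"series too short: {bold.n_volumes} volumes, cannot discard {n_discard}"
        )
    return Bold4D(
        data=bold.data[..., n_discard:], voxel_size_mm=bold.voxel_size_mm, tr_s=bold.tr_s
    )


def smooth_gaussian(bold: Bold4D, fwhm_mm: float = 4.0) -> Bold4D:
    """Isotropic 3D Gaussian smoothing of each volume (reflective boundaries)."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if bold.voxel_size_mm <= 0:
        raise ValueError("voxel size must be positive")
    if fwhm_mm == 0:
        return Bold4D(bold.data.copy(), bold.voxel_size_mm, bold.tr_s)
    sigma_vox = fwhm_mm * _FWHM_TO_SIGMA / bold.voxel_size_mm
    out = ndimage.gaussian_filter(bold.data, sigma=(sigma_vox,) * 3 + (0.0,), mode="reflect")
    return Bold4D(out, bold.voxel_size_mm, bold.tr_s)


def detrend_linear(ts: np.ndarray) -> np.ndarray:
    """Remove the least-squares line from each series (last axis is time)."""
    ts = np.asarray(ts, dtype=np.float64)
    T = ts.shape[-1]
    if T < 3:
        raise ValueError(f"need at least 3 time points to detrend; got {T}")
    t = np.arange(T, dtype=np.float64)
    tc = t - t.mean()
    denom = np.dot(tc, tc)
    mean = ts.mean(axis=-1, keepdims=True)
    slope = (ts @ tc) / denom
    return ts - mean - slope[..., None] * tc


def bandpass(
    ts: np.ndarray,
    tr_s: float,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    transition_hz: float = 0.002,
) -> np.ndarray:
    """Zero-phase band-pass via frequency-domain masking with cosine-tapered
    edges; last axis is time."""
    ts = np.asarray(ts, dtype=np.float64)
    nyquist = 1.0 / (2.0 * tr_s)
    if not 0 <= low_hz < high_hz < nyquist:
        raise ValueError(
            f"band [{low_hz}, {high_hz}] Hz invalid for Nyquist {nyquist:.4f} Hz"
        )
    T = ts.shape[-1]
    freqs = np.fft.rfftfreq(T, d=tr_s)
    w = np.zeros(freqs.size)
    w[(freqs >= low_hz) & (freqs <= high_hz)] = 1.0
    tw = transition_hz
    if tw > 0:
        rise = (freqs >= low_hz - tw) & (freqs < low_hz)
        w[rise] = 0.5 * (1.0 + np.cos(np.pi * (low_hz - freqs[rise]) / tw))
        fall = (freqs > high_hz) & (freqs <= high_hz + tw)
        w[fall] = 0.5 * (1.0 + np.cos(np.pi * (freqs[fall] - high_hz) / tw))
    spec = np.fft.rfft(ts, axis=-1) * w
    return np.fft.irfft(spec, n=T, axis=-1)


def friston24(motion: MotionTrace) -> NuisanceDesign:
    """Friston 24-parameter motion expansion: [p, p(t-1), p^2, p(t-1)^2].

    The first lagged row is set to 0 so the row count stays T.
    """
    p = motion.params
    lag = np.vstack([np.zeros((1, 6)), p[:-1]])
    cols = np.hstack([p, lag, p**2, lag**2])
    names = [f"{kind}_{ax}" for kind in ("mp", "mp_lag", "mp_sq", "mp_lag_sq") for ax in range(6)]
    return NuisanceDesign(columns=cols, labels=names)


def framewise_displacement(motion: MotionTrace, head_radius_mm: float = 50.0) -> FdSeries:
    """Framewise displacement in mm; rotations converted to arc length on a
    sphere of ``head_radius_mm``. FD of the first volume is 0 by definition."""
    p = motion.params
    if p.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute framewise displacement")
    dp = np.abs(np.diff(p, axis=0))
    fd = np.zeros(p.shape[0])
    fd[1:] = dp[:, :3].sum(axis=1) + head_radius_mm * dp[:, 3:].sum(axis=1)
    return FdSeries(fd=fd, mean_fd=float(fd.mean()), head_radius_mm=head_radius_mm)


def qc_exclude(
    motion: MotionTrace, max_trans_mm: float = 2.0, max_rot_deg: float = 2.0
) -> bool:
    """True iff motion *exceeds* (strictly) the translation or rotation limit."""
    trans_ok = np.abs(motion.translations_mm).max() <= max_trans_mm
    rot_deg = np.degrees(np.abs(motion.rotations_rad)).max()
    return not (trans_ok and rot_deg <= max_rot_deg)


def _offending_columns(X: np.ndarray, labels: list[str]) -> list[str]:
    """Columns that add no rank given their predecessors (collinearity culprits)."""
    bad, rank = [], 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r == rank:
            bad.append(labels[j])
        rank = r
    return bad


def nuisance_regress(ts_matrix: np.ndarray, design: NuisanceDesign) -> np.ndarray:
    """Residualize each voxel series (rows of a V x T matrix) on the nuisance
    design plus an intercept. All-zero design columns are inert and dropped;
    collinear non-zero columns raise with the offending labels named."""
    ts_matrix = np.asarray(ts_matrix, dtype=np.float64)
    T = ts_matrix.shape[-1]
    if design.columns.shape[0] != T:
        raise ValueError(
            f"design has {design.columns.shape[0]} rows but series length is {T}"
        )
    norms = np.linalg.norm(design.columns, axis=0)
    keep = norms > 0
    cols = design.columns[:, keep]
    labels = [l for l, k in zip(design.labels, keep) if k]
    X = np.column_stack([np.ones(T), cols])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _offending_columns(X, ["intercept"] + labels)
        raise ValueError(f"rank-deficient nuisance design; offending columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, ts_matrix.T, rcond=None)
    return (ts_matrix.T - X @ beta).T


def scrub(
    ts_matrix: np.ndarray,
    fd: FdSeries,
    threshold_mm: float = 0.2,
    min_volumes: int = 50,
) -> tuple[np.ndarray, CensorMask]:
    """Censor frames with FD strictly above the threshold (order preserved)."""
    ts_matrix = np.asarray(ts_matrix)
    T = ts_matrix.shape[-1]
    if fd.fd.size != T:
        raise ValueError(f"FD length {fd.fd.size} does not match series length {T}")
    kept = np.flatnonzero(fd.fd <= threshold_mm)
    mask = CensorMask(kept=kept, threshold_mm=threshold_mm, n_total=T)
    if kept.size < min_volumes:
        mask.insufficient = True
        warnings.warn(
            f"only {kept.size} volumes survive scrubbing (< {min_volumes}); subject flagged",
            stacklevel=2,
        )
    return ts_matrix[..., kept], mask


def tissue_mean_signal(bold: Bold4D, tissue_mask: np.ndarray) -> np.ndarray:
    """Per-volume mean intensity over the mask voxels."""
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if tissue_mask.shape != bold.grid_shape:
        raise ValueError(
            f"mask shape {tissue_mask.shape} does not match grid {bold.grid_shape}"
        )
    if not tissue_mask.any():
        raise ValueError("tissue mask is empty")
    return bold.data[tissue_mask].mean(axis=0)


def preprocess_subject(
    bold: Bold4D,
    motion: MotionTrace,
    wm_mask: np.ndarray,
    csf_mask: np.ndarray,
    config: PreprocConfig = PreprocConfig(),
) -> PreprocResult:
    """Run the full chain on one subject.

    Motion QC (2 mm / 2 degree rule) is evaluated on the raw trace; excluded
    subjects return early with ``excluded=True`` and no cleaned data.
    """
    if motion.n_volumes != bold.n_volumes:
        raise ValueError(
            f"motion rows ({motion.n_volumes}) != BOLD volumes ({bold.n_volumes})"
        )
    if qc_exclude(motion, config.max_trans_mm, config.max_rot_deg):
        logger.info("subject excluded by the %.0f mm / %.0f deg motion rule",
                    config.max_trans_mm, config.max_rot_deg)
        return PreprocResult(clean=None, censor=None, fd=None, excluded=True,
                             qc={"excluded": True})

    b = discard_initial(bold, config.n_discard)
    m = MotionTrace(params=motion.params[config.n_discard:])

    # tissue nuisance signals come from the *unsmoothed* data (then detrended
    # and filtered like everything else) so gray-matter signal smeared across
    # compartment boundaries by the smoothing kernel cannot contaminate them
    def _tissue_regressor(mask: np.ndarray) -> np.ndarray:
        sig = detrend_linear(tissue_mean_signal(b, mask))
        return bandpass(sig, b.tr_s, config.band_low_hz, config.band_high_hz)

    wm_sig = _tissue_regressor(wm_mask)
    csf_sig = _tissue_regressor(csf_mask)

    b = smooth_gaussian(b, config.fwhm_mm)
    grid = b.grid_shape
    ts = b.data.reshape(-1, b.n_volumes)
    ts = detrend_linear(ts)
    ts = bandpass(ts, b.tr_s, config.band_low_hz, config.band_high_hz)

    design = friston24(m)
    full = NuisanceDesign(
        columns=np.column_stack([design.columns, wm_sig, csf_sig]),
        labels=design.labels + ["wm_mean", "csf_mean"],
    )
    ts = nuisance_regress(ts, full)

    fd = framewise_displacement(m, config.head_radius_mm)
    ts, censor = scrub(ts, fd, config.fd_threshold_mm, config.min_volumes)
    clean = Bold4D(ts.reshape(*grid, -1), b.voxel_size_mm, b.tr_s)
    qc = {
        "excluded": False,
        "mean_fd_mm": fd.mean_fd,
        "n_censored": int(censor.n_total - censor.n_kept),
        "n_kept": int(censor.n_kept),
        "insufficient_volumes": bool(censor.insufficient),
    }
    logger.info("preprocessed subject: %s", qc)
    return PreprocResult(clean=clean, censor=censor, fd=fd, excluded=False, qc=qc)
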