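"""Voxel-wise covariate-adjusted group inference with permutation-based
family-wise error control, cluster reporting, clinical correlation, the
region-pair (ROI-ROI) connectivity test, and summary-statistic tests.

The group model at each voxel is an ordinary least-squares fit of the
Fisher-z GFC value on [intercept, group, mean FD, age]; the reported t is the
group coefficient over its standard error (df = n - p). Family-wise error is
controlled by the maxT permutation method with Freedman-Lane handling of the
nuisance covariates: covariates are regressed out, their residuals permuted,
the covariate fit re-added, and the maximum |t| over voxels recorded per
permutation. FWE p-values use the (1 + #extreme) / (n_perm + 1) estimator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sstats

from .core import Bold4D
from .gfcmetric import GrayMask, fisher_z
from .preproc import tissue_mean_signal

logger = logging.getLogger(__name__)


def build_design(
    group: np.ndarray, mean_fd: np.ndarray, age: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Design matrix [1, group(patient=1), mean FD, age]; group column is 1."""
    group = np.asarray(group, dtype=np.float64)
    n = group.size
    X = np.column_stack([np.ones(n), group, np.asarray(mean_fd, float), np.asarray(age, float)])
    return X, ["intercept", "group", "mean_fd", "age"]


@dataclass
class StatMapResult:
    t: np.ndarray  # per-voxel t statistic for the group coefficient
    df: int
    fwe_p: np.ndarray  # maxT-adjusted p per voxel
    p_uncorrected: np.ndarray  # single-voxel permutation p (same permutations)
    n_perm: int
    seed: int


@dataclass
class ClusterRecord:
    voxels: np.ndarray  # (n, 3) int voxel coordinates
    peak_ijk: tuple[int, int, int]
    n_voxels: int
    peak_t: float
    sign: int  # +1 / -1
    p_fwe_peak: float
    peak_mm: tuple[float, float, float] | None = None


class _Glm:
    """Cached pieces of the voxel-wise OLS fit for one design."""

    def __init__(self, design: np.ndarray, coef_index: int = 1):
        design = np.asarray(design, dtype=np.float64)
        n, p = design.shape
        if np.linalg.matrix_rank(design) < p:
            raise ValueError("design matrix is rank deficient")
        self.X = design
        self.c = coef_index
        self.pinv = np.linalg.pinv(design)
        self.xtx_inv_cc = np.linalg.inv(design.T @ design)[coef_index, coef_index]
        self.df = n - p
        if self.df < 1:
            raise ValueError(f"non-positive degrees of freedom (n={n}, p={p})")

    def t_stats(self, Y: np.ndarray, warn_degenerate: bool = True) -> np.ndarray:
        """t for the contrast coefficient at each column of Y (n x V)."""
        beta = self.pinv @ Y
        resid = Y - self.X @ beta
        sigma2 = (resid**2).sum(axis=0) / self.df
        se = np.sqrt(sigma2 * self.xtx_inv_cc)
        # zero residual variance up to rounding in the data's own scale
        scale = (Y**2).mean(axis=0)
        degenerate = sigma2 <= 1e-20 * np.maximum(scale, 1e-300)
        if degenerate.any() and warn_degenerate:
            warnings.warn(
                f"{int(degenerate.sum())} voxels with zero residual variance; t set to 0",
                stacklevel=2,
            )
        return np.where(degenerate, 0.0, beta[self.c] / np.where(degenerate, 1.0, se))


def voxelwise_glm_t(
    z_maps: np.ndarray, design: np.ndarray, coef_index: int = 1
) -> tuple[np.ndarray, int]:
    """Per-voxel group t statistics from the covariate-adjusted linear model.

    ``z_maps`` is subjects x voxels; ``design`` is subjects x p with the group
    indicator at ``coef_index``. With a two-column [1, group] design this is
    exactly the pooled two-sample t-test.
    """
    Y = np.asarray(z_maps, dtype=np.float64)
    glm = _Glm(design, coef_index)
    groups = np.asarray(design)[:, coef_index]
    for g in np.unique(groups):
        if (groups == g).sum() < 2:
            raise ValueError("each group needs at least 2 subjects")
    return glm.t_stats(Y), glm.df


def permutation_fwe(
    z_maps: np.ndarray,
    design: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    coef_index: int = 1,
    alpha: float = 0.05,
    return_null: bool = False,
) -> StatMapResult | tuple[StatMapResult, np.ndarray]:
    """maxT permutation FWE-adjusted p-values with Freedman-Lane covariates.

    Nuisance covariates (all design columns except the tested one) are fitted
    and their residuals permuted; each permuted dataset is refitted under the
    full model and the maximum |t| over voxels recorded.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if 1.0 / (n_perm + 1) > alpha / 10.0:
        warnings.warn(
            f"n_perm={n_perm} is small for alpha={alpha}; p resolution is 1/{n_perm + 1}",
            stacklevel=2,
        )
    Y = np.asarray(z_maps, dtype=np.float64)
    X = np.asarray(design, dtype=np.float64)
    n = Y.shape[0]
    glm = _Glm(X, coef_index)
    t_obs = glm.t_stats(Y)
    abs_obs = np.abs(t_obs)

    Z = np.delete(X, coef_index, axis=1)
    gamma, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    fit_z = Z @ gamma
    resid_z = Y - fit_z

    rng = np.random.default_rng(seed)
    max_t = np.empty(n_perm)
    exceed = np.zeros(Y.shape[1], dtype=np.int64)
    for j in range(n_perm):
        perm = rng.permutation(n)
        t_perm = np.abs(glm.t_stats(fit_z + resid_z[perm], warn_degenerate=False))
        max_t[j] = t_perm.max()
        exceed += t_perm >= abs_obs
    fwe_p = (1.0 + (max_t[:, None] >= abs_obs[None, :]).sum(axis=0)) / (n_perm + 1.0)
    p_unc = (1.0 + exceed) / (n_perm + 1.0)
    result = StatMapResult(
        t=t_obs, df=glm.df, fwe_p=fwe_p, p_uncorrected=p_unc, n_perm=n_perm, seed=seed
    )
    return (result, max_t) if return_null else result


_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def extract_clusters(
    t: np.ndarray,
    fwe_p: np.ndarray,
    mask: GrayMask,
    alpha: float = 0.05,
    connectivity: int = 26,
    affine: np.ndarray | None = None,
) -> list[ClusterRecord]:
    """Connected components of suprathreshold voxels, separately per t sign.

    Sorted by |peak t| descending; ties broken by lexicographic peak
    coordinate. Peak mm coordinates are emitted only when an affine is given.
    """
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])
    t_vol = mask.to_volume(t, fill=0.0)
    p_vol = mask.to_volume(fwe_p, fill=1.0)
    records: list[ClusterRecord] = []
    for sign in (1, -1):
        sig = (p_vol < alpha) & (np.sign(t_vol) == sign) & mask.mask
        labeled, n_comp = ndimage.label(sig, structure=structure)
        for comp in range(1, n_comp + 1):
            vox = np.argwhere(labeled == comp)
            tv = t_vol[tuple(vox.T)]
            best = np.abs(tv).max()
            candidates = vox[np.abs(tv) >= best - 1e-12]
            order = np.lexsort(candidates.T[::-1])  # lexicographic by (x, y, z)
            peak = tuple(int(v) for v in candidates[order[0]])
            peak_mm = None
            if affine is not None:
                hom = affine @ np.array([*peak, 1.0])
                peak_mm = tuple(float(v) for v in hom[:3])
            records.append(
                ClusterRecord(
                    voxels=vox,
                    peak_ijk=peak,
                    n_voxels=int(vox.shape[0]),
                    peak_t=float(t_vol[peak]),
                    sign=sign,
                    p_fwe_peak=float(p_vol[peak]),
                    peak_mm=peak_mm,
                )
            )
    records.sort(key=lambda r: (-abs(r.peak_t), r.peak_ijk))
    return records


def cluster_mean_feature(
    z_maps: np.ndarray, mask: GrayMask, cluster: ClusterRecord
) -> np.ndarray:
    """Per-subject mean z over the cluster voxels."""
    if cluster.n_voxels < 1:
        raise ValueError("cluster is empty")
    cols = mask.lookup[tuple(cluster.voxels.T)]
    if np.any(cols < 0):
        raise ValueError("cluster contains voxels outside the gray-matter mask")
    return np.asarray(z_maps, dtype=np.float64)[:, cols].mean(axis=1)


# ---------------------------------------------------------------------------
# scalar statistics


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-tailed p for a sample Pearson r via t = r*sqrt((n-2)/(1-r^2))."""
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sstats.t.sf(abs(t), df=n - 2))


def pearson_r_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson correlation and its two-tailed t-based p-value."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 4:
        raise ValueError("need equal-length inputs with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    return r, pearson_p_from_r(r, x.size)


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Bonferroni-adjusted per-test significance level alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def ttest_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int, pooled: bool = True
) -> tuple[float, float, float]:
    """Two-sample t-test from group means, SDs and sizes.

    Pooled (Student) variance by default; returns (t, df, two-tailed p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 per group")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("SDs must be positive")
    if pooled:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        v1, v2 = s1**2 / n1, s2**2 / n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    t = (m1 - m2) / se
    p = 2.0 * sstats.t.sf(abs(t), df=df)
    return float(t), float(df), float(p)


def chi2_2x2(
    a: int, b: int, c: int, d: int, continuity: bool = False
) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]] (no Yates correction
    by default); returns (chi2, df=1, p)."""
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("table has a zero margin")
    delta = abs(a * d - b * c)
    if continuity:
        delta = max(delta - n / 2.0, 0.0)
    chi2 = n * delta**2 / np.prod([float(m) for m in margins])
    return float(chi2), 1, float(sstats.chi2.sf(chi2, df=1))


def shapiro_normality(x: np.ndarray) -> tuple[float, float]:
    """Shapiro-Wilk normality check (W, p); a gate, not a fidelity claim."""
    w, p = sstats.shapiro(np.asarray(x, dtype=np.float64))
    return float(w), float(p)


@dataclass
class RoiFcResult:
    z: np.ndarray  # per-subject Fisher-z ROI-ROI correlation
    t: float
    df: float
    p: float
    group_means: dict = field(default_factory=dict)


def roi_fc_group_test(
    bolds: list[Bold4D],
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    groups: np.ndarray,
) -> RoiFcResult:
    """Group comparison of the functional connectivity between two regions.

    Per subject: Pearson r between the two mask-mean series, Fisher z; then a
    pooled two-sample t-test of z across groups (patient = 1).
    """
    groups = np.asarray(groups)
    if len(bolds) != groups.size:
        raise ValueError("one group label per subject required")
    zs = np.empty(len(bolds))
    for i, bold in enumerate(bolds):
        sa = tissue_mean_signal(bold, mask_a)
        sb = tissue_mean_signal(bold, mask_b)
        if sa.std() == 0 or sb.std() == 0:
            raise ValueError(f"degenerate (constant) region-mean series for subject {i}")
        r = float(np.corrcoef(sa, sb)[0, 1])
        zs[i] = fisher_z(max(-1.0, min(1.0, r)))
    pat, con = zs[groups == 1], zs[groups == 0]
    if pat.size < 2 or con.size < 2:
        raise ValueError("each group needs at least 2 subjects")
    if pat.std(ddof=1) == 0 and con.std(ddof=1) == 0:
        # degenerate: no within-group variability at all
        equal = pat.mean() == con.mean()
        t = 0.0 if equal else float(np.sign(pat.mean() - con.mean()) * np.inf)
        df = float(pat.size + con.size - 2)
        p = 1.0 if equal else 0.0
    else:
        t, df, p = ttest_from_summary(
            pat.mean(), pat.std(ddof=1), pat.size, con.mean(), con.std(ddof=1), con.size
        )
    return RoiFcResult(
        z=zs, t=t, df=df, p=p,
        group_means={"patient": float(pat.mean()), "control": float(con.mean())},
    )
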