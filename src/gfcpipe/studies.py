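"""Replicate simulation studies: error-rate calibration, planted-effect
recovery, and classifier sanity checks.

These run many seeded synthetic cohorts through the GFC -> group-inference
chain (via :func:`gfcpipe.pipeline.cohort_zmaps`, the reduced detrend +
standardize route) and summarize detection and false-positive behaviour.
Seeds are spawned deterministically from a single master seed.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .classify import FeatureTable, svm_loo, svm_permutation_test
from .gfcmetric import gray_matter_mask
from .groupstats import cluster_mean_feature, extract_clusters, permutation_fwe, pearson_r_p
from .pipeline import cohort_design, cohort_zmaps
from .simdata import SimConfig, generate_cohort

logger = logging.getLogger(__name__)

_MOD = 2**31


def _child_seeds(seed: int, n: int, salt: int = 0) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([seed, salt]))
    return rng.integers(0, _MOD, size=n)


def fwe_calibration_study(
    n_replicates: int = 200,
    seed: int = 0,
    n_perm: int = 500,
    n_subjects: int = 20,
    alpha: float = 0.05,
    base_config: SimConfig | None = None,
) -> dict:
    """Family-wise false-positive rate of the permutation maxT procedure.

    Each replicate generates a null cohort (``effect_delta = 0``), computes
    per-subject GFC z-maps, runs the covariate-adjusted permutation test, and
    records whether any voxel reaches FWE p < alpha.
    """
    if base_config is None:
        base_config = SimConfig()
    base = dataclasses.replace(
        base_config,
        effect_delta=0.0,
        n_patients=n_subjects // 2,
        n_controls=n_subjects - n_subjects // 2,
    )
    seeds = _child_seeds(seed, 2 * n_replicates, salt=1)
    false_positives = 0
    for rep in range(n_replicates):
        cfg = dataclasses.replace(base, seed=int(seeds[2 * rep]))
        subjects, truth = generate_cohort(cfg)
        gm = gray_matter_mask(truth.gm_prob, 0.2)
        maps = cohort_zmaps(subjects, gm)
        design, _ = cohort_design(subjects)
        res = permutation_fwe(maps, design, n_perm=n_perm, seed=int(seeds[2 * rep + 1]),
                              alpha=alpha)
        false_positives += bool(np.any(res.fwe_p < alpha))
    rate = false_positives / n_replicates
    logger.info("FWE calibration: %d/%d replicates with a false positive (rate %.3f)",
                false_positives, n_replicates, rate)
    return {"rate": rate, "n_replicates": n_replicates, "alpha": alpha, "n_perm": n_perm}


def recovery_study(
    n_replicates: int = 50,
    seed: int = 0,
    n_perm: int = 500,
    effect_delta: float = 0.4,
    alpha: float = 0.05,
    base_config: SimConfig | None = None,
) -> dict:
    """Planted-effect recovery across replicate cohorts.

    Per replicate: (a) every planted cluster contains a voxel at FWE p <
    alpha, (b) the extracted per-subject feature of the strongest detected
    cluster is lower in patients, and (c) the patient feature-score Pearson
    correlation is negative.
    """
    if base_config is None:
        base_config = SimConfig()
    base = dataclasses.replace(base_config, effect_delta=effect_delta)
    seeds = _child_seeds(seed, 2 * n_replicates, salt=2)
    detected = feature_lower = corr_negative = all_three = 0
    for rep in range(n_replicates):
        cfg = dataclasses.replace(base, seed=int(seeds[2 * rep]))
        subjects, truth = generate_cohort(cfg)
        gm = gray_matter_mask(truth.gm_prob, 0.2)
        maps = cohort_zmaps(subjects, gm)
        design, _ = cohort_design(subjects)
        res = permutation_fwe(maps, design, n_perm=n_perm, seed=int(seeds[2 * rep + 1]),
                              alpha=alpha)
        ok_detect = all(
            np.min(res.fwe_p[gm.lookup[tuple(vox.T)]]) < alpha
            for vox in truth.cluster_voxels
        )
        clusters = extract_clusters(res.t, res.fwe_p, gm, alpha=alpha)
        negatives = [c for c in clusters if c.sign < 0]
        ok_lower = ok_corr = False
        if negatives:
            feature = cluster_mean_feature(maps, gm, negatives[0])
            patients = np.array([s.group == "patient" for s in subjects])
            ok_lower = feature[patients].mean() < feature[~patients].mean()
            scores = np.array([s.score for s in subjects])[patients]
            r, _ = pearson_r_p(feature[patients], scores)
            ok_corr = r < 0
        detected += ok_detect
        feature_lower += ok_lower
        corr_negative += ok_corr
        all_three += ok_detect and ok_lower and ok_corr
    n = n_replicates
    out = {
        "detection_rate": detected / n,
        "feature_direction_rate": feature_lower / n,
        "correlation_sign_rate": corr_negative / n,
        "joint_rate": all_three / n,
        "n_replicates": n,
        "effect_delta": effect_delta,
    }
    logger.info("recovery study: %s", out)
    return out


def separable_classifier_case(
    seed: int = 0, n_per_class: int = 10, n_perm: int = 1000
) -> dict:
    """Wide-margin separable 1-D feature: LOO metrics and permutation p."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    patients = rng.normal(-3.0, 0.2, n_per_class)
    controls = rng.normal(3.0, 0.2, n_per_class)
    x = np.concatenate([patients, controls])[:, None]
    labels = np.concatenate([np.ones(n_per_class, bool), np.zeros(n_per_class, bool)])
    ids = [f"s{i}" for i in range(2 * n_per_class)]
    ft = FeatureTable(x=x, ids=ids, labels=labels)
    report = svm_loo(ft)
    obs, p, null = svm_permutation_test(ft, n_perm=n_perm, seed=seed)
    return {
        "accuracy": report.accuracy,
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "perm_p": p,
        "null_mean_accuracy": float(null.mean()),
    }


def classifier_chance_study(n_seeds: int = 200, seed: int = 0, n: int = 40) -> dict:
    """LOO accuracy on pure-noise features with randomly assigned labels."""
    seeds = _child_seeds(seed, n_seeds, salt=4)
    accs = np.empty(n_seeds)
    for i in range(n_seeds):
        rng = np.random.default_rng(seeds[i])
        x = rng.normal(size=(n, 1))
        while True:
            labels = rng.random(n) < 0.5
            if 2 <= labels.sum() <= n - 2:
                break
        ft = FeatureTable(x=x, ids=[f"s{j}" for j in range(n)], labels=labels)
        accs[i] = svm_loo(ft).accuracy
    mean = float(accs.mean())
    se = float(accs.std(ddof=1) / np.sqrt(n_seeds))
    return {"mean_accuracy": mean, "se": se, "n_seeds": n_seeds, "n": n}
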