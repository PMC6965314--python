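"""Experiment orchestration: staged execution from (optionally simulated)
cohort on disk to stat maps, cluster table, clinical correlations and the
classifier report.

Each stage reads its inputs from, and writes its artifacts to, the configured
directories, so the command-line subcommands compose; :func:`run_experiment`
chains all stages and returns the combined report.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .classify import FeatureTable, svm_kfold, svm_loo, svm_permutation_test
from .gfcmetric import GrayMask, fisher_z, gfc_fast, gfc_subject, gray_matter_mask, standardize
from .groupstats import (
    bonferroni_threshold,
    cluster_mean_feature,
    extract_clusters,
    pearson_r_p,
    permutation_fwe,
    roi_fc_group_test,
    build_design,
    shapiro_normality,
)
from .io import RunConfig
from .preproc import framewise_displacement, preprocess_subject, detrend_linear
from .simdata import SyntheticSubject, generate_cohort, write_cohort

logger = logging.getLogger(__name__)


def cohort_zmaps(
    subjects: list[SyntheticSubject], gm: GrayMask, detrend: bool = True
) -> np.ndarray:
    """Fisher-z GFC maps (subjects x V) straight from generated series.

    A reduced chain (linear detrend + standardization only) used by the
    replicate simulation studies, where the planted signals are already
    band-limited and motion artifacts are not injected into the BOLD model.
    """
    maps = np.empty((len(subjects), gm.n_voxels))
    for i, s in enumerate(subjects):
        ts = gm.extract(s.bold.data)
        if detrend:
            ts = detrend_linear(ts)
        std, zero_var = standardize(ts)
        if zero_var.any():
            raise ValueError("unexpected zero-variance voxel in generated data")
        maps[i] = fisher_z(gfc_fast(std))
    return maps


def cohort_design(subjects: list[SyntheticSubject], head_radius_mm: float = 50.0):
    """Group design [1, group, mean FD, age] straight from subject objects."""
    group = np.array([1.0 if s.group == "patient" else 0.0 for s in subjects])
    mean_fd = np.array(
        [framewise_displacement(s.motion, head_radius_mm).mean_fd for s in subjects]
    )
    age = np.array([s.age for s in subjects])
    return build_design(group, mean_fd, age)


# ---------------------------------------------------------------------------
# staged execution on disk


def stage_simulate(cfg: RunConfig) -> dict:
    if cfg.simulate is None:
        raise ValueError("configuration has no simulate section")
    import dataclasses

    sim = dataclasses.replace(cfg.simulate, seed=cfg.simulate.seed + cfg.seed)
    subjects, truth = generate_cohort(sim)
    manifest = write_cohort(subjects, truth, cfg.cohort_dir, overwrite=True)
    return {"n_subjects": len(subjects), "files": sum(len(v) for v in manifest.values())}


def _subject_table(cfg: RunConfig) -> pd.DataFrame:
    return gio.read_participants(Path(cfg.cohort_dir) / "participants.tsv")


def stage_preprocess(cfg: RunConfig) -> dict:
    root = Path(cfg.cohort_dir)
    out = Path(cfg.out_dir) / "preproc"
    out.mkdir(parents=True, exist_ok=True)
    table = _subject_table(cfg)
    wm = gio.read_volume(root / "tissue" / "wm_prob.nii.gz") > 0.8
    csf = gio.read_volume(root / "tissue" / "csf_prob.nii.gz") > 0.8
    qc_all: dict[str, dict] = {}
    mean_fd, excluded, usable = [], [], []
    for row in table.itertuples(index=False):
        bold = gio.read_bold(root / f"{row.id}_bold.nii.gz")
        motion = gio.read_motion(root / f"{row.id}_motion.txt", n_volumes=bold.n_volumes)
        res = preprocess_subject(bold, motion, wm, csf, cfg.preproc)
        qc_all[row.id] = res.qc
        excluded.append(res.excluded)
        if res.excluded:
            mean_fd.append(float("nan"))
            usable.append(False)
            continue
        mean_fd.append(res.fd.mean_fd)
        usable.append(not res.censor.insufficient)
        gio.write_bold(res.clean, out / f"{row.id}_clean.nii.gz",
                       descrip=f"hash={cfg.config_hash()}")
    table = table.assign(mean_fd=mean_fd, excluded=excluded, usable=usable)
    gio.write_participants(
        table, Path(cfg.out_dir) / "participants_qc.tsv",
        meta=f"config_hash={cfg.config_hash()} seed={cfg.seed}",
    )
    (out / "qc.json").write_text(json.dumps(qc_all, indent=2))
    n_drop = int(np.sum(~np.array(usable)))
    logger.info("preprocessing complete: %d subjects, %d excluded/flagged",
                len(table), n_drop)
    return {"n_subjects": len(table), "n_excluded": n_drop}


def _usable_table(cfg: RunConfig) -> pd.DataFrame:
    table = gio.read_participants(Path(cfg.out_dir) / "participants_qc.tsv")
    return table[table["usable"]].reset_index(drop=True)


def stage_gfc(cfg: RunConfig) -> dict:
    root = Path(cfg.cohort_dir)
    pre = Path(cfg.out_dir) / "preproc"
    out = Path(cfg.out_dir) / "gfc"
    out.mkdir(parents=True, exist_ok=True)
    gm_prob = gio.read_volume(root / "tissue" / "gm_prob.nii.gz")
    mask = gray_matter_mask(gm_prob, cfg.gfc.gm_threshold)
    table = _usable_table(cfg)
    voxel_size = None
    for row in table.itertuples(index=False):
        bold = gio.read_bold(pre / f"{row.id}_clean.nii.gz")
        voxel_size = bold.voxel_size_mm
        gmap = gfc_subject(bold, mask, censor=None, min_volumes=cfg.gfc.min_volumes)
        gio.write_volume(gmap.z_volume(), bold.voxel_size_mm,
                         out / f"{row.id}_gfc_z.nii.gz")
    gio.write_volume(mask.mask.astype(np.float64), voxel_size or 1.0,
                     out / "gray_mask.nii.gz")
    return {"n_maps": len(table), "n_gray_voxels": mask.n_voxels}


def _load_zmaps(cfg: RunConfig) -> tuple[pd.DataFrame, GrayMask, np.ndarray, float]:
    out = Path(cfg.out_dir) / "gfc"
    mask_vol = gio.read_volume(out / "gray_mask.nii.gz") > 0.5
    mask = GrayMask(mask=mask_vol, threshold=cfg.gfc.gm_threshold)
    table = _usable_table(cfg)
    maps = np.empty((len(table), mask.n_voxels))
    voxel = 3.0
    for i, row in enumerate(table.itertuples(index=False)):
        path = out / f"{row.id}_gfc_z.nii.gz"
        import nibabel as nib

        img = nib.load(str(path))
        voxel = float(img.header.get_zooms()[0])
        maps[i] = np.asarray(img.dataobj, dtype=np.float64)[mask.mask]
    return table, mask, maps, voxel


def stage_group(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir) / "group"
    out.mkdir(parents=True, exist_ok=True)
    table, mask, maps, voxel = _load_zmaps(cfg)
    group = (table["group"] == "patient").to_numpy(dtype=np.float64)
    design, _ = build_design(group, table["mean_fd"].to_numpy(), table["age"].to_numpy())
    result = permutation_fwe(
        maps, design, n_perm=cfg.group.n_perm, seed=cfg.seed, alpha=cfg.group.alpha
    )
    clusters = extract_clusters(
        result.t, result.fwe_p, mask, alpha=cfg.group.alpha,
        connectivity=cfg.group.connectivity,
        affine=np.diag([voxel, voxel, voxel, 1.0]),
    )
    gio.write_volume(mask.to_volume(result.t, fill=0.0), voxel, out / "t_map.nii.gz")
    gio.write_volume(mask.to_volume(result.fwe_p, fill=1.0), voxel, out / "fwe_p.nii.gz")
    rows = []
    for i, c in enumerate(clusters):
        rows.append(
            {
                "cluster": i + 1,
                "peak_x": c.peak_ijk[0], "peak_y": c.peak_ijk[1], "peak_z": c.peak_ijk[2],
                "peak_x_mm": c.peak_mm[0] if c.peak_mm else float("nan"),
                "peak_y_mm": c.peak_mm[1] if c.peak_mm else float("nan"),
                "peak_z_mm": c.peak_mm[2] if c.peak_mm else float("nan"),
                "n_voxels": c.n_voxels, "peak_t": c.peak_t, "p_fwe": c.p_fwe_peak,
                "sign": c.sign,
            }
        )
    cluster_table = pd.DataFrame(
        rows, columns=["cluster", "peak_x", "peak_y", "peak_z", "peak_x_mm", "peak_y_mm",
                       "peak_z_mm", "n_voxels", "peak_t", "p_fwe", "sign"],
    )
    with open(out / "clusters.tsv", "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        cluster_table.to_csv(fh, sep="\t", index=False)
    (out / "cluster_voxels.json").write_text(
        json.dumps([c.voxels.tolist() for c in clusters])
    )

    report: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_perm": cfg.group.n_perm,
        "alpha": cfg.group.alpha,
        "df": result.df,
        "n_clusters": len(clusters),
        "clusters": rows,
    }
    # region-pair FC test between the two strongest clusters (when present),
    # computed on the preprocessed series
    if len(clusters) >= 2:
        pre = Path(cfg.out_dir) / "preproc"
        bolds = [gio.read_bold(pre / f"{r.id}_clean.nii.gz")
                 for r in table.itertuples(index=False)]
        mask_a = np.zeros(mask.mask.shape, dtype=bool)
        mask_a[tuple(clusters[0].voxels.T)] = True
        mask_b = np.zeros(mask.mask.shape, dtype=bool)
        mask_b[tuple(clusters[1].voxels.T)] = True
        roi = roi_fc_group_test(bolds, mask_a, mask_b, group)
        report["roi_fc"] = {"t": roi.t, "df": roi.df, "p": roi.p,
                            "group_means": roi.group_means}
    (out / "group_report.json").write_text(json.dumps(report, indent=2))
    return report


def _load_clusters(cfg: RunConfig) -> list:
    out = Path(cfg.out_dir) / "group"
    table = pd.read_csv(out / "clusters.tsv", sep="\t", comment="#")
    voxel_sets = json.loads((out / "cluster_voxels.json").read_text())
    from .groupstats import ClusterRecord

    clusters = []
    for row, vox in zip(table.itertuples(index=False), voxel_sets):
        clusters.append(
            ClusterRecord(
                voxels=np.asarray(vox, dtype=np.int64),
                peak_ijk=(int(row.peak_x), int(row.peak_y), int(row.peak_z)),
                n_voxels=int(row.n_voxels), peak_t=float(row.peak_t),
                sign=int(row.sign), p_fwe_peak=float(row.p_fwe),
            )
        )
    return clusters


def stage_correlate(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir) / "correlate"
    out.mkdir(parents=True, exist_ok=True)
    table, mask, maps, _ = _load_zmaps(cfg)
    clusters = _load_clusters(cfg)
    patients = (table["group"] == "patient").to_numpy()
    scores = table["score"].to_numpy(dtype=np.float64)
    results = []
    m = max(len(clusters), 1)
    threshold = bonferroni_threshold(cfg.group.alpha, m)
    for i, cluster in enumerate(clusters):
        feature = cluster_mean_feature(maps, mask, cluster)
        x = feature[patients]
        y = scores[patients]
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 4:
            continue
        r, p = pearson_r_p(x[ok], y[ok])
        w, p_norm = shapiro_normality(x[ok])
        scatter = pd.DataFrame({"id": table["id"][patients][ok],
                                "feature": x[ok], "score": y[ok]})
        with open(out / f"cluster_{i + 1:02d}_scatter.tsv", "w") as fh:
            fh.write(f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n")
            scatter.to_csv(fh, sep="\t", index=False)
        results.append(
            {"cluster": i + 1, "r": r, "p": p, "n": int(ok.sum()),
             "significant_bonferroni": bool(p < threshold),
             "shapiro_w": w, "shapiro_p": p_norm}
        )
    report = {
        "config_hash": cfg.config_hash(), "seed": cfg.seed,
        "bonferroni_threshold": threshold, "correlations": results,
    }
    (out / "correlations.json").write_text(json.dumps(report, indent=2))
    return report


def stage_classify(cfg: RunConfig) -> dict:
    out = Path(cfg.out_dir) / "classify"
    out.mkdir(parents=True, exist_ok=True)
    table, mask, maps, _ = _load_zmaps(cfg)
    clusters = _load_clusters(cfg)
    labels = (table["group"] == "patient").to_numpy()
    ids = list(table["id"])
    reports = []
    feat_cols = {}
    for i, cluster in enumerate(clusters):
        feature = cluster_mean_feature(maps, mask, cluster)
        feat_cols[f"cluster_{i + 1}"] = feature
        ft = FeatureTable(x=feature[:, None], ids=ids, labels=labels,
                          feature_names=[f"cluster_{i + 1}"])
        loo = svm_loo(ft, C=cfg.classify.C)
        kf = svm_kfold(ft, k=cfg.classify.k, seed=cfg.seed, C=cfg.classify.C)
        obs, perm_p, _ = svm_permutation_test(
            ft, n_perm=cfg.classify.n_perm_svm, seed=cfg.seed, C=cfg.classify.C
        )
        reports.append(
            {
                "feature": f"cluster_{i + 1}",
                "loo": {"accuracy": loo.accuracy, "sensitivity": loo.sensitivity,
                        "specificity": loo.specificity,
                        "balanced_accuracy": loo.balanced_accuracy},
                "kfold": {"k": cfg.classify.k, "accuracy": kf.accuracy,
                          "balanced_accuracy": kf.balanced_accuracy},
                "permutation": {"n_perm": cfg.classify.n_perm_svm,
                                "observed_accuracy": obs, "p": perm_p},
            }
        )
    if feat_cols:
        features = pd.DataFrame({"id": ids, "group": table["group"], **feat_cols})
        with open(out / "features.tsv", "w") as fh:
            fh.write(f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n")
            features.to_csv(fh, sep="\t", index=False)
    report = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "classifiers": reports}
    (out / "classifier_report.json").write_text(json.dumps(report, indent=2))
    return report


def run_experiment(cfg: RunConfig) -> dict:
    """Execute simulate (optional) -> preprocess -> gfc -> group -> correlate
    -> classify, writing all artifacts plus a provenance log."""
    t0 = time.time()
    report: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "stages": {}}
    stages = []
    if cfg.simulate is not None:
        stages.append(("simulate", stage_simulate))
    stages += [
        ("preprocess", stage_preprocess),
        ("gfc", stage_gfc),
        ("group", stage_group),
        ("correlate", stage_correlate),
        ("classify", stage_classify),
    ]
    for name, fn in stages:
        start = time.time()
        try:
            report["stages"][name] = fn(cfg)
        except Exception as err:
            raise RuntimeError(f"stage '{name}' failed: {err}") from err
        logger.info("stage %-10s done in %.1f s", name, time.time() - start)
    report["elapsed_s"] = time.time() - t0
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import gfcpipe

    provenance = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "version": gfcpipe.__version__,
        "config": cfg.to_dict(),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
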