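"""Seeded synthetic resting-state cohorts with known planted connectivity effects.

The generator emulates the study conditions the pipeline is built for: two
groups (patients / controls), 250 volumes at TR = 2 s on a small 3 mm grid,
a latent-signal BOLD model in which one or two compact gray-matter clusters
have reduced global coupling in patients, motion traces with occasional
framewise-displacement spikes, and a clinical severity score negatively
related to the planted cluster coupling.

BOLD model
----------
Each subject carries ``n_latents`` band-limited (0.01-0.08 Hz) latent signals
of unit variance, synthesized in the frequency domain with random phases.
Latent 1 is global: every gray-matter voxel i follows

    y_i(t) = w_i * g_1(t) + sector/compartment terms + drift + noise

with w_i = ``baseline_coupling`` everywhere except the planted cluster
voxels, where w_i equals the subject's coupling value c_s.  Controls draw
c_s around ``baseline_coupling``; patients around
``baseline_coupling - effect_delta`` (both jittered by
``coupling_jitter_sd``), so patients' cluster voxels correlate less with the
rest of gray matter — exactly the signature the GFC statistic measures.
Remaining latents load on disjoint angular sectors of gray matter to provide
network-like structure; white matter and CSF compartments carry their own
shared signals so nuisance regression has genuine tissue signals to remove.

The clinical score is ``score_mean + score_slope * (c_s - E[c_s])`` plus
truncated-normal noise, planting a negative coupling-score relationship when
``score_slope`` is negative.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .core import Bold4D, MotionTrace

logger = logging.getLogger(__name__)

GROUP_PATIENT = "patient"
GROUP_CONTROL = "control"

# Fixed structural constants of the simulated head. Sector/compartment
# couplings are deliberately weaker than the global latent so the planted
# group effect dominates the cluster voxels' connectivity profile.
_SECTOR_COUPLING = 0.3
_WM_COUPLING = 0.5
_CSF_COUPLING = 0.5
_BASELINE_INTENSITY = 100.0
_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI = 39.0, 9.0, 18.0, 60.0
_P_MALE = 0.4
_MOTION_STEP_TRANS_MM = 0.005
_MOTION_STEP_ROT_RAD = 5e-5
_MOTION_SPIKE_MM = 0.3


@dataclass(frozen=True)
class SimConfig:
    """Cohort generation parameters; identical configs yield identical cohorts."""

    n_patients: int = 19
    n_controls: int = 21
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 3.0
    n_volumes: int = 250
    tr_s: float = 2.0
    n_latents: int = 3
    baseline_coupling: float = 0.6
    effect_delta: float = 0.3
    # (center voxel, radius in voxels); defaults are two ~19-voxel spheres in
    # the gray-matter shell, echoing the scale of the reported clusters.
    cluster_specs: tuple[tuple[tuple[int, int, int], float], ...] = (
        ((9, 5, 5), 1.5),
        ((2, 6, 6), 1.5),
    )
    noise_sd: float = 1.0
    coupling_jitter_sd: float = 0.08
    drift_sd: float = 0.3
    motion_spike_rate: float = 0.02
    score_slope: float = -50.0
    score_noise_sd: float = 4.45
    score_mean: float = 16.32
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0 or self.n_controls <= 0:
            raise ValueError("subject counts must be positive")
        if self.n_volumes <= 0 or self.n_latents <= 0:
            raise ValueError("n_volumes and n_latents must be positive")
        if self.tr_s <= 0 or self.voxel_size_mm <= 0:
            raise ValueError("tr_s and voxel_size_mm must be positive")
        if not 0.0 <= self.baseline_coupling <= 1.0:
            raise ValueError("baseline_coupling must lie in [0, 1]")
        if self.effect_delta < 0 or self.baseline_coupling - self.effect_delta < 0:
            raise ValueError("require 0 <= effect_delta <= baseline_coupling")
        if not 0.0 <= self.motion_spike_rate <= 1.0:
            raise ValueError("motion_spike_rate must be a probability")
        if len(self.grid_shape) != 3 or any(s < 2 for s in self.grid_shape):
            raise ValueError("grid_shape must be three voxel counts >= 2")
        for center, radius in self.cluster_specs:
            if radius <= 0:
                raise ValueError("cluster radius must be positive")
            if any(dim < 2 * radius for dim in self.grid_shape):
                raise ValueError(
                    f"degenerate grid: dimension smaller than cluster diameter {2 * radius}"
                )
            if any(not 0 <= c < dim for c, dim in zip(center, self.grid_shape)):
                raise ValueError(f"cluster center {center} outside grid {self.grid_shape}")
        freqs = np.fft.rfftfreq(self.n_volumes, d=self.tr_s)
        if not np.any((freqs >= 0.01) & (freqs <= 0.08)):
            raise ValueError("no frequency bin falls in the 0.01-0.08 Hz band")


@dataclass
class SyntheticSubject:
    id: str
    group: str
    age: float
    sex: str
    score: float  # NaN for controls (severity is only rated in patients)
    bold: Bold4D
    motion: MotionTrace


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    cluster_voxels: list[np.ndarray]  # per cluster, (n_i, 3) int voxel coords
    coupling: dict[str, float]  # subject id -> planted cluster coupling c_s
    score_slope: float
    gm_prob: np.ndarray
    wm_prob: np.ndarray
    csf_prob: np.ndarray
    config: SimConfig
    # per-subject global latent g_1 (kept in memory only; not serialized)
    global_latents: dict[str, np.ndarray] = field(default_factory=dict)


def tissue_probability_maps(
    grid_shape: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gray/white/CSF probability volumes as three disjoint concentric shells.

    White matter forms the core (normalized ellipsoidal radius <= 0.40), gray
    matter the mid shell (0.40, 0.85], CSF the outer rim (0.85, 1.0]; outside
    the head all probabilities are zero.
    """
    idx = np.indices(grid_shape, dtype=np.float64)
    rho2 = np.zeros(grid_shape)
    for ax, dim in enumerate(grid_shape):
        center = (dim - 1) / 2.0
        semi = max((dim - 1) / 2.0, 1.0)
        rho2 += ((idx[ax] - center) / semi) ** 2
    rho = np.sqrt(rho2)
    wm = rho <= 0.40
    gm = (rho > 0.40) & (rho <= 0.85)
    csf = (rho > 0.85) & (rho <= 1.0)
    head = rho <= 1.0
    gm_prob = np.where(gm, 0.9, np.where(head, 0.03, 0.0))
    wm_prob = np.where(wm, 0.9, np.where(head, 0.03, 0.0))
    csf_prob = np.where(csf, 0.9, np.where(head, 0.03, 0.0))
    return gm_prob, wm_prob, csf_prob


def _cluster_voxel_sets(config: SimConfig, gm: np.ndarray) -> list[np.ndarray]:
    """Voxel coordinates of each planted cluster, clipped to gray matter."""
    idx = np.indices(config.grid_shape)
    sets: list[np.ndarray] = []
    taken = np.zeros(config.grid_shape, dtype=bool)
    for center, radius in config.cluster_specs:
        d2 = sum((idx[ax] - center[ax]) ** 2 for ax in range(3))
        sphere = (d2 <= radius**2) & gm
        if not sphere.any():
            raise ValueError(f"cluster at {center} has no gray-matter voxels")
        if (sphere & taken).any():
            raise ValueError("cluster specifications overlap")
        taken |= sphere
        sets.append(np.argwhere(sphere))
    return sets


def _band_limited_signal(
    rng: np.random.Generator, n: int, tr_s: float, low_hz: float = 0.01, high_hz: float = 0.08
) -> np.ndarray:
    """Unit-variance signal with power confined to [low_hz, high_hz]."""
    freqs = np.fft.rfftfreq(n, d=tr_s)
    in_band = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.zeros(freqs.size, dtype=np.complex128)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=int(in_band.sum()))
    spec[in_band] = np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0:
        raise ValueError("band-limited signal degenerate (no usable frequency bin)")
    return x / sd


def _sector_assignment(config: SimConfig, gm: np.ndarray, cluster_union: np.ndarray) -> np.ndarray:
    """Assign non-cluster gray voxels to n_latents-1 azimuthal sectors (-1 = none)."""
    sectors = np.full(config.grid_shape, -1, dtype=np.int64)
    n_sectors = config.n_latents - 1
    if n_sectors <= 0:
        return sectors
    idx = np.indices(config.grid_shape, dtype=np.float64)
    cx = (config.grid_shape[0] - 1) / 2.0
    cy = (config.grid_shape[1] - 1) / 2.0
    theta = np.arctan2(idx[1] - cy, idx[0] - cx)  # (-pi, pi]
    bucket = np.floor((theta + np.pi) / (2.0 * np.pi) * n_sectors).astype(np.int64)
    bucket = np.clip(bucket, 0, n_sectors - 1)
    eligible = gm & ~cluster_union
    sectors[eligible] = bucket[eligible]
    return sectors


def _motion_trace(rng: np.random.Generator, config: SimConfig) -> MotionTrace:
    T = config.n_volumes
    steps = np.concatenate(
        [
            rng.normal(0.0, _MOTION_STEP_TRANS_MM, size=(T, 3)),
            rng.normal(0.0, _MOTION_STEP_ROT_RAD, size=(T, 3)),
        ],
        axis=1,
    )
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    # single-frame displacement spikes large enough to exceed FD 0.2 mm
    spike = rng.random(T) < config.motion_spike_rate
    spike[0] = False
    axes = rng.integers(0, 3, size=T)
    for t in np.flatnonzero(spike):
        params[t, axes[t]] += _MOTION_SPIKE_MM * rng.choice([-1.0, 1.0])
    return MotionTrace(params=params)


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _simulate_bold(
    rng: np.random.Generator,
    config: SimConfig,
    geometry: dict,
    coupling: float,
) -> tuple[Bold4D, np.ndarray]:
    """One subject's BOLD volume; returns the data and the global latent g_1."""
    T = config.n_volumes
    n_vox = int(np.prod(config.grid_shape))
    g_global = _band_limited_signal(rng, T, config.tr_s)
    sector_signals = [
        _band_limited_signal(rng, T, config.tr_s) for _ in range(config.n_latents - 1)
    ]
    wm_signal = _band_limited_signal(rng, T, config.tr_s)
    csf_signal = _band_limited_signal(rng, T, config.tr_s)

    data = rng.normal(0.0, config.noise_sd, size=(n_vox, T))
    head = geometry["head_flat"]
    data[head] += _BASELINE_INTENSITY
    if config.drift_sd > 0:
        ramp = np.linspace(-0.5, 0.5, T)
        amp = rng.normal(0.0, config.drift_sd, size=n_vox)
        data += np.outer(amp, ramp)

    data[geometry["gm_flat"]] += config.baseline_coupling * g_global
    # planted cluster voxels: replace the baseline weight with the subject's c_s
    data[geometry["cluster_flat"]] += (coupling - config.baseline_coupling) * g_global
    for j, sig in enumerate(sector_signals):
        data[geometry["sector_flat"][j]] += _SECTOR_COUPLING * sig
    data[geometry["wm_flat"]] += _WM_COUPLING * wm_signal
    data[geometry["csf_flat"]] += _CSF_COUPLING * csf_signal

    bold = Bold4D(
        data=data.reshape(*config.grid_shape, T),
        voxel_size_mm=config.voxel_size_mm,
        tr_s=config.tr_s,
    )
    return bold, g_global


def _cohort_geometry(config: SimConfig) -> tuple[dict, list[np.ndarray], tuple]:
    gm_prob, wm_prob, csf_prob = tissue_probability_maps(config.grid_shape)
    gm = gm_prob > 0.2
    wm = wm_prob > 0.8
    csf = csf_prob > 0.8
    head = (gm_prob + wm_prob + csf_prob) > 0
    cluster_sets = _cluster_voxel_sets(config, gm)
    cluster_union = np.zeros(config.grid_shape, dtype=bool)
    for vox in cluster_sets:
        cluster_union[tuple(vox.T)] = True
    sectors = _sector_assignment(config, gm, cluster_union)
    flat = lambda m: np.flatnonzero(m.ravel())  # noqa: E731
    geometry = {
        "gm_flat": flat(gm),
        "wm_flat": flat(wm),
        "csf_flat": flat(csf),
        "head_flat": flat(head),
        "cluster_flat": flat(cluster_union),
        "sector_flat": [
            np.flatnonzero((sectors == j).ravel()) for j in range(config.n_latents - 1)
        ],
    }
    return geometry, cluster_sets, (gm_prob, wm_prob, csf_prob)


def generate_cohort(config: SimConfig) -> tuple[list[SyntheticSubject], SyntheticTruth]:
    """Generate a full synthetic cohort with planted group effects.

    Returns the subject list (patients first) and the ground truth needed for
    recovery testing. Deterministic in ``config.seed``.
    """
    config.validate()
    geometry, cluster_sets, probs = _cohort_geometry(config)

    n_total = config.n_patients + config.n_controls
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_total)

    subjects: list[SyntheticSubject] = []
    truth = SyntheticTruth(
        cluster_voxels=cluster_sets,
        coupling={},
        score_slope=config.score_slope,
        gm_prob=probs[0],
        wm_prob=probs[1],
        csf_prob=probs[2],
        config=config,
    )
    planted_patient_mean = config.baseline_coupling - config.effect_delta
    for i in range(n_total):
        rng = np.random.default_rng(children[i])
        is_patient = i < config.n_patients
        group = GROUP_PATIENT if is_patient else GROUP_CONTROL
        subj_id = f"sub-{i + 1:02d}"
        age = _truncnorm(rng, _AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI)
        sex = "M" if rng.random() < _P_MALE else "F"
        center = planted_patient_mean if is_patient else config.baseline_coupling
        coupling = float(np.clip(rng.normal(center, config.coupling_jitter_sd), 0.0, 1.0))
        if is_patient:
            score = (
                config.score_mean
                + config.score_slope * (coupling - planted_patient_mean)
                + rng.normal(0.0, config.score_noise_sd)
            )
            score = float(max(score, 0.0))
        else:
            score = float("nan")
        bold, g_global = _simulate_bold(rng, config, geometry, coupling)
        motion = _motion_trace(rng, config)
        subjects.append(
            SyntheticSubject(
                id=subj_id, group=group, age=age, sex=sex, score=score, bold=bold, motion=motion
            )
        )
        truth.coupling[subj_id] = coupling
        truth.global_latents[subj_id] = g_global
    return subjects, truth


# ---------------------------------------------------------------------------
# disk round trip


def write_cohort(
    subjects: list[SyntheticSubject],
    truth: SyntheticTruth,
    out_dir: str | Path,
    overwrite: bool = False,
) -> dict[str, list[str]]:
    """Write a cohort to disk; returns a manifest of created files.

    Layout: one ``<id>_bold.nii.gz`` and ``<id>_motion.txt`` per subject, a
    ``participants.tsv`` (id, group, age, sex, score), tissue probability
    volumes under ``tissue/``, and ``truth.json``.
    """
    from . import io as gio  # local import to avoid a cycle at module load

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    (out / "tissue").mkdir(exist_ok=True)

    cfg = truth.config
    manifest: dict[str, list[str]] = {
        "bold": [],
        "motion": [],
        "participants": [],
        "tissue": [],
        "truth": [],
    }
    rows = []
    for s in subjects:
        bold_path = out / f"{s.id}_bold.nii.gz"
        motion_path = out / f"{s.id}_motion.txt"
        gio.write_bold(s.bold, bold_path)
        gio.write_motion(s.motion, motion_path)
        manifest["bold"].append(str(bold_path))
        manifest["motion"].append(str(motion_path))
        rows.append(
            {"id": s.id, "group": s.group, "age": s.age, "sex": s.sex, "score": s.score}
        )
    import pandas as pd

    participants = pd.DataFrame(rows, columns=["id", "group", "age", "sex", "score"])
    ppath = out / "participants.tsv"
    gio.write_participants(participants, ppath)
    manifest["participants"].append(str(ppath))

    for name, vol in (
        ("gm_prob", truth.gm_prob),
        ("wm_prob", truth.wm_prob),
        ("csf_prob", truth.csf_prob),
    ):
        path = out / "tissue" / f"{name}.nii.gz"
        gio.write_volume(vol, cfg.voxel_size_mm, path)
        manifest["tissue"].append(str(path))

    tpath = out / "truth.json"
    payload = {
        "score_slope": truth.score_slope,
        "coupling": truth.coupling,
        "cluster_voxels": [v.tolist() for v in truth.cluster_voxels],
        "config": _config_to_jsonable(cfg),
    }
    tpath.write_text(json.dumps(payload, indent=2))
    manifest["truth"].append(str(tpath))
    logger.info("wrote cohort of %d subjects to %s", len(subjects), out)
    return manifest


def _config_to_jsonable(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["grid_shape"] = list(cfg.grid_shape)
    d["cluster_specs"] = [[list(c), r] for c, r in cfg.cluster_specs]
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
    if "grid_shape" in d:
        d["grid_shape"] = tuple(int(x) for x in d["grid_shape"])
    if "cluster_specs" in d:
        d["cluster_specs"] = tuple(
            (tuple(int(x) for x in c), float(r)) for c, r in d["cluster_specs"]
        )
    return SimConfig(**d)


def read_cohort(cohort_dir: str | Path) -> tuple[list[SyntheticSubject], SyntheticTruth]:
    """Read a cohort previously written by :func:`write_cohort`."""
    from . import io as gio

    root = Path(cohort_dir)
    tpath = root / "truth.json"
    if not tpath.exists():
        raise FileNotFoundError(f"no truth.json under {root}")
    payload = json.loads(tpath.read_text())
    cfg = config_from_dict(payload["config"])
    participants = gio.read_participants(root / "participants.tsv")
    subjects = []
    for row in participants.itertuples(index=False):
        bold = gio.read_bold(root / f"{row.id}_bold.nii.gz", tr_fallback=cfg.tr_s)
        motion = gio.read_motion(root / f"{row.id}_motion.txt", n_volumes=bold.n_volumes)
        score = float(row.score) if np.isfinite(row.score) else float("nan")
        subjects.append(
            SyntheticSubject(
                id=row.id,
                group=row.group,
                age=float(row.age),
                sex=row.sex,
                score=score,
                bold=bold,
                motion=motion,
            )
        )
    gm_prob = gio.read_volume(root / "tissue" / "gm_prob.nii.gz")
    wm_prob = gio.read_volume(root / "tissue" / "wm_prob.nii.gz")
    csf_prob = gio.read_volume(root / "tissue" / "csf_prob.nii.gz")
    truth = SyntheticTruth(
        cluster_voxels=[np.asarray(v, dtype=np.int64) for v in payload["cluster_voxels"]],
        coupling={k: float(v) for k, v in payload["coupling"].items()},
        score_slope=float(payload["score_slope"]),
        gm_prob=gm_prob,
        wm_prob=wm_prob,
        csf_prob=csf_prob,
        config=cfg,
    )
    return subjects, truth
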