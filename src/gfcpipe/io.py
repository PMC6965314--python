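"""File formats (NIfTI-1 volumes, motion text, participants TSV) and the run
configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import Bold4D, MotionTrace
from .preproc import PreprocConfig
from .simdata import SimConfig, config_from_dict


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def write_bold(bold: Bold4D, path: str | Path, descrip: str = "") -> None:
    """Write a 4D BOLD volume as NIfTI-1 (float32), TR in the time zoom."""
    img = nib.Nifti1Image(bold.data.astype(np.float32), _affine(bold.voxel_size_mm))
    img.header.set_zooms((bold.voxel_size_mm,) * 3 + (bold.tr_s,))
    img.header.set_xyzt_units("mm", "sec")
    if descrip:
        img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def read_bold(path: str | Path, tr_fallback: float | None = None) -> Bold4D:
    """Read a 4D NIfTI; voxel size and TR come from the header.

    A missing/zero TR falls back to ``tr_fallback`` with a warning, or raises
    if no fallback is given.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D BOLD file, got ndim={data.ndim}")
    zooms = img.header.get_zooms()
    voxel = float(zooms[0])
    if not np.allclose(zooms[:3], voxel, rtol=1e-3):
        warnings.warn(f"{path}: anisotropic voxels {zooms[:3]}; using {voxel}", stacklevel=2)
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr <= 0:
        if tr_fallback is None:
            raise ValueError(f"{path}: TR missing from header and no fallback given")
        warnings.warn(f"{path}: TR missing from header; using fallback {tr_fallback} s",
                      stacklevel=2)
        tr = tr_fallback
    return Bold4D(data=data, voxel_size_mm=voxel, tr_s=tr)


def write_volume(vol: np.ndarray, voxel_size_mm: float, path: str | Path) -> None:
    """Write a 3D volume (e.g. tissue probability or statistic map) as NIfTI."""
    vol = np.asarray(vol)
    if vol.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={vol.ndim}")
    img = nib.Nifti1Image(vol.astype(np.float32), _affine(voxel_size_mm))
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_volume(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    return data


def write_motion(motion: MotionTrace, path: str | Path) -> None:
    """Six whitespace-separated columns, one row per volume (mm, radians)."""
    np.savetxt(str(path), motion.params, fmt="%.10g")


def read_motion(
    path: str | Path, n_volumes: int | None = None, rotations: str = "radians"
) -> MotionTrace:
    """Parse the first six columns of a motion parameter text file.

    ``rotations`` may be "radians" (default) or "degrees" (converted).
    """
    try:
        table = np.loadtxt(str(path), dtype=np.float64, ndmin=2)
    except ValueError as err:
        raise ValueError(f"{path}: non-numeric motion parameters ({err})") from err
    if table.shape[1] < 6:
        raise ValueError(f"{path}: need >= 6 columns, found {table.shape[1]}")
    params = table[:, :6].copy()
    if rotations == "degrees":
        params[:, 3:] = np.radians(params[:, 3:])
    elif rotations != "radians":
        raise ValueError("rotations must be 'radians' or 'degrees'")
    if n_volumes is not None and params.shape[0] != n_volumes:
        raise ValueError(
            f"{path}: motion file has {params.shape[0]} rows but the BOLD series "
            f"has {n_volumes} volumes"
        )
    return MotionTrace(params=params)


def write_participants(table: pd.DataFrame, path: str | Path, meta: str = "") -> None:
    with open(path, "w") as fh:
        if meta:
            fh.write(f"# {meta}\n")
        table.to_csv(fh, sep="\t", index=False, na_rep="n/a")


def read_participants(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", comment="#", na_values=["n/a"])
    required = {"id", "group", "age", "sex", "score"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: participants table missing columns {sorted(missing)}")
    if table["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate subject ids")
    bad = set(table["group"]) - {"patient", "control"}
    if bad:
        raise ValueError(f"{path}: unknown group labels {sorted(bad)}")
    return table


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class GfcConfig:
    gm_threshold: float = 0.2
    min_volumes: int = 50


@dataclass(frozen=True)
class GroupConfig:
    alpha: float = 0.05
    n_perm: int = 1000
    connectivity: int = 26


@dataclass(frozen=True)
class ClassifyConfig:
    k: int = 5
    n_perm_svm: int = 10000
    C: float = 1.0


@dataclass
class RunConfig:
    """Parameters of the full experiment; serializes losslessly to YAML."""

    cohort_dir: str = "cohort"
    out_dir: str = "results"
    seed: int = 0
    simulate: SimConfig | None = field(default_factory=SimConfig)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    gfc: GfcConfig = field(default_factory=GfcConfig)
    group: GroupConfig = field(default_factory=GroupConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)

    def to_dict(self) -> dict:
        d: dict = {
            "cohort_dir": self.cohort_dir,
            "out_dir": self.out_dir,
            "seed": self.seed,
            "preproc": dataclasses.asdict(self.preproc),
            "gfc": dataclasses.asdict(self.gfc),
            "group": dataclasses.asdict(self.group),
            "classify": dataclasses.asdict(self.classify),
        }
        if self.simulate is not None:
            sim = dataclasses.asdict(self.simulate)
            sim["grid_shape"] = list(self.simulate.grid_shape)
            sim["cluster_specs"] = [[list(c), r] for c, r in self.simulate.cluster_specs]
            d["simulate"] = sim
        else:
            d["simulate"] = None
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {"cohort_dir", "out_dir", "seed", "simulate", "preproc", "gfc",
                 "group", "classify"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")

        def build(section_cls, payload):
            if payload is None:
                return section_cls()
            fields = {f.name for f in dataclasses.fields(section_cls)}
            extra = set(payload) - fields
            if extra:
                raise ValueError(
                    f"unknown keys in {section_cls.__name__}: {sorted(extra)}"
                )
            return section_cls(**payload)

        sim = d.get("simulate")
        return cls(
            cohort_dir=str(d.get("cohort_dir", "cohort")),
            out_dir=str(d.get("out_dir", "results")),
            seed=int(d.get("seed", 0)),
            simulate=None if sim is None else config_from_dict(sim),
            preproc=build(PreprocConfig, d.get("preproc")),
            gfc=build(GfcConfig, d.get("gfc")),
            group=build(GroupConfig, d.get("group")),
            classify=build(ClassifyConfig, d.get("classify")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ValueError(f"{path}: configuration must be a mapping")
        return cls.from_dict(payload)
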