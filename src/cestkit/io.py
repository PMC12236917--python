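"""Readers and writers for the pipeline's on-disk artifacts.

Volumetric data travel as NIfTI-1 (identity affine, voxel indices 0-based,
row-major); offset lists and tidy tables as UTF-8 CSV with a header row;
reports and manifests as JSON; configuration as YAML.  All numeric
payloads round-trip losslessly at 64-bit precision.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = ["IOError_", "write_nifti", "read_nifti", "write_offsets_csv",
           "read_offsets_csv", "write_table", "read_table", "write_json",
           "read_json", "save_config_yaml", "load_config_yaml",
           "save_phantom", "load_phantom"]


class IOError_(ValueError):
    """Raised for malformed pipeline files."""


def write_nifti(path, data: np.ndarray, dtype=np.float64) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine=np.eye(4))
    nib.save(img, str(path))


def read_nifti(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise IOError_(f"no such file: {path}")
    try:
        return np.asarray(nib.load(str(path)).dataobj)
    except Exception as exc:  # nibabel raises several types for bad files
        raise IOError_(f"cannot read NIfTI {path}: {exc}") from exc


def write_offsets_csv(path, axis: np.ndarray) -> None:
    pd.DataFrame({"offset_ppm": np.asarray(axis, dtype=float)}).to_csv(path, index=False)


def read_offsets_csv(path) -> np.ndarray:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise IOError_(f"cannot parse offsets CSV {path}: {exc}") from exc
    if "offset_ppm" not in df.columns:
        raise IOError_(f"{path}: missing required column 'offset_ppm'")
    axis = df["offset_ppm"].to_numpy(dtype=float)
    if not np.all(np.isfinite(axis)):
        raise IOError_(f"{path}: non-finite offsets in 'offset_ppm'")
    if np.any(np.diff(axis) <= 0):
        warnings.warn(f"{path}: offsets not strictly increasing; sorting on load")
        axis = np.unique(axis)
    return axis


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_table(path, required: set[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise IOError_(f"cannot parse table {path}: {exc}") from exc
    if required:
        missing = required - set(df.columns)
        if missing:
            raise IOError_(f"{path}: missing columns {sorted(missing)}")
    return df


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify))


def read_json(path):
    path = Path(path)
    try:
        return json.loads(path.read_text())
    except Exception as exc:
        raise IOError_(f"cannot parse JSON {path}: {exc}") from exc


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def save_config_yaml(path, obj) -> None:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    Path(path).write_text(yaml.safe_dump(_yaml_clean(obj), sort_keys=True))


def load_config_yaml(path) -> dict:
    path = Path(path)
    try:
        out = yaml.safe_load(path.read_text())
    except Exception as exc:
        raise IOError_(f"cannot parse YAML {path}: {exc}") from exc
    if not isinstance(out, dict):
        raise IOError_(f"{path}: top level must be a mapping")
    return out


def _yaml_clean(obj):
    """Recursively convert numpy scalars/arrays and tuple keys for YAML."""
    if isinstance(obj, dict):
        return {(k if isinstance(k, str) else "|".join(map(str, k))): _yaml_clean(v)
                for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_clean(v) for v in obj]
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# -- phantom dataset directory layout ---------------------------------------
#
#   <dir>/offsets.csv, wassr_offsets.csv, labels.nii.gz, subjects.csv,
#   sub-<id>_z.nii.gz, sub-<id>_wassr.nii.gz, region_ids.json,
#   truth_b0.nii.gz, truth_amplitudes.nii.gz, truth_regions.csv, truth.json

def save_phantom(dataset, out_dir) -> Path:
    """Write a simulated study to a directory (one 4D NIfTI per subject)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_offsets_csv(out_dir / "offsets.csv", dataset.axis)
    write_offsets_csv(out_dir / "wassr_offsets.csv", dataset.wassr_axis)
    write_nifti(out_dir / "labels.nii.gz", dataset.labels, dtype=np.int16)
    write_table(out_dir / "subjects.csv", dataset.subjects)
    write_json(out_dir / "region_ids.json",
               {str(k): v for k, v in dataset.region_ids.items()})
    for s, sid in enumerate(dataset.subjects["subject"]):
        write_nifti(out_dir / f"sub-{sid}_z.nii.gz", dataset.z[s])
        write_nifti(out_dir / f"sub-{sid}_wassr.nii.gz", dataset.wassr[s])
    t = dataset.truth
    write_nifti(out_dir / "truth_b0.nii.gz", t.b0)
    write_nifti(out_dir / "truth_amplitudes.nii.gz", t.amplitudes)
    write_table(out_dir / "truth_regions.csv", t.region_amplitudes)
    write_json(out_dir / "truth.json", {
        "pool_names": list(t.pool_names),
        "b0_coeffs": list(dataset.config.b0_coeffs),
        "noise_sigma": dataset.config.noise_sigma,
        "subject_cv": dataset.config.subject_cv,
        "seed": dataset.config.seed,
    })
    return out_dir


def load_phantom(in_dir):
    """Read a phantom directory back into a :class:`~cestkit.synthetic.PhantomDataset`."""
    from .synthetic import GroundTruth, PhantomConfig, PhantomDataset

    in_dir = Path(in_dir)
    axis = read_offsets_csv(in_dir / "offsets.csv")
    wassr_axis = read_offsets_csv(in_dir / "wassr_offsets.csv")
    labels = read_nifti(in_dir / "labels.nii.gz").astype(np.int16)
    subjects = read_table(in_dir / "subjects.csv", required={"subject", "arm"})
    region_ids = {int(k): v for k, v in read_json(in_dir / "region_ids.json").items()}
    z = np.stack([read_nifti(in_dir / f"sub-{sid}_z.nii.gz")
                  for sid in subjects["subject"]])
    wassr = np.stack([read_nifti(in_dir / f"sub-{sid}_wassr.nii.gz")
                      for sid in subjects["subject"]])
    if z.shape[-1] != axis.size:
        raise IOError_(
            f"offsets CSV has {axis.size} rows but Z stack has {z.shape[-1]} volumes"
        )
    if wassr.shape[-1] != wassr_axis.size:
        raise IOError_(
            f"WASSR offsets CSV has {wassr_axis.size} rows but stack has "
            f"{wassr.shape[-1]} volumes"
        )
    meta = read_json(in_dir / "truth.json")
    truth = GroundTruth(
        amplitudes=read_nifti(in_dir / "truth_amplitudes.nii.gz"),
        pool_names=tuple(meta["pool_names"]),
        b0=read_nifti(in_dir / "truth_b0.nii.gz"),
        labels=labels, region_ids=region_ids, subjects=subjects,
        region_amplitudes=read_table(in_dir / "truth_regions.csv"),
    )
    cfg = PhantomConfig(grid_shape=tuple(labels.shape),
                        b0_coeffs=tuple(meta["b0_coeffs"]),
                        noise_sigma=float(meta["noise_sigma"]),
                        subject_cv=float(meta["subject_cv"]),
                        seed=int(meta["seed"]))
    return PhantomDataset(z=z, wassr=wassr, axis=axis, wassr_axis=wassr_axis,
                          labels=labels, region_ids=region_ids, subjects=subjects,
                          truth=truth, config=cfg)
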