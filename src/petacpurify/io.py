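"""Volume I/O, dataset manifests, and run configuration.

All volumes travel as NIfTI-1 (float32 on disk; metric accumulation happens
in float64 elsewhere).  A dataset is a directory of per-case NIfTI files
plus one JSON manifest listing, for every case, its file paths, artifact
label, split and seed.  Configs are versioned YAML with strict keys.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import yaml

from .grid import VoxelGrid
from .phantoms import PairedCase

MANIFEST_SCHEMA_VERSION = "1"
CONFIG_SCHEMA_VERSION = "1"


def write_volume(grid: VoxelGrid, path) -> None:
    """NIfTI-1, RAS with identity rotation, spacing on the affine diagonal."""
    affine = np.diag(list(grid.spacing_mm) + [1.0])
    img = nib.Nifti1Image(grid.data.astype(np.float32), affine)
    img.header.set_zooms(grid.spacing_mm)
    nib.save(img, str(path))


def read_volume(path) -> VoxelGrid:
    """Load a single 3D NIfTI volume; orientation normalized to RAS."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got shape {data.shape}")
    if np.iscomplexobj(data):
        raise ValueError(f"{path}: complex-valued images are not supported")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite voxels")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelGrid(data.astype(np.float32), spacing)


@dataclass
class CaseEntry:
    case_id: str
    non_ac: str
    ct_ac: str
    artifact_label: str = "none"
    split: str = "train"
    seed: int = 0
    clean_ref: Optional[str] = None
    masks: dict = field(default_factory=dict)
    artifact_params: dict = field(default_factory=dict)


@dataclass
class DatasetManifest:
    cases: list[CaseEntry]
    config_hash: str = ""
    schema_version: str = MANIFEST_SCHEMA_VERSION

    def validate(self, root: Optional[Path] = None, check_files: bool = True) -> None:
        if self.schema_version != MANIFEST_SCHEMA_VERSION:
            raise ValueError(f"unknown manifest schema_version {self.schema_version!r}")
        ids = [c.case_id for c in self.cases]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate case_id(s): {dupes}")
        for c in self.cases:
            if c.split not in ("train", "test"):
                raise ValueError(f"case {c.case_id}: invalid split {c.split!r}")
            if check_files:
                for rel in filter(None, [c.non_ac, c.ct_ac, c.clean_ref,
                                         *c.masks.values()]):
                    p = (root / rel) if root else Path(rel)
                    if not p.exists():
                        raise FileNotFoundError(f"case {c.case_id}: missing file {p}")


def save_manifest(manifest: DatasetManifest, path) -> None:
    path = Path(path)
    manifest.validate(root=path.parent, check_files=False)
    payload = {
        "schema_version": manifest.schema_version,
        "config_hash": manifest.config_hash,
        "cases": [asdict(c) for c in manifest.cases],
    }
    path.write_text(json.dumps(payload, indent=2))


def load_manifest(path, check_files: bool = True) -> DatasetManifest:
    path = Path(path)
    payload = json.loads(path.read_text())
    manifest = DatasetManifest(
        cases=[CaseEntry(**c) for c in payload["cases"]],
        config_hash=payload.get("config_hash", ""),
        schema_version=payload.get("schema_version", "?"),
    )
    manifest.validate(root=path.parent, check_files=check_files)
    return manifest


def write_dataset(cases: list[PairedCase], out_dir, config: Optional[dict] = None) -> DatasetManifest:
    """Write every paired case (volumes as .nii.gz) plus the JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for case in cases:
        names = {}
        for tag, grid in (("nonac", case.non_ac), ("ctac", case.ct_ac),
                          ("cleanref", case.clean_ref)):
            if grid is None:
                continue
            fname = f"{case.case_id}_{tag}.nii.gz"
            write_volume(grid, out / fname)
            names[tag] = fname
        entries.append(CaseEntry(
            case_id=case.case_id,
            non_ac=names["nonac"],
            ct_ac=names["ctac"],
            clean_ref=names.get("cleanref"),
            artifact_label=case.artifact_label,
            split=case.split or "train",
            seed=case.seed,
            artifact_params=_jsonable(case.artifact_params),
        ))
    manifest = DatasetManifest(cases=entries, config_hash=config_hash(config or {}))
    save_manifest(manifest, out / "manifest.json")
    return manifest


def write_phantom_masks(phantom, out_dir) -> dict[str, str]:
    """Write a phantom's organ masks as `<case_id>_mask_<organ>.nii.gz`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = {}
    for organ, mask in phantom.organ_masks.items():
        fname = f"{phantom.case_id}_mask_{organ}.nii.gz"
        write_volume(
            VoxelGrid(mask.astype(np.float32), phantom.activity.spacing_mm),
            out / fname,
        )
        names[organ] = fname
    return names


def load_dataset(manifest_path) -> list[PairedCase]:
    path = Path(manifest_path)
    manifest = load_manifest(path)
    cases = []
    for e in manifest.cases:
        cases.append(PairedCase(
            case_id=e.case_id,
            non_ac=read_volume(path.parent / e.non_ac),
            ct_ac=read_volume(path.parent / e.ct_ac),
            clean_ref=read_volume(path.parent / e.clean_ref) if e.clean_ref else None,
            artifact_label=e.artifact_label,
            split=e.split,
            artifact_params=e.artifact_params,
            seed=e.seed,
        ))
    return cases


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(_jsonable(config), sort_keys=True).encode()
    ).hexdigest()[:16]


# --- run configuration -----------------------------------------------------

_CONFIG_SCHEMA = {
    "schema_version": str,
    "seed": int,
    "simulate": {
        "n_train": int, "n_test": int, "artifact_fraction": float,
        "artifact_mix": dict, "grid_shape": list, "noise_scale": float,
        "geometry_jitter": float, "n_angles": int,
    },
    "model": {
        "base_features": int, "n_layers": int, "output_head": str,
    },
    "stage1": {
        "loss": str, "learning_rate": float, "batch_size": int,
        "momentum": float, "epochs": int, "patch_size": list,
        "lr_schedule": str,
    },
    "stage2": {
        "loss": str, "learning_rate": float, "batch_size": int,
        "momentum": float, "epochs": int, "patch_size": list,
        "lr_schedule": str,
    },
    "purify": {"threshold_k": float},
}


def _check_keys(data: dict, schema: dict, prefix: str = "") -> None:
    for key, val in data.items():
        if key not in schema:
            raise ValueError(f"unknown config key {prefix + key!r}")
        if isinstance(schema[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key {prefix + key!r} must be a mapping")
            _check_keys(val, schema[key], prefix + key + ".")


def load_config(path) -> dict:
    """Strict YAML config: unknown keys are errors, not warnings."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    version = str(data.get("schema_version", CONFIG_SCHEMA_VERSION))
    if version != CONFIG_SCHEMA_VERSION:
        raise ValueError(f"unknown config schema_version {version!r}")
    _check_keys(data, _CONFIG_SCHEMA)
    return data
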