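"""Readers and writers: NIfTI/NRRD volumes, feature CSVs, GLCM archives, configs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk
import yaml

from .glcm import GLCMSet, DEFAULT_CLEANSE_THRESHOLD, DEFAULT_N_LEVELS
from .selection import FeatureTable

__all__ = [
    "RunConfig",
    "load_volume_mask",
    "save_volume",
    "write_feature_table",
    "read_feature_table",
    "write_glcm_archive",
    "read_glcm_archive",
]



def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _read_image(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if _is_nifti(path):
        img = nib.load(str(path))
        # canonical (slice, row, column) index order
        return np.asarray(img.get_fdata()).transpose(2, 1, 0)
    if path.suffix.lower() == ".nrrd":
        img = sitk.ReadImage(str(path))
        return sitk.GetArrayFromImage(img).astype(float)
    raise ValueError(f"unsupported image format: {path}")


def load_volume_mask(volume_path, mask_path) -> tuple[np.ndarray, np.ndarray]:
    """Load a volume and its binary mask and check they share a grid."""
    vpath, mpath = Path(volume_path), Path(mask_path)
    vol = _read_image(vpath)
    mask = _read_image(mpath)
    if vol.shape != mask.shape:
        raise ValueError(
            f"grid mismatch: {vpath} has shape {vol.shape} but {mpath} has {mask.shape}"
        )
    return vol, mask > 0.5


def save_volume(array: np.ndarray, path) -> None:
    """Write a 3D array as NIfTI or NRRD depending on the suffix."""
    path = Path(path)
    arr = np.asarray(array, dtype=float)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(arr.transpose(2, 1, 0), affine=np.eye(4)), str(path))
    elif path.suffix.lower() == ".nrrd":
        sitk.WriteImage(sitk.GetImageFromArray(arr), str(path))
    else:
        raise ValueError(f"unsupported image format: {path}")


def write_feature_table(table: FeatureTable, csv_path, sample_ids=None,
                        metadata: dict | None = None) -> None:
    """Feature CSV (id, label, features) with a sidecar JSON of run metadata."""
    csv_path = Path(csv_path)
    n = table.matrix.shape[0]
    ids = sample_ids if sample_ids is not None else [f"sample_{i:03d}" for i in range(n)]
    df = pd.DataFrame(table.matrix, columns=table.feature_labels)
    df.insert(0, "label", table.labels)
    df.insert(0, "id", ids)
    df.to_csv(csv_path, index=False)
    side = {
        "feature_labels": table.feature_labels,
        "group_assignment": [int(g) for g in table.group_assignment],
    }
    if metadata:
        side.update(metadata)
    csv_path.with_suffix(".json").write_text(json.dumps(side, indent=1))


def read_feature_table(csv_path, group_map_path=None) -> FeatureTable:
    """Read a feature CSV (id, label, features) plus its group map."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    feature_cols = [c for c in df.columns if c not in ("id", "label")]
    side_path = Path(group_map_path) if group_map_path else csv_path.with_suffix(".json")
    if not side_path.exists():
        raise FileNotFoundError(f"group map not found: {side_path}")
    side = json.loads(side_path.read_text())
    groups = np.asarray(side["group_assignment"], dtype=int)
    return FeatureTable(
        matrix=df[feature_cols].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
        feature_labels=feature_cols,
        group_assignment=groups,
    )


def write_glcm_archive(glcms: GLCMSet, path) -> None:
    """Save the 13 count matrices keyed ``d_{x}{y}{z}`` in one npz archive."""
    arrays = {g.displacement.label: g.counts for g in glcms.glcms.values()}
    np.savez(Path(path), **arrays)


def read_glcm_archive(path) -> dict[str, np.ndarray]:
    with np.load(Path(path)) as z:
        return {k: z[k] for k in z.files}


@dataclass
class RunConfig:
    """A fully serializable pipeline configuration; a saved config re-runs identically."""

    volumes_dir: str = ""
    masks_dir: str = ""
    labels_csv: str = ""
    output_dir: str = "out"
    n_levels: int = DEFAULT_N_LEVELS
    cleanse_threshold: float = DEFAULT_CLEANSE_THRESHOLD
    symmetrize: bool = True
    registry: str = "eHM28"  # "eHM28" | "haralick14"
    mode: str = "nested"
    n_repeats: int = 100
    inner_repeats: int = 10
    n_trees: int = 5000
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    @property
    def digest(self) -> str:
        """Stable hash recorded in every output for provenance."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
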