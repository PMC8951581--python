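"""Volumes, label maps, the ET/TC/WT region algebra, splits and NIfTI I/O.

Label codes follow the BraTS convention: 0 background, 1 necrotic /
non-enhancing tumor core, 2 peritumoral edema, 4 enhancing tumor.  The
evaluation regions are nested unions of those codes:

* ET (enhancing tumor)      = {4}
* TC (tumor core)           = {1, 4}
* WT (whole tumor)          = {1, 2, 4}

On-disk layout per case: ``<case_id>/<case_id>_<modality>.nii.gz`` for
modalities ``t1, t1ce, t2, flair`` plus ``<case_id>_seg.nii.gz``.
Volumes keep (x, y, z) axis order as stored in the file; no
reorientation is performed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import yaml

MODALITIES: tuple[str, ...] = ("t1", "t1ce", "t2", "flair")
LABEL_CODES: tuple[int, ...] = (0, 1, 2, 4)
#: class-index (softmax channel) -> label code
CLASS_TO_CODE = np.array([0, 1, 2, 4], dtype=np.int16)

__all__ = [
    "MODALITIES", "LABEL_CODES", "CLASS_TO_CODE",
    "MultimodalVolume", "LabelMap", "Region", "DatasetSplit",
    "labels_to_class_indices", "one_hot_labels",
    "region_mask", "split_cohort", "zscore_normalize",
    "read_case", "write_case", "read_case_dir",
    "load_config", "save_config",
]


@dataclass
class MultimodalVolume:
    """A 4-channel 3-D intensity volume, channels ordered (t1, t1ce, t2, flair)."""

    data: np.ndarray  # (4, X, Y, Z) float32
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    case_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4 or self.data.shape[0] != len(MODALITIES):
            raise ValueError(
                f"expected ({len(MODALITIES)}, X, Y, Z) data, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class LabelMap:
    """Integer voxel labels restricted to the BraTS codes {0, 1, 2, 4}."""

    data: np.ndarray  # (X, Y, Z) int16

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map must be integer-valued")
        self.data = self.data.astype(np.int16)
        bad = np.setdiff1d(np.unique(self.data), LABEL_CODES)
        if bad.size:
            counts = {int(v): int((self.data == v).sum()) for v in bad}
            raise ValueError(f"unknown label value(s) {counts} (value: n_voxels)")

    @property
    def n_voxels(self) -> int:
        return int(self.data.size)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape


class Region(enum.Enum):
    """The three nested evaluation regions."""

    ET = "ET"
    TC = "TC"
    WT = "WT"


_REGION_CODES: dict[Region, tuple[int, ...]] = {
    Region.ET: (4,),
    Region.TC: (1, 4),
    Region.WT: (1, 2, 4),
}


def labels_to_class_indices(labels: np.ndarray) -> np.ndarray:
    """Map label codes {0,1,2,4} to contiguous class indices {0,1,2,3}."""
    lut = np.zeros(5, dtype=np.int64)
    for idx, code in enumerate(LABEL_CODES):
        lut[code] = idx
    return lut[np.asarray(labels, dtype=np.int64)]


def one_hot_labels(labels: np.ndarray, n_classes: int = 4) -> np.ndarray:
    """One-hot encode a label volume to a (C, ...) float32 array."""
    idx = labels_to_class_indices(labels)
    out = np.zeros((n_classes,) + idx.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = idx == c
    return out


def region_mask(labels: LabelMap | np.ndarray, region: Region) -> np.ndarray:
    """Binary mask of an evaluation region (ET={4}, TC={1,4}, WT={1,2,4})."""
    data = labels.data if isinstance(labels, LabelMap) else np.asarray(labels)
    return np.isin(data, _REGION_CODES[Region(region)])


@dataclass
class DatasetSplit:
    train_ids: list[str]
    test_ids: list[str]
    seed: int

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


def split_cohort(case_ids: Sequence[str], test_fraction: float,
                 seed: int) -> DatasetSplit:
    """Random, seed-deterministic train/test split.

    The test-set size is round(n * test_fraction), clipped so both sides
    are non-empty; it differs from the exact fraction by at most one case.
    """
    ids = list(case_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 cases to split")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    n_test = int(np.clip(round(len(ids) * test_fraction), 1, len(ids) - 1))
    perm = np.random.default_rng(seed).permutation(len(ids))
    test = sorted(ids[i] for i in perm[:n_test])
    train = sorted(ids[i] for i in perm[n_test:])
    return DatasetSplit(train_ids=train, test_ids=test, seed=seed)


def zscore_normalize(data: np.ndarray) -> np.ndarray:
    """Per-channel z-score over nonzero voxels; degenerate channels unchanged.

    An all-zero channel (no brain voxels) or a constant nonzero channel is
    returned as-is rather than divided by a zero standard deviation.
    """
    out = np.array(data, dtype=np.float32, copy=True)
    for c in range(out.shape[0]):
        nz = out[c] != 0
        if not nz.any():
            continue
        sd = out[c][nz].std()
        if sd == 0:
            continue
        out[c][nz] = (out[c][nz] - out[c][nz].mean()) / sd
    return out


# ---------------------------------------------------------------------------
# NIfTI case I/O


def read_case(modality_paths: Mapping[str, Path | str], label_path: Path | str,
              case_id: str = "", normalize: bool = True
              ) -> tuple[MultimodalVolume, LabelMap]:
    """Read one case from per-modality NIfTI files plus a label file.

    Channel order is fixed to (t1, t1ce, t2, flair) by the mapping keys,
    not by filename order.  Per-channel z-score normalisation over
    nonzero voxels is applied on load unless ``normalize=False``.
    """
    missing = [m for m in MODALITIES if m not in modality_paths]
    if missing:
        raise ValueError(f"missing modalities: {missing}")
    channels, spacing, shape = [], None, None
    for m in MODALITIES:
        img = nib.load(str(modality_paths[m]))
        arr = np.asarray(img.dataobj, dtype=np.float32)
        if shape is None:
            shape = arr.shape
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        elif arr.shape != shape:
            raise ValueError(
                f"modality {m!r} shape {arr.shape} != {shape}")
        channels.append(arr)
    seg = nib.load(str(label_path))
    seg_arr = np.asarray(seg.dataobj)
    if seg_arr.shape != shape:
        raise ValueError(f"label shape {seg_arr.shape} != image shape {shape}")
    data = np.stack(channels)
    if normalize:
        data = zscore_normalize(data)
    labels = LabelMap(np.rint(seg_arr).astype(np.int16))
    return MultimodalVolume(data, voxel_spacing=spacing, case_id=case_id), labels


def write_case(volume: MultimodalVolume, labels: LabelMap,
               out_dir: Path | str) -> Path:
    """Write a case as ``<case_id>/<case_id>_<modality>.nii.gz`` + seg file."""
    case_dir = Path(out_dir) / volume.case_id
    case_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.voxel_spacing) + [1.0])
    for c, m in enumerate(MODALITIES):
        nib.save(nib.Nifti1Image(volume.data[c], affine),
                 str(case_dir / f"{volume.case_id}_{m}.nii.gz"))
    nib.save(nib.Nifti1Image(labels.data.astype(np.int16), affine),
             str(case_dir / f"{volume.case_id}_seg.nii.gz"))
    return case_dir


def read_case_dir(case_dir: Path | str, normalize: bool = True
                  ) -> tuple[MultimodalVolume, LabelMap]:
    """Read a case laid out as written by :func:`write_case`."""
    case_dir = Path(case_dir)
    cid = case_dir.name
    paths = {m: case_dir / f"{cid}_{m}.nii.gz" for m in MODALITIES}
    return read_case(paths, case_dir / f"{cid}_seg.nii.gz",
                     case_id=cid, normalize=normalize)


# ---------------------------------------------------------------------------
# run configuration


def load_config(path: Path | str) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} is not a mapping")
    return cfg


def save_config(cfg: dict, path: Path | str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
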