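"""Dataset manifests, slice loading and network-compatible resampling.

Images are single-channel PNG (8/16-bit) or NIfTI slice files; masks are
integer label maps in the same formats.  A manifest is a CSV with columns
(patient_id, slice, image, mask) whose paths are relative to the manifest's
directory, accompanied by a ``labels.json`` dictionary mapping class index
to organ name (index 0 is background, indices contiguous).

Loaded images are min-max normalised per slice to [0, 1] (a zero-range
slice maps to all zeros); an optional CT-style window (center/width in the
stored units) can be applied before normalisation.  Masks are loaded as
integers, unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

__all__ = [
    "DatasetManifest",
    "load_array",
    "load_sample",
    "resize_keep_aspect",
    "ResizeTransform",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def load_array(path) -> np.ndarray:
    """Read a 2-D array from PNG or NIfTI (single-slice volumes squeezed)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith(_NIFTI_SUFFIXES):
        arr = np.asanyarray(nib.load(path).dataobj)
    else:
        arr = iio.imread(path)
    arr = np.squeeze(np.asarray(arr))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single 2-D slice, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class ManifestRecord:
    patient_id: str
    slice_index: int
    image_path: Path
    mask_path: Path


class DatasetManifest:
    """Slice records plus the label dictionary of a dataset on disk."""

    def __init__(self, records, labels: dict):
        self.records = list(records)
        self.labels = {int(k): str(v) for k, v in labels.items()}
        indices = sorted(self.labels)
        if indices != list(range(len(indices))):
            raise ValueError(
                f"label indices must be contiguous from 0, got {indices}"
            )
        seen = set()
        for r in self.records:
            key = (r.patient_id, r.slice_index)
            if key in seen:
                raise ValueError(f"duplicate slice index {key}")
            seen.add(key)

    @classmethod
    def load(cls, manifest_path, labels_path=None) -> "DatasetManifest":
        manifest_path = Path(manifest_path)
        root = manifest_path.parent
        if labels_path is None:
            labels_path = root / "labels.json"
        labels = json.loads(Path(labels_path).read_text())
        table = pd.read_csv(manifest_path, dtype={"patient_id": str})
        records = []
        for row in table.itertuples():
            rec = ManifestRecord(
                patient_id=row.patient_id,
                slice_index=int(row.slice),
                image_path=root / row.image,
                mask_path=root / row.mask,
            )
            for p in (rec.image_path, rec.mask_path):
                if not p.exists():
                    raise FileNotFoundError(f"manifest refers to missing file {p}")
            records.append(rec)
        return cls(records, labels)

    @property
    def num_classes(self) -> int:
        return len(self.labels)

    @property
    def patient_ids(self) -> list:
        out = []
        for r in self.records:
            if r.patient_id not in out:
                out.append(r.patient_id)
        return out

    def by_patient(self) -> dict:
        groups: dict = {}
        for r in self.records:
            groups.setdefault(r.patient_id, []).append(r)
        for recs in groups.values():
            recs.sort(key=lambda r: r.slice_index)
        return groups

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _normalize(image: np.ndarray, window=None) -> np.ndarray:
    image = image.astype(np.float64)
    if window is not None:
        center, width = window
        lo, hi = center - width / 2.0, center + width / 2.0
        image = np.clip(image, lo, hi)
    lo, hi = image.min(), image.max()
    if hi == lo:  # constant slice: zero-range guard
        return np.zeros_like(image)
    return (image - lo) / (hi - lo)


def load_sample(record: ManifestRecord, labels: dict | None = None, window=None):
    """Load one (image, mask) pair.

    Returns the image as a (1, H, W) float array min-max scaled to [0, 1]
    and the mask as an (H, W) integer array.  When ``labels`` is given, mask
    values outside the dictionary raise with the value and file named.
    """
    image = _normalize(load_array(record.image_path), window=window)
    mask = load_array(record.mask_path)
    if not np.issubdtype(mask.dtype, np.integer):
        if not np.all(mask == np.round(mask)):
            raise ValueError(f"{record.mask_path}: mask is not integer-valued")
        mask = np.round(mask)
    mask = mask.astype(np.int64)
    if labels is not None:
        bad = set(np.unique(mask)) - set(int(k) for k in labels)
        if bad:
            raise ValueError(
                f"mask value(s) {sorted(bad)} in {record.mask_path} missing "
                f"from the label dictionary"
            )
    return image[None], mask


@dataclass(frozen=True)
class ResizeTransform:
    """Bookkeeping of one aspect-preserving resize, enough to invert it."""

    original_shape: tuple
    scaled_shape: tuple
    pad_top: int
    pad_left: int
    target: int

    def inverse_mask(self, mask: np.ndarray) -> np.ndarray:
        """Map a target-sized mask back to the original grid (crop the
        padding, nearest-neighbour rescale)."""
        h, w = self.scaled_shape
        crop = mask[self.pad_top : self.pad_top + h, self.pad_left : self.pad_left + w]
        if self.scaled_shape == self.original_shape:
            return crop.copy()
        return (
            _sk_resize(
                crop.astype(np.float64),
                self.original_shape,
                order=0,
                anti_aliasing=False,
                preserve_range=True,
            )
            .round()
            .astype(mask.dtype)
        )


def resize_keep_aspect(image: np.ndarray, mask: np.ndarray | None, target: int = 256):
    """Scale so the longer side equals ``target`` (aspect ratio preserved),
    then pad symmetrically with background to ``target x target``.

    The image is interpolated bilinearly and padded with 0; the mask uses
    nearest-neighbour interpolation (no new labels) and pads with class 0.
    Returns ``(image, mask, transform)``; the transform records offsets for
    the inverse mapping.
    """
    image = np.asarray(image, dtype=np.float64)
    squeeze = image.ndim == 3 and image.shape[0] == 1
    if squeeze:
        image = image[0]
    if image.ndim != 2 or min(image.shape) < 1 or target < 1:
        raise ValueError(f"need a non-empty 2-D image, got shape {image.shape}")
    H, W = image.shape
    scale = target / max(H, W)
    new_h = max(1, round(H * scale))
    new_w = max(1, round(W * scale))
    out_img = _sk_resize(
        image, (new_h, new_w), order=1, anti_aliasing=scale < 1, preserve_range=True
    )
    pad_top = (target - new_h) // 2
    pad_left = (target - new_w) // 2
    canvas = np.zeros((target, target), dtype=np.float64)
    canvas[pad_top : pad_top + new_h, pad_left : pad_left + new_w] = out_img
    transform = ResizeTransform((H, W), (new_h, new_w), pad_top, pad_left, target)
    out_mask = None
    if mask is not None:
        mask = np.asarray(mask)
        if mask.shape != (H, W):
            raise ValueError(f"mask shape {mask.shape} != image shape {(H, W)}")
        scaled = (
            _sk_resize(
                mask.astype(np.float64),
                (new_h, new_w),
                order=0,
                anti_aliasing=False,
                preserve_range=True,
            )
            .round()
            .astype(mask.dtype)
        )
        out_mask = np.zeros((target, target), dtype=mask.dtype)
        out_mask[pad_top : pad_top + new_h, pad_left : pad_left + new_w] = scaled
    if squeeze:
        canvas = canvas[None]
    return canvas, out_mask, transform
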