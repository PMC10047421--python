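"""CT volume ingestion: HU windowing, slice extraction/filtering, manifests.

Volumes arrive as NIfTI files (or plain arrays) in Hounsfield units with a
voxel-aligned label volume.  Axial slices are windowed to [0,1] with the
standard linear display transform, slices with too few annotated pixels
are dropped, and the survivors are persisted as 2D rasters plus a CSV
manifest that the training CLI consumes.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

MANIFEST_COLUMNS = ["volume_id", "slice_index", "n_lesion_pixels",
                    "image_path", "mask_path"]
DEFAULT_MIN_ANNOTATED_PIXELS = 100


@dataclasses.dataclass(frozen=True)
class WindowSpec:
    """CT display window: maps [level - width/2, level + width/2] HU to [0,1].

    Defaults follow the bone-and-soft-tissue window used for rib reading
    (width 1000 HU, level 600 HU).
    """

    width: float = 1000.0
    level: float = 600.0

    def __post_init__(self):
        if not self.width > 0:
            raise ValueError(f"window width must be positive, got {self.width}")

    @property
    def lower(self) -> float:
        return self.level - self.width / 2.0

    @property
    def upper(self) -> float:
        return self.level + self.width / 2.0


@dataclasses.dataclass
class SliceSample:
    """One windowed 2D image with its binary lesion mask and provenance."""

    image: np.ndarray
    mask: np.ndarray
    volume_id: str
    slice_index: int

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.image.ndim != 2:
            raise ValueError("image must be 2D")
        if self.image.shape != self.mask.shape:
            raise ValueError(f"image {self.image.shape} and mask "
                             f"{self.mask.shape} shapes differ")
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image intensities must lie in [0,1]")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")
        if self.slice_index < 0:
            raise ValueError("slice_index must be >= 0")

    @property
    def n_lesion_pixels(self) -> int:
        return int(self.mask.sum())


def apply_window(hu_image: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Linear HU -> [0,1] display mapping with hard clipping outside the
    window.  Monotone in HU and idempotent once composed with itself on the
    [0,1] scale of a unit-width window."""
    hu_image = np.asarray(hu_image, dtype=np.float64)
    if not np.isfinite(hu_image).all():
        bad = int((~np.isfinite(hu_image)).sum())
        raise ValueError(f"hu_image contains {bad} non-finite value(s)")
    out = (hu_image - spec.lower) / spec.width
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def extract_slices(volume: np.ndarray, mask_volume: np.ndarray,
                   spec: WindowSpec = WindowSpec(),
                   min_annotated_pixels: int = DEFAULT_MIN_ANNOTATED_PIXELS,
                   volume_id: str = "volume", slice_axis: int = -1,
                   ) -> list[SliceSample]:
    """Window a volume and keep axial slices with enough annotated pixels.

    The label volume is binarized (any positive label counts as lesion) and
    a slice is retained iff its binary mask has at least
    `min_annotated_pixels` foreground pixels.
    """
    volume = np.asarray(volume)
    mask_volume = np.asarray(mask_volume)
    if volume.shape != mask_volume.shape:
        raise ValueError(f"volume {volume.shape} and mask "
                         f"{mask_volume.shape} shapes differ")
    if min_annotated_pixels < 0:
        raise ValueError("min_annotated_pixels must be >= 0")
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    volume = np.moveaxis(volume, slice_axis, 0)
    mask_volume = np.moveaxis(mask_volume, slice_axis, 0)
    samples = []
    for k in range(volume.shape[0]):
        binary = (mask_volume[k] > 0).astype(np.uint8)
        if int(binary.sum()) < min_annotated_pixels:
            continue
        samples.append(SliceSample(image=apply_window(volume[k], spec),
                                   mask=binary, volume_id=volume_id,
                                   slice_index=k))
    return samples


def load_nifti_pair(image_path, mask_path):
    """Load a NIfTI volume/mask pair as float64 HU and integer label arrays."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(os.fspath(image_path)).dataobj)
    msk = np.asanyarray(nib.load(os.fspath(mask_path)).dataobj)
    return np.asarray(vol, dtype=np.float64), np.asarray(msk)


def _write_raster(array: np.ndarray, path: Path, fmt: str):
    if fmt == "npy":
        np.save(path, array)
    elif fmt == "png":
        if array.dtype == np.uint8:
            iio.imwrite(path, array)
        else:
            # lossless 16-bit quantization of [0,1] intensities
            iio.imwrite(path, np.round(array * 65535).astype(np.uint16))
    else:
        raise ValueError(f"unknown raster format {fmt!r}")


def _read_raster(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".npy":
        return np.load(path)
    arr = iio.imread(path)
    if arr.dtype == np.uint16:
        return (arr / 65535.0).astype(np.float32)
    return arr


def write_manifest(samples: list[SliceSample], destination,
                   raster_format: str = "npy") -> int:
    """Persist samples under `destination` and write manifest.csv.

    `raster_format='npy'` round-trips arrays bit-exactly; 'png' stores
    images as 16-bit grayscale PNG (lossless for the quantized values).
    Returns the number of records written.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    ext = {"npy": ".npy", "png": ".png"}[raster_format]
    rows = []
    for s in samples:
        stem = f"{s.volume_id}_{s.slice_index:05d}"
        image_path = dest / f"{stem}_img{ext}"
        mask_path = dest / f"{stem}_msk{ext}"
        try:
            _write_raster(s.image, image_path, raster_format)
            _write_raster(s.mask, mask_path, raster_format)
        except OSError as exc:
            raise OSError(f"failed writing raster under {dest}: {exc}") from exc
        rows.append({"volume_id": s.volume_id, "slice_index": s.slice_index,
                     "n_lesion_pixels": s.n_lesion_pixels,
                     "image_path": image_path.name,
                     "mask_path": mask_path.name})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(dest / "manifest.csv", index=False)
    return len(rows)


def read_manifest(manifest_path) -> list[SliceSample]:
    """Load every sample referenced by a manifest.csv."""
    manifest_path = Path(manifest_path)
    if manifest_path.is_dir():
        manifest_path = manifest_path / "manifest.csv"
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    samples = []
    for rec in df.itertuples(index=False):
        image = _read_raster(base / rec.image_path)
        mask = _read_raster(base / rec.mask_path)
        samples.append(SliceSample(image=image, mask=(mask > 0).astype(np.uint8),
                                   volume_id=str(rec.volume_id),
                                   slice_index=int(rec.slice_index)))
    return samples
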