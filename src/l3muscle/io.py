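"""Readers and writers for CT slices, masks, label maps and configuration.

Grids use (row, col) indexing, 0-based, origin top-left; pixel spacing is
stored as (row_mm, col_mm).  Supported on-disk formats:

* NIfTI (``.nii``/``.nii.gz``) — HU as float32, masks/labels as uint8,
  spacing in the header zooms; lossless round-trip.
* DICOM (``.dcm``) — read-only for CT slices; rescale slope/intercept are
  applied to recover HU and ``PixelSpacing`` supplies the spacing.
* PNG16 + JSON sidecar — HU stored as ``uint16`` with a fixed +1024 offset
  (1 HU quantization), spacing carried by ``<stem>.json``; masks/labels as
  8-bit PNG.

Tabular outputs are UTF-8 comma-separated CSV with a header row and floats
at 6 significant digits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
import yaml
from PIL import Image

from .phantom import CTSlice, LabeledPhantom

__all__ = [
    "RunConfig",
    "read_ct",
    "read_mask",
    "read_labels",
    "write_ct",
    "write_mask",
    "write_labels",
    "export_phantom",
    "write_table",
    "HU_PNG_OFFSET",
]

HU_PNG_OFFSET = 1024
CSV_FLOAT_FORMAT = "%.6g"


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Resolved pipeline settings; defaults are the published operating point."""

    epsilon: float = 10.0
    min_samples: int = 5
    threshold: int | None = -29  # None -> derive by sweeping
    sweep_low: int = -60
    sweep_high: int = 0
    seed: int = 0
    ba_orientation: str = "pred_minus_ref"
    alpha: float = 0.05
    holm: bool = False
    involvement_threshold: float = 0.05

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a YAML or JSON config document; unknown keys are rejected."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# CT slices
# ---------------------------------------------------------------------------


def _nifti_spacing(img) -> tuple[float, float]:
    zooms = img.header.get_zooms()[:2]
    if len(zooms) < 2 or zooms[0] <= 0 or zooms[1] <= 0:
        raise ValueError(f"NIfTI header lacks positive pixel zooms: {zooms}")
    return float(zooms[0]), float(zooms[1])


def _squeeze2d(arr: np.ndarray) -> np.ndarray:
    arr = np.squeeze(np.asarray(arr))
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D slice, got shape {arr.shape}")
    return arr


def read_ct(path: str | Path) -> CTSlice:
    """Read a CT slice (NIfTI, DICOM, or PNG16 + JSON sidecar) as HU + spacing."""
    path = Path(path)
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        return CTSlice(hu=_squeeze2d(np.asanyarray(img.dataobj)), pixel_spacing=_nifti_spacing(img))
    if suffix.endswith(".dcm"):
        ds = pydicom.dcmread(str(path))
        if "PixelSpacing" not in ds:
            raise ValueError(f"{path}: DICOM lacks PixelSpacing")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        hu = ds.pixel_array.astype(np.float32) * slope + intercept
        spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
        return CTSlice(hu=_squeeze2d(hu), pixel_spacing=spacing)
    if suffix.endswith(".png"):
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(f"{path}: missing JSON sidecar with pixel_spacing")
        meta = json.loads(sidecar.read_text())
        if "pixel_spacing" not in meta:
            raise ValueError(f"{sidecar}: sidecar lacks 'pixel_spacing'")
        raw = np.asarray(Image.open(path), dtype=np.int64)
        hu = (raw - int(meta.get("hu_offset", HU_PNG_OFFSET))).astype(np.float32)
        return CTSlice(hu=_squeeze2d(hu), pixel_spacing=tuple(float(v) for v in meta["pixel_spacing"]))
    raise ValueError(f"unsupported CT format: {path}")


def write_ct(path: str | Path, ct: CTSlice) -> Path:
    """Write a CT slice as NIfTI (lossless) or PNG16+JSON (1 HU quantization)."""
    path = Path(path)
    if path.name.lower().endswith((".nii", ".nii.gz")):
        affine = np.diag([ct.pixel_spacing[0], ct.pixel_spacing[1], 1.0, 1.0])
        img = nib.Nifti1Image(ct.hu.astype(np.float32), affine)
        img.header.set_zooms((ct.pixel_spacing[0], ct.pixel_spacing[1]))
        nib.save(img, str(path))
        return path
    if path.suffix.lower() == ".png":
        stored = np.rint(ct.hu).astype(np.int64) + HU_PNG_OFFSET
        if stored.min() < 0 or stored.max() > 65535:
            raise ValueError("HU values outside the PNG16 storable range")
        Image.fromarray(stored.astype(np.uint16)).save(path)
        path.with_suffix(".json").write_text(
            json.dumps(
                {"pixel_spacing": list(ct.pixel_spacing), "hu_offset": HU_PNG_OFFSET},
                sort_keys=True,
            )
        )
        return path
    raise ValueError(f"unsupported CT output format: {path}")


# ---------------------------------------------------------------------------
# Masks and label maps
# ---------------------------------------------------------------------------


def _read_grid(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.name.lower().endswith((".nii", ".nii.gz")):
        return _squeeze2d(np.asanyarray(nib.load(str(path)).dataobj))
    if path.suffix.lower() == ".png":
        return _squeeze2d(np.asarray(Image.open(path)))
    raise ValueError(f"unsupported mask/label format: {path}")


def read_mask(path: str | Path, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read a binary mask; any nonzero value is foreground."""
    arr = _read_grid(path)
    if expected_shape is not None and arr.shape != tuple(expected_shape):
        raise ValueError(f"{path}: mask shape {arr.shape} != expected {tuple(expected_shape)}")
    return arr != 0


def read_labels(path: str | Path, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Read an integer region-label map."""
    arr = _read_grid(path)
    if expected_shape is not None and arr.shape != tuple(expected_shape):
        raise ValueError(f"{path}: label shape {arr.shape} != expected {tuple(expected_shape)}")
    return arr.astype(np.uint8)


def _write_grid(path: str | Path, arr: np.ndarray, spacing: tuple[float, float] | None) -> Path:
    path = Path(path)
    if path.name.lower().endswith((".nii", ".nii.gz")):
        sp = spacing or (1.0, 1.0)
        affine = np.diag([sp[0], sp[1], 1.0, 1.0])
        img = nib.Nifti1Image(arr.astype(np.uint8), affine)
        img.header.set_zooms(sp)
        nib.save(img, str(path))
        return path
    if path.suffix.lower() == ".png":
        Image.fromarray(arr.astype(np.uint8)).save(path)
        return path
    raise ValueError(f"unsupported mask/label output format: {path}")


def write_mask(path: str | Path, mask: np.ndarray, spacing: tuple[float, float] | None = None) -> Path:
    return _write_grid(path, np.asarray(mask, dtype=bool).astype(np.uint8), spacing)


def write_labels(path: str | Path, labels: np.ndarray, spacing: tuple[float, float] | None = None) -> Path:
    return _write_grid(path, np.asarray(labels, dtype=np.uint8), spacing)


def export_phantom(
    phantom: LabeledPhantom,
    out_dir: str | Path,
    *,
    model_mask: np.ndarray | None = None,
    fmt: str = "nifti",
) -> dict[str, Path]:
    """Write one phantom subject (CT, reference, labels, optional model mask).

    Returns the written paths keyed by artifact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = {"nifti": ".nii", "png": ".png"}.get(fmt)
    if ext is None:
        raise ValueError(f"unknown export format {fmt!r} (use 'nifti' or 'png')")
    sid = phantom.subject.subject_id
    sp = phantom.slice.pixel_spacing
    paths = {
        "ct": write_ct(out_dir / f"{sid}_ct{ext}", phantom.slice),
        "reference": write_mask(out_dir / f"{sid}_ref{ext}", phantom.reference_mask, sp),
        "labels": write_labels(out_dir / f"{sid}_labels{ext}", phantom.region_labels, sp),
    }
    if model_mask is not None:
        paths["model"] = write_mask(out_dir / f"{sid}_model{ext}", model_mask, sp)
    return paths


def write_table(path: str | Path, df: pd.DataFrame) -> Path:
    """Write a CSV table with the package-wide dialect (deterministic bytes)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)
    return path
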