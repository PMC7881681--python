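"""Reading TI series from DICOM and writing maps in standard formats.

The reader assembles one MOLLI series from a directory of magnitude DICOM
files: the inversion time comes from the standard ``InversionTime``
attribute, rescale slope/intercept are applied, and the stack is sorted
TI-ascending regardless of filesystem order.  Mixed-series or multi-slice
directories are rejected rather than guessed.

Maps are written as NIfTI (float, invalid pixels NaN, bit-exact round-trip),
CSV (one row per pixel) or PNG preview with a color scale bar; every write
is accompanied by a JSON sidecar recording the provenance needed to
recompute the map (TIs, method, threshold, clamp).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .mapping import ParameterMap, TIImageStack

__all__ = [
    "read_ti_series",
    "write_ti_series",
    "write_map",
    "read_map",
    "write_sidecar",
    "read_sidecar",
]

_SC_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.7"  # secondary capture


def read_ti_series(path) -> TIImageStack:
    """Read one MOLLI TI series from a directory of DICOM files.

    Returns a magnitude :class:`TIImageStack` sorted by ascending inversion
    time.  Raises ``ValueError`` naming the offending file on a missing
    ``InversionTime``, inconsistent dimensions, mixed series or duplicate TIs.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"no such directory: {path}")
    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() == ".dcm")
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"no DICOM files found in {path}")

    frames, tis = [], []
    dims = None
    spacing = None
    series_uid = None
    for f in files:
        ds = pydicom.dcmread(f)
        if "InversionTime" not in ds:
            raise ValueError(f"{f.name}: missing InversionTime attribute")
        ti = float(ds.InversionTime)
        uid = str(getattr(ds, "SeriesInstanceUID", ""))
        if series_uid is None:
            series_uid = uid
        elif uid != series_uid:
            raise ValueError(f"{f.name}: belongs to a different series (mixed directory)")
        pix = ds.pixel_array.astype(float)
        if pix.ndim != 2:
            raise ValueError(f"{f.name}: expected a single-frame 2-D image")
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        pix = pix * slope + intercept
        if dims is None:
            dims = pix.shape
            ps = getattr(ds, "PixelSpacing", [1.0, 1.0])
            spacing = (float(ps[0]), float(ps[1]))
        elif pix.shape != dims:
            raise ValueError(f"{f.name}: image size {pix.shape} differs from {dims}")
        if ti in tis:
            raise ValueError(f"{f.name}: duplicate InversionTime {ti} ms")
        frames.append(pix)
        tis.append(ti)

    order = np.argsort(tis)
    voxels = np.stack([frames[i] for i in order], axis=-1)
    return TIImageStack(
        voxels=voxels,
        tis=np.asarray(tis)[order],
        protocol="custom",
        pixel_spacing=spacing,
        is_magnitude=True,
    )


def write_ti_series(stack: TIImageStack, path, seed: int = 0) -> list[Path]:
    """Write a stack as minimal single-frame DICOM files (test/CLI fixture writer).

    Synthetic secondary-capture-like files: pixel values are rounded to
    uint16, so a stack with integral voxels in [0, 65535] round-trips
    exactly.  Not intended for clinical interchange.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if np.any(stack.voxels < 0) or np.any(stack.voxels > 65535):
        raise ValueError("fixture writer stores uint16; voxels must lie in [0, 65535]")
    series_uid = generate_uid(entropy_srcs=[f"mollifit-series-{seed}"])
    out = []
    for i in range(stack.n_ti):
        ds = Dataset()
        ds.file_meta = FileMetaDataset()
        ds.file_meta.MediaStorageSOPClassUID = _SC_SOP_CLASS
        ds.file_meta.MediaStorageSOPInstanceUID = generate_uid(
            entropy_srcs=[f"mollifit-instance-{seed}-{i}"]
        )
        ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.SOPClassUID = _SC_SOP_CLASS
        ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = generate_uid(entropy_srcs=[f"mollifit-study-{seed}"])
        ds.Modality = "MR"
        ds.PatientName = "PHANTOM^SYNTHETIC"
        ds.PatientID = "MOLLIFIT"
        ds.InversionTime = float(stack.tis[i])
        ds.InstanceNumber = i + 1
        ds.Rows, ds.Columns = stack.shape
        ds.PixelSpacing = [stack.pixel_spacing[0], stack.pixel_spacing[1]]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.PixelData = np.rint(stack.voxels[:, :, i]).astype(np.uint16).tobytes()
        fname = path / f"ti_{i:02d}.dcm"
        ds.save_as(fname, enforce_file_format=True)
        out.append(fname)
    return out


def _grid_and_valid(map_or_grid):
    if isinstance(map_or_grid, ParameterMap):
        return map_or_grid.t1, map_or_grid.valid, map_or_grid.pixel_spacing
    grid = np.asarray(map_or_grid, dtype=float)
    return grid, np.isfinite(grid), (1.0, 1.0)


def write_map(map_or_grid, path, format: str = "nifti") -> Path:
    """Write a parameter map (or bare grid, e.g. ECV) to ``path``.

    ``format``: ``"nifti"`` (float64, invalid pixels NaN, bit-exact
    round-trip), ``"csv"`` (columns row, col, t1, valid) or ``"png"``
    (preview with scale bar, invalid pixels blank).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    grid, valid, spacing = _grid_and_valid(map_or_grid)
    data = np.where(valid, grid, np.nan)

    if format == "nifti":
        affine = np.diag([spacing[0], spacing[1], 1.0, 1.0])
        nib.save(nib.Nifti1Image(data.astype(np.float64), affine), str(path))
    elif format == "csv":
        rows, cols = np.indices(grid.shape)
        pd.DataFrame(
            {
                "row": rows.ravel(),
                "col": cols.ravel(),
                "t1": data.ravel(),
                "valid": valid.ravel(),
            }
        ).to_csv(path, index=False)
    elif format == "png":
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        masked = np.ma.masked_invalid(data)
        im = ax.imshow(masked, cmap="magma", origin="upper")
        fig.colorbar(im, ax=ax, label="T1 (ms)")
        ax.set_xlabel("col")
        ax.set_ylabel("row")
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def read_map(path) -> np.ndarray:
    """Read a NIfTI map written by :func:`write_map` (NaN = invalid)."""
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=np.float64)[:, :]


def write_sidecar(path, **metadata) -> Path:
    """JSON sidecar with everything needed to recompute the artifact."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    path.write_text(json.dumps(metadata, indent=2, default=_default, sort_keys=True))
    return path


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
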