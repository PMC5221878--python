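"""CT slice model, Hounsfield-unit calibration, display windowing and mask I/O.

A :class:`CTSlice` is one axial CT image held as a floating-point matrix of
Hounsfield units (HU) with per-axis pixel spacing in millimetres.  Pixels are
addressed ``(row, col)``, 0-based, and geometric quantities refer to pixel
centers; every millimetre quantity downstream is derived from the spacing
carried here.  Integer storage conventions of on-disk formats (DICOM rescale
slope/intercept) are resolved at this boundary so the rest of the pipeline
never sees raw stored values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "CTSlice",
    "WindowPreset",
    "LUNG_WINDOW",
    "MEDIASTINAL_WINDOW",
    "apply_window",
    "load_ct_slice",
    "save_ct_slice_dicom",
    "save_mask_png",
    "load_mask_png",
    "mask_to_rle",
    "rle_to_mask",
    "save_mask_rle_json",
    "load_mask_rle_json",
]


@dataclass(frozen=True)
class WindowPreset:
    """Display window: linear HU -> [0, 1] map centred at ``level``."""

    level: float
    width: float
    name: str = ""

    def __post_init__(self) -> None:
        if not self.width > 0:
            raise ValueError(f"window width must be > 0, got {self.width}")


#: Lung window used while seeding/growing the tumor ROI.
LUNG_WINDOW = WindowPreset(level=-700.0, width=1500.0, name="lung")
#: Mediastinal window used while separating vessels/chest wall.
MEDIASTINAL_WINDOW = WindowPreset(level=50.0, width=450.0, name="mediastinal")


@dataclass
class CTSlice:
    """One axial CT image in Hounsfield units.

    Parameters
    ----------
    pixels
        2-D float matrix of HU values (finite).
    spacing_row, spacing_col
        Pixel spacing in mm along rows (vertical) and columns (horizontal);
        strictly positive.  Anisotropic spacing is supported throughout.
    thickness_mm
        Nominal reconstruction thickness tag (1.0 or 5.0 in the intended
        protocol); metadata only.
    kernel
        Reconstruction kernel tag, ``"sharp"`` (high-frequency) or
        ``"standard"``.
    id
        Opaque identifier.
    """

    pixels: np.ndarray
    spacing_row: float
    spacing_col: float
    thickness_mm: float = 1.0
    kernel: str = "sharp"
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError(f"pixels must be a non-empty 2-D matrix, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("pixels contain non-finite HU values")
        if not (self.spacing_row > 0 and self.spacing_col > 0):
            raise ValueError(
                f"pixel spacing must be strictly positive, got "
                f"({self.spacing_row}, {self.spacing_col})"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_row * self.spacing_col


def apply_window(ct: CTSlice, preset: WindowPreset) -> np.ndarray:
    """Map HU to display intensities in [0, 1] under a window preset.

    HU at or below ``level - width/2`` clamp to 0, at or above
    ``level + width/2`` clamp to 1; the map is linear in between (so
    ``HU == level`` maps to 0.5).  Monotone non-decreasing in HU.
    """
    lo = preset.level - preset.width / 2.0
    out = (ct.pixels - lo) / preset.width
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------

_KERNEL_SHARP_HINTS = ("sharp", "b70", "b80", "high", "hf", "lung", "edge")


def _kernel_tag(raw: str) -> str:
    raw_l = str(raw).lower()
    return "sharp" if any(h in raw_l for h in _KERNEL_SHARP_HINTS) else "standard"


def _squeeze_single_slice(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        if 1 in arr.shape:
            arr = arr.reshape([s for s in arr.shape if s != 1][:2]) if arr.size else arr
        else:
            raise ValueError(
                f"expected a single 2-D slice, got a volume of shape {arr.shape}"
            )
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got {arr.ndim}-D input")
    return arr


def load_ct_slice(
    source: str | Path | np.ndarray,
    *,
    spacing: Sequence[float] | None = None,
    thickness_mm: float | None = None,
    kernel: str | None = None,
    id: str | None = None,
) -> CTSlice:
    """Load a CT slice from DICOM, NPY/CSV raster (with JSON sidecar), or array.

    For DICOM, HU are recovered as ``stored * RescaleSlope + RescaleIntercept``
    and spacing is taken from ``PixelSpacing`` (row, col).  For plain rasters
    the pixels are assumed to already be HU and metadata comes from a sidecar
    JSON file (same stem, ``.json`` suffix) or from the keyword arguments,
    which take precedence.  A 3-D input is accepted only if it contains a
    single slice.

    Raises
    ------
    ValueError
        If spacing cannot be determined (the message names the missing field)
        or the input is not a single 2-D slice.
    """
    meta: dict = {}
    if isinstance(source, np.ndarray):
        px = _squeeze_single_slice(np.asarray(source, dtype=float))
        src_id = "array"
    else:
        path = Path(source)
        suffix = path.suffix.lower()
        src_id = path.stem
        if suffix in (".dcm", ".dicom", ""):
            import pydicom

            ds = pydicom.dcmread(str(path), force=True)
            raw = ds.pixel_array
            px = _squeeze_single_slice(np.asarray(raw, dtype=float))
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            px = px * slope + intercept
            if getattr(ds, "PixelSpacing", None) is not None:
                meta["spacing"] = [float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])]
            if getattr(ds, "SliceThickness", None) is not None:
                meta["thickness_mm"] = float(ds.SliceThickness)
            if getattr(ds, "ConvolutionKernel", None) is not None:
                meta["kernel"] = _kernel_tag(str(ds.ConvolutionKernel))
        elif suffix == ".npy":
            px = _squeeze_single_slice(np.asarray(np.load(path), dtype=float))
            meta.update(_read_sidecar(path))
        elif suffix == ".csv":
            px = _squeeze_single_slice(np.loadtxt(path, delimiter=",", dtype=float, ndmin=2))
            meta.update(_read_sidecar(path))
        else:
            raise ValueError(f"unsupported image format: {suffix!r}")

    if spacing is not None:
        meta["spacing"] = [float(spacing[0]), float(spacing[1])]
    if thickness_mm is not None:
        meta["thickness_mm"] = float(thickness_mm)
    if kernel is not None:
        meta["kernel"] = kernel

    if "spacing" not in meta:
        raise ValueError("missing required metadata field: spacing (mm per pixel)")

    return CTSlice(
        pixels=px,
        spacing_row=meta["spacing"][0],
        spacing_col=meta["spacing"][1],
        thickness_mm=meta.get("thickness_mm", 1.0),
        kernel=meta.get("kernel", "standard"),
        id=id if id is not None else meta.get("id", src_id),
    )


def _read_sidecar(path: Path) -> dict:
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            return json.load(fh)
    return {}


def save_ct_slice_dicom(ct: CTSlice, path: str | Path) -> Path:
    """Write a slice as a minimal single-frame CT DICOM file.

    HU are stored as signed 16-bit integers with slope 1 / intercept 0, so
    integer-valued HU rasters round-trip bit-exactly through
    :func:`load_ct_slice`.  Non-integer HU are rounded to the nearest integer
    on write (the format stores integers).
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    path = Path(path)
    stored = np.round(ct.pixels).astype(np.int16)

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=file_meta, preamble=b"\0" * 128)
    ds.SOPClassUID = file_meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.SeriesInstanceUID = generate_uid()
    ds.StudyInstanceUID = generate_uid()
    ds.PatientName = "phantom"
    ds.PatientID = ct.id or "phantom"
    ds.Rows, ds.Columns = stored.shape
    ds.PixelSpacing = [f"{ct.spacing_row:.6f}", f"{ct.spacing_col:.6f}"]
    ds.SliceThickness = f"{ct.thickness_mm:.3f}"
    ds.ConvolutionKernel = ct.kernel
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.RescaleSlope = "1"
    ds.RescaleIntercept = "0"
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return path


# ---------------------------------------------------------------------------
# mask I/O
# ---------------------------------------------------------------------------


def save_mask_png(mask: np.ndarray, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit PNG (foreground 255, background 0)."""
    from PIL import Image

    path = Path(path)
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(path)
    return path


def load_mask_png(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG; any non-zero pixel is foreground."""
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("L"))
    return arr > 0


def mask_to_rle(mask: np.ndarray) -> dict:
    """Row-major run-length encoding: alternating background/foreground runs.

    The first run counts background pixels (possibly 0), as in the common
    uncompressed-RLE mask convention.
    """
    m = np.asarray(mask, dtype=bool).ravel()
    if m.size == 0:
        return {"shape": list(np.asarray(mask).shape), "counts": []}
    change = np.flatnonzero(np.diff(m.astype(np.int8))) + 1
    bounds = np.concatenate(([0], change, [m.size]))
    counts = np.diff(bounds).tolist()
    if m[0]:  # convention: start with a (possibly zero-length) background run
        counts = [0] + counts
    return {"shape": list(np.asarray(mask).shape), "counts": counts}


def rle_to_mask(rle: Mapping) -> np.ndarray:
    shape = tuple(rle["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos = 0
    fg = False
    for run in rle["counts"]:
        if fg:
            flat[pos : pos + run] = True
        pos += run
        fg = not fg
    return flat.reshape(shape)


def save_mask_rle_json(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(mask_to_rle(mask), fh)
    return path


def load_mask_rle_json(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        return rle_to_mask(json.load(fh))
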