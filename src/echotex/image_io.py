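"""Reading ultrasonograms and preparing 8-bit normalized grey images.

B-mode scanners export frames either as single-frame DICOM or as ordinary
raster files (PNG/TIFF/BMP).  The analysis chain is: read the container,
collapse RGB to 8-bit grey (ITU-R BT.601 luma), then linearly stretch the
grey levels onto the full 0-255 range ("byte-scale" normalization)

    G_i = T * (f_i - f_min) / (f_max - f_min),   T = 255,

with f_min/f_max the per-image extrema, before any region-of-interest
statistic is computed.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from PIL import Image, UnidentifiedImageError

__all__ = [
    "FormatError",
    "RawImage",
    "GreyImage",
    "read_image",
    "rgb_to_grey",
    "byte_scale_normalize",
    "write_png",
    "parse_plane_from_name",
    "read_manifest",
    "PLANES",
]

logger = logging.getLogger(__name__)

PLANES = ("L", "T", "O1", "O2")

_PLANE_RE = re.compile(r"_(L|T|O1|O2)$", re.IGNORECASE)


class FormatError(ValueError):
    """Raised for unreadable or unsupported image containers."""


def round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round to nearest integer with ties going away from zero-wards up.

    Used everywhere a float grey level becomes an integer one so results
    are bit-exact across platforms (numpy's default rounds half to even).
    """
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5)


@dataclass
class RawImage:
    """Pixel matrix as read from the container, before grey conversion.

    ``pixels`` is (rows, cols) for grey or (rows, cols, 3) for RGB;
    ``bit_depth`` is bits per sample.  ``plane`` is the scanning-plane label
    (L, T, O1, O2) or None when unlabeled.
    """

    pixels: np.ndarray
    channels: int
    bit_depth: int
    source_id: str = ""
    plane: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.size == 0:
            raise ValueError("image has no pixels")
        if self.channels not in (1, 3):
            raise ValueError(f"channels must be 1 or 3, got {self.channels}")
        expected_ndim = 2 if self.channels == 1 else 3
        if self.pixels.ndim != expected_ndim:
            raise ValueError(
                f"{self.channels}-channel image must be {expected_ndim}-D, "
                f"got shape {self.pixels.shape}"
            )
        top = (1 << self.bit_depth) - 1
        if self.pixels.min() < 0 or self.pixels.max() > top:
            raise ValueError(f"sample values outside [0, {top}]")
        if self.plane is not None and self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}; expected one of {PLANES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class GreyImage:
    """8-bit single-channel image, optionally byte-scale normalized."""

    pixels: np.ndarray
    normalized: bool = False
    plane: str | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("GreyImage requires a non-empty 2-D matrix")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("grey levels must lie in [0, 255]")
        if self.pixels.dtype != np.uint8:
            self.pixels = self.pixels.astype(np.uint8)
        if self.plane is not None and self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}; expected one of {PLANES}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def parse_plane_from_name(path: str | Path) -> str | None:
    """Extract a scanning-plane label from a ``..._L`` / ``..._o2`` file stem."""
    m = _PLANE_RE.search(Path(path).stem)
    return m.group(1).upper() if m else None


def _is_dicom(path: Path) -> bool:
    if path.suffix.lower() in (".dcm", ".dicom"):
        return True
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def _read_dicom(path: Path) -> RawImage:
    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # pydicom raises a zoo of types
        raise FormatError(f"cannot read DICOM file {path}: {exc}") from exc
    n_frames = int(getattr(ds, "NumberOfFrames", 1) or 1)
    if n_frames > 1:
        raise FormatError(
            f"{path} is a multi-frame DICOM ({n_frames} frames); "
            "export the frame of interest as a single-frame file first"
        )
    try:
        pixels = ds.pixel_array
    except Exception as exc:
        raise FormatError(f"cannot decode pixel data of {path}: {exc}") from exc
    samples = int(getattr(ds, "SamplesPerPixel", 1))
    bits = int(getattr(ds, "BitsStored", 8))
    if samples == 1 and str(getattr(ds, "PhotometricInterpretation", "")) == "MONOCHROME1":
        # MONOCHROME1 displays low values bright; flip to larger = brighter.
        pixels = ((1 << bits) - 1) - pixels
    if samples not in (1, 3):
        raise FormatError(f"{path}: unsupported SamplesPerPixel={samples}")
    if samples == 1 and bits not in (8, 16):
        raise FormatError(f"{path}: unsupported BitsStored={bits} for greyscale")
    return RawImage(pixels=pixels, channels=samples, bit_depth=bits,
                    source_id=str(path))


def _read_raster(path: Path) -> RawImage:
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode == "P":
                im = im.convert("RGB")
                mode = "RGB"
            arr = np.asarray(im)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise FormatError(f"cannot read image file {path}: {exc}") from exc
    if mode in ("RGBA", "LA"):
        raise FormatError(
            f"{path} has an alpha channel; remove it before analysis"
        )
    if mode == "RGB":
        return RawImage(pixels=arr, channels=3, bit_depth=8, source_id=str(path))
    if mode == "L":
        return RawImage(pixels=arr, channels=1, bit_depth=8, source_id=str(path))
    if mode in ("I", "I;16", "I;16B", "I;16L"):
        return RawImage(pixels=arr.astype(np.int64), channels=1, bit_depth=16,
                        source_id=str(path))
    raise FormatError(f"{path}: unsupported image mode {mode!r}")


def read_image(path: str | Path, plane: str | None = None) -> RawImage:
    """Read a single-frame DICOM, PNG, TIFF or BMP ultrasonogram.

    The scanning-plane label is taken from ``plane`` when given, otherwise
    parsed from a ``_L`` / ``_T`` / ``_O1`` / ``_O2`` file-name suffix.
    """
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no such image file: {path}")
    raw = _read_dicom(path) if _is_dicom(path) else _read_raster(path)
    raw.plane = plane if plane is not None else parse_plane_from_name(path)
    if raw.plane is not None and raw.plane not in PLANES:
        raise ValueError(f"unknown plane {raw.plane!r}")
    return raw


def _rescale_to_8bit(values: np.ndarray) -> np.ndarray:
    """Linear min-max stretch of deeper-than-8-bit samples onto 0-255."""
    values = values.astype(np.float64)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values, dtype=np.uint8)
    return round_half_up(255.0 * (values - lo) / (hi - lo)).astype(np.uint8)


# ITU-R BT.601 luma weights for RGB -> grey.
_LUMA = np.array([0.299, 0.587, 0.114])


def rgb_to_grey(img: RawImage) -> GreyImage:
    """Collapse an RGB frame to 8-bit grey with BT.601 luma weights.

    Grey input passes through unchanged (16-bit samples are min-max
    rescaled to 8 bits first).  The result is not yet normalized.
    """
    if img.channels == 1:
        if img.bit_depth > 8:
            pixels = _rescale_to_8bit(img.pixels)
        else:
            pixels = img.pixels.astype(np.uint8)
    else:
        if img.bit_depth != 8:
            raise ValueError("RGB input must be 8 bits per sample")
        luma = img.pixels.astype(np.float64) @ _LUMA
        pixels = round_half_up(luma).astype(np.uint8)
    return GreyImage(pixels=pixels, normalized=False,
                     plane=img.plane, source_id=img.source_id)


def byte_scale_normalize(img: GreyImage) -> GreyImage:
    """Stretch grey levels to fill 0-255: G = 255(f - f_min)/(f_max - f_min).

    f_min/f_max are the whole-image extrema.  A constant image has no
    defined stretch; it maps to all zeros with a warning so batch runs
    survive degenerate frames.  Normalizing an already-normalized image is
    a no-op (the stretch is idempotent).
    """
    if img.normalized:
        return img
    f = img.pixels.astype(np.float64)
    f_min, f_max = f.min(), f.max()
    if f_max == f_min:
        warnings.warn(
            f"constant image {img.source_id or '<unnamed>'} "
            "(f_max == f_min); normalized output set to all zeros",
            stacklevel=2,
        )
        logger.warning("constant image %s: byte-scale undefined, output zeroed",
                       img.source_id)
        out = np.zeros_like(img.pixels)
    else:
        out = round_half_up(255.0 * (f - f_min) / (f_max - f_min)).astype(np.uint8)
    return GreyImage(pixels=out, normalized=True,
                     plane=img.plane, source_id=img.source_id)


def write_png(img: GreyImage, path: str | Path) -> Path:
    """Write an 8-bit grey PNG; round-trips bit-identically via read_image."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img.pixels, mode="L").save(path, format="PNG")
    return path


MANIFEST_COLUMNS = ("bird_id", "group", "plane", "path")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read an image manifest CSV with columns bird_id, group, plane, path."""
    df = pd.read_csv(path, dtype={"bird_id": str, "group": str, "plane": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {missing}")
    bad = sorted(set(df["plane"]) - set(PLANES))
    if bad:
        raise ValueError(f"manifest {path} has unknown plane labels: {bad}")
    return df[list(MANIFEST_COLUMNS)]
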