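"""Hyperspectral cube and annotation-mask I/O.

Cubes are stored as ENVI pairs (plain-text ``.hdr`` plus raw binary, BSQ on
write; BSQ/BIL/BIP accepted on read).  Annotation masks are single-channel
PNGs with the label enum {0 unlabeled, 1 esophagus, 2 stomach, 3 cancer}.
All readers validate metadata and reject inconsistencies rather than coerce.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "LABEL_UNLABELED",
    "LABEL_ESOPHAGUS",
    "LABEL_STOMACH",
    "LABEL_CANCER",
    "CLASS_NAMES",
    "HyperCube",
    "AnnotationMask",
    "FormatError",
    "read_cube",
    "write_cube",
    "read_mask",
    "write_mask",
    "cube_to_rgb",
]

LABEL_UNLABELED = 0
LABEL_ESOPHAGUS = 1
LABEL_STOMACH = 2
LABEL_CANCER = 3

#: names of the three annotated tissue classes, indexed by label - 1
CLASS_NAMES = ("esophagus", "stomach", "cancer")

_VALID_LABELS = frozenset({0, 1, 2, 3})


class FormatError(ValueError):
    """Inconsistent or unsupported on-disk metadata."""


@dataclass
class HyperCube:
    """Reflectance cube: H x W spatial by B spectral bands.

    Parameters
    ----------
    reflectance : ndarray, shape (H, W, B)
        Non-negative, finite reflectance values (unitless).
    wavelengths : ndarray, shape (B,)
        Strictly increasing band-center wavelengths in nm.
    patient_id : str
        Provenance tag used for patient-wise cross-validation.
    """

    reflectance: np.ndarray
    wavelengths: np.ndarray
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.reflectance.ndim != 3:
            raise FormatError("reflectance must be H x W x B")
        if self.wavelengths.ndim != 1 or self.wavelengths.size != self.reflectance.shape[2]:
            raise FormatError(
                f"wavelength count {self.wavelengths.size} does not match "
                f"band count {self.reflectance.shape[2]}"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise FormatError("reflectance contains non-finite values")
        if np.any(self.reflectance < 0):
            raise FormatError("reflectance must be >= 0")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise FormatError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.reflectance.shape

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[2]


@dataclass
class AnnotationMask:
    """Per-pixel tissue labels aligned to a cube's spatial grid."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 2:
            raise FormatError("mask must be a 2-D label grid")
        present = set(np.unique(self.labels).tolist())
        if not present <= _VALID_LABELS:
            raise FormatError(f"mask contains labels outside {{0,1,2,3}}: {sorted(present - _VALID_LABELS)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def check_aligned(self, cube: HyperCube) -> None:
        if self.labels.shape != cube.reflectance.shape[:2]:
            raise FormatError(
                f"mask shape {self.labels.shape} does not match cube "
                f"spatial shape {cube.reflectance.shape[:2]}"
            )


# ---------------------------------------------------------------------------
# ENVI

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16, 13: np.uint32}


def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("missing ENVI magic line")
    # strip the magic, then collect key = value entries; {...} blocks may span lines
    body = text.lstrip()[4:]
    fields: dict[str, str] = {}
    # horizontal whitespace only around '=': an empty value must not swallow
    # the following line
    pattern = re.compile(r"^[ \t]*([\w ]+?)[ \t]*=[ \t]*(\{[^}]*\}|[^\n]*)", re.M)
    for m in pattern.finditer(body):
        key = m.group(1).strip().lower()
        val = m.group(2).strip()
        if val.startswith("{"):
            val = val[1:-1]
        fields[key] = val
    return fields


def read_cube(path: str | Path, patient_id: str | None = None) -> HyperCube:
    """Read an ENVI cube (``.hdr`` beside the binary, any of BSQ/BIL/BIP)."""
    path = Path(path)
    hdr_path = path if path.suffix == ".hdr" else path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FormatError(f"no ENVI header found for {path}")
    fields = _parse_envi_header(hdr_path.read_text())

    try:
        lines = int(fields["lines"])
        samples = int(fields["samples"])
        bands = int(fields["bands"])
        dtype_code = int(fields["data type"])
        interleave = fields.get("interleave", "bsq").strip().lower()
    except KeyError as exc:
        raise FormatError(f"ENVI header missing required field: {exc}") from exc

    if "wavelength" not in fields:
        raise FormatError("ENVI header missing wavelength metadata")
    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].replace("\n", " ").split(",") if tok.strip()]
    )
    if wavelengths.size != bands:
        raise FormatError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )
    if dtype_code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type {dtype_code}")
    byte_order = int(fields.get("byte order", 0))
    dtype = np.dtype(_ENVI_DTYPES[dtype_code]).newbyteorder("<" if byte_order == 0 else ">")
    offset = int(fields.get("header offset", 0))

    bin_path = hdr_path.with_suffix("") if hdr_path != path else path.with_suffix(".raw")
    if not bin_path.exists():
        for cand in (hdr_path.with_suffix(".raw"), hdr_path.with_suffix(".img"),
                     hdr_path.with_suffix(".dat")):
            if cand.exists():
                bin_path = cand
                break
    if not bin_path.exists():
        raise FormatError(f"no binary file found next to {hdr_path}")

    raw = np.fromfile(bin_path, dtype=dtype, offset=offset)
    expected = lines * samples * bands
    if raw.size != expected:
        raise FormatError(
            f"binary holds {raw.size} values, header implies {expected}"
        )
    if interleave == "bsq":
        data = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(lines, samples, bands)
    else:
        raise FormatError(f"unknown interleave {interleave!r}")

    pid = patient_id if patient_id is not None else fields.get("description", "").strip()
    return HyperCube(np.ascontiguousarray(data, dtype=np.float64), wavelengths, pid)


def write_cube(cube: HyperCube, path: str | Path) -> Path:
    """Write a cube as float32 little-endian BSQ with a ``.hdr`` sidecar.

    Returns the path of the binary file.  Round-trips with :func:`read_cube`
    bit-exactly for float32-representable data.
    """
    path = Path(path)
    if path.suffix == ".hdr":
        path = path.with_suffix(".raw")
    h, w, b = cube.shape
    wl = ", ".join(f"{x:.6f}" for x in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"description = {cube.patient_id}\n"
        f"samples = {w}\n"
        f"lines = {h}\n"
        f"bands = {b}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{ {wl} }}\n"
    )
    path.parent.mkdir(parents=True, exist_ok=True)
    path.with_suffix(path.suffix + ".hdr").write_text(hdr)
    bsq = np.ascontiguousarray(cube.reflectance.transpose(2, 0, 1), dtype="<f4")
    bsq.tofile(path)
    return path


# ---------------------------------------------------------------------------
# Masks

def write_mask(mask: AnnotationMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(mask.labels, mode="L").save(path, format="PNG")
    return path


def read_mask(path: str | Path, cube: HyperCube | None = None) -> AnnotationMask:
    """Read a label PNG; if ``cube`` is given, require spatial alignment."""
    img = Image.open(path)
    if img.mode not in ("L", "P", "I"):
        img = img.convert("L")
    labels = np.asarray(img)
    if labels.ndim != 2:
        raise FormatError("mask PNG must be single-channel")
    mask = AnnotationMask(labels)
    if cube is not None:
        mask.check_aligned(cube)
    return mask


# ---------------------------------------------------------------------------
# RGB preview

#: default band windows (nm) for the RGB reconstruction, chosen in
#: hemoglobin-insensitive regions; purely cosmetic.
RGB_WINDOWS = {"R": (614.0, 624.0), "G": (540.0, 550.0), "B": (530.0, 540.0)}


def cube_to_rgb(cube: HyperCube, windows: dict | None = None) -> np.ndarray:
    """Reconstruct an 8-bit RGB preview from band-window means.

    Each channel is the mean reflectance over its wavelength window,
    min-max scaled to 0..255 over the image (a spatially constant channel
    maps to mid-gray 127).
    """
    windows = windows or RGB_WINDOWS
    out = np.empty(cube.shape[:2] + (3,), dtype=np.uint8)
    for i, ch in enumerate(("R", "G", "B")):
        lo, hi = windows[ch]
        sel = (cube.wavelengths >= lo) & (cube.wavelengths <= hi)
        if not sel.any():
            raise FormatError(f"RGB window {ch} {lo}-{hi} nm outside wavelength range")
        band = cube.reflectance[:, :, sel].mean(axis=2)
        bmin, bmax = band.min(), band.max()
        if bmax - bmin <= 0:
            out[:, :, i] = 127
        else:
            out[:, :, i] = np.round(255.0 * (band - bmin) / (bmax - bmin)).astype(np.uint8)
    return out
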