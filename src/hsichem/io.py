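"""Hypercube containers, ENVI-style I/O, reflectance calibration, ROI and masking.

Conventions: arrays are row-major ``(rows, cols, bands)``; coordinates are
0-based; an ROI is the half-open window ``[start, start + size)``.
"""
from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

REFLECTANCE_CEILING = 1.05

_ENVI_DTYPES = {1: "u1", 2: "i2", 3: "i4", 4: "f4", 5: "f8", 12: "u2", 13: "u4", 14: "i8"}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class Hypercube:
    """A (rows, cols, bands) data block with its wavelength axis.

    ``kind`` is ``"raw"`` for detector intensities and ``"reflectance"``
    after black/white calibration.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    kind: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be 3-D (rows, cols, bands), got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength axis length {len(self.wavelengths)} != band count {self.data.shape[2]}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")
        if self.kind not in ("raw", "reflectance"):
            raise ValueError(f"unknown cube kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band_index(self, wavelength_nm: float) -> int:
        """Nearest-band lookup; ties resolve to the lower index."""
        d = np.abs(self.wavelengths - wavelength_nm)
        return int(np.argmin(d))  # argmin returns first (lower) index on ties


@dataclass
class ReferenceFrame:
    """Dark ('black') or white reference; full frame or a single broadcastable line."""

    data: np.ndarray
    role: str = "white"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("reference frame must be 3-D (rows or 1, cols, bands)")
        if self.role not in ("black", "white"):
            raise ValueError(f"reference role must be 'black' or 'white', got {self.role!r}")


@dataclass
class ROISelection:
    height: int = 100
    width: int = 100
    row_start: int | None = None
    col_start: int | None = None
    placement: str = "center"

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("ROI size must be positive")
        if self.placement not in ("center", "explicit"):
            raise ValueError("placement must be 'center' or 'explicit'")
        if self.placement == "explicit" and (self.row_start is None or self.col_start is None):
            raise ValueError("explicit placement requires row_start and col_start")

    def resolve(self, n_rows: int, n_cols: int) -> tuple[int, int]:
        if self.placement == "center":
            r0 = (n_rows - self.height) // 2
            c0 = (n_cols - self.width) // 2
        else:
            r0, c0 = int(self.row_start), int(self.col_start)
        if r0 < 0 or c0 < 0 or r0 + self.height > n_rows or c0 + self.width > n_cols:
            raise ValueError(
                f"ROI {self.height}x{self.width} at ({r0},{c0}) does not fit in "
                f"{n_rows}x{n_cols} scene"
            )
        return r0, c0


# ---------------------------------------------------------------------------
# ENVI-style container
# ---------------------------------------------------------------------------

def _parse_envi_header(path: Path) -> dict:
    text = path.read_text()
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError(f"{path}: missing ENVI magic line")
    fields: dict[str, str] = {}
    # collapse {...} blocks that may span lines
    body = text.split("\n", 1)[1]
    i = 0
    while i < len(body):
        eq = body.find("=", i)
        if eq == -1:
            break
        key = body[i:eq].strip().lower()
        rest = body[eq + 1 :].lstrip()
        if rest.startswith("{"):
            close = rest.find("}")
            if close == -1:
                raise ValueError(f"{path}: unterminated {{...}} block for key {key!r}")
            val = rest[1:close]
            consumed = (eq + 1) + (len(body[eq + 1 :]) - len(rest)) + close + 1
        else:
            nl = rest.find("\n")
            nl = len(rest) if nl == -1 else nl
            val = rest[:nl]
            consumed = (eq + 1) + (len(body[eq + 1 :]) - len(rest)) + nl
        fields[key] = val.strip()
        i = consumed
    return fields


def read_envi(header_path: str | Path) -> Hypercube:
    """Read a band-sequential/interleaved ENVI cube (``.hdr`` + sibling data file)."""
    header_path = Path(header_path)
    hdr = _parse_envi_header(header_path)
    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in hdr:
            raise ValueError(f"{header_path}: header missing required field {key!r}")
    if "wavelength" not in hdr:
        raise ValueError(f"{header_path}: header has no 'wavelength' list")
    cols = int(hdr["samples"])
    rows = int(hdr["lines"])
    bands = int(hdr["bands"])
    interleave = hdr["interleave"].lower()
    byte_order = int(hdr.get("byte order", 0))
    code = int(hdr["data type"])
    if code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(_ENVI_DTYPES[code]).newbyteorder("<" if byte_order == 0 else ">")
    wavelengths = np.array([float(w) for w in hdr["wavelength"].replace("\n", " ").split(",")])
    if len(wavelengths) != bands:
        raise ValueError(f"wavelength list length {len(wavelengths)} != bands {bands}")

    data_path = header_path.with_suffix(".dat")
    if not data_path.exists():
        data_path = header_path.with_suffix("")
        if not data_path.exists():
            raise FileNotFoundError(f"no data file next to {header_path}")
    flat = np.fromfile(data_path, dtype=dtype)
    if flat.size != rows * cols * bands:
        raise ValueError(
            f"{data_path}: has {flat.size} values, header implies {rows * cols * bands}"
        )
    if interleave == "bsq":
        data = flat.reshape(bands, rows, cols).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(rows, bands, cols).transpose(0, 2, 1)
    elif interleave == "bip":
        data = flat.reshape(rows, cols, bands)
    else:
        raise ValueError(f"unsupported interleave {interleave!r}")
    kind = hdr.get("hsichem kind", "raw")
    return Hypercube(np.ascontiguousarray(data.astype(np.float64)), wavelengths, kind=kind)


def write_envi(cube: Hypercube, header_path: str | Path, interleave: str = "bsq") -> None:
    """Write ``cube`` as ``.hdr`` + ``.dat`` (float64, little endian)."""
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(".hdr")
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    rows, cols, bands = cube.shape
    data = np.asarray(cube.data, dtype="<f8")
    if interleave == "bsq":
        out = data.transpose(2, 0, 1)
    elif interleave == "bil":
        out = data.transpose(0, 2, 1)
    else:
        out = data
    wl = ", ".join(f"{w:.6f}" for w in cube.wavelengths)
    header_path.write_text(
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "data type = 5\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"hsichem kind = {cube.kind}\n"
        f"wavelength = {{{wl}}}\n"
    )
    np.ascontiguousarray(out).tofile(header_path.with_suffix(".dat"))


# ---------------------------------------------------------------------------
# Calibration and spectra extraction
# ---------------------------------------------------------------------------

def calibrate_reflectance(
    cube: Hypercube, black: ReferenceFrame, white: ReferenceFrame
) -> Hypercube:
    """Black/white correction R = (I - B) / (W - B).

    Reference frames broadcast over rows when given as a single line.
    Output is clipped to [0, 1.05]; the number of clipped voxels is logged.
    """
    if black.role != "black" or white.role != "white":
        raise ValueError("reference roles must be (black, white) in that order")
    b = black.data
    w = white.data
    denom = w - b
    if np.any(denom <= 0):
        bad = np.unique(np.where(np.any(denom <= 0, axis=(0, 1)))[0]) if denom.ndim == 3 else []
        raise ValueError(f"white - black <= 0 at band indices {list(map(int, bad))[:10]}")
    r = (cube.data - b) / denom
    n_clip = int(np.count_nonzero((r < 0) | (r > REFLECTANCE_CEILING)))
    if n_clip:
        log.info("calibrate_reflectance: clipped %d voxels to [0, %.2f]", n_clip, REFLECTANCE_CEILING)
    r = np.clip(r, 0.0, REFLECTANCE_CEILING)
    return Hypercube(r, cube.wavelengths, kind="reflectance")


def extract_roi(cube: Hypercube, roi: ROISelection) -> Hypercube:
    """Cut the ROI sub-cube; raises if the window does not fit (no silent shrink)."""
    r0, c0 = roi.resolve(cube.shape[0], cube.shape[1])
    sub = cube.data[r0 : r0 + roi.height, c0 : c0 + roi.width, :]
    return Hypercube(sub.copy(), cube.wavelengths, kind=cube.kind)


def mean_spectrum(cube: Hypercube, mask: np.ndarray | None = None) -> np.ndarray:
    """Per-band arithmetic mean over (optionally masked) pixels."""
    if mask is None:
        return cube.data.reshape(-1, cube.n_bands).mean(axis=0)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError(f"mask shape {mask.shape} != spatial shape {cube.shape[:2]}")
    if not mask.any():
        raise ValueError("mask selects no pixels")
    return cube.data[mask].mean(axis=0)


def foreground_mask(
    cube: Hypercube,
    threshold_band_nm: float,
    threshold: float,
    keep: str = "below",
    largest_component: bool = True,
) -> np.ndarray:
    """Threshold the reflectance image at the band nearest ``threshold_band_nm``.

    ``keep='below'`` marks pixels darker than the threshold as foreground
    (sample darker than a bright dish); ``'above'`` inverts the rule.
    """
    if not (cube.wavelengths[0] <= threshold_band_nm <= cube.wavelengths[-1]):
        raise ValueError(
            f"threshold band {threshold_band_nm} nm outside range "
            f"[{cube.wavelengths[0]}, {cube.wavelengths[-1]}]"
        )
    if keep not in ("below", "above"):
        raise ValueError("keep must be 'below' or 'above'")
    img = cube.data[:, :, cube.band_index(threshold_band_nm)]
    mask = img < threshold if keep == "below" else img > threshold
    if not mask.any():
        raise ValueError("foreground mask is empty")
    if largest_component:
        labels, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
    return mask
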