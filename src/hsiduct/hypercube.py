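"""Hyperspectral cube data model and ENVI/PGM on-disk formats.

A :class:`Hypercube` is a ``rows x cols x bands`` array of dimensionless
reflectance values together with the band-center wavelengths (nm).  Cubes
are stored on disk as standard ENVI pairs (text ``.hdr`` header plus raw
binary), the de-facto interchange format for hyperspectral imagery; all
three interleaves (BSQ, BIL, BIP) and both byte orders are supported.
Binary ground-truth masks travel as 8-bit PGM or single-band ENVI.
"""

from __future__ import annotations

import os
import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Hypercube",
    "Mask",
    "PixelMatrix",
    "read_envi",
    "write_envi",
    "read_mask",
    "write_mask_pgm",
    "pixel_spectrum",
    "band_image",
    "flatten_pixels",
    "field_of_view_cm2",
]

# ENVI "data type" codes <-> numpy dtypes (subset actually produced/consumed)
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class Hypercube:
    """Reflectance cube: ``data[row, col, band]`` with band wavelengths in nm."""

    data: np.ndarray
    wavelengths: np.ndarray
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must have 3 axes, got {self.data.ndim}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                "wavelengths length must equal the band axis length "
                f"({len(self.wavelengths)} != {self.data.shape[2]})"
            )
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite reflectance values")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < 0.0 or hi > 1.0:
            warnings.warn(
                f"reflectance outside [0, 1] (range [{lo:.4g}, {hi:.4g}]); "
                "values kept as-is",
                stacklevel=2,
            )

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]


@dataclass
class Mask:
    """Binary tissue-class image: 0 = non-cancer, 1 = cancer."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask must be a 2-D label image")
        vals = np.unique(self.labels)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError(f"mask values must be in {{0, 1}}, found {vals}")
        self.labels = self.labels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def cancer_fraction(self) -> float:
        return float(self.labels.mean())


@dataclass
class PixelMatrix:
    """Pixel-by-band matrix with (row, col) provenance and optional labels."""

    spectra: np.ndarray
    coords: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra)
        self.coords = np.asarray(self.coords)
        if self.spectra.ndim != 2 or self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("spectra must be 2-D and coords n x 2")
        if len(self.spectra) != len(self.coords):
            raise ValueError("spectra and coords row counts differ")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.spectra):
                raise ValueError("labels length differs from spectra rows")

    def __len__(self) -> int:
        return len(self.spectra)


# ---------------------------------------------------------------------------
# ENVI header parsing / writing
# ---------------------------------------------------------------------------

def _parse_envi_header(path: str) -> dict[str, str]:
    with open(path, "r") as fh:
        text = fh.read()
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError(f"{path}: not an ENVI header (missing ENVI magic)")
    # strip brace-delimited values onto single logical lines
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    header: dict[str, str] = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        header[key.strip().lower()] = value.strip()
    return header


def _header_list(value: str) -> list[float]:
    inner = value.strip().lstrip("{").rstrip("}")
    return [float(tok) for tok in inner.replace(",", " ").split()]


def _raw_path_for(header_path: str) -> str:
    base, _ = os.path.splitext(header_path)
    for ext in (".img", ".raw", ".dat", ""):
        candidate = base + ext
        if candidate != header_path and os.path.exists(candidate):
            return candidate
    raise FileNotFoundError(f"no companion raw file found for header {header_path}")


def read_envi(path: str) -> Hypercube:
    """Read an ENVI header/raw pair into a :class:`Hypercube`.

    Parameters
    ----------
    path
        Path to the ``.hdr`` text header; the raw file is located next to
        it (``.img``, ``.raw``, ``.dat`` or extension-less).

    Raises
    ------
    FileNotFoundError
        Missing header or raw file.
    ValueError
        Header missing a required field (the error names it), or an
        unsupported ``data type`` / ``interleave``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"ENVI header not found: {path}")
    header = _parse_envi_header(path)
    for key in ("samples", "lines", "bands", "data type", "interleave"):
        if key not in header:
            raise ValueError(f"{path}: ENVI header missing required field '{key}'")
    if "wavelength" not in header:
        raise ValueError(f"{path}: ENVI header missing required field 'wavelength'")

    samples = int(header["samples"])  # cols
    lines = int(header["lines"])  # rows
    bands = int(header["bands"])
    code = int(header["data type"])
    if code not in _ENVI_DTYPES:
        raise ValueError(f"{path}: unsupported ENVI 'data type' code {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    byte_order = int(header.get("byte order", "0"))
    dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")
    interleave = header["interleave"].lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"{path}: unsupported 'interleave' value '{interleave}'")

    raw_path = _raw_path_for(path)
    offset = int(header.get("header offset", "0"))
    flat = np.fromfile(raw_path, dtype=dtype, offset=offset)
    expected = samples * lines * bands
    if flat.size != expected:
        raise ValueError(
            f"{raw_path}: raw size {flat.size} does not match header dims {expected}"
        )
    if interleave == "bsq":
        data = flat.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        data = flat.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:  # bip
        data = flat.reshape(lines, samples, bands)
    data = np.ascontiguousarray(data).astype(dtype.newbyteorder("="), copy=False)

    wavelengths = np.array(_header_list(header["wavelength"]))
    metadata = {
        k: v.strip("{} ")
        for k, v in header.items()
        if k.startswith("hsiduct ")
    }
    metadata = {k.removeprefix("hsiduct "): v for k, v in metadata.items()}
    return Hypercube(data=data, wavelengths=wavelengths, metadata=metadata)


def write_envi(
    cube: Hypercube,
    path: str,
    interleave: str = "bsq",
    byte_order: int = 0,
) -> tuple[str, str]:
    """Write ``cube`` as an ENVI header/raw pair; returns (hdr_path, raw_path).

    ``path`` may be the ``.hdr`` path or a bare stem; the raw file gets a
    ``.img`` extension.  Free-form cube metadata is preserved under
    ``hsiduct <key>`` header entries.
    """
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave '{interleave}'")
    if byte_order not in (0, 1):
        raise ValueError("byte order must be 0 (little) or 1 (big)")
    base, ext = os.path.splitext(path)
    hdr_path = path if ext == ".hdr" else path + ".hdr"
    base = os.path.splitext(hdr_path)[0]
    raw_path = base + ".img"

    dtype = np.dtype(cube.data.dtype)
    if dtype not in _DTYPE_CODES:
        dtype = np.dtype(np.float32)
    code = _DTYPE_CODES[dtype]
    out_dtype = dtype.newbyteorder("<" if byte_order == 0 else ">")

    if interleave == "bsq":
        arr = cube.data.transpose(2, 0, 1)
    elif interleave == "bil":
        arr = cube.data.transpose(0, 2, 1)
    else:
        arr = cube.data
    np.ascontiguousarray(arr, dtype=out_dtype).tofile(raw_path)

    wl = ", ".join(f"{w:.6g}" for w in cube.wavelengths)
    lines = [
        "ENVI",
        "description = {hsiduct reflectance cube}",
        f"samples = {cube.cols}",
        f"lines = {cube.rows}",
        f"bands = {cube.bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {code}",
        f"interleave = {interleave}",
        f"byte order = {byte_order}",
        "wavelength units = Nanometers",
        f"wavelength = {{ {wl} }}",
    ]
    for key, value in cube.metadata.items():
        lines.append(f"hsiduct {key} = {{{value}}}")
    with open(hdr_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return hdr_path, raw_path


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

def write_mask_pgm(mask: Mask, path: str) -> str:
    """Write a binary mask as 8-bit PGM (P5) with values 0/1."""
    rows, cols = mask.shape
    with open(path, "wb") as fh:
        fh.write(f"P5\n{cols} {rows}\n255\n".encode())
        fh.write(mask.labels.astype(np.uint8).tobytes())
    return path


def _read_pgm(path: str) -> np.ndarray:
    with open(path, "rb") as fh:
        raw = fh.read()
    tokens: list[bytes] = []
    i = 0
    # P2/P5 header: magic, width, height, maxval, with '#' comments allowed
    while len(tokens) < 4:
        while i < len(raw) and raw[i : i + 1].isspace():
            i += 1
        if raw[i : i + 1] == b"#":
            while i < len(raw) and raw[i : i + 1] != b"\n":
                i += 1
            continue
        start = i
        while i < len(raw) and not raw[i : i + 1].isspace():
            i += 1
        tokens.append(raw[start:i])
    magic = tokens[0].decode()
    width, height, maxval = (int(t) for t in tokens[1:4])
    if magic == "P5":
        i += 1  # single whitespace after maxval
        dtype = np.uint8 if maxval < 256 else np.dtype(">u2")
        data = np.frombuffer(raw, dtype=dtype, count=width * height, offset=i)
    elif magic == "P2":
        data = np.array(raw[i:].split()[: width * height], dtype=int)
    else:
        raise ValueError(f"{path}: unsupported PGM magic '{magic}'")
    return data.reshape(height, width)


def read_mask(path: str) -> Mask:
    """Read a binary mask from PGM (P2/P5) or a single-band ENVI cube.

    Any non-zero pixel is treated as cancer (label 1).
    """
    if path.endswith(".hdr"):
        cube = read_envi(path)
        if cube.bands != 1:
            raise ValueError(f"{path}: mask ENVI cube must have exactly 1 band")
        img = cube.data[:, :, 0]
    else:
        img = _read_pgm(path)
    return Mask(labels=(np.asarray(img) != 0).astype(np.uint8))


# ---------------------------------------------------------------------------
# Accessors
# ---------------------------------------------------------------------------

def pixel_spectrum(cube: Hypercube, row: int, col: int) -> np.ndarray:
    """Return the length-``bands`` spectrum of one pixel."""
    if not (0 <= row < cube.rows and 0 <= col < cube.cols):
        raise IndexError(
            f"pixel ({row}, {col}) outside cube of shape "
            f"{cube.rows} x {cube.cols}"
        )
    return cube.data[row, col, :].copy()


def band_image(cube: Hypercube, wavelength_nm: float) -> tuple[np.ndarray, float]:
    """Return the 2-D slice of the band nearest ``wavelength_nm`` and its center.

    Ties between two equally-near centers resolve to the lower wavelength.
    Requests farther than half the band spacing outside the sensor range
    raise ``ValueError``.
    """
    wl = cube.wavelengths
    half_spacing = float(np.median(np.diff(wl)) / 2) if len(wl) > 1 else 0.0
    if wavelength_nm < wl[0] - half_spacing or wavelength_nm > wl[-1] + half_spacing:
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside sensor range "
            f"[{wl[0]}, {wl[-1]}] nm (+/- {half_spacing} nm)"
        )
    idx = int(np.argmin(np.abs(wl - wavelength_nm)))  # argmin keeps first = lower
    return cube.data[:, :, idx].copy(), float(wl[idx])


def nearest_band_index(wavelengths: np.ndarray, wavelength_nm: float) -> int:
    """Index of the band center nearest ``wavelength_nm`` (ties -> lower)."""
    return int(np.argmin(np.abs(np.asarray(wavelengths) - wavelength_nm)))


def field_of_view_cm2(width_um: float, height_um: float) -> float:
    """Sensor field-of-view area in cm^2 from its width/height in microns."""
    if width_um <= 0 or height_um <= 0:
        raise ValueError("field-of-view dimensions must be positive")
    return (width_um * 1e-4) * (height_um * 1e-4)


def flatten_pixels(
    cube: Hypercube,
    mask: Mask | None = None,
    select: np.ndarray | None = None,
) -> PixelMatrix:
    """Flatten a cube to a pixel-by-band matrix in row-major pixel order.

    ``mask`` supplies per-pixel labels; ``select`` (boolean image) restricts
    which pixels become rows.  Without ``select`` every pixel is kept.
    """
    spatial = (cube.rows, cube.cols)
    if mask is not None and mask.shape != spatial:
        raise ValueError(f"mask shape {mask.shape} != cube spatial shape {spatial}")
    if select is None:
        keep = np.ones(spatial, dtype=bool)
    else:
        select = np.asarray(select, dtype=bool)
        if select.shape != spatial:
            raise ValueError(
                f"selection shape {select.shape} != cube spatial shape {spatial}"
            )
        keep = select
    rr, cc = np.nonzero(keep)  # nonzero scans row-major
    spectra = cube.data[rr, cc, :]
    coords = np.stack([rr, cc], axis=1)
    labels = mask.labels[rr, cc].astype(np.int64) if mask is not None else None
    return PixelMatrix(spectra=spectra, coords=coords, labels=labels)
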