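"""Hyperspectral cube container, TIFF I/O, reflectance calibration and denoising.

The central raster object is a 3-D array indexed (row, col, band) with an
explicit, strictly increasing wavelength axis in nanometres.  Cubes are stored
on disk as multi-page 32-bit float TIFF stacks (one page per band, first page
= shortest wavelength) with a JSON wavelength sidecar next to the stack.

Reflectance calibration rescales raw counts between a dark-current cube and a
white-reference cube,

    I_ref = (I_raw - I_dark) / (I_white - I_dark),

yielding relative reflectance (0 = no reflectance, 1 = the white board);
specular highlights may exceed 1.  Where the denominator is not safely
positive the output is set to 0 and the guarded voxel count is recorded in
the result's metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from .errors import CalibrationError, ContractError, FormatError

logger = logging.getLogger(__name__)

#: Reference wavelength grid: 400-1000 nm inclusive at 5 nm -> 121 bands.
REFERENCE_WAVELENGTHS_NM = np.arange(400.0, 1000.0 + 2.5, 5.0)

#: Default pseudo-RGB band picks (nm), red/green/blue.
DEFAULT_RGB_BANDS_NM = (610.0, 540.0, 470.0)


@dataclass
class Hypercube:
    """A (rows x cols x bands) reflectance or raw-count raster.

    Parameters
    ----------
    data:
        Non-negative 3-D array, band axis last.
    wavelengths_nm:
        Strictly increasing wavelength per band, nanometres.
    meta:
        Free-form provenance map (file path, calibration counters, ...).
    """

    data: np.ndarray
    wavelengths_nm: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        if self.data.ndim != 3:
            raise ContractError(f"cube data must be 3-D (rows, cols, bands), got ndim={self.data.ndim}")
        if self.wavelengths_nm.ndim != 1 or len(self.wavelengths_nm) != self.data.shape[2]:
            raise ContractError(
                f"wavelength axis length {self.wavelengths_nm.size} != band count {self.data.shape[2]}"
            )
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise ContractError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ContractError("cube data contains non-finite values")

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.data.shape[0], self.data.shape[1]

    def band_index(self, wavelength_nm: float) -> int:
        """Index of the band nearest to ``wavelength_nm`` (must be in range)."""
        w = self.wavelengths_nm
        if not (w[0] <= wavelength_nm <= w[-1]):
            raise ContractError(
                f"wavelength {wavelength_nm} nm outside cube range [{w[0]}, {w[-1]}] nm"
            )
        return int(np.argmin(np.abs(w - wavelength_nm)))


@dataclass
class CalibrationSet:
    """White-reference and dark-current cubes sharing the raw cube's geometry."""

    white: Hypercube
    dark: Hypercube

    def __post_init__(self) -> None:
        if self.white.data.shape != self.dark.data.shape:
            raise ContractError("white and dark cubes must share shape")
        if not np.array_equal(self.white.wavelengths_nm, self.dark.wavelengths_nm):
            raise ContractError("white and dark cubes must share the wavelength axis")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".wavelengths.json")


def write_cube(path: str | Path, cube: Hypercube) -> Path:
    """Write a cube as a multi-page 32-bit float TIFF plus wavelength sidecar.

    Page k holds band k; the sidecar ``<name>.wavelengths.json`` is a plain
    JSON list in the same order.
    """
    path = Path(path)
    pages = np.moveaxis(cube.data.astype(np.float32, copy=False), 2, 0)
    tifffile.imwrite(path, pages)
    _sidecar_path(path).write_text(json.dumps([float(w) for w in cube.wavelengths_nm]))
    return path


def read_cube(path: str | Path, wavelengths_nm=None) -> Hypercube:
    """Read a multi-page TIFF stack (one page per band) into a Hypercube.

    The wavelength axis comes from ``wavelengths_nm`` if given, else from the
    JSON sidecar written by :func:`write_cube`.  Page order is assumed to map
    to ascending wavelength.
    """
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except Exception as exc:  # tifffile raises a zoo of error types
        raise FormatError(f"cannot read TIFF stack {path}: {exc}") from exc
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None, ...]
    if pages.ndim != 3:
        raise FormatError(f"{path}: expected a stack of 2-D pages, got ndim={pages.ndim}")
    if not np.issubdtype(pages.dtype, np.number):
        raise FormatError(f"{path}: non-numeric page dtype {pages.dtype}")

    if wavelengths_nm is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FormatError(f"no wavelength axis given and sidecar {sidecar} missing")
        wavelengths_nm = json.loads(sidecar.read_text())
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    if len(wavelengths_nm) != pages.shape[0]:
        raise FormatError(
            f"{path}: page count {pages.shape[0]} != wavelength count {len(wavelengths_nm)}"
        )
    data = np.moveaxis(pages, 0, 2)
    return Hypercube(data=data, wavelengths_nm=wavelengths_nm, meta={"path": str(path)})


def read_envi(header_path: str | Path) -> Hypercube:
    """Read a BSQ-interleaved ENVI-style raster (header + raw binary pair).

    Supports the minimal header subset: ``samples``, ``lines``, ``bands``,
    ``data type`` (4 = float32, 5 = float64), ``interleave = bsq`` and an
    optional ``wavelength = { ... }`` block.
    """
    header_path = Path(header_path)
    fields: dict[str, str] = {}
    text = header_path.read_text()
    # fold multi-line { ... } blocks before parsing key = value lines
    text = text.replace("\n", " \n")
    import re

    for m in re.finditer(r"^\s*([a-z ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)$", text, re.MULTILINE | re.IGNORECASE):
        fields[m.group(1).strip().lower()] = m.group(2).strip()
    try:
        samples, lines, bands = (int(fields[k]) for k in ("samples", "lines", "bands"))
    except KeyError as exc:
        raise FormatError(f"{header_path}: missing ENVI field {exc}") from exc
    if fields.get("interleave", "bsq").lower() != "bsq":
        raise FormatError(f"{header_path}: only BSQ interleave is supported")
    dtype = {4: np.float32, 5: np.float64}.get(int(fields.get("data type", 4)))
    if dtype is None:
        raise FormatError(f"{header_path}: unsupported ENVI data type {fields.get('data type')}")
    raw_path = header_path.with_suffix(".raw")
    if not raw_path.exists():
        raw_path = header_path.with_suffix("")
    data = np.fromfile(raw_path, dtype=dtype)
    if data.size != samples * lines * bands:
        raise FormatError(f"{raw_path}: size {data.size} != {lines}x{samples}x{bands}")
    cube = np.moveaxis(data.reshape(bands, lines, samples), 0, 2)
    if "wavelength" in fields:
        wl = [float(x) for x in fields["wavelength"].strip("{} ").split(",") if x.strip()]
    else:
        wl = list(range(bands))
    return Hypercube(data=cube, wavelengths_nm=wl, meta={"path": str(raw_path)})


def calibrate_reflectance(raw: Hypercube, cal: CalibrationSet, eps: float = 1e-6) -> Hypercube:
    """Per-voxel white/dark balance: (raw - dark) / (white - dark).

    Voxels whose denominator is <= ``eps`` are set to 0 and counted in the
    output's ``meta["guarded_voxels"]``.  A band whose entire denominator
    plane is degenerate raises :class:`CalibrationError` naming the band.
    """
    if raw.data.shape != cal.white.data.shape:
        raise ContractError(
            f"raw shape {raw.data.shape} != calibration shape {cal.white.data.shape}"
        )
    if not np.array_equal(raw.wavelengths_nm, cal.white.wavelengths_nm):
        raise ContractError("raw and calibration cubes must share the wavelength axis")

    denom = cal.white.data.astype(np.float64) - cal.dark.data.astype(np.float64)
    bad = denom <= eps
    dead_bands = np.flatnonzero(bad.all(axis=(0, 1)))
    if dead_bands.size:
        b = int(dead_bands[0])
        raise CalibrationError(
            f"band {b} ({raw.wavelengths_nm[b]:g} nm): white - dark <= {eps} over the full plane"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ref = (raw.data.astype(np.float64) - cal.dark.data) / denom
    n_guarded = int(bad.sum())
    if n_guarded:
        ref[bad] = 0.0
        logger.warning("calibration guard hit at %d voxels (denominator <= %g)", n_guarded, eps)
    meta = dict(raw.meta, calibrated=True, guarded_voxels=n_guarded)
    return Hypercube(data=ref, wavelengths_nm=raw.wavelengths_nm, meta=meta)


def gaussian_denoise(cube: Hypercube, sigma: float = 2.0) -> Hypercube:
    """Separable 3-D Gaussian smoothing over rows, cols and bands.

    The kernel is the normalized sampled Gaussian truncated at 4 sigma and the
    border is mirror (reflect) padded, so constant cubes are preserved.
    """
    if sigma <= 0:
        raise ContractError(f"sigma must be positive, got {sigma}")
    smoothed = ndimage.gaussian_filter(cube.data, sigma=sigma, mode="reflect", truncate=4.0)
    return Hypercube(data=smoothed, wavelengths_nm=cube.wavelengths_nm,
                     meta=dict(cube.meta, denoise_sigma=sigma))


def pseudo_rgb(cube: Hypercube, bands_nm=DEFAULT_RGB_BANDS_NM, window_nm: float = 0.0) -> np.ndarray:
    """Render a three-channel 8-bit preview from three wavelengths.

    Each channel is the nearest band plane (or the mean of planes within
    ``+-window_nm``), min-max scaled to [0, 255] independently.  The preview
    only feeds an external hand-landmark detector; no colorimetric accuracy
    is intended.
    """
    channels = []
    for w in bands_nm:
        if window_nm > 0:
            lo, hi = w - window_nm, w + window_nm
            sel = (cube.wavelengths_nm >= lo) & (cube.wavelengths_nm <= hi)
            if not sel.any():
                raise ContractError(f"no bands within +-{window_nm} nm of {w} nm")
            plane = cube.data[:, :, sel].mean(axis=2)
        else:
            plane = cube.data[:, :, cube.band_index(w)].astype(float)
        mn, mx = float(plane.min()), float(plane.max())
        if mx > mn:
            plane = (plane - mn) / (mx - mn) * 255.0
        else:
            plane = np.zeros_like(plane)
        channels.append(np.floor(plane + 0.5).astype(np.uint8))
    return np.stack(channels, axis=2)
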