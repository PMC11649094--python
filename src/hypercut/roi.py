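"""Line-ROI construction from hand landmarks and cross-sectional reslicing.

The sampling line is defined anatomically: it starts at hand landmark #0 (the
wrist) and runs toward the midpoint of landmarks #9 and #13 (the middle/ring
finger bases), optionally extended beyond the midpoint.  Reslicing the cube
along that line, one bilinear sample per step and per band, yields the 2-D
spatial-spectral cross-section that feeds feature extraction.

Coordinates are (row, col), 0-based, with pixel centers at integer positions.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
from skimage.transform import resize as _sk_resize

from .errors import ContractError, DegenerateGeometryError, FormatError
from .hypercube import Hypercube

logger = logging.getLogger(__name__)

N_LANDMARKS = 21  # MediaPipe hand model: points #0..#20


@dataclass
class HandLandmarks:
    """21 named (row, col) pixel coordinates following the MediaPipe hand model."""

    points: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_LANDMARKS, 2):
            raise ContractError(
                f"expected {N_LANDMARKS} (row, col) landmarks, got shape {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ContractError("landmark coordinates must be finite")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({"points": self.points.tolist(), "source": self.source}))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "HandLandmarks":
        obj = json.loads(Path(path).read_text())
        if "points" not in obj:
            raise FormatError(f"{path}: missing 'points' key")
        return cls(points=np.asarray(obj["points"], dtype=float), source=obj.get("source", ""))

    @classmethod
    def from_csv(cls, path: str | Path) -> "HandLandmarks":
        """CSV with columns index,row,col (header optional)."""
        import pandas as pd

        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        if not {"index", "row", "col"} <= set(cols):
            raise FormatError(f"{path}: need columns index,row,col")
        df = df.sort_values(cols["index"])
        return cls(points=df[[cols["row"], cols["col"]]].to_numpy(float), source=str(path))


@dataclass
class LineROI:
    """Oriented sampling segment in pixel coordinates."""

    start: np.ndarray
    end: np.ndarray
    length_px: float = field(init=False)

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        self.length_px = float(np.linalg.norm(self.end - self.start))
        if self.length_px <= 0:
            raise DegenerateGeometryError("line ROI has zero length")

    @property
    def direction(self) -> np.ndarray:
        return (self.end - self.start) / self.length_px


@dataclass
class CrossSection:
    """The resliced spatial-spectral image: rows = samples along the line, cols = bands."""

    image: np.ndarray
    wavelengths_nm: np.ndarray
    roi: LineROI

    def __post_init__(self) -> None:
        if self.image.ndim != 2:
            raise ContractError("cross-section image must be 2-D (samples x bands)")
        if self.image.shape[1] != len(self.wavelengths_nm):
            raise ContractError("cross-section column count must equal band count")


def line_from_landmarks(lm: HandLandmarks, extension: float = 1.0) -> LineROI:
    """Line ROI from landmark #0 toward the midpoint of landmarks #9 and #13.

    ``extension`` scales the segment past the midpoint (1.0 = stop exactly at
    the midpoint).
    """
    if extension <= 0:
        raise ContractError(f"extension must be positive, got {extension}")
    start = lm.points[0]
    midpoint = 0.5 * (lm.points[9] + lm.points[13])
    if np.linalg.norm(midpoint - start) < 1e-9:
        raise DegenerateGeometryError(
            "landmark #0 coincides with the midpoint of #9 and #13; no line direction"
        )
    end = start + extension * (midpoint - start)
    return LineROI(start=start, end=end)


def sample_cross_section(
    cube: Hypercube, roi: LineROI, step_px: float = 1.0, clip: bool = True
) -> CrossSection:
    """Reslice the cube along the ROI with bilinear interpolation per band.

    Samples sit at ``start + k * step_px * direction`` for
    ``k = 0 .. floor(length/step)``.  Sample positions outside the raster are
    clipped to the bounds with a logged warning (``clip=True``, the default,
    since hand placement is unconstrained) or raise (``clip=False``).
    """
    if step_px <= 0:
        raise ContractError(f"step_px must be positive, got {step_px}")
    n_samples = int(np.floor(roi.length_px / step_px)) + 1
    ks = np.arange(n_samples)[:, None]
    pos = roi.start[None, :] + ks * step_px * roi.direction[None, :]

    rows, cols = cube.spatial_shape
    lo = np.zeros(2)
    hi = np.array([rows - 1, cols - 1], dtype=float)
    out_of_bounds = (pos < lo) | (pos > hi)
    if out_of_bounds.any():
        if not clip:
            raise ContractError("line ROI exits the raster and clipping is disabled")
        n_bad = int(out_of_bounds.any(axis=1).sum())
        logger.warning("clipped %d/%d ROI samples to the raster bounds", n_bad, n_samples)
        pos = np.clip(pos, lo, hi)

    r, c = pos[:, 0], pos[:, 1]
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r0 = np.minimum(r0, rows - 2) if rows > 1 else np.zeros_like(r0)
    c0 = np.minimum(c0, cols - 2) if cols > 1 else np.zeros_like(c0)
    wr = (r - r0)[:, None]
    wc = (c - c0)[:, None]
    d = cube.data
    r1 = np.minimum(r0 + 1, rows - 1)
    c1 = np.minimum(c0 + 1, cols - 1)
    image = (
        d[r0, c0] * (1 - wr) * (1 - wc)
        + d[r1, c0] * wr * (1 - wc)
        + d[r0, c1] * (1 - wr) * wc
        + d[r1, c1] * wr * wc
    )
    return CrossSection(image=image, wavelengths_nm=cube.wavelengths_nm, roi=roi)


def standardize_section(
    cs: CrossSection,
    out_shape: tuple[int, int] = (100, 100),
    orientation: str = "spatial-rows",
) -> np.ndarray:
    """Bilinear-resize the cross-section to ``out_shape`` and convert to 8-bit.

    ``orientation="spatial-rows"`` keeps spatial samples along rows and
    wavelength along columns; ``"wavelength-rows"`` transposes first (the
    display convention with lambda running top to bottom).  The gray mapping
    is per-image min-max to [0, 255], rounded half-up; a constant image maps
    to all zeros with a warning.
    """
    img = np.asarray(cs.image, dtype=float)
    if img.size == 0:
        raise ContractError("cross-section is empty")
    if orientation == "wavelength-rows":
        img = img.T
    elif orientation != "spatial-rows":
        raise ContractError(f"unknown orientation {orientation!r}")

    if img.shape != tuple(out_shape):
        img = _sk_resize(img, out_shape, order=1, anti_aliasing=False, preserve_range=True)

    mn, mx = float(img.min()), float(img.max())
    if mx == mn:
        warnings.warn("constant cross-section: 8-bit conversion maps everything to 0")
        return np.zeros(out_shape, dtype=np.uint8)
    scaled = (img - mn) / (mx - mn) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)


def save_section_png(img8: np.ndarray, path: str | Path) -> Path:
    """Write a standardized 8-bit section losslessly as PNG."""
    path = Path(path)
    iio.imwrite(path, np.asarray(img8, dtype=np.uint8))
    return path
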