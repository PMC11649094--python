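"""Local-binary-pattern block histograms for the standardized cross-section.

Per pixel, the P circular neighbors at radius R are compared against the
center (``>=`` sets the bit by default).  The reference binning maps each
pixel to the *number* of passing neighbors, 0..P, which for P=8 yields the
9 bins per block histogram and hence the 5x5x9 = 225-dimensional vector for
a 100x100 image split into 20x20 blocks.  That binning is rotation-invariant
and is the only natural 9-bin scheme for P=8; a uniform-pattern variant
(bins = P+2) is available behind the config but is not the reference path.

Borders are replicate-padded so every pixel yields a code and each block's
histogram sums exactly to the block area (counts, not frequencies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ContractError


@dataclass
class LBPConfig:
    """Neighborhood, binning and block layout of the feature extractor."""

    neighbors: int = 8          # P
    radius: float = 1.0         # R, pixels
    bins: int = 9
    block: tuple[int, int] = (20, 20)
    compare: str = ">="         # tie rule: neighbor vs center
    method: str = "counts"      # "counts" (reference) or "uniform"

    def __post_init__(self) -> None:
        if self.neighbors < 1 or self.radius <= 0:
            raise ContractError("neighbors must be >= 1 and radius positive")
        if self.compare not in (">=", ">"):
            raise ContractError(f"compare must be '>=' or '>', got {self.compare!r}")
        if self.method == "counts" and self.bins != self.neighbors + 1:
            raise ContractError(
                f"counts binning needs bins == neighbors + 1, got bins={self.bins}, P={self.neighbors}"
            )
        if self.method == "uniform" and self.bins != self.neighbors + 2:
            raise ContractError("uniform binning needs bins == neighbors + 2")
        if self.method not in ("counts", "uniform"):
            raise ContractError(f"unknown LBP method {self.method!r}")


@dataclass
class FeatureVector:
    """Concatenated per-block code histograms, block-major, bins innermost."""

    values: np.ndarray
    blocks: tuple[int, int]
    bins: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = self.blocks[0] * self.blocks[1] * self.bins
        if self.values.shape != (expected,):
            raise ContractError(f"expected {expected} values, got shape {self.values.shape}")
        if (self.values < 0).any():
            raise ContractError("histogram counts must be non-negative")

    def __len__(self) -> int:
        return self.values.size


def _neighbor_offsets(P: int, R: float) -> np.ndarray:
    """(dy, dx) offsets of the P neighbors.

    The reference P=8, R=1 configuration uses the 8-connected lattice
    neighbors (the classic LBP convention); other configurations sample the
    circle of radius R, with near-integer coordinates snapped to the lattice.
    """
    if P == 8 and R == 1:
        return np.array([
            (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)
        ], dtype=float)
    k = np.arange(P)
    ang = 2.0 * np.pi * k / P
    off = np.stack([-R * np.sin(ang), R * np.cos(ang)], axis=1)
    snapped = np.round(off)
    near = np.abs(off - snapped) < 1e-9
    off[near] = snapped[near]
    return off


def lbp_code_image(img: np.ndarray, cfg: LBPConfig | None = None) -> np.ndarray:
    """Per-pixel LBP code with replicate-padded borders; same shape as ``img``."""
    cfg = cfg or LBPConfig()
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ContractError("LBP input must be a 2-D image")
    need = int(np.ceil(2 * cfg.radius + 1))
    if min(img.shape) < need:
        raise ContractError(f"image {img.shape} smaller than the {need}-pixel neighborhood")

    if cfg.method == "uniform":
        from skimage.feature import local_binary_pattern

        pad = int(np.ceil(cfg.radius))
        padded = np.pad(img, pad, mode="edge")
        codes = local_binary_pattern(padded, cfg.neighbors, cfg.radius, method="uniform")
        return codes[pad:-pad, pad:-pad].astype(np.int64)

    pad = int(np.ceil(cfg.radius))
    padded = np.pad(img, pad, mode="edge")
    H, W = img.shape
    counts = np.zeros((H, W), dtype=np.int64)
    rows = np.arange(H) + pad
    cols = np.arange(W) + pad
    for dy, dx in _neighbor_offsets(cfg.neighbors, cfg.radius):
        if dy == int(dy) and dx == int(dx):
            nb = padded[int(dy) + pad : int(dy) + pad + H, int(dx) + pad : int(dx) + pad + W]
        else:
            rr, cc = np.meshgrid(rows + dy, cols + dx, indexing="ij")
            nb = ndimage.map_coordinates(padded, [rr, cc], order=1, mode="nearest")
        if cfg.compare == ">=":
            counts += nb >= img
        else:
            counts += nb > img
    return counts


def block_histograms(codes: np.ndarray, cfg: LBPConfig | None = None) -> FeatureVector:
    """Histogram codes per non-overlapping block (row-major) and concatenate."""
    cfg = cfg or LBPConfig()
    codes = np.asarray(codes)
    H, W = codes.shape
    bh, bw = cfg.block
    if H % bh or W % bw:
        raise ContractError(f"image shape {codes.shape} not divisible by block {cfg.block}")
    nbr, nbc = H // bh, W // bw
    if codes.min() < 0 or codes.max() >= cfg.bins:
        raise ContractError(f"codes outside [0, {cfg.bins})")
    block_id = (np.arange(H)[:, None] // bh) * nbc + (np.arange(W)[None, :] // bw)
    flat = block_id * cfg.bins + codes
    hist = np.bincount(flat.ravel(), minlength=nbr * nbc * cfg.bins)
    return FeatureVector(values=hist.astype(float), blocks=(nbr, nbc), bins=cfg.bins)


def extract_feature_vector(img: np.ndarray, cfg: LBPConfig | None = None) -> FeatureVector:
    """Full extractor: LBP code image -> concatenated block histograms."""
    cfg = cfg or LBPConfig()
    return block_histograms(lbp_code_image(img, cfg), cfg)


def save_features(
    path: str | Path,
    vectors: np.ndarray,
    subject_ids,
    capture_ids,
) -> Path:
    """Write feature vectors to CSV: subject_id, capture_id, f000..fNNN."""
    vectors = np.asarray(vectors, dtype=float)
    cols = [f"f{i:03d}" for i in range(vectors.shape[1])]
    df = pd.DataFrame(vectors, columns=cols)
    df.insert(0, "capture_id", list(capture_ids))
    df.insert(0, "subject_id", list(subject_ids))
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def load_features(path: str | Path):
    """Read a feature CSV back as (vectors, subject_ids, capture_ids)."""
    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    return (
        df[feat_cols].to_numpy(float),
        df["subject_id"].to_numpy(),
        df["capture_id"].to_numpy(),
    )
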