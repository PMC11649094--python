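"""2-D embedding of LBP feature vectors: PCA, t-SNE, UMAP, k-means agreement.

PCA is implemented from first principles (mean-centering, sample covariance,
symmetric eigendecomposition) so the deterministic reference path has no
backend dependency; the eigenvector sign is fixed by making the
largest-magnitude loading positive.  t-SNE and UMAP are delegated to
scikit-learn and umap-learn behind a uniform contract that guarantees only
shape, finiteness and seed-determinism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .errors import CapabilityError, ContractError


@dataclass
class EmbeddingConfig:
    method: str = "pca"          # pca | tsne | umap
    n_components: int = 2
    random_state: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("pca", "tsne", "umap"):
            raise ContractError(f"unknown embedding method {self.method!r}")
        if self.n_components < 1:
            raise ContractError("n_components must be >= 1")


@dataclass
class Embedding:
    coords: np.ndarray
    labels: np.ndarray | None
    config: EmbeddingConfig
    explained_variance_ratio: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ContractError("embedding coordinates must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.coords):
                raise ContractError("one label per embedded row required")


def reduce_pca(vectors: np.ndarray, cfg: EmbeddingConfig | None = None, labels=None) -> Embedding:
    """Mean-centered projection onto the top eigenvectors of the covariance.

    Returns an :class:`Embedding` whose ``explained_variance_ratio`` holds the
    retained components' share of total variance, in descending order.
    """
    cfg = cfg or EmbeddingConfig(method="pca")
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ContractError("PCA needs an N x d matrix with N >= 2")
    if cfg.n_components > X.shape[1]:
        raise ContractError("n_components exceeds feature dimension")

    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / (X.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]

    comps = eigvecs[:, : cfg.n_components].copy()
    for j in range(comps.shape[1]):       # deterministic sign
        i = np.argmax(np.abs(comps[:, j]))
        if comps[i, j] < 0:
            comps[:, j] = -comps[:, j]

    total = eigvals.sum()
    ratios = eigvals[: cfg.n_components] / total if total > 0 else np.zeros(cfg.n_components)
    return Embedding(coords=Xc @ comps, labels=labels, config=cfg,
                     explained_variance_ratio=ratios)


def reduce_nonlinear(vectors: np.ndarray, cfg: EmbeddingConfig, labels=None) -> Embedding:
    """Delegate to t-SNE or UMAP with a fixed seed.

    The contract guarantees output shape, finiteness and determinism for a
    pinned backend version; geometry is whatever the backend produces.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ContractError("nonlinear embedding needs an N x d matrix with N >= 2")
    if cfg.method == "tsne":
        try:
            from sklearn.manifold import TSNE
        except ImportError as exc:  # pragma: no cover
            raise CapabilityError("t-SNE backend (scikit-learn) unavailable") from exc
        # default perplexity, clamped so tiny cohorts stay valid
        perplexity = min(30.0, max(1.0, (X.shape[0] - 1) / 3.0))
        model = TSNE(n_components=cfg.n_components, random_state=cfg.random_state,
                     perplexity=perplexity)
        coords = model.fit_transform(X)
    elif cfg.method == "umap":
        try:
            from umap import UMAP
        except ImportError as exc:
            raise CapabilityError("UMAP backend (umap-learn) unavailable") from exc
        n_neighbors = min(15, X.shape[0] - 1)
        model = UMAP(n_components=cfg.n_components, random_state=cfg.random_state,
                     n_neighbors=n_neighbors)
        coords = np.asarray(model.fit_transform(X), dtype=float)
    else:
        raise ContractError(f"reduce_nonlinear requires tsne or umap, got {cfg.method!r}")
    return Embedding(coords=coords, labels=labels, config=cfg)


def reduce(vectors: np.ndarray, cfg: EmbeddingConfig, labels=None) -> Embedding:
    """Dispatch on ``cfg.method``."""
    if cfg.method == "pca":
        return reduce_pca(vectors, cfg, labels=labels)
    return reduce_nonlinear(vectors, cfg, labels=labels)


def kmeans_agreement(emb: Embedding, k: int = 10, random_state: int = 0) -> float:
    """Adjusted Rand index between k-means clusters of the embedding and its labels."""
    if emb.labels is None:
        raise ContractError("embedding carries no subject labels")
    n = len(emb.coords)
    if k > n:
        raise ContractError(f"k={k} exceeds sample count {n}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=random_state)
    pred = km.fit_predict(emb.coords)
    return float(adjusted_rand_score(emb.labels, pred))


def save_embedding(path: str | Path, emb: Embedding, capture_ids=None) -> Path:
    """CSV: subject_id, capture_id, dim1..dimK, method."""
    df = pd.DataFrame(
        emb.coords, columns=[f"dim{i+1}" for i in range(emb.coords.shape[1])]
    )
    df.insert(0, "capture_id", capture_ids if capture_ids is not None else range(len(df)))
    df.insert(0, "subject_id", emb.labels if emb.labels is not None else [""] * len(df))
    df["method"] = emb.config.method
    path = Path(path)
    df.to_csv(path, index=False)
    return path
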