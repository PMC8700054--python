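"""Scatter-matrix principal component analysis.

The scatter matrix of N feature vectors x_i with mean mu is
F_v = sum_i (x_i - mu)(x_i - mu)^T; the projection M maximizing the variance
M_k^T F_v M_k under M_k^T M_k = 1 consists of the top eigenvectors of F_v,
and the reduced coordinates are y_i = M^T (x_i - mu).  With N << F (here
~10^3 samples of ~10^4 features) the eigenvectors are obtained from the thin
SVD of the centered data matrix rather than the explicit F x F scatter; the
two routes agree exactly (scatter eigenvalues are the squared singular
values), which the test suite asserts on small instances.

Eigenvector signs are fixed so each component's largest-magnitude entry is
positive, making projections reproducible across runs and libraries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Number of principal components used by the study pipeline.
DEFAULT_N_COMPONENTS = 200


@dataclass(frozen=True)
class PCAProjection:
    """Fitted projection: mean, orthonormal components (F x K), eigenvalues."""

    mean: np.ndarray
    components: np.ndarray  # F x K, columns orthonormal
    eigenvalues: np.ndarray  # K scatter eigenvalues, descending
    n_fit: int

    def __post_init__(self) -> None:
        if self.components.shape[1] != self.eigenvalues.size:
            raise ValueError("components / eigenvalues shape mismatch")
        if np.any(np.diff(self.eigenvalues) > 1e-8 * max(self.eigenvalues[0], 1.0)):
            raise ValueError("eigenvalues must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]


def fit_pca(X: np.ndarray, n_components: int = DEFAULT_N_COMPONENTS) -> PCAProjection:
    """Top-K scatter-matrix PCA of an N x F training matrix.

    Requires K <= min(N-1, F): the scatter of N centered points has rank at
    most N-1, so no more informative components exist.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 rows")
    n, f = X.shape
    if n_components > min(n - 1, f):
        raise ValueError(
            f"n_components={n_components} exceeds min(N-1, F)={min(n - 1, f)}"
        )
    mean = X.mean(axis=0)
    centered = X - mean
    if not np.any(centered):
        raise ValueError("zero-variance input: all rows identical")
    # thin SVD of centered data; scatter eigenvalues are squared singular values
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    components = vt[:n_components].T.copy()
    eigenvalues = (s[:n_components] ** 2).copy()
    # deterministic sign: largest-magnitude entry of each component positive
    flip = np.sign(components[np.abs(components).argmax(axis=0), np.arange(n_components)])
    flip[flip == 0] = 1.0
    components *= flip
    return PCAProjection(
        mean=mean, components=components, eigenvalues=eigenvalues, n_fit=n
    )


def transform(proj: PCAProjection, X: np.ndarray) -> np.ndarray:
    """Reduced coordinates y_i = M^T (x_i - mu), shape N x K."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != proj.mean.size:
        raise ValueError(
            f"X has {X.shape[1]} columns, projection expects {proj.mean.size}"
        )
    return (X - proj.mean) @ proj.components


def inverse_transform(proj: PCAProjection, Y: np.ndarray) -> np.ndarray:
    """Reconstruction mu + M y; lossless when K spans the data."""
    return np.atleast_2d(Y) @ proj.components.T + proj.mean


def explained_variance_ratio(proj: PCAProjection, total_scatter: float) -> np.ndarray:
    """Per-component share of the full scatter trace."""
    return proj.eigenvalues / total_scatter


def save_projection(proj: PCAProjection, path: str | Path) -> None:
    path = Path(path)
    np.save(path.with_suffix(".npy"), proj.components)
    meta = {
        "mean": proj.mean.tolist(),
        "eigenvalues": proj.eigenvalues.tolist(),
        "n_fit": proj.n_fit,
        "n_components": proj.n_components,
    }
    path.with_suffix(".json").write_text(json.dumps(meta))


def load_projection(path: str | Path) -> PCAProjection:
    path = Path(path)
    components = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return PCAProjection(
        mean=np.asarray(meta["mean"]),
        components=components,
        eigenvalues=np.asarray(meta["eigenvalues"]),
        n_fit=int(meta["n_fit"]),
    )


__all__ = [
    "PCAProjection",
    "DEFAULT_N_COMPONENTS",
    "fit_pca",
    "transform",
    "inverse_transform",
    "explained_variance_ratio",
    "save_projection",
    "load_projection",
]
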