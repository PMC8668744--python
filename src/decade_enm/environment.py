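"""Environmental predictors: stack loading, PCA reduction, value extraction.

Bioclim-style layers carry incommensurable units, so each layer is
centered and scaled to unit variance before principal component analysis.
The leading axes whose cumulative explained variance first reaches the
threshold (default 95%) become the model predictors; all later stages see
only these score layers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .raster import RasterStack, read_ascii_grid, stack_layers

__all__ = ["PCAModel", "load_raster_stack", "pca_transform", "extract_values"]


@dataclass
class PCAModel:
    """Fitted standardize-then-rotate model for the environmental stack."""

    means: np.ndarray            # per retained (non-constant) input layer
    scales: np.ndarray
    loadings: np.ndarray         # (n_layers_used, n_axes), orthonormal columns
    eigenvalues: np.ndarray
    variance_fraction: np.ndarray
    n_retained: int
    layer_names: list[str]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "layer_names": self.layer_names,
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "variance_fraction": self.variance_fraction.tolist(),
            "n_retained": self.n_retained,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Project raw layer values (rows = samples) onto the retained axes."""
        z = (np.asarray(values, float) - self.means) / self.scales
        return z @ self.loadings[:, : self.n_retained]


def load_raster_stack(paths: Sequence[str | Path]) -> RasterStack:
    """Read ESRI ASCII grid layers and combine them on a shared grid.

    All files must be on an identical grid; the unified nodata mask is
    the union of per-layer nodata (a cell missing anywhere is masked
    everywhere).
    """
    if not paths:
        raise ValueError("need at least one raster path")
    return stack_layers(read_ascii_grid(p) for p in paths)


def pca_transform(
    stack: RasterStack, var_threshold: float = 0.95
) -> tuple[RasterStack, PCAModel]:
    """Reduce a standardized stack to its leading principal-component axes.

    Retains the smallest number of axes whose cumulative explained
    variance is at least ``var_threshold``. Zero-variance layers are
    dropped with a warning; axis signs are fixed by making each axis's
    largest-magnitude loading positive so output is reproducible.

    Returns the score stack (one layer per retained axis) and the fitted
    :class:`PCAModel`.
    """
    X = stack.values_matrix()
    if X.shape[0] < 2:
        raise ValueError("need at least 2 non-nodata cells for PCA")

    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("degenerate input: all layers are constant")
    if not keep.all():
        dropped = [n for n, k in zip(stack.names, keep) if not k]
        warnings.warn(f"dropping zero-variance layers: {dropped}")
    names = [n for n, k in zip(stack.names, keep) if k]
    Xk = X[:, keep]
    mean = Xk.mean(axis=0)
    scale = sd[keep]
    Z = (Xk - mean) / scale

    pca = PCA(svd_solver="full")
    pca.fit(Z)
    loadings = pca.components_.T.copy()        # (layers, axes)
    # deterministic sign: largest-|loading| entry of each axis is positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings *= flip

    frac = pca.explained_variance_ratio_
    n_retained = int(np.searchsorted(np.cumsum(frac), var_threshold - 1e-12) + 1)
    n_retained = min(n_retained, loadings.shape[1])

    model = PCAModel(
        means=mean,
        scales=scale,
        loadings=loadings,
        eigenvalues=pca.explained_variance_.copy(),
        variance_fraction=frac.copy(),
        n_retained=n_retained,
        layer_names=names,
    )

    scores = Z @ loadings[:, :n_retained]
    score_data = np.full((n_retained, stack.n_rows, stack.n_cols), np.nan)
    rr, cc = stack.valid_indices()
    for a in range(n_retained):
        score_data[a, rr, cc] = scores[:, a]
    score_stack = stack.with_data(
        score_data, names=[f"pc_{a + 1}" for a in range(n_retained)]
    )
    return score_stack, model


def extract_values(stack: RasterStack, points: np.ndarray) -> np.ndarray:
    """Look up layer values at point locations (containing-cell rule).

    ``points`` is an (n, 2) array of x, y coordinates. Rows landing on
    nodata cells come back as NaN; points outside the extent raise an
    error naming the offending indices.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of x, y")
    row, col = stack.index_of(points[:, 0], points[:, 1])
    return stack.data[:, row, col].T
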