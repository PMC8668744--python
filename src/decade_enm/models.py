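"""Presence-only suitability models: contrast data and the three algorithms.

True absences are unavailable for most presence-only datasets, so two
kinds of contrast data are generated from the environmental score stack:

* pseudo-absences drawn from cells *outside* the environmental envelope
  of the presences (places the presences themselves declare unsuitable),
  used by the absence-requiring learners (random forest, SVM);
* background points drawn uniformly from the whole study area, used by
  the presence-background maximum-entropy-style model.

All three algorithms share a fit/predict surface and emit suitability in
[0, 1] over the study grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, StandardScaler
from sklearn.svm import SVC

from .raster import RasterStack

__all__ = [
    "ALGORITHMS",
    "Envelope",
    "SuitabilityModel",
    "build_envelope",
    "sample_pseudo_absences",
    "sample_background",
    "fit_model",
    "predict_suitability",
]

ALGORITHMS = ("MXT", "RDF", "SVM")


@dataclass
class Envelope:
    """Per-axis (min, max) bounds of the presence environmental values."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.atleast_1d(np.asarray(self.lower, float))
        self.upper = np.atleast_1d(np.asarray(self.upper, float))
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower/upper length mismatch")
        if np.any(self.lower > self.upper):
            raise ValueError("envelope lower bound exceeds upper bound")

    def outside(self, values: np.ndarray) -> np.ndarray:
        """Boolean per row: fails the envelope on at least one axis."""
        v = np.atleast_2d(np.asarray(values, float))
        return np.any((v < self.lower) | (v > self.upper), axis=1)


@dataclass
class SuitabilityModel:
    """A fitted suitability learner with its training metadata."""

    algorithm: str
    estimator: object
    n_axes: int
    n_presence: int
    n_contrast: int
    seed: int
    config: dict = field(default_factory=dict)

    def predict(self, env: np.ndarray) -> np.ndarray:
        """Suitability in [0, 1] for rows of environmental values."""
        env = np.atleast_2d(np.asarray(env, float))
        if env.shape[1] != self.n_axes:
            raise ValueError(
                f"expected {self.n_axes} environmental axes, got {env.shape[1]}"
            )
        p = self.estimator.predict_proba(env)[:, 1]
        return np.clip(p, 0.0, 1.0)


def build_envelope(presence_env: np.ndarray, trim_fraction: float = 0.0) -> Envelope:
    """Per-axis quantile envelope of the presence environmental values.

    ``trim_fraction`` = 0 gives the strict min–max envelope; a positive
    fraction trims that share from each tail.
    """
    v = np.atleast_2d(np.asarray(presence_env, float))
    if v.shape[0] < 2:
        raise ValueError("need at least 2 presence rows")
    if np.isnan(v).any():
        raise ValueError("presence environmental values contain missing data")
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    lo = np.quantile(v, trim_fraction, axis=0)
    hi = np.quantile(v, 1.0 - trim_fraction, axis=0)
    return Envelope(lower=lo, upper=hi)


def _valid_cell_centers(stack: RasterStack) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = stack.valid_indices()
    x, y = stack.cell_center(rows, cols)
    return np.column_stack([x, y]), np.column_stack([rows, cols])


def sample_pseudo_absences(
    score_stack: RasterStack,
    envelope: Envelope,
    n: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Sample cells outside the presence envelope as pseudo-absences.

    Candidates are the non-nodata cells failing the envelope on at least
    one axis; ``n`` distinct cells are drawn uniformly without
    replacement. If fewer candidates exist, all are returned with a
    warning. Returns (n, 2) x, y coordinates of cell centers.
    """
    xy, _ = _valid_cell_centers(score_stack)
    env = score_stack.values_matrix()
    cand = envelope.outside(env)
    n_cand = int(cand.sum())
    if n_cand == 0:
        raise ValueError(
            "envelope covers the entire study region; no unsuitable cells"
        )
    rng = np.random.default_rng(seed)
    if n_cand < n:
        warnings.warn(
            f"only {n_cand} cells outside the envelope; returning all of them"
        )
        return xy[cand]
    pick = rng.choice(np.flatnonzero(cand), size=n, replace=False)
    return xy[pick]


def sample_background(
    score_stack: RasterStack, n: int = 10_000, seed: int = 0
) -> np.ndarray:
    """Sample background points uniformly (with replacement) over the region."""
    xy, _ = _valid_cell_centers(score_stack)
    if len(xy) == 0:
        raise ValueError("raster has no non-nodata cells")
    rng = np.random.default_rng(seed)
    pick = rng.integers(0, len(xy), size=n)
    return xy[pick]


def _make_estimator(algorithm: str, config: dict, seed: int, class_weight):
    if algorithm == "MXT":
        # presence-vs-background binomial with linear + quadratic features
        # and ridge regularization: the standard open reformulation of the
        # maximum-entropy suitability model
        return Pipeline(
            [
                ("features", PolynomialFeatures(degree=2, include_bias=False)),
                ("scale", StandardScaler()),
                (
                    "glm",
                    LogisticRegression(
                        C=config.get("C", 1.0),
                        max_iter=config.get("max_iter", 2000),
                        class_weight=class_weight,
                    ),
                ),
            ]
        )
    if algorithm == "RDF":
        return RandomForestClassifier(
            n_estimators=config.get("n_estimators", 500),
            min_samples_leaf=config.get("min_samples_leaf", 1),
            class_weight=class_weight,
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "SVM":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svc",
                    SVC(
                        kernel="rbf",
                        C=config.get("C", 1.0),
                        gamma=config.get("gamma", "scale"),
                        probability=True,  # Platt-calibrated output in [0,1]
                        class_weight=class_weight,
                        random_state=seed,
                    ),
                ),
            ]
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def fit_model(
    algorithm: str,
    presence_env: np.ndarray,
    contrast_env: np.ndarray,
    config: dict | None = None,
    seed: int = 0,
) -> SuitabilityModel:
    """Fit one suitability algorithm on presence vs contrast environments.

    The contrast set is background points for MXT and envelope
    pseudo-absences for RDF/SVM; class weights are balanced so the
    typically much larger contrast set does not swamp the presences.
    """
    config = dict(config or {})
    P = np.atleast_2d(np.asarray(presence_env, float))
    A = np.atleast_2d(np.asarray(contrast_env, float))
    if P.shape[0] < 5:
        raise ValueError("need at least 5 presence rows to fit")
    if A.shape[0] < 1:
        raise ValueError("need at least 1 contrast row to fit")
    if P.shape[1] != A.shape[1]:
        raise ValueError("presence and contrast axis counts differ")
    X = np.vstack([A, P])
    y = np.concatenate([np.zeros(len(A), int), np.ones(len(P), int)])
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate single-class training data")
    est = _make_estimator(algorithm, config, seed, class_weight="balanced")
    with warnings.catch_warnings():
        # SVC(probability=True) still gives Platt calibration here; the
        # CV-based alternative needs more per-class data than the smallest
        # windows guarantee
        warnings.simplefilter("ignore", FutureWarning)
        est.fit(X, y)
    return SuitabilityModel(
        algorithm=algorithm,
        estimator=est,
        n_axes=P.shape[1],
        n_presence=len(P),
        n_contrast=len(A),
        seed=seed,
        config=config,
    )


def predict_suitability(model: SuitabilityModel, score_stack: RasterStack) -> RasterStack:
    """Predict suitability for every non-nodata cell of the score stack."""
    if score_stack.n_layers != model.n_axes:
        raise ValueError(
            f"stack has {score_stack.n_layers} axes, model expects {model.n_axes}"
        )
    env = score_stack.values_matrix()
    p = model.predict(env)
    out = np.full((1, score_stack.n_rows, score_stack.n_cols), np.nan)
    rr, cc = score_stack.valid_indices()
    out[0, rr, cc] = p
    return score_stack.with_data(out, names=[f"suitability_{model.algorithm}"])
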