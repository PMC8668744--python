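"""Spatial evaluation and agreement ensembles.

Models are evaluated with a geographic two-fold split: the grid is tiled
as a checkerboard and blocks alternate between folds, so the held-out
data is spatially interleaved with — but not adjacent to — the training
data. Accuracy is the true skill statistic (TSS = sensitivity +
specificity − 1) at the threshold maximizing sensitivity + specificity.
Binary maps from the three algorithms are summed into an agreement
ensemble (0–3 algorithms per cell), whose cell counts yield the
conservative (all three agree) and non-conservative (any algorithm)
predicted-area proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import SuitabilityModel, fit_model
from .raster import RasterStack

__all__ = [
    "CheckerboardPartition",
    "EvaluationResult",
    "checkerboard_partition",
    "confusion_stats",
    "select_threshold",
    "evaluate_model",
    "binarize",
    "ensemble_sum",
    "area_proportion",
]


@dataclass
class CheckerboardPartition:
    """Alternating block assignment of grid cells to folds A (0) and B (1)."""

    block_size: int
    fold: np.ndarray  # (n_rows, n_cols) int array of 0/1

    def fold_of_points(self, stack: RasterStack, xy: np.ndarray) -> np.ndarray:
        """Points inherit the fold of their containing cell."""
        xy = np.atleast_2d(np.asarray(xy, float))
        row, col = stack.index_of(xy[:, 0], xy[:, 1])
        return self.fold[row, col]


@dataclass
class EvaluationResult:
    """Cross-validated skill of one algorithm in one temporal window."""

    algorithm: str
    window: str
    tss: float
    sensitivity: float
    specificity: float
    threshold: float
    per_fold: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert abs(self.tss - (self.sensitivity + self.specificity - 1.0)) < 1e-9


def checkerboard_partition(stack: RasterStack, block_size: int) -> CheckerboardPartition:
    """Tile the grid into ``block_size``-cell squares with alternating folds."""
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    r = np.arange(stack.n_rows) // block_size
    c = np.arange(stack.n_cols) // block_size
    fold = (r[:, None] + c[None, :]) % 2
    return CheckerboardPartition(block_size=block_size, fold=fold)


def confusion_stats(
    presence_scores: np.ndarray,
    absence_scores: np.ndarray,
    threshold: float,
) -> tuple[float, float, float]:
    """Sensitivity, specificity and TSS at a threshold (score >= τ ⇒ presence)."""
    p = np.asarray(presence_scores, float)
    a = np.asarray(absence_scores, float)
    if p.size == 0 or a.size == 0:
        raise ValueError("both score lists must be non-empty")
    sens = float(np.mean(p >= threshold))
    spec = float(np.mean(a < threshold))
    return sens, spec, sens + spec - 1.0


def select_threshold(presence_scores: np.ndarray, absence_scores: np.ndarray) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the unique observed scores; ties are broken toward the
    smallest maximizing threshold (the one keeping the largest predicted
    area).
    """
    p = np.asarray(presence_scores, float)
    a = np.asarray(absence_scores, float)
    if p.size == 0 or a.size == 0:
        raise ValueError("both score lists must be non-empty")
    candidates = np.unique(np.concatenate([p, a]))
    # exact integer scan: sens(τ) = #(p >= τ)/n_p, spec(τ) = #(a < τ)/n_a;
    # scaling by n_p * n_a keeps ties exact (no float round-off)
    n_ge = p.size - np.searchsorted(np.sort(p), candidates, side="left")
    n_lt = np.searchsorted(np.sort(a), candidates, side="left")
    total = n_ge * a.size + n_lt * p.size
    return float(candidates[int(np.argmax(total))])


def evaluate_model(
    algorithm: str,
    presence_xy: np.ndarray,
    presence_env: np.ndarray,
    contrast_xy: np.ndarray,
    contrast_env: np.ndarray,
    partition: CheckerboardPartition,
    stack: RasterStack,
    config: dict | None = None,
    seed: int = 0,
    window: str = "",
) -> EvaluationResult:
    """Two-fold checkerboard evaluation of one algorithm.

    Fits on fold A and scores fold B, then the reverse. Each fold's
    threshold is selected on the training-fold scores (selecting it on
    the held-out scores would optimistically bias TSS); reported
    sensitivity/specificity/TSS are the fold means. The reported
    threshold — used downstream to binarize maps — is re-derived from
    the pooled out-of-fold scores.
    """
    pf = partition.fold_of_points(stack, presence_xy)
    cf = partition.fold_of_points(stack, contrast_xy)
    for f in (0, 1):
        if (pf == f).sum() < 1 or (cf == f).sum() < 1:
            raise ValueError(
                "checkerboard fold with a single class; increase block_size"
            )

    sens_l, spec_l, tss_l, detail = [], [], [], []
    oof_p, oof_a = [], []
    for train, test in ((0, 1), (1, 0)):
        model = fit_model(
            algorithm,
            presence_env[pf == train],
            contrast_env[cf == train],
            config=config,
            seed=seed,
        )
        tau = select_threshold(
            model.predict(presence_env[pf == train]),
            model.predict(contrast_env[cf == train]),
        )
        ps = model.predict(presence_env[pf == test])
        cs = model.predict(contrast_env[cf == test])
        sens, spec, tss = confusion_stats(ps, cs, tau)
        sens_l.append(sens)
        spec_l.append(spec)
        tss_l.append(tss)
        oof_p.append(ps)
        oof_a.append(cs)
        detail.append(
            {"train_fold": train, "threshold": tau, "sensitivity": sens,
             "specificity": spec, "tss": tss}
        )
    pooled_tau = select_threshold(np.concatenate(oof_p), np.concatenate(oof_a))
    sens = float(np.mean(sens_l))
    spec = float(np.mean(spec_l))
    return EvaluationResult(
        algorithm=algorithm,
        window=window,
        tss=sens + spec - 1.0,
        sensitivity=sens,
        specificity=spec,
        threshold=pooled_tau,
        per_fold=detail,
    )


def binarize(suit_map: RasterStack, threshold: float) -> RasterStack:
    """Presence/absence map: 1 where suitability >= threshold, nodata kept."""
    band = suit_map.data[0]
    out = np.where(suit_map.valid, (band >= threshold).astype(float), np.nan)
    return suit_map.with_data(out[None, :, :], names=["binary"])


def ensemble_sum(binary_maps: list[RasterStack]) -> RasterStack:
    """Agreement ensemble: per-cell count of algorithms predicting presence."""
    if len(binary_maps) != 3:
        raise ValueError("ensemble requires exactly 3 binary maps")
    first = binary_maps[0]
    for m in binary_maps[1:]:
        if not first.same_grid(m):
            raise ValueError("binary maps are not on the same grid")
    total = np.zeros((first.n_rows, first.n_cols))
    valid = np.ones_like(first.valid)
    for m in binary_maps:
        total += np.nan_to_num(m.data[0])
        valid &= m.valid
    out = np.where(valid, total, np.nan)
    return first.with_data(out[None, :, :], names=["ensemble"])


def area_proportion(ensemble: RasterStack, mode: str) -> float:
    """Share of the study area predicted suitable.

    ``conservative``: cells where all three algorithms agree (value 3);
    ``nonconservative``: cells predicted by at least one (value >= 1).
    Denominator is the count of non-nodata cells.
    """
    vals = ensemble.data[0][ensemble.valid]
    if vals.size == 0:
        raise ValueError("ensemble raster has no non-nodata cells")
    if mode == "conservative":
        return float(np.mean(vals >= 3))
    if mode == "nonconservative":
        return float(np.mean(vals >= 1))
    raise ValueError("mode must be 'conservative' or 'nonconservative'")
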