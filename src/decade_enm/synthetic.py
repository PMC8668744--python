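"""Virtual-species simulation: landscapes, truth, research centers, biased sampling.

The generator produces everything the downstream pipeline consumes —
smooth multi-layer environmental rasters, a logistic virtual species with
a known suitability surface, research-center coordinates, and
decade-stamped occurrence records whose sampling can be biased toward the
centers — so the whole analysis is testable with known ground truth.
Every function is deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .raster import RasterStack

__all__ = [
    "Landscape",
    "VirtualSpeciesTruth",
    "SamplingPlan",
    "generate_landscape",
    "define_virtual_species",
    "place_research_centers",
    "sample_occurrences",
    "DEFAULT_RECORDS_PER_PERIOD",
    "DEFAULT_DECADE_BREAKS",
]

# Study-condition defaults: the historical accumulation schedule of the
# motivating dataset — eight cumulative windows starting in 1900 with
# per-period additions summing to 153 records.
DEFAULT_DECADE_BREAKS = [1900, 1950, 1960, 1970, 1980, 1990, 2000, 2010, 2020]
DEFAULT_RECORDS_PER_PERIOD = [30, 1, 9, 8, 3, 23, 70, 9]


@dataclass
class Landscape:
    """A seeded stack of smooth synthetic environmental fields."""

    raster_stack: RasterStack
    seed: int


@dataclass
class VirtualSpeciesTruth:
    """Known suitability truth of a simulated species.

    ``suitability`` holds the inverse-logit of a linear combination of the
    landscape layers; ``presence_mask`` is the deterministic cut at 0.5.
    """

    suitability: RasterStack
    presence_mask: np.ndarray
    response_params: dict

    @property
    def landscape_grid(self) -> RasterStack:
        return self.suitability


@dataclass
class SamplingPlan:
    """Temporal sampling schedule for occurrence generation.

    ``decade_breaks`` has one more entry than ``records_per_period``;
    period *i* spans the integer years ``(breaks[i], breaks[i+1]]``.
    ``bias_strength`` is the exponential distance-decay rate toward the
    nearest research center (0 = unbiased).
    """

    decade_breaks: list[int] = field(default_factory=lambda: list(DEFAULT_DECADE_BREAKS))
    records_per_period: list[int] = field(default_factory=lambda: list(DEFAULT_RECORDS_PER_PERIOD))
    bias_strength: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        breaks = list(self.decade_breaks)
        if any(nxt <= cur for cur, nxt in zip(breaks, breaks[1:])):
            raise ValueError("decade_breaks must be strictly increasing")
        if len(self.records_per_period) != len(breaks) - 1:
            raise ValueError(
                "records_per_period must have len(decade_breaks) - 1 entries"
            )
        if any(n < 0 for n in self.records_per_period):
            raise ValueError("records_per_period must be non-negative")
        if self.bias_strength < 0:
            raise ValueError("bias_strength must be non-negative")


def generate_landscape(
    extent: tuple[float, float, float, float],
    n_rows: int,
    n_cols: int,
    n_layers: int,
    seed: int,
    n_bumps: int = 25,
) -> Landscape:
    """Simulate smooth environmental layers on a regular grid.

    Each layer is a superposition of ``n_bumps`` Gaussian bumps with
    seeded centers, signed amplitudes and widths, giving spatially
    autocorrelated fields reminiscent of interpolated climate surfaces.

    Parameters
    ----------
    extent
        (xmin, ymin, xmax, ymax) of the study area.
    n_rows, n_cols
        Grid dimensions; at least 8 each.
    n_layers
        Number of layers; at least 2.
    seed
        Seed for the layer generator; same seed gives bit-identical output.
    """
    xmin, ymin, xmax, ymax = extent
    if n_rows < 8 or n_cols < 8:
        raise ValueError("n_rows and n_cols must be >= 8")
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    if xmax <= xmin or ymax <= ymin:
        raise ValueError("extent must have positive width and height")

    cell_size = (xmax - xmin) / n_cols
    y_span = ymax - ymin
    # non-square extents keep the x-derived cell size; rows cover y_span
    cell_size_y = y_span / n_rows
    rng = np.random.default_rng(seed)
    diag = float(np.hypot(xmax - xmin, ymax - ymin))

    cols = xmin + (np.arange(n_cols) + 0.5) * cell_size
    rows_y = ymin + (n_rows - np.arange(n_rows) - 0.5) * cell_size_y
    gx, gy = np.meshgrid(cols, rows_y)

    layers = np.empty((n_layers, n_rows, n_cols))
    for k in range(n_layers):
        cx = rng.uniform(xmin, xmax, n_bumps)
        cy = rng.uniform(ymin, ymax, n_bumps)
        amp = rng.normal(0.0, 1.0, n_bumps)
        width = rng.uniform(0.08, 0.25, n_bumps) * diag
        f = np.zeros((n_rows, n_cols))
        for c_x, c_y, a, w in zip(cx, cy, amp, width):
            f += a * np.exp(-((gx - c_x) ** 2 + (gy - c_y) ** 2) / (2.0 * w * w))
        layers[k] = f

    stack = RasterStack(
        data=layers,
        x_origin=xmin,
        y_origin=ymin,
        cell_size=cell_size,
        names=[f"env_{k}" for k in range(n_layers)],
    )
    return Landscape(raster_stack=stack, seed=seed)


def define_virtual_species(
    landscape: Landscape,
    coefficients: np.ndarray,
    intercept: float,
) -> VirtualSpeciesTruth:
    """Build a logistic virtual species from a landscape.

    Per-cell suitability is ``expit(intercept + Σ coef_k * layer_k)``;
    the true presence mask is the cells with suitability >= 0.5 (the
    symmetric cut of the logistic response).
    """
    stack = landscape.raster_stack
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.shape != (stack.n_layers,):
        raise ValueError(
            f"expected {stack.n_layers} coefficients, got {coefficients.shape}"
        )
    lin = intercept + np.tensordot(coefficients, stack.data, axes=(0, 0))
    suit = expit(lin)
    suit[~stack.valid] = np.nan
    suit_stack = stack.with_data(suit[None, :, :], names=["suitability"])
    presence = stack.valid & (suit >= 0.5)
    return VirtualSpeciesTruth(
        suitability=suit_stack,
        presence_mask=presence,
        response_params={"intercept": float(intercept),
                         "coefficients": coefficients.tolist()},
    )


def place_research_centers(
    extent: tuple[float, float, float, float],
    n_centers: int,
    seed: int,
) -> pd.DataFrame:
    """Draw research-center coordinates uniformly inside the extent.

    Returns a table with columns ``id, longitude, latitude``.
    """
    if n_centers < 1:
        raise ValueError("n_centers must be >= 1")
    xmin, ymin, xmax, ymax = extent
    rng = np.random.default_rng(seed)
    # shrink 2% from each edge so centers are strictly interior
    mx, my = 0.02 * (xmax - xmin), 0.02 * (ymax - ymin)
    xs = rng.uniform(xmin + mx, xmax - mx, n_centers)
    ys = rng.uniform(ymin + my, ymax - my, n_centers)
    return pd.DataFrame(
        {"id": [f"center_{i}" for i in range(n_centers)],
         "longitude": xs, "latitude": ys}
    )


def sample_occurrences(
    truth: VirtualSpeciesTruth,
    centers: pd.DataFrame,
    plan: SamplingPlan,
) -> pd.DataFrame:
    """Sample decade-stamped occurrence records from the true presence cells.

    Each record is drawn (with replacement across records) from the
    presence cells with probability proportional to
    ``suitability * exp(-bias_strength * distance_to_nearest_center)``,
    mimicking detectability rising with habitat quality and collection
    effort concentrating near research centers. Coordinates are the cell
    center plus a small uniform jitter that stays inside the cell, so
    value extraction round-trips to the generating cell. Years are drawn
    uniformly on the integers of each period.

    Returns a table with columns ``longitude, latitude, year, source``.
    """
    if sum(plan.records_per_period) < 1:
        raise ValueError("plan must request at least one record in total")
    grid = truth.suitability
    mask = truth.presence_mask
    if not mask.any():
        raise ValueError("degenerate truth: presence mask is empty")

    rows, cols = np.nonzero(mask)
    cx, cy = grid.cell_center(rows, cols)
    suit = grid.data[0][rows, cols]

    centers_xy = centers[["longitude", "latitude"]].to_numpy(dtype=float)
    d2 = (cx[:, None] - centers_xy[None, :, 0]) ** 2 + (
        cy[:, None] - centers_xy[None, :, 1]
    ) ** 2
    dist = np.sqrt(d2.min(axis=1))

    w = suit * np.exp(-plan.bias_strength * dist)
    if not np.isfinite(w).all() or w.sum() <= 0:
        raise ValueError("sampling weights degenerate (check bias_strength)")
    p = w / w.sum()

    rng = np.random.default_rng(plan.seed)
    jitter_half = 0.45 * grid.cell_size  # strictly inside the cell
    frames: list[pd.DataFrame] = []
    for i, n in enumerate(plan.records_per_period):
        if n == 0:
            continue
        start, end = plan.decade_breaks[i], plan.decade_breaks[i + 1]
        idx = rng.choice(len(rows), size=n, replace=True, p=p)
        years = rng.integers(start + 1, end + 1, size=n)  # (start, end]
        jx = rng.uniform(-jitter_half, jitter_half, size=n)
        jy = rng.uniform(-jitter_half, jitter_half, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "longitude": cx[idx] + jx,
                    "latitude": cy[idx] + jy,
                    "year": years.astype(int),
                    "source": "synthetic",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
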