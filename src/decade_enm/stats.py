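"""The two trend tests on accumulating records.

*Decade effect*: beta regression (logit link, precision φ) of the
predicted-area proportion on the cumulative number of records across the
temporal windows, run separately for the conservative and
non-conservative area definitions. Proportions exactly on {0, 1} are
first squeezed into the open interval with the usual
``(y·(n−1) + 0.5)/n`` transform.

*Wallacean distance*: per record, the planar Euclidean distance to the
nearest research center; per year, the maximum such distance; then a
weighted least-squares regression of the yearly maxima on year, weighted
by the number of distances computed that year. A rising slope would mean
new records push progressively farther from the research centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial.distance import cdist
from scipy.special import logit
from scipy.stats import chi2 as stats_chi2
from statsmodels.othermod.betareg import BetaModel

__all__ = [
    "BetaRegressionResult",
    "WallaceanResult",
    "squeeze_proportions",
    "beta_regression",
    "decade_effect_test",
    "nearest_center_distance",
    "wallacean_test",
]


@dataclass
class BetaRegressionResult:
    """Maximum-likelihood beta regression fit (logit mean link)."""

    intercept: float
    slope: float
    precision: float
    se_intercept: float
    se_slope: float
    z_intercept: float
    z_slope: float
    p_intercept: float
    p_slope: float
    loglik: float
    pseudo_r2: float
    n: int
    loglik_null: float = np.nan
    p_slope_lr: float = np.nan
    mode: str = ""
    predictor: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": ["intercept", "slope", "precision"],
                "estimate": [self.intercept, self.slope, self.precision],
                "se": [self.se_intercept, self.se_slope, np.nan],
                "statistic": [self.z_intercept, self.z_slope, np.nan],
                "p": [self.p_intercept, self.p_slope, np.nan],
            }
        )


@dataclass
class WallaceanResult:
    """Weighted regression of yearly maximum center distance on year."""

    slope: float
    intercept: float
    adj_r2: float
    f_stat: float
    p_value: float
    per_year: pd.DataFrame  # columns: year, max_distance, weight

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": ["intercept", "slope"],
                "estimate": [self.intercept, self.slope],
                "adj_r2": [self.adj_r2] * 2,
                "F": [self.f_stat] * 2,
                "p": [self.p_value] * 2,
            }
        )


def squeeze_proportions(y: np.ndarray, n: int) -> np.ndarray:
    """Map proportions into the open interval (0, 1) if any sit on a boundary.

    Applies ``y' = (y·(n−1) + 0.5)/n`` only when some value equals 0 or 1;
    strictly interior data pass through unchanged.
    """
    y = np.asarray(y, dtype=float)
    if n < 2:
        raise ValueError("n must be >= 2")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    if np.any((y == 0.0) | (y == 1.0)):
        return (y * (n - 1) + 0.5) / n
    return y


def beta_regression(x: np.ndarray, y: np.ndarray) -> BetaRegressionResult:
    """Fit ``y ~ Beta(μφ, (1−μ)φ)`` with ``logit(μ) = b0 + b1·x`` by ML.

    Wald z statistics and two-sided p values per coefficient; the pseudo-R²
    is the squared correlation between the linear predictor and logit(y).
    A likelihood-ratio p value for the slope (``p_slope_lr``) is reported
    alongside: on short window series (n of order 10) the Wald test runs
    anticonservative while the LR test stays near nominal size.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError(
            "response on the boundary; squeeze_proportions must be applied first"
        )
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")

    X = sm.add_constant(x)
    model = BetaModel(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False)
        if not res.mle_retvals.get("converged", True):
            # small samples defeat the default optimizer; warm-start from a
            # simplex search, then polish with a gradient method
            rough = model.fit(method="nm", maxiter=5000, disp=False)
            res = model.fit(start_params=rough.params, method="bfgs",
                            maxiter=1000, disp=False)
            if not res.mle_retvals.get("converged", True) and rough.mle_retvals.get(
                "converged", False
            ):
                res = rough
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError(f"beta regression did not converge: {res.mle_retvals}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null_res = BetaModel(y, np.ones((len(y), 1))).fit(disp=False)
    lr_stat = max(2.0 * (res.llf - null_res.llf), 0.0)
    p_lr = float(stats_chi2.sf(lr_stat, 1))

    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    zvals = np.asarray(res.tvalues)
    pvals = np.asarray(res.pvalues)
    eta = X @ params[:2]
    r = np.corrcoef(eta, logit(y))[0, 1]
    return BetaRegressionResult(
        intercept=float(params[0]),
        slope=float(params[1]),
        precision=float(model.link_precision.inverse(params[2])),
        se_intercept=float(bse[0]),
        se_slope=float(bse[1]),
        z_intercept=float(zvals[0]),
        z_slope=float(zvals[1]),
        p_intercept=float(pvals[0]),
        p_slope=float(pvals[1]),
        loglik=float(res.llf),
        pseudo_r2=float(r * r),
        n=len(y),
        loglik_null=float(null_res.llf),
        p_slope_lr=p_lr,
    )


def decade_effect_test(
    summaries: pd.DataFrame,
    mode: str = "conservative",
    predictor: str = "total_records",
) -> BetaRegressionResult:
    """Beta regression of windowed area proportion on record accumulation.

    ``summaries`` needs columns ``window, n_records,
    proportion_conservative, proportion_nonconservative`` (one row per
    cumulative window). The default predictor is the cumulative record
    count; ``window_index`` regresses on window order instead.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 windows for the decade-effect test")
    if mode not in ("conservative", "nonconservative"):
        raise ValueError("mode must be 'conservative' or 'nonconservative'")
    if predictor == "total_records":
        x = summaries["n_records"].to_numpy(dtype=float)
    elif predictor == "window_index":
        x = np.arange(len(summaries), dtype=float)
    else:
        raise ValueError("predictor must be 'total_records' or 'window_index'")
    y = summaries[f"proportion_{mode}"].to_numpy(dtype=float)
    y = squeeze_proportions(y, n=len(y))
    result = beta_regression(x, y)
    result.mode = mode
    result.predictor = predictor
    return result


def nearest_center_distance(
    occ: pd.DataFrame, centers: pd.DataFrame
) -> np.ndarray:
    """Per record, the planar Euclidean distance to the closest center.

    Distances are in the units of the input coordinates (the analysis
    convention for geographic data here is raw-degree Euclidean distance;
    see :func:`great_circle_distance` for a spherical alternative).
    """
    if len(centers) < 1:
        raise ValueError("need at least one research center")
    pts = occ[["longitude", "latitude"]].to_numpy(dtype=float)
    ctr = centers[["longitude", "latitude"]].to_numpy(dtype=float)
    return cdist(pts, ctr).min(axis=1)


def great_circle_distance(occ: pd.DataFrame, centers: pd.DataFrame) -> np.ndarray:
    """Nearest-center distance on the sphere (km), optional alternative."""
    if len(centers) < 1:
        raise ValueError("need at least one research center")
    R = 6371.0
    lon1 = np.radians(occ["longitude"].to_numpy(float))[:, None]
    lat1 = np.radians(occ["latitude"].to_numpy(float))[:, None]
    lon2 = np.radians(centers["longitude"].to_numpy(float))[None, :]
    lat2 = np.radians(centers["latitude"].to_numpy(float))[None, :]
    dphi = lat2 - lat1
    dlmb = lon2 - lon1
    a = np.sin(dphi / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlmb / 2) ** 2
    return (2 * R * np.arcsin(np.sqrt(a))).min(axis=1)


def wallacean_test(
    occ: pd.DataFrame,
    centers: pd.DataFrame,
    weight: str = "count",
    metric: str = "euclidean",
) -> WallaceanResult:
    """Weighted regression of yearly maximum nearest-center distance on year.

    Per year with records, the response is the maximum distance to the
    nearest research center and the weight is the number of distances
    computed that year (``weight='sum'`` uses their sum instead). Reports
    the slope, the ADJUSTED R² (which can be negative), the overall F
    statistic and its p value.
    """
    if weight not in ("count", "sum"):
        raise ValueError("weight must be 'count' or 'sum'")
    dist_fn = nearest_center_distance if metric == "euclidean" else great_circle_distance
    d = dist_fn(occ, centers)
    per = (
        pd.DataFrame({"year": occ["year"].to_numpy(int), "distance": d})
        .groupby("year")
        .agg(max_distance=("distance", "max"),
             weight=("distance", "count" if weight == "count" else "sum"))
        .reset_index()
    )
    if len(per) < 3:
        raise ValueError("need records in at least 3 distinct years")

    X = sm.add_constant(per["year"].to_numpy(dtype=float))
    fit = sm.WLS(per["max_distance"].to_numpy(dtype=float), X,
                 weights=per["weight"].to_numpy(dtype=float)).fit()
    return WallaceanResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        adj_r2=float(fit.rsquared_adj),
        f_stat=float(fit.fvalue),
        p_value=float(fit.f_pvalue),
        per_year=per.rename(columns={"weight": "weight"}),
    )
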