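"""End-to-end cumulative-window analysis.

For each temporal window the pipeline: extracts environmental scores at
the (cell-thinned) presences, builds the envelope and its pseudo-
absences, samples background, evaluates the three algorithms on the
checkerboard split, refits each algorithm on all window data, thresholds
at max(sensitivity + specificity), sums the binary maps into the 0–3
agreement ensemble, and records the conservative / non-conservative
predicted-area proportions. The window series then feeds the two trend
tests: beta regression of area on cumulative records, and the weighted
regression of yearly maximum nearest-center distance on year.

Principal components are fitted once on the full environmental stack and
reused for every window (the environment is treated as time-invariant).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .environment import extract_values, load_raster_stack, pca_transform
from .evaluation import (
    area_proportion,
    binarize,
    checkerboard_partition,
    ensemble_sum,
    evaluate_model,
)
from .models import (
    ALGORITHMS,
    build_envelope,
    fit_model,
    predict_suitability,
    sample_background,
    sample_pseudo_absences,
)
from .occurrences import (
    DEFAULT_END_YEARS,
    build_windows,
    filter_records,
    read_occurrences,
    thin_to_cells,
)
from .raster import RasterStack, write_ascii_grid
from .stats import decade_effect_test, wallacean_test

logger = logging.getLogger("decade_enm")

__all__ = ["RunConfig", "ReportBundle", "run_decade_analysis", "run_from_stack"]

MIN_PRESENCES_PER_WINDOW = 5


@dataclass
class RunConfig:
    """Structured inputs and knobs for one full analysis run."""

    occurrences: str
    rasters: list[str]
    centers: str
    output_dir: str = "out"
    region: tuple[float, float, float, float] | None = None  # default: raster extent
    min_year: int = 1900
    end_years: list[int] = field(default_factory=lambda: list(DEFAULT_END_YEARS))
    n_pseudo: int = 50
    n_background: int = 10_000
    block_size: int | None = None
    var_threshold: float = 0.95
    trim_fraction: float = 0.0
    algorithm_configs: dict = field(default_factory=dict)
    thin: bool = True
    seed: int = 0
    write_rasters: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


@dataclass
class ReportBundle:
    """All tabular outputs of one run plus the reproducibility manifest."""

    windows_table: pd.DataFrame     # period, added, total, TSS per algorithm
    area_summaries: pd.DataFrame    # window, n_records, proportions
    beta_conservative: object
    beta_nonconservative: object
    wallacean: object
    manifest: dict
    ensembles: dict = field(default_factory=dict)  # window label -> RasterStack

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir) / "report"
        out.mkdir(parents=True, exist_ok=True)
        self.windows_table.to_csv(out / "table1.csv", index=False)
        self.area_summaries.to_csv(out / "areas.csv", index=False)
        beta = pd.concat(
            [
                self.beta_conservative.to_frame().assign(mode="conservative"),
                self.beta_nonconservative.to_frame().assign(mode="nonconservative"),
            ]
        )
        beta.to_csv(out / "beta_regression.csv", index=False)
        self.wallacean.to_frame().to_csv(out / "wallacean.csv", index=False)
        self.wallacean.per_year.to_csv(out / "wallacean_per_year.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return out


def _auto_block_size(stack: RasterStack, presence_xy: np.ndarray, seed: int) -> int:
    """Smallest power-of-two block size giving both folds >= 25% of presences."""
    size = max(2, min(stack.n_rows, stack.n_cols) // 8)
    while size < max(stack.n_rows, stack.n_cols):
        part = checkerboard_partition(stack, size)
        f = part.fold_of_points(stack, presence_xy)
        share = f.mean()
        if 0.25 <= share <= 0.75:
            return size
        size *= 2
        logger.warning("checkerboard block size doubled to %d", size)
    return size


def run_from_stack(
    stack: RasterStack,
    occ: pd.DataFrame,
    centers: pd.DataFrame,
    config: RunConfig,
    output_dir: Path | None = None,
) -> ReportBundle:
    """Run the analysis on in-memory inputs (library entry point)."""
    rng_master = np.random.default_rng(config.seed)
    seeds = {k: int(rng_master.integers(2**31)) for k in
             ("pseudo", "background", "model", "eval")}

    region = config.region if config.region is not None else stack.extent
    occ_clean, report = filter_records(occ, region, min_year=config.min_year)
    if occ_clean.empty:
        logger.warning("no occurrence records survive filtering")
    windows = build_windows(occ_clean, config.end_years, start_year=config.min_year)

    score_stack, pca_model = pca_transform(stack, config.var_threshold)
    logger.info("retained %d principal axes", pca_model.n_retained)

    rows = []
    summaries = []
    ensembles: dict[str, RasterStack] = {}
    prev_total = 0
    for win in windows:
        total = len(win.records)
        added = total - prev_total
        prev_total = total
        row = {"period": win.label, "added_points": added, "total_points": total,
               "tss_mxt": np.nan, "tss_rdf": np.nan, "tss_svm": np.nan}
        pres = thin_to_cells(win.records, score_stack) if config.thin else win.records
        if len(pres) < MIN_PRESENCES_PER_WINDOW:
            logger.warning(
                "window %s skipped: %d presences (< %d)",
                win.label, len(pres), MIN_PRESENCES_PER_WINDOW,
            )
            rows.append(row)
            continue

        pres_xy = pres[["longitude", "latitude"]].to_numpy(float)
        pres_env = extract_values(score_stack, pres_xy)
        ok = ~np.isnan(pres_env).any(axis=1)
        pres_xy, pres_env = pres_xy[ok], pres_env[ok]

        envelope = build_envelope(pres_env, trim_fraction=config.trim_fraction)
        pa_xy = sample_pseudo_absences(
            score_stack, envelope, n=config.n_pseudo, seed=seeds["pseudo"]
        )
        pa_env = extract_values(score_stack, pa_xy)
        bg_xy = sample_background(
            score_stack, n=config.n_background, seed=seeds["background"]
        )
        bg_env = extract_values(score_stack, bg_xy)

        block = config.block_size or _auto_block_size(score_stack, pres_xy, seeds["eval"])
        partition = checkerboard_partition(score_stack, block)

        binaries = []
        for alg in ALGORITHMS:
            contrast_xy, contrast_env = (
                (bg_xy, bg_env) if alg == "MXT" else (pa_xy, pa_env)
            )
            alg_cfg = config.algorithm_configs.get(alg, {})
            try:
                ev = evaluate_model(
                    alg, pres_xy, pres_env, contrast_xy, contrast_env,
                    partition, score_stack, config=alg_cfg,
                    seed=seeds["model"], window=win.label,
                )
            except ValueError as exc:
                raise RuntimeError(
                    f"window {win.label}, algorithm {alg}: {exc}"
                ) from exc
            row[f"tss_{alg.lower()}"] = ev.tss
            model = fit_model(alg, pres_env, contrast_env,
                              config=alg_cfg, seed=seeds["model"])
            suit = predict_suitability(model, score_stack)
            binaries.append(binarize(suit, ev.threshold))
            if output_dir is not None and config.write_rasters:
                wdir = output_dir / win.label.replace("–", "-")
                wdir.mkdir(parents=True, exist_ok=True)
                write_ascii_grid(suit, wdir / f"suitability_{alg}.asc")
                write_ascii_grid(binaries[-1], wdir / f"binary_{alg}.asc")

        ens = ensemble_sum(binaries)
        ensembles[win.label] = ens
        if output_dir is not None and config.write_rasters:
            wdir = output_dir / win.label.replace("–", "-")
            wdir.mkdir(parents=True, exist_ok=True)
            write_ascii_grid(ens, wdir / "ensemble.asc", fmt="%d")
        summaries.append(
            {
                "window": win.label,
                "n_records": total,
                "proportion_conservative": area_proportion(ens, "conservative"),
                "proportion_nonconservative": area_proportion(ens, "nonconservative"),
            }
        )
        rows.append(row)

    windows_table = pd.DataFrame(rows)
    area_summaries = pd.DataFrame(summaries)

    beta_cons = decade_effect_test(area_summaries, "conservative")
    beta_noncons = decade_effect_test(area_summaries, "nonconservative")
    wall = wallacean_test(occ_clean, centers)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "derived_seeds": seeds,
        "n_retained_axes": int(pca_model.n_retained),
        "filter_report": report.to_frame().set_index("rule")["count"].to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: v for k, v in vars(config).items() if k != "algorithm_configs"},
                sort_keys=True, default=str,
            ).encode()
        ).hexdigest(),
    }
    return ReportBundle(
        windows_table=windows_table,
        area_summaries=area_summaries,
        beta_conservative=beta_cons,
        beta_nonconservative=beta_noncons,
        wallacean=wall,
        manifest=manifest,
        ensembles=ensembles,
    )


def run_decade_analysis(config: RunConfig) -> ReportBundle:
    """Run the full analysis from files named in the config and write outputs."""
    stack = load_raster_stack(config.rasters)
    occ = read_occurrences(config.occurrences)
    centers = pd.read_csv(config.centers)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = run_from_stack(stack, occ, centers, config, output_dir=out_dir)
    bundle.write(out_dir)
    return bundle
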