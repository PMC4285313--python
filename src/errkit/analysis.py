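"""End-to-end analysis driver: config -> report files.

Runs a requested list of correction methods on one dataset and writes
tab-separated reports plus a ``run.json`` echoing the configuration, so a
run is fully reproducible from its output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (CorrectionResult, FitError, fit_naive_logistic,
                          fit_rc_model, heteroscedasticity_diagnostic,
                          rc_correct, rc_correct_probit, rc_lognormal,
                          sensitivity_grid)
from .categorized import impute_then_categorize, macmahon, quantile_trend_correct
from .dataio import read_dataset
from .dataset import Dataset
from .reconstruction import (estimate_conditional_moments, mi_correct,
                             moment_reconstruct)

log = logging.getLogger("errkit")

KNOWN_METHODS = ("naive", "rc", "rc_probit", "rc_sens", "rc_lognormal",
                 "mr", "mi", "macmahon", "quantile_trend", "impute_categorize")


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    input: str
    columns: dict = field(default_factory=dict)
    exposure_scale: str = "natural"  # {"natural", "log"}
    methods: list = field(default_factory=lambda: ["naive", "rc"])
    thetas: list = field(default_factory=lambda: [1.0, 0.75, 0.5])
    rhos: list = field(default_factory=lambda: [0.0, 0.5])
    psi_y: list = field(default_factory=lambda: [0.0, 0.0])
    theta_y: list = field(default_factory=lambda: [1.0, 1.0])
    rho_y: list = field(default_factory=lambda: [0.0, 0.0])
    q: int = 5
    m: int = 20
    n_boot: int = 0
    seed: int = 0
    outdir: str = "errkit_out"

    def __post_init__(self) -> None:
        unknown = set(self.methods) - set(KNOWN_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if self.exposure_scale not in ("natural", "log"):
            raise ValueError("exposure_scale must be 'natural' or 'log'")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _result_row(method: str, r: CorrectionResult) -> dict:
    lo_a, hi_a = r.ci_naive_lambda
    if r.se_full is not None:
        lo_b, hi_b = r.ci_95
        se_b = r.se_full
    else:
        se_b = lo_b = hi_b = np.nan
    return {"method": method, "beta": r.beta, "se_a": r.se_naive_lambda,
            "ci_a_lo": lo_a, "ci_a_hi": hi_a, "se_b": se_b,
            "ci_b_lo": lo_b, "ci_b_hi": hi_b,
            "params": json.dumps(r.params, default=str)}


def _check_preconditions(config: AnalysisConfig, dataset: Dataset) -> None:
    needs_repeats = set(config.methods) - {"naive"}
    if needs_repeats and dataset.n_repeat == 0:
        raise FitError("all correction methods need repeat measurements, "
                       "but no subject has W2")
    differential = {"mr", "mi", "impute_categorize"} & set(config.methods)
    if differential:
        for y in (0, 1):
            if not ((dataset.y == y) & dataset.has_repeat).any():
                raise FitError(f"MR/MI need repeats in both outcome groups; "
                               f"none with Y={y}")


def run_analysis(config: AnalysisConfig, dataset: Dataset | None = None) -> dict:
    """Execute the configured methods; returns a status dict.

    Writes results.tsv, sensitivity.tsv, categorized.tsv,
    heteroscedasticity_diagnostic.tsv and run.json into the output
    directory (only the files the requested methods produce). A method
    whose preconditions fail is logged and skipped; status is "ok",
    "partial" (some skipped) or "failed" (all failed).
    """
    if dataset is None:
        dataset = read_dataset(config.input, config.columns or None)
    _check_preconditions(config, dataset)
    work = dataset.with_log_exposure() if config.exposure_scale == "log" else dataset

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    skipped: dict[str, str] = {}
    extra: dict[str, object] = {}

    naive = rc = None
    if not ({"naive", "rc", "rc_probit", "rc_sens", "quantile_trend"}
            .isdisjoint(config.methods)):
        naive = fit_naive_logistic(work)
        rc = fit_rc_model(work)

    psi_y, theta_y, rho_y = (tuple(config.psi_y), tuple(config.theta_y),
                             tuple(config.rho_y))

    for method in config.methods:
        try:
            if method == "naive":
                rows.append({"method": "naive", "beta": naive.beta_star_scalar,
                             "se_a": naive.se_star_scalar,
                             "ci_a_lo": naive.beta_star_scalar - 1.959963984540054 * naive.se_star_scalar,
                             "ci_a_hi": naive.beta_star_scalar + 1.959963984540054 * naive.se_star_scalar,
                             "se_b": np.nan, "ci_b_lo": np.nan,
                             "ci_b_hi": np.nan, "params": "{}"})
            elif method == "rc":
                rows.append(_result_row("rc", rc_correct(naive, rc)))
            elif method == "rc_probit":
                rows.append(_result_row("rc_probit", rc_correct_probit(naive, rc)))
            elif method == "rc_sens":
                # infeasible cells (lambda* <= rho) become NaN rows in the
                # report rather than voiding the whole grid
                cells = []
                for theta in config.thetas:
                    for rho in config.rhos:
                        try:
                            cells.append(sensitivity_grid(naive, rc, [theta],
                                                          [rho]))
                        except FitError as exc:
                            log.warning("sensitivity cell theta=%s rho=%s "
                                        "infeasible: %s", theta, rho, exc)
                            cells.append(pd.DataFrame([{
                                "theta": theta, "rho": rho, "beta": np.nan,
                                "se_naive_lambda": np.nan, "se_full": np.nan,
                                "ci_lo": np.nan, "ci_hi": np.nan}]))
                grid = pd.concat(cells, ignore_index=True)
                grid.to_csv(outdir / "sensitivity.tsv", sep="\t", index=False)
                extra["sensitivity_grid_cells"] = len(grid)
            elif method == "rc_lognormal":
                if config.exposure_scale == "log":
                    raise FitError("rc_lognormal applies to the natural scale")
                res, fit = rc_lognormal(work, n_boot=config.n_boot,
                                        seed=config.seed)
                rows.append(_result_row("rc_lognormal", res))
                extra["lognormal_fit"] = {"lam_log": fit.lam_log,
                                          "sigma_u2": fit.sigma_u2}
            elif method == "mr":
                moments = estimate_conditional_moments(work, psi_y, theta_y,
                                                       rho_y)
                _, res = moment_reconstruct(work, moments,
                                            n_boot=config.n_boot,
                                            seed=config.seed)
                rows.append(_result_row("mr", res))
            elif method == "mi":
                _, res = mi_correct(work, psi_y, theta_y, rho_y, M=config.m,
                                    seed=config.seed, n_boot=config.n_boot)
                rows.append(_result_row("mi", res))
            elif method == "macmahon":
                qa = macmahon(work, config.q)
                _append_categorized(outdir, qa)
            elif method == "impute_categorize":
                qa = impute_then_categorize(work, "mi", config.q, psi_y,
                                            theta_y, rho_y, M=config.m,
                                            seed=config.seed)
                _append_categorized(outdir, qa)
            elif method == "quantile_trend":
                from .categorized import assign_quantiles
                groups = assign_quantiles(work.w1, config.q).astype(float)
                trend_ds = Dataset(work.df.assign(w1=groups))
                naive_trend = fit_naive_logistic(trend_ds)
                for rho in config.rhos:
                    try:
                        r = quantile_trend_correct(naive_trend, rc, rho=rho)
                    except FitError as exc:
                        log.warning("quantile_trend rho=%s infeasible: %s",
                                    rho, exc)
                        continue
                    rows.append(_result_row(f"quantile_trend(rho={rho})", r))
        except (FitError, ValueError) as exc:
            log.warning("method %s skipped: %s", method, exc)
            skipped[method] = str(exc)

    if dataset.n_repeat >= 3:
        diag = heteroscedasticity_diagnostic(dataset)
        diag.table.to_csv(outdir / "heteroscedasticity_diagnostic.tsv",
                          sep="\t", index=False)
        extra["heteroscedasticity"] = {"slope": diag.slope,
                                       "slope_se": diag.slope_se,
                                       "p_value": diag.p_value}

    if rows:
        pd.DataFrame(rows).to_csv(outdir / "results.tsv", sep="\t", index=False)

    status = "ok" if not skipped else (
        "failed" if len(skipped) == len(config.methods) else "partial")
    run_info = {"config": asdict(config), "seed": config.seed,
                "errkit_version": __version__,
                "numpy_version": np.__version__,
                "n": dataset.n, "n_cases": dataset.n_cases,
                "n_repeat": dataset.n_repeat,
                "skipped": skipped, "status": status, **extra}
    (outdir / "run.json").write_text(json.dumps(run_info, indent=2,
                                                default=str))
    return run_info


def _append_categorized(outdir: Path, qa) -> None:
    path = outdir / "categorized.tsv"
    table = qa.table.assign(method=qa.method)
    if path.exists():
        table = pd.concat([pd.read_csv(path, sep="\t"), table],
                          ignore_index=True)
    table.to_csv(path, sep="\t", index=False)
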