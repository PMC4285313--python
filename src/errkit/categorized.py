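"""Corrections when a continuous exposure is analyzed in quantile groups.

Categorizing a mismeasured continuous exposure misclassifies subjects near
the group boundaries, and the misclassification is differential even when
the underlying error is not. Three corrections are provided:

* MacMahon's graphical method — naive per-group log ORs plotted against
  unbiased "usual exposure" estimates (means of the repeat measurement
  within groups of the first measurement),
* impute-then-categorize — categorize moment-reconstructed or multiply
  imputed exposures instead of W1,
* a trend correction — for a linear trend across Q quantile groups the
  naive per-group-increase estimate needs dividing by corr(X, W1), i.e.
  sqrt(lambda*) under classical error, or equivalently multiplying by
  sqrt((1 - rho)/(lambda* - rho)) under systematic error; the exposure
  scaling theta cancels, so only rho must be assumed. The correction is
  always smaller than the 1/lambda needed on the continuous scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import child_seed
from .calibration import (CorrectionResult, FitError, NaiveFit, RCModelFit,
                          _design, fit_logistic)
from .dataset import Dataset
from .reconstruction import (estimate_conditional_moments, mi_impute,
                             reconstruct_values, rubins_rules)
from .uncertainty import wald_ci

__all__ = ["QuantileAnalysis", "assign_quantiles", "macmahon",
           "impute_then_categorize", "quantile_trend_correct"]


@dataclass
class QuantileAnalysis:
    """Per-group results of a categorized exposure analysis.

    ``table`` columns: group, n, n_cases, usual_exposure, log_or, se,
    ci_lo, ci_hi — the data behind a MacMahon-style plot. The reference
    group 1 has log OR 0 by construction.
    """

    Q: int
    groups: np.ndarray
    table: pd.DataFrame
    method: str


def assign_quantiles(values: np.ndarray, Q: int) -> np.ndarray:
    """Quantile group labels 1..Q with sizes differing by at most one.

    Uses empirical-quantile (rank-based) cutting; ties are broken by
    stable input order so group sizes stay balanced. Fails if the values
    carry too much tie mass to form Q groups.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if Q < 2:
        raise ValueError("Q must be >= 2")
    if n < Q:
        raise ValueError(f"cannot form {Q} groups from {n} values")
    n_distinct = np.unique(values).size
    if n_distinct < Q:
        counts = pd.Series(values).value_counts()
        raise ValueError(
            f"only {n_distinct} distinct values for {Q} groups; largest tie "
            f"mass {int(counts.iloc[0])} at value {counts.index[0]}")
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (ranks * Q // n) + 1


def _group_log_ors(y: np.ndarray, groups: np.ndarray, z: np.ndarray,
                   Q: int) -> pd.DataFrame:
    """Logistic fit with group indicators (group 1 = reference) and Z."""
    dummies = [(groups == q).astype(float) for q in range(2, Q + 1)]
    design = _design(dummies + [z[:, j] for j in range(z.shape[1])])
    res = fit_logistic(y, design, [f"g{q}" for q in range(2, Q + 1)])
    rows = [{"group": 1, "log_or": 0.0, "se": 0.0, "ci_lo": 0.0, "ci_hi": 0.0}]
    for i, q in enumerate(range(2, Q + 1)):
        b, s = float(res.params[1 + i]), float(res.bse[1 + i])
        lo, hi = wald_ci(b, s)
        rows.append({"group": q, "log_or": b, "se": s, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows)


def _finish_table(base: pd.DataFrame, groups: np.ndarray, y: np.ndarray,
                  usual: dict) -> pd.DataFrame:
    base = base.copy()
    base["n"] = [int((groups == q).sum()) for q in base["group"]]
    base["n_cases"] = [int(y[groups == q].sum()) for q in base["group"]]
    base["usual_exposure"] = [usual.get(q, np.nan) for q in base["group"]]
    cols = ["group", "n", "n_cases", "usual_exposure", "log_or", "se",
            "ci_lo", "ci_hi"]
    return base[cols]


def macmahon(dataset: Dataset, Q: int) -> QuantileAnalysis:
    """MacMahon's method: naive group ORs vs usual exposure per group.

    Groups are quantiles of W1. The mean of the repeat W2 among repeat
    subjects in a W1-group is an unbiased estimate of mean usual exposure
    in that group, because the error in W2 is independent of the W1-based
    grouping (classical error). Groups without repeat subjects get a
    missing usual exposure with a warning.
    """
    if dataset.n_repeat == 0:
        raise FitError("MacMahon's method needs repeat measurements")
    groups = assign_quantiles(dataset.w1, Q)
    base = _group_log_ors(dataset.y, groups, dataset.z, Q)
    usual = {}
    for q in range(1, Q + 1):
        in_group = (groups == q) & dataset.has_repeat
        if in_group.any():
            usual[q] = float(dataset.w2[in_group].mean())
        else:
            warnings.warn(f"group {q} has no repeat subjects; usual "
                          "exposure not estimable")
    table = _finish_table(base, groups, dataset.y, usual)
    return QuantileAnalysis(Q=Q, groups=groups, table=table, method="macmahon")


def impute_then_categorize(dataset: Dataset, method: str, Q: int,
                           psi_y=(0.0, 0.0), theta_y=(1.0, 1.0),
                           rho_y=(0.0, 0.0), M: int = 20,
                           seed: int = 0) -> QuantileAnalysis:
    """Impute the continuous exposure (MR or MI), then categorize it.

    MR: the reconstructed values are categorized once and analyzed like a
    true exposure. MI: each imputed dataset is categorized and fitted, and
    the per-group log ORs are pooled across imputations by Rubin's rules.
    The usual-exposure column reports the mean imputed exposure per group.
    """
    method = method.lower()
    if method not in ("mr", "mi"):
        raise ValueError("method must be 'mr' or 'mi'")
    moments = estimate_conditional_moments(dataset, psi_y, theta_y, rho_y)
    y, z = dataset.y, dataset.z

    if method == "mr":
        x_imp = reconstruct_values(dataset, moments)
        groups = assign_quantiles(x_imp, Q)
        base = _group_log_ors(y, groups, z, Q)
        usual = {q: float(x_imp[groups == q].mean()) for q in range(1, Q + 1)}
        table = _finish_table(base, groups, y, usual)
        return QuantileAnalysis(Q=Q, groups=groups, table=table,
                                method="mr_categorize")

    draws = mi_impute(dataset, moments, M, child_seed(seed, "categorize_mi"))
    per_imp = []
    usual_sum = np.zeros(Q)
    for m in range(M):
        groups_m = assign_quantiles(draws[m], Q)
        per_imp.append(_group_log_ors(y, groups_m, z, Q))
        usual_sum += [draws[m][groups_m == q].mean() for q in range(1, Q + 1)]
    rows = [{"group": 1, "log_or": 0.0, "se": 0.0, "ci_lo": 0.0, "ci_hi": 0.0}]
    for q in range(2, Q + 1):
        ests = [t.loc[t["group"] == q, "log_or"].iloc[0] for t in per_imp]
        vars_ = [t.loc[t["group"] == q, "se"].iloc[0] ** 2 for t in per_imp]
        pooled, _, _, T = rubins_rules(ests, vars_)
        se = float(np.sqrt(T))
        lo, hi = wald_ci(pooled, se)
        rows.append({"group": q, "log_or": pooled, "se": se,
                     "ci_lo": lo, "ci_hi": hi})
    groups = assign_quantiles(draws.mean(axis=0), Q)  # representative grouping
    usual = {q: float(usual_sum[q - 1] / M) for q in range(1, Q + 1)}
    table = _finish_table(pd.DataFrame(rows), groups, y, usual)
    return QuantileAnalysis(Q=Q, groups=groups, table=table,
                            method="mi_categorize")


def quantile_trend_correct(naive_trend: NaiveFit, rc: RCModelFit,
                           rho: float = 0.0) -> CorrectionResult:
    """Correct the per-quantile-group trend for measurement error.

    ``naive_trend`` is the logistic fit of Y on the W1 quantile-group
    number (treated as continuous) and Z. For quantile groups of a
    normally distributed exposure the naive trend is attenuated by
    corr(X, W1 | Z) rather than by the RDR, so

        beta_G = beta*_G * sqrt((1 - rho) / (lambda* - rho))

    which at rho = 0 is beta*_G / sqrt(lambda*). theta cancels: only the
    error correlation rho must be assumed. Applies only to quantile (not
    fixed-cutpoint) groups, and equally to SD-standardized exposures.
    """
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must be in [0, 1)")
    lam_star = rc.lam
    if lam_star <= rho:
        raise FitError(f"lambda* = {lam_star:.4f} <= rho = {rho}; "
                       "correction undefined")
    factor = float(np.sqrt((1.0 - rho) / (lam_star - rho)))
    beta_star, se_star = naive_trend.beta_star_scalar, naive_trend.se_star_scalar
    beta = beta_star * factor
    se_a = se_star * factor
    # delta method: d beta / d lambda* = -beta / (2 (lambda* - rho))
    var_full = factor**2 * se_star**2 \
        + (beta / (2.0 * (lam_star - rho)))**2 * rc.var_lam
    return CorrectionResult(beta=beta, se_naive_lambda=se_a,
                            se_full=float(np.sqrt(var_full)),
                            method="quantile_trend",
                            params={"rho": rho},
                            diagnostics={"lam_star": lam_star,
                                         "factor": factor})
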