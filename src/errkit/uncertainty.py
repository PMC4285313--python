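"""Shared variance machinery: delta method and whole-pipeline bootstrap."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from ._rng import child_seed, stream
from .dataset import Dataset

__all__ = ["wald_ci", "delta_var_rc", "BootstrapSpec", "BootstrapResult",
           "bootstrap_correct"]


def wald_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-reference confidence interval beta +/- z * se."""
    if se < 0:
        raise ValueError("se must be >= 0")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (beta - z * se, beta + z * se)


def delta_var_rc(beta_star: float, var_beta_star: float, lam: float,
                 var_lam: float) -> float:
    """Variance of the calibrated estimate beta_star / lam.

    First-order delta method for the ratio, treating the naive estimate and
    the regression dilution ratio as independent (they come from the outcome
    model and the repeat regression respectively):

        var(beta_hat) = var(beta*)/lam^2 + beta*^2 var(lam)/lam^4
    """
    if lam <= 0:
        raise ValueError("delta method requires lam > 0")
    if var_beta_star < 0 or var_lam < 0:
        raise ValueError("variances must be >= 0")
    return var_beta_star / lam**2 + beta_star**2 * var_lam / lam**4


@dataclass(frozen=True)
class BootstrapSpec:
    """Resampling plan for whole-pipeline standard errors.

    Resampling is stratified by (outcome, repeat availability) so every
    resample preserves the case/control split and the repeat-subset size.
    """

    n_boot: int = 200
    seed: int = 0
    ci_type: str = "normal"  # {"normal", "percentile"}
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.n_boot < 50:
            raise ValueError("n_boot must be >= 50 for a usable SE")
        if self.ci_type == "percentile" and self.n_boot < 999:
            raise ValueError("percentile CIs need n_boot >= 999")
        if self.ci_type not in ("normal", "percentile"):
            raise ValueError(f"unknown ci_type {self.ci_type!r}")


@dataclass
class BootstrapResult:
    se: float
    ci: tuple[float, float]
    estimates: np.ndarray
    n_failed: int


def bootstrap_correct(dataset: Dataset, estimator: Callable[[Dataset, int], float],
                      spec: BootstrapSpec) -> BootstrapResult:
    """Bootstrap SE/CI for any estimator run on the full dataset.

    ``estimator(dataset, seed)`` must re-run the complete pipeline —
    including re-estimation of calibration or error-model moments — and
    return a scalar estimate; the seed argument lets stochastic estimators
    (multiple imputation) re-seed per resample.
    """
    y = dataset.y
    strata = [np.flatnonzero((y == lev) & (dataset.has_repeat == rep))
              for lev in (0, 1) for rep in (False, True)]
    strata = [s for s in strata if s.size]
    rng = stream(spec.seed, "bootstrap_resampling")
    point = estimator(dataset, child_seed(spec.seed, "bootstrap_point"))

    estimates = []
    n_failed = 0
    for b in range(spec.n_boot):
        idx = np.concatenate([rng.choice(s, size=s.size, replace=True)
                              for s in strata])
        try:
            est = estimator(dataset.resample(idx),
                            child_seed(spec.seed, f"bootstrap_rep_{b}"))
        except Exception:
            n_failed += 1
            if n_failed > 0.1 * spec.n_boot:
                raise RuntimeError(
                    f"estimator failed on {n_failed} of {b + 1} bootstrap "
                    "resamples (>10%); aborting")
            continue
        estimates.append(est)
    estimates = np.asarray(estimates)
    se = float(np.std(estimates, ddof=1))
    if spec.ci_type == "percentile":
        lo, hi = np.quantile(estimates, [(1 - spec.level) / 2,
                                         0.5 + spec.level / 2])
        ci = (float(lo), float(hi))
    else:
        ci = wald_ci(point, se, spec.level)
    return BootstrapResult(se=se, ci=ci, estimates=estimates, n_failed=n_failed)
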