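"""Moment reconstruction and multiple imputation for differential error.

Both methods build imputed values of the true exposure X conditionally on
all observed data including the outcome, so they remain valid when the
measurement error distribution depends on Y (differential error), where
regression calibration does not.

The error model is W_ij = psi_y + theta_y * X + eps_ij with error SD
sigma_eps_y and within-person error correlation rho_y, all allowed to
differ between outcome levels y = 0, 1. The analyst supplies (psi_y,
theta_y, rho_y) — they are not identifiable from repeated measurements —
and the remaining moments are estimated from the data:

    sigma_eps_y^2 = [var(W1|y,Z) - cov(W1,W2|y,Z)] / (1 - rho_y)
    var(X|y,Z)    = [cov(W1,W2|y,Z) - rho_y var(W1|y,Z)] / [theta_y^2 (1-rho_y)]
    E(X|y,Z)      = [E(W1|y,Z) - psi_y] / theta_y

Moment reconstruction (MR) deterministically rescales W1 so that the first
two moments of the reconstructed exposure given Y match those of X given Y.
Multiple imputation (MI) draws X from its normal conditional distribution
given (W1, [W2,] Y, Z) and pools per-imputation logistic fits with Rubin's
rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from ._rng import child_seed, stream
from .calibration import CorrectionResult, FitError, _design, fit_logistic
from .dataset import Dataset

__all__ = ["ConditionalMoments", "MIResult", "estimate_conditional_moments",
           "moment_reconstruct", "mi_impute", "rubins_rules", "mi_correct",
           "mvn_conditional"]


class ModelContradictionError(FitError):
    """Estimated variances are negative: the assumed error model cannot
    hold for these data (e.g. repeats agree less than the assumed error
    correlation allows)."""


@dataclass
class ConditionalMoments:
    """Per-outcome-level conditional moments of (X, W1, W2) given Z.

    ``w1_coefs[y]`` are OLS coefficients (const, Z) of E(W1 | Y=y, Z);
    variances are Z-residual variances within stratum.
    """

    psi_y: tuple[float, float]
    theta_y: tuple[float, float]
    rho_y: tuple[float, float]
    w1_coefs: dict
    var_w1_y: dict
    cov_w12_y: dict
    sigma_eps2_y: dict
    var_x_y: dict

    def exp_w1(self, y: int, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(np.asarray(z, dtype=float))
        return _design([z[:, j] for j in range(z.shape[1])],
                       n=z.shape[0]) @ self.w1_coefs[y]

    def exp_x(self, y: int, z: np.ndarray) -> np.ndarray:
        return (self.exp_w1(y, z) - self.psi_y[y]) / self.theta_y[y]


def estimate_conditional_moments(dataset: Dataset,
                                 psi_y=(0.0, 0.0),
                                 theta_y=(1.0, 1.0),
                                 rho_y=(0.0, 0.0)) -> ConditionalMoments:
    """Estimate stratum-wise moments of W1, W2 and the implied X moments.

    Within each outcome stratum, E(W1|Y,Z) is a linear model in Z fitted on
    all subjects; var(W1|Y,Z) is its residual variance; cov(W1,W2|Y,Z) is
    the cross-product of Z-residuals over the repeat subset (dof n-k-1).
    """
    for th in theta_y:
        if th <= 0:
            raise ValueError("theta_y must be > 0")
    for r in rho_y:
        if not (0.0 <= r < 1.0):
            raise ValueError("rho_y must be in [0, 1)")
    k = dataset.z.shape[1]
    w1_coefs, var_w1, cov_w12, sig_eps2, var_x = {}, {}, {}, {}, {}
    for y in (0, 1):
        mask = dataset.y == y
        if mask.sum() < k + 2:
            raise FitError(f"too few subjects with Y={y}")
        z_y = dataset.z[mask]
        w1_y = dataset.w1[mask]
        design = _design([z_y[:, j] for j in range(k)], n=z_y.shape[0])
        fit = sm.OLS(w1_y, design).fit()
        w1_coefs[y] = np.asarray(fit.params)
        var_w1[y] = float(fit.mse_resid)

        rep = mask & dataset.has_repeat
        if rep.sum() < k + 2:
            raise FitError(
                f"no usable repeat measurements in stratum Y={y}; repeated "
                "measures are needed in both outcome groups")
        z_r = dataset.z[rep]
        design_r = _design([z_r[:, j] for j in range(k)], n=z_r.shape[0])
        r1 = sm.OLS(dataset.w1[rep], design_r).fit().resid
        r2 = sm.OLS(dataset.w2[rep], design_r).fit().resid
        cov_w12[y] = float(r1 @ r2 / (rep.sum() - k - 1))

        rho, theta = rho_y[y], theta_y[y]
        s2 = (var_w1[y] - cov_w12[y]) / (1.0 - rho)
        vx = (cov_w12[y] - rho * var_w1[y]) / (theta**2 * (1.0 - rho))
        if s2 < 0:
            raise ModelContradictionError(
                f"stratum Y={y}: cov(W1,W2|Z) = {cov_w12[y]:.4f} exceeds "
                f"var(W1|Z) = {var_w1[y]:.4f}; implied error variance is "
                "negative under the assumed rho")
        if vx < 0:
            raise ModelContradictionError(
                f"stratum Y={y}: implied var(X|Y,Z) = {vx:.4f} < 0; the "
                f"assumed rho = {rho} exceeds the observed repeat agreement")
        sig_eps2[y], var_x[y] = s2, vx
    return ConditionalMoments(psi_y=tuple(psi_y), theta_y=tuple(theta_y),
                              rho_y=tuple(rho_y), w1_coefs=w1_coefs,
                              var_w1_y=var_w1, cov_w12_y=cov_w12,
                              sigma_eps2_y=sig_eps2, var_x_y=var_x)


# ---------------------------------------------------------------------------
# moment reconstruction


def reconstruct_values(dataset: Dataset, moments: ConditionalMoments) -> np.ndarray:
    """The MR transform of W1, stratum by stratum.

    X_MR = E(X|Y,Z) + (W1 - E(W1|Y,Z)) * sqrt(var(X|Y,Z) / var(W1|Y,Z)),
    which matches the first two joint moments of (X, Y) given Z.
    """
    x_mr = np.empty(dataset.n)
    for y in (0, 1):
        mask = dataset.y == y
        z_y = dataset.z[mask]
        scale = np.sqrt(moments.var_x_y[y] / moments.var_w1_y[y])
        x_mr[mask] = moments.exp_x(y, z_y) \
            + (dataset.w1[mask] - moments.exp_w1(y, z_y)) * scale
    return x_mr


def moment_reconstruct(dataset: Dataset, moments: ConditionalMoments,
                       n_boot: int = 0, seed: int = 0
                       ) -> tuple[np.ndarray, CorrectionResult]:
    """MR-corrected logistic fit; bootstrap SE re-estimates the moments."""
    x_mr = reconstruct_values(dataset, moments)
    k = dataset.z.shape[1]
    design = _design([x_mr] + [dataset.z[:, j] for j in range(k)])
    res = fit_logistic(dataset.y, design, ["x_mr"])
    se_b = None
    if n_boot:
        from .uncertainty import BootstrapSpec, bootstrap_correct

        def estimator(ds: Dataset, _seed: int) -> float:
            m = estimate_conditional_moments(ds, moments.psi_y,
                                             moments.theta_y, moments.rho_y)
            xm = reconstruct_values(ds, m)
            d = _design([xm] + [ds.z[:, j] for j in range(ds.z.shape[1])])
            return float(fit_logistic(ds.y, d, ["x_mr"]).params[1])

        boot = bootstrap_correct(dataset, estimator,
                                 BootstrapSpec(n_boot=n_boot, seed=seed))
        se_b = boot.se
    result = CorrectionResult(beta=float(res.params[1]),
                              se_naive_lambda=float(res.bse[1]),
                              se_full=se_b, method="mr",
                              params={"psi_y": moments.psi_y,
                                      "theta_y": moments.theta_y,
                                      "rho_y": moments.rho_y})
    return x_mr, result


# ---------------------------------------------------------------------------
# multiple imputation


def mvn_conditional(mu_x: np.ndarray, v: float, c: np.ndarray,
                    sigma_w: np.ndarray, w: np.ndarray,
                    mu_w: np.ndarray) -> tuple[np.ndarray, float]:
    """Conditional mean and variance of scalar X given a Gaussian block W.

    Standard multivariate-normal conditioning: mean = mu_x +
    c' Sigma_W^{-1} (w - mu_w), variance = v - c' Sigma_W^{-1} c, where c
    = cov(X, W) and Sigma_W = var(W). ``w`` and ``mu_w`` have one row per
    subject.
    """
    try:
        weights = np.linalg.solve(sigma_w, c)
    except np.linalg.LinAlgError:
        # exactly singular (e.g. zero error variance): the minimum-norm
        # solution is valid only if the system is consistent
        weights = np.linalg.pinv(sigma_w) @ c
        if not np.allclose(sigma_w @ weights, c, atol=1e-10):
            raise FitError("singular measurement covariance matrix") from None
    cond_var = float(v - c @ weights)
    cond_mean = mu_x + (np.atleast_2d(w) - np.atleast_2d(mu_w)) @ weights
    return np.asarray(cond_mean).ravel(), cond_var


def _stratum_conditionals(moments: ConditionalMoments, y: int):
    """Covariance blocks of (X, W1, W2) given (Y=y, Z) under the error model."""
    theta = moments.theta_y[y]
    rho = moments.rho_y[y]
    v = moments.var_x_y[y]
    s2 = moments.sigma_eps2_y[y]
    c = np.array([theta * v, theta * v])
    sigma_w = np.array([[theta**2 * v + s2, theta**2 * v + rho * s2],
                        [theta**2 * v + rho * s2, theta**2 * v + s2]])
    return v, c, sigma_w


def mi_impute(dataset: Dataset, moments: ConditionalMoments, M: int,
              seed: int) -> np.ndarray:
    """Draw M imputed true-exposure vectors, shape (M, n).

    Subjects without a repeat are imputed from X | W1, Y, Z; subjects with
    one from X | W1, W2, Y, Z — both are exact Gaussian conditionals of
    the assumed joint model, so the extra repeat always tightens the
    conditional variance.
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    n = dataset.n
    cond_mean = np.empty(n)
    cond_sd = np.empty(n)
    for y in (0, 1):
        v, c, sigma_w = _stratum_conditionals(moments, y)
        for with_rep in (False, True):
            mask = (dataset.y == y) & (dataset.has_repeat == with_rep)
            if not mask.any():
                continue
            z_m = dataset.z[mask]
            mu_x = moments.exp_x(y, z_m)
            mu_w1 = moments.exp_w1(y, z_m)
            if with_rep:
                w = np.column_stack([dataset.w1[mask], dataset.w2[mask]])
                mu_w = np.column_stack([mu_w1, mu_w1])  # same error model in W2
                mean, var = mvn_conditional(mu_x, v, c, sigma_w, w, mu_w)
            else:
                mean, var = mvn_conditional(mu_x, v, c[:1], sigma_w[:1, :1],
                                            dataset.w1[mask, None],
                                            mu_w1[:, None])
            if var < -1e-12:
                raise ModelContradictionError(
                    f"negative conditional variance {var:.3e} in stratum Y={y}")
            cond_mean[mask] = mean
            cond_sd[mask] = np.sqrt(max(var, 0.0))
    draws = np.empty((M, n))
    for m in range(M):
        rng = stream(child_seed(seed, f"imputation_{m}"), "mi_draws")
        draws[m] = cond_mean + cond_sd * rng.standard_normal(n)
    return draws


def rubins_rules(estimates, variances) -> tuple[float, float, float, float]:
    """Pool M complete-data estimates: returns (pooled, A, B, T).

    A = mean within-imputation variance, B = between-imputation sample
    variance, T = A + (1 + 1/M) B.
    """
    estimates = np.asarray(estimates, dtype=float)
    variances = np.asarray(variances, dtype=float)
    M = estimates.size
    if M < 2:
        raise ValueError("Rubin's rules need at least 2 imputations")
    if (variances <= 0).any():
        raise ValueError("within-imputation variances must be positive")
    pooled = float(estimates.mean())
    A = float(variances.mean())
    B = float(estimates.var(ddof=1))
    T = A + (1.0 + 1.0 / M) * B
    return pooled, A, B, T


@dataclass
class MIResult:
    M: int
    estimates: np.ndarray
    variances: np.ndarray
    pooled: float
    within_var: float    # A
    between_var: float   # B
    total_var: float     # T = A + (1 + 1/M) B
    seed: int


def mi_correct(dataset: Dataset, psi_y=(0.0, 0.0), theta_y=(1.0, 1.0),
               rho_y=(0.0, 0.0), M: int = 20, seed: int = 0,
               n_boot: int = 0) -> tuple[MIResult, CorrectionResult]:
    """Full MI pipeline: moments -> M imputations -> logistic fits -> pool.

    The Rubin total variance ignores uncertainty in the estimated error
    moments; ``n_boot`` > 0 additionally bootstraps the whole chain
    (re-estimating moments and re-imputing per resample) for a fully
    propagated SE.
    """
    def run(ds: Dataset, run_seed: int) -> tuple[float, float, np.ndarray, np.ndarray]:
        moments = estimate_conditional_moments(ds, psi_y, theta_y, rho_y)
        draws = mi_impute(ds, moments, M, run_seed)
        k = ds.z.shape[1]
        est = np.empty(M)
        var = np.empty(M)
        for m in range(M):
            design = _design([draws[m]] + [ds.z[:, j] for j in range(k)])
            res = fit_logistic(ds.y, design, ["x_imp"])
            est[m] = res.params[1]
            var[m] = res.bse[1] ** 2
        pooled, A, B, T = rubins_rules(est, var)
        return pooled, T, est, var

    pooled, T, est, var = run(dataset, seed)
    _, A, B, _ = rubins_rules(est, var)
    se_b = None
    if n_boot:
        from .uncertainty import BootstrapSpec, bootstrap_correct
        boot = bootstrap_correct(dataset, lambda ds, s: run(ds, s)[0],
                                 BootstrapSpec(n_boot=n_boot, seed=seed))
        se_b = boot.se
    mi_res = MIResult(M=M, estimates=est, variances=var, pooled=pooled,
                      within_var=A, between_var=B, total_var=T, seed=seed)
    corr = CorrectionResult(beta=pooled, se_naive_lambda=float(np.sqrt(T)),
                            se_full=se_b, method="mi",
                            params={"psi_y": tuple(psi_y),
                                    "theta_y": tuple(theta_y),
                                    "rho_y": tuple(rho_y), "M": M})
    return mi_res, corr
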