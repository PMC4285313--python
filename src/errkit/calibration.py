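"""Regression calibration corrections for exposure measurement error.

The naive logistic fit of the outcome on the error-prone measurement W1
attenuates the exposure log odds ratio by the regression dilution ratio
(RDR) lambda = cov(X, W1 | Z) / var(W1 | Z). With a repeat measurement W2
whose error shares the distribution of the error in W1, lambda is estimated
as the slope of the linear regression of W2 on W1 and Z, and the corrected
log OR is beta_hat = beta*_hat / lambda_hat — equivalently, the logistic
model refitted on the calibrated predictions E(X | W1, Z).

Extensions implemented here:

* a probit-refined correction that improves the plain-RC approximation for
  large effect sizes,
* a sensitivity analysis for systematic error W = psi + theta*X + eps with
  within-person error correlation rho, where the repeat regression slope
  lambda* relates to the RDR via lambda = (lambda* - rho) / (theta (1 - rho)),
* multivariate RC for several jointly mismeasured exposures,
* an exact correction for multiplicative lognormal (heteroscedastic) error
  when a natural-scale linear effect is wanted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit

from ._rng import stream
from .dataset import Dataset
from .uncertainty import delta_var_rc, wald_ci

__all__ = [
    "FitError", "NaiveFit", "RCModelFit", "CorrectionResult", "LognormalFit",
    "MultivariateRCResult", "HeteroscedasticityDiagnostic",
    "fit_naive_logistic", "fit_rc_model", "predict_expected_exposure",
    "rc_correct", "rc_correct_probit", "rc_sensitivity", "sensitivity_grid",
    "fit_rc_multivariate", "heteroscedasticity_diagnostic", "rc_lognormal",
    "logistic_probit_scale_constant", "fit_logistic",
]


class FitError(RuntimeError):
    """A model fit failed (non-convergence, separation, collinearity)."""


# ---------------------------------------------------------------------------
# logistic fitting


@dataclass
class NaiveFit:
    """Maximum-likelihood logistic fit of Y on exposure columns and Z."""

    beta_star: np.ndarray       # exposure coefficient(s)
    se_star: np.ndarray
    params: np.ndarray          # full coefficient vector (const, exposures, Z)
    cov: np.ndarray
    exposure_names: list[str]
    n: int
    converged: bool

    @property
    def beta_star_scalar(self) -> float:
        if self.beta_star.size != 1:
            raise ValueError("scalar access on a multivariate fit")
        return float(self.beta_star[0])

    @property
    def se_star_scalar(self) -> float:
        if self.se_star.size != 1:
            raise ValueError("scalar access on a multivariate fit")
        return float(self.se_star[0])


def fit_logistic(y: np.ndarray, design: np.ndarray, names: list[str]):
    """Newton-Raphson logistic regression with explicit failure modes."""
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise FitError("outcome must take both values 0 and 1")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FitError("design matrix is rank deficient (collinear columns)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(method="newton", maxiter=100,
                                          tol=1e-10, disp=0)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise FitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        raise FitError("logistic fit did not converge in 100 iterations")
    if not np.isfinite(res.params).all() or np.abs(res.params).max() > 1e4:
        raise FitError("logistic fit diverged (possible separation)")
    return res


def _design(columns: list[np.ndarray], n: int | None = None) -> np.ndarray:
    """Intercept-plus-columns design matrix; ``n`` needed if columns is empty."""
    if not columns:
        return np.ones((n, 1))
    return np.column_stack([np.ones(np.asarray(columns[0]).shape[0])] + columns)


def fit_naive_logistic(dataset: Dataset,
                       exposure_columns: tuple[str, ...] = ("w1",)) -> NaiveFit:
    """Fit the naive outcome model: logistic Y on exposures and all Z."""
    cols = [dataset.df[c].to_numpy(dtype=float) for c in exposure_columns]
    design = _design(cols + [dataset.z[:, j] for j in range(dataset.z.shape[1])])
    res = fit_logistic(dataset.y, design, list(exposure_columns))
    k = len(exposure_columns)
    return NaiveFit(
        beta_star=np.asarray(res.params[1:1 + k]),
        se_star=np.asarray(res.bse[1:1 + k]),
        params=np.asarray(res.params),
        cov=np.asarray(res.cov_params()),
        exposure_names=list(exposure_columns),
        n=dataset.n,
        converged=True,
    )


# ---------------------------------------------------------------------------
# the RC (repeat-regression) model


@dataclass
class RCModelFit:
    """OLS of W2 on W1 and Z over the repeat subset.

    ``lam`` is the W1 slope — the estimated regression dilution ratio under
    classical error, or lambda* under a systematic error model.
    ``var_w1_given_z`` is the residual variance of W1 given Z over all
    subjects, needed by the probit refinement.
    """

    mu: float
    lam: float
    delta: np.ndarray
    resid_var: float
    var_lam: float
    n_repeat: int
    var_w1_given_z: float

    @property
    def se_lam(self) -> float:
        return float(np.sqrt(self.var_lam))


def residual_variance_given_z(values: np.ndarray, z: np.ndarray) -> float:
    """Residual variance of `values` after OLS on Z (with intercept)."""
    design = _design([z[:, j] for j in range(z.shape[1])], n=values.shape[0])
    res = sm.OLS(values, design).fit()
    return float(res.mse_resid)


def fit_rc_model(dataset: Dataset) -> RCModelFit:
    """Estimate the calibration regression from the repeat subset."""
    k = dataset.z.shape[1]
    rep = dataset.repeat_subset()
    if rep.n < k + 3:
        raise FitError(f"only {rep.n} subjects with a repeat measurement; "
                       f"need at least {k + 3}")
    design = _design([rep.w1] + [rep.z[:, j] for j in range(k)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FitError("collinear design in the calibration regression")
    res = sm.OLS(rep.w2, design).fit()
    return RCModelFit(
        mu=float(res.params[0]),
        lam=float(res.params[1]),
        delta=np.asarray(res.params[2:]),
        resid_var=float(res.mse_resid),
        var_lam=float(res.bse[1] ** 2),
        n_repeat=rep.n,
        var_w1_given_z=residual_variance_given_z(dataset.w1, dataset.z),
    )


def predict_expected_exposure(rc: RCModelFit, dataset: Dataset) -> np.ndarray:
    """Calibrated predictions mu + lam*W1 + delta'Z for every subject."""
    return rc.mu + rc.lam * dataset.w1 + dataset.z @ rc.delta


# ---------------------------------------------------------------------------
# corrections


@dataclass
class CorrectionResult:
    """A corrected log odds ratio with two SE flavours.

    ``se_naive_lambda`` ignores the sampling error of the calibration
    parameters; ``se_full`` propagates it (delta method or bootstrap) and
    may be None when no propagation was requested.
    """

    beta: float
    se_naive_lambda: float
    se_full: float | None
    method: str
    params: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    @property
    def ci_naive_lambda(self) -> tuple[float, float]:
        return wald_ci(self.beta, self.se_naive_lambda)

    @property
    def ci_95(self) -> tuple[float, float]:
        se = self.se_full if self.se_full is not None else self.se_naive_lambda
        return wald_ci(self.beta, se)


def rc_correct(naive: NaiveFit, rc: RCModelFit) -> CorrectionResult:
    """Classical regression calibration: beta_hat = beta*_hat / lambda_hat."""
    beta_star, se_star = naive.beta_star_scalar, naive.se_star_scalar
    if rc.lam <= 0:
        raise FitError(f"estimated RDR lambda = {rc.lam:.4f} <= 0; the "
                       "direction of the correction is undefined")
    beta = beta_star / rc.lam
    se_a = se_star / rc.lam
    se_b = float(np.sqrt(delta_var_rc(beta_star, se_star**2, rc.lam, rc.var_lam)))
    return CorrectionResult(beta=beta, se_naive_lambda=se_a, se_full=se_b,
                            method="rc",
                            diagnostics={"lam": rc.lam, "var_lam": rc.var_lam})


@lru_cache(maxsize=1)
def logistic_probit_scale_constant() -> float:
    """Scale c minimizing sup_x |logistic_cdf(x) - normal_cdf(c x)|.

    Computed once by dense-grid sup-norm minimization; approximately 0.59
    (the reciprocal of the familiar 1.702).
    """
    x = np.linspace(0.0, 10.0, 4001)  # the objective is symmetric in x

    def sup_gap(c: float) -> float:
        return float(np.max(np.abs(expit(x) - stats.norm.cdf(c * x))))

    res = optimize.minimize_scalar(sup_gap, bounds=(0.4, 0.8), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x)


def _probit_beta(beta_star: float, lam: float, var_w1_z: float) -> float:
    ell = logistic_probit_scale_constant()
    sigma2_xw = lam * (1.0 - lam) * var_w1_z
    disc = lam**2 - ell**2 * beta_star**2 * sigma2_xw
    if disc <= 0:
        raise FitError("probit refinement undefined (negative discriminant)")
    return beta_star / np.sqrt(disc)


def rc_correct_probit(naive: NaiveFit, rc: RCModelFit) -> CorrectionResult:
    """Probit-refined RC for the logistic outcome model.

    The plain correction beta*/lambda ignores that the logistic model is
    fitted on W1, which carries residual exposure uncertainty
    var(X | W1, Z) = lambda (1 - lambda) var(W1 | Z). Inverting the
    probit-marginalized relation beta* = beta lambda / sqrt(1 + l^2 beta^2
    var(X|W1,Z)) gives

        beta_hat = beta* / sqrt(lambda^2 - l^2 beta*^2 var(X|W1,Z))

    with l the logistic-probit scale constant (~0.59). When var(X|W1,Z)
    is small this reduces to the plain RC estimate. If the term under the
    square root is not positive the function falls back to plain RC with a
    warning.
    """
    beta_star, se_star = naive.beta_star_scalar, naive.se_star_scalar
    if rc.lam <= 0:
        raise FitError("estimated RDR lambda <= 0")
    try:
        beta = _probit_beta(beta_star, rc.lam, rc.var_w1_given_z)
    except FitError:
        warnings.warn("probit refinement has negative discriminant; "
                      "falling back to plain regression calibration")
        out = rc_correct(naive, rc)
        out.method = "rc_probit_fallback"
        return out

    # numerical delta method in (beta*, lambda); var(W1|Z) error is ignored
    def f(b, lam):
        return _probit_beta(b, lam, rc.var_w1_given_z)

    hb = max(1e-6, 1e-6 * abs(beta_star))
    hl = max(1e-6, 1e-6 * rc.lam)
    g_b = (f(beta_star + hb, rc.lam) - f(beta_star - hb, rc.lam)) / (2 * hb)
    g_l = (f(beta_star, rc.lam + hl) - f(beta_star, rc.lam - hl)) / (2 * hl)
    se_a = float(abs(g_b) * se_star)
    se_b = float(np.sqrt(g_b**2 * se_star**2 + g_l**2 * rc.var_lam))
    return CorrectionResult(beta=float(beta), se_naive_lambda=se_a, se_full=se_b,
                            method="rc_probit",
                            diagnostics={"lam": rc.lam,
                                         "l": logistic_probit_scale_constant(),
                                         "var_w1_given_z": rc.var_w1_given_z})


def rc_sensitivity(naive: NaiveFit, rc: RCModelFit, theta: float,
                   rho: float) -> CorrectionResult:
    """RC under assumed systematic error parameters (theta, rho).

    Under W = psi + theta*X + eps with within-person error correlation rho,
    the repeat-regression slope lambda* estimates
    (theta^2 var(X|Z) + rho sigma_eps^2) / var(W1|Z), and the RDR is
    recovered as lambda = (lambda* - rho) / (theta (1 - rho)). The shift
    psi never enters. theta = 1, rho = 0 is exactly the classical
    correction.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if not (0.0 <= rho < 1.0):
        raise ValueError("rho must be in [0, 1)")
    lam_star = rc.lam
    if lam_star <= rho:
        raise FitError(f"lambda* = {lam_star:.4f} <= rho = {rho}; the "
                       "assumed error correlation explains the whole "
                       "repeat agreement and the correction is undefined")
    lam = (lam_star - rho) / (theta * (1.0 - rho))
    beta_star, se_star = naive.beta_star_scalar, naive.se_star_scalar
    beta = beta_star / lam
    se_a = se_star / lam
    # delta method with d(lam)/d(lam*) = 1 / (theta (1 - rho))
    var_full = (se_star**2 / lam**2
                + beta_star**2 * rc.var_lam / (lam**4 * theta**2 * (1 - rho)**2))
    return CorrectionResult(beta=beta, se_naive_lambda=se_a,
                            se_full=float(np.sqrt(var_full)),
                            method="rc_sensitivity",
                            params={"theta": theta, "rho": rho},
                            diagnostics={"lam_star": lam_star, "lam": lam})


def sensitivity_grid(naive: NaiveFit, rc: RCModelFit, thetas, rhos) -> pd.DataFrame:
    """Corrected estimates over the cartesian grid of (theta, rho) values."""
    rows = []
    for theta in thetas:
        for rho in rhos:
            r = rc_sensitivity(naive, rc, theta, rho)
            lo, hi = r.ci_95
            rows.append({"theta": theta, "rho": rho, "beta": r.beta,
                         "se_naive_lambda": r.se_naive_lambda,
                         "se_full": r.se_full, "ci_lo": lo, "ci_hi": hi})
    return pd.DataFrame(rows, columns=["theta", "rho", "beta",
                                       "se_naive_lambda", "se_full",
                                       "ci_lo", "ci_hi"])


# ---------------------------------------------------------------------------
# multivariate RC


@dataclass
class MultivariateRCResult:
    beta: np.ndarray                 # corrected log ORs, one per exposure
    beta_naive: np.ndarray
    se: np.ndarray | None            # bootstrap SEs (None if n_boot = 0)
    calibration_coefs: pd.DataFrame  # rows: const, W1 block, Z block
    exposures: list[str]
    n_repeat: int


def fit_rc_multivariate(df: pd.DataFrame, w1_cols: list[str], w2_cols: list[str],
                        z_cols: list[str] = (), y_col: str = "y",
                        n_boot: int = 200, seed: int = 0) -> MultivariateRCResult:
    """RC with several error-prone exposures.

    Each true exposure's conditional expectation given all first
    measurements and Z is estimated by OLS of its repeat on the full W1
    vector and Z over the subset with repeats for every exposure; the
    logistic outcome model is then refitted on the predictions. SEs come
    from a stratified nonparametric bootstrap of the whole procedure
    (set ``n_boot=0`` to skip).
    """
    if len(w1_cols) != len(w2_cols):
        raise ValueError("w1_cols and w2_cols must pair up")
    z_cols = list(z_cols)

    def estimate(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
        rep = frame.dropna(subset=list(w2_cols))
        k = len(w1_cols)
        if len(rep) < len(w1_cols) + len(z_cols) + 3:
            raise FitError("too few subjects with repeats for every exposure")
        design_rep = _design([rep[c].to_numpy(dtype=float)
                              for c in list(w1_cols) + z_cols])
        if np.linalg.matrix_rank(design_rep) < design_rep.shape[1]:
            raise FitError("collinear W1/Z block in multivariate calibration")
        coefs = {}
        design_all = _design([frame[c].to_numpy(dtype=float)
                              for c in list(w1_cols) + z_cols])
        preds = []
        for w1c, w2c in zip(w1_cols, w2_cols):
            res = sm.OLS(rep[w2c].to_numpy(dtype=float), design_rep).fit()
            coefs[w1c] = res.params
            preds.append(design_all @ res.params)
        design_out = _design(preds + [frame[c].to_numpy(dtype=float)
                                      for c in z_cols])
        logit = fit_logistic(frame[y_col].to_numpy(), design_out, list(w1_cols))
        beta = np.asarray(logit.params[1:1 + k])
        coef_df = pd.DataFrame(coefs, index=["const"] + list(w1_cols) + z_cols)
        return beta, np.asarray(preds), coef_df

    beta, _, coef_df = estimate(df)
    naive_design = _design([df[c].to_numpy(dtype=float)
                            for c in list(w1_cols) + z_cols])
    naive = fit_logistic(df[y_col].to_numpy(), naive_design, list(w1_cols))
    beta_naive = np.asarray(naive.params[1:1 + len(w1_cols)])

    se = None
    if n_boot:
        y = df[y_col].to_numpy()
        has_rep = df[list(w2_cols)].notna().all(axis=1).to_numpy()
        strata = [np.flatnonzero((y == lev) & (has_rep == r))
                  for lev in (0, 1) for r in (False, True)]
        strata = [s for s in strata if s.size]
        rng = stream(seed, "rc_multivariate_bootstrap")
        reps = []
        failures = 0
        for _ in range(n_boot):
            idx = np.concatenate([rng.choice(s, s.size, replace=True)
                                  for s in strata])
            try:
                reps.append(estimate(df.iloc[idx].reset_index(drop=True))[0])
            except FitError:
                failures += 1
                if failures > 0.1 * n_boot:
                    raise
        se = np.std(np.vstack(reps), axis=0, ddof=1)

    rep_count = int(df[list(w2_cols)].notna().all(axis=1).sum())
    return MultivariateRCResult(beta=beta, beta_naive=beta_naive, se=se,
                                calibration_coefs=coef_df,
                                exposures=list(w1_cols), n_repeat=rep_count)


# ---------------------------------------------------------------------------
# heteroscedasticity screen and lognormal correction


@dataclass
class HeteroscedasticityDiagnostic:
    """Per-subject (mean, sd) of the repeat pair plus an sd-on-mean trend.

    A positive, significant slope indicates error variance increasing with
    exposure level — multiplicative rather than additive error.
    """

    table: pd.DataFrame  # columns: id, mean, sd
    slope: float
    slope_se: float
    p_value: float


def heteroscedasticity_diagnostic(dataset: Dataset) -> HeteroscedasticityDiagnostic:
    rep = dataset.repeat_subset()
    if rep.n == 0:
        raise FitError("no repeat measurements available")
    pair = np.column_stack([rep.w1, rep.w2])
    means = pair.mean(axis=1)
    sds = pair.std(axis=1, ddof=1)
    res = sm.OLS(sds, sm.add_constant(means)).fit()
    table = pd.DataFrame({"id": rep.df["id"].to_numpy(), "mean": means, "sd": sds})
    return HeteroscedasticityDiagnostic(table=table, slope=float(res.params[1]),
                                        slope_se=float(res.bse[1]),
                                        p_value=float(res.pvalues[1]))


@dataclass
class LognormalFit:
    """Fitted lognormal measurement model on the log scale.

    ``lam_log`` is the log-scale RDR var(log X | Z) / var(log W | Z);
    ``sigma_u2`` the log-scale error variance. The implied log-X moments
    use the natural-scale unbiasedness E(W | X) = X, which shifts the log
    mean by sigma_u^2 / 2.
    """

    mu_w: float
    var_w: float
    sigma_u2: float
    lam_log: float
    mu_x_log: float
    var_x_log: float
    z_coefs: np.ndarray  # OLS of log W1 on (const, Z): conditional mean model

    def expected_x(self, w1: np.ndarray, z: np.ndarray) -> np.ndarray:
        """E(X | W1, Z) under the fitted joint lognormal model."""
        w1 = np.asarray(w1, dtype=float)
        if (w1 <= 0).any():
            raise ValueError("lognormal model requires W1 > 0")
        z = np.atleast_2d(np.asarray(z, dtype=float))
        logw1 = np.log(w1)
        e_logw1_z = _design([z[:, j] for j in range(z.shape[1])],
                            n=w1.shape[0]) @ self.z_coefs
        mu_x_cond = e_logw1_z + 0.5 * self.sigma_u2 \
            + self.lam_log * (logw1 - e_logw1_z)
        var_x_cond = self.var_x_log * (1.0 - self.lam_log)
        return np.exp(mu_x_cond + 0.5 * var_x_cond)


def fit_lognormal_model(dataset: Dataset) -> LognormalFit:
    """Estimate the log-scale error model from the repeat subset."""
    if (dataset.w1 <= 0).any():
        raise FitError("lognormal correction requires W1 > 0 for all subjects")
    rep = dataset.repeat_subset()
    if rep.n == 0:
        raise FitError("no repeat measurements available")
    if (rep.w2 <= 0).any():
        raise FitError("lognormal correction requires W2 > 0")

    k = dataset.z.shape[1]
    logw1 = np.log(dataset.w1)
    design_z = _design([dataset.z[:, j] for j in range(k)], n=dataset.n)
    z_fit = sm.OLS(logw1, design_z).fit()
    var_logw1_z = float(z_fit.mse_resid)

    rep_design = _design([np.log(rep.w1)] + [rep.z[:, j] for j in range(k)])
    rc_log = sm.OLS(np.log(rep.w2), rep_design).fit()
    lam_log = float(rc_log.params[1])
    if lam_log <= 0:
        raise FitError(f"log-scale RDR = {lam_log:.4f} <= 0")
    if lam_log > 1:
        raise FitError(f"log-scale RDR = {lam_log:.4f} > 1 implies negative "
                       "error variance — repeats more variable between than "
                       "within subjects contradicts the model")
    sigma_u2 = (1.0 - lam_log) * var_logw1_z
    var_x_log = var_logw1_z - sigma_u2
    mu_w = float(np.mean(logw1))
    return LognormalFit(mu_w=mu_w, var_w=var_logw1_z, sigma_u2=sigma_u2,
                        lam_log=lam_log, mu_x_log=mu_w + 0.5 * sigma_u2,
                        var_x_log=var_x_log, z_coefs=np.asarray(z_fit.params))


def rc_lognormal(dataset: Dataset, n_boot: int = 0,
                 seed: int = 0) -> tuple[CorrectionResult, LognormalFit]:
    """RC for multiplicative lognormal error, natural-scale linear effect.

    W_ij = X v_ij with log v normal and E(W | X) = X. Assuming log W1 and
    log X jointly normal given Z, E(X | W1, Z) has a closed lognormal form;
    the logistic outcome model refitted on these expectations estimates the
    log OR per unit of natural-scale exposure. Propagated SEs require the
    whole-pipeline bootstrap (``n_boot`` resamples; 0 skips it).
    """
    fit = fit_lognormal_model(dataset)
    ex = fit.expected_x(dataset.w1, dataset.z)
    k = dataset.z.shape[1]
    design = _design([ex] + [dataset.z[:, j] for j in range(k)])
    logit = fit_logistic(dataset.y, design, ["expected_x"])
    beta = float(logit.params[1])
    se_a = float(logit.bse[1])

    se_b = None
    if n_boot:
        from .uncertainty import BootstrapSpec, bootstrap_correct

        def estimator(ds: Dataset, _seed: int) -> float:
            f = fit_lognormal_model(ds)
            e = f.expected_x(ds.w1, ds.z)
            d = _design([e] + [ds.z[:, j] for j in range(ds.z.shape[1])])
            return float(fit_logistic(ds.y, d, ["expected_x"]).params[1])

        boot = bootstrap_correct(dataset, estimator,
                                 BootstrapSpec(n_boot=n_boot, seed=seed))
        se_b = boot.se
    result = CorrectionResult(beta=beta, se_naive_lambda=se_a, se_full=se_b,
                              method="rc_lognormal",
                              diagnostics={"lam_log": fit.lam_log,
                                           "sigma_u2": fit.sigma_u2})
    return result, fit
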