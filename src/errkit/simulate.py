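"""Synthetic cohort and case-control data with known true exposure.

Data are generated from a logistic exposure-outcome model

    logit P(Y=1 | X, Z) = beta0 + beta * X + gamma' Z

with the true exposure X normal (or lognormal) given Z, and error-prone
measurements W_ij produced under one of four error models:

* ``classical``            W_ij = X + eps_ij, independent mean-zero errors
* ``systematic``           W_ij = psi + theta * X + eps_ij with within-person
                           error correlation rho
* ``differential``         as systematic but with (psi, theta, rho, sigma_eps)
                           depending on the realized outcome Y
* ``heteroscedastic_lognormal``  W_ij = X * v_ij multiplicative, with
                           log v_ij ~ N(-sigma_u^2/2, sigma_u^2) so that
                           E(W | X) = X on the natural scale

Correlated repeat errors are realized through a shared person effect:
eps_ij = b_i + e_ij with var(b_i) = rho * sigma_eps^2 and
var(e_ij) = (1 - rho) * sigma_eps^2, which requires rho >= 0.

Because every estimator in the package targets the generating ``beta``,
any of them can be validated by parameter recovery on these datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._rng import stream
from .dataset import Dataset

__all__ = [
    "TrueExposureSpec",
    "ErrorSpec",
    "OutcomeSpec",
    "StudySpec",
    "generate_true_exposure",
    "apply_error_model",
    "generate_outcome",
    "generate_study",
    "SCENARIOS",
    "make_scenario",
]

ERROR_KINDS = ("classical", "systematic", "heteroscedastic_lognormal", "differential")


@dataclass(frozen=True)
class TrueExposureSpec:
    """Distribution of the true exposure X given covariates Z.

    On the ``lognormal`` scale the parameters describe log X, and the
    generated X = exp(normal draw) is strictly positive.
    """

    mu_x: float = 0.0
    sigma_x: float = 1.0
    z_coefs: tuple[float, ...] = ()
    scale: str = "natural"  # {"natural", "lognormal"}

    def __post_init__(self) -> None:
        if not np.isfinite([self.mu_x, self.sigma_x, *self.z_coefs]).all():
            raise ValueError("non-finite exposure spec values")
        if self.sigma_x < 0:
            raise ValueError("sigma_x must be >= 0")
        if self.scale not in ("natural", "lognormal"):
            raise ValueError(f"unknown exposure scale {self.scale!r}")


@dataclass(frozen=True)
class ErrorSpec:
    """Parameters of the measurement error model, per outcome level.

    ``psi_by_y``, ``theta_by_y``, ``rho_by_y`` and ``sigma_eps_by_y`` are
    (value for Y=0, value for Y=1) pairs; non-differential kinds must have
    equal entries. ``sigma_u`` is the log-scale error SD of the
    multiplicative (heteroscedastic) model and is ignored otherwise.
    """

    kind: str = "classical"
    psi_by_y: tuple[float, float] = (0.0, 0.0)
    theta_by_y: tuple[float, float] = (1.0, 1.0)
    rho_by_y: tuple[float, float] = (0.0, 0.0)
    sigma_eps_by_y: tuple[float, float] = (1.0, 1.0)
    sigma_u: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ERROR_KINDS:
            raise ValueError(f"unknown error kind {self.kind!r}")
        for rho in self.rho_by_y:
            if not (0.0 <= rho < 1.0):
                raise ValueError("rho must be in [0, 1); the shared-person-effect "
                                 "construction does not support negative rho")
        if any(s < 0 for s in self.sigma_eps_by_y) or self.sigma_u < 0:
            raise ValueError("error SDs must be >= 0")
        if self.kind != "differential":
            for name in ("psi_by_y", "theta_by_y", "rho_by_y", "sigma_eps_by_y"):
                pair = getattr(self, name)
                if pair[0] != pair[1]:
                    raise ValueError(f"non-differential kind requires equal {name}")
        if self.kind == "classical":
            if self.psi_by_y != (0.0, 0.0) or self.theta_by_y != (1.0, 1.0) \
                    or self.rho_by_y != (0.0, 0.0):
                raise ValueError("classical error forces psi=0, theta=1, rho=0")

    @classmethod
    def classical(cls, sigma_eps: float) -> "ErrorSpec":
        return cls(kind="classical", sigma_eps_by_y=(sigma_eps, sigma_eps))

    @classmethod
    def systematic(cls, psi: float, theta: float, rho: float,
                   sigma_eps: float) -> "ErrorSpec":
        return cls(kind="systematic", psi_by_y=(psi, psi), theta_by_y=(theta, theta),
                   rho_by_y=(rho, rho), sigma_eps_by_y=(sigma_eps, sigma_eps))

    @classmethod
    def differential(cls, psi_by_y=(0.0, 0.0), theta_by_y=(1.0, 1.0),
                     rho_by_y=(0.0, 0.0), sigma_eps_by_y=(1.0, 1.0)) -> "ErrorSpec":
        return cls(kind="differential", psi_by_y=tuple(psi_by_y),
                   theta_by_y=tuple(theta_by_y), rho_by_y=tuple(rho_by_y),
                   sigma_eps_by_y=tuple(sigma_eps_by_y))

    @classmethod
    def heteroscedastic_lognormal(cls, sigma_u: float) -> "ErrorSpec":
        return cls(kind="heteroscedastic_lognormal", sigma_eps_by_y=(0.0, 0.0),
                   sigma_u=sigma_u)


@dataclass(frozen=True)
class OutcomeSpec:
    """Logistic outcome model: logit P(Y=1) = beta0 + beta*X + gamma'Z."""

    beta0: float = -1.0
    beta: float = 0.3
    gamma: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite([self.beta0, self.beta, *self.gamma]).all():
            raise ValueError("non-finite outcome spec values")


@dataclass(frozen=True)
class StudySpec:
    """Sampling design: cohort of size n, or nested case-control.

    ``repeat_fraction`` of subjects (sampled within each outcome stratum)
    carry the repeat measurement W2. ``z_kinds`` gives the marginal
    distribution of each covariate column ("normal" = standard normal,
    "bernoulli" = Bernoulli(0.5)).
    """

    n: int = 5000
    repeat_fraction: float = 0.5
    design: str = "cohort"  # {"cohort", "case_control"}
    n_cases: int | None = None
    n_controls: int | None = None
    seed: int = 0
    z_kinds: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not (0.0 < self.repeat_fraction <= 1.0):
            raise ValueError("repeat_fraction must be in (0, 1]")
        if self.design not in ("cohort", "case_control"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "case_control":
            if not self.n_cases or not self.n_controls:
                raise ValueError("case_control design needs n_cases and n_controls")
        for k in self.z_kinds:
            if k not in ("normal", "bernoulli"):
                raise ValueError(f"unknown covariate kind {k!r}")


# ---------------------------------------------------------------------------


def generate_true_exposure(spec: TrueExposureSpec, z: np.ndarray,
                           seed: int) -> np.ndarray:
    """Draw the true exposure X given the covariate matrix ``z``."""
    z = np.atleast_2d(np.asarray(z, dtype=float))
    n = z.shape[0]
    coefs = np.asarray(spec.z_coefs, dtype=float)
    if coefs.size and z.shape[1] != coefs.size:
        raise ValueError("z has wrong number of columns for z_coefs")
    mean = spec.mu_x + (z @ coefs if coefs.size else 0.0)
    rng = stream(seed, "true_exposure")
    latent = mean + spec.sigma_x * rng.standard_normal(n)
    return np.exp(latent) if spec.scale == "lognormal" else latent


def generate_outcome(x: np.ndarray, z: np.ndarray, spec: OutcomeSpec,
                     seed: int) -> np.ndarray:
    """Bernoulli outcome draws from the logistic model."""
    x = np.asarray(x, dtype=float)
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if not np.isfinite(x).all():
        raise ValueError("non-finite exposure values")
    gamma = np.asarray(spec.gamma, dtype=float)
    eta = spec.beta0 + spec.beta * x + (z @ gamma if gamma.size else 0.0)
    rng = stream(seed, "outcome")
    return (rng.random(x.size) < expit(eta)).astype(int)


def apply_error_model(x: np.ndarray, y: np.ndarray, spec: ErrorSpec,
                      seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Generate the pair of error-prone measurements (W1, W2).

    Both repeats are produced for every subject; the study-level generator
    masks W2 afterwards. For differential error the parameters are indexed
    by the realized outcome.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ValueError("X and Y must have the same length")
    n = x.size
    rng = stream(seed, "errors")

    if spec.kind == "heteroscedastic_lognormal":
        if (x <= 0).any():
            raise ValueError("multiplicative lognormal error requires X > 0")
        su = spec.sigma_u
        # log v ~ N(-su^2/2, su^2) => E(v) = 1, W unbiased for X on natural scale
        logv = -0.5 * su**2 + su * rng.standard_normal((n, 2))
        w = x[:, None] * np.exp(logv)
        return w[:, 0], w[:, 1]

    psi = np.asarray(spec.psi_by_y)[y]
    theta = np.asarray(spec.theta_by_y)[y]
    rho = np.asarray(spec.rho_by_y)[y]
    sig = np.asarray(spec.sigma_eps_by_y)[y]
    # shared person effect + independent parts gives corr(eps_1, eps_2) = rho
    b = np.sqrt(rho) * sig * rng.standard_normal(n)
    e = np.sqrt(1.0 - rho)[:, None] * sig[:, None] * rng.standard_normal((n, 2))
    base = psi + theta * x
    return base + b + e[:, 0], base + b + e[:, 1]


def _generate_z(n: int, kinds: tuple[str, ...], seed: int) -> np.ndarray:
    rng = stream(seed, "covariates")
    cols = []
    for k in kinds:
        if k == "bernoulli":
            cols.append(rng.integers(0, 2, n).astype(float))
        else:
            cols.append(rng.standard_normal(n))
    return np.column_stack(cols) if cols else np.empty((n, 0))


def _assemble(x, y, w1, w2, z, repeat_fraction, seed) -> pd.DataFrame:
    n = x.size
    has_w2 = np.zeros(n, dtype=bool)
    rng = stream(seed, "repeat_selection")
    for level in (0, 1):
        idx = np.flatnonzero(y == level)
        n_rep = int(round(repeat_fraction * idx.size))
        if idx.size:
            chosen = rng.choice(idx, size=n_rep, replace=False)
            has_w2[chosen] = True
    w2 = np.where(has_w2, w2, np.nan)
    data = {"id": np.arange(n), "y": y, "w1": w1, "w2": w2}
    for j in range(z.shape[1]):
        data[f"z{j + 1}"] = z[:, j]
    data["x"] = x
    return pd.DataFrame(data)


def generate_study(true_spec: TrueExposureSpec, error_spec: ErrorSpec,
                   outcome_spec: OutcomeSpec, study_spec: StudySpec) -> Dataset:
    """Generate a full study dataset under the four specs.

    Errors are drawn after the outcome so that differential error models
    condition on the realized Y. In the case-control design a super-cohort
    of size max(n, 20*(n_cases + n_controls)) is generated and the
    requested numbers of cases and controls are sampled without
    replacement.
    """
    seed = study_spec.seed
    if study_spec.design == "cohort":
        n = study_spec.n
    else:
        n = max(study_spec.n, 20 * (study_spec.n_cases + study_spec.n_controls))
    n_gamma = len(outcome_spec.gamma)
    kinds = study_spec.z_kinds or ("normal",) * max(n_gamma, len(true_spec.z_coefs))
    z = _generate_z(n, kinds, seed)
    x = generate_true_exposure(true_spec, z, seed)
    y = generate_outcome(x, z, outcome_spec, seed)
    w1, w2 = apply_error_model(x, y, error_spec, seed)

    if study_spec.design == "case_control":
        rng = stream(seed, "case_control_sampling")
        cases = np.flatnonzero(y == 1)
        controls = np.flatnonzero(y == 0)
        if cases.size < study_spec.n_cases:
            raise ValueError(
                f"super-cohort produced {cases.size} cases; "
                f"{study_spec.n_cases} requested")
        if controls.size < study_spec.n_controls:
            raise ValueError(
                f"super-cohort produced {controls.size} controls; "
                f"{study_spec.n_controls} requested")
        keep = np.concatenate([
            rng.choice(cases, size=study_spec.n_cases, replace=False),
            rng.choice(controls, size=study_spec.n_controls, replace=False),
        ])
        keep.sort()
        x, y, w1, w2, z = x[keep], y[keep], w1[keep], w2[keep], z[keep]

    df = _assemble(x, y, w1, w2, z, study_spec.repeat_fraction, seed)
    df["id"] = np.arange(len(df))
    return Dataset(df)


# -- canonical test scenarios ----------------------------------------------
#
# These fixed parameter sets are the study conditions used throughout the
# test suite: a classical-error cohort with regression dilution ratio 0.5,
# a differential mean-shift variant of it, a systematic-error variant, and
# a lognormal exposure with multiplicative error.

def make_scenario(name: str, seed: int, n: int | None = None) -> Dataset:
    """Generate one of the canonical named scenarios under ``seed``."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    true_spec, error_spec, outcome_spec, study = SCENARIOS[name]
    study = StudySpec(n=n or study.n, repeat_fraction=study.repeat_fraction,
                      design=study.design, n_cases=study.n_cases,
                      n_controls=study.n_controls, seed=seed,
                      z_kinds=study.z_kinds)
    return generate_study(true_spec, error_spec, outcome_spec, study)


SCENARIOS: dict[str, tuple] = {
    # sigma_X = sigma_eps = 1 => RDR lambda = 0.5
    "classical_recovery": (
        TrueExposureSpec(mu_x=0.0, sigma_x=1.0),
        ErrorSpec.classical(sigma_eps=1.0),
        OutcomeSpec(beta0=-1.0, beta=0.3),
        StudySpec(n=5000, repeat_fraction=0.5),
    ),
    # cases report with a mean shift of 0.5 * sigma_X
    "differential_shift": (
        TrueExposureSpec(mu_x=0.0, sigma_x=1.0),
        ErrorSpec.differential(psi_by_y=(0.0, 0.5)),
        OutcomeSpec(beta0=-1.0, beta=0.3),
        StudySpec(n=5000, repeat_fraction=0.5),
    ),
    # proportional systematic error with person-specific (correlated) errors
    "systematic_person_effect": (
        TrueExposureSpec(mu_x=0.0, sigma_x=1.0),
        ErrorSpec.systematic(psi=0.5, theta=0.8, rho=0.3, sigma_eps=1.0),
        OutcomeSpec(beta0=-1.0, beta=0.3),
        StudySpec(n=5000, repeat_fraction=0.5),
    ),
    # positive exposure, multiplicative error, natural-scale linear effect
    "lognormal_heteroscedastic": (
        TrueExposureSpec(mu_x=0.0, sigma_x=0.5, scale="lognormal"),
        ErrorSpec.heteroscedastic_lognormal(sigma_u=0.4),
        OutcomeSpec(beta0=-1.3, beta=0.2),
        StudySpec(n=5000, repeat_fraction=0.5),
    ),
    # nested case-control sample under classical error
    "case_control_classical": (
        TrueExposureSpec(mu_x=0.0, sigma_x=1.0),
        ErrorSpec.classical(sigma_eps=1.0),
        OutcomeSpec(beta0=-2.5, beta=0.3),
        StudySpec(n=1, repeat_fraction=0.26, design="case_control",
                  n_cases=305, n_controls=1222),
    ),
}
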