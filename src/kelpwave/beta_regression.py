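"""Beta regression in the mean–precision parameterization, with a Cauchy mean link.

The response y ∈ (0,1) is modelled as Beta(μφ, (1−μ)φ), so E[y] = μ and
Var[y] = μ(1−μ)/(1+φ). The mean submodel is g(μ) = β0 + β1·x with link g
(Cauchy by default — the quantile function of the standard Cauchy distribution,
g(μ) = tan(π(μ−½)) — heavier-tailed than logit, so fitted means approach 0/1
more slowly). The precision φ is either constant or log-linear in the
covariate; the latter is compared to the former by a likelihood-ratio test to
detect variance-function misspecification.

Fitting is maximum likelihood with the analytic score and a quasi-Newton
optimizer; standard errors come from the observed information (numerical
Hessian of the analytic score). Explanatory power is reported as pseudo-R²,
the squared Pearson correlation between the fitted linear predictor and the
link-transformed response. Models fitted to the same data are compared by AIC,
with fits within 1 AIC of the minimum reported as co-best.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "cauchy_link",
    "inverse_cauchy_link",
    "LINKS",
    "BetaRegSpec",
    "BetaRegFit",
    "loglik",
    "fit_betareg",
    "pseudo_r2",
    "lr_test_precision",
    "compare_models",
]

_MU_EPS = 1e-12


def cauchy_link(mu):
    """η = tan(π(μ − ½)); the standard-Cauchy quantile function."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0.0) or np.any(mu >= 1.0):
        raise ValueError("mu must lie strictly inside (0, 1)")
    return np.tan(np.pi * (mu - 0.5))


def inverse_cauchy_link(eta):
    """μ = arctan(η)/π + ½; the standard-Cauchy CDF."""
    return np.arctan(np.asarray(eta, dtype=float)) / np.pi + 0.5


def _logit(mu):
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0.0) or np.any(mu >= 1.0):
        raise ValueError("mu must lie strictly inside (0, 1)")
    return np.log(mu / (1.0 - mu))


def _probit(mu):
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0.0) or np.any(mu >= 1.0):
        raise ValueError("mu must lie strictly inside (0, 1)")
    return stats.norm.ppf(mu)


# link name -> (g, g^{-1}, dmu/deta)
LINKS = {
    "cauchy": (
        cauchy_link,
        inverse_cauchy_link,
        lambda eta: 1.0 / (np.pi * (1.0 + np.asarray(eta, float) ** 2)),
    ),
    "logit": (
        _logit,
        lambda eta: special.expit(eta),
        lambda eta: special.expit(eta) * (1.0 - special.expit(eta)),
    ),
    "probit": (
        _probit,
        lambda eta: stats.norm.cdf(eta),
        lambda eta: stats.norm.pdf(eta),
    ),
}


@dataclass(frozen=True)
class BetaRegSpec:
    """Model specification: mean link and precision structure."""

    mean_link: Literal["cauchy", "logit", "probit"] = "cauchy"
    precision_model: Literal["constant", "varying"] = "constant"

    def __post_init__(self) -> None:
        if self.mean_link not in LINKS:
            raise ValueError(f"unknown mean link {self.mean_link!r}")
        if self.precision_model not in ("constant", "varying"):
            raise ValueError(f"unknown precision model {self.precision_model!r}")

    @property
    def n_params(self) -> int:
        return 3 if self.precision_model == "constant" else 4


@dataclass
class BetaRegFit:
    """One fitted beta regression: estimates, uncertainty, and fit measures."""

    spec: BetaRegSpec
    beta: np.ndarray  # mean submodel (intercept, slope)
    gamma: np.ndarray  # precision submodel on the log scale
    loglik: float
    aic: float
    pseudo_r2: float
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    converged: bool
    n: int
    grad_norm: float = math.nan
    x: np.ndarray = field(default=None, repr=False)
    y: np.ndarray = field(default=None, repr=False)

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.beta, self.gamma])

    @property
    def phi(self) -> np.ndarray:
        """Fitted precision per observation."""
        Z = _precision_design(self.x, self.spec)
        return np.exp(Z @ self.gamma)

    def to_dict(self) -> dict:
        names = ["beta0", "beta1"] + (
            ["log_phi"] if self.spec.precision_model == "constant" else ["gamma0", "gamma1"]
        )
        return {
            "mean_link": self.spec.mean_link,
            "precision_model": self.spec.precision_model,
            "coefficients": {
                name: {
                    "estimate": float(est),
                    "se": float(se),
                    "z": float(z),
                    "p": float(p),
                }
                for name, est, se, z, p in zip(names, self.params, self.se, self.z, self.p)
            },
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "pseudo_r2": float(self.pseudo_r2),
            "n": int(self.n),
            "converged": bool(self.converged),
        }


def _mean_design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x])


def _precision_design(x: np.ndarray, spec: BetaRegSpec) -> np.ndarray:
    if spec.precision_model == "constant":
        return np.ones((len(x), 1))
    return np.column_stack([np.ones_like(x), x])


def _unpack(params: np.ndarray, spec: BetaRegSpec) -> tuple[np.ndarray, np.ndarray]:
    return params[:2], params[2:]


def loglik(
    params: np.ndarray, y: np.ndarray, x: np.ndarray, spec: BetaRegSpec
) -> float:
    """Beta log-likelihood Σ log f(y; μφ, (1−μ)φ) at the given parameters.

    μ comes from the mean link applied to β0 + β1·x and φ from the (log-linear)
    precision model. Returns −inf for parameter values yielding a non-finite
    density, which optimizers treat as infeasible.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ValueError("responses must lie strictly inside (0, 1)")
    beta, gamma = _unpack(np.asarray(params, float), spec)
    _, ginv, _ = LINKS[spec.mean_link]
    eta = _mean_design(x) @ beta
    mu = np.clip(ginv(eta), _MU_EPS, 1.0 - _MU_EPS)
    phi = np.exp(_precision_design(x, spec) @ gamma)
    if not np.all(np.isfinite(phi)) or np.any(phi <= 0):
        return -np.inf
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = np.sum(
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )
    return float(ll) if np.isfinite(ll) else -np.inf


def _score(
    params: np.ndarray, y: np.ndarray, x: np.ndarray, spec: BetaRegSpec
) -> np.ndarray:
    """Analytic gradient of the log-likelihood."""
    beta, gamma = _unpack(np.asarray(params, float), spec)
    X = _mean_design(x)
    Z = _precision_design(x, spec)
    _, ginv, dmu_deta = LINKS[spec.mean_link]
    eta = X @ beta
    mu = np.clip(ginv(eta), _MU_EPS, 1.0 - _MU_EPS)
    phi = np.exp(Z @ gamma)
    ystar = np.log(y) - np.log1p(-y)
    mustar = special.digamma(mu * phi) - special.digamma((1.0 - mu) * phi)
    d_beta = X.T @ (phi * (ystar - mustar) * dmu_deta(eta))
    d_gamma = Z.T @ (
        phi
        * (
            mu * (ystar - mustar)
            + np.log1p(-y)
            - special.digamma((1.0 - mu) * phi)
            + special.digamma(phi)
        )
    )
    return np.concatenate([d_beta, d_gamma])


def _start_values(y: np.ndarray, x: np.ndarray, spec: BetaRegSpec) -> np.ndarray:
    """OLS of g(y) on x for β; method-of-moments φ from the residual variance."""
    g, ginv, dmu_deta = LINKS[spec.mean_link]
    gy = g(y)
    X = _mean_design(x)
    beta0, *_ = np.linalg.lstsq(X, gy, rcond=None)
    eta_hat = X @ beta0
    resid = gy - eta_hat
    sigma2_eta = max(float(np.mean(resid**2)), 1e-8)
    mu_hat = np.clip(ginv(eta_hat), 1e-6, 1.0 - 1e-6)
    # delta method: Var(y) ≈ Var(g(y)) * (dμ/dη)²; match to μ(1−μ)/(1+φ)
    var_y = sigma2_eta * dmu_deta(eta_hat) ** 2
    phi_i = mu_hat * (1.0 - mu_hat) / np.maximum(var_y, 1e-10) - 1.0
    phi0 = float(np.clip(np.median(phi_i), 0.5, 1e4))
    if spec.precision_model == "constant":
        gamma0 = np.array([np.log(phi0)])
    else:
        gamma0 = np.array([np.log(phi0), 0.0])
    return np.concatenate([beta0, gamma0])


def _numerical_hessian(params, y, x, spec, rel_step=1e-5) -> np.ndarray:
    """Central finite differences of the analytic score."""
    k = len(params)
    H = np.zeros((k, k))
    for j in range(k):
        h = rel_step * max(1.0, abs(params[j]))
        up = params.copy()
        dn = params.copy()
        up[j] += h
        dn[j] -= h
        H[:, j] = (_score(up, y, x, spec) - _score(dn, y, x, spec)) / (2 * h)
    return (H + H.T) / 2.0


def fit_betareg(
    y: Sequence[float],
    x: Sequence[float],
    spec: BetaRegSpec | None = None,
    max_iter: int = 500,
) -> BetaRegFit:
    """Maximum-likelihood beta regression of y on a single covariate.

    Starting values come from least squares on the link-transformed response;
    the optimizer is BFGS on the analytic score. Standard errors are from the
    observed information; p-values are two-sided Wald z against the standard
    normal. Non-convergence is flagged rather than raised, and flagged fits are
    refused by the model-comparison helpers.
    """
    spec = spec or BetaRegSpec()
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D arrays of equal length")
    if np.any(y <= 0.0) or np.any(y >= 1.0):
        raise ValueError("responses must lie strictly inside (0, 1)")
    if len(y) < spec.n_params + 1:
        raise ValueError(
            f"need at least {spec.n_params + 1} observations for {spec.n_params} parameters"
        )

    theta0 = _start_values(y, x, spec)

    def neg_ll(p):
        ll = loglik(p, y, x, spec)
        return -ll if np.isfinite(ll) else 1e12

    def neg_score(p):
        s = _score(p, y, x, spec)
        return -np.where(np.isfinite(s), s, 0.0)

    res = optimize.minimize(
        neg_ll,
        theta0,
        jac=neg_score,
        method="BFGS",
        options={"maxiter": max_iter, "gtol": 1e-8},
    )
    # polish with Nelder–Mead if the quasi-Newton step stalled away from a root
    grad = _score(res.x, y, x, spec)
    if not np.all(np.isfinite(grad)) or np.max(np.abs(grad)) > 1e-4:
        res2 = optimize.minimize(
            neg_ll, res.x, method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12}
        )
        if res2.fun <= res.fun:
            res = res2
            grad = _score(res.x, y, x, spec)

    theta = res.x
    ll = loglik(theta, y, x, spec)
    grad_norm = float(np.max(np.abs(grad)))
    converged = bool(np.isfinite(ll)) and grad_norm < 1e-3

    H = _numerical_hessian(theta, y, x, spec)
    info = -H  # observed information
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        # singular information (e.g. a constant covariate): pseudo-inverse
        # leaves the identifiable directions usable
        cov = np.linalg.pinv(info)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(cov))
        z = theta / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    beta, gamma = _unpack(theta, spec)
    fit = BetaRegFit(
        spec=spec,
        beta=beta,
        gamma=gamma,
        loglik=ll,
        aic=-2.0 * ll + 2.0 * spec.n_params,
        pseudo_r2=math.nan,
        se=se,
        z=z,
        p=p,
        converged=converged,
        n=len(y),
        grad_norm=grad_norm,
        x=x,
        y=y,
    )
    fit.pseudo_r2 = pseudo_r2(fit)
    return fit


def pseudo_r2(fit: BetaRegFit) -> float:
    """Squared Pearson correlation between η̂ and the link-transformed response.

    Defined as 0 when the linear predictor has zero variance (intercept-only
    fits).
    """
    g, _, _ = LINKS[fit.spec.mean_link]
    eta_hat = _mean_design(fit.x) @ fit.beta
    gy = g(fit.y)
    if np.std(eta_hat) == 0.0 or np.std(gy) == 0.0:
        return 0.0
    r = np.corrcoef(eta_hat, gy)[0, 1]
    return float(r**2)


def lr_test_precision(
    fit_constant: BetaRegFit, fit_varying: BetaRegFit
) -> tuple[float, int, float]:
    """Likelihood-ratio test of covariate-dependent precision.

    Compares the constant-φ model (reduced) to the log-linear-φ model (full)
    fitted to the same data. Returns ``(statistic, df, p)`` with the statistic
    clamped at 0 and p from the χ² distribution.
    """
    if fit_constant.n != fit_varying.n:
        raise ValueError("fits must use the same observations")
    if not (np.array_equal(fit_constant.y, fit_varying.y)):
        raise ValueError("fits must share the same response vector")
    if fit_constant.spec.mean_link != fit_varying.spec.mean_link:
        raise ValueError("fits must share the mean link to be nested")
    df = fit_varying.spec.n_params - fit_constant.spec.n_params
    if df <= 0:
        raise ValueError("the varying-precision model must nest the constant one")
    if not (fit_constant.converged and fit_varying.converged):
        raise ValueError("refusing LR test on non-converged fits")
    statistic = max(0.0, 2.0 * (fit_varying.loglik - fit_constant.loglik))
    p = float(stats.chi2.sf(statistic, df)) if statistic > 0 else 1.0
    return statistic, df, p


def compare_models(fits: dict[str, BetaRegFit]) -> dict:
    """Rank fits of the same response by AIC; fits within 1 of the best tie.

    Returns ``{"ranking": [(name, aic), ...], "best": [names within 1 ΔAIC]}``.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ns = {f.n for f in fits.values()}
    if len(ns) > 1:
        raise ValueError("fits were made on different sample sizes")
    for name, f in fits.items():
        if not f.converged:
            raise ValueError(f"refusing comparison with non-converged fit {name!r}")
    ranking = sorted(((name, f.aic) for name, f in fits.items()), key=lambda t: t[1])
    best_aic = ranking[0][1]
    co_best = [name for name, aic in ranking if aic - best_aic < 1.0]
    return {"ranking": ranking, "best": co_best}
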