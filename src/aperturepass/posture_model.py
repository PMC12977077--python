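"""Posture model: a logistic-mean mixed-effects model on scaled rotations.

The scaled rotation y in (0, 1) of participant i on trial j is modeled as

    y_ij | u_i  ~  TruncatedNormal( mu_ij, sigma_eps^2; 0, 1 )
    mu_ij       =  logistic( x_ij' beta + u_i )
    u_i         ~  N(0, sigma_u^2)

i.e. a continuous-response analogue of a logit-link GLMM: the logistic mean
captures the bend between the straight posture at wide apertures and the
saturating rotation at narrow ones, the participant random intercept u_i
captures stable individual offsets on the linear-predictor scale, and the
observation noise acts on the response scale, truncated to the unit
interval so the likelihood is proper on a bounded response.

The marginal likelihood integrates u_i by adaptive Gauss-Hermite quadrature
(Laplace-centered, 9 nodes by default).  Standard errors come from the
inverse observed information; Wald z and two-sided normal p-values mirror
the usual GLMM output, and effect sizes are odds ratios exp(beta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logit, ndtr

from .errors import ConvergenceError, DesignError

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)

#: analysis factor name -> coded column in the prepared table
FACTOR_COLUMNS = {
    "environment": "coded_environment",
    "condition": "coded_condition",
    "order": "coded_order",
    "fatigue": "coded_fatigue",
    "body_visible": "coded_bodyvisible",
}


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of one posture model."""

    analysis_id: str
    factors: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    ratio_col: str = "ax_centered"
    response_col: str = "scaled_rotation"

    def __post_init__(self):
        for a, b in self.interactions:
            if a not in self.factors or b not in self.factors:
                raise DesignError(f"interaction {a}:{b} references undeclared factor")

    @property
    def term_names(self) -> tuple[str, ...]:
        return (
            ("intercept", "ax_ratio")
            + self.factors
            + tuple(f"{a}:{b}" for a, b in self.interactions)
        )


def posture_spec(analysis_id: str) -> ModelSpec:
    """The published fixed-effect structures.

    ``combined``: environment, condition, order, fatigue with the
    environment:order and condition:order interactions.  ``feedback``:
    body_visible, condition, order, fatigue with body_visible:order and
    condition:order.  ``exp1``: a single-environment reduction (condition,
    order, fatigue, condition:order).
    """
    if analysis_id == "combined":
        return ModelSpec(
            "combined",
            ("environment", "condition", "order", "fatigue"),
            (("environment", "order"), ("condition", "order")),
        )
    if analysis_id == "feedback":
        return ModelSpec(
            "feedback",
            ("body_visible", "condition", "order", "fatigue"),
            (("body_visible", "order"), ("condition", "order")),
        )
    if analysis_id == "exp1":
        return ModelSpec(
            "exp1",
            ("condition", "order", "fatigue"),
            (("condition", "order"),),
        )
    raise DesignError(f"unknown analysis {analysis_id!r}")


@dataclass
class FitResult:
    """Estimates and inference for one fitted posture model."""

    spec: ModelSpec
    names: tuple[str, ...]
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    wald_z: dict[str, float]
    p_values: dict[str, float]
    sigma_u: float
    sigma_eps: float
    log_likelihood: float
    bic: float
    n_obs: int
    n_groups: int
    converged: bool
    n_quad: int = 9

    @property
    def random_intercept_variance(self) -> float:
        return self.sigma_u**2

    @property
    def odds_ratios_(self) -> dict[str, float]:
        return {k: float(np.exp(v)) for k, v in self.coefficients.items()}

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": list(self.names),
                "estimate": [self.coefficients[n] for n in self.names],
                "se": [self.standard_errors[n] for n in self.names],
                "z": [self.wald_z[n] for n in self.names],
                "p": [self.p_values[n] for n in self.names],
                "odds_ratio": [np.exp(self.coefficients[n]) for n in self.names],
            }
        )


def design_matrix(table: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, tuple[str, ...]]:
    """Assemble [1, ratio, factors..., interactions...] from coded columns."""
    cols = [np.ones(len(table)), table[spec.ratio_col].to_numpy(float)]
    for f in spec.factors:
        cols.append(table[FACTOR_COLUMNS[f]].to_numpy(float))
    fidx = {f: i + 2 for i, f in enumerate(spec.factors)}
    for a, b in spec.interactions:
        cols.append(cols[fidx[a]] * cols[fidx[b]])
    X = np.column_stack(cols)
    if not np.all(np.isfinite(X)):
        raise DesignError("missing or non-finite covariates")
    return X, spec.term_names


# ---------------------------------------------------------------------------
# marginal likelihood via adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

def _obs_loglik(y, mu, se):
    """Truncated-normal log density on (0, 1) around mean mu."""
    z = (y - mu) / se
    log_z_norm = np.log(ndtr((1.0 - mu) / se) - ndtr(-mu / se))
    return -0.5 * z * z - np.log(se) - _LOG_SQRT_2PI - log_z_norm


def _npdf(x):
    return np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)


class _MarginalLoglik:
    """Callable negative marginal log likelihood with a warm-started inner
    Laplace step (the participant modes persist across evaluations)."""

    def __init__(self, X, y, groups, n_groups, n_quad):
        self.X = X
        self.y = y
        self.g = groups
        self.n_groups = n_groups
        t, w = hermgauss(n_quad)
        self.t = t
        self.logw = np.log(w)
        self.u = np.zeros(n_groups)

    def _inner_mode(self, eta, su, se, max_iter=60, tol=1e-10):
        y, g, N = self.y, self.g, self.n_groups
        u = self.u.copy()
        su2, se2 = su * su, se * se
        curv = None
        for _ in range(max_iter):
            mu = expit(eta + u[g])
            m1 = mu * (1.0 - mu)
            gz = (_npdf(-mu / se) - _npdf((1.0 - mu) / se)) / (
                se * (ndtr((1.0 - mu) / se) - ndtr(-mu / se))
            )
            gobs = ((y - mu) / se2 - gz) * m1
            grad = np.bincount(g, gobs, N) - u / su2
            curv = -(np.bincount(g, m1 * m1, N) / se2 + 1.0 / su2)
            step = np.clip(-grad / curv, -2.0, 2.0)
            u += step
            if np.max(np.abs(step)) < tol:
                break
        self.u = u
        return u, curv

    def loglik(self, theta):
        p = self.X.shape[1]
        beta = theta[:p]
        su = float(np.exp(theta[p]))
        se = float(np.exp(theta[p + 1]))
        eta = self.X @ beta
        u_hat, curv = self._inner_mode(eta, su, se)
        sd_hat = 1.0 / np.sqrt(-curv)
        terms = np.empty((len(self.t), self.n_groups))
        log_su_norm = -np.log(su) - _LOG_SQRT_2PI
        for k, (tk, lwk) in enumerate(zip(self.t, self.logw)):
            uk = u_hat + np.sqrt(2.0) * sd_hat * tk
            mu = expit(eta + uk[self.g])
            obs = np.bincount(self.g, _obs_loglik(self.y, mu, se), self.n_groups)
            prior = -0.5 * (uk / su) ** 2 + log_su_norm
            terms[k] = lwk + tk * tk + obs + prior
        tmax = terms.max(axis=0)
        ll_g = tmax + np.log(np.exp(terms - tmax).sum(axis=0))
        ll_g += 0.5 * np.log(2.0) + np.log(sd_hat)
        return float(ll_g.sum())

    def __call__(self, theta):
        return -self.loglik(theta)


def _start_values(X, y):
    z = logit(np.clip(y, 1e-4, 1 - 1e-4))
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = y - expit(X @ beta)
    se0 = max(float(resid.std()), 1e-2)
    return beta, 0.3, se0


def _numeric_hessian(fun, x, step=1e-4):
    n = len(x)
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit_posture_model(
    table: pd.DataFrame,
    spec: ModelSpec,
    n_quad: int = 9,
    n_restarts: int = 3,
    clamp: float = 1e-6,
    group_col: str = "participant_id",
) -> FitResult:
    """Maximize the marginal likelihood and return estimates with Wald
    inference.

    The optimizer is a bounded quasi-Newton on (beta, log sigma_u,
    log sigma_eps) with jittered restarts; standard errors are the square
    roots of the diagonal of the inverse observed information (numeric
    Hessian at the optimum).
    """
    y = table[spec.response_col].to_numpy(float)
    if np.any(y < 0) or np.any(y > 1):
        raise DesignError("response outside [0, 1]")
    y = np.clip(y, clamp, 1.0 - clamp)
    X, names = design_matrix(table, spec)
    codes, uniques = pd.factorize(table[group_col])
    if len(uniques) < 2:
        raise DesignError("need at least 2 participants")

    nll = _MarginalLoglik(X, y, codes, len(uniques), n_quad)
    beta0, su0, se0 = _start_values(X, y)
    p = X.shape[1]
    bounds = [(None, None)] * p + [
        (np.log(1e-4), np.log(5.0)),
        (np.log(1e-4), np.log(1.0)),
    ]
    rng = np.random.default_rng(0)
    best = None
    for r in range(max(1, n_restarts)):
        b = beta0.copy()
        if r > 0:
            b = b * (1.0 + 0.05 * rng.standard_normal(p)) + 0.02 * rng.standard_normal(p)
        x0 = np.concatenate([b, [np.log(su0), np.log(se0)]])
        nll.u = np.zeros(nll.n_groups)
        res = minimize(
            nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-10, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
    theta = best.x
    converged = bool(best.success)

    se_vec = np.full(p + 2, np.nan)
    try:
        H = _numeric_hessian(nll, theta)
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        if np.any(diag[:p] <= 0):
            raise np.linalg.LinAlgError("non-PD information")
        se_vec = np.sqrt(np.abs(diag))
    except np.linalg.LinAlgError:
        converged = False
        warnings.warn("singular observed information; standard errors unavailable")

    ll = -best.fun
    k = p + 2
    n = len(y)
    coef = dict(zip(names, theta[:p]))
    ses = dict(zip(names, se_vec[:p]))
    zvals = {m: coef[m] / ses[m] if ses[m] > 0 else np.nan for m in names}
    pvals = {m: 2.0 * (1.0 - ndtr(abs(zvals[m]))) for m in names}
    return FitResult(
        spec=spec,
        names=names,
        coefficients={m: float(v) for m, v in coef.items()},
        standard_errors={m: float(v) for m, v in ses.items()},
        wald_z={m: float(v) for m, v in zvals.items()},
        p_values={m: float(v) for m, v in pvals.items()},
        sigma_u=float(np.exp(theta[p])),
        sigma_eps=float(np.exp(theta[p + 1])),
        log_likelihood=float(ll),
        bic=float(-2.0 * ll + k * np.log(n)),
        n_obs=int(n),
        n_groups=int(len(uniques)),
        converged=converged,
        n_quad=n_quad,
    )


def odds_ratios(fit: FitResult) -> dict[str, float]:
    """exp(estimate) for every coefficient."""
    if not fit.converged:
        raise ConvergenceError("fit did not converge; odds ratios unreliable")
    return fit.odds_ratios_


def predict_curve(
    fit: FitResult | Mapping[str, float],
    factor_settings: Mapping[str, float],
    ratio_grid: Sequence[float],
) -> np.ndarray:
    """Fitted scaled rotation over a centered-ratio grid, random effect at 0.

    ``factor_settings`` must supply a value in [-1, +1] for every factor in
    the model; interaction terms use the products of the given settings.
    """
    coefs = fit.coefficients if isinstance(fit, FitResult) else dict(fit)
    x = np.asarray(ratio_grid, dtype=float)
    lp = coefs["intercept"] + coefs["ax_ratio"] * x
    for name, est in coefs.items():
        if name in ("intercept", "ax_ratio"):
            continue
        if ":" in name:
            a, b = name.split(":")
            lp = lp + est * _setting(factor_settings, a) * _setting(factor_settings, b)
        else:
            lp = lp + est * _setting(factor_settings, name)
    return expit(lp)


def _setting(settings: Mapping[str, float], name: str) -> float:
    try:
        v = float(settings[name])
    except KeyError:
        raise DesignError(f"no setting supplied for factor {name!r}") from None
    if not -1.0 <= v <= 1.0:
        raise DesignError(f"factor setting {name}={v} outside [-1, +1]")
    return v
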