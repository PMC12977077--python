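"""Posture-variance analysis: SD aggregation and the logit-derivative LMM.

Trial-to-trial posture variance is summarized as the sample SD of the
scaled rotation over the repetitions of each unique combination of
participant, segment, aperture level, and design factors (fatigue is
aggregated out to obtain repetitions).  The SDs are then modeled with a
Gaussian linear mixed model with a participant random intercept.  Because
posture variance peaks where the posture curve bends, a *logit-derivative*
regressor p(1-p), with p = logistic(a + b x) taken from the corresponding
posture fit, is added to the linear ratio term; a BIC comparison (on ML
refits) decides between the purely linear and the expanded model.

Effect sizes are semi-partial R^2 values in the marginal-R^2 style for
mixed models: the variance share of the fixed-effect predictions relative
to fixed + random-intercept + residual variance, and per effect the drop in
marginal R^2 when that effect is removed (a documented approximation of the
usual semi-partial statistic, floored at zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .errors import DesignError
from .posture_model import FACTOR_COLUMNS, FitResult

#: grouping factors (besides participant, segment, and aperture level)
VARIANCE_FACTORS = {
    "combined": ("environment", "condition", "order"),
    "feedback": ("body_visible", "condition", "order"),
    "exp1": ("condition", "order"),
}


@dataclass
class VarianceFit:
    names: tuple[str, ...]
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    t_values: dict[str, float]
    p_values: dict[str, float]
    r2_beta: dict[str, float]
    random_intercept_variance: float
    residual_variance: float
    log_likelihood_ml: float
    bic: float
    n_obs: int
    converged: bool

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "effect": list(self.names),
                "estimate": [self.coefficients[n] for n in self.names],
                "se": [self.standard_errors[n] for n in self.names],
                "t": [self.t_values[n] for n in self.names],
                "p": [self.p_values[n] for n in self.names],
                "r2_beta": [self.r2_beta.get(n, np.nan) for n in self.names],
            }
        )


def aggregate_sds(
    table: pd.DataFrame,
    factors: Sequence[str],
    min_repetitions: int = 2,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Sample SDs (n-1 denominator) of the scaled rotation per unique
    combination of participant, segment, aperture level, and the given
    factors; groups with fewer than ``min_repetitions`` repetitions are
    dropped and counted in the audit."""
    if table.empty:
        raise DesignError("empty trial table")
    keys = ["participant_id", "segment", "width_index"] + [
        FACTOR_COLUMNS[f] for f in factors
    ]
    agg = (
        table.groupby(keys, dropna=False)
        .agg(
            sd_scaled=("scaled_rotation", "std"),
            n_reps=("scaled_rotation", "size"),
            ax_centered=("ax_centered", "mean"),
        )
        .reset_index()
    )
    small = agg["n_reps"] < min_repetitions
    audit = {
        "groups_total": int(len(agg)),
        "groups_dropped_single": int(small.sum()),
        "groups_kept": int((~small).sum()),
    }
    return agg.loc[~small].reset_index(drop=True), audit


def logit_derivative_regressor(ax_centered, a: float, b: float):
    """p(1-p) with p = logistic(a + b x): the bell-shaped derivative of the
    posture curve (up to the constant b), peaking at 0.25 where p = 1/2."""
    if not (np.isfinite(a) and np.isfinite(b)) or b == 0:
        raise DesignError("need finite a, b with b != 0")
    p = expit(a + b * np.asarray(ax_centered, dtype=float))
    return p * (1.0 - p)


def _variance_design(
    rows: pd.DataFrame, factors: Sequence[str], interactions: Sequence[tuple[str, str]],
    expanded: bool,
) -> tuple[np.ndarray, tuple[str, ...]]:
    cols = [np.ones(len(rows)), rows["ax_centered"].to_numpy(float)]
    names = ["intercept", "ax_linear"]
    if expanded:
        cols.append(rows["ax_logit_deriv"].to_numpy(float))
        names.append("ax_logit_deriv")
    vals = {}
    for f in factors:
        vals[f] = rows[FACTOR_COLUMNS[f]].to_numpy(float)
        cols.append(vals[f])
        names.append(f)
    for a, b in interactions:
        cols.append(vals[a] * vals[b])
        names.append(f"{a}:{b}")
    return np.column_stack(cols), tuple(names)


def _marginal_r2(X, beta, var_u, var_e) -> float:
    var_f = float(np.var(X @ beta))
    return var_f / (var_f + var_u + var_e)


def _fit_one(
    rows: pd.DataFrame,
    factors: Sequence[str],
    interactions: Sequence[tuple[str, str]],
    expanded: bool,
    compute_r2: bool,
) -> VarianceFit:
    X, names = _variance_design(rows, factors, interactions, expanded)
    y = rows["sd_scaled"].to_numpy(float)
    groups, _ = pd.factorize(rows["participant_id"])
    n, k_fixed = X.shape

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        reml = MixedLM(y, X, groups).fit(reml=True)
        ml = MixedLM(y, X, groups).fit(reml=False)

    k = k_fixed + 2  # fixed effects + random-intercept and residual variances
    bic = -2.0 * float(ml.llf) + k * np.log(n)
    var_u = float(np.asarray(ml.cov_re)[0, 0])
    var_e = float(ml.scale)

    r2: dict[str, float] = {}
    if compute_r2:
        full_r2 = _marginal_r2(X, ml.fe_params, var_u, var_e)
        for j, name in enumerate(names):
            if name == "intercept":
                continue
            Xr = np.delete(X, j, axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                mr = MixedLM(y, Xr, groups).fit(reml=False)
            red_r2 = _marginal_r2(
                Xr, mr.fe_params, float(np.asarray(mr.cov_re)[0, 0]), float(mr.scale)
            )
            r2[name] = max(0.0, full_r2 - red_r2)

    coefs = dict(zip(names, np.asarray(reml.fe_params, dtype=float)))
    ses = dict(zip(names, np.asarray(reml.bse_fe, dtype=float)))
    tvals = {m: coefs[m] / ses[m] if ses[m] > 0 else np.nan for m in names}
    pvals = {m: 2.0 * (1.0 - ndtr(abs(tvals[m]))) for m in names}
    return VarianceFit(
        names=names,
        coefficients=coefs,
        standard_errors=ses,
        t_values=tvals,
        p_values=pvals,
        r2_beta=r2,
        random_intercept_variance=float(np.asarray(reml.cov_re)[0, 0]),
        residual_variance=float(reml.scale),
        log_likelihood_ml=float(ml.llf),
        bic=float(bic),
        n_obs=int(n),
        converged=bool(reml.converged and ml.converged),
    )


def fit_variance_model(
    rows: pd.DataFrame,
    analysis: str,
    posture_fit: FitResult | tuple[float, float],
    compute_r2: bool = True,
) -> tuple[VarianceFit, VarianceFit]:
    """Fit the linear and the logit-derivative-expanded SD model.

    ``posture_fit`` supplies (a, b) = (intercept, ratio slope) for the
    logit-derivative regressor — either a posture :class:`FitResult` at
    reference factor settings or an explicit pair.  Returns
    (linear_fit, expanded_fit); compare their ``bic`` fields (ML refits) to
    choose the variance structure.
    """
    if analysis not in VARIANCE_FACTORS:
        raise DesignError(f"unknown analysis {analysis!r}")
    factors = VARIANCE_FACTORS[analysis]
    interactions = (
        [(factors[0], "order"), ("condition", "order")]
        if len(factors) == 3
        else [("condition", "order")]
    )
    if isinstance(posture_fit, FitResult):
        a = posture_fit.coefficients["intercept"]
        b = posture_fit.coefficients["ax_ratio"]
    else:
        a, b = posture_fit
    rows = rows.copy()
    rows["ax_logit_deriv"] = logit_derivative_regressor(rows["ax_centered"], a, b)
    linear = _fit_one(rows, factors, interactions, expanded=False, compute_r2=compute_r2)
    expanded = _fit_one(rows, factors, interactions, expanded=True, compute_r2=compute_r2)
    return linear, expanded


def r2_beta(fit: VarianceFit, effect: str) -> float:
    """Semi-partial effect size of one fixed effect (see module docstring)."""
    if effect not in fit.r2_beta:
        raise DesignError(f"effect {effect!r} absent from fit (or r2 not computed)")
    return fit.r2_beta[effect]


def simulate_sd_rows(
    a: float,
    b: float,
    c_linear: float,
    c_bump: float,
    n_participants: int,
    seed: int,
    intercept: float = 0.07,
    participant_sd: float = 0.01,
    noise_sd: float = 0.012,
    factors: Sequence[str] = ("environment", "condition", "order"),
    effects: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Synthetic SD rows with a known linear-plus-bump variance structure.

    SD = intercept + c_linear * x + c_bump * p(1-p) + factor effects + u_i
    + noise, over the 9-level centered ratio grid and all -1/+1 factor
    combinations; used to exercise the linear-vs-expanded model comparison.
    """
    rng = np.random.default_rng(seed)
    effects = dict(effects or {})
    x_grid = np.linspace(-0.5, 0.5, 9)
    combos = [()]
    for _ in factors:
        combos = [c + (s,) for c in combos for s in (-1.0, +1.0)]
    rows = []
    for i in range(n_participants):
        u = rng.normal(0.0, participant_sd)
        jitter = rng.normal(0.0, 0.02)
        for w, x0 in enumerate(x_grid, start=1):
            x = x0 + jitter
            bump = float(logit_derivative_regressor(x, a, b))
            for combo in combos:
                sd = intercept + c_linear * x + c_bump * bump + u
                for f, s in zip(factors, combo):
                    sd += effects.get(f, 0.0) * s
                sd += rng.normal(0.0, noise_sd)
                rows.append(
                    (f"p{i + 1:02d}", "shoulder", w, x, max(sd, 1e-4), 4)
                    + combo
                )
    cols = ["participant_id", "segment", "width_index", "ax_centered",
            "sd_scaled", "n_reps"] + [FACTOR_COLUMNS[f] for f in factors]
    return pd.DataFrame(rows, columns=cols)
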