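"""Derived thresholds: points-of-change, critical values, factor shifts.

With a negative ratio slope the fitted posture curve crosses any rotation
level exactly once; inverting the linear predictor at a level L gives the
A/X ratio at which L of the maximum rotation is reached:

    x(L) = (logit(L) - b0 - sum_f b_f * setting_f) / b_ratio  + centering mean

The *point-of-change* is the 50% crossing and the *critical value* the 5%
crossing (the width below which a rotation is initiated).  Because the
factors enter the linear predictor additively, moving a -1/+1 coded factor
from -1 to +1 translates the whole curve horizontally by -2 b_f / b_ratio —
the same offset at every level — which is how critical-value differences
between factor levels are obtained.  Interaction terms are excluded from
these formulas (a warning is emitted when a fitted interaction is not small
relative to its main effects).
"""

from __future__ import annotations

import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import logit

from .errors import DesignError
from .posture_model import FitResult

#: default reporting levels
CRITICAL_LEVEL = 0.05
POINT_OF_CHANGE_LEVEL = 0.5


def _coefs(fit: FitResult | Mapping[str, float]) -> dict[str, float]:
    if isinstance(fit, FitResult):
        return dict(fit.coefficients)
    return dict(fit)


def _main_factors(coefs: Mapping[str, float]) -> list[str]:
    return [k for k in coefs if k not in ("intercept", "ax_ratio") and ":" not in k]


def _warn_large_interactions(coefs: Mapping[str, float]) -> None:
    for name, est in coefs.items():
        if ":" not in name:
            continue
        a, b = name.split(":")
        mains = [abs(coefs[f]) for f in (a, b) if f in coefs]
        if mains and abs(est) > 0.1 * max(mains):
            warnings.warn(
                f"interaction {name} ({est:+.3f}) is not small relative to its "
                "main effects; level shifts ignore it",
                stacklevel=3,
            )


def iso_level_ratio(
    fit: FitResult | Mapping[str, float],
    level: float,
    factor_settings: Mapping[str, float] | None = None,
    centering_mean: float = 0.0,
) -> float:
    """Un-centered A/X ratio at which the fitted curve crosses ``level``."""
    if not 0.0 < level < 1.0:
        raise DesignError("level must lie in (0, 1)")
    coefs = _coefs(fit)
    b_ratio = coefs["ax_ratio"]
    if b_ratio == 0:
        raise DesignError("zero ratio slope: the curve never crosses the level")
    _warn_large_interactions(coefs)
    settings = dict(factor_settings or {})
    lp_offset = coefs.get("intercept", 0.0)
    for f in _main_factors(coefs):
        lp_offset += coefs[f] * settings.get(f, 0.0)
    x = (float(logit(level)) - lp_offset) / b_ratio
    return float(x + centering_mean)


def factor_level_shift(fit: FitResult | Mapping[str, float], factor_name: str) -> float:
    """Horizontal curve shift when ``factor_name`` moves from -1 to +1.

    Equal to -2 b_f / b_ratio, identical at every rotation level (parallel
    curves).
    """
    coefs = _coefs(fit)
    if factor_name not in coefs:
        raise DesignError(f"factor {factor_name!r} absent from fit")
    return float(-2.0 * coefs[factor_name] / coefs["ax_ratio"])


def per_sequence_fatigue_shift(
    fit: FitResult | Mapping[str, float], n_sequences: int
) -> float:
    """Critical-ratio drift per sequence, in percent of body width.

    The fatigue code spans -1..+1 over ``n_sequences`` sequences, so the
    total shift spreads over n_sequences - 1 steps.
    """
    if n_sequences < 2:
        raise DesignError("need at least 2 sequences")
    total = abs(factor_level_shift(fit, "fatigue"))
    return float(100.0 * total / (n_sequences - 1))


def threshold_table(
    fit: FitResult | Mapping[str, float],
    centering_mean: float,
    n_sequences: int | None = None,
    levels: tuple[float, ...] = (CRITICAL_LEVEL, POINT_OF_CHANGE_LEVEL),
) -> pd.DataFrame:
    """Points-of-change and critical values at reference and +-1 factor
    settings, plus all per-factor shifts.

    Columns: level, setting, ratio, pct (ratio x 100, percent of body
    width), shift (Δratio for the factor rows; NaN for reference rows).
    """
    coefs = _coefs(fit)
    rows = []
    for level in levels:
        ref = iso_level_ratio(coefs, level, None, centering_mean)
        rows.append((level, "reference", ref, 100.0 * ref, np.nan))
        for f in _main_factors(coefs):
            shift = factor_level_shift(coefs, f)
            for s in (-1.0, +1.0):
                x = iso_level_ratio(coefs, level, {f: s}, centering_mean)
                rows.append((level, f"{f}={s:+.0f}", x, 100.0 * x, shift))
    out = pd.DataFrame(rows, columns=["level", "setting", "ratio", "pct", "shift"])
    if n_sequences is not None and "fatigue" in coefs:
        out.attrs["per_sequence_fatigue_shift_pct"] = per_sequence_fatigue_shift(
            coefs, n_sequences
        )
    return out
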