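"""Build model-ready trial tables: ratios, scaling, coding, exclusions.

The analysis data sets are assembled per research question: the *combined*
set pools all real-environment trials with the virtual-environment trials in
which the participant's body was visible (and poles could be knocked over);
the *feedback* set holds all virtual-environment trials.  Within each
assembled set the rotation angles are divided by the participant-and-segment
maximum over the included trials, the aperture-to-body-width ratio (A/S for
shoulder and thorax, A/H for pelvis) is centered around the set's mean, and
the two-level design factors are coded -1/+1 with fatigue mapped linearly
onto [-1, +1] across each experiment's sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DesignError

#: -1 level / +1 level of each two-level factor
FACTOR_LEVELS = {
    "environment": ("real", "virtual"),
    "condition": ("randomized", "ordered"),
    "order": ("increasing", "decreasing"),
    "body_visible": (False, True),
}

ANALYSES = ("combined", "feedback", "exp1")


@dataclass
class PreparedDataset:
    """An assembled analysis table plus its bookkeeping."""

    analysis: str
    table: pd.DataFrame          # included rows only, fully coded and scaled
    full: pd.DataFrame           # all candidate rows with exclusion flags
    audit: dict[str, int]        # per-reason exclusion row counts
    centering_means: dict[str, float]  # segment -> mean un-centered ratio
    n_sequences_by_experiment: dict[str, int]


def compute_ax_ratio(aperture_width_cm, body_width_cm):
    """Aperture width over body width (A/S or A/H)."""
    aperture = np.asarray(aperture_width_cm, dtype=float)
    body = np.asarray(body_width_cm, dtype=float)
    if np.any(aperture <= 0) or np.any(body <= 0):
        raise DesignError("widths must be positive")
    return aperture / body


def center_ratios(ratios) -> tuple[np.ndarray, float]:
    """Subtract the arithmetic mean; returns (centered, mean)."""
    r = np.asarray(ratios, dtype=float)
    mean = float(r.mean())
    return r - mean, mean


def scale_rotation_by_max(
    df: pd.DataFrame,
    value_col: str = "alpha_deg",
    group_cols: tuple[str, ...] = ("participant_id", "segment"),
    excluded_col: str = "excluded",
) -> pd.Series:
    """Divide each angle by its participant x segment maximum.

    The maximum is taken over non-excluded rows only; excluded rows are
    still scaled (by the same max) so their values remain interpretable.
    """
    include = ~df[excluded_col] if excluded_col in df else pd.Series(True, index=df.index)
    gmax = (
        df[value_col]
        .where(include)
        .groupby([df[c] for c in group_cols])
        .transform("max")
    )
    if gmax.isna().any():
        raise DesignError("a participant/segment group has no included trials")
    if (gmax <= 0).any():
        bad = df.loc[gmax <= 0, list(group_cols)].drop_duplicates()
        raise DesignError(f"all-zero rotation group(s): {bad.to_dict('records')}")
    return df[value_col] / gmax


def encode_order(df: pd.DataFrame) -> pd.DataFrame:
    """Label each trial increasing/decreasing from the trial n-1 comparison.

    Within every sequence, trial n is *increasing* if its aperture is wider
    than trial n-1's and *decreasing* otherwise; the first trial of each
    sequence has no predecessor and is flagged for exclusion.  In ordered
    sequences this reproduces the sequence's plan label for trials 2..9.
    """
    df = df.sort_values(
        ["participant_id", "segment", "sequence_index_global", "trial_index_in_sequence"]
    ).copy()
    grp = df.groupby(
        ["participant_id", "segment", "sequence_index_global"], sort=False
    )
    prev = grp["aperture_width_cm"].shift(1)
    diff = df["aperture_width_cm"] - prev
    if (diff == 0).any():
        raise DesignError("duplicate aperture widths within a sequence")
    df["order_label"] = np.where(
        prev.isna(), None, np.where(diff > 0, "increasing", "decreasing")
    )
    df["first_trial"] = prev.isna()
    return df


def encode_factors(
    df: pd.DataFrame, n_sequences_by_experiment: Mapping[str, int]
) -> pd.DataFrame:
    """Attach the -1/+1 factor codes and the linear fatigue code.

    Sign convention: randomized / real / increasing / body-not-visible map to
    -1; ordered / virtual / decreasing / body-visible to +1 (so the positive
    published environment effect means more rotation in the virtual
    environment).  Fatigue runs from -1 at each experiment's first sequence
    to +1 at its last.
    """
    df = df.copy()

    def _code(col, factor):
        lo, hi = FACTOR_LEVELS[factor]
        vals = df[col]
        known = vals.isin([lo, hi]) | vals.isna()
        if not known.all():
            raise DesignError(
                f"unknown {factor} level(s): {sorted(vals[~known].unique().tolist())}"
            )
        return np.where(vals.isna(), 0.0, np.where(vals == hi, 1.0, -1.0))

    df["coded_environment"] = _code("experiment", "environment")
    df["coded_condition"] = _code("condition", "condition")
    df["coded_order"] = _code("order_label", "order")
    df["coded_bodyvisible"] = _code("body_visible", "body_visible")
    n_by_exp = df["experiment"].map(dict(n_sequences_by_experiment))
    if n_by_exp.isna().any():
        raise DesignError("missing sequence total for an experiment")
    df["coded_fatigue"] = np.where(
        n_by_exp > 1,
        -1.0 + 2.0 * (df["sequence_index_global"] - 1) / (n_by_exp - 1),
        0.0,
    )
    return df


def apply_exclusions(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Flag excluded rows and return per-reason counts.

    Reasons, in priority order: ``aborted_sequence`` (real environment:
    every trial of a sequence in which a pass failed), ``failed`` (virtual
    environment: the failed trial only), ``first_trial`` (no predecessor for
    the order comparison).
    """
    df = df.copy()
    aborted = df.get("sequence_aborted", pd.Series(False, index=df.index)).fillna(False)
    aborted &= df["experiment"] == "real"
    failed = df.get("failed", pd.Series(False, index=df.index)).fillna(False)
    failed &= df["experiment"] == "virtual"
    first = df["first_trial"]
    reason = np.select(
        [aborted.to_numpy(), failed.to_numpy(), first.to_numpy()],
        ["aborted_sequence", "failed", "first_trial"],
        default="",
    )
    df["exclusion_reason"] = reason
    df["excluded"] = reason != ""
    audit = {
        r: int((reason == r).sum())
        for r in ("aborted_sequence", "failed", "first_trial")
    }
    audit["included"] = int((reason == "").sum())
    audit["total"] = int(len(df))
    return df, audit


def assemble_analysis_dataset(rows: pd.DataFrame, analysis: str) -> pd.DataFrame:
    """Select the rows belonging to one analysis.

    ``combined``: all real-environment trials plus virtual-environment
    trials with a visible body.  ``feedback``: all virtual-environment
    trials (both visibility levels).  ``exp1``: the real environment alone.
    """
    if analysis == "combined":
        keep = (rows["experiment"] == "real") | (
            (rows["experiment"] == "virtual") & (rows["body_visible"] == True)  # noqa: E712
        )
    elif analysis == "feedback":
        keep = rows["experiment"] == "virtual"
    elif analysis == "exp1":
        keep = rows["experiment"] == "real"
    else:
        raise DesignError(f"unknown analysis {analysis!r}; expected one of {ANALYSES}")
    out = rows.loc[keep].copy()
    if out.empty:
        raise DesignError(f"analysis {analysis!r} selects no rows")
    return out


def prepare_trials(
    angles: pd.DataFrame,
    trial_meta: pd.DataFrame,
    participants: pd.DataFrame,
    analysis: str,
    n_sequences_by_experiment: Mapping[str, int] | None = None,
) -> PreparedDataset:
    """Full preparation: merge, select, exclude, code, scale, center.

    ``angles`` carries one row per segment x trial (from the kinematics
    module, or the generator's true angles); ``trial_meta`` the design
    metadata per trial; ``participants`` the body widths.
    """
    meta_cols = [
        "participant_id", "experiment", "task_id", "condition", "body_visible",
        "sequence_index_global", "trial_index_in_sequence", "width_index",
        "aperture_width_cm", "failed", "sequence_aborted",
    ]
    meta_cols = [c for c in meta_cols if c in trial_meta.columns]
    merged = angles.merge(
        trial_meta[meta_cols],
        on=["participant_id", "task_id", "sequence_index_global", "trial_index_in_sequence"],
        validate="many_to_one",
    ).merge(
        participants[["participant_id", "shoulder_width_cm", "hip_width_cm"]],
        on="participant_id",
        validate="many_to_one",
    )
    if len(merged) != len(angles):
        raise DesignError("angle rows without matching trial metadata")

    if n_sequences_by_experiment is None:
        n_sequences_by_experiment = (
            merged.groupby("experiment")["sequence_index_global"].max().to_dict()
        )

    rows = assemble_analysis_dataset(merged, analysis)
    rows = encode_order(rows)
    rows, audit = apply_exclusions(rows)
    rows = encode_factors(rows, n_sequences_by_experiment)

    body = np.where(
        rows["segment"] == "pelvis",
        rows["hip_width_cm"],
        rows["shoulder_width_cm"],
    )
    rows["ax_ratio"] = compute_ax_ratio(rows["aperture_width_cm"], body)
    rows["scaled_rotation"] = scale_rotation_by_max(rows)

    include = ~rows["excluded"]
    centering_means: dict[str, float] = {}
    rows["ax_centered"] = np.nan
    for segment, seg_rows in rows.groupby("segment"):
        mean = float(seg_rows.loc[include[seg_rows.index], "ax_ratio"].mean())
        centering_means[segment] = mean
        rows.loc[seg_rows.index, "ax_centered"] = seg_rows["ax_ratio"] - mean

    table = rows.loc[include].reset_index(drop=True)
    return PreparedDataset(
        analysis=analysis,
        table=table,
        full=rows.reset_index(drop=True),
        audit=audit,
        centering_means=centering_means,
        n_sequences_by_experiment=dict(n_sequences_by_experiment),
    )


def truth_angles_frame(trials: pd.DataFrame) -> pd.DataFrame:
    """Expand a generator trial table into the angles layout (one row per
    segment), using the true rotation angles.  Useful for analyses that do
    not go through marker trajectories."""
    parts = []
    for segment in ("shoulder", "thorax", "pelvis"):
        part = trials[
            ["participant_id", "task_id", "sequence_index_global",
             "trial_index_in_sequence", "walk_direction", "true_alpha_deg"]
        ].copy()
        part["segment"] = segment
        part = part.rename(columns={"true_alpha_deg": "alpha_deg"})
        parts.append(part)
    return pd.concat(parts, ignore_index=True)
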