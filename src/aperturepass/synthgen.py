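"""Synthetic study generator for aperture-passage posture experiments.

This module produces a complete synthetic data set with the statistical
structure the downstream analysis assumes: a cohort of participants with
measured shoulder/hip widths and stable individual offsets, the two
experimental designs (a real-environment study with randomized and ordered
aperture sequences, and a virtual-environment study that additionally varies
body visibility), per-trial "true" trunk rotations drawn from a logistic law
in the aperture-to-body-width ratio, and — optionally — raw marker
trajectories of a walker passing back and forth through the aperture, from
which the kinematics module can recover those rotations.

The generative posture law is the exact inverse of the model fitted by
:mod:`aperturepass.posture_model`: the linear predictor is

    lp = b0 + b_ratio * (A/S - anchor) + sum_f b_f * code_f + u_i

with participant random intercepts ``u_i ~ N(0, sigma_u^2)``, and the
observed scaled rotation is a truncated-normal perturbation (on (0, 1)) of
``logistic(lp)``.  Factor codes live on the -1/+1 scale used throughout the
analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import truncnorm

from .errors import DesignError, GeometryError

MARKER_NAMES = ("LAC", "RAC", "C7", "T8", "IJ", "PX", "LASI", "RASI", "LPSI", "RPSI")

SEGMENTS = ("shoulder", "thorax", "pelvis")

#: Un-centered A/S ratio at which the generator's linear predictor is anchored
#: (the mean design ratio for a 40 cm shoulder); the analysis pipeline still
#: centers empirically.
RATIO_ANCHOR = 1.375

_ENV_CODE = {"exp1": -1.0, "exp2": +1.0}
_EXPERIMENT_LABEL = {"exp1": "real", "exp2": "virtual"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskSpec:
    task_id: str
    condition: str  # "randomized" | "ordered"
    body_visible: bool | None  # None = not manipulated (real environment)
    n_sequences: int


@dataclass(frozen=True)
class DesignSpec:
    experiment_id: str
    tasks: tuple[TaskSpec, ...]
    aperture_widths_cm: tuple[float, ...]
    n_trials_per_sequence: int = 9

    @property
    def n_sequences_total(self) -> int:
        return sum(t.n_sequences for t in self.tasks)

    @property
    def total_trials(self) -> int:
        return self.n_sequences_total * self.n_trials_per_sequence

    def task(self, task_id: str) -> TaskSpec:
        for t in self.tasks:
            if t.task_id == task_id:
                return t
        raise DesignError(f"unknown task_id {task_id!r}")


@dataclass(frozen=True)
class SequencePlan:
    sequence_index_global: int  # 1-based counter since experiment start
    task_id: str
    order_label: str  # "randomized" | "increasing" | "decreasing"
    width_indices: tuple[int, ...]  # permutation or monotone run of 1..9


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    shoulder_width_cm: float
    hip_width_cm: float
    random_intercept: float
    max_rotation_deg: float
    rotation_side: int = +1  # +1 rotates left shoulder forward, -1 the mirror

    def __post_init__(self):
        if self.shoulder_width_cm <= 0 or self.hip_width_cm <= 0:
            raise DesignError("body widths must be positive")
        if not 0 < self.max_rotation_deg <= 180:
            raise DesignError("max_rotation_deg must lie in (0, 180]")


@dataclass(frozen=True)
class GeneratorTruth:
    """True parameters of the generative posture law.

    ``beta0`` is the linear predictor at the anchored ratio with all factor
    codes at 0; ``beta_ratio`` (negative) is the slope per unit A/X ratio.
    Factor effects are per unit of the -1/+1 code.  ``sigma_eps`` acts on the
    scaled-rotation scale, ``sigma_u`` on the linear-predictor scale.
    """

    beta0: float
    beta_ratio: float
    beta_env: float = 0.0
    beta_cond: float = 0.0
    beta_order: float = 0.0
    beta_fatigue: float = 0.0
    beta_bodyvis: float = 0.0
    sigma_u: float = 0.5
    sigma_eps: float = 0.05
    failure_rate: float = 0.0
    ratio_anchor: float = RATIO_ANCHOR

    def __post_init__(self):
        if self.beta_ratio >= 0:
            raise DesignError("beta_ratio must be negative (wider gap, less rotation)")
        if self.sigma_u < 0 or self.sigma_eps < 0:
            raise DesignError("scale parameters must be non-negative")
        if not 0 <= self.failure_rate < 1:
            raise DesignError("failure_rate must lie in [0, 1)")


@dataclass(frozen=True)
class AnthropometryConfig:
    """Cohort distributions (invented defaults; truncated at +-3 SD)."""

    shoulder_mean_cm: float = 40.0
    shoulder_sd_cm: float = 3.0
    hip_mean_cm: float = 34.0
    hip_sd_cm: float = 3.0
    max_rotation_mean_deg: float = 85.0
    max_rotation_sd_deg: float = 5.0
    sigma_u: float = 0.5

    def __post_init__(self):
        for name in ("shoulder_mean_cm", "hip_mean_cm", "max_rotation_mean_deg"):
            if getattr(self, name) <= 0:
                raise DesignError(f"{name} must be positive")
        for name in ("shoulder_sd_cm", "hip_sd_cm", "max_rotation_sd_deg", "sigma_u"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be non-negative")


@dataclass(frozen=True)
class GeometryConfig:
    """Walkway and marker-placement geometry for trajectory synthesis (mm)."""

    walkway_length_m: float = 5.0
    aperture_y_m: float = 2.5
    trial_duration_s: float = 3.0
    sampling_rate_hz: float = 100.0
    shoulder_height_mm: float = 1420.0
    c7_height_mm: float = 1470.0
    t8_height_mm: float = 1260.0
    ij_height_mm: float = 1440.0
    px_height_mm: float = 1240.0
    asi_height_mm: float = 980.0
    psi_height_mm: float = 1000.0
    c7_back_mm: float = 70.0
    t8_back_mm: float = 90.0
    ij_front_mm: float = 50.0
    px_front_mm: float = 70.0
    asi_front_mm: float = 60.0
    psi_back_mm: float = 80.0
    psi_separation_mm: float = 90.0
    #: fraction of a pass over which the yaw bump extends (raised cosine)
    yaw_bump_fraction: float = 0.4

    def __post_init__(self):
        heights = (
            self.shoulder_height_mm, self.c7_height_mm, self.t8_height_mm,
            self.ij_height_mm, self.px_height_mm, self.asi_height_mm,
            self.psi_height_mm,
        )
        if min(heights) <= 0:
            raise GeometryError("marker heights must be positive")


@dataclass
class MarkerTrajectory:
    """One continuous recording of a 9-trial sequence (positions in mm)."""

    participant_id: str
    task_id: str
    sequence_index_global: int
    sampling_rate_hz: float
    time_s: np.ndarray  # (n,)
    positions: dict[str, np.ndarray]  # marker -> (n, 3)

    @property
    def n_frames(self) -> int:
        return self.time_s.shape[0]


@dataclass
class SimulatedExperiment:
    design: DesignSpec
    truth: GeneratorTruth
    participants: list[ParticipantProfile]
    plans: dict[str, list[SequencePlan]]  # participant_id -> plans
    trials: pd.DataFrame


# ---------------------------------------------------------------------------
# designs and sequence plans
# ---------------------------------------------------------------------------

def build_design(experiment_id: str) -> DesignSpec:
    """Return the task/sequence structure of the named experiment.

    ``exp1`` (real environment): one randomized task of 5 sequences and one
    ordered task of 10 sequences (45 + 90 trials).  ``exp2`` (virtual
    environment): randomized/ordered task pairs without and with a visible
    body, 4/8/4/8 sequences (36 + 72 + 36 + 72 trials).  Both use apertures
    of 35..75 cm in 5 cm steps.
    """
    widths = tuple(float(w) for w in range(35, 80, 5))
    if experiment_id == "exp1":
        tasks = (
            TaskSpec("task1", "randomized", None, 5),
            TaskSpec("task2", "ordered", None, 10),
        )
    elif experiment_id == "exp2":
        tasks = (
            TaskSpec("task1", "randomized", False, 4),
            TaskSpec("task2", "ordered", False, 8),
            TaskSpec("task3", "randomized", True, 4),
            TaskSpec("task4", "ordered", True, 8),
        )
    else:
        raise DesignError(f"unknown experiment_id {experiment_id!r}")
    return DesignSpec(experiment_id, tasks, widths)


def _ordered_labels(n_sequences: int, rng: np.random.Generator) -> list[str]:
    # half increasing / half decreasing, shuffled, no run of 3+ equal labels
    half = n_sequences // 2
    labels = ["increasing"] * half + ["decreasing"] * (n_sequences - half)
    while True:
        rng.shuffle(labels)
        if not any(
            labels[i] == labels[i + 1] == labels[i + 2]
            for i in range(len(labels) - 2)
        ):
            return list(labels)


def plan_sequences(design: DesignSpec, seed: int) -> list[SequencePlan]:
    """Draw the per-sequence aperture plans for one traversal of a design.

    Randomized tasks receive an independent permutation of widths 1..9 for
    each sequence; ordered tasks a shuffled half-increasing/half-decreasing
    label sequence with no more than two identical labels in a row.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = design.n_trials_per_sequence
    plans: list[SequencePlan] = []
    g = 0
    for task in design.tasks:
        if task.condition == "randomized":
            for _ in range(task.n_sequences):
                g += 1
                widths = tuple(int(w) for w in rng.permutation(n) + 1)
                plans.append(SequencePlan(g, task.task_id, "randomized", widths))
        else:
            for label in _ordered_labels(task.n_sequences, rng):
                g += 1
                widths = tuple(range(1, n + 1))
                if label == "decreasing":
                    widths = widths[::-1]
                plans.append(SequencePlan(g, task.task_id, label, widths))
    return plans


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------

def sample_participants(
    n: int,
    config: AnthropometryConfig | None = None,
    seed: int = 0,
    prefix: str = "p",
) -> list[ParticipantProfile]:
    """Draw a cohort: body widths from +-3 SD truncated normals, random
    intercepts from N(0, sigma_u^2), and a coin-flip rotation side."""
    if n < 1:
        raise DesignError("need at least one participant")
    cfg = config or AnthropometryConfig()
    rng = np.random.default_rng(seed)

    def _trunc(mean, sd, size):
        if sd == 0:
            return np.full(size, mean)
        return truncnorm.rvs(-3, 3, loc=mean, scale=sd, size=size, random_state=rng)

    shoulders = _trunc(cfg.shoulder_mean_cm, cfg.shoulder_sd_cm, n)
    hips = _trunc(cfg.hip_mean_cm, cfg.hip_sd_cm, n)
    maxrot = np.clip(
        _trunc(cfg.max_rotation_mean_deg, cfg.max_rotation_sd_deg, n), 1.0, 180.0
    )
    if cfg.sigma_u == 0:
        intercepts = np.zeros(n)
    else:
        intercepts = rng.normal(0.0, cfg.sigma_u, n)
    sides = rng.choice([-1, +1], size=n)
    width = len(str(n))
    return [
        ParticipantProfile(
            participant_id=f"{prefix}{i + 1:0{width}d}",
            shoulder_width_cm=float(shoulders[i]),
            hip_width_cm=float(hips[i]),
            random_intercept=float(intercepts[i]),
            max_rotation_deg=float(maxrot[i]),
            rotation_side=int(sides[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _slope_intercept(x50: float, x05: float) -> tuple[float, float]:
    """Solve the logistic location/slope hitting the 50% level at ``x50`` and
    the 5% level at ``x05`` (both in un-centered A/X units)."""
    b_ratio = (logit(0.05) - logit(0.5)) / (x05 - x50)
    b0 = -b_ratio * (x50 - RATIO_ANCHOR)
    return float(b0), float(b_ratio)


def preset(name: str) -> GeneratorTruth:
    """Documented parameter sets calibrated to the published group results.

    * ``real_env``: the real-environment curve — point-of-change at ratio
      1.024, critical value (5% level) at 1.207, no factor effects.
    * ``virtual_env``: point-of-change 1.245, critical value 1.428.
    * ``combined``: both environments; the environment code shifts the
      critical ratio by +-0.1105 around 1.3175 and the order code by
      +-0.0145 (inverse hysteresis: increasing sequences switch earlier).
    * ``exp2_feedback``: the virtual experiment with body-visibility
      (+-0.040) and fatigue (+-0.077) shifts around a 1.580 critical ratio.

    Failure rates default to 0.0011/trial for the real design (whole
    sequences abort, ~1% of trials lost) and 0.065/trial for the virtual
    design.
    """
    l05 = float(logit(0.05))
    if name == "real_env":
        b0, b1 = _slope_intercept(1.024, 1.207)
        return GeneratorTruth(beta0=b0, beta_ratio=b1, failure_rate=0.0011)
    if name == "virtual_env":
        b0, b1 = _slope_intercept(1.245, 1.428)
        return GeneratorTruth(beta0=b0, beta_ratio=b1, failure_rate=0.065)
    if name == "combined":
        # slope of the real-environment pair; 5% level centered between the
        # real (1.207) and virtual (1.428) critical ratios
        _, b1 = _slope_intercept(1.024, 1.207)
        x05_center = (1.207 + 1.428) / 2.0
        x50_center = x05_center - l05 / b1
        b0 = -b1 * (x50_center - RATIO_ANCHOR)
        return GeneratorTruth(
            beta0=b0,
            beta_ratio=b1,
            beta_env=-b1 * 0.1105,
            beta_order=-b1 * 0.0145,
            failure_rate=0.0011,
        )
    if name == "exp2_feedback":
        b1 = -10.014  # published virtual-environment shoulder slope
        x05_center = (1.540 + 1.620) / 2.0
        x50_center = x05_center - l05 / b1
        b0 = -b1 * (x50_center - RATIO_ANCHOR)
        return GeneratorTruth(
            beta0=b0,
            beta_ratio=b1,
            beta_bodyvis=-b1 * 0.040,
            beta_order=-b1 * 0.014,
            beta_fatigue=-b1 * (1.657 - 1.503) / 2.0,
            failure_rate=0.065,
        )
    raise DesignError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# trial outcomes
# ---------------------------------------------------------------------------

def _order_codes(width_indices: Sequence[int]) -> np.ndarray:
    """-1/+1 order codes from the trial n-1 comparison; first trial gets 0
    (it is removed from every analysis data set anyway)."""
    w = np.asarray(width_indices)
    codes = np.zeros(len(w))
    diff = np.sign(np.diff(w))
    if np.any(diff == 0):
        raise DesignError("duplicate widths within a sequence")
    # increasing -> -1, decreasing -> +1 (sign convention of the analysis)
    codes[1:] = np.where(diff > 0, -1.0, +1.0)
    return codes


def simulate_trial_outcomes(
    truth: GeneratorTruth,
    plans: Sequence[SequencePlan],
    participants: Sequence[ParticipantProfile],
    design: DesignSpec,
    seed: int,
) -> pd.DataFrame:
    """Draw true per-trial outcomes for every participant x plan x trial.

    Returns a long table with design metadata, the -1/+1 factor codes the
    generator used, the true scaled rotation (logistic mean plus truncated
    noise, clipped to (1e-6, 1-1e-6)), the true rotation angle in degrees,
    the alternating walk direction (+1 = toward the far end), and the failure
    flag.  For the real-environment design a failed trial aborts its whole
    sequence (``sequence_aborted``)."""
    if {p.task_id for p in plans} - {t.task_id for t in design.tasks}:
        raise DesignError("plans reference tasks absent from the design")
    rng = np.random.default_rng(seed)
    n_seq_total = design.n_sequences_total
    env_code = _ENV_CODE[design.experiment_id]
    rows = []
    for part in participants:
        for plan in plans:
            task = design.task(plan.task_id)
            cond_code = -1.0 if task.condition == "randomized" else +1.0
            bv_code = 0.0 if task.body_visible is None else (
                +1.0 if task.body_visible else -1.0
            )
            if n_seq_total > 1:
                fat_code = -1.0 + 2.0 * (plan.sequence_index_global - 1) / (
                    n_seq_total - 1
                )
            else:
                fat_code = 0.0
            order_codes = _order_codes(plan.width_indices)
            for j, widx in enumerate(plan.width_indices):
                aperture = design.aperture_widths_cm[widx - 1]
                ratio = aperture / part.shoulder_width_cm
                lp = (
                    truth.beta0
                    + truth.beta_ratio * (ratio - truth.ratio_anchor)
                    + truth.beta_env * env_code
                    + truth.beta_cond * cond_code
                    + truth.beta_order * order_codes[j]
                    + truth.beta_fatigue * fat_code
                    + truth.beta_bodyvis * bv_code
                    + part.random_intercept
                )
                rows.append(
                    (
                        part.participant_id,
                        design.experiment_id,
                        _EXPERIMENT_LABEL[design.experiment_id],
                        plan.task_id,
                        task.condition,
                        task.body_visible,
                        plan.sequence_index_global,
                        j + 1,
                        widx,
                        aperture,
                        +1 if j % 2 == 0 else -1,
                        ratio,
                        env_code,
                        cond_code,
                        order_codes[j],
                        fat_code,
                        bv_code,
                        lp,
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "participant_id", "experiment_id", "experiment", "task_id",
            "condition", "body_visible", "sequence_index_global",
            "trial_index_in_sequence", "width_index", "aperture_width_cm",
            "walk_direction", "ax_ratio", "coded_environment",
            "coded_condition", "coded_order", "coded_fatigue",
            "coded_bodyvisible", "lp",
        ],
    )
    mean = expit(df["lp"].to_numpy())
    if truth.sigma_eps > 0:
        a = (0.0 - mean) / truth.sigma_eps
        b = (1.0 - mean) / truth.sigma_eps
        y = truncnorm.rvs(a, b, loc=mean, scale=truth.sigma_eps, random_state=rng)
    else:
        y = mean
    df["true_scaled_rotation"] = np.clip(y, 1e-6, 1 - 1e-6)
    maxrot = df["participant_id"].map(
        {p.participant_id: p.max_rotation_deg for p in participants}
    )
    df["true_alpha_deg"] = df["true_scaled_rotation"] * maxrot
    if truth.failure_rate > 0:
        df["failed"] = rng.random(len(df)) < truth.failure_rate
    else:
        df["failed"] = False
    if design.experiment_id == "exp1":
        df["sequence_aborted"] = df.groupby(
            ["participant_id", "sequence_index_global"]
        )["failed"].transform("any")
    else:
        df["sequence_aborted"] = False
    return df


# ---------------------------------------------------------------------------
# marker trajectories
# ---------------------------------------------------------------------------

def _marker_template(
    participant: ParticipantProfile, geometry: GeometryConfig
) -> np.ndarray:
    """Body-frame marker offsets (10, 3) in mm, facing +y, origin on the
    floor under the trunk axis."""
    g = geometry
    s_mm = participant.shoulder_width_cm * 10.0
    h_mm = participant.hip_width_cm * 10.0
    return np.array(
        [
            [-s_mm / 2, 0.0, g.shoulder_height_mm],          # LAC
            [+s_mm / 2, 0.0, g.shoulder_height_mm],          # RAC
            [0.0, -g.c7_back_mm, g.c7_height_mm],            # C7
            [0.0, -g.t8_back_mm, g.t8_height_mm],            # T8
            [0.0, +g.ij_front_mm, g.ij_height_mm],           # IJ
            [0.0, +g.px_front_mm, g.px_height_mm],           # PX
            [-h_mm / 2, +g.asi_front_mm, g.asi_height_mm],   # LASI
            [+h_mm / 2, +g.asi_front_mm, g.asi_height_mm],   # RASI
            [-g.psi_separation_mm / 2, -g.psi_back_mm, g.psi_height_mm],  # LPSI
            [+g.psi_separation_mm / 2, -g.psi_back_mm, g.psi_height_mm],  # RPSI
        ]
    )


def synthesize_marker_trajectory(
    participant: ParticipantProfile,
    sequence_outcomes: pd.DataFrame,
    geometry: GeometryConfig | None = None,
) -> MarkerTrajectory:
    """Forward-simulate one continuous 9-trial recording.

    The walker traverses the 5 m walkway back and forth, one pass per trial,
    with a smooth cosine pace profile.  Trunk yaw follows a raised-cosine
    bump spanning the central fraction of each pass and peaking exactly at
    the aperture crossing with the trial's true rotation angle; the bump's
    sign is the participant's fixed rotation side.  All ten markers ride on
    one rigid trunk/pelvis body, so within-segment distances are constant to
    machine precision.
    """
    geo = geometry or GeometryConfig()
    seq = sequence_outcomes.sort_values("trial_index_in_sequence")
    if seq["sequence_index_global"].nunique() != 1:
        raise DesignError("outcomes must belong to a single sequence")
    n_trials = len(seq)
    fs = geo.sampling_rate_hz
    n = int(round(geo.trial_duration_s * fs))
    walk_mm = geo.walkway_length_m * 1000.0
    template = _marker_template(participant, geo)

    tau = (np.arange(n) + 0.5) / n  # pass phase in (0, 1)
    progress = 0.5 * (1.0 - np.cos(np.pi * tau))
    half = geo.yaw_bump_fraction / 2.0
    bump = np.where(
        np.abs(tau - 0.5) <= half,
        0.5 * (1.0 + np.cos(2.0 * np.pi * (tau - 0.5) / geo.yaw_bump_fraction)),
        0.0,
    )

    y_parts, phi_parts = [], []
    for k, (_, trial) in enumerate(seq.iterrows()):
        forward = k % 2 == 0
        y0, y1 = (0.0, walk_mm) if forward else (walk_mm, 0.0)
        y_parts.append(y0 + (y1 - y0) * progress)
        yaw = math.radians(participant.rotation_side * trial["true_alpha_deg"]) * bump
        phi_parts.append(yaw if forward else math.pi + yaw)
    y = np.concatenate(y_parts)
    phi = np.concatenate(phi_parts)

    c, s = np.cos(phi), np.sin(phi)
    positions = {}
    for m, name in enumerate(MARKER_NAMES):
        bx, by, bz = template[m]
        positions[name] = np.column_stack(
            [c * bx - s * by, s * bx + c * by + y, np.full(y.shape, bz)]
        )
    time_s = np.arange(n * n_trials) / fs
    return MarkerTrajectory(
        participant_id=participant.participant_id,
        task_id=str(seq["task_id"].iloc[0]),
        sequence_index_global=int(seq["sequence_index_global"].iloc[0]),
        sampling_rate_hz=fs,
        time_s=time_s,
        positions=positions,
    )


# ---------------------------------------------------------------------------
# whole-study convenience
# ---------------------------------------------------------------------------

def simulate_experiment(
    experiment_id: str,
    truth: GeneratorTruth,
    n_participants: int,
    seed: int,
    anthropometry: AnthropometryConfig | None = None,
    participant_prefix: str | None = None,
) -> SimulatedExperiment:
    """Simulate one experiment end to end (without marker trajectories).

    Each participant receives an individually drawn sequence plan, as in the
    original protocol.  The anthropometry's ``sigma_u`` is overridden by the
    truth's random-intercept scale so the cohort matches the posture law.
    """
    design = build_design(experiment_id)
    cfg = replace(anthropometry or AnthropometryConfig(), sigma_u=truth.sigma_u)
    ss = np.random.SeedSequence(seed)
    part_seed, plan_seed, trial_seed = (
        int(s) % 2**31 for s in ss.generate_state(3)
    )
    prefix = participant_prefix or ("r" if experiment_id == "exp1" else "v")
    participants = sample_participants(n_participants, cfg, part_seed, prefix=prefix)
    plans: dict[str, list[SequencePlan]] = {}
    tables = []
    for i, part in enumerate(participants):
        plans[part.participant_id] = plan_sequences(design, plan_seed + i)
        tables.append(
            simulate_trial_outcomes(
                truth, plans[part.participant_id], [part], design, trial_seed + i
            )
        )
    trials = pd.concat(tables, ignore_index=True)
    return SimulatedExperiment(design, truth, participants, plans, trials)


def simulate_combined_study(
    truth: GeneratorTruth,
    n_exp1: int,
    n_exp2: int,
    seed: int,
    anthropometry: AnthropometryConfig | None = None,
    failure_rate_exp2: float = 0.065,
) -> tuple[SimulatedExperiment, SimulatedExperiment]:
    """Simulate both environments from one truth (the ``combined`` preset).

    The virtual-environment half uses its own documented per-trial failure
    rate; everything else is shared.
    """
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(s) % 2**31 for s in ss.generate_state(2))
    exp1 = simulate_experiment("exp1", truth, n_exp1, s1, anthropometry)
    truth2 = replace(truth, failure_rate=failure_rate_exp2)
    exp2 = simulate_experiment("exp2", truth2, n_exp2, s2, anthropometry)
    return exp1, exp2


def participants_frame(participants: Sequence[ParticipantProfile], experiment_id: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in participants],
            "shoulder_width_cm": [p.shoulder_width_cm for p in participants],
            "hip_width_cm": [p.hip_width_cm for p in participants],
            "experiment": [_EXPERIMENT_LABEL[experiment_id]] * len(participants),
        }
    )
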