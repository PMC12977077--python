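"""File formats: marker CSV dialect, trial tables, fits, and run configs.

Marker trajectories are stored as wide CSV, one file per participant x task
x sequence (``{participant}_{task}_{seq}.csv``), with columns ``frame,
time_s, LAC_x, LAC_y, LAC_z, ..., RPSI_z`` in millimetres.  All round trips
are lossless to full float precision (values serialized with repr).
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .posture_model import FitResult, posture_spec
from .synthgen import MARKER_NAMES, MarkerTrajectory

MARKER_COLUMNS = ["frame", "time_s"] + [
    f"{m}_{axis}" for m in MARKER_NAMES for axis in "xyz"
]

_TRIAL_LEVELS = {
    "condition": {"randomized", "ordered"},
    "experiment": {"real", "virtual"},
}

_FILENAME_RE = re.compile(r"^(?P<participant>[^_]+)_(?P<task>[^_]+)_(?P<seq>\d+)\.csv$")


def marker_filename(trajectory: MarkerTrajectory) -> str:
    return (
        f"{trajectory.participant_id}_{trajectory.task_id}_"
        f"{trajectory.sequence_index_global}.csv"
    )


def write_marker_csv(trajectory: MarkerTrajectory, path: str | Path) -> Path:
    path = Path(path)
    data = {"frame": np.arange(trajectory.n_frames), "time_s": trajectory.time_s}
    for m in MARKER_NAMES:
        pos = trajectory.positions[m]
        for k, axis in enumerate("xyz"):
            data[f"{m}_{axis}"] = pos[:, k]
    pd.DataFrame(data)[MARKER_COLUMNS].to_csv(
        path, index=False, float_format="%.17g"
    )
    return path


def read_marker_csv(
    path: str | Path,
    participant_id: str | None = None,
    task_id: str | None = None,
    sequence_index_global: int | None = None,
) -> MarkerTrajectory:
    """Read one marker file; metadata defaults to the filename pattern."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing}")
    values = df[MARKER_COLUMNS[1:]].to_numpy(float)
    if not np.all(np.isfinite(values)):
        raise SchemaError(f"{path.name}: non-finite positions or times")
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) <= 0):
        raise SchemaError(f"{path.name}: time not strictly increasing")
    if participant_id is None or task_id is None or sequence_index_global is None:
        m = _FILENAME_RE.match(path.name)
        if m is None:
            raise SchemaError(
                f"{path.name}: cannot infer metadata; expected "
                "{participant}_{task}_{seq}.csv"
            )
        participant_id = participant_id or m["participant"]
        task_id = task_id or m["task"]
        sequence_index_global = sequence_index_global or int(m["seq"])
    fs = 1.0 / float(np.median(np.diff(t)))
    positions = {
        m: df[[f"{m}_x", f"{m}_y", f"{m}_z"]].to_numpy(float) for m in MARKER_NAMES
    }
    return MarkerTrajectory(
        participant_id=participant_id,
        task_id=task_id,
        sequence_index_global=sequence_index_global,
        sampling_rate_hz=round(fs, 6),
        time_s=t,
        positions=positions,
    )


def write_trials_csv(trials: pd.DataFrame, path: str | Path) -> Path:
    """Write the generator trial table; true (unobservable) values get a
    ``truth_`` prefix so downstream consumers cannot mistake them for data."""
    out = trials.rename(
        columns={
            "lp": "truth_lp",
            "true_scaled_rotation": "truth_scaled_rotation",
            "true_alpha_deg": "truth_alpha_deg",
        }
    )
    out.to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _validate_levels(df, Path(path).name)
    return df.rename(
        columns={
            "truth_lp": "lp",
            "truth_scaled_rotation": "true_scaled_rotation",
            "truth_alpha_deg": "true_alpha_deg",
        }
    )


def _validate_levels(df: pd.DataFrame, name: str) -> None:
    for col, levels in _TRIAL_LEVELS.items():
        if col in df.columns:
            bad = set(df[col].dropna().unique()) - levels
            if bad:
                raise SchemaError(f"{name}: unknown {col} level(s) {sorted(bad)}")


def write_trial_table_csv(table: pd.DataFrame, path: str | Path) -> Path:
    table.to_csv(path, index=False, float_format="%.17g")
    return Path(path)


def read_trial_table_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _validate_levels(df, Path(path).name)
    if "excluded" in df.columns:
        df["excluded"] = df["excluded"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# fit serialization
# ---------------------------------------------------------------------------

def fit_to_dict(
    fit: FitResult,
    segment: str,
    centering_mean: float,
    n_sequences: int | None = None,
    extra: dict | None = None,
) -> dict:
    d = {
        "analysis": fit.spec.analysis_id,
        "segment": segment,
        "effects": list(fit.names),
        "coefficients": fit.coefficients,
        "standard_errors": fit.standard_errors,
        "wald_z": fit.wald_z,
        "p_values": fit.p_values,
        "odds_ratios": fit.odds_ratios_,
        "sigma_u": fit.sigma_u,
        "sigma_eps": fit.sigma_eps,
        "log_likelihood": fit.log_likelihood,
        "bic": fit.bic,
        "n_obs": fit.n_obs,
        "n_groups": fit.n_groups,
        "converged": fit.converged,
        "centering_mean": centering_mean,
        "n_sequences": n_sequences,
    }
    if extra:
        d.update(extra)
    return d


def fit_from_dict(d: dict) -> tuple[FitResult, str, float, int | None]:
    spec = posture_spec(d["analysis"])
    fit = FitResult(
        spec=spec,
        names=tuple(d["effects"]),
        coefficients=d["coefficients"],
        standard_errors=d["standard_errors"],
        wald_z=d["wald_z"],
        p_values=d["p_values"],
        sigma_u=d["sigma_u"],
        sigma_eps=d["sigma_eps"],
        log_likelihood=d["log_likelihood"],
        bic=d["bic"],
        n_obs=d["n_obs"],
        n_groups=d["n_groups"],
        converged=d["converged"],
    )
    return fit, d["segment"], d["centering_mean"], d.get("n_sequences")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    seed: int = 0
    preset: str = "combined"
    n_participants: dict = field(default_factory=lambda: {"exp1": 27, "exp2": 21})
    analyses: tuple[str, ...] = ("combined",)
    segments: tuple[str, ...] = ("shoulder", "thorax", "pelvis")
    trajectories: bool = True
    write_markers: bool = False
    compute_r2: bool = True
    n_quad: int = 9
    n_restarts: int = 3

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in d.items() if k in known})
        cfg.analyses = tuple(cfg.analyses)
        cfg.segments = tuple(cfg.segments)
        for a in cfg.analyses:
            if a not in ("combined", "feedback", "exp1"):
                raise SchemaError(f"unknown analysis {a!r}")
        for s in cfg.segments:
            if s not in ("shoulder", "thorax", "pelvis"):
                raise SchemaError(f"unknown segment {s!r}")
        if not isinstance(cfg.seed, int):
            raise SchemaError("seed must be an integer")
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["analyses"] = list(self.analyses)
        d["segments"] = list(self.segments)
        return d


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(json.load(fh))


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
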