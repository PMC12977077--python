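"""End-to-end orchestration: simulate -> extract -> prepare -> fit -> report.

Every stage draws its randomness from a seed derived from the run seed, and
every artifact written embeds the configuration hash and the seeds used, so
a rerun with the same configuration reproduces the outputs exactly.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as apio
from .errors import ConvergenceError
from .posture_model import fit_posture_model, posture_spec
from .synthgen import (
    GeometryConfig,
    SimulatedExperiment,
    participants_frame,
    preset,
    simulate_combined_study,
    simulate_experiment,
    synthesize_marker_trajectory,
)
from .kinematics import extract_sequence_angles
from .thresholds import threshold_table, per_sequence_fatigue_shift
from .trialprep import prepare_trials, truth_angles_frame
from .variance import VARIANCE_FACTORS, aggregate_sds, fit_variance_model

_ANALYSIS_EXPERIMENTS = {
    "combined": ("exp1", "exp2"),
    "feedback": ("exp2",),
    "exp1": ("exp1",),
}

_FATIGUE_SEQUENCES = {"combined": None, "feedback": 24, "exp1": 15}


def simulate_study(config: apio.RunConfig) -> dict[str, SimulatedExperiment]:
    """Simulate the experiments required by the configured analyses."""
    needed = sorted({e for a in config.analyses for e in _ANALYSIS_EXPERIMENTS[a]})
    truth = preset(config.preset)
    sims: dict[str, SimulatedExperiment] = {}
    if needed == ["exp1", "exp2"]:
        sims["exp1"], sims["exp2"] = simulate_combined_study(
            truth,
            config.n_participants["exp1"],
            config.n_participants["exp2"],
            config.seed,
        )
    else:
        for i, e in enumerate(needed):
            sims[e] = simulate_experiment(
                e, truth, config.n_participants[e], config.seed + i
            )
    return sims


def extract_study_angles(
    sims: dict[str, SimulatedExperiment],
    geometry: GeometryConfig | None = None,
    markers_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Synthesize marker trajectories sequence by sequence and run the
    kinematics extraction on each; optionally persist the marker CSVs."""
    geo = geometry or GeometryConfig()
    aperture_y_mm = geo.aperture_y_m * 1000.0
    if markers_dir is not None:
        markers_dir = Path(markers_dir)
        markers_dir.mkdir(parents=True, exist_ok=True)
    frames = []
    for sim in sims.values():
        by_part = {p.participant_id: p for p in sim.participants}
        for (pid, gseq), seq_rows in sim.trials.groupby(
            ["participant_id", "sequence_index_global"], sort=True
        ):
            traj = synthesize_marker_trajectory(by_part[pid], seq_rows, geo)
            if markers_dir is not None:
                apio.write_marker_csv(traj, markers_dir / apio.marker_filename(traj))
            frames.append(extract_sequence_angles(traj, aperture_y_mm))
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: apio.RunConfig, out_dir: str | Path) -> dict:
    """Run the full analysis and write the report bundle.

    Produces, per analysis and segment, the posture fit table, the
    thresholds report, and the variance-model comparison, plus the
    exclusions audit and a run-metadata file.  Raises
    :class:`ConvergenceError` if any posture fit fails to converge.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = apio.config_hash(config)
    meta = {"config": config.to_dict(), "config_hash": chash, "timings_s": {}}
    bundle: dict = {"config_hash": chash, "analyses": {}}

    t0 = time.perf_counter()
    sims = simulate_study(config)
    participants = pd.concat(
        [participants_frame(s.participants, e) for e, s in sims.items()],
        ignore_index=True,
    )
    trials = pd.concat([s.trials for s in sims.values()], ignore_index=True)
    participants.to_csv(out / "participants.csv", index=False)
    apio.write_trials_csv(trials, out / "trials.csv")
    meta["timings_s"]["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if config.trajectories:
        angles = extract_study_angles(
            sims, markers_dir=(out / "markers") if config.write_markers else None
        )
    else:
        angles = truth_angles_frame(trials)
    angles.to_csv(out / "angles.csv", index=False)
    meta["timings_s"]["extract"] = time.perf_counter() - t0

    n_seq_by_exp = {
        ("real" if e == "exp1" else "virtual"): s.design.n_sequences_total
        for e, s in sims.items()
    }

    for analysis in config.analyses:
        t0 = time.perf_counter()
        prepared = prepare_trials(angles, trials, participants, analysis, n_seq_by_exp)
        apio.write_trial_table_csv(prepared.table, out / f"table_{analysis}.csv")
        apio.write_json(
            {"config_hash": chash, "audit": prepared.audit,
             "centering_means": prepared.centering_means},
            out / f"audit_{analysis}.json",
        )
        spec = posture_spec(analysis)
        ana: dict = {"audit": prepared.audit, "segments": {}}
        sd_rows, sd_audit = aggregate_sds(
            prepared.table, VARIANCE_FACTORS[analysis]
        )
        for segment in config.segments:
            seg_table = prepared.table[prepared.table["segment"] == segment]
            fit = fit_posture_model(
                seg_table, spec, n_quad=config.n_quad, n_restarts=config.n_restarts
            )
            if not fit.converged:
                raise ConvergenceError(
                    f"posture fit did not converge ({analysis}/{segment})"
                )
            mean = prepared.centering_means[segment]
            n_seq = _FATIGUE_SEQUENCES[analysis]
            fit_dict = apio.fit_to_dict(
                fit, segment, mean, n_seq, extra={"config_hash": chash}
            )
            apio.write_json(fit_dict, out / f"fit_{analysis}_{segment}.json")
            fit.summary_frame().round(3).to_csv(
                out / f"fit_{analysis}_{segment}.csv", index=False
            )
            thr = threshold_table(fit, mean, n_seq)
            thr.round(4).to_csv(
                out / f"thresholds_{analysis}_{segment}.csv", index=False
            )
            thr_json = {
                "config_hash": chash,
                "rows": thr.to_dict("records"),
            }
            if n_seq is not None and "fatigue" in fit.coefficients:
                thr_json["per_sequence_fatigue_shift_pct"] = (
                    per_sequence_fatigue_shift(fit, n_seq)
                )
            apio.write_json(thr_json, out / f"thresholds_{analysis}_{segment}.json")

            seg_sd = sd_rows[sd_rows["segment"] == segment]
            lin, expd = fit_variance_model(
                seg_sd, analysis, fit, compute_r2=config.compute_r2
            )
            lin.summary_frame().round(4).to_csv(
                out / f"variance_{analysis}_{segment}.csv", index=False
            )
            apio.write_json(
                {
                    "config_hash": chash,
                    "bic_linear": lin.bic,
                    "bic_expanded": expd.bic,
                    "preferred": "expanded" if expd.bic < lin.bic else "linear",
                    "sd_audit": sd_audit,
                },
                out / f"variance_comparison_{analysis}_{segment}.json",
            )
            ana["segments"][segment] = {
                "fit": fit,
                "centering_mean": mean,
                "thresholds": thr,
                "variance_linear": lin,
                "variance_expanded": expd,
            }
        bundle["analyses"][analysis] = ana
        meta["timings_s"][f"analysis_{analysis}"] = time.perf_counter() - t0

    apio.write_json(meta, out / "run_meta.json")
    bundle["meta"] = meta
    return bundle
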