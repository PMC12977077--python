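"""Segment kinematics: from marker trajectories to rotation angles at passes.

Three horizontal direction vectors define the orientation of the shoulder
girdle, thorax, and pelvis: the shoulder vector connects the left to the
right acromion; thorax and pelvis vectors are the cross products of
forward-pointing support vectors with the global vertical, which places them
in the floor plane.  The rotation angle ``alpha`` of a segment is the
absolute four-quadrant angle of its direction vector's floor projection,
evaluated at the frame where the segment center is closest (in the walking
direction) to the aperture; 0 deg means passing squarely, 90 deg fully
sideways.  Because the recording covers back-and-forth walking, the
direction vector is negated for passes toward the start position so that a
straight pass reads 0 deg in both directions.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import GeometryError, MarkerError, PassDetectionError
from .synthgen import MARKER_NAMES, MarkerTrajectory

Z_AXIS = np.array([0.0, 0.0, 1.0])

_SEGMENT_MARKERS = {
    "shoulder": ("LAC", "RAC"),
    "thorax": ("C7", "T8", "IJ", "PX"),
    "pelvis": ("LASI", "RASI", "LPSI", "RPSI"),
}


def _get(positions: Mapping[str, np.ndarray], name: str) -> np.ndarray:
    try:
        p = np.asarray(positions[name], dtype=float)
    except KeyError:
        raise MarkerError(f"missing marker {name!r}") from None
    if not np.all(np.isfinite(p)):
        raise MarkerError(f"marker {name!r} has non-finite coordinates")
    return p


def segment_centers(
    positions: Mapping[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(SC, TC, PC): shoulder = acromion midpoint, thorax and pelvis the
    means of their four markers.  Accepts single frames (3,) or series
    (n, 3)."""
    for name in MARKER_NAMES:
        _get(positions, name)
    sc = (_get(positions, "LAC") + _get(positions, "RAC")) / 2.0
    tc = (
        _get(positions, "PX") + _get(positions, "IJ")
        + _get(positions, "C7") + _get(positions, "T8")
    ) / 4.0
    pc = (
        _get(positions, "LASI") + _get(positions, "RASI")
        + _get(positions, "LPSI") + _get(positions, "RPSI")
    ) / 4.0
    return sc, tc, pc


def segment_direction_vectors(
    positions: Mapping[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(v_shoulder, v_thorax, v_pelvis).

    v_shoulder = RAC - LAC.  For thorax/pelvis a forward support vector s is
    crossed with the vertical: v = s x z, which lies in the x-y plane.
    """
    v_sh = _get(positions, "RAC") - _get(positions, "LAC")
    s_th = (
        (_get(positions, "PX") + _get(positions, "IJ")) / 2.0
        - (_get(positions, "C7") + _get(positions, "T8")) / 2.0
    )
    s_pe = (
        (_get(positions, "LASI") + _get(positions, "RASI")) / 2.0
        - (_get(positions, "LPSI") + _get(positions, "RPSI")) / 2.0
    )
    for name, s in (("thorax", s_th), ("pelvis", s_pe)):
        horiz = np.linalg.norm(np.atleast_2d(s)[..., :2], axis=-1)
        if np.any(horiz < 1e-9):
            raise GeometryError(f"degenerate {name} support vector (no horizontal component)")
    v_th = np.cross(s_th, Z_AXIS)
    v_pe = np.cross(s_pe, Z_AXIS)
    return v_sh, v_th, v_pe


def detect_aperture_passes(
    y: np.ndarray,
    aperture_y: float,
    expected_count: int,
    sampling_rate_hz: float = 100.0,
    smooth_window: int = 5,
    min_separation_s: float = 1.0,
) -> np.ndarray:
    """Frame indices of the local minima of |y - aperture_y|.

    The distance series is smoothed with a short moving average and minima
    closer than ``min_separation_s`` are suppressed (keeping the deeper one).
    Exactly ``expected_count`` minima must remain, one per aperture pass.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("need a 1-D series of at least 3 samples")
    if expected_count < 1:
        raise ValueError("expected_count must be >= 1")
    d = np.abs(y - aperture_y)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        d = np.convolve(d, kernel, mode="same")
    distance = max(1, int(round(min_separation_s * sampling_rate_hz)))
    idx, _ = find_peaks(-d, distance=distance)
    if len(idx) != expected_count:
        raise PassDetectionError(len(idx), expected_count)
    return idx


def rotation_angle_at_pass(v: np.ndarray, walk_direction: int) -> float:
    """Absolute rotation angle (deg) of direction vector ``v`` at a pass.

    For passes toward -y the vector is negated first, so straight walking
    reads 0 deg regardless of travel direction.
    """
    v = np.asarray(v, dtype=float)
    if walk_direction < 0:
        v = -v
    vx, vy = float(v[0]), float(v[1])
    if vx == 0.0 and vy == 0.0:
        raise GeometryError("direction vector has no floor-plane projection")
    return float(abs(np.degrees(np.arctan2(vy, vx))))


def extract_sequence_angles(
    trajectory: MarkerTrajectory,
    aperture_y_mm: float,
    expected_count: int = 9,
    smooth_window: int = 5,
    min_separation_s: float = 1.0,
) -> pd.DataFrame:
    """Per-segment pass events for one recorded sequence.

    Passes are detected per segment on that segment's own center series, the
    walk direction is inferred from the center velocity just before the pass
    frame, and the rotation angle is evaluated at the pass frame.  Returns a
    tidy frame with columns participant_id, task_id, sequence_index_global,
    segment, trial_index_in_sequence, frame_index, walk_direction, alpha_deg.
    """
    centers = dict(
        zip(("shoulder", "thorax", "pelvis"), segment_centers(trajectory.positions))
    )
    v_all = dict(
        zip(
            ("shoulder", "thorax", "pelvis"),
            segment_direction_vectors(trajectory.positions),
        )
    )
    rows = []
    for segment in ("shoulder", "thorax", "pelvis"):
        y = centers[segment][:, 1]
        passes = detect_aperture_passes(
            y,
            aperture_y_mm,
            expected_count,
            trajectory.sampling_rate_hz,
            smooth_window,
            min_separation_s,
        )
        for trial, frame in enumerate(passes, start=1):
            lo = max(0, frame - 5)
            dy = y[frame] - y[lo] if frame > lo else y[frame + 1] - y[frame]
            direction = +1 if dy >= 0 else -1
            alpha = rotation_angle_at_pass(v_all[segment][frame], direction)
            rows.append(
                (
                    trajectory.participant_id,
                    trajectory.task_id,
                    trajectory.sequence_index_global,
                    segment,
                    trial,
                    int(frame),
                    direction,
                    alpha,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id", "task_id", "sequence_index_global", "segment",
            "trial_index_in_sequence", "frame_index", "walk_direction",
            "alpha_deg",
        ],
    )
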