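"""Offline velocity-threshold saccade detection on raw 1 kHz gaze traces.

The cascade mirrors the standard EyeLink-style offline pipeline:

1. blink gaps (invalid samples) are absorbed outward while the surrounding
   speed exceeds 30 °/s, then filled by cubic-spline interpolation;
2. the trace is smoothed with a 3rd-order Savitzky-Golay filter, window 15;
3. speed is the first derivative of position (first differences × 1000);
4. saccade onset requires speed > 30 °/s sustained for at least 10 ms;
   completion is the first sample back below 30 °/s;
5. candidates are filtered on amplitude (1°–40°), duration (> 15 ms),
   initial speed (< 0.075 °/ms), terminal speed (< 0.3 °/ms) and the
   first-quartile velocity criterion (≥ 0.15 × peak), which discards
   pursuit-like movements with uniformly low early velocity;
6. accepted saccades get their *raw* (unsmoothed) trajectory back — a
   real-time consumer would only ever see raw samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

from .trace import GazeTrace, Saccade

__all__ = [
    "DetectionParams",
    "interpolate_blinks",
    "smooth_trace",
    "compute_speed",
    "detect_saccades",
    "filter_saccades",
    "restore_raw",
    "run_detection",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds of the detection cascade (speeds in °/s unless noted)."""

    sg_order: int = 3
    sg_window: int = 15
    speed_on: float = 30.0      # onset threshold
    min_on_ms: int = 10         # sustained suprathreshold duration at onset
    speed_off: float = 30.0     # completion threshold
    amp_min: float = 1.0
    amp_max: float = 40.0
    dur_min: int = 15
    v_init_max: float = 75.0    # 0.075 °/ms
    v_term_max: float = 300.0   # 0.3 °/ms
    q1_peak_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_order:
            raise ValueError("sg_window must be odd and larger than sg_order")
        for name in ("speed_on", "min_on_ms", "speed_off", "amp_min", "amp_max",
                     "dur_min", "v_init_max", "v_term_max", "q1_peak_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _instantaneous_speed(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-sample speed (°/s); index i holds the speed of the step into
    sample i, with the first entry duplicating the second."""
    speed = np.empty(len(x))
    if len(x) < 2:
        speed[:] = 0.0
        return speed
    speed[1:] = np.hypot(np.diff(x), np.diff(y)) * 1000.0
    speed[0] = speed[1]
    return speed


def interpolate_blinks(trace: GazeTrace,
                       params: DetectionParams = DetectionParams()) -> GazeTrace:
    """Fill blink/track-loss gaps with cubic splines.

    Samples flanking each gap are first absorbed into it, expanding outward
    sample-by-sample while the instantaneous speed on that side exceeds the
    30 °/s threshold (blink artefacts produce spurious high-velocity
    excursions).  Gaps touching the trace boundary cannot be interpolated
    and are dropped with a warning.  The returned trace is fully valid.
    """
    if trace.valid.all():
        return trace
    valid = trace.valid.copy()
    n = len(trace)
    speed = _instantaneous_speed(trace.x, trace.y)
    invalid_runs = _bool_runs(~valid)
    for start, stop in invalid_runs:  # stop is exclusive
        # speed[i] is the step from sample i-1 into sample i; only steps
        # between two originally-valid samples are meaningful here
        left = start - 1
        while left >= 1 and speed[left] > params.speed_on:
            valid[left] = False
            left -= 1
        right = stop
        while right < n - 1 and speed[right + 1] > params.speed_on:
            valid[right] = False
            right += 1

    keep = slice(0, n)
    if not valid[0] or not valid[-1]:
        good = np.flatnonzero(valid)
        if len(good) == 0:
            raise ValueError("trace has no valid samples to interpolate from")
        keep = slice(int(good[0]), int(good[-1]) + 1)
        logger.warning(
            "dropping %d boundary samples with no flanking valid data",
            n - (keep.stop - keep.start),
        )
    t = trace.t[keep]
    x = trace.x[keep].copy()
    y = trace.y[keep].copy()
    v = valid[keep]
    if not v.all():
        cs_x = CubicSpline(t[v], x[v])
        cs_y = CubicSpline(t[v], y[v])
        x[~v] = cs_x(t[~v])
        y[~v] = cs_y(t[~v])
    return GazeTrace(t=t, x=x, y=y, valid=np.ones(len(t), dtype=bool),
                     participant_id=trace.participant_id,
                     stimulus_id=trace.stimulus_id, screen=trace.screen)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index pairs of the True runs of a boolean mask."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def smooth_trace(trace: GazeTrace,
                 params: DetectionParams = DetectionParams()) -> GazeTrace:
    """Savitzky-Golay smoothing of x and y independently (order 3, window
    15 by default; reflective boundary padding).  Length is preserved."""
    if len(trace) < params.sg_window:
        raise ValueError(
            f"trace length {len(trace)} shorter than the filter window "
            f"{params.sg_window}"
        )
    x = savgol_filter(trace.x, params.sg_window, params.sg_order, mode="mirror")
    y = savgol_filter(trace.y, params.sg_window, params.sg_order, mode="mirror")
    return GazeTrace(t=trace.t, x=x, y=y, valid=trace.valid.copy(),
                     participant_id=trace.participant_id,
                     stimulus_id=trace.stimulus_id, screen=trace.screen)


def compute_speed(trace: GazeTrace) -> np.ndarray:
    """Per-sample speed sequence in °/s from first differences."""
    if len(trace) < 2:
        raise ValueError("speed needs at least 2 samples")
    return _instantaneous_speed(trace.x, trace.y)


def detect_saccades(trace: GazeTrace,
                    params: DetectionParams = DetectionParams()) -> list[Saccade]:
    """Candidate saccades: maximal runs with speed > 30 °/s whose first
    10 ms all exceed the threshold.

    The onset is the first suprathreshold sample and the offset the first
    subthreshold sample after it; the candidate trajectory spans
    [onset, offset] inclusive.  The trace should already be
    blink-interpolated and smoothed.
    """
    speed = compute_speed(trace)
    out: list[Saccade] = []
    for start, stop in _bool_runs(speed > params.speed_on):
        if stop - start < params.min_on_ms:
            continue
        offset = stop  # first subthreshold sample after the run
        if offset >= len(trace):
            continue  # saccade still in flight at trace end
        traj = np.column_stack(
            [trace.x[start:offset + 1], trace.y[start:offset + 1]]
        )
        out.append(
            Saccade(trajectory=traj, participant_id=trace.participant_id,
                    stimulus_id=trace.stimulus_id,
                    onset_ms=int(trace.t[start]))
        )
    return out


def _quartile_index(duration: int) -> int:
    return int(round(duration / 4.0))


def saccade_passes_filters(s: Saccade,
                           params: DetectionParams = DetectionParams()) -> bool:
    """The six acceptance predicates applied to one candidate."""
    speed = _instantaneous_speed(s.trajectory[:, 0], s.trajectory[:, 1])
    m = s.duration_ms
    peak = speed.max()
    q1 = speed[_quartile_index(m)]
    return (
        params.amp_min < s.amplitude_deg < params.amp_max
        and m > params.dur_min
        and speed[0] < params.v_init_max
        and speed[-1] < params.v_term_max
        and q1 >= params.q1_peak_frac * peak
    )


def filter_saccades(candidates: list[Saccade],
                    params: DetectionParams = DetectionParams()) -> list[Saccade]:
    """Keep candidates with 1° < d < 40°, duration > 15 ms, initial speed
    < 75 °/s, terminal speed < 300 °/s and first-quartile speed ≥ 0.15 ×
    peak speed."""
    return [s for s in candidates if saccade_passes_filters(s, params)]


def restore_raw(accepted: list[Saccade], raw_trace: GazeTrace) -> list[Saccade]:
    """Swap each accepted saccade's smoothed trajectory for the raw samples
    over [onset, offset]; landing/amplitude/direction are recomputed."""
    t0 = int(raw_trace.t[0])
    out: list[Saccade] = []
    for s in accepted:
        i0 = s.onset_ms - t0
        i1 = i0 + s.duration_ms
        if i0 < 0 or i1 >= len(raw_trace):
            raise RuntimeError("saccade indices fall outside the raw trace")
        traj = np.column_stack([raw_trace.x[i0:i1 + 1], raw_trace.y[i0:i1 + 1]])
        out.append(
            Saccade(trajectory=traj, participant_id=s.participant_id,
                    stimulus_id=s.stimulus_id, onset_ms=s.onset_ms)
        )
    return out


def run_detection(trace: GazeTrace,
                  params: DetectionParams = DetectionParams()) -> list[Saccade]:
    """Full cascade: blink interpolation → smoothing → detection →
    filtering → raw-trajectory restoration."""
    interpolated = interpolate_blinks(trace, params)
    smoothed = smooth_trace(interpolated, params)
    candidates = detect_saccades(smoothed, params)
    accepted = filter_saccades(candidates, params)
    restored = restore_raw(accepted, interpolated)
    logger.info(
        "detection: %d candidates, %d accepted after filters", len(candidates),
        len(accepted),
    )
    return restored
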