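"""Gaze-trace and saccade data model, units, and CSV I/O.

Conventions used throughout the package:

* Gaze position is expressed in **degrees of visual angle**, with the origin
  at the screen centre, x increasing rightward and y increasing upward.
* Time is integer **milliseconds** at exactly 1 kHz: consecutive samples of a
  trace differ by 1 ms.
* A saccade's *amplitude* is the straight-line distance between its onset and
  landing points (not the path length); its *direction* is the atan2 angle of
  the onset→landing displacement in (−π, π].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScreenGeometry",
    "GazeTrace",
    "Saccade",
    "ParticipantMeta",
    "StimulusMeta",
    "FormatError",
    "DataError",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_saccade_table",
    "write_saccade_table",
]

#: Decimal precision (degrees) guaranteed to survive a CSV round trip.
CSV_PRECISION = 6

GAZE_COLUMNS = ["t_ms", "x_deg", "y_deg", "valid"]
SACCADE_COLUMNS = [
    "participant_id",
    "stimulus_id",
    "onset_ms",
    "duration_ms",
    "x1",
    "y1",
    "xM",
    "yM",
    "amplitude_deg",
    "direction_rad",
    "peak_speed_dps",
]
TRAJECTORY_COLUMNS = ["saccade_index", "t_ms", "x_deg", "y_deg"]


class FormatError(ValueError):
    """A file does not have the expected columns/structure."""


class DataError(ValueError):
    """A file parses but violates a data invariant (gaps, ranges, order)."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Viewing area in degrees of visual angle, centred on the origin."""

    width_deg: float = 33.0
    height_deg: float = 19.0

    def __post_init__(self) -> None:
        if self.width_deg <= 0 or self.height_deg <= 0:
            raise ValueError("screen extents must be positive")

    @property
    def x_range(self) -> tuple[float, float]:
        return (-self.width_deg / 2.0, self.width_deg / 2.0)

    @property
    def y_range(self) -> tuple[float, float]:
        return (-self.height_deg / 2.0, self.height_deg / 2.0)

    def contains(self, x: float, y: float) -> bool:
        return (
            self.x_range[0] <= x <= self.x_range[1]
            and self.y_range[0] <= y <= self.y_range[1]
        )


@dataclass
class GazeTrace:
    """One 1 kHz viewing session: arrays ``t`` (int ms), ``x``/``y`` (deg),
    ``valid`` (False during blinks or track loss)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    participant_id: str = "p0"
    stimulus_id: str = "s0"
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise DataError("t, x, y, valid must have equal length")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise DataError("timestamps must be strictly increasing")
            if np.any(dt != 1):
                raise DataError("gaze trace must be sampled at exactly 1 kHz (1 ms steps)")
        if n and np.any(~np.isfinite(self.x[self.valid])):
            raise DataError("x must be finite where valid")
        if n and np.any(~np.isfinite(self.y[self.valid])):
            raise DataError("y must be finite where valid")

    def __len__(self) -> int:
        return len(self.t)

    def positions(self) -> np.ndarray:
        """(n, 2) array of x/y samples."""
        return np.column_stack([self.x, self.y])

    def copy(self) -> "GazeTrace":
        return GazeTrace(
            t=self.t.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            valid=self.valid.copy(),
            participant_id=self.participant_id,
            stimulus_id=self.stimulus_id,
            screen=self.screen,
        )


def _trajectory_fields(trajectory: np.ndarray) -> tuple:
    onset = (float(trajectory[0, 0]), float(trajectory[0, 1]))
    landing = (float(trajectory[-1, 0]), float(trajectory[-1, 1]))
    dx = landing[0] - onset[0]
    dy = landing[1] - onset[1]
    amplitude = math.hypot(dx, dy)
    direction = math.atan2(dy, dx)
    steps = np.diff(trajectory, axis=0)
    if len(steps):
        peak_speed = float(np.max(np.hypot(steps[:, 0], steps[:, 1])) * 1000.0)
    else:
        peak_speed = 0.0
    return onset, landing, amplitude, direction, peak_speed


@dataclass
class Saccade:
    """One detected or simulated saccade.

    ``trajectory`` holds the (x, y) samples at 1 ms steps from the onset
    sample to the landing sample inclusive; ``duration_ms`` therefore equals
    ``len(trajectory) - 1``.  Summary fields (onset, landing, amplitude,
    direction, peak speed) are derived from the trajectory when one is given.
    """

    trajectory: np.ndarray | None = None
    onset: tuple[float, float] = (0.0, 0.0)
    landing: tuple[float, float] = (0.0, 0.0)
    duration_ms: int = 0
    amplitude_deg: float = 0.0
    direction_rad: float = 0.0
    peak_speed_dps: float = 0.0
    participant_id: str = "p0"
    stimulus_id: str = "s0"
    onset_ms: int = 0

    def __post_init__(self) -> None:
        if self.trajectory is not None:
            self.trajectory = np.asarray(self.trajectory, dtype=np.float64)
            if self.trajectory.ndim != 2 or self.trajectory.shape[1] != 2:
                raise DataError("trajectory must be an (n, 2) array")
            if len(self.trajectory) < 2:
                raise DataError("trajectory needs at least 2 samples")
            (self.onset, self.landing, self.amplitude_deg,
             self.direction_rad, self.peak_speed_dps) = _trajectory_fields(self.trajectory)
            self.duration_ms = len(self.trajectory) - 1

    def validate_filtered(self) -> None:
        """Check the invariants that hold for any saccade that passed the
        detection filters (1° ≤ d ≤ 40°, duration ≥ 15 ms, consistency)."""
        if not (1.0 <= self.amplitude_deg <= 40.0):
            raise DataError(
                f"amplitude {self.amplitude_deg:.3f}° outside the accepted [1°, 40°] range"
            )
        if self.duration_ms < 15:
            raise DataError(f"duration {self.duration_ms} ms below the 15 ms minimum")
        if self.trajectory is not None:
            if abs(self.duration_ms - (len(self.trajectory) - 1)) > 1:
                raise DataError("duration inconsistent with trajectory length")
            d = math.hypot(
                self.landing[0] - self.onset[0], self.landing[1] - self.onset[1]
            )
            if abs(d - self.amplitude_deg) > 1e-9:
                raise DataError("amplitude inconsistent with onset/landing")


@dataclass(frozen=True)
class ParticipantMeta:
    participant_id: str
    age: float
    gender: str = "unknown"

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")


GENRES = ("nature_documentary", "cartoon", "drama", "other")


@dataclass(frozen=True)
class StimulusMeta:
    stimulus_id: str
    genre: str = "other"

    def __post_init__(self) -> None:
        if self.genre not in GENRES:
            raise ValueError(f"genre must be one of {GENRES}")


# ---------------------------------------------------------------------------
# CSV I/O


def _float_fmt(v: float) -> str:
    return f"{v:.{CSV_PRECISION}f}"


def read_gaze_csv(path: str | Path, screen: ScreenGeometry | None = None,
                  participant_id: str = "p0", stimulus_id: str = "s0") -> GazeTrace:
    """Read a gaze trace from a ``t_ms,x_deg,y_deg,valid`` CSV file.

    Raises :class:`FormatError` on missing columns and :class:`DataError` on
    non-monotone time or gaps (the 1 kHz grid must be complete).
    """
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gaze CSV {path} missing columns: {missing}")
    return GazeTrace(
        t=df["t_ms"].to_numpy(),
        x=df["x_deg"].to_numpy(dtype=float),
        y=df["y_deg"].to_numpy(dtype=float),
        valid=df["valid"].to_numpy(dtype=bool),
        participant_id=participant_id,
        stimulus_id=stimulus_id,
        screen=screen or ScreenGeometry(),
    )


def write_gaze_csv(trace: GazeTrace, path: str | Path) -> None:
    """Write a gaze trace; re-readable bit-exactly at 6 decimals of a degree."""
    df = pd.DataFrame(
        {
            "t_ms": trace.t,
            "x_deg": trace.x,
            "y_deg": trace.y,
            "valid": trace.valid.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format=f"%.{CSV_PRECISION}f")


def write_saccade_table(saccades: Sequence[Saccade], path: str | Path,
                        include_trajectories: bool = True) -> None:
    """Write a saccade summary CSV; trajectories go to ``<stem>_trajectories.csv``."""
    path = Path(path)
    rows = []
    for s in saccades:
        rows.append(
            {
                "participant_id": s.participant_id,
                "stimulus_id": s.stimulus_id,
                "onset_ms": s.onset_ms,
                "duration_ms": s.duration_ms,
                "x1": s.onset[0],
                "y1": s.onset[1],
                "xM": s.landing[0],
                "yM": s.landing[1],
                "amplitude_deg": s.amplitude_deg,
                "direction_rad": s.direction_rad,
                "peak_speed_dps": s.peak_speed_dps,
            }
        )
    pd.DataFrame(rows, columns=SACCADE_COLUMNS).to_csv(
        path, index=False, float_format=f"%.{CSV_PRECISION}f"
    )
    if include_trajectories:
        traj_rows = []
        for i, s in enumerate(saccades):
            if s.trajectory is None:
                continue
            for k, (x, y) in enumerate(s.trajectory):
                traj_rows.append((i, s.onset_ms + k, x, y))
        pd.DataFrame(traj_rows, columns=TRAJECTORY_COLUMNS).to_csv(
            _trajectory_path(path), index=False, float_format=f"%.{CSV_PRECISION}f"
        )


def _trajectory_path(path: Path) -> Path:
    return path.with_name(path.stem + "_trajectories" + path.suffix)


def read_saccade_table(path: str | Path, with_trajectories: bool | None = None,
                       validate: bool = True) -> list[Saccade]:
    """Read a saccade table written by :func:`write_saccade_table`.

    If ``with_trajectories`` is None, the companion trajectory file is loaded
    when it exists.  With ``validate=True`` each row is checked against the
    post-filter invariants (amplitude in [1°, 40°], duration ≥ 15 ms).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SACCADE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"saccade CSV {path} missing columns: {missing}")
    tpath = _trajectory_path(path)
    if with_trajectories is None:
        with_trajectories = tpath.exists()
    trajs: dict[int, np.ndarray] = {}
    if with_trajectories:
        tdf = pd.read_csv(tpath)
        tmiss = [c for c in TRAJECTORY_COLUMNS if c not in tdf.columns]
        if tmiss:
            raise FormatError(f"trajectory CSV {tpath} missing columns: {tmiss}")
        for idx, grp in tdf.groupby("saccade_index", sort=True):
            grp = grp.sort_values("t_ms")
            trajs[int(idx)] = grp[["x_deg", "y_deg"]].to_numpy(dtype=float)
    out: list[Saccade] = []
    for i, row in df.iterrows():
        traj = trajs.get(int(i))
        if traj is not None:
            s = Saccade(
                trajectory=traj,
                participant_id=str(row["participant_id"]),
                stimulus_id=str(row["stimulus_id"]),
                onset_ms=int(row["onset_ms"]),
            )
        else:
            s = Saccade(
                onset=(float(row["x1"]), float(row["y1"])),
                landing=(float(row["xM"]), float(row["yM"])),
                duration_ms=int(row["duration_ms"]),
                amplitude_deg=float(row["amplitude_deg"]),
                direction_rad=float(row["direction_rad"]),
                peak_speed_dps=float(row["peak_speed_dps"]),
                participant_id=str(row["participant_id"]),
                stimulus_id=str(row["stimulus_id"]),
                onset_ms=int(row["onset_ms"]),
            )
        if validate:
            s.validate_filtered()
        out.append(s)
    return out


def write_participants_csv(metas: Iterable[ParticipantMeta], path: str | Path) -> None:
    pd.DataFrame(
        [(m.participant_id, m.age, m.gender) for m in metas],
        columns=["participant_id", "age", "gender"],
    ).to_csv(path, index=False)


def read_participants_csv(path: str | Path) -> list[ParticipantMeta]:
    df = pd.read_csv(path)
    return [
        ParticipantMeta(str(r.participant_id), float(r.age), str(r.gender))
        for r in df.itertuples()
    ]
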