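"""Saccade landing-point prediction with LSTMs and a fine-grained dual loss.

The predictor consumes the first ``N`` milliseconds of a saccade (Cartesian
samples at 1 kHz) and outputs the landing point.  Two target strategies are
supported:

* ``coordinates`` — one network regresses the landing point (x_M, y_M)
  directly;
* ``polar`` — two networks predict the saccade direction α and displacement
  d, composed as ``x_L = x_1 + d cos α``, ``y_L = y_1 + d sin α``.

Three training objectives are available: a plain regression loss (``l1``), a
categorical cross-entropy on a discretized version of the target (``l2``),
and the fine-grained combination ``l3 = l1 + β·l2`` (β = 0.7) that trains a
regression head and an auxiliary softmax head jointly.  For the combined
loss the final prediction always comes from the regression head; the
classification head only shapes the representation during training.

Discretization for the classification head: the screen rectangle is split
into an 8 × 8 = 64-cell grid for coordinate targets; displacement uses 32
equidistant values on [0.1°, 40°] and angle 32 values on [0, π].

Six models are trained per ensemble, one per prediction horizon
N ∈ {10, 15, 20, 25, 30, 35} ms; in flight, the prediction is refreshed
every 5 ms with the largest-horizon model whose N does not exceed the
samples available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .nn import SequenceNet
from .trace import Saccade, ScreenGeometry

__all__ = [
    "HORIZONS",
    "DiscretizationScheme",
    "ModelSpec",
    "Prediction",
    "PredictorEnsemble",
    "LandingPointModel",
    "LandingPointResults",
    "truncate_pad",
    "discretize_landing",
    "undiscretize_landing",
    "discretize_scalar",
    "undiscretize_scalar",
    "euclidean_error",
    "loss_l1",
    "loss_l2",
    "loss_l3",
    "compose_from_polar",
    "build_model",
    "train_model",
]

#: The six prediction horizons (ms of saccade data consumed).
HORIZONS = (10, 15, 20, 25, 30, 35)

#: Cadence of the in-flight prediction refresh, ms.
UPDATE_INTERVAL_MS = 5

PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class DiscretizationScheme:
    """Bin layout used by the cross-entropy loss."""

    grid_rows: int = 8
    grid_cols: int = 8
    n_disp_bins: int = 32
    disp_lo: float = 0.1
    disp_hi: float = 40.0
    n_angle_bins: int = 32
    angle_lo: float = 0.0
    angle_hi: float = math.pi

    @property
    def n_cells(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def disp_spacing(self) -> float:
        return (self.disp_hi - self.disp_lo) / (self.n_disp_bins - 1)

    @property
    def angle_spacing(self) -> float:
        return (self.angle_hi - self.angle_lo) / (self.n_angle_bins - 1)


def truncate_pad(trajectory: np.ndarray, n: int) -> np.ndarray:
    """First ``n`` samples of a trajectory, zero-padded at the end if the
    saccade is shorter than the horizon."""
    trajectory = np.asarray(trajectory, dtype=np.float64)
    if trajectory.ndim != 2 or trajectory.shape[1] != 2 or len(trajectory) == 0:
        raise ValueError("trajectory must be a non-empty (m, 2) array")
    if len(trajectory) >= n:
        return trajectory[:n].copy()
    out = np.zeros((n, 2), dtype=np.float64)
    out[: len(trajectory)] = trajectory
    return out


def discretize_landing(point: Sequence[float], screen: ScreenGeometry,
                       scheme: DiscretizationScheme | None = None) -> int:
    """Row-major index of the grid cell containing ``point``; off-screen
    points clamp to the nearest edge cell.  Row 0 is the bottom row."""
    scheme = scheme or DiscretizationScheme()
    x, y = float(point[0]), float(point[1])
    cw = screen.width_deg / scheme.grid_cols
    ch = screen.height_deg / scheme.grid_rows
    col = int(np.clip(math.floor((x - screen.x_range[0]) / cw), 0, scheme.grid_cols - 1))
    row = int(np.clip(math.floor((y - screen.y_range[0]) / ch), 0, scheme.grid_rows - 1))
    return row * scheme.grid_cols + col


def undiscretize_landing(index: int, screen: ScreenGeometry,
                         scheme: DiscretizationScheme | None = None) -> tuple[float, float]:
    """Centre of grid cell ``index`` (inverse of :func:`discretize_landing`
    up to half a cell diagonal)."""
    scheme = scheme or DiscretizationScheme()
    if not 0 <= index < scheme.n_cells:
        raise ValueError(f"cell index {index} out of range [0, {scheme.n_cells})")
    row, col = divmod(index, scheme.grid_cols)
    cw = screen.width_deg / scheme.grid_cols
    ch = screen.height_deg / scheme.grid_rows
    return (
        screen.x_range[0] + (col + 0.5) * cw,
        screen.y_range[0] + (row + 0.5) * ch,
    )


def discretize_scalar(value: float, lo: float, hi: float, n_bins: int = 32) -> int:
    """Index of the nearest of ``n_bins`` equidistant values spanning
    [lo, hi]; out-of-range values clamp, exact midpoints take the lower
    index."""
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    spacing = (hi - lo) / (n_bins - 1)
    q = (float(value) - lo) / spacing
    k = math.ceil(q - 0.5)  # ties round down
    return int(np.clip(k, 0, n_bins - 1))


def undiscretize_scalar(index: int, lo: float, hi: float, n_bins: int = 32) -> float:
    if not 0 <= index < n_bins:
        raise ValueError("bin index out of range")
    return lo + index * (hi - lo) / (n_bins - 1)


def euclidean_error(p: Sequence[float], t: Sequence[float]) -> float:
    """l2 norm between predicted and true landing points, degrees."""
    return math.hypot(float(t[0]) - float(p[0]), float(t[1]) - float(p[1]))


def loss_l1(p: Sequence[float], t: Sequence[float]) -> float:
    """Regression loss: the (unsquared) Euclidean norm ‖T − P‖."""
    p = np.asarray(p, dtype=float)
    t = np.asarray(t, dtype=float)
    return float(np.linalg.norm(t - p))


def loss_l2(probs: Sequence[float], true_class: int, n_classes: int | None = None) -> float:
    """Categorical cross-entropy −log p̂[T̂] with probabilities floored at
    1e-12 (the one-hot target selects a single term of the sum)."""
    probs = np.asarray(probs, dtype=float)
    if n_classes is not None and len(probs) != n_classes:
        raise ValueError(f"probability vector has length {len(probs)}, expected {n_classes}")
    if not 0 <= true_class < len(probs):
        raise ValueError("class index out of range")
    return float(-np.log(max(float(probs[true_class]), PROB_FLOOR)))


def loss_l3(p, t, probs, true_class, beta: float = 0.7) -> float:
    """Fine-grained loss: L1 + β·L2 with β = 0.7 by default."""
    return loss_l1(p, t) + beta * loss_l2(probs, true_class)


def compose_from_polar(x1: float, y1: float, d: float, alpha: float) -> tuple[float, float]:
    """Landing point from onset, displacement and direction:
    ``(x1 + d cos α, y1 + d sin α)``."""
    if d < 0:
        raise ValueError("displacement must be non-negative")
    return (x1 + d * math.cos(alpha), y1 + d * math.sin(alpha))


# ---------------------------------------------------------------------------
# Model specification and training


@dataclass(frozen=True)
class ModelSpec:
    """Architecture/loss configuration for a single network at one horizon.

    ``target``: ``"coordinates"`` (landing x, y), ``"angle"`` (direction α)
    or ``"displacement"`` (amplitude d).  The regression head has G1 = 2
    units for coordinates and 1 otherwise; the classification head has
    G2 = 64 cells for coordinates and 32 bins otherwise.
    """

    target: str = "coordinates"
    loss: str = "l3"
    units: tuple[int, int] = (64, 64)
    horizon: int = 35
    beta: float = 0.7
    bidirectional: bool = False
    cell: str = "lstm"
    scheme: DiscretizationScheme = field(default_factory=DiscretizationScheme)

    def __post_init__(self) -> None:
        if self.target not in ("coordinates", "angle", "displacement"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.loss not in ("l1", "l2", "l3"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.horizon not in HORIZONS:
            raise ValueError(f"horizon must be one of {HORIZONS}")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.bidirectional:
            raise NotImplementedError("bidirectional LSTMs are not implemented")

    @property
    def g1(self) -> int:
        return 2 if self.target == "coordinates" else 1

    @property
    def g2(self) -> int:
        return self.scheme.n_cells if self.target == "coordinates" else 32


def build_model(spec: ModelSpec, seed: int = 0, dtype=np.float32) -> SequenceNet:
    """Instantiate the untrained network for ``spec``.

    Two stacked LSTM layers (``spec.units``) feed, from the final hidden
    state, a linear head (for ``l1``/``l3``) and/or a softmax head (for
    ``l2``/``l3``).  ``net.n_params`` gives the trainable parameter count,
    4·((I+H)·H + H) per recurrent layer plus head weights and biases.
    """
    reg = spec.g1 if spec.loss in ("l1", "l3") else None
    cls = spec.g2 if spec.loss in ("l2", "l3") else None
    return SequenceNet(
        2, spec.units, reg_units=reg, cls_units=cls, loss=spec.loss,
        beta=spec.beta, cell=spec.cell, seed=seed, dtype=dtype,
    )


def _regression_targets(saccades: Sequence[Saccade], target: str) -> np.ndarray:
    if target == "coordinates":
        return np.array([s.landing for s in saccades], dtype=np.float64)
    if target == "angle":
        return np.array([[s.direction_rad] for s in saccades], dtype=np.float64)
    return np.array([[s.amplitude_deg] for s in saccades], dtype=np.float64)


def _class_targets(saccades: Sequence[Saccade], spec: ModelSpec,
                   screen: ScreenGeometry) -> np.ndarray:
    sch = spec.scheme
    if spec.target == "coordinates":
        return np.array(
            [discretize_landing(s.landing, screen, sch) for s in saccades], dtype=np.int64
        )
    if spec.target == "angle":
        return np.array(
            [discretize_scalar(s.direction_rad, sch.angle_lo, sch.angle_hi, sch.n_angle_bins)
             for s in saccades],
            dtype=np.int64,
        )
    return np.array(
        [discretize_scalar(s.amplitude_deg, sch.disp_lo, sch.disp_hi, sch.n_disp_bins)
         for s in saccades],
        dtype=np.int64,
    )


def stack_inputs(saccades: Sequence[Saccade], n: int) -> np.ndarray:
    """(n_saccades, n, 2) array of truncated/zero-padded input sequences."""
    return np.stack([truncate_pad(s.trajectory, n) for s in saccades])


@dataclass
class TrainedModel:
    """One trained network with its spec and training history."""

    spec: ModelSpec
    net: SequenceNet
    screen: ScreenGeometry
    history: list[float]
    seed: int

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        """Model output for a batch of truncated sequences.

        For ``l1``/``l3`` the regression head is the prediction; for a pure
        ``l2`` model the argmax class is mapped back through the inverse
        discretization.
        """
        pred, probs = self.net.predict(X)
        if pred is not None:
            return np.asarray(pred, dtype=np.float64)
        idx = np.argmax(probs, axis=1)
        sch = self.spec.scheme
        if self.spec.target == "coordinates":
            return np.array(
                [undiscretize_landing(int(i), self.screen, sch) for i in idx]
            )
        if self.spec.target == "angle":
            vals = [undiscretize_scalar(int(i), sch.angle_lo, sch.angle_hi, sch.n_angle_bins)
                    for i in idx]
        else:
            vals = [undiscretize_scalar(int(i), sch.disp_lo, sch.disp_hi, sch.n_disp_bins)
                    for i in idx]
        return np.array(vals, dtype=np.float64)[:, None]


def train_model(spec: ModelSpec, saccades: Sequence[Saccade], seed: int = 0, *,
                screen: ScreenGeometry | None = None, epochs: int = 60,
                batch_size: int = 256, lr: float = 1e-3) -> TrainedModel:
    """Train one network for one horizon with Adam (max ``epochs`` epochs).

    Inputs are the raw Cartesian samples in degrees, truncated/zero-padded
    to ``spec.horizon``; training is deterministic for a fixed seed.
    """
    saccades = list(saccades)
    if not saccades:
        raise ValueError("empty training set")
    screen = screen or ScreenGeometry()
    X = stack_inputs(saccades, spec.horizon).astype(np.float32)
    t_reg = _regression_targets(saccades, spec.target) if spec.loss in ("l1", "l3") else None
    t_cls = _class_targets(saccades, spec, screen) if spec.loss in ("l2", "l3") else None
    net = build_model(spec, seed=seed)
    history = net.fit(X, t_reg, t_cls, epochs=epochs, batch_size=batch_size,
                      lr=lr, seed=seed + 1)
    return TrainedModel(spec=spec, net=net, screen=screen, history=history, seed=seed)


# ---------------------------------------------------------------------------
# Ensembles and in-flight prediction


@dataclass(frozen=True)
class Prediction:
    """One landing-point estimate made from a saccade prefix."""

    xL: float
    yL: float
    horizon_used: int
    elapsed_ms: int

    @property
    def point(self) -> tuple[float, float]:
        return (self.xL, self.yL)


class PredictorEnsemble:
    """Six trained models, one per horizon N ∈ {10, 15, 20, 25, 30, 35}.

    For the ``polar`` strategy each horizon holds an (angle, displacement)
    pair of networks whose outputs are composed with the saccade onset.
    """

    def __init__(self, models: dict[int, TrainedModel | tuple[TrainedModel, TrainedModel]]):
        if set(models) != set(HORIZONS):
            raise ValueError(f"ensemble must cover exactly the horizons {HORIZONS}")
        self.models = dict(sorted(models.items()))
        first = next(iter(self.models.values()))
        self.polar = isinstance(first, tuple)

    @property
    def horizons(self) -> tuple[int, ...]:
        return tuple(self.models)

    @property
    def n_params(self) -> int:
        """Parameter count of a single-horizon model (pair total if polar)."""
        m = self.models[HORIZONS[0]]
        return sum(x.n_params for x in m) if self.polar else m.n_params

    def predict_at_horizon(self, trajectories: Sequence[np.ndarray], n: int) -> np.ndarray:
        """Landing predictions for trajectory prefixes using the horizon-``n``
        model; inputs shorter than ``n`` are zero-padded."""
        X = np.stack([truncate_pad(t, n) for t in trajectories]).astype(np.float32)
        model = self.models[n]
        if not self.polar:
            return self.models[n].predict_batch(X)
        angle_m, disp_m = model
        alpha = angle_m.predict_batch(X)[:, 0]
        d = np.maximum(disp_m.predict_batch(X)[:, 0], 0.0)
        onsets = np.array([t[0] for t in trajectories], dtype=np.float64)
        return np.column_stack(
            [onsets[:, 0] + d * np.cos(alpha), onsets[:, 1] + d * np.sin(alpha)]
        )

    def predict(self, partial_trajectory: np.ndarray) -> Prediction | None:
        """Single prediction from the samples available so far.

        Selects the model with the largest horizon N not exceeding the
        number of available samples; with fewer than 10 samples there is
        not enough data and ``None`` is returned.
        """
        partial = np.asarray(partial_trajectory, dtype=np.float64)
        m = len(partial)
        if m < min(HORIZONS):
            return None
        n = max(h for h in self.horizons if h <= m)
        point = self.predict_at_horizon([partial], n)[0]
        return Prediction(float(point[0]), float(point[1]), horizon_used=n, elapsed_ms=m)

    def inflight(self, saccade: Saccade) -> list[Prediction]:
        """Prediction refreshed every 5 ms: one estimate at elapsed
        10, 15, 20, … ms until the saccade ends."""
        if saccade.trajectory is None:
            raise ValueError("in-flight prediction needs a trajectory")
        out: list[Prediction] = []
        elapsed = min(HORIZONS)
        while elapsed <= saccade.duration_ms:
            pred = self.predict(saccade.trajectory[:elapsed])
            if pred is not None:
                out.append(Prediction(pred.xL, pred.yL, pred.horizon_used, elapsed))
            elapsed += UPDATE_INTERVAL_MS
        return out


# ---------------------------------------------------------------------------
# Model / Results interface


class LandingPointModel:
    """Landing-point prediction model over a corpus of training saccades.

    Parameters
    ----------
    train_saccades
        Saccades with trajectories (detected or simulated).
    target
        ``"coordinates"`` for direct (x_M, y_M) regression or ``"polar"``
        for the direction + displacement pair of networks.
    loss
        ``"l1"``, ``"l2"`` or ``"l3"`` (fine-grained combination, β = 0.7).
    units
        LSTM widths for the two layers, e.g. ``(64, 64)``.

    ``fit`` trains the full six-horizon ensemble and returns a
    :class:`LandingPointResults`.
    """

    def __init__(self, train_saccades: Sequence[Saccade], *,
                 target: str = "coordinates", loss: str = "l3",
                 units: tuple[int, int] = (64, 64), beta: float = 0.7,
                 cell: str = "lstm",
                 screen: ScreenGeometry | None = None,
                 scheme: DiscretizationScheme | None = None):
        if target not in ("coordinates", "polar"):
            raise ValueError("target must be 'coordinates' or 'polar'")
        self.saccades = list(train_saccades)
        if not self.saccades:
            raise ValueError("empty training set")
        self.target = target
        self.loss = loss
        self.units = tuple(units)
        self.beta = beta
        self.cell = cell
        self.screen = screen or ScreenGeometry()
        self.scheme = scheme or DiscretizationScheme()

    def _specs(self, horizon: int) -> list[ModelSpec]:
        base = dict(loss=self.loss, units=self.units, horizon=horizon,
                    beta=self.beta, cell=self.cell, scheme=self.scheme)
        if self.target == "coordinates":
            return [ModelSpec(target="coordinates", **base)]
        return [ModelSpec(target="angle", **base),
                ModelSpec(target="displacement", **base)]

    def fit(self, seed: int = 0, *, epochs: int = 60, batch_size: int = 256,
            lr: float = 1e-3) -> "LandingPointResults":
        models: dict[int, TrainedModel | tuple] = {}
        for k, n in enumerate(HORIZONS):
            trained = [
                train_model(spec, self.saccades, seed=seed + 101 * k + 13 * j,
                            screen=self.screen, epochs=epochs,
                            batch_size=batch_size, lr=lr)
                for j, spec in enumerate(self._specs(n))
            ]
            models[n] = trained[0] if len(trained) == 1 else tuple(trained)
        ensemble = PredictorEnsemble(models)
        return LandingPointResults(self, ensemble, seed=seed, epochs=epochs)


class LandingPointResults:
    """Fitted six-horizon ensemble with training diagnostics."""

    def __init__(self, model: LandingPointModel, ensemble: PredictorEnsemble,
                 seed: int, epochs: int):
        self.model = model
        self.ensemble = ensemble
        self.seed = seed
        self.epochs = epochs

    @property
    def n_params(self) -> int:
        return self.ensemble.n_params

    def predict(self, partial_trajectory: np.ndarray) -> Prediction | None:
        return self.ensemble.predict(partial_trajectory)

    def predict_at_horizon(self, trajectories, n: int) -> np.ndarray:
        return self.ensemble.predict_at_horizon(trajectories, n)

    def inflight(self, saccade: Saccade) -> list[Prediction]:
        return self.ensemble.inflight(saccade)

    def final_losses(self) -> dict[int, float]:
        out = {}
        for n, m in self.ensemble.models.items():
            if isinstance(m, tuple):
                out[n] = sum(x.history[-1] for x in m)
            else:
                out[n] = m.history[-1]
        return out

    def summary(self) -> str:
        m = self.model
        lines = [
            "Saccade landing-point predictor",
            "=" * 47,
            f"target:          {m.target}",
            f"loss:            {m.loss} (beta={m.beta})" if m.loss == "l3"
            else f"loss:            {m.loss}",
            f"LSTM units:      {m.units[0]} x {m.units[1]}",
            f"parameters/N:    {self.n_params:,}",
            f"training set:    {len(m.saccades):,} saccades",
            f"epochs:          {self.epochs}   seed: {self.seed}",
            "-" * 47,
            "horizon N (ms)   final training loss",
        ]
        for n, loss in self.final_losses().items():
            lines.append(f"      {n:2d}            {loss:12.4f}")
        return "\n".join(lines)
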