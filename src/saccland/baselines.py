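"""Published comparison methods: polynomial fitting, FFNN, simple RNN, and
the center-bias reference.

Every baseline exposes the same interface as the main predictor's ensemble
(``predict_at_horizon`` over the six horizons and ``predict`` on a partial
trajectory) so the evaluation protocol can swap methods freely.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .nn import MLP, SequenceNet
from .predictor import (HORIZONS, Prediction, compose_from_polar, stack_inputs,
                        truncate_pad)
from .trace import Saccade

__all__ = [
    "PolyfitModel",
    "polyfit_train",
    "CenterBiasModel",
    "FFNNBaseline",
    "RNNBaseline",
]


def _predict_dispatch(self, partial_trajectory: np.ndarray) -> Prediction | None:
    partial = np.asarray(partial_trajectory, dtype=np.float64)
    m = len(partial)
    if m < min(HORIZONS):
        return None
    n = max(h for h in HORIZONS if h <= m)
    point = self.predict_at_horizon([partial], n)[0]
    return Prediction(float(point[0]), float(point[1]), horizon_used=n, elapsed_ms=m)


class PolyfitModel:
    """Per-horizon degree-2 polynomial mapping the observed partial
    displacement (onset → last available sample) to the full saccade
    amplitude: 3 coefficients × 6 horizons = 18 parameters.

    The direction is taken from the available samples (angle between the
    first and last sample of the prefix) and the landing point composed as
    onset + amplitude·(cos α, sin α).
    """

    degree = 2

    def __init__(self, coeffs: dict[int, np.ndarray]):
        self.coeffs = dict(sorted(coeffs.items()))

    @property
    def n_params(self) -> int:
        return sum(len(c) for c in self.coeffs.values())

    @staticmethod
    def _partial_displacement(prefix: np.ndarray) -> float:
        return float(math.hypot(prefix[-1, 0] - prefix[0, 0],
                                prefix[-1, 1] - prefix[0, 1]))

    def predict_at_horizon(self, trajectories: Sequence[np.ndarray], n: int) -> np.ndarray:
        out = np.empty((len(trajectories), 2))
        for i, traj in enumerate(trajectories):
            prefix = np.asarray(traj, dtype=np.float64)[:n]
            disp = self._partial_displacement(prefix)
            dx = prefix[-1, 0] - prefix[0, 0]
            dy = prefix[-1, 1] - prefix[0, 1]
            alpha = math.atan2(dy, dx) if disp > 0 else 0.0
            amp = max(float(np.polyval(self.coeffs[n], disp)), 0.0)
            out[i] = compose_from_polar(prefix[0, 0], prefix[0, 1], amp, alpha)
        return out

    predict = _predict_dispatch


def polyfit_train(training_saccades: Sequence[Saccade],
                  horizons: Sequence[int] = HORIZONS) -> PolyfitModel:
    """Least-squares fit of the degree-2 amplitude polynomial per horizon."""
    saccades = list(training_saccades)
    coeffs: dict[int, np.ndarray] = {}
    for n in horizons:
        if len(saccades) < 3:
            raise ValueError("need at least 3 training saccades per horizon")
        disp = np.array(
            [PolyfitModel._partial_displacement(truncate_pad(s.trajectory, n))
             for s in saccades]
        )
        amp = np.array([s.amplitude_deg for s in saccades])
        if np.ptp(disp) < 1e-12:
            raise ValueError(
                f"degenerate design at horizon {n}: all partial displacements equal"
            )
        coeffs[n] = np.polyfit(disp, amp, deg=PolyfitModel.degree)
    return PolyfitModel(coeffs)


@dataclass
class CenterBiasModel:
    """2D Gaussian over landing points, fitted to the training set; a
    prediction is a random draw that ignores the saccade entirely."""

    mean: np.ndarray
    cov: np.ndarray
    rng: np.random.Generator

    @classmethod
    def fit(cls, training_saccades: Sequence[Saccade],
            seed: int = 0) -> "CenterBiasModel":
        pts = np.array([s.landing for s in training_saccades], dtype=np.float64)
        if len(pts) == 0:
            raise ValueError("empty training set")
        mean = pts.mean(axis=0)
        cov = np.cov(pts.T) if len(pts) > 1 else np.zeros((2, 2))
        cov = np.atleast_2d(cov)
        return cls(mean=mean, cov=cov, rng=np.random.default_rng(seed))

    def sample(self, size: int = 1) -> np.ndarray:
        return self.rng.multivariate_normal(self.mean, self.cov, size=size,
                                            method="cholesky" if _spd(self.cov)
                                            else "svd")

    def predict_at_horizon(self, trajectories: Sequence[np.ndarray], n: int) -> np.ndarray:
        return self.sample(len(trajectories))

    predict = _predict_dispatch


def _spd(cov: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False


class _PerHorizonNets:
    """Shared machinery for the FFNN/RNN baselines: one small network per
    horizon, trained on truncated/zero-padded coordinate sequences with a
    squared-error loss on the landing point."""

    def __init__(self, nets: dict[int, MLP | SequenceNet]):
        self.nets = dict(sorted(nets.items()))

    @property
    def n_params(self) -> int:
        """Parameter count of the smallest-horizon network (the convention
        for reporting a single per-model figure)."""
        return self.nets[min(self.nets)].n_params

    def predict_at_horizon(self, trajectories: Sequence[np.ndarray], n: int) -> np.ndarray:
        X = np.stack([truncate_pad(t, n) for t in trajectories]).astype(np.float32)
        pred = self.nets[n].predict(X)
        if isinstance(pred, tuple):
            pred = pred[0]
        return np.asarray(pred, dtype=np.float64)

    predict = _predict_dispatch


class FFNNBaseline(_PerHorizonNets):
    """Feed-forward baseline: flattened N×2 input, two 32-unit ReLU hidden
    layers, 2-unit linear output (1,794 parameters at N = 10)."""

    @classmethod
    def train(cls, training_saccades: Sequence[Saccade], seed: int = 0, *,
              horizons: Sequence[int] = HORIZONS, hidden: tuple[int, int] = (32, 32),
              epochs: int = 60, batch_size: int = 256, lr: float = 1e-3) -> "FFNNBaseline":
        saccades = list(training_saccades)
        if not saccades:
            raise ValueError("empty training set")
        targets = np.array([s.landing for s in saccades], dtype=np.float64)
        nets: dict[int, MLP] = {}
        for k, n in enumerate(horizons):
            X = stack_inputs(saccades, n).astype(np.float32)
            net = MLP(2 * n, hidden, 2, seed=seed + 31 * k)
            net.fit(X, targets, epochs=epochs, batch_size=batch_size, lr=lr,
                    seed=seed + 31 * k + 1)
            nets[n] = net
        return cls(nets)


class RNNBaseline(_PerHorizonNets):
    """Simple (tanh) recurrent baseline, two 32-unit layers, linear 2-unit
    head on the final hidden state."""

    @classmethod
    def train(cls, training_saccades: Sequence[Saccade], seed: int = 0, *,
              horizons: Sequence[int] = HORIZONS, hidden: tuple[int, int] = (32, 32),
              epochs: int = 60, batch_size: int = 256, lr: float = 1e-3) -> "RNNBaseline":
        saccades = list(training_saccades)
        if not saccades:
            raise ValueError("empty training set")
        targets = np.array([s.landing for s in saccades], dtype=np.float64)
        nets: dict[int, SequenceNet] = {}
        for k, n in enumerate(horizons):
            X = stack_inputs(saccades, n).astype(np.float32)
            net = SequenceNet(2, hidden, reg_units=2, cls_units=None, loss="l1",
                              cell="rnn", seed=seed + 31 * k)
            net.fit(X, targets, None, epochs=epochs, batch_size=batch_size,
                    lr=lr, seed=seed + 31 * k + 1)
            nets[n] = net
        return cls(nets)
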