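"""Open-set evaluation protocol and stratified error analyses.

Models are trained on one set of participants and evaluated on a disjoint
set (80 % / 20 % split, repeated with fresh random splits).  Because each
test participant contributes a different number of saccades, every reported
mean is a mean of per-user means, never a pooled mean over saccades.  The
headline error of a saccade is the mean of the six errors from the six
horizon models (N = 10 … 35 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .predictor import HORIZONS, euclidean_error
from .trace import ParticipantMeta, Saccade, StimulusMeta

__all__ = [
    "SplitPlan",
    "make_splits",
    "evaluate",
    "EvaluationReport",
    "stratify_covariates",
    "error_vs_length_curve",
    "run_open_set",
]


class ProtocolViolation(RuntimeError):
    """A test saccade belongs to a training participant."""


@dataclass(frozen=True)
class SplitPlan:
    """One subject-disjoint train/test partition."""

    repeat_index: int
    train_participants: frozenset[str]
    test_participants: frozenset[str]
    seed: int

    def __post_init__(self) -> None:
        if self.train_participants & self.test_participants:
            raise ValueError("train and test participants must be disjoint")


def make_splits(participant_ids: Sequence[str], n_repeats: int = 10,
                test_frac: float = 0.2, seed: int = 0) -> list[SplitPlan]:
    """Seeded random open-set splits; test size = round(test_frac · P),
    at least 1 participant."""
    ids = sorted(set(participant_ids))
    if len(ids) < 5:
        raise ValueError("need at least 5 participants for an open-set split")
    rng = np.random.default_rng(seed)
    n_test = max(int(round(test_frac * len(ids))), 1)
    plans = []
    for r in range(n_repeats):
        perm = rng.permutation(len(ids))
        test = frozenset(ids[i] for i in perm[:n_test])
        train = frozenset(ids[i] for i in perm[n_test:])
        plans.append(SplitPlan(repeat_index=r + 1, train_participants=train,
                               test_participants=test, seed=seed))
    return plans


def _user_mean(df: pd.DataFrame, col: str = "error") -> float:
    """Mean of per-user means (the protocol's anti-bias weighting)."""
    return float(df.groupby("participant_id")[col].mean().mean())


@dataclass
class EvaluationReport:
    """Per-saccade errors plus the stratified summaries derived from them."""

    per_saccade: pd.DataFrame  # participant_id, stimulus_id, amplitude, error, err_<N>...
    headline_mean: float
    per_user: pd.Series
    by_length: dict[str, float]
    by_horizon: dict[int, float]
    by_age: dict[str, float] = field(default_factory=dict)
    by_genre: dict[str, float] = field(default_factory=dict)
    repeat_means: list[float] = field(default_factory=list)

    @property
    def repeat_mean(self) -> float:
        return float(np.mean(self.repeat_means)) if self.repeat_means else self.headline_mean

    @property
    def repeat_std(self) -> float:
        """Sample standard deviation of the per-repeat headline means."""
        if len(self.repeat_means) < 2:
            return float("nan")
        return float(np.std(self.repeat_means, ddof=1))

    def summary(self) -> str:
        lines = [
            "Open-set evaluation report",
            "=" * 46,
            f"test users:       {len(self.per_user)}",
            f"test saccades:    {len(self.per_saccade):,}",
            f"headline error:   {self.headline_mean:.3f} deg",
        ]
        if len(self.repeat_means) > 1:
            lines.append(
                f"across repeats:   {self.repeat_mean:.3f} "
                f"(sd {self.repeat_std:.3f}) deg over {len(self.repeat_means)}"
            )
        lines.append("-" * 46)
        for name, v in self.by_length.items():
            lines.append(f"  E_{name:<8s}  {v:8.3f} deg")
        for n, v in self.by_horizon.items():
            lines.append(f"  N = {n:2d} ms     {v:8.3f} deg")
        return "\n".join(lines)


def evaluate(predictor, test_saccades: Sequence[Saccade],
             participant_meta: Mapping[str, ParticipantMeta] | Iterable[ParticipantMeta] | None = None,
             stimulus_meta: Mapping[str, StimulusMeta] | Iterable[StimulusMeta] | None = None,
             allowed_participants: Iterable[str] | None = None,
             horizons: Sequence[int] = HORIZONS) -> EvaluationReport:
    """Evaluate any predictor exposing ``predict_at_horizon`` on a test set.

    Per saccade and per horizon the error is the l2 norm between predicted
    and true landing point; the saccade's summary error is the mean over
    the six horizons.  Raises :class:`ProtocolViolation` if a test saccade
    belongs to a participant outside ``allowed_participants``.
    """
    saccades = list(test_saccades)
    if not saccades:
        raise ValueError("empty test set")
    if allowed_participants is not None:
        allowed = set(allowed_participants)
        bad = {s.participant_id for s in saccades} - allowed
        if bad:
            raise ProtocolViolation(
                f"test saccades from non-test participants: {sorted(bad)}"
            )
    trajs = [s.trajectory for s in saccades]
    landings = np.array([s.landing for s in saccades])
    rows = {
        "participant_id": [s.participant_id for s in saccades],
        "stimulus_id": [s.stimulus_id for s in saccades],
        "amplitude": [s.amplitude_deg for s in saccades],
    }
    err_cols = []
    for n in horizons:
        pred = np.asarray(predictor.predict_at_horizon(trajs, n))
        err = np.hypot(pred[:, 0] - landings[:, 0], pred[:, 1] - landings[:, 1])
        rows[f"err_{n}"] = err
        err_cols.append(f"err_{n}")
    df = pd.DataFrame(rows)
    df["error"] = df[err_cols].mean(axis=1)

    per_user = df.groupby("participant_id")["error"].mean()
    headline = float(per_user.mean())
    by_length = {
        "d<5": _user_mean(df[df["amplitude"] < 5.0]) if (df["amplitude"] < 5.0).any() else float("nan"),
        "d<15": _user_mean(df[df["amplitude"] < 15.0]) if (df["amplitude"] < 15.0).any() else float("nan"),
        "d>15": _user_mean(df[df["amplitude"] >= 15.0]) if (df["amplitude"] >= 15.0).any() else float("nan"),
        "all": headline,
    }
    by_horizon = {
        n: float(df.groupby("participant_id")[f"err_{n}"].mean().mean())
        for n in horizons
    }
    report = EvaluationReport(
        per_saccade=df, headline_mean=headline, per_user=per_user,
        by_length=by_length, by_horizon=by_horizon,
    )
    strata = stratify_covariates(df, participant_meta, stimulus_meta)
    report.by_age = strata["by_age"]
    report.by_genre = strata["by_genre"]
    return report


def _as_mapping(meta, key: str):
    if meta is None:
        return {}
    if isinstance(meta, Mapping):
        return dict(meta)
    return {getattr(m, key): m for m in meta}


def stratify_covariates(per_saccade: pd.DataFrame,
                        participant_meta=None, stimulus_meta=None,
                        age_cutoff: float = 60.0) -> dict:
    """Grouped means: age below/at-or-above 60 years, stimulus genre, and
    the best/worst per-user curves.  Participants or stimuli with no
    metadata fall into an ``unknown`` group."""
    pmeta = _as_mapping(participant_meta, "participant_id")
    smeta = _as_mapping(stimulus_meta, "stimulus_id")
    df = per_saccade.copy()

    def age_group(pid: str) -> str:
        m = pmeta.get(pid)
        if m is None:
            return "unknown"
        return "<60" if m.age < age_cutoff else ">=60"

    def genre(sid: str) -> str:
        m = smeta.get(sid)
        return m.genre if m is not None else "unknown"

    by_age: dict[str, float] = {}
    if pmeta:
        df["age_group"] = df["participant_id"].map(age_group)
        for grp, sub in df.groupby("age_group"):
            by_age[grp] = _user_mean(sub)
    by_genre: dict[str, float] = {}
    if smeta:
        df["genre"] = df["stimulus_id"].map(genre)
        for grp, sub in df.groupby("genre"):
            by_genre[grp] = _user_mean(sub)
    per_user = per_saccade.groupby("participant_id")["error"].mean()
    return {
        "by_age": by_age,
        "by_genre": by_genre,
        "best_user": (per_user.idxmin(), float(per_user.min())),
        "worst_user": (per_user.idxmax(), float(per_user.max())),
    }


def error_vs_length_curve(errors: Sequence[float], amplitudes: Sequence[float],
                          bin_width: float = 2.5) -> pd.DataFrame:
    """Mean error binned by true saccade amplitude (for the error-vs-length
    curve); columns bin_lo, bin_hi, mean_error, n."""
    err = np.asarray(errors, dtype=float)
    amp = np.asarray(amplitudes, dtype=float)
    if err.shape != amp.shape:
        raise ValueError("errors and amplitudes must be paired")
    idx = np.floor(amp / bin_width).astype(int)
    rows = []
    for k in sorted(set(idx)):
        sel = idx == k
        rows.append((k * bin_width, (k + 1) * bin_width,
                     float(err[sel].mean()), int(sel.sum())))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "mean_error", "n"])


def run_open_set(saccades: Sequence[Saccade], trainer: Callable,
                 n_repeats: int = 10, test_frac: float = 0.2, seed: int = 0,
                 participant_meta=None, stimulus_meta=None) -> list[EvaluationReport]:
    """Full protocol: repeated subject-disjoint splits, train via
    ``trainer(train_saccades, repeat_index)``, evaluate on the held-out
    participants.  Returns one report per repeat, each carrying the list of
    headline means across repeats."""
    ids = sorted({s.participant_id for s in saccades})
    plans = make_splits(ids, n_repeats=n_repeats, test_frac=test_frac, seed=seed)
    reports: list[EvaluationReport] = []
    for plan in plans:
        train = [s for s in saccades if s.participant_id in plan.train_participants]
        test = [s for s in saccades if s.participant_id in plan.test_participants]
        predictor = trainer(train, plan.repeat_index)
        reports.append(
            evaluate(predictor, test, participant_meta, stimulus_meta,
                     allowed_participants=plan.test_participants)
        )
    means = [r.headline_mean for r in reports]
    for r in reports:
        r.repeat_means = means
    return reports
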