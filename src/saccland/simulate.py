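"""Synthetic saccade and gaze-session generator.

Emulates the statistical structure of large natural-viewing saccade corpora
so that detection, training and evaluation can be exercised without an eye
tracker:

* amplitudes follow a truncated lognormal on [1°, 40°] calibrated to a mean
  of 5.8°;
* durations follow the main sequence ``M = d0 + d1·A`` (defaults 21 ms +
  2.2 ms/°, so the mean-amplitude saccade lasts ≈ 34 ms);
* speed follows a Gaussian profile peaking mid-flight, its peak capped at
  the main-sequence saturation ``η (1 − e^{−A/c})`` (η = 750 °/s, c = 16°);
* trajectories carry a single-arc perpendicular curvature and i.i.d.
  Gaussian tracker noise (σ = 0.1° per sample);
* per-user lognormal multipliers on the velocity scale and duration slope
  give each simulated participant an individual neuromotor signature, which
  is what makes open-set (subject-disjoint) evaluation meaningful;
* sessions alternate fixations (200–400 ms, 0.05° jitter) with saccades and
  can contain blink gaps (50–150 ms of invalid samples).

All sampling goes through an explicit ``numpy.random.Generator``; the same
seed reproduces a corpus byte-for-byte in CSV export.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.stats import lognorm, norm

from .trace import GazeTrace, ParticipantMeta, Saccade, ScreenGeometry

__all__ = [
    "SimulatorParams",
    "UserProfile",
    "sample_user_profile",
    "sample_amplitudes",
    "main_sequence_duration",
    "peak_speed_cap",
    "velocity_profile",
    "synth_saccade",
    "synth_session",
    "synth_corpus",
]


@dataclass(frozen=True)
class SimulatorParams:
    """Tunable generator parameters (degrees, milliseconds, °/s)."""

    amp_min: float = 1.0
    amp_max: float = 40.0
    amp_mean: float = 5.8          # target mean of the truncated lognormal
    amp_sigma: float = 0.8         # lognormal shape (log-scale spread)
    dur_intercept: float = 21.0    # d0, ms
    dur_slope: float = 2.2         # d1, ms per degree
    vpeak_scale: float = 750.0     # η, °/s
    vpeak_sat: float = 16.0        # c, degrees
    curvature_max_frac: float = 0.15
    noise_sigma: float = 0.1       # tracker noise per sample, degrees
    fixation_dur_range: tuple[float, float] = (200.0, 400.0)
    fixation_jitter: float = 0.05
    blink_rate: float = 6.0        # blinks per minute
    blink_dur_range: tuple[float, float] = (50.0, 150.0)
    user_sigma: float = 0.1        # log-scale spread of per-user multipliers
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)

    def __post_init__(self) -> None:
        if not (0 < self.amp_min < self.amp_max):
            raise ValueError("need 0 < amp_min < amp_max")
        if not (self.amp_min <= self.amp_mean <= self.amp_max):
            raise ValueError("amp_mean must lie within [amp_min, amp_max]")
        for name in ("amp_sigma", "dur_intercept", "dur_slope", "vpeak_scale",
                     "vpeak_sat"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class UserProfile:
    """Per-participant neuromotor multipliers (both > 0)."""

    participant_id: str = "p0"
    age: float = 50.0
    eta_mult: float = 1.0    # scales the peak-velocity ceiling
    slope_mult: float = 1.0  # scales the duration/amplitude slope

    def __post_init__(self) -> None:
        if self.eta_mult <= 0 or self.slope_mult <= 0:
            raise ValueError("profile multipliers must be positive")


DEFAULT_PROFILE = UserProfile()


@lru_cache(maxsize=16)
def _amp_lognormal_mu(amp_min: float, amp_max: float, mean: float, sigma: float) -> float:
    """Location μ of a lognormal(μ, σ) whose truncation to
    [amp_min, amp_max] has the requested mean."""
    la, lb = math.log(amp_min), math.log(amp_max)

    def trunc_mean(mu: float) -> float:
        z_a, z_b = (la - mu) / sigma, (lb - mu) / sigma
        mass = norm.cdf(z_b) - norm.cdf(z_a)
        tilt = norm.cdf(z_b - sigma) - norm.cdf(z_a - sigma)
        return math.exp(mu + 0.5 * sigma**2) * tilt / mass

    return brentq(lambda mu: trunc_mean(mu) - mean, -3.0, 4.0, xtol=1e-12)


def sample_amplitudes(params: SimulatorParams, rng: np.random.Generator,
                      size: int) -> np.ndarray:
    """Truncated-lognormal amplitudes via inverse-CDF sampling."""
    mu = _amp_lognormal_mu(params.amp_min, params.amp_max,
                           params.amp_mean, params.amp_sigma)
    dist = lognorm(s=params.amp_sigma, scale=math.exp(mu))
    lo, hi = dist.cdf(params.amp_min), dist.cdf(params.amp_max)
    return dist.ppf(rng.uniform(lo, hi, size=size))


def sample_user_profile(params: SimulatorParams, rng: np.random.Generator,
                        participant_id: str = "p0") -> UserProfile:
    """Draw one participant: lognormal(0, user_sigma) multipliers and an age
    uniform on [20, 80] years."""
    eta_mult, slope_mult = np.exp(rng.normal(0.0, params.user_sigma, size=2))
    age = float(rng.uniform(20.0, 80.0))
    return UserProfile(participant_id=participant_id, age=age,
                       eta_mult=float(eta_mult), slope_mult=float(slope_mult))


def main_sequence_duration(amplitude: float, profile: UserProfile = DEFAULT_PROFILE,
                           params: SimulatorParams = SimulatorParams()) -> int:
    """Main-sequence duration ``round(d0 + slope_mult·d1·A)`` in ms."""
    if not params.amp_min <= amplitude <= params.amp_max:
        raise ValueError(
            f"amplitude {amplitude}° outside [{params.amp_min}, {params.amp_max}]"
        )
    return int(round(params.dur_intercept
                     + profile.slope_mult * params.dur_slope * amplitude))


def peak_speed_cap(amplitude: float, profile: UserProfile = DEFAULT_PROFILE,
                   params: SimulatorParams = SimulatorParams()) -> float:
    """Main-sequence peak-velocity ceiling ``η (1 − e^{−A/c})`` in °/s."""
    return (params.vpeak_scale * profile.eta_mult
            * (1.0 - math.exp(-amplitude / params.vpeak_sat)))


def velocity_profile(amplitude: float, duration: int,
                     profile: UserProfile = DEFAULT_PROFILE,
                     params: SimulatorParams = SimulatorParams()) -> np.ndarray:
    """Per-ms speed sequence (°/s, length ``duration``) for one saccade.

    A Gaussian bump centred at ``round(M/2)`` with σ = M/6, normalised so
    the time-integral equals the amplitude exactly.  If the implied peak
    exceeds the main-sequence ceiling, σ is widened until it fits.
    """
    if duration < 15:
        raise ValueError("saccade duration must be at least 15 ms")
    m = int(duration)
    centre = round(m / 2)
    cap = peak_speed_cap(amplitude, profile, params)
    sigma = m / 6.0
    k = np.arange(m, dtype=np.float64)
    for _ in range(200):
        g = np.exp(-0.5 * ((k - centre) / sigma) ** 2)
        v = g / g.sum() * amplitude * 1000.0  # °/s; sum(v)/1000 == amplitude
        if v.max() <= cap:
            break
        sigma *= 1.05
    return v


def synth_saccade(start: tuple[float, float], direction: float, amplitude: float,
                  profile: UserProfile, params: SimulatorParams,
                  rng: np.random.Generator, *, participant_id: str = "p0",
                  stimulus_id: str = "s0", onset_ms: int = 0) -> Saccade:
    """Simulate one saccade from ``start`` along ``direction`` (radians).

    The speed profile is integrated along the direction; a single-arc
    perpendicular offset ``h·sin(π t / M)`` (h uniform up to
    ``curvature_max_frac · A``, random sign) models trajectory curvature,
    and i.i.d. Gaussian tracker noise is added to every sample.  The landing
    point is the final (noisy) trajectory sample.
    """
    x0, y0 = float(start[0]), float(start[1])
    xe = x0 + amplitude * math.cos(direction)
    ye = y0 + amplitude * math.sin(direction)
    if not params.screen.contains(x0, y0) or not params.screen.contains(xe, ye):
        raise ValueError("saccade endpoints must lie on the screen")
    m = main_sequence_duration(amplitude, profile, params)
    v = velocity_profile(amplitude, m, profile, params)
    disp = np.concatenate([[0.0], np.cumsum(v) / 1000.0])  # length m+1, ends at A
    ux, uy = math.cos(direction), math.sin(direction)
    h = rng.uniform(0.0, params.curvature_max_frac * amplitude)
    h *= rng.choice([-1.0, 1.0])
    t = np.arange(m + 1, dtype=np.float64)
    w = h * np.sin(math.pi * t / m)
    xs = x0 + disp * ux - w * uy
    ys = y0 + disp * uy + w * ux
    if params.noise_sigma > 0:
        xs = xs + rng.normal(0.0, params.noise_sigma, size=m + 1)
        ys = ys + rng.normal(0.0, params.noise_sigma, size=m + 1)
    return Saccade(trajectory=np.column_stack([xs, ys]),
                   participant_id=participant_id, stimulus_id=stimulus_id,
                   onset_ms=onset_ms)


_PLACEMENT_MARGIN = 0.25  # inset (deg) keeping noiseless endpoints on screen


def _pick_target(pos: tuple[float, float], amplitude: float,
                 params: SimulatorParams, rng: np.random.Generator
                 ) -> tuple[float, float]:
    """(direction, amplitude) keeping the landing on screen.

    Directions are drawn uniformly with rejection; if none fits (a long
    saccade from near an edge), the saccade is redirected toward the screen
    centre and shortened to what fits.
    """
    sx, sy = params.screen.x_range, params.screen.y_range
    m = _PLACEMENT_MARGIN
    for _ in range(64):
        direction = rng.uniform(-math.pi, math.pi)
        xe = pos[0] + amplitude * math.cos(direction)
        ye = pos[1] + amplitude * math.sin(direction)
        if sx[0] + m <= xe <= sx[1] - m and sy[0] + m <= ye <= sy[1] - m:
            return direction, amplitude
    direction = math.atan2(-pos[1], -pos[0])
    if pos == (0.0, 0.0):
        direction = 0.0
    # longest step toward the centre that stays inside the inset rectangle
    lo, hi = 0.0, amplitude
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        xe = pos[0] + mid * math.cos(direction)
        ye = pos[1] + mid * math.sin(direction)
        if sx[0] + m <= xe <= sx[1] - m and sy[0] + m <= ye <= sy[1] - m:
            lo = mid
        else:
            hi = mid
    return direction, max(lo, params.amp_min)


def synth_session(n_saccades: int, profile: UserProfile, params: SimulatorParams,
                  rng: np.random.Generator, *, stimulus_id: str = "s0",
                  with_blinks: bool = False) -> tuple[GazeTrace, list[Saccade]]:
    """One viewing session alternating fixations and saccades.

    Returns the 1 kHz gaze trace together with the ground-truth saccade list
    (the exact noisy trajectories embedded in the trace), for use as a
    detection/training oracle.
    """
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    valid: list[np.ndarray] = []
    truth: list[Saccade] = []
    pos = (float(rng.uniform(-4.0, 4.0)), float(rng.uniform(-3.0, 3.0)))
    t_now = 0

    def add_fixation() -> None:
        nonlocal t_now
        dur = int(rng.uniform(*params.fixation_dur_range))
        fx = pos[0] + rng.normal(0.0, params.fixation_jitter, size=dur)
        fy = pos[1] + rng.normal(0.0, params.fixation_jitter, size=dur)
        ok = np.ones(dur, dtype=bool)
        if with_blinks:
            p_blink = params.blink_rate * dur / 60000.0
            if rng.uniform() < p_blink:
                b = int(rng.uniform(*params.blink_dur_range))
                b = min(b, max(dur - 20, 0))
                if b > 0:
                    start = int(rng.uniform(10, dur - b - 9))
                    fx[start:start + b] = np.nan
                    fy[start:start + b] = np.nan
                    ok[start:start + b] = False
        xs.append(fx)
        ys.append(fy)
        valid.append(ok)
        t_now += dur

    add_fixation()
    amps = sample_amplitudes(params, rng, size=max(n_saccades, 1))
    for i in range(n_saccades):
        direction, amp = _pick_target(pos, float(amps[i]), params, rng)
        sac = synth_saccade(pos, direction, amp, profile, params, rng,
                            participant_id=profile.participant_id,
                            stimulus_id=stimulus_id, onset_ms=t_now)
        truth.append(sac)
        xs.append(sac.trajectory[:, 0])
        ys.append(sac.trajectory[:, 1])
        valid.append(np.ones(len(sac.trajectory), dtype=bool))
        t_now += len(sac.trajectory)
        pos = (sac.trajectory[-1, 0] - 0.0, sac.trajectory[-1, 1] - 0.0)
        # re-centre the fixation on the noiseless landing neighbourhood
        pos = (float(np.clip(pos[0], *params.screen.x_range)),
               float(np.clip(pos[1], *params.screen.y_range)))
        add_fixation()
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    ok = np.concatenate(valid)
    trace = GazeTrace(t=np.arange(len(x)), x=x, y=y, valid=ok,
                      participant_id=profile.participant_id,
                      stimulus_id=stimulus_id, screen=params.screen)
    return trace, truth


def synth_corpus(n_users: int, saccades_per_user: int,
                 params: SimulatorParams = SimulatorParams(), seed: int = 0,
                 profiles: list[UserProfile] | None = None,
                 genres: tuple[str, ...] = ("nature_documentary", "cartoon", "drama"),
                 ) -> tuple[list[Saccade], list[ParticipantMeta]]:
    """Corpus of independent saccades for ``n_users`` simulated participants.

    Saccades are drawn directly (random on-screen start, truncated-lognormal
    amplitude, direction keeping the landing on screen) without assembling
    full sessions, which is what training and evaluation consume.  Stimulus
    ids cycle through the genre list so genre stratification has data.
    """
    rng = np.random.default_rng(seed)
    saccades: list[Saccade] = []
    metas: list[ParticipantMeta] = []
    for u in range(n_users):
        pid = f"u{u:03d}"
        profile = (profiles[u] if profiles is not None
                   else sample_user_profile(params, rng, pid))
        if profile.participant_id != pid:
            profile = UserProfile(pid, profile.age, profile.eta_mult,
                                  profile.slope_mult)
        metas.append(ParticipantMeta(pid, profile.age))
        amps = sample_amplitudes(params, rng, size=saccades_per_user)
        margin = _PLACEMENT_MARGIN
        for i in range(saccades_per_user):
            pos = (float(rng.uniform(params.screen.x_range[0] + margin,
                                     params.screen.x_range[1] - margin)),
                   float(rng.uniform(params.screen.y_range[0] + margin,
                                     params.screen.y_range[1] - margin)))
            direction, amp = _pick_target(pos, float(amps[i]), params, rng)
            stim = f"s{i % len(genres)}"
            saccades.append(
                synth_saccade(pos, direction, amp, profile, params, rng,
                              participant_id=pid, stimulus_id=stim, onset_ms=0)
            )
    return saccades, metas
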