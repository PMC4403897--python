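"""Seeded synthetic cohorts of tongue-pressure trials.

No public recordings of palatal tongue-pressure waveforms exist, so every
downstream stage (extraction, calibration of analysis choices, cohort
statistics) is exercised on simulated data. The generator emulates the two
study tasks:

* **ITS** (isometric tongue strength): a smooth rise, a noisy ~3 s hold
  near the participant's maximum, and a release back to baseline.
* **ITE** (isometric tongue endurance): a rise above the 100 mmHg
  threshold followed by a linearly fatiguing plateau, calibrated so the
  pressure first drops below the threshold exactly ``endurance`` seconds
  after it first rose above it, then a rapid release.

Population parameters default to the gender-specific summary statistics of
a published normative pilot cohort: peak strength pressures are Normal
(males 573.74 +/- 143.11 mmHg, females 488.24 +/- 108.96 mmHg; endurance
peaks 556.20 +/- 138.33 and 539.80 +/- 149.83), and endurance durations are
lognormal with parameters solved from the reported medians and IQRs
(males 10.25 s, IQR 7.96-16.80; females 13.15 s, IQR 9.89-20.50).

The per-participant latent peak is the *personal best*: the value the
max-across-trials aggregation recovers. One of the two trials realises it
exactly; the other falls short by a uniform shortfall. Generated traces
are rescaled so the realised sample maximum equals the drawn peak, so the
configured distribution describes achieved maxima — which is what the
summary tables of strength studies report.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy import stats

from .features import DEFAULT_THRESHOLD_MMHG, PressureTrace

__all__ = [
    "TaskProfile",
    "GenderParams",
    "CohortConfig",
    "SimulatedParticipant",
    "SimulatedCohort",
    "simulate_its_trace",
    "simulate_ite_trace",
    "inject_artifact",
    "simulate_cohort",
    "lognormal_from_median_iqr",
]

#: Probit of 0.75; quartiles of a lognormal sit at exp(mu -/+ z75*sigma).
_Z75 = stats.norm.ppf(0.75)


def lognormal_from_median_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Solve (mu, sigma) of a lognormal from its median and quartiles.

    ``mu = log(median)`` matches the median exactly; ``sigma`` is chosen so
    the ratio of the quartiles matches (a two-parameter family cannot match
    median, Q1 and Q3 simultaneously).
    """
    if not (0 < q1 < median < q3):
        raise ValueError("need 0 < q1 < median < q3")
    return math.log(median), math.log(q3 / q1) / (2 * _Z75)


@dataclass(frozen=True)
class TaskProfile:
    """Waveform-shape parameters for one task.

    Durations are seconds, pressures mmHg. ``fatigue_rate`` is the fraction
    of the peak lost per second on an endurance plateau when no explicit
    endurance target overrides it; the cohort generator calibrates decay to
    the drawn endurance instead.
    """

    rise_time: float = 0.5
    hold_time_mean: float = 3.0
    hold_time_sd: float = 0.3
    plateau_noise_sd: float = 5.0
    fatigue_rate: float = 0.05
    release_time: float = 0.4
    baseline_time: float = 0.5

    def __post_init__(self):
        for name in ("rise_time", "hold_time_mean", "release_time", "baseline_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hold_time_sd < 0 or self.plateau_noise_sd < 0 or self.fatigue_rate < 0:
            raise ValueError("sd and rate parameters must be non-negative")


@dataclass(frozen=True)
class GenderParams:
    """Population parameters for one gender."""

    pmaxS_mean: float
    pmaxS_sd: float
    pmaxE_mean: float
    pmaxE_sd: float
    t100_median: float
    t100_iqr: tuple[float, float]

    def __post_init__(self):
        if min(self.pmaxS_mean, self.pmaxE_mean) <= DEFAULT_THRESHOLD_MMHG:
            raise ValueError("peak-pressure means must exceed 100 mmHg")
        if min(self.pmaxS_sd, self.pmaxE_sd) <= 0:
            raise ValueError("peak-pressure sds must be positive")
        q1, q3 = self.t100_iqr
        if not (0 < q1 < self.t100_median < q3):
            raise ValueError("t100 IQR must bracket the median")


MALE_DEFAULTS = GenderParams(
    pmaxS_mean=573.74, pmaxS_sd=143.11,
    pmaxE_mean=556.20, pmaxE_sd=138.33,
    t100_median=10.25, t100_iqr=(7.96, 16.80),
)
FEMALE_DEFAULTS = GenderParams(
    pmaxS_mean=488.24, pmaxS_sd=108.96,
    pmaxE_mean=539.80, pmaxE_sd=149.83,
    t100_median=13.15, t100_iqr=(9.89, 20.50),
)


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a simulated cohort.

    ``strength_endurance_corr`` couples a participant's two latent peaks
    (the same tongue produces both). ``peak_floor`` keeps latent peaks
    physiological by truncated redraw; ``sensor_max`` clips generated
    samples to the sensor span.
    """

    n_male: int = 16
    n_female: int = 18
    male: GenderParams = MALE_DEFAULTS
    female: GenderParams = FEMALE_DEFAULTS
    age_range: tuple[float, float] = (18.0, 40.0)
    sampling_rate: float = 100.0
    trials_per_task: int = 2
    artifact_probability: float = 0.1
    strength_endurance_corr: float = 0.7
    trial_shortfall_max: float = 0.1
    peak_floor: float = 150.0
    sensor_max: float = 1500.0
    profile: TaskProfile = TaskProfile()
    seed: int = 0

    def __post_init__(self):
        if self.n_male < 0 or self.n_female < 0 or self.n_male + self.n_female < 1:
            raise ValueError("cohort needs at least one participant")
        if not 0 <= self.artifact_probability <= 1:
            raise ValueError("artifact_probability must lie in [0, 1]")
        if not -1 < self.strength_endurance_corr < 1:
            raise ValueError("strength_endurance_corr must lie in (-1, 1)")
        if self.trials_per_task < 1:
            raise ValueError("trials_per_task must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 <= self.trial_shortfall_max < 1:
            raise ValueError("trial_shortfall_max must lie in [0, 1)")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    """C1 ramp 0->1 on [0, 1] (half-cosine)."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(x, 0.0, 1.0)))


def _finalize(times, pressures, peak, sample_period, task, trial_index, sensor_max):
    p = np.clip(pressures, 0.0, sensor_max)
    m = p.max()
    if m > 0:
        p = p * (peak / m)  # realised maximum equals the drawn peak
    p = np.clip(p, 0.0, sensor_max)
    return PressureTrace(
        times=times, pressures=p, sample_period=sample_period,
        task=task, trial_index=trial_index,
    )


def simulate_its_trace(
    peak: float,
    profile: TaskProfile = TaskProfile(),
    rng: np.random.Generator | None = None,
    *,
    sampling_rate: float = 100.0,
    trial_index: int = 1,
    hold_time: float | None = None,
    sensor_max: float = 1500.0,
) -> PressureTrace:
    """Simulate a strength trial: rise, noisy hold near ``peak``, release.

    With zero plateau noise the extracted pmax equals ``peak`` exactly; a
    ``peak`` below the analysis threshold produces a trial the extraction
    stage flags as excluded.
    """
    if peak <= 0:
        raise ValueError("peak must be positive")
    rng = np.random.default_rng() if rng is None else rng
    dt = 1.0 / sampling_rate
    if hold_time is None:
        hold_time = max(0.5, rng.normal(profile.hold_time_mean, profile.hold_time_sd))
    total = profile.baseline_time + profile.rise_time + hold_time + profile.release_time
    times = np.arange(0.0, total + dt / 2, dt)
    t0 = profile.baseline_time
    t1 = t0 + profile.rise_time
    t2 = t1 + hold_time
    t3 = t2 + profile.release_time
    env = np.zeros_like(times)
    rise = (times >= t0) & (times < t1)
    env[rise] = peak * _smoothstep((times[rise] - t0) / profile.rise_time)
    hold = (times >= t1) & (times < t2)
    env[hold] = peak
    rel = (times >= t2) & (times <= t3)
    env[rel] = peak * (1.0 - _smoothstep((times[rel] - t2) / profile.release_time))
    noisy = hold | rise | rel
    if profile.plateau_noise_sd > 0:
        env[noisy] += rng.normal(0.0, profile.plateau_noise_sd, noisy.sum())
    return _finalize(times, env, peak, dt, "ITS", trial_index, sensor_max)


def simulate_ite_trace(
    peak: float,
    endurance: float,
    profile: TaskProfile = TaskProfile(),
    rng: np.random.Generator | None = None,
    *,
    sampling_rate: float = 100.0,
    trial_index: int = 1,
    threshold: float = DEFAULT_THRESHOLD_MMHG,
    sensor_max: float = 1500.0,
    constant_plateau: bool = False,
) -> PressureTrace:
    """Simulate an endurance trial with a fatiguing plateau.

    The linear decay from ``peak`` is calibrated so the pressure first
    drops below ``threshold`` exactly ``endurance`` seconds after it first
    rose above it: at zero noise the extracted t100 matches ``endurance``
    to within a couple of sample periods, and the trace holds exactly one
    supra-threshold segment. With ``constant_plateau`` the pressure holds
    at ``peak`` without fatigue and is cut at the same instant (the
    zero-fatigue rectangle limit, whose pressure-time product approaches
    peak times duration).
    """
    if peak <= threshold:
        raise ValueError("peak must exceed the analysis threshold")
    if endurance <= 0:
        raise ValueError("endurance must be positive")
    rng = np.random.default_rng() if rng is None else rng
    dt = 1.0 / sampling_rate
    t0 = profile.baseline_time
    t1 = t0 + profile.rise_time
    # linear rise crosses the threshold at t_up < t1
    t_up = t0 + profile.rise_time * threshold / peak
    t_down = t_up + endurance  # decay must reach threshold here
    if t_down <= t1:
        raise ValueError(
            "infeasible endurance: threshold would be re-crossed during the rise"
        )
    decay_rate = 0.0 if constant_plateau else (peak - threshold) / (t_down - t1)
    total = t_down + profile.release_time
    times = np.arange(0.0, total + dt / 2, dt)
    env = np.zeros_like(times)
    rise = (times >= t0) & (times < t1)
    env[rise] = peak * (times[rise] - t0) / profile.rise_time
    plateau = (times >= t1) & (times < t_down)
    env[plateau] = peak - decay_rate * (times[plateau] - t1)
    cut_from = peak if constant_plateau else threshold
    rel = (times >= t_down) & (times <= total)
    env[rel] = cut_from * (1.0 - _smoothstep((times[rel] - t_down) / profile.release_time))
    active = rise | plateau | rel
    if profile.plateau_noise_sd > 0:
        env[active] += rng.normal(0.0, profile.plateau_noise_sd, active.sum())
    return _finalize(times, env, peak, dt, "ITE", trial_index, sensor_max)


def inject_artifact(
    trace: PressureTrace,
    rng: np.random.Generator | None = None,
    *,
    peak_range: tuple[float, float] = (40.0, 99.0),
    max_width: float = 0.3,
) -> PressureTrace:
    """Add a brief sub-threshold probing blip on the pre-effort baseline.

    Emulates a tongue inadvertently probing the sensor before the cued
    effort: a smooth bump shorter than ``max_width`` seconds with a peak
    below the 100 mmHg threshold, superposed where the trace is at
    baseline. Extracted features are unchanged by construction.
    """
    rng = np.random.default_rng() if rng is None else rng
    t = trace.times
    p = trace.pressures
    lo, hi = peak_range
    amp = rng.uniform(lo, hi)
    width = rng.uniform(0.1, max_width)
    # place the blip inside the leading baseline (before pressure leaves 0)
    nonzero = np.flatnonzero(p > 1e-9)
    t_effort = t[nonzero[0]] if len(nonzero) else t[-1]
    t_end = min(t_effort - 0.02, t[0] + width) if t_effort - t[0] > width + 0.02 else None
    if t_end is None:
        # no usable baseline window; extend the trace backwards is not
        # allowed (times start at 0), so leave the trace unmodified
        return trace
    center = t[0] + width / 2
    bump = amp * np.exp(-0.5 * ((t - center) / (width / 6)) ** 2)
    bump[np.abs(t - center) > width / 2] = 0.0
    # blip sits on the zero baseline and amp <= 99, hence stays sub-threshold
    new_p = np.minimum(np.clip(p + bump, 0.0, None), np.maximum(p, 99.5))
    return PressureTrace(
        times=t, pressures=new_p,
        sample_period=trace.sample_period, task=trace.task,
        trial_index=trace.trial_index,
    )


@dataclass(frozen=True)
class SimulatedParticipant:
    """Latent values and generated trials for one participant."""

    participant_id: str
    gender: Literal["male", "female"]
    age: float
    latent_pmaxS: float
    latent_pmaxE: float
    latent_endurance: float
    its_trials: tuple[PressureTrace, ...]
    ite_trials: tuple[PressureTrace, ...]


@dataclass(frozen=True)
class SimulatedCohort:
    """A generated cohort plus its provenance (config and seed)."""

    participants: tuple[SimulatedParticipant, ...]
    config: CohortConfig

    @property
    def n_traces(self) -> int:
        return sum(len(p.its_trials) + len(p.ite_trials) for p in self.participants)


def _draw_truncated_normal(rng, mean, sd, floor, size):
    """Normal draws redrawn until above ``floor`` (keeps peaks physiological)."""
    out = rng.normal(mean, sd, size)
    bad = out <= floor
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= floor
    return out


def _draw_latents(rng, params: GenderParams, n: int, corr: float, floor: float):
    cov = np.array([[1.0, corr], [corr, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    pmaxS = params.pmaxS_mean + params.pmaxS_sd * z[:, 0]
    pmaxE = params.pmaxE_mean + params.pmaxE_sd * z[:, 1]
    # redraw non-physiological peaks independently (rare at default params)
    bad = pmaxS <= floor
    if bad.any():
        pmaxS[bad] = _draw_truncated_normal(
            rng, params.pmaxS_mean, params.pmaxS_sd, floor, int(bad.sum())
        )
    bad = pmaxE <= floor
    if bad.any():
        pmaxE[bad] = _draw_truncated_normal(
            rng, params.pmaxE_mean, params.pmaxE_sd, floor, int(bad.sum())
        )
    mu, sigma = lognormal_from_median_iqr(params.t100_median, *params.t100_iqr)
    endurance = rng.lognormal(mu, sigma, n)
    return pmaxS, pmaxE, endurance


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Generate a full cohort of ITS and ITE trials, reproducible from the seed.

    Per participant, latent personal-best peaks (bivariate normal across
    the two tasks) and a lognormal endurance are drawn from the
    gender-specific distributions; ``trials_per_task`` trials are generated
    per task, one of which realises the personal best while the others fall
    short by a uniform fraction up to ``trial_shortfall_max``.
    """
    rng = np.random.default_rng(config.seed)
    participants: list[SimulatedParticipant] = []
    idx = 0
    for gender, n, params in (
        ("male", config.n_male, config.male),
        ("female", config.n_female, config.female),
    ):
        if n == 0:
            continue
        pmaxS, pmaxE, endurance = _draw_latents(
            rng, params, n, config.strength_endurance_corr, config.peak_floor
        )
        ages = rng.uniform(*config.age_range, n)
        for i in range(n):
            idx += 1
            pid = f"P{idx:04d}"
            k = config.trials_per_task
            best_its = int(rng.integers(k))
            best_ite = int(rng.integers(k))
            its, ite = [], []
            for j in range(k):
                fS = 1.0 if j == best_its else 1.0 - rng.uniform(0, config.trial_shortfall_max)
                trace = simulate_its_trace(
                    pmaxS[i] * fS, config.profile, rng,
                    sampling_rate=config.sampling_rate, trial_index=j + 1,
                    sensor_max=config.sensor_max,
                )
                if rng.uniform() < config.artifact_probability:
                    trace = inject_artifact(trace, rng)
                its.append(trace)
                fE = 1.0 if j == best_ite else 1.0 - rng.uniform(0, config.trial_shortfall_max)
                trace = simulate_ite_trace(
                    pmaxE[i] * fE, endurance[i] * fE, config.profile, rng,
                    sampling_rate=config.sampling_rate, trial_index=j + 1,
                    sensor_max=config.sensor_max,
                )
                if rng.uniform() < config.artifact_probability:
                    trace = inject_artifact(trace, rng)
                ite.append(trace)
            participants.append(
                SimulatedParticipant(
                    participant_id=pid, gender=gender, age=float(ages[i]),
                    latent_pmaxS=float(pmaxS[i]), latent_pmaxE=float(pmaxE[i]),
                    latent_endurance=float(endurance[i]),
                    its_trials=tuple(its), ite_trials=tuple(ite),
                )
            )
    return SimulatedCohort(participants=tuple(participants), config=config)
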