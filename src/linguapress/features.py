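"""Feature extraction from isometric tongue-pressure waveforms.

A trial is a gauge-pressure trace (mmHg vs. seconds, nominally 100 Hz)
recorded while a participant pushes the tongue against a palatal sensor.
Four parameters summarise a trial:

* ``pmax`` — the maximum pressure reached (PmaxS for a strength trial,
  PmaxE for an endurance trial);
* ``t100`` — the time the pressure stays above the 100 mmHg analysis
  threshold, measured between interpolated threshold crossings;
* ``pt100`` — the pressure-time product (area under the pressure-time
  curve, an impulse analogue) over the supra-threshold region;
* the exclusion flag — trials that never exceed 100 mmHg carry no usable
  effort and are excluded from analysis.

The 100 mmHg threshold separates deliberate effort from probing artifacts
(a tongue briefly touching the sensor); everything below it is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "DEFAULT_THRESHOLD_MMHG",
    "MMHG_PER_KPA",
    "PressureTrace",
    "Segment",
    "FeatureSet",
    "convert_mmHg_to_kPa",
    "convert_kPa_to_mmHg",
    "extract_peak_segments",
    "compute_pmax",
    "compute_t100",
    "compute_pt100",
    "extract_features",
    "aggregate_trials",
]

#: Analysis threshold separating deliberate tongue effort from probing
#: artifacts, in mmHg.
DEFAULT_THRESHOLD_MMHG = 100.0

#: 1 mmHg = 133.3224 Pa.
KPA_PER_MMHG = 0.1333224
MMHG_PER_KPA = 1.0 / KPA_PER_MMHG

Task = Literal["ITS", "ITE"]


def convert_mmHg_to_kPa(p):
    """Convert a pressure from mmHg to kPa (1 mmHg = 133.3224 Pa)."""
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("pressure must be finite")
    out = p * KPA_PER_MMHG
    return float(out) if out.ndim == 0 else out


def convert_kPa_to_mmHg(p):
    """Inverse of :func:`convert_mmHg_to_kPa`; round-trips to 1e-9."""
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("pressure must be finite")
    out = p * MMHG_PER_KPA
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PressureTrace:
    """One trial's pressure waveform.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing, starting at 0.
    pressures
        Gauge pressures in mmHg, same length as ``times``, non-negative.
    sample_period
        Nominal sampling period in seconds (0.01 for the 100 Hz device).
    task
        ``"ITS"`` (strength, ~3 s push) or ``"ITE"`` (endurance, push
        until the pressure dips below threshold).
    trial_index
        1-based trial number within the task.
    """

    times: np.ndarray
    pressures: np.ndarray
    sample_period: float = 0.01
    task: Task = "ITS"
    trial_index: int = 1

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        pressures = np.asarray(self.pressures, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "pressures", pressures)
        if times.ndim != 1 or pressures.ndim != 1:
            raise ValueError("times and pressures must be 1-D")
        if len(times) != len(pressures):
            raise ValueError(
                f"times and pressures differ in length "
                f"({len(times)} vs {len(pressures)})"
            )
        if len(times) < 2:
            raise ValueError("trace has fewer than 2 samples")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(pressures)):
            raise ValueError("trace contains non-finite samples")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(pressures < 0):
            raise ValueError("pressures must be non-negative (gauge pressure)")
        if self.sample_period <= 0:
            raise ValueError("sample_period must be positive")
        med = float(np.median(dt))
        if abs(med - self.sample_period) > 0.2 * self.sample_period:
            raise ValueError(
                f"median inter-sample gap {med:.4g} s deviates more than 20% "
                f"from the nominal sample period {self.sample_period:g} s"
            )
        if self.task not in ("ITS", "ITE"):
            raise ValueError(f"task must be 'ITS' or 'ITE', got {self.task!r}")
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class Segment:
    """A maximal run of samples strictly above the analysis threshold.

    ``t_rise``/``t_fall`` are the threshold-crossing times obtained by
    linear interpolation between the bracketing samples (or the trace
    endpoints when the trace starts/ends above threshold).
    ``sample_span`` is the half-open index range ``[start, stop)`` of the
    supra-threshold samples.
    """

    t_rise: float
    t_fall: float
    sample_span: tuple[int, int]
    threshold: float

    def __post_init__(self):
        if self.t_fall < self.t_rise:
            raise ValueError("t_fall must be >= t_rise")

    @property
    def duration(self) -> float:
        return self.t_fall - self.t_rise


@dataclass(frozen=True)
class FeatureSet:
    """Extracted parameters for one trial (or one aggregated participant-task).

    ``pmax`` holds PmaxS for an ITS trial and PmaxE for an ITE trial.
    ``excluded`` is set when the trace never rises above the threshold, in
    which case ``t100 = pt100 = 0`` and the trial is dropped downstream.
    """

    pmax: float
    t100: float
    pt100: float
    threshold: float = DEFAULT_THRESHOLD_MMHG
    n_segments: int = 0
    excluded: bool = False
    segment: Segment | None = None
    aggregation_rule: str | None = None

    @property
    def pmax_kPa(self) -> float:
        return convert_mmHg_to_kPa(self.pmax)


def _interp_crossing(t0, t1, p0, p1, threshold):
    """Time at which the line through (t0,p0)-(t1,p1) crosses threshold."""
    return t0 + (threshold - p0) * (t1 - t0) / (p1 - p0)


def extract_peak_segments(
    trace: PressureTrace, threshold: float = DEFAULT_THRESHOLD_MMHG
) -> list[Segment]:
    """Find maximal contiguous runs of samples strictly above ``threshold``.

    Crossing times are linearly interpolated between the bracketing
    samples; a sample exactly at the threshold is a crossing point, not a
    member of a run. Single-sample runs are retained. Returns an empty
    list when the trace never exceeds the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    t = trace.times
    p = trace.pressures
    above = p > threshold
    if not above.any():
        return []
    # run boundaries from the sign changes of `above`
    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = edges[~above[edges]] + 1
    stops = edges[above[edges]] + 1
    if above[0]:
        starts = np.concatenate(([0], starts))
    if above[-1]:
        stops = np.concatenate((stops, [len(p)]))
    segments = []
    for start, stop in zip(starts, stops):
        if start == 0:
            t_rise = float(t[0])
        else:
            t_rise = _interp_crossing(
                t[start - 1], t[start], p[start - 1], p[start], threshold
            )
        if stop == len(p):
            t_fall = float(t[-1])
        else:
            t_fall = _interp_crossing(
                t[stop - 1], t[stop], p[stop - 1], p[stop], threshold
            )
        segments.append(
            Segment(
                t_rise=float(t_rise),
                t_fall=float(t_fall),
                sample_span=(int(start), int(stop)),
                threshold=float(threshold),
            )
        )
    return segments


def compute_pmax(trace: PressureTrace) -> float:
    """Maximum sample pressure over the whole trial (PmaxS / PmaxE)."""
    return float(np.max(trace.pressures))


def compute_t100(segment: Segment) -> float:
    """Supra-threshold duration ``t_fall - t_rise`` in seconds."""
    return segment.duration


def compute_pt100(trace: PressureTrace, segment: Segment) -> float:
    """Pressure-time product over one supra-threshold segment, in mmHg*s.

    Trapezoidal integral of the absolute pressure (area down to 0, not the
    excess over the threshold) from ``t_rise`` to ``t_fall``. The boundary
    contributions use the interpolated crossing points, where the pressure
    equals the threshold; when the segment abuts a trace endpoint the
    recorded endpoint sample is used instead.
    """
    start, stop = segment.sample_span
    if segment.duration == 0.0:
        return 0.0
    t = trace.times[start:stop]
    p = trace.pressures[start:stop]
    ts, ps = [t], [p]
    if segment.t_rise < t[0]:
        ts.insert(0, [segment.t_rise])
        ps.insert(0, [segment.threshold])
    if segment.t_fall > t[-1]:
        ts.append([segment.t_fall])
        ps.append([segment.threshold])
    tt = np.concatenate(ts)
    pp = np.concatenate(ps)
    return float(np.trapezoid(pp, tt))


def extract_features(
    trace: PressureTrace, threshold: float = DEFAULT_THRESHOLD_MMHG
) -> FeatureSet:
    """Extract the four trial parameters, applying the exclusion rule.

    The analysis segment is the supra-threshold segment with the largest
    pressure-time product (earliest ``t_rise`` on ties); ``t100`` and
    ``pt100`` are computed over it, ``pmax`` over the whole trace. A trace
    that never exceeds the threshold yields ``t100 = pt100 = 0`` with the
    exclusion flag set.
    """
    segments = extract_peak_segments(trace, threshold)
    if not segments:
        return FeatureSet(
            pmax=compute_pmax(trace),
            t100=0.0,
            pt100=0.0,
            threshold=threshold,
            n_segments=0,
            excluded=True,
        )
    areas = [compute_pt100(trace, s) for s in segments]
    best = max(range(len(segments)), key=lambda i: (areas[i], -segments[i].t_rise))
    seg = segments[best]
    return FeatureSet(
        pmax=compute_pmax(trace),
        t100=compute_t100(seg),
        pt100=areas[best],
        threshold=threshold,
        n_segments=len(segments),
        excluded=False,
        segment=seg,
    )


AggregationRule = Literal["max", "mean"]


def aggregate_trials(
    features: Sequence[FeatureSet], rule: AggregationRule = "max"
) -> FeatureSet:
    """Combine per-trial features into one per-participant value.

    ``rule="max"`` (strength-testing convention: the personal best) takes
    the element-wise maximum of pmax/t100/pt100 across non-excluded
    trials; ``rule="mean"`` their arithmetic mean. Raises ``ValueError``
    when every trial is excluded — the participant is then missing for
    this task.
    """
    if rule not in ("max", "mean"):
        raise ValueError(f"unknown aggregation rule {rule!r}")
    kept = [f for f in features if not f.excluded]
    if not kept:
        raise ValueError("all trials excluded: participant missing for this task")
    agg = np.max if rule == "max" else np.mean
    thresholds = {f.threshold for f in kept}
    if len(thresholds) > 1:
        raise ValueError("trials were extracted with different thresholds")
    return FeatureSet(
        pmax=float(agg([f.pmax for f in kept])),
        t100=float(agg([f.t100 for f in kept])),
        pt100=float(agg([f.pt100 for f in kept])),
        threshold=thresholds.pop(),
        n_segments=max(f.n_segments for f in kept),
        excluded=False,
        aggregation_rule=rule,
    )
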