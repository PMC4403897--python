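"""Shared fixtures: analytically tractable worked traces.

The rectangle and triangle traces are built so their 100 mmHg threshold
crossings land exactly on known times, giving closed-form t100 and Pt100.
"""

import numpy as np
import pytest

from linguapress import PressureTrace


def make_rect_trace(level=200.0, start=1.0, stop=5.0, total=8.0, dt=0.01, eps=1e-9):
    """Rectangular pulse with near-vertical edges.

    Edge samples at ``start +/- eps`` make the interpolated threshold
    crossing land at ``start`` exactly when ``level = 2 * threshold``;
    the pulse area approaches ``level * (stop - start)``.
    """
    times = np.concatenate([
        np.arange(0.0, start - 2 * dt, dt),
        [start - eps, start + eps],
        np.arange(start + dt, stop - dt / 2, dt),
        [stop - eps, stop + eps],
        np.arange(stop + dt, total, dt),
    ])
    pressures = np.where((times > start - eps / 2) & (times < stop + eps / 2), level, 0.0)
    return PressureTrace(times, pressures)


def make_triangle_trace(peak=300.0, apex=3.0, total=6.0, dt=0.01):
    """Symmetric triangle 0 -> peak -> 0 with vertices on sample points."""
    times = np.arange(0.0, total + dt / 2, dt)
    slope = peak / apex
    pressures = np.where(times <= apex, slope * times, peak - slope * (times - apex))
    return PressureTrace(times, np.clip(pressures, 0.0, None))


def make_noisy_plateau(rng, level=None, hold=None, dt=0.01):
    """Smooth random plateau trial with mild noise (for numeric oracles)."""
    level = rng.uniform(200.0, 600.0) if level is None else level
    hold = rng.uniform(2.0, 6.0) if hold is None else hold
    rise, rel = 0.5, 0.5
    total = 0.5 + rise + hold + rel
    t = np.arange(0.0, total, dt)
    env = np.zeros_like(t)
    up = (t >= 0.5) & (t < 0.5 + rise)
    env[up] = level * (t[up] - 0.5) / rise
    mid = (t >= 0.5 + rise) & (t < 0.5 + rise + hold)
    env[mid] = level + rng.normal(0.0, 3.0, mid.sum())
    down = t >= 0.5 + rise + hold
    env[down] = np.clip(level * (1 - (t[down] - (0.5 + rise + hold)) / rel), 0.0, None)
    return PressureTrace(t, np.clip(env, 0.0, None))


@pytest.fixture
def rect_trace():
    return make_rect_trace()


@pytest.fixture
def triangle_trace():
    return make_triangle_trace()


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
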