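"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from buridan import (Burst, FilterConfig, StepSeries, Trajectory, derive_steps,
                     gen_cohort, SimParams)

settings.register_profile(
    "suite", deadline=None, max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def burst_from_points(points, hz: float = 10.0, t0: float = 0.0) -> Burst:
    """Build an evenly sampled burst from a list of (x, y) points."""
    pts = np.asarray(points, dtype=float)
    t = t0 + np.arange(len(pts)) / hz
    return Burst(t=t, x=pts[:, 0], y=pts[:, 1])


def traj_from_points(points, hz: float = 10.0) -> Trajectory:
    return Trajectory(bursts=[burst_from_points(points, hz)])


def steps_from_points(points, hz: float = 10.0,
                      config: FilterConfig | None = None) -> StepSeries:
    cfg = config or FilterConfig(resample_hz=hz)
    return derive_steps(traj_from_points(points, hz), cfg)


def random_walk_points(rng: np.random.Generator, n: int = 40,
                       pause_prob: float = 0.4, step: float = 2.0):
    """A small random path with genuine pauses, for oracle comparisons."""
    pts = [np.zeros(2)]
    for _ in range(n):
        if rng.random() < pause_prob:
            pts.append(pts[-1].copy())
        else:
            ang = rng.uniform(0, 2 * np.pi)
            r = step * rng.random()
            pts.append(pts[-1] + r * np.array([np.cos(ang), np.sin(ang)]))
    return np.array(pts)


@pytest.fixture(scope="session")
def correlated_cohort():
    """A 20-walk correlated cohort with the shipped defaults."""
    return gen_cohort("correlated", 20, SimParams.defaults("correlated"), seed=11)


@pytest.fixture(scope="session")
def levy_cohort():
    return gen_cohort("levy", 20, SimParams.defaults("levy"), seed=12)
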