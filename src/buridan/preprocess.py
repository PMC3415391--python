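"""Trajectory preprocessing: resampling, jitter filtering, step series.

Every behavioural metric is defined on an evenly sampled (10 Hz),
noise-filtered trajectory.  Preprocessing runs per burst — a burst is a
maximal uninterrupted tracking segment, and the animal may have been
physically moved between bursts, so no interpolation or step ever crosses
a burst boundary.

The pipeline is: linear resampling onto a 10 Hz grid anchored at the burst
start, then a sequential minimum-movement filter that snaps sub-threshold
displacements (default < 0.8 mm, centroid jitter from camera noise or
grooming) back onto the previous position, recomputing downstream
distances from the rewritten point.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = [
    "Burst",
    "Trajectory",
    "StepSeries",
    "FilterConfig",
    "resample_burst",
    "resample",
    "filter_min_movement",
    "derive_steps",
    "preprocess",
]

log = logging.getLogger(__name__)


@dataclass
class Burst:
    """One uninterrupted tracking segment: times (s) and positions (mm)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValidationError("t, x, y must have equal length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("timestamps must be strictly increasing within a burst")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0


@dataclass
class Trajectory:
    """A burst-segmented trajectory in the arena-centred mm frame."""

    bursts: list[Burst]

    def n_samples(self) -> int:
        return sum(len(b) for b in self.bursts)

    def duration_s(self) -> float:
        return sum(b.duration_s for b in self.bursts)

    def positions(self) -> np.ndarray:
        """All samples stacked, shape (n, 2), burst order preserved."""
        if not self.bursts:
            return np.empty((0, 2))
        return np.concatenate([np.column_stack([b.x, b.y]) for b in self.bursts])


@dataclass(frozen=True)
class FilterConfig:
    """Preprocessing thresholds.

    min_move_mm : displacements smaller than this are treated as jitter
        and snapped back (strict comparison: exactly 0.8 mm is kept).
    resample_hz : target sampling rate of the even grid.
    jump_speed_mms : speeds above this are flagged as jumps; jumps are
        excluded from the median speed but kept in the distance total.
    """

    min_move_mm: float = 0.8
    resample_hz: float = 10.0
    jump_speed_mms: float = 50.0

    def __post_init__(self) -> None:
        if self.min_move_mm < 0 or self.resample_hz <= 0 or self.jump_speed_mms <= 0:
            raise ValidationError("filter thresholds must be positive")


def resample_burst(burst: Burst, hz: float = 10.0) -> Burst | None:
    """Linearly interpolate one burst onto an even grid anchored at its start.

    The grid starts at the burst's first timestamp with spacing ``1/hz``
    and ends at or before its last timestamp.  Single-point bursts carry
    no step information and are dropped with a warning.
    """
    if len(burst) < 2:
        log.warning("dropping single-point burst (no steps can be derived)")
        return None
    dt = 1.0 / hz
    span = burst.t[-1] - burst.t[0]
    # 1e-9 guard keeps a grid point that lands on the last sample despite
    # floating-point rounding of the span.
    n = int(math.floor(span / dt + 1e-9)) + 1
    t_new = burst.t[0] + dt * np.arange(n)
    x_new = np.interp(t_new, burst.t, burst.x)
    y_new = np.interp(t_new, burst.t, burst.y)
    return Burst(t=t_new, x=x_new, y=y_new)


def resample(traj: Trajectory, hz: float = 10.0) -> Trajectory:
    """Resample every burst; bursts too short to resample are dropped."""
    out = [rb for b in traj.bursts if (rb := resample_burst(b, hz)) is not None]
    return Trajectory(bursts=out)


def filter_min_movement(burst: Burst, min_move_mm: float = 0.8) -> Burst:
    """Sequential minimum-displacement filter (idempotent).

    Walks the burst once: whenever the displacement from the previous
    *rewritten* position is smaller than the threshold, the point is
    rewritten onto that position, and the displacement to the next point
    is measured from there.  Genuine slow progress therefore accumulates
    until it clears the threshold in a single kept step, while isolated
    jitter is erased entirely.
    """
    x = burst.x.copy()
    y = burst.y.copy()
    if len(x) == 0:
        return Burst(t=burst.t.copy(), x=x, y=y)
    ax, ay = x[0], y[0]
    for i in range(1, len(x)):
        if math.hypot(x[i] - ax, y[i] - ay) < min_move_mm:
            x[i], y[i] = ax, ay
        else:
            ax, ay = x[i], y[i]
    return Burst(t=burst.t.copy(), x=x, y=y)


@dataclass
class StepSeries:
    """Per-step kinematics of a preprocessed trajectory.

    One entry per within-burst consecutive sample pair.  ``alpha`` is the
    absolute movement angle in degrees (NaN for zero-length steps);
    ``gamma`` is the turning angle between the two nearest moving steps,
    assigned to the later one and wrapped to (-180, 180] (NaN elsewhere) —
    a pause between two moving steps does not break the pair, because a
    heading is only defined while moving.  ``dt`` is the sample interval
    in seconds, so ``speed = length / dt``.
    """

    burst: np.ndarray          # burst index per step
    t: np.ndarray              # start time of each step (s)
    x0: np.ndarray
    y0: np.ndarray
    x1: np.ndarray
    y1: np.ndarray
    length: np.ndarray         # mm
    speed: np.ndarray          # mm/s
    alpha: np.ndarray          # deg, NaN when length == 0
    gamma: np.ndarray          # deg in (-180, 180], NaN when undefined
    is_jump: np.ndarray        # speed > jump threshold
    dt: float = 0.1

    def __len__(self) -> int:
        return self.length.size

    @property
    def moving(self) -> np.ndarray:
        return self.length > 0


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    """Wrap angle differences into (-180, 180]."""
    w = -(np.mod(-np.asarray(a, dtype=float) + 180.0, 360.0) - 180.0)
    return w


def derive_steps(traj: Trajectory, config: FilterConfig | None = None) -> StepSeries:
    """Derive the per-step series from a resampled, filtered trajectory."""
    config = config or FilterConfig()
    dt = 1.0 / config.resample_hz
    cols: dict[str, list] = {k: [] for k in
                             ("burst", "t", "x0", "y0", "x1", "y1",
                              "length", "speed", "alpha", "gamma")}
    for bi, b in enumerate(traj.bursts):
        if len(b) < 2:
            continue
        dx = np.diff(b.x)
        dy = np.diff(b.y)
        length = np.hypot(dx, dy)
        speed = length / dt
        alpha = np.degrees(np.arctan2(dy, dx))
        alpha[length == 0] = np.nan
        gamma = np.full_like(alpha, np.nan)
        mv = np.flatnonzero(length > 0)
        if mv.size >= 2:
            gamma[mv[1:]] = _wrap_deg(alpha[mv[1:]] - alpha[mv[:-1]])
        cols["burst"].append(np.full(length.size, bi))
        cols["t"].append(b.t[:-1])
        cols["x0"].append(b.x[:-1])
        cols["y0"].append(b.y[:-1])
        cols["x1"].append(b.x[1:])
        cols["y1"].append(b.y[1:])
        cols["length"].append(length)
        cols["speed"].append(speed)
        cols["alpha"].append(alpha)
        cols["gamma"].append(gamma)
    if not cols["length"]:
        empty = np.empty(0)
        return StepSeries(burst=np.empty(0, dtype=int), t=empty, x0=empty, y0=empty,
                          x1=empty, y1=empty, length=empty, speed=empty,
                          alpha=empty, gamma=empty,
                          is_jump=np.empty(0, dtype=bool), dt=dt)
    cat = {k: np.concatenate(v) for k, v in cols.items()}
    return StepSeries(
        burst=cat["burst"].astype(int), t=cat["t"],
        x0=cat["x0"], y0=cat["y0"], x1=cat["x1"], y1=cat["y1"],
        length=cat["length"], speed=cat["speed"],
        alpha=cat["alpha"], gamma=cat["gamma"],
        is_jump=cat["speed"] > config.jump_speed_mms, dt=dt,
    )


def preprocess(traj: Trajectory, config: FilterConfig | None = None) -> Trajectory:
    """Full pipeline: resample to the even grid, then jitter-filter.

    Resampling runs first so the filter sees evenly spaced displacements.
    """
    config = config or FilterConfig()
    traj = resample(traj, config.resample_hz)
    return Trajectory(bursts=[filter_min_movement(b, config.min_move_mm)
                              for b in traj.bursts])
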