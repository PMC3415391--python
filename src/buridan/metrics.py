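"""Per-individual behavioural metrics for circular-arena walking assays.

All metrics operate on the preprocessed 10 Hz step series (see
:mod:`buridan.preprocess`).  Medians are used throughout because the
underlying per-step distributions are heavy-tailed; group summaries later
take means and standard errors of the per-individual medians.

The eleven metrics:

median speed, total distance, median turning angle, meander,
centrophobism (moving / sitting), median stripe deviation, number of
stripe-to-stripe walks, and two activity segmentations — a stillness
duration threshold (TT: any pause longer than 1 s) and a dual speed
threshold with hysteresis on a 1 s sliding window (ST: walking above
2.7 mm/s, resting below 1 mm/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

from .calibration import ArenaGeometry
from .errors import ValidationError
from .preprocess import StepSeries, Trajectory

__all__ = [
    "ActivityConfig", "ActivitySummary", "MetricSet",
    "median_speed", "total_distance", "median_turning_angle", "meander",
    "centrophobism", "stripe_deviation", "count_walks",
    "activity_tt", "activity_st", "compute_metrics",
]


@dataclass(frozen=True)
class ActivityConfig:
    """Thresholds for the two activity segmentations.

    pause_threshold_s : a still period must exceed this to count as a
        pause in the TT segmentation (strict: exactly 1.0 s stays active).
    window_s : sliding-window length for the ST mean speed.
    st_low / st_high : hysteresis thresholds in mm/s — resting at or
        below the low one, walking at or above the high one, previous
        state kept in between.
    bout_displacement_mm : cumulative path length a TT bout must exceed
        to enter the long-bout median.
    """

    pause_threshold_s: float = 1.0
    window_s: float = 1.0
    st_low: float = 1.0
    st_high: float = 2.7
    bout_displacement_mm: float = 10.0

    def __post_init__(self) -> None:
        if not (self.st_low < self.st_high):
            raise ValidationError("st_low must be < st_high")


@dataclass
class ActivitySummary:
    """Summary of one activity segmentation."""

    total_time_s: float
    n_pauses: int
    median_pause_s: float      # NaN when no pauses
    median_bout_s: float       # NaN when no bouts
    median_bout_ge1cm_s: float = float("nan")   # TT only


@dataclass
class MetricSet:
    """All per-individual metrics; NaN marks an undefined value."""

    id: str = ""
    group: str = ""
    median_speed: float = float("nan")
    total_distance: float = float("nan")
    median_turning_angle: float = float("nan")
    meander: float = float("nan")
    centrophobism_moving: float = float("nan")
    centrophobism_sitting: float = float("nan")
    median_stripe_deviation: float = float("nan")
    n_walks: float = float("nan")
    tt_total_time_s: float = float("nan")
    tt_n_pauses: float = float("nan")
    tt_median_pause_s: float = float("nan")
    tt_median_bout_s: float = float("nan")
    tt_median_bout_ge1cm_s: float = float("nan")
    st_total_time_s: float = float("nan")
    st_n_pauses: float = float("nan")
    st_median_pause_s: float = float("nan")
    st_median_bout_s: float = float("nan")

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    ST_FIELDS = ("st_total_time_s", "st_n_pauses", "st_median_pause_s",
                 "st_median_bout_s")


def _median_or_nan(values: np.ndarray) -> float:
    return float(np.median(values)) if values.size else float("nan")


def median_speed(steps: StepSeries) -> float:
    """Median instantaneous speed over moving, non-jump steps (mm/s).

    Zero-length steps are pauses, not slow movement, and speeds above the
    jump threshold are tracking artefacts or jumps; both are excluded.
    Returns NaN when no step qualifies.
    """
    sel = steps.moving & ~steps.is_jump
    return _median_or_nan(steps.speed[sel])


def total_distance(steps: StepSeries) -> float:
    """Total path length in mm, jumps included."""
    return float(np.sum(steps.length))


def median_turning_angle(steps: StepSeries) -> float:
    """Median absolute turning angle in degrees (NaN if no turn defined)."""
    g = steps.gamma[~np.isnan(steps.gamma)]
    return _median_or_nan(np.abs(g))


def meander(steps: StepSeries) -> float:
    """Median tortuosity: |turning angle| / speed, in deg*s/mm.

    The speed paired with each turning angle is that of the later of the
    two moving steps defining it (the step the angle is assigned to).
    """
    sel = ~np.isnan(steps.gamma) & (steps.speed > 0)
    if not sel.any():
        return float("nan")
    return float(np.median(np.abs(steps.gamma[sel]) / steps.speed[sel]))


def centrophobism(traj: Trajectory, platform_radius_mm: float = 58.5
                  ) -> tuple[float, float]:
    """Centre-avoidance indices for moving and sitting samples.

    The arena splits into an inner disk of radius R/sqrt(2) and an outer
    ring of equal area; each 10 Hz sample is classified moving (nonzero
    displacement from the previous sample) or sitting, and per class the
    index is (N_out - N_in) / (N_out + N_in): +1 all outside, -1 all
    inside, 0 for a spatially uniform distribution.  The first sample of
    a burst has no previous displacement and counts as sitting.
    Returns (moving_index, sitting_index); NaN for an empty class.
    """
    r_in = platform_radius_mm / math.sqrt(2.0)
    counts = {True: [0, 0], False: [0, 0]}   # moving? -> [n_out, n_in]
    for b in traj.bursts:
        if len(b) == 0:
            continue
        rad = np.hypot(b.x, b.y)
        disp = np.concatenate([[0.0], np.hypot(np.diff(b.x), np.diff(b.y))])
        mov = disp > 0
        out = rad > r_in
        for m in (True, False):
            counts[m][0] += int(np.sum(out & (mov == m)))
            counts[m][1] += int(np.sum(~out & (mov == m)))
    def index(n_out: int, n_in: int) -> float:
        tot = n_out + n_in
        return (n_out - n_in) / tot if tot else float("nan")
    return index(*counts[True]), index(*counts[False])


def stripe_deviation(steps: StepSeries,
                     stripe_centers: tuple[tuple[float, float], tuple[float, float]]
                     = ((0.0, 146.5), (0.0, -146.5))) -> float:
    """Median angle between each movement and the stripe most in front.

    For every moving step, the angle between the velocity vector and the
    vector from the step's start position to each stripe centre is
    computed, and the smaller of the two is kept (the stripe in the
    direction of movement).  For stripe-free (endogenous) experiments the
    metric is still evaluated against the nominal stripe positions, which
    yields its chance level (median 45 deg for random walks).
    """
    sel = steps.moving
    if not sel.any():
        return float("nan")
    vx = steps.x1[sel] - steps.x0[sel]
    vy = steps.y1[sel] - steps.y0[sel]
    head = np.arctan2(vy, vx)
    best = np.full(vx.shape, np.inf)
    for sx, sy in stripe_centers:
        ang = np.arctan2(sy - steps.y0[sel], sx - steps.x0[sel])
        dev = np.abs(np.degrees(np.angle(np.exp(1j * (ang - head)))))
        best = np.minimum(best, dev)
    return float(np.median(best))


def count_walks(traj: Trajectory, platform_radius_mm: float = 58.5,
                stripe_axis: tuple[float, float] = (0.0, 1.0),
                zone_fraction: float = 0.8) -> int:
    """Number of stripe-to-stripe walks.

    The two end zones are the circular segments where the signed
    projection of the position onto the stripe axis exceeds +0.8 R (zone
    A) or falls below -0.8 R (zone B); one walk is counted for each
    passage from one zone to the other.
    """
    ax, ay = stripe_axis
    norm = math.hypot(ax, ay)
    if norm == 0:
        raise ValidationError("stripe axis must be nonzero")
    thresh = zone_fraction * platform_radius_mm
    walks = 0
    last_zone = 0
    for b in traj.bursts:
        proj = (b.x * ax + b.y * ay) / norm
        zones = np.where(proj > thresh, 1, np.where(proj < -thresh, -1, 0))
        for z in zones[zones != 0]:
            if last_zone != 0 and z != last_zone:
                walks += 1
            last_zone = z
    return walks


def _runs(flags: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode a boolean array as (start, length, value)."""
    out = []
    i = 0
    n = flags.size
    while i < n:
        j = i
        while j < n and flags[j] == flags[i]:
            j += 1
        out.append((i, j - i, bool(flags[i])))
        i = j
    return out


def activity_tt(steps: StepSeries, config: ActivityConfig | None = None
                ) -> ActivitySummary:
    """Time-threshold activity segmentation.

    Within each burst, a pause is a maximal run of zero-movement steps
    whose duration strictly exceeds the pause threshold; every other step
    (including still runs at or below the threshold) is active.  Total
    activity plus total pause time equals the record duration.  Bouts are
    the maximal active segments; the long-bout median keeps only bouts
    whose cumulative path length exceeds ``bout_displacement_mm``.
    """
    config = config or ActivityConfig()
    dt = steps.dt
    pause_durs: list[float] = []
    bout_durs: list[float] = []
    bout_durs_long: list[float] = []
    total_steps = 0
    pause_steps = 0
    for bi in np.unique(steps.burst):
        sel = steps.burst == bi
        length = steps.length[sel]
        total_steps += length.size
        still = length == 0
        is_pause = np.zeros(length.size, dtype=bool)
        for start, run, val in _runs(still):
            if val and run * dt > config.pause_threshold_s:
                is_pause[start:start + run] = True
                pause_durs.append(run * dt)
                pause_steps += run
        for start, run, val in _runs(is_pause):
            if not val:
                dur = run * dt
                bout_durs.append(dur)
                if float(np.sum(length[start:start + run])) > config.bout_displacement_mm:
                    bout_durs_long.append(dur)
    return ActivitySummary(
        total_time_s=(total_steps - pause_steps) * dt,
        n_pauses=len(pause_durs),
        median_pause_s=_median_or_nan(np.asarray(pause_durs)),
        median_bout_s=_median_or_nan(np.asarray(bout_durs)),
        median_bout_ge1cm_s=_median_or_nan(np.asarray(bout_durs_long)),
    )


def _st_classify(length: np.ndarray, dt: float, config: ActivityConfig
                 ) -> np.ndarray | None:
    """Hysteresis walking/resting state per sample of one burst.

    The mean speed at a sample is the path length in the 1 s window
    centred on it.  Samples whose window is truncated by the record edge
    inherit the state of the nearest fully-windowed sample.  Returns None
    when the burst is shorter than the window.
    """
    w = int(round(config.window_s / dt))          # steps per window
    half = w // 2
    n_samples = length.size + 1
    first = half
    last = n_samples - 1 - (w - half)
    if last < first:
        return None
    # window for sample i covers steps [i - half, i + (w - half))
    csum = np.concatenate([[0.0], np.cumsum(length)])
    idx = np.arange(first, last + 1)
    speed = (csum[idx + (w - half)] - csum[idx - half]) / config.window_s
    state = np.empty(idx.size, dtype=bool)        # True = walking
    cur = bool(speed[0] >= config.st_high)
    for i, v in enumerate(speed):
        if v >= config.st_high:
            cur = True
        elif v <= config.st_low:
            cur = False
        state[i] = cur
    full = np.empty(n_samples, dtype=bool)
    full[first:last + 1] = state
    full[:first] = state[0]
    full[last + 1:] = state[-1]
    return full


def activity_st(steps: StepSeries, config: ActivityConfig | None = None
                ) -> ActivitySummary:
    """Speed-threshold activity segmentation with hysteresis.

    Each 10 Hz sample is classified walking or resting from the distance
    travelled in the centred 1 s window (walking at or above ``st_high``,
    resting at or below ``st_low``, previous state kept in between).
    Rest runs are the pauses and walk runs the bouts; durations count
    samples times the sample interval.  Bursts shorter than the window
    are skipped; if none is long enough every output is NaN.
    """
    config = config or ActivityConfig()
    dt = steps.dt
    pause_durs: list[float] = []
    bout_durs: list[float] = []
    walk_samples = 0
    any_burst = False
    for bi in np.unique(steps.burst):
        length = steps.length[steps.burst == bi]
        state = _st_classify(length, dt, config)
        if state is None:
            continue
        any_burst = True
        walk_samples += int(np.sum(state))
        for _, run, val in _runs(state):
            (bout_durs if val else pause_durs).append(run * dt)
    if not any_burst:
        return ActivitySummary(float("nan"), 0, float("nan"), float("nan"))
    return ActivitySummary(
        total_time_s=walk_samples * dt,
        n_pauses=len(pause_durs),
        median_pause_s=_median_or_nan(np.asarray(pause_durs)),
        median_bout_s=_median_or_nan(np.asarray(bout_durs)),
    )


def compute_metrics(traj: Trajectory, steps: StepSeries,
                    geometry: ArenaGeometry | None = None,
                    activity: ActivityConfig | None = None,
                    id: str = "", group: str = "") -> MetricSet:
    """Evaluate all metrics on one preprocessed individual."""
    geometry = geometry or ArenaGeometry()
    activity = activity or ActivityConfig()
    cm, cs = centrophobism(traj, geometry.platform_radius_mm)
    tt = activity_tt(steps, activity)
    st = activity_st(steps, activity)
    return MetricSet(
        id=id, group=group,
        median_speed=median_speed(steps),
        total_distance=total_distance(steps),
        median_turning_angle=median_turning_angle(steps),
        meander=meander(steps),
        centrophobism_moving=cm,
        centrophobism_sitting=cs,
        median_stripe_deviation=stripe_deviation(steps, geometry.stripe_centers_mm),
        n_walks=count_walks(traj, geometry.platform_radius_mm, geometry.stripe_axis),
        tt_total_time_s=tt.total_time_s,
        tt_n_pauses=tt.n_pauses,
        tt_median_pause_s=tt.median_pause_s,
        tt_median_bout_s=tt.median_bout_s,
        tt_median_bout_ge1cm_s=tt.median_bout_ge1cm_s,
        st_total_time_s=st.total_time_s,
        st_n_pauses=st.n_pauses,
        st_median_pause_s=st.median_pause_s,
        st_median_bout_s=st.median_bout_s,
    )
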