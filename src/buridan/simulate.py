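"""Platform-bounded correlated walks and Lévy-walks with a pause process.

These generators establish chance levels for the arena metrics (median
stripe deviation, centrophobism) and provide cohorts with known
statistics for debugging the analysis chain.

Both walk types share the heading model: the first heading is uniform,
and every subsequent heading follows a wrapped normal distribution around
the previous one with concentration ``r`` (increment s.d.
``sigma = sqrt(-2 ln r)``).  The heading diffuses at every time step,
pauses included; turning angles measured later by the analysis are only
defined between moving steps, which is why a modest per-step sigma
(~4.8 deg at r = 0.9965) yields a median turning angle near 8 deg once
pauses stretch the effective gap between headings.

Step lengths are a Bernoulli pause process times a speed draw:

* correlated walk — draw = h_i * Chi(df)/E[Chi(df)], so the per-walk
  scale ``h_i`` is the mean step length in mm;
* Lévy-walk — draw = lo_i * U^(1/(1-mu)), the standard inverse-CDF
  power-law sampler (Pareto tail index mu - 1).

Per-walk scales are drawn once per individual, uniformly within the
configured spread, giving the cohort the between-individual variability a
correlation analysis needs.

Walks start at the arena centre.  An out-of-bounds candidate position is
replaced by its radial projection onto the platform rim and the heading
sequence restarts from a fresh uniform angle — so at the rim the next
movement points outward with probability > 0.5 and the walk tends to
linger at the border, as a real walk trapped on a moat-bounded
platform does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .preprocess import Burst, Trajectory

__all__ = ["SimParams", "SimWalk", "gen_headings", "gen_step_lengths",
           "apply_boundary", "simulate_walk", "gen_cohort"]


@dataclass(frozen=True)
class SimParams:
    """Generator parameters.

    Defaults are the shipped calibration: they reproduce the reference
    summary statistics (median moving speed ~13.4 / 13.9 mm/s, median
    turning angle ~8.3 deg, time-threshold activity ~33% of 900 s) for a
    standard 900 s, 10 Hz session on a 58.5 mm-radius platform.
    """

    kind: str = "correlated"        # "correlated" | "levy"
    n_steps: int = 8999             # movements; 9000 positions
    f: float = 0.15                 # per-step moving probability
    r: float = 0.9965               # wrapped-normal heading concentration
    h: float = 0.88                 # mean step length, mm (correlated; calibrated)
    h_spread: float = 0.3           # per-walk uniform half-range on h
    lo: float = 0.8                 # Lévy scale, mm
    lo_spread: float = 0.4
    mu: float = 2.6                 # Lévy exponent (> 1)
    chi_df: int = 1                 # d.o.f. of the Chi speed distribution (calibrated)
    platform_radius_mm: float = 58.5
    sample_hz: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("correlated", "levy"):
            raise ValidationError(f"unknown walk kind {self.kind!r}")
        if not (0.0 <= self.f <= 1.0):
            raise ValidationError("f must lie in [0, 1]")
        if not (0.0 < self.r < 1.0):
            raise ValidationError("r must lie in (0, 1)")
        if self.mu <= 1.0:
            raise ValidationError("mu must be > 1")

    @staticmethod
    def defaults(kind: str) -> "SimParams":
        """Shipped calibrated defaults for either walk kind."""
        if kind == "correlated":
            return SimParams(kind="correlated", f=0.15, r=0.9965)
        if kind == "levy":
            return SimParams(kind="levy", f=0.12, r=0.9963)
        raise ValidationError(f"unknown walk kind {kind!r}")

    @property
    def sigma_rad(self) -> float:
        """Wrapped-normal heading increment s.d. in radians."""
        return math.sqrt(-2.0 * math.log(self.r))


@dataclass
class SimWalk:
    """One simulated walk: positions (n_steps+1, 2) in mm at 10 Hz."""

    positions: np.ndarray
    params: SimParams
    scale: float                    # the per-walk h_i (or lo_i) actually used

    def to_trajectory(self) -> Trajectory:
        """View the walk as a single-burst Trajectory (already at 10 Hz)."""
        n = self.positions.shape[0]
        t = np.arange(n) / self.params.sample_hz
        return Trajectory(bursts=[Burst(t=t, x=self.positions[:, 0],
                                        y=self.positions[:, 1])])


def gen_headings(n: int, r: float, rng: np.random.Generator) -> np.ndarray:
    """Free (unbounded) heading sequence: uniform start, wrapped-normal steps.

    Returned in radians; increments have s.d. sqrt(-2 ln r), so the mean
    resultant length of the increment distribution is r.
    """
    if not (0.0 < r < 1.0):
        raise ValidationError("r must lie in (0, 1)")
    sigma = math.sqrt(-2.0 * math.log(r))
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    inc = rng.normal(0.0, sigma, size=n - 1) if n > 1 else np.empty(0)
    return np.concatenate([[theta0], theta0 + np.cumsum(inc)])


def _chi_mean(df: int) -> float:
    return math.sqrt(2.0) * math.gamma((df + 1) / 2.0) / math.gamma(df / 2.0)


def gen_step_lengths(params: SimParams, rng: np.random.Generator,
                     scale: float | None = None) -> np.ndarray:
    """Step lengths (mm) for one walk: Bernoulli(f) pauses times a draw.

    ``scale`` is the per-individual h (correlated) or lo (Lévy); when
    omitted the central default is used without spread.
    """
    n = params.n_steps
    moving = rng.random(n) < params.f
    if params.kind == "correlated":
        s = params.h if scale is None else scale
        chi = np.sqrt(rng.chisquare(params.chi_df, size=n))
        draw = s * chi / _chi_mean(params.chi_df)
    else:
        s = params.lo if scale is None else scale
        u = 1.0 - rng.random(n)          # in (0, 1]; avoids U = 0
        draw = s * u ** (1.0 / (1.0 - params.mu))
    return np.where(moving, draw, 0.0)


def apply_boundary(candidate: np.ndarray, platform_radius_mm: float) -> tuple[np.ndarray, bool]:
    """Clamp one candidate position into the platform disk.

    Returns the (possibly projected) position and whether the boundary
    was hit.  The nearest in-disk point to an outside candidate is its
    radial projection onto the rim.
    """
    rad = math.hypot(candidate[0], candidate[1])
    if rad <= platform_radius_mm:
        return candidate, False
    return candidate * (platform_radius_mm / rad), True


def simulate_walk(params: SimParams, rng: np.random.Generator,
                  scale: float | None = None) -> SimWalk:
    """Generate one platform-bounded walk.

    Positions are built iteratively from the arena centre.  The heading
    advances by a wrapped-normal increment at every step; after a
    boundary contact the heading sequence restarts from a fresh uniform
    angle at the next step.
    """
    n = params.n_steps
    R = params.platform_radius_mm
    if scale is None:
        scale = params.h if params.kind == "correlated" else params.lo
    lengths = gen_step_lengths(params, rng, scale)
    inc = rng.normal(0.0, params.sigma_rad, size=n)
    pos = np.empty((n + 1, 2))
    pos[0] = 0.0
    theta = rng.uniform(0.0, 2.0 * math.pi)
    restart = False
    for k in range(n):
        if restart:
            theta = rng.uniform(0.0, 2.0 * math.pi)
            restart = False
        elif k > 0:
            theta += inc[k]
        cand = pos[k] + lengths[k] * np.array([math.cos(theta), math.sin(theta)])
        pos[k + 1], hit = apply_boundary(cand, R)
        if hit:
            restart = True
    return SimWalk(positions=pos, params=params, scale=scale)


def gen_cohort(kind: str, n_walks: int = 20, params: SimParams | None = None,
               seed: int | np.random.SeedSequence = 0) -> list[SimWalk]:
    """Generate a cohort of independent walks, reproducible under ``seed``.

    Each walk draws its own speed scale uniformly within the configured
    spread (h +/- h_spread or lo +/- lo_spread) before the walk itself is
    generated.
    """
    if n_walks < 1:
        raise ValidationError("n_walks must be >= 1")
    params = params or SimParams.defaults(kind)
    if params.kind != kind:
        params = replace(params, kind=kind)
    rng = np.random.default_rng(seed)
    walks = []
    for _ in range(n_walks):
        if kind == "correlated":
            scale = rng.uniform(params.h - params.h_spread, params.h + params.h_spread)
        else:
            scale = rng.uniform(params.lo - params.lo_spread, params.lo + params.lo_spread)
        walks.append(simulate_walk(params, rng, scale))
    return walks
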