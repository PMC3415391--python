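"""Behavioural metrics: worked examples plus brute-force oracle equivalence.

The oracles recompute each metric with plain Python loops straight from
the position list, independently of the vectorized implementations.
"""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from buridan import (ActivityConfig, activity_st, activity_tt, centrophobism,
                     compute_metrics, count_walks, derive_steps, meander,
                     median_speed, median_turning_angle, stripe_deviation,
                     total_distance)

from conftest import (burst_from_points, random_walk_points,
                      steps_from_points, traj_from_points)

DT = 0.1


# ---------------------------------------------------------------- oracles

def _wrap(a):
    while a <= -180.0:
        a += 360.0
    while a > 180.0:
        a -= 360.0
    return a


def oracle_steps(points):
    """(length, alpha_or_None) per consecutive pair, via plain loops."""
    out = []
    for (x0, y0), (x1, y1) in zip(points[:-1], points[1:]):
        d = math.hypot(x1 - x0, y1 - y0)
        a = math.degrees(math.atan2(y1 - y0, x1 - x0)) if d > 0 else None
        out.append((d, a))
    return out


def oracle_median_speed(points, jump=50.0):
    sp = [d / DT for d, _ in oracle_steps(points) if 0 < d / DT <= jump]
    return statistics.median(sp) if sp else float("nan")


def oracle_total_distance(points):
    return sum(d for d, _ in oracle_steps(points))


def oracle_gammas(points):
    alphas = [a for _, a in oracle_steps(points) if a is not None]
    return [_wrap(a1 - a0) for a0, a1 in zip(alphas[:-1], alphas[1:])]


def oracle_median_turn(points):
    g = [abs(v) for v in oracle_gammas(points)]
    return statistics.median(g) if g else float("nan")


def oracle_meander(points):
    steps = oracle_steps(points)
    moving = [(i, d) for i, (d, a) in enumerate(steps) if a is not None]
    vals = []
    for (i0, _), (i1, d1) in zip(moving[:-1], moving[1:]):
        a0, a1 = steps[i0][1], steps[i1][1]
        vals.append(abs(_wrap(a1 - a0)) / (d1 / DT))
    return statistics.median(vals) if vals else float("nan")


def oracle_centrophobism(points, R=58.5):
    r_in = R / math.sqrt(2)
    n = {True: [0, 0], False: [0, 0]}
    prev = None
    for p in points:
        mov = prev is not None and math.hypot(p[0] - prev[0], p[1] - prev[1]) > 0
        outside = math.hypot(p[0], p[1]) > r_in
        n[mov][0 if outside else 1] += 1
        prev = p
    def idx(c):
        return (c[0] - c[1]) / (c[0] + c[1]) if sum(c) else float("nan")
    return idx(n[True]), idx(n[False])


def oracle_stripe_dev(points, centers=((0.0, 146.5), (0.0, -146.5))):
    vals = []
    for (x0, y0), (x1, y1) in zip(points[:-1], points[1:]):
        if (x0, y0) == (x1, y1):
            continue
        head = math.atan2(y1 - y0, x1 - x0)
        devs = []
        for sx, sy in centers:
            ang = math.atan2(sy - y0, sx - x0)
            devs.append(abs(_wrap(math.degrees(ang - head))))
        vals.append(min(devs))
    return statistics.median(vals) if vals else float("nan")


def oracle_count_walks(points, R=58.5):
    count, last = 0, 0
    for _, y in points:
        zone = 1 if y > 0.8 * R else (-1 if y < -0.8 * R else 0)
        if zone:
            if last and zone != last:
                count += 1
            last = zone
    return count


def oracle_activity_tt(points, pause_s=1.0):
    lengths = [d for d, _ in oracle_steps(points)]
    pauses, bouts = [], []
    runs, cur, val = [], 0, None
    for still in [d == 0 for d in lengths]:
        if still == val:
            cur += 1
        else:
            if val is not None:
                runs.append((val, cur))
            val, cur = still, 1
    if val is not None:
        runs.append((val, cur))
    is_pause = []
    for still, n in runs:
        p = still and n * DT > pause_s
        if p:
            pauses.append(n * DT)
        is_pause.extend([p] * n)
    # bouts: maximal non-pause segments
    i = 0
    while i < len(is_pause):
        if not is_pause[i]:
            j = i
            while j < len(is_pause) and not is_pause[j]:
                j += 1
            bouts.append((j - i) * DT)
            i = j
        else:
            i += 1
    active = (len(lengths) - sum(n for s, n in runs if s and n * DT > pause_s)) * DT
    return active, len(pauses), bouts


# ----------------------------------------------------------- worked examples

class TestMedianSpeed:
    def test_jump_excluded(self):
        # moving speeds 10 and 20 mm/s plus one 60 mm/s jump
        s = steps_from_points([(0, 0), (1, 0), (3, 0), (9, 0)])
        assert median_speed(s) == pytest.approx(15.0)

    def test_all_still_gives_nan(self):
        s = steps_from_points([(0, 0), (0, 0), (0, 0)])
        assert math.isnan(median_speed(s))


class TestTotalDistance:
    def test_simple_sum(self):
        s = steps_from_points([(0, 0), (1, 0), (3, 0), (6, 0)])
        assert total_distance(s) == pytest.approx(6.0)

    def test_empty(self):
        s = steps_from_points([(0, 0)])
        assert total_distance(s) == 0.0

    def test_jumps_counted_in_distance(self):
        s = steps_from_points([(0, 0), (6, 0), (10, 0)])
        assert s.is_jump[0]
        assert total_distance(s) == pytest.approx(10.0)


class TestTurningAngle:
    def test_straight_path(self):
        assert median_turning_angle(
            steps_from_points([(0, 0), (1, 0), (2, 0)])) == 0.0

    def test_alternating_right_angles(self):
        pts = [(0, 0), (1, 0), (1, 1), (2, 1), (2, 2)]
        assert median_turning_angle(steps_from_points(pts)) == pytest.approx(90.0)


class TestMeander:
    def test_straight_path_zero(self):
        assert meander(steps_from_points([(0, 0), (1, 0), (2, 0)])) == 0.0

    def test_single_turn_ratio(self):
        # 90 deg turn at 10 mm/s -> 9 deg*s/mm
        s = steps_from_points([(0, 0), (1, 0), (1, 1)])
        assert meander(s) == pytest.approx(9.0)

    def test_doubling_speed_halves_meander(self):
        slow = steps_from_points([(0, 0), (1, 0), (1, 1)])
        fast = steps_from_points([(0, 0), (2, 0), (2, 2)])
        assert meander(fast) == pytest.approx(meander(slow) / 2.0)


class TestCentrophobism:
    def test_all_outside(self):
        pts = [(50 * math.cos(a), 50 * math.sin(a))
               for a in np.linspace(0, 2 * math.pi, 20)]
        cm, cs = centrophobism(traj_from_points(pts))
        assert cm == 1.0 and cs == 1.0

    def test_even_split_is_zero(self):
        pts = [(0, 0)] * 5 + [(50, 0)] * 5    # 5 sitting in, 5 sitting out
        traj = traj_from_points(pts)
        # first 5 samples inside, one moving transition lands outside
        cm, cs = centrophobism(traj)
        assert cm == 1.0                       # the single moving sample is out
        assert cs == pytest.approx((4 - 5) / 9.0)

    def test_inner_disk_has_equal_area(self):
        R = 58.5
        r_in = R / math.sqrt(2)
        assert math.pi * r_in**2 == pytest.approx(math.pi * R**2 / 2)

    def test_bounds(self):
        rng = np.random.default_rng(2)
        pts = random_walk_points(rng, 60, step=10.0)
        cm, cs = centrophobism(traj_from_points(pts))
        for v in (cm, cs):
            if not math.isnan(v):
                assert -1.0 <= v <= 1.0


class TestStripeDeviation:
    def test_aimed_at_stripe(self):
        s = steps_from_points([(0, 0), (0, 1)])
        assert stripe_deviation(s) == pytest.approx(0.0)

    def test_perpendicular_to_both(self):
        s = steps_from_points([(0, 0), (1, 0)])
        assert stripe_deviation(s) == pytest.approx(90.0, abs=0.5)

    def test_smaller_angle_chosen(self):
        # moving at 45 deg from origin: near stripe at 45, far at 135
        s = steps_from_points([(0, 0), (1, 1)])
        assert stripe_deviation(s) == pytest.approx(45.0)


class TestCountWalks:
    def test_one_passage(self):
        pts = [(0, 55), (0, 0), (0, -55)]
        assert count_walks(traj_from_points(pts)) == 1

    def test_aba_counts_two(self):
        pts = [(0, 55), (0, -55), (0, 55)]
        assert count_walks(traj_from_points(pts)) == 2

    def test_subthreshold_oscillation_counts_zero(self):
        pts = [(0, 40), (0, -40)] * 4          # only +/-0.7 R
        assert count_walks(traj_from_points(pts)) == 0

    def test_reentry_same_zone_not_counted(self):
        pts = [(0, 55), (0, 0), (0, 55), (0, -55)]
        assert count_walks(traj_from_points(pts)) == 1


class TestActivityTT:
    def test_hand_traced_segmentation(self):
        # 3 s moving, 2 s still, 5 s moving -> 1 pause (2 s), 8 s active
        pts = ([(i, 0) for i in range(31)] + [(30, 0)] * 20
               + [(30 + i, 0) for i in range(1, 51)])
        s = steps_from_points(pts)
        rec = activity_tt(s)
        assert rec.n_pauses == 1
        assert rec.median_pause_s == pytest.approx(2.0)
        assert rec.total_time_s == pytest.approx(8.0)

    def test_short_rest_counts_active(self):
        # 0.5 s still gap inside movement -> no pause
        pts = ([(i, 0) for i in range(11)] + [(10, 0)] * 5
               + [(10 + i, 0) for i in range(1, 11)])
        rec = activity_tt(steps_from_points(pts))
        assert rec.n_pauses == 0
        assert rec.total_time_s == pytest.approx((len(pts) - 1) * DT)

    def test_entirely_still_record(self):
        rec = activity_tt(steps_from_points([(0, 0)] * 31))
        assert rec.total_time_s == 0.0
        assert rec.n_pauses == 1
        assert rec.median_pause_s == pytest.approx(3.0)

    def test_exactly_1s_still_is_active(self):
        # strict threshold: a pause must be longer than 1 s
        pts = ([(i, 0) for i in range(6)] + [(5, 0)] * 10
               + [(5 + i, 0) for i in range(1, 6)])
        assert activity_tt(steps_from_points(pts)).n_pauses == 0

    def test_long_bout_median_filters_small_displacement(self):
        # two bouts: 15 mm travelled vs 0.9*5=4.5 mm; separated by a pause
        pts = ([(1.5 * i, 0) for i in range(11)] + [(15, 0)] * 20
               + [(15 + 0.9 * i, 0) for i in range(1, 6)])
        rec = activity_tt(steps_from_points(pts))
        assert rec.median_bout_s != rec.median_bout_ge1cm_s
        assert rec.median_bout_ge1cm_s == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    def test_activity_plus_pause_conserves_duration(self, seed):
        rng = np.random.default_rng(seed)
        pts = random_walk_points(rng, 80, pause_prob=0.6)
        s = steps_from_points(pts)
        rec = activity_tt(s)
        active, n_pauses, _ = oracle_activity_tt([tuple(p) for p in pts])
        assert rec.total_time_s == pytest.approx(active)
        assert rec.n_pauses == n_pauses


class TestActivityST:
    @staticmethod
    def _constant_speed_steps(v_mms, seconds):
        n = int(seconds * 10)
        pts = [(v_mms * DT * i, 0.0) for i in range(n + 1)]
        return steps_from_points(pts)

    def test_constant_fast_all_walking(self):
        rec = activity_st(self._constant_speed_steps(5.0, 5))
        assert rec.total_time_s == pytest.approx(5.1)   # all 51 samples walking
        assert rec.n_pauses == 0

    def test_constant_slow_all_resting(self):
        rec = activity_st(self._constant_speed_steps(0.5, 5))
        assert rec.total_time_s == 0.0
        assert rec.n_pauses == 1

    def test_hysteresis_hand_trace(self):
        # speeds 0.5 -> 2.0 -> 3.0 -> 2.0 -> 0.5 mm/s, 2 s each:
        # rest -> rest (held) -> walk -> walk (held) -> rest
        speeds = [0.5] * 20 + [2.0] * 20 + [3.0] * 20 + [2.0] * 20 + [0.5] * 20
        x = np.concatenate([[0.0], np.cumsum(np.array(speeds) * DT)])
        s = steps_from_points(np.column_stack([x, np.zeros_like(x)]))
        cfg = ActivityConfig()
        states = []
        from buridan.metrics import _st_classify
        full = _st_classify(s.length, DT, cfg)
        centers = [10, 30, 50, 70, 90]
        assert [bool(full[c]) for c in centers] == [False, False, True, True, False]

    def test_record_shorter_than_window_missing(self):
        rec = activity_st(steps_from_points([(0, 0), (1, 0), (2, 0)]))
        assert math.isnan(rec.total_time_s)


# ------------------------------------------------------ oracle equivalence

@given(st.integers(0, 2**31 - 1))
def test_metrics_match_bruteforce_oracles(seed):
    """Every metric equals a naive loop-based recomputation."""
    rng = np.random.default_rng(seed)
    pts = random_walk_points(rng, 50, pause_prob=0.45, step=30.0)
    pts = np.clip(pts, -58.0, 58.0)
    tuples = [tuple(p) for p in pts]
    traj = traj_from_points(pts)
    s = derive_steps(traj)

    def eq(a, b):
        if math.isnan(b):
            assert math.isnan(a)
        else:
            assert a == pytest.approx(b, rel=1e-9)

    eq(median_speed(s), oracle_median_speed(tuples))
    eq(total_distance(s), oracle_total_distance(tuples))
    eq(median_turning_angle(s), oracle_median_turn(tuples))
    eq(meander(s), oracle_meander(tuples))
    eq(stripe_deviation(s), oracle_stripe_dev(tuples))
    cm, cs = centrophobism(traj)
    ocm, ocs = oracle_centrophobism(tuples)
    eq(cm, ocm)
    eq(cs, ocs)
    assert count_walks(traj) == oracle_count_walks(tuples)
    rec = activity_tt(s)
    active, n_pauses, bouts = oracle_activity_tt(tuples)
    eq(rec.total_time_s, active)
    assert rec.n_pauses == n_pauses
    if bouts:
        eq(rec.median_bout_s, statistics.median(bouts))


def test_compute_metrics_returns_complete_record():
    rng = np.random.default_rng(4)
    pts = np.clip(random_walk_points(rng, 200, step=15.0), -58, 58)
    traj = traj_from_points(pts)
    ms = compute_metrics(traj, derive_steps(traj), id="f1", group="WT")
    assert ms.id == "f1" and ms.group == "WT"
    assert ms.total_distance > 0
    assert -1 <= ms.centrophobism_moving <= 1
    assert 0 <= ms.median_stripe_deviation <= 180
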