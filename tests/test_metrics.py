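import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stopchange import (MetricError, change_signal_rt, correction_point,
                        find_ir_crossing, latency_difference, mean_path,
                        trial_latency, vincentize)
from conftest import (CHANGE, ENTRANCE, GO, clean_change_traj, make_traj,
                      waypoint_traj)


def _random_change_traj(rng, n=80):
    """A jittery path that starts below the beam and wanders upward."""
    t = np.cumsum(rng.uniform(0.02, 0.1, n))
    y = np.concatenate([
        rng.uniform(-0.4, -0.01, 5),
        np.clip(np.cumsum(rng.normal(0.03, 0.12, n - 5)) - 0.2, -0.6, 2.2),
    ])
    x = np.cumsum(rng.normal(0.0, 0.15, n))
    traj = make_traj(np.column_stack([t, x, y]))
    find_ir_crossing(traj)
    return traj


# --- vincentize ----------------------------------------------------------

def test_vincentize_linear_path():
    traj = waypoint_traj([(0, -0.2), (0, 1.0)], total_time=1.0,
                         trial_index=1)
    traj.t_end = 1.0
    vp = vincentize(traj, 20)
    ks = np.arange(1, 21) / 20
    np.testing.assert_allclose(vp.points[:, 1], -0.2 + 1.2 * ks,
                               atol=1e-12)
    np.testing.assert_allclose(vp.points[:, 0], 0.0, atol=1e-12)
    assert vp.n == 20
    np.testing.assert_allclose(vp.start, [0, -0.2], atol=1e-12)


def test_vincentize_requires_completion():
    traj = waypoint_traj([(0, -0.2), (0, 1.0)], total_time=1.0,
                         trial_index=1)
    assert traj.t_end is None
    with pytest.raises(MetricError, match="completion"):
        vincentize(traj, 20)


def test_vincentize_matches_dense_resampling_oracle():
    # piecewise path whose speed doubles halfway through
    rng = np.random.default_rng(5)
    for _ in range(20):
        wps = rng.uniform(-1, 1, size=(rng.integers(3, 8), 2))
        seg_t = rng.uniform(0.2, 2.0, len(wps) - 1)
        t = np.concatenate([[0], np.cumsum(seg_t)])
        traj = make_traj(np.column_stack([t, wps[:, 0], wps[:, 1]]),
                         trial_index=1)
        traj.t_end = float(t[-1])
        n = 20
        vp = vincentize(traj, n)
        # oracle: dense uniform-time resampling, then pick every 500th
        dense_t = np.linspace(t[0], t[-1], 10_000 + 1)
        dx = np.interp(dense_t, t, wps[:, 0])
        dy = np.interp(dense_t, t, wps[:, 1])
        idx = (np.arange(1, n + 1) * (10_000 // n)).astype(int)
        np.testing.assert_allclose(vp.points,
                                   np.column_stack([dx[idx], dy[idx]]),
                                   atol=1e-9)
        # endpoints exact
        np.testing.assert_allclose(vp.points[-1], wps[-1], atol=1e-9)


def test_vincent_polyline_not_longer_than_raw_path():
    rng = np.random.default_rng(9)
    for _ in range(20):
        wps = rng.uniform(-1, 1, size=(12, 2))
        t = np.cumsum(rng.uniform(0.1, 0.5, 12))
        traj = make_traj(np.column_stack([t, wps[:, 0], wps[:, 1]]),
                         trial_index=1)
        traj.t_end = float(t[-1])
        vp = vincentize(traj, 20)
        poly = np.vstack([vp.start, vp.points])
        arc = lambda p: np.sum(np.hypot(*np.diff(p, axis=0).T))
        assert arc(poly) <= arc(wps) + 1e-9


# --- mean_path -----------------------------------------------------------

def test_mean_path_idempotent_and_symmetric():
    traj = clean_change_traj()
    find_ir_crossing(traj)
    trial_latency(traj)
    vp = vincentize(traj, 20)
    m = mean_path([vp, vp])
    np.testing.assert_allclose(m.points, vp.points, atol=1e-12)
    mirrored = vincentize(traj, 20)
    mirrored.points = vp.points * np.array([-1.0, 1.0])
    mm = mean_path([vp, mirrored])
    np.testing.assert_allclose(mm.points[:, 0], 0.0, atol=1e-12)


def test_mean_path_equals_columnwise_average():
    rng = np.random.default_rng(3)
    paths = []
    for _ in range(100):
        traj = waypoint_traj(rng.uniform(-1, 1, size=(5, 2)), 2.0,
                             trial_index=1)
        traj.t_end = 2.0
        paths.append(vincentize(traj, 20))
    m = mean_path(paths)
    np.testing.assert_allclose(
        m.points, np.mean([p.points for p in paths], axis=0), atol=1e-12)


def test_mean_path_rejects_mixed_n():
    traj = waypoint_traj([(0, -0.2), (0, 1)], 1.0, trial_index=1)
    traj.t_end = 1.0
    with pytest.raises(MetricError, match="mixed"):
        mean_path([vincentize(traj, 10), vincentize(traj, 20)])


# --- correction point and CSRT ------------------------------------------

def test_correction_point_unique_maximum():
    traj = waypoint_traj([(0.0, -0.05), (0.0, 0.0), (0.8, 0.8), (-1, 1)],
                         total_time=4.0, n_samples=2000)
    find_ir_crossing(traj)
    cp = correction_point(traj)
    assert cp.x == pytest.approx(0.8, abs=1e-3)
    assert cp.y == pytest.approx(0.8, abs=1e-3)
    assert cp.dist == pytest.approx(np.hypot(0.8, 0.8), abs=2e-3)


def test_straight_to_change_gives_zero_distance():
    # heads directly from the crossing to the Change plate: x never
    # exceeds the crossing x, so the correction is at the crossing itself
    traj = waypoint_traj([(0.1, -0.3), (0.0, 0.0), (-1.0, 1.0)],
                         total_time=3.0)
    find_ir_crossing(traj)
    cp = correction_point(traj)
    assert cp.dist == 0.0
    assert cp.t_rel == 0.0
    assert change_signal_rt(traj) == 0.0


def test_correction_point_matches_argmax_oracle():
    rng = np.random.default_rng(17)
    checked = 0
    for _ in range(300):
        traj = _random_change_traj(rng)
        if traj.t_cross is None:
            continue
        checked += 1
        cp = correction_point(traj)
        # oracle: exhaustive max over the crossing point and all samples
        # strictly after it, earliest on ties
        cands = [(traj.t_cross, traj.cross_point[0], traj.cross_point[1])]
        for t, x, y in traj.samples:
            if t > traj.t_cross:
                cands.append((t, x, y))
        best = max(cands, key=lambda c: (c[1], -c[0]))
        assert cp.x == pytest.approx(best[1], abs=1e-12)
        assert cp.t_abs == pytest.approx(best[0], abs=1e-12)
        assert cp.t_rel >= 0
    assert checked > 100


def test_csrt_is_time_between_crossing_and_correction():
    traj = waypoint_traj([(0.0, -0.5), (0.3, 0.5), (0.9, 0.9), (-1, 1)],
                         total_time=8.0, n_samples=400)
    find_ir_crossing(traj)
    cp = correction_point(traj)
    assert change_signal_rt(traj) == pytest.approx(cp.t_abs - traj.t_cross)


def test_pathlength_distance_at_least_euclidean():
    rng = np.random.default_rng(23)
    for _ in range(50):
        traj = _random_change_traj(rng)
        if traj.t_cross is None:
            continue
        eu = correction_point(traj, "EUCLIDEAN").dist
        pl = correction_point(traj, "PATHLENGTH").dist
        assert pl >= eu - 1e-12


# --- latency -------------------------------------------------------------

def test_trial_latency_straight_path():
    L = np.hypot(*(GO - ENTRANCE))
    T = 5.0 / (1 - 0.2 / L)  # so the capture circle is hit at t = 5.0
    traj = waypoint_traj([ENTRANCE, GO], total_time=T, trial_index=1,
                         n_samples=500)
    lat = trial_latency(traj, capture_radius=0.2)
    assert lat == pytest.approx(5.0, abs=1e-6)
    assert traj.t_end == pytest.approx(5.0, abs=1e-6)


def test_trial_latency_stops_short():
    traj = waypoint_traj([(0, -0.2), (0.4, 0.4)], total_time=3.0,
                         trial_index=1)
    assert trial_latency(traj) is None
    assert "no_completion" in traj.flags


def test_change_latency_needs_crossing():
    traj = make_traj([[0, 0, -0.2], [1, 0.2, -0.1]], trial_index=6)
    assert trial_latency(traj) is None
    assert "no_completion" in traj.flags


def test_latency_difference_examples():
    assert latency_difference(4.1, 6.9) == pytest.approx(2.8)
    assert latency_difference(3.0, 3.0) == 0.0


@given(a=st.floats(0, 130), b=st.floats(0, 130))
@settings(max_examples=50, deadline=None)
def test_latency_difference_antisymmetric(a, b):
    assert latency_difference(a, b) == -latency_difference(b, a)
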