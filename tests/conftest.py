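"""Shared builders: hand-constructed standardised trajectories and the
mixed QC cohort used by the exclusion tests."""

from __future__ import annotations

import numpy as np
import pytest

from stopchange import (PipelineConfig, StdTrajectory, TrialMeta,
                        find_ir_crossing, trial_latency)

ENTRANCE = np.array([0.0, -0.2])
GO = np.array([1.0, 1.0])
CHANGE = np.array([-1.0, 1.0])


def make_traj(samples, trial_index=6, bird_id="t0", enclosure="A",
              entrance=ENTRANCE) -> StdTrajectory:
    samples = np.asarray(samples, float)
    meta = TrialMeta(bird_id=bird_id, trial_index=trial_index,
                     enclosure=enclosure)
    return StdTrajectory(meta=meta, samples=samples,
                         t_entry=float(samples[0, 0]),
                         entrance=np.asarray(entrance, float))


def waypoint_traj(waypoints, total_time, n_samples=200, **kw):
    """Constant-speed piecewise-linear path through waypoints, sampled
    uniformly in time."""
    wp = np.asarray(waypoints, float)
    seg = np.diff(wp, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    s = np.linspace(0.0, cum[-1], n_samples)
    x = np.interp(s, cum, wp[:, 0])
    y = np.interp(s, cum, wp[:, 1])
    t = s / cum[-1] * total_time
    return make_traj(np.column_stack([t, x, y]), **kw)


def straight_go_traj(total_time=5.0, trial_index=1, **kw):
    return waypoint_traj([ENTRANCE, GO], total_time,
                         trial_index=trial_index, **kw)


def clean_change_traj(total_time=6.0, trial_index=6, **kw):
    """Committed run at Go, then a turn to the Change plate after the
    beam.  Pre-crossing samples lie on the entrance->Go segment exactly."""
    cross = np.array([1.0 / 6.0, 0.0])  # on the entrance->Go line at y=0
    turn = np.array([0.55, 0.45])
    return waypoint_traj([ENTRANCE, cross, turn, CHANGE], total_time,
                         trial_index=trial_index, **kw)


def stalled_traj(trial_index=2, stall_at=130.0, **kw):
    """A bird that enters and then loiters short of the plate forever."""
    t = np.linspace(0.0, stall_at, 260)
    x = np.full_like(t, 0.4)
    y = np.full_like(t, 0.3)
    x[:10] = np.linspace(0.0, 0.4, 10)
    y[:10] = np.linspace(-0.2, 0.3, 10)
    return make_traj(np.column_stack([t, x, y]), trial_index=trial_index,
                     **kw)


def deviant_change_traj(offset_ratio=0.40, trial_index=6, **kw):
    """Trial-6 path whose pre-crossing leg bulges sideways by
    ``offset_ratio`` of the entrance->Go line length."""
    seg = GO - ENTRANCE
    L = np.hypot(*seg)
    perp = np.array([seg[1], -seg[0]]) / L
    # bulge sits early on the approach (y < 0, i.e. before the beam);
    # waypoints double as samples so the peak offset is hit exactly
    bulge = ENTRANCE + 0.08 * seg + offset_ratio * L * perp
    cross = np.array([1.0 / 6.0, 0.0])
    wp = np.asarray([ENTRANCE, bulge, cross, [0.55, 0.45], CHANGE], float)
    seglen = np.hypot(*np.diff(wp, axis=0).T)
    t = np.concatenate([[0.0], np.cumsum(seglen)]) / seglen.sum() * 6.0
    return make_traj(np.column_stack([t, wp[:, 0], wp[:, 1]]),
                     trial_index=trial_index, **kw)


def six_trials(bird_id, kind="clean", enclosure="A"):
    """A bird's full 6-trial dict in the standardised frame."""
    trials = {}
    for idx in (1, 2, 4, 5):
        trials[idx] = straight_go_traj(5.0 - 0.2 * idx, trial_index=idx,
                                       bird_id=bird_id,
                                       enclosure=enclosure)
    trials[3] = clean_change_traj(6.5, trial_index=3, bird_id=bird_id,
                                  enclosure=enclosure)
    if kind == "timeout":
        trials[2] = stalled_traj(trial_index=2, bird_id=bird_id,
                                 enclosure=enclosure)
    if kind == "deviant":
        trials[6] = deviant_change_traj(0.40, bird_id=bird_id,
                                        enclosure=enclosure)
    else:
        trials[6] = clean_change_traj(6.0, trial_index=6,
                                      bird_id=bird_id,
                                      enclosure=enclosure)
    return trials


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def qc_cohort(config):
    """12 birds: 4 with a timeout trial, 2 deviating >0.33 pre-crossing
    on trial 6, 6 clean.  Returns (cohort, latencies)."""
    cohort = {}
    kinds = (["timeout"] * 4) + (["deviant"] * 2) + (["clean"] * 6)
    for i, kind in enumerate(kinds):
        bird = f"{kind[:3]}{i:02d}"
        cohort[bird] = six_trials(bird, kind)
    latencies = {}
    for bird, trials in cohort.items():
        for traj in trials.values():
            find_ir_crossing(traj)
        latencies[bird] = {
            idx: trial_latency(traj, config.capture_radius)
            for idx, traj in trials.items()
        }
    return cohort, latencies
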