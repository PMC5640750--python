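"""Per-trial inhibitory-control measures from standardised trajectories.

Three measures summarise a bird's ability to cancel and replace an ongoing
approach when the rewarded feeder location switches at the infrared beam:

* **latency difference** — completion latency of the last Change trial
  (trial 6) minus that of the last Go trial (trial 5); positive values mean
  the bird was slower when inhibition was required;
* **correction distance** — how far past the beam the bird kept gaining
  ground toward the now-wrong Go plate before turning (distance from the
  beam-crossing point to the trajectory-correction point);
* **change-signal reaction time (CSRT)** — the time taken to cover that
  distance, the continuous-task analogue of the stop-signal reaction time.

Paths are also Vincentized — resampled at fixed latency quantiles — so
trajectories of different durations can be averaged pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arena import CHANGE_PLATE_STD, GO_PLATE_STD, StdTrajectory
from .datamodel import CHANGE, GO, MetricError, PipelineConfig, TrialMeta


@dataclass
class VincentPath:
    """A path resampled at n latency quantiles (k/n, k = 1..n).

    ``start`` keeps the raw start position for plotting; the quantile
    points themselves exclude quantile 0.
    """

    meta: TrialMeta | None
    points: np.ndarray  # (n, 2)
    start: np.ndarray  # (2,)

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class CorrectionPoint:
    """The post-signal sample of maximal x: where the turn to the new
    target begins."""

    x: float
    y: float
    t_abs: float
    t_rel: float  # seconds since beam crossing
    dist: float  # from the crossing point, per configured metric


@dataclass
class ICMeasures:
    """The three per-bird measures (block-2 headline values).

    Trial-3 analogues are computed identically but kept separate: the first
    Change trial a bird ever sees cannot cleanly index inhibition, so the
    headline measures use trial 6 only.
    """

    bird_id: str
    latency_diff: float
    corr_dist: float
    csrt: float
    corr_x: float | None = None
    corr_y: float | None = None
    cross_x: float | None = None
    trial3_corr_dist: float | None = None
    trial3_csrt: float | None = None


MEASURE_NAMES = ("latency_diff", "corr_dist", "csrt")


def _position_at(traj: StdTrajectory, times: np.ndarray) -> np.ndarray:
    t = traj.samples[:, 0]
    x = np.interp(times, t, traj.samples[:, 1])
    y = np.interp(times, t, traj.samples[:, 2])
    return np.column_stack([x, y])


def vincentize(traj: StdTrajectory, n: int = 20) -> VincentPath:
    """Resample a completed trajectory at n latency quantiles.

    Point k is the (linearly interpolated) position at time
    ``t_entry + (k/n) * (t_end - t_entry)``; point n is the completion
    position exactly.
    """
    if n < 2:
        raise MetricError("n_quantiles must be >= 2")
    if traj.t_end is None:
        raise MetricError(
            f"no completion for bird {traj.meta.bird_id} trial "
            f"{traj.meta.trial_index}: cannot Vincentize"
        )
    ks = np.arange(1, n + 1) / n
    times = traj.t_entry + ks * (traj.t_end - traj.t_entry)
    pts = _position_at(traj, times)
    start = _position_at(traj, np.array([traj.t_entry]))[0]
    return VincentPath(meta=traj.meta, points=pts, start=start)


def mean_path(paths: list[VincentPath]) -> VincentPath:
    """Pointwise mean of Vincentized paths sharing the same n."""
    if not paths:
        raise MetricError("mean_path of empty list")
    ns = {p.n for p in paths}
    if len(ns) != 1:
        raise MetricError(f"mixed quantile counts {sorted(ns)}")
    pts = np.mean([p.points for p in paths], axis=0)
    start = np.mean([p.start for p in paths], axis=0)
    return VincentPath(meta=None, points=pts, start=start)


def _post_cross_samples(traj: StdTrajectory) -> np.ndarray:
    """Samples from the crossing to completion (crossing point prepended)."""
    if traj.t_cross is None or traj.cross_point is None:
        raise MetricError(
            f"no beam crossing for bird {traj.meta.bird_id} trial "
            f"{traj.meta.trial_index}"
        )
    t = traj.samples[:, 0]
    hi = t.searchsorted(traj.t_end, side="right") if traj.t_end is not None \
        else len(t)
    lo = t.searchsorted(traj.t_cross, side="right")
    seg = traj.samples[lo:hi]
    head = np.array([[traj.t_cross, traj.cross_point[0],
                      traj.cross_point[1]]])
    return np.vstack([head, seg])


def correction_point(traj: StdTrajectory,
                     distance_metric: str = "EUCLIDEAN") -> CorrectionPoint:
    """Find the trajectory-correction point of a Change trial.

    Among samples at/after the beam crossing, the sample of maximal
    x-coordinate (earliest on ties): the moment the bird stops gaining
    ground toward the Go plate.  If the path never exceeds the crossing
    x the crossing point itself is returned with zero distance.
    """
    if traj.meta.trial_type != CHANGE:
        raise MetricError("correction_point is defined for Change trials")
    seg = _post_cross_samples(traj)
    if len(seg) < 2:
        raise MetricError(
            f"no samples after crossing (bird {traj.meta.bird_id})"
        )
    xs = seg[:, 1]
    # argmax picks the earliest maximal sample; when nothing exceeds the
    # crossing x the crossing point itself (index 0) wins the tie.
    i = int(np.argmax(xs))
    t_i, x_i, y_i = seg[i]
    if i == 0:
        dist = 0.0
    elif distance_metric == "EUCLIDEAN":
        dist = float(np.hypot(x_i - seg[0, 1], y_i - seg[0, 2]))
    elif distance_metric == "PATHLENGTH":
        d = np.diff(seg[: i + 1, 1:], axis=0)
        dist = float(np.sum(np.hypot(d[:, 0], d[:, 1])))
    else:
        raise MetricError(f"unknown distance metric {distance_metric!r}")
    return CorrectionPoint(x=float(x_i), y=float(y_i), t_abs=float(t_i),
                           t_rel=float(t_i - traj.t_cross), dist=dist)


def change_signal_rt(traj: StdTrajectory) -> float:
    """Time from the beam crossing to the trajectory-correction point."""
    cp = correction_point(traj)
    return cp.t_rel


def trial_latency(traj: StdTrajectory,
                  capture_radius: float = 0.2) -> float | None:
    """Completion latency: entry to first arrival at the active plate.

    The active target is the Go plate for Go trials; for Change trials it
    is the Change plate, reachable only after the beam crossing (before it
    the plate is covered).  Arrival is the first time the path comes
    within ``capture_radius`` of the plate centre, sub-frame interpolated.
    Returns ``None`` (and flags the trajectory) when the bird never
    arrives — this feeds the timeout exclusion rule.
    """
    if traj.meta.trial_type == GO:
        target = GO_PLATE_STD
        seg = traj.samples
    else:
        if traj.t_cross is None:
            traj.flags.add("no_completion")
            return None
        target = CHANGE_PLATE_STD
        seg = _post_cross_samples(traj)
    d = np.hypot(seg[:, 1] - target[0], seg[:, 2] - target[1])
    inside = np.nonzero(d <= capture_radius)[0]
    if len(inside) == 0:
        traj.flags.add("no_completion")
        return None
    i = int(inside[0])
    if i == 0:
        t_end = seg[0, 0]
    else:
        # interpolate the circle entry between samples i-1 and i
        frac = (d[i - 1] - capture_radius) / (d[i - 1] - d[i])
        t_end = seg[i - 1, 0] + frac * (seg[i, 0] - seg[i - 1, 0])
    traj.t_end = float(t_end)
    return float(t_end - traj.t_entry)


def latency_difference(lat5: float, lat6: float) -> float:
    """Trial-6 minus trial-5 completion latency (positive = slower when
    the target changed)."""
    return lat6 - lat5


def compute_trial_row(traj: StdTrajectory, config: PipelineConfig) -> dict:
    """One tidy metrics row for a standardised trial.

    Computes latency (setting t_end) and, for Change trials with a
    crossing, the correction point and CSRT.  Missing events are flagged
    rather than raised.
    """
    from .arena import find_ir_crossing

    if traj.t_cross is None and "no_crossing" not in traj.flags:
        find_ir_crossing(traj)
    lat = trial_latency(traj, config.capture_radius)
    row = {
        "bird_id": traj.meta.bird_id,
        "trial_index": traj.meta.trial_index,
        "trial_type": traj.meta.trial_type,
        "block": traj.meta.block,
        "enclosure": traj.meta.enclosure,
        "latency_s": lat,
        "cross_x": traj.cross_point[0] if traj.cross_point is not None
        else np.nan,
        "csrt_s": np.nan,
        "corr_dist": np.nan,
        "corr_x": np.nan,
        "corr_y": np.nan,
    }
    if (traj.meta.trial_type == CHANGE and traj.t_cross is not None
            and lat is not None):
        cp = correction_point(traj, config.distance_metric)
        row.update(csrt_s=cp.t_rel, corr_dist=cp.dist,
                   corr_x=cp.x, corr_y=cp.y)
    row["flags"] = ";".join(sorted(traj.flags))
    return row


def compute_ic_measures(trials: dict[int, StdTrajectory],
                        metrics: pd.DataFrame) -> ICMeasures | None:
    """Assemble the per-bird measure triple from the per-trial table.

    Requires usable trials 5 and 6; returns ``None`` when any headline
    ingredient is missing (such birds are excluded upstream anyway).
    """
    m = metrics.set_index("trial_index")
    needed = {5, 6}
    if not needed <= set(m.index):
        return None
    lat5, lat6 = m.loc[5, "latency_s"], m.loc[6, "latency_s"]
    if pd.isna(lat5) or pd.isna(lat6) or pd.isna(m.loc[6, "csrt_s"]):
        return None
    t3_dist = m.loc[3, "corr_dist"] if 3 in m.index else None
    t3_csrt = m.loc[3, "csrt_s"] if 3 in m.index else None
    return ICMeasures(
        bird_id=str(metrics["bird_id"].iloc[0]),
        latency_diff=latency_difference(float(lat5), float(lat6)),
        corr_dist=float(m.loc[6, "corr_dist"]),
        csrt=float(m.loc[6, "csrt_s"]),
        corr_x=float(m.loc[6, "corr_x"]),
        corr_y=float(m.loc[6, "corr_y"]),
        cross_x=float(m.loc[6, "cross_x"]),
        trial3_corr_dist=None if pd.isna(t3_dist) else float(t3_dist),
        trial3_csrt=None if pd.isna(t3_csrt) else float(t3_csrt),
    )


def measures_frame(measures: list[ICMeasures]) -> pd.DataFrame:
    df = pd.DataFrame([{
        "bird_id": m.bird_id, "latency_diff": m.latency_diff,
        "corr_dist": m.corr_dist, "csrt": m.csrt,
        "corr_x": m.corr_x, "corr_y": m.corr_y, "cross_x": m.cross_x,
    } for m in measures])
    return df.set_index("bird_id").sort_index()
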