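"""Cohort exclusion rules and the auditable exclusion report.

Two behavioural rules decide whether a bird's six trials enter analysis:

* **timeout** — a bird that failed to complete any one of its six trials
  in under two minutes is excluded entirely (slow birds are unmotivated
  and their tortuous paths make correction points unreliable);
* **pre-crossing deviation** — on trial 6 the approach to the beam must be
  a committed run at the Go plate: birds whose path before the crossing
  deviated from the straight entrance-to-Go line by more than 33% of that
  line's length are excluded (their correction cannot index cancelling an
  initiated response).

Both thresholds are strict inequalities ("less than 2 min", "more than
33%"): a latency of exactly 120 s is a timeout, a deviation ratio of
exactly 0.33 is retained.  Birds with fewer than six usable trials are
flagged MISSING_DATA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import GO_PLATE_STD, StdTrajectory
from .datamodel import PipelineConfig

TIMEOUT = "TIMEOUT"
PRECROSS_DEVIATION = "PRECROSS_DEVIATION"
MISSING_DATA = "MISSING_DATA"

REASONS = (TIMEOUT, PRECROSS_DEVIATION, MISSING_DATA)

DEFAULT_ENTRANCE = np.array([0.0, -0.2])


@dataclass
class ExclusionReport:
    birds: pd.DataFrame  # bird_id, excluded, reasons
    detail: pd.DataFrame  # per-trial rows behind each decision
    reason_counts: dict = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.birds)

    @property
    def n_retained(self) -> int:
        return int((~self.birds["excluded"]).sum())

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_excluded": self.n_input - self.n_retained,
            "reason_counts": dict(self.reason_counts),
        }


def timeout_filter(trials: dict[int, StdTrajectory],
                   latencies: dict[int, float | None],
                   timeout_s: float = 120.0) -> set[str]:
    """Flag a bird whose six trials are incomplete or too slow."""
    reasons: set[str] = set()
    if set(trials) != {1, 2, 3, 4, 5, 6}:
        reasons.add(MISSING_DATA)
    for idx in trials:
        lat = latencies.get(idx)
        if lat is None or lat >= timeout_s:  # "< 2 min" is strict
            reasons.add(TIMEOUT)
            break
    return reasons


def _point_segment_distance(points: np.ndarray, a: np.ndarray,
                            b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.hypot(*(points - proj).T)


def precrossing_deviation(traj6: StdTrajectory,
                          functional: str = "MAX") -> float | None:
    """Deviation ratio of the trial-6 approach from the entrance->Go line.

    Ratio = (max — or mean, if configured — perpendicular offset of the
    samples between entry and the beam crossing from the straight segment
    entrance -> Go plate) divided by the length of that segment.  Returns
    ``None`` when there are no pre-crossing samples (missing data).
    """
    if traj6.t_cross is None:
        return None
    entrance = traj6.entrance if traj6.entrance is not None \
        else DEFAULT_ENTRANCE
    t = traj6.samples[:, 0]
    pre = traj6.samples[(t >= traj6.t_entry) & (t <= traj6.t_cross), 1:]
    if len(pre) == 0:
        return None
    seg_len = float(np.hypot(*(GO_PLATE_STD - entrance)))
    d = _point_segment_distance(pre, np.asarray(entrance, float),
                                GO_PLATE_STD)
    agg = np.max(d) if functional == "MAX" else np.mean(d)
    return float(agg / seg_len)


def bird_reasons(trials: dict[int, StdTrajectory],
                 latencies: dict[int, float | None],
                 config: PipelineConfig) -> tuple[set[str], dict]:
    """All exclusion reasons for one bird, plus the numbers behind them."""
    reasons = timeout_filter(trials, latencies, config.timeout_s)
    ratio = None
    if 6 in trials:
        ratio = precrossing_deviation(trials[6], config.deviation_functional)
        if ratio is None:
            reasons.add(MISSING_DATA)
        # "> 33%" is strict; the epsilon keeps a ratio exactly at the
        # threshold retained in the face of floating-point rounding
        elif ratio > config.deviation_threshold * (1 + 1e-9):
            reasons.add(PRECROSS_DEVIATION)
    else:
        reasons.add(MISSING_DATA)
    return reasons, {"deviation_ratio": ratio}


def apply_exclusions(cohort: dict[str, dict[int, StdTrajectory]],
                     latencies: dict[str, dict[int, float | None]],
                     config: PipelineConfig,
                     ) -> tuple[list[str], ExclusionReport]:
    """Apply both rules to every bird; return retained ids and the report.

    Ordering is deterministic (sorted bird_id).  A bird violating several
    rules appears once with each reason listed.
    """
    rows, detail_rows = [], []
    counts = {r: 0 for r in REASONS}
    retained = []
    for bird_id in sorted(cohort):
        trials = cohort[bird_id]
        lats = latencies.get(bird_id, {})
        reasons, extra = bird_reasons(trials, lats, config)
        for r in reasons:
            counts[r] += 1
        if not reasons:
            retained.append(bird_id)
        rows.append({
            "bird_id": bird_id,
            "excluded": bool(reasons),
            "reasons": ";".join(sorted(reasons)),
            "deviation_ratio": extra["deviation_ratio"],
        })
        for idx in sorted(trials):
            detail_rows.append({
                "bird_id": bird_id, "trial_index": idx,
                "latency_s": lats.get(idx),
                "timed_out": lats.get(idx) is None
                or lats.get(idx) >= config.timeout_s,
            })
    report = ExclusionReport(
        birds=pd.DataFrame(rows),
        detail=pd.DataFrame(detail_rows),
        reason_counts={k: v for k, v in counts.items() if v},
    )
    return retained, report
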