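"""Typed data model and table I/O for the stop-change trajectory pipeline.

Tracking tables are long-format CSV (one row per video frame); covariate
tables are one row per bird.  All times are seconds from the bird entering
the arena; raw coordinates are whatever length unit the tracker emitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("stopchange")

GO = "GO"
CHANGE = "CHANGE"

#: trial indices that are Change trials in the fixed 6-trial schedule
CHANGE_TRIALS = frozenset({3, 6})

#: motivation latency ceiling (seconds) applied to Baseline Worm Acquisition
BWA_CEILING = 120.0


class StopChangeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(StopChangeError):
    """A file does not have the expected columns/structure."""


class ValidationError(StopChangeError):
    """Well-formed input violating a semantic invariant."""


class CalibrationError(StopChangeError):
    """Degenerate or inconsistent arena calibration."""


class MetricError(StopChangeError):
    """A per-trial measure cannot be computed (e.g. no completion)."""


class EmptyCohortError(StopChangeError):
    """No birds remain after quality control."""


def trial_type_for(trial_index: int) -> str:
    return CHANGE if trial_index in CHANGE_TRIALS else GO


@dataclass(frozen=True)
class TrialMeta:
    """Identity of one trial of the 6-trial Go/Change schedule.

    Trials 1, 2, 4, 5 are Go trials; trials 3 and 6 are Change trials.
    Block 1 covers trials 1-3, block 2 covers trials 4-6; two trials are
    run per day over three consecutive days.
    """

    bird_id: str
    trial_index: int
    enclosure: str = "A"
    mirrored: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.trial_index <= 6:
            raise ValidationError(
                f"trial_index must be 1..6, got {self.trial_index} "
                f"(bird {self.bird_id})"
            )
        if self.enclosure not in ("A", "B", "C", "D"):
            raise ValidationError(f"unknown enclosure {self.enclosure!r}")

    @property
    def trial_type(self) -> str:
        return trial_type_for(self.trial_index)

    @property
    def block(self) -> int:
        return 1 if self.trial_index <= 3 else 2

    @property
    def session_day(self) -> int:
        return (self.trial_index + 1) // 2


@dataclass
class RawTrack:
    """Time-stamped 2-D positions of one bird in one trial (raw coords)."""

    meta: TrialMeta
    samples: np.ndarray  # (n, 3) columns t, x, y

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValidationError(
                f"samples must be (n, 3) [t, x, y], got {self.samples.shape}"
            )
        if len(self.samples) < 2:
            raise ValidationError(
                f"track needs >= 2 samples (bird {self.meta.bird_id}, "
                f"trial {self.meta.trial_index})"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(
                f"non-finite coordinate in bird {self.meta.bird_id}, "
                f"trial {self.meta.trial_index}; interpolate or drop gaps first"
            )
        if np.any(np.diff(self.samples[:, 0]) <= 0):
            raise ValidationError(
                f"timestamps not strictly increasing in bird "
                f"{self.meta.bird_id}, trial {self.meta.trial_index}"
            )

    @property
    def t(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def xy(self) -> np.ndarray:
        return self.samples[:, 1:]


@dataclass
class BirdCovariates:
    """Per-bird morphology and motivation covariates.

    ``bwa`` (Baseline Worm Acquisition) is the latency to take a free
    mealworm, ceiling-clamped at 120 s; ``to`` (Test Order) is the rank in
    which the bird voluntarily entered the arena (low = early entrant);
    ``trial4_rt`` is the trial-4 completion latency used as a speed control.
    """

    bird_id: str
    sex: str  # F | M
    mass: float  # grams
    tarsus: float  # millimetres
    bwa: float  # seconds, [0, 120]
    to: float  # rank score
    trial4_rt: float | None = None
    enclosure: str = "A"

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValidationError(
                f"unknown sex code {self.sex!r} for bird {self.bird_id}"
            )
        if not self.mass > 0:
            raise ValidationError(f"mass must be > 0 (bird {self.bird_id})")
        if not self.tarsus > 0:
            raise ValidationError(f"tarsus must be > 0 (bird {self.bird_id})")
        if self.bwa > BWA_CEILING:
            logger.warning(
                "bird %s: BWA %.1f s exceeds %.0f s ceiling, clamped",
                self.bird_id, self.bwa, BWA_CEILING,
            )
            self.bwa = BWA_CEILING
        if self.bwa < 0:
            raise ValidationError(f"negative BWA for bird {self.bird_id}")


@dataclass
class PipelineConfig:
    """Tunable knobs of the analysis pipeline, loadable from YAML/JSON."""

    n_quantiles: int = 20
    timeout_s: float = 120.0
    deviation_threshold: float = 0.33
    capture_radius: float = 0.2  # standardised units (1 unit = 25 cm)
    distance_metric: str = "EUCLIDEAN"  # or PATHLENGTH
    deviation_functional: str = "MAX"  # or MEAN
    rng_seed: int = 0
    sampling_dt: float = 0.04  # seconds per frame used by the simulator
    out_dir: str = "stopchange_out"
    column_map: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_quantiles < 2:
            raise ValidationError("n_quantiles must be >= 2")
        for name in ("timeout_s", "deviation_threshold", "capture_radius",
                     "sampling_dt"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")
        if self.distance_metric not in ("EUCLIDEAN", "PATHLENGTH"):
            raise ValidationError(
                f"distance_metric must be EUCLIDEAN or PATHLENGTH, "
                f"got {self.distance_metric!r}"
            )
        if self.deviation_functional not in ("MAX", "MEAN"):
            raise ValidationError("deviation_functional must be MAX or MEAN")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: getattr(self, k) for k in self.__dataclass_fields__}, fh
            )

    def with_(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# tracking-table I/O

TRACK_COLUMNS = ("bird_id", "trial_index", "t", "x", "y")


def read_tracks(path: str | Path,
                column_map: dict | None = None) -> list[RawTrack]:
    """Read a long-format tracking CSV into one :class:`RawTrack` per trial.

    Required columns: bird_id, trial_index, t, x, y.  Optional columns
    ``enclosure`` and ``mirrored`` are carried into :class:`TrialMeta`.
    ``column_map`` renames dialects, e.g. ``{"time_s": "t"}``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"tracking table {path} is missing column(s) {missing}"
        )
    tracks: list[RawTrack] = []
    has_enc = "enclosure" in df.columns
    has_mir = "mirrored" in df.columns
    for (bird_id, trial_index), g in df.groupby(
            ["bird_id", "trial_index"], sort=True):
        g = g.sort_values("t")
        meta = TrialMeta(
            bird_id=str(bird_id),
            trial_index=int(trial_index),
            enclosure=str(g["enclosure"].iloc[0]) if has_enc else "A",
            mirrored=bool(g["mirrored"].iloc[0]) if has_mir else False,
        )
        tracks.append(RawTrack(meta, g[["t", "x", "y"]].to_numpy(float)))
    logger.info("read %d tracks from %s", len(tracks), path)
    return tracks


def write_tracks(tracks: Iterable[RawTrack], path: str | Path) -> None:
    frames = []
    for tr in tracks:
        f = pd.DataFrame(tr.samples, columns=["t", "x", "y"])
        f.insert(0, "bird_id", tr.meta.bird_id)
        f.insert(1, "trial_index", tr.meta.trial_index)
        f.insert(2, "enclosure", tr.meta.enclosure)
        f.insert(3, "mirrored", tr.meta.mirrored)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")


# ---------------------------------------------------------------------------
# covariate-table I/O

COVARIATE_COLUMNS = ("bird_id", "sex", "mass", "tarsus", "bwa", "to")


def read_covariates(path: str | Path) -> list[BirdCovariates]:
    """Read a per-bird covariate CSV; BWA values above 120 s are clamped."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty and not set(COVARIATE_COLUMNS) <= set(df.columns):
        return []
    missing = [c for c in COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"covariate table {path} is missing column(s) {missing}"
        )
    out = []
    for _, row in df.iterrows():
        out.append(BirdCovariates(
            bird_id=str(row["bird_id"]),
            sex=str(row["sex"]),
            mass=float(row["mass"]),
            tarsus=float(row["tarsus"]),
            bwa=float(row["bwa"]),
            to=float(row["to"]),
            trial4_rt=(float(row["trial4_rt"])
                       if "trial4_rt" in df.columns
                       and pd.notna(row["trial4_rt"]) else None),
            enclosure=(str(row["enclosure"])
                       if "enclosure" in df.columns else "A"),
        ))
    return out


def write_covariates(covs: Iterable[BirdCovariates], path: str | Path) -> None:
    pd.DataFrame([{
        "bird_id": c.bird_id, "sex": c.sex, "mass": c.mass,
        "tarsus": c.tarsus, "bwa": c.bwa, "to": c.to,
        "trial4_rt": c.trial4_rt, "enclosure": c.enclosure,
    } for c in covs]).to_csv(path, index=False, float_format="%.17g")


def covariates_frame(covs: Sequence[BirdCovariates]) -> pd.DataFrame:
    """Covariates as a DataFrame indexed by bird_id."""
    df = pd.DataFrame([{
        "bird_id": c.bird_id, "sex": c.sex, "mass": c.mass,
        "tarsus": c.tarsus, "bwa": c.bwa, "to": c.to,
        "trial4_rt": c.trial4_rt, "enclosure": c.enclosure,
    } for c in covs])
    return df.set_index("bird_id")
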