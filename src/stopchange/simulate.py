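"""Agent-based stand-in for the study's raw tracking data.

Birds are simulated as kinematic walkers in the standardised arena frame:
from the entrance, the heading relaxes toward the active feeder plate at a
bounded turn rate with Gaussian heading noise, advancing ``v * dt`` per
frame.  Every bird initially heads for the Go plate (the empirically
observed initial bias); on Change trials the active plate switches to the
Change location at (first beam crossing) + tau, so the per-bird
change-detection delay tau is the exact generative analogue of the
change-signal reaction time and supports parameter-recovery tests.

A per-trial timeout propensity injects non-participants: tortuous
wanderers that pace the lower arena for the full trial cap and never
complete, reproducing the study's large drop-out fraction.  Default
parameters are chosen to emulate the study conditions (6-trial Go/Change
schedule, four enclosures with B/D mirrored, ~58% of birds with at least
one timeout trial, Go-trial latencies of a few seconds).

Tracks are emitted in raw per-arena coordinates (centimetres, with a
small camera rotation per arena and a genuine reflection for the mirrored
enclosures) together with the matching calibrations, so the full
standardisation path is exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import ArenaCalibration
from .datamodel import (CHANGE, BirdCovariates, RawTrack, TrialMeta,
                        ValidationError, trial_type_for)

ENTRANCE_STD = (0.0, -0.2)
GO_STD = (1.0, 1.0)
CHANGE_STD = (-1.0, 1.0)
IR_STD = ((-1.2, 0.0), (1.2, 0.0))

#: wanderers pace this box (they never get within reach of a plate)
WANDER_BOX = ((-1.4, 1.4), (-0.55, 0.75))


@dataclass(frozen=True)
class SimParams:
    """Population-level generative parameters (one bird = one draw)."""

    speed_mean: float = 0.45  # units/s; 1 unit = 25 cm
    speed_sd: float = 0.08
    heading_noise_sd: float = 0.05  # rad/sqrt(s)
    tau_low: float = 0.2  # change-detection delay, uniform bounds (s)
    tau_high: float = 3.0
    turn_rate: float = 20.0  # rad/s heading relaxation limit
    p_timeout: float = 0.135  # per-trial wandering propensity
    tortuosity: float = 6.0  # heading-noise multiplier for wanderers
    dt: float = 0.04  # sampling interval (25 fps)
    capture_radius: float = 0.2  # arrival radius (5 cm)
    max_t: float = 130.0  # hard trial cap (s)
    sex_effect_tau: float = 0.0  # added to tau for males (s)
    size_effect_tau: float = 0.0  # per body-size SD (s)
    trial1_slowdown: float = 1.0  # optional familiarisation speed factor

    def __post_init__(self) -> None:
        if self.speed_mean <= 0 or self.dt <= 0:
            raise ValidationError("speed and dt must be > 0")
        if self.tau_low < 0 or self.tau_high < self.tau_low:
            raise ValidationError("invalid tau bounds")
        if not 0 <= self.p_timeout <= 1:
            raise ValidationError("p_timeout must be in [0, 1]")


@dataclass
class SimBird:
    bird_id: str
    enclosure: str
    mirrored: bool
    sex: str
    mass: float
    tarsus: float
    bwa: float
    to: float
    v: float
    tau: float
    noise_sd: float


@dataclass
class SimCohort:
    tracks: list[RawTrack]
    covariates: list[BirdCovariates]
    truth: pd.DataFrame  # one row per trial, aligned with tracks
    calibrations: dict[str, ArenaCalibration]
    birds: list[SimBird] = field(default_factory=list)


# ---------------------------------------------------------------------------
# per-arena raw frames

_ARENA_ANGLES = {"A": 0.035, "B": -0.05, "C": 0.02, "D": -0.015}
_ARENA_OFFSETS = {"A": (40.0, 25.0), "B": (38.0, 22.0),
                  "C": (42.0, 27.0), "D": (37.0, 24.0)}
_SCALE_CM = 25.0  # raw unit is a centimetre


def _std_to_raw(enclosure: str) -> tuple[np.ndarray, np.ndarray]:
    """Affine std->raw for one arena: mirror (B/D), scale, rotate, shift."""
    th = _ARENA_ANGLES[enclosure]
    R = np.array([[math.cos(th), -math.sin(th)],
                  [math.sin(th), math.cos(th)]])
    mirror = np.diag([-1.0, 1.0]) if enclosure in ("B", "D") else np.eye(2)
    A = R @ (_SCALE_CM * np.eye(2)) @ mirror
    b = np.asarray(_ARENA_OFFSETS[enclosure], float)
    return A, b


def arena_calibration(enclosure: str) -> ArenaCalibration:
    """Ground-truth calibration of one simulated arena."""
    A, b = _std_to_raw(enclosure)

    def f(p):
        return tuple((A @ np.asarray(p, float) + b).tolist())

    return ArenaCalibration(
        go_plate=f(GO_STD), change_plate=f(CHANGE_STD),
        ir_line=(f(IR_STD[0]), f(IR_STD[1])), entrance=f(ENTRANCE_STD),
        mirrored=enclosure in ("B", "D"),
    )


# ---------------------------------------------------------------------------
# single-trial kinematics


def _wrap(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def simulate_trial(bird: SimBird, meta: TrialMeta, rng: np.random.Generator,
                   params: SimParams, wander: bool = False,
                   ) -> tuple[RawTrack, dict]:
    """Simulate one trial; returns the raw-coordinate track and the
    ground-truth row (crossing time, arrival time, injected timeout)."""
    dt = params.dt
    if wander:
        xy, t = _wander_path(bird, rng, params)
        t_cross = _first_up_crossing(t, xy[:, 1])
        truth = {"bird_id": bird.bird_id, "trial_index": meta.trial_index,
                 "tau": bird.tau, "v": bird.v,
                 "t_cross_true": t_cross, "arrival_time": np.nan,
                 "timeout_injected": True}
        return _emit(meta, bird, t, xy), truth

    v = bird.v / (params.trial1_slowdown if meta.trial_index == 1 else 1.0)
    is_change = trial_type_for(meta.trial_index) == CHANGE
    noise = bird.noise_sd * math.sqrt(dt)
    omega_dt = params.turn_rate * dt
    step = v * dt
    r2 = params.capture_radius ** 2

    x, y = ENTRANCE_STD
    tx, ty = GO_STD  # initial Go bias: every trial starts aimed at Go
    # the rewarded (arrival) plate: on Change trials the Go plate is
    # covered at the beam, so only the Change plate can end the trial
    rx, ry = CHANGE_STD if is_change else GO_STD
    h = math.atan2(ty - y, tx - x)
    n_max = int(params.max_t / dt) + 1
    z = rng.standard_normal(n_max)

    ts = [0.0]
    xs = [x]
    ys = [y]
    t_cross = None
    t_switch = math.inf
    arrival = None
    for i in range(1, n_max):
        t = i * dt
        if is_change and t_cross is not None and t >= t_switch \
                and (tx, ty) != CHANGE_STD:
            tx, ty = CHANGE_STD
        want = math.atan2(ty - y, tx - x)
        d = _wrap(want - h)
        if d > omega_dt:
            d = omega_dt
        elif d < -omega_dt:
            d = -omega_dt
        h = h + d + noise * z[i]
        xn = x + step * math.cos(h)
        yn = y + step * math.sin(h)
        if t_cross is None and y < 0.0 <= yn:
            t_cross = t - dt + dt * (0.0 - y) / (yn - y)
            t_switch = t_cross + bird.tau
        x, y = xn, yn
        ts.append(t)
        xs.append(x)
        ys.append(y)
        dx, dy = x - rx, y - ry
        if dx * dx + dy * dy <= r2:
            arrival = t
            break

    truth = {"bird_id": bird.bird_id, "trial_index": meta.trial_index,
             "tau": bird.tau, "v": bird.v,
             "t_cross_true": np.nan if t_cross is None else t_cross,
             "arrival_time": np.nan if arrival is None else arrival,
             "timeout_injected": False}
    xy = np.column_stack([xs, ys])
    return _emit(meta, bird, np.asarray(ts), xy), truth


def _wander_path(bird: SimBird, rng: np.random.Generator,
                 params: SimParams) -> tuple[np.ndarray, np.ndarray]:
    """Tortuous non-participant path for the full trial cap (vectorised)."""
    dt = params.dt
    n = int(params.max_t / dt) + 1
    dh = bird.noise_sd * params.tortuosity * math.sqrt(dt) \
        * rng.standard_normal(n - 1)
    h = rng.uniform(-math.pi, math.pi) + np.cumsum(dh)
    speed = 0.6 * bird.v * dt
    dxy = speed * np.column_stack([np.cos(h), np.sin(h)])
    xy = np.vstack([[ENTRANCE_STD], dxy]).cumsum(axis=0)
    (x0, x1), (y0, y1) = WANDER_BOX
    xy[:, 0] = _fold(xy[:, 0], x0, x1)
    xy[:, 1] = _fold(xy[:, 1], y0, y1)
    t = np.arange(n) * dt
    return xy, t


def _fold(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect values into [lo, hi] (triangle wave)."""
    span = hi - lo
    v = np.mod(v - lo, 2.0 * span)
    return lo + np.where(v > span, 2.0 * span - v, v)


def _first_up_crossing(t: np.ndarray, y: np.ndarray) -> float:
    below = y < 0
    idx = np.nonzero(below[:-1] & ~below[1:])[0]
    if len(idx) == 0:
        return np.nan
    i = int(idx[0])
    return float(t[i] + (t[i + 1] - t[i]) * (0.0 - y[i]) / (y[i + 1] - y[i]))


def _emit(meta: TrialMeta, bird: SimBird, t: np.ndarray,
          xy_std: np.ndarray) -> RawTrack:
    A, b = _std_to_raw(bird.enclosure)
    raw = xy_std @ A.T + b
    return RawTrack(meta, np.column_stack([t, raw]))


# ---------------------------------------------------------------------------
# cohort generation

_ENCLOSURES = ("A", "B", "C", "D")


def _draw_bird(i: int, enclosure: str, pop: SimParams,
               rng: np.random.Generator) -> SimBird:
    sex = "M" if rng.random() < 0.5 else "F"
    # juvenile sexual dimorphism: males ~30% heavier; mass-tarsus
    # correlation ~0.6 within sex pools to ~0.83 overall, so the 2-variable
    # size component explains ~91% of the variance
    if sex == "M":
        mass_mu, mass_sd, tars_mu = 1040.0, 70.0, 68.0
    else:
        mass_mu, mass_sd, tars_mu = 800.0, 60.0, 62.0
    zm = rng.standard_normal()
    mass = mass_mu + mass_sd * zm
    tarsus = tars_mu + 3.0 * (0.6 * zm
                              + math.sqrt(1 - 0.6 ** 2)
                              * rng.standard_normal())
    bwa = float(rng.gamma(2.15, 11.26))  # mean ~24 s, sd ~17 s
    size_z = (mass - 920.0) / 140.0  # crude cohort-level size standardised
    tau = rng.uniform(pop.tau_low, pop.tau_high) \
        + (pop.sex_effect_tau if sex == "M" else 0.0) \
        + pop.size_effect_tau * size_z
    return SimBird(
        bird_id=f"b{i:03d}", enclosure=enclosure,
        mirrored=enclosure in ("B", "D"), sex=sex,
        mass=max(mass, 300.0), tarsus=max(tarsus, 40.0), bwa=bwa,
        to=0.0,  # filled with shuffled ranks below
        v=max(rng.normal(pop.speed_mean, pop.speed_sd), 0.2),
        tau=max(tau, 0.0), noise_sd=pop.heading_noise_sd,
    )


def simulate_cohort(pop: SimParams, n_birds: int, seed: int) -> SimCohort:
    """Simulate a full cohort: 6 trials per bird, enclosures assigned
    round-robin A-D (B/D mirrored), covariates with the configured sex and
    size effects on tau, all reproducible from the seed."""
    if n_birds < 1:
        raise ValidationError("n_birds must be >= 1")
    rng = np.random.default_rng(seed)
    birds = [_draw_bird(i, _ENCLOSURES[i % 4], pop, rng)
             for i in range(n_birds)]
    for bird, rank in zip(birds, rng.permutation(n_birds) + 1):
        bird.to = float(rank)

    tracks: list[RawTrack] = []
    truth_rows: list[dict] = []
    for bird in birds:
        for trial in range(1, 7):
            meta = TrialMeta(bird_id=bird.bird_id, trial_index=trial,
                             enclosure=bird.enclosure,
                             mirrored=bird.mirrored)
            wander = rng.random() < pop.p_timeout
            track, truth = simulate_trial(bird, meta, rng, pop,
                                          wander=wander)
            tracks.append(track)
            truth_rows.append(truth)
    truth = pd.DataFrame(truth_rows)

    t4 = truth.set_index(["bird_id", "trial_index"])["arrival_time"]
    covs = []
    for bird in birds:
        rt4 = t4.get((bird.bird_id, 4), np.nan)
        covs.append(BirdCovariates(
            bird_id=bird.bird_id, sex=bird.sex, mass=bird.mass,
            tarsus=bird.tarsus, bwa=bird.bwa, to=bird.to,
            trial4_rt=None if pd.isna(rt4) else float(rt4),
            enclosure=bird.enclosure,
        ))
    cals = {e: arena_calibration(e) for e in _ENCLOSURES}
    return SimCohort(tracks=tracks, covariates=covs, truth=truth,
                     calibrations=cals, birds=birds)


# ---------------------------------------------------------------------------
# recovery diagnostics


def recovery_report(truth: pd.DataFrame, metrics: pd.DataFrame,
                    scores: pd.Series | None = None) -> dict:
    """Compare pipeline estimates against simulator ground truth.

    Joins trial-6 rows on bird_id and reports rank correlation and error
    of CSRT against the true detection delay tau, the tau-monotonicity of
    the correction distance, and (optionally) the IC-score-tau
    correlation, whose sign convention requires it to be negative.
    """
    from scipy import stats as sps

    t6 = truth[truth["trial_index"] == 6].set_index("bird_id")
    m6 = metrics[metrics["trial_index"] == 6].set_index("bird_id")
    common = t6.index.intersection(m6.index)
    if len(common) == 0:
        raise ValidationError("no overlapping bird ids")
    t6, m6 = t6.loc[common], m6.loc[common]
    ok = m6["csrt_s"].notna()
    if ok.sum() < 3:
        raise ValidationError("too few usable trial-6 measures")
    tau = t6.loc[ok, "tau"].to_numpy()
    csrt = m6.loc[ok, "csrt_s"].to_numpy()
    report = {
        "n": int(ok.sum()),
        "spearman_csrt_tau": float(sps.spearmanr(csrt, tau).statistic),
        "mean_abs_csrt_error": float(np.mean(np.abs(csrt - tau))),
        "spearman_corrdist_tau": float(
            sps.spearmanr(m6.loc[ok, "corr_dist"], tau).statistic),
    }
    if scores is not None:
        common_s = scores.index.intersection(t6.index[ok])
        if len(common_s) >= 3:
            report["pearson_score_tau"] = float(np.corrcoef(
                scores.loc[common_s],
                t6.loc[common_s, "tau"])[0, 1])
    return report


def simulate_score_cohort(n: int, coeffs: dict, seed: int,
                          n_enclosures: int = 4,
                          enclosure_sd: float = 0.3,
                          noise_sd: float = 1.0) -> pd.DataFrame:
    """Direct generator for mixed-model calibration studies.

    Draws covariates, enclosure random intercepts and residual noise, and
    builds IC scores from the supplied coefficients (keys sex_m,
    body_size, bwa, to, trial4_rt, intercept).  Used to check coverage of
    the mixed-model estimator without the expense of trajectory
    simulation.
    """
    rng = np.random.default_rng(seed)
    enc = np.array(list("ABCD" * 10))[:n_enclosures]
    df = pd.DataFrame({
        "sex": rng.choice(["F", "M"], n),
        "body_size": rng.standard_normal(n),
        "bwa": rng.gamma(2.15, 11.26, n),
        "to": rng.permutation(n) + 1.0,
        "trial4_rt": rng.gamma(4.0, 1.2, n),
        "enclosure": rng.choice(enc, n),
    })
    re = dict(zip(enc, enclosure_sd * rng.standard_normal(n_enclosures)))
    y = np.full(n, float(coeffs.get("intercept", 0.0)))
    y += coeffs.get("sex_m", 0.0) * (df["sex"] == "M").to_numpy(float)
    for k in ("body_size", "bwa", "to", "trial4_rt"):
        y += coeffs.get(k, 0.0) * df[k].to_numpy(float)
    y += df["enclosure"].map(re).to_numpy(float)
    y += noise_sd * rng.standard_normal(n)
    df["ic_score"] = y
    return df
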