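"""End-to-end pipeline: standardise, measure, exclude, score, infer.

``run_pipeline`` is a pure function of (tracks, covariates, calibrations,
config): the same inputs and seed give byte-identical output tables.
Stages log their counts; optional stages (PCA, inference) are skipped with
a warning when the retained cohort is too small to support them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as tm
from . import qc, scoring, stats
from .arena import ArenaCalibration, build_transform, apply_transform, \
    find_ir_crossing, StdTrajectory
from .datamodel import (BirdCovariates, EmptyCohortError, PipelineConfig,
                        RawTrack, ValidationError, covariates_frame)

logger = logging.getLogger("stopchange")

SCHEMA_VERSION = 1


@dataclass
class PipelineResult:
    metrics: pd.DataFrame  # per-trial rows, pre-QC
    exclusions: qc.ExclusionReport
    measures: pd.DataFrame  # per retained bird
    ic_score: scoring.ICScore | None
    body_size: scoring.BodySizeScore | None
    correlations: tuple[pd.DataFrame, pd.DataFrame] | None
    anova: stats.AnovaResult | None
    coordinate_tests: pd.DataFrame | None
    mixed_model: stats.MixedModelResult | None
    mean_paths: pd.DataFrame | None
    summary: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "trial_metrics.csv", index=False)
        self.exclusions.birds.to_csv(out / "exclusions.csv", index=False)
        self.exclusions.detail.to_csv(out / "exclusion_detail.csv",
                                      index=False)
        self.measures.to_csv(out / "ic_measures.csv")
        if self.ic_score is not None:
            sc = self.ic_score.scores.to_frame()
            if self.body_size is not None:
                sc = sc.join(self.body_size.scores)
            sc.to_csv(out / "scores.csv")
            with open(out / "loadings.json", "w") as fh:
                json.dump({
                    "ic": {"loadings": self.ic_score.loadings.to_dict(),
                           "eigenvalue": self.ic_score.eigenvalue,
                           "var_explained": self.ic_score.var_explained},
                    "body_size": None if self.body_size is None else {
                        "loadings": self.body_size.loadings.to_dict(),
                        "eigenvalue": self.body_size.eigenvalue,
                        "var_explained": self.body_size.var_explained},
                }, fh, indent=2)
        if self.anova is not None:
            self.anova.table.to_csv(out / "anova.csv", index=False)
            self.anova.posthoc.to_csv(out / "posthoc.csv", index=False)
            pd.DataFrame(self.anova.trends).T.rename_axis("block") \
                .to_csv(out / "quadratic_trends.csv")
        if self.coordinate_tests is not None:
            self.coordinate_tests.to_csv(out / "coordinate_tests.csv",
                                         index=False)
        if self.mixed_model is not None:
            self.mixed_model.table.to_csv(out / "mixed_model.csv",
                                          index=False)
        if self.mean_paths is not None:
            self.mean_paths.to_csv(out / "mean_paths.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary, fh, indent=2, default=float)


def standardize_cohort(tracks: list[RawTrack],
                       calibrations: dict[str, ArenaCalibration],
                       ) -> dict[str, dict[int, StdTrajectory]]:
    """Map every raw track into the arena frame, grouped by bird."""
    transforms = {e: build_transform(c) for e, c in calibrations.items()}
    cohort: dict[str, dict[int, StdTrajectory]] = {}
    for track in tracks:
        enc = track.meta.enclosure
        if enc not in transforms:
            raise ValidationError(
                f"no calibration for enclosure {enc!r}")
        traj = apply_transform(track, transforms[enc],
                               calibrations[enc].entrance)
        cohort.setdefault(track.meta.bird_id, {})[
            track.meta.trial_index] = traj
    return cohort


def run_pipeline(tracks: list[RawTrack],
                 covariates: list[BirdCovariates] | None,
                 calibrations: dict[str, ArenaCalibration],
                 config: PipelineConfig) -> PipelineResult:
    if not tracks:
        raise EmptyCohortError("no input tracks")
    cohort = standardize_cohort(tracks, calibrations)
    logger.info("standardised %d trials from %d birds",
                len(tracks), len(cohort))

    # per-trial metrics (pre-QC) -----------------------------------------
    rows = []
    latencies: dict[str, dict[int, float | None]] = {}
    for bird_id in sorted(cohort):
        for idx in sorted(cohort[bird_id]):
            traj = cohort[bird_id][idx]
            find_ir_crossing(traj)
            row = tm.compute_trial_row(traj, config)
            rows.append(row)
            latencies.setdefault(bird_id, {})[idx] = row["latency_s"]
    metrics = pd.DataFrame(rows)

    # exclusions ----------------------------------------------------------
    retained, report = qc.apply_exclusions(cohort, latencies, config)
    logger.info("QC: %d of %d birds retained (%s)", len(retained),
                len(cohort), report.reason_counts or "no exclusions")
    if not retained:
        raise EmptyCohortError(
            f"no birds retained after QC: {report.reason_counts}")

    # per-bird measures ----------------------------------------------------
    ms = []
    for bird_id in retained:
        m = tm.compute_ic_measures(
            cohort[bird_id], metrics[metrics["bird_id"] == bird_id])
        if m is not None:
            ms.append(m)
    measures = tm.measures_frame(ms) if ms else pd.DataFrame()

    # composite scores ----------------------------------------------------
    ic_score = body_size = correlations = None
    if len(measures) >= 5:
        ic_score = scoring.ic_pca_score(measures)
        correlations = scoring.measure_correlations(measures)
    else:
        logger.warning("only %d usable birds: skipping the IC component",
                       len(measures))
    cov_df = covariates_frame(covariates) if covariates else None
    if cov_df is not None:
        cov_ret = cov_df.loc[cov_df.index.intersection(measures.index)]
        if len(cov_ret) >= 3:
            body_size = scoring.body_size_pc(cov_ret)

    # inference ------------------------------------------------------------
    anova = coord = mixed = None
    wide = metrics.pivot_table(index="bird_id", columns="trial_index",
                               values="latency_s")
    wide = wide.loc[wide.index.intersection(retained)]
    if len(wide) >= 3 and wide.notna().all().all():
        anova = stats.rm_anova(wide)
    t6 = metrics[(metrics["trial_index"] == 6)
                 & metrics["bird_id"].isin(measures.index)]
    if len(t6) >= 2:
        coord_rows = []
        for col, ref, label in (("cross_x", 0.0, "crossing x vs midline"),
                                ("corr_x", 0.0, "correction x vs midline"),
                                ("corr_y", 0.0, "correction y vs beam")):
            vals = t6[col].dropna().to_numpy()
            if len(vals) >= 2 and np.std(vals) > 0:
                r = stats.coordinate_ttest(vals, ref)
                r["test"] = label
                coord_rows.append(r)
        coord = pd.DataFrame(coord_rows) if coord_rows else None
    if (ic_score is not None and cov_df is not None
            and body_size is not None):
        data = cov_df.join(ic_score.scores, how="inner") \
            .join(body_size.scores, how="inner")
        t4 = wide[4] if 4 in wide.columns else None
        if t4 is not None:
            data["trial4_rt"] = data["trial4_rt"].fillna(t4)
        data = data.dropna(
            subset=["ic_score", "body_size", "bwa", "to", "trial4_rt"])
        if len(data) >= 10:
            try:
                mixed = stats.fit_ic_model(data)
            except (ValueError, np.linalg.LinAlgError) as e:
                logger.warning("mixed model not fitted: %s", e)

    # mean Vincentized paths ----------------------------------------------
    mp_rows = []
    for idx in range(1, 7):
        vps = []
        for bird_id in measures.index:
            traj = cohort[bird_id].get(idx)
            if traj is not None and traj.t_end is not None:
                vps.append(tm.vincentize(traj, config.n_quantiles))
        if vps:
            mp = tm.mean_path(vps)
            for k, (x, y) in enumerate(mp.points, start=1):
                mp_rows.append({"trial_index": idx, "quantile": k,
                                "mean_x": x, "mean_y": y})
    mean_paths = pd.DataFrame(mp_rows) if mp_rows else None

    summary = {
        "schema_version": SCHEMA_VERSION,
        "n_birds_input": len(cohort),
        "n_trials_input": len(tracks),
        "qc": report.summary(),
        "n_birds_scored": len(measures),
        "measure_means": measures[list(tm.MEASURE_NAMES)].mean().to_dict()
        if len(measures) else {},
        "ic_eigenvalue": None if ic_score is None else ic_score.eigenvalue,
        "ic_var_explained": None if ic_score is None
        else ic_score.var_explained,
        "body_size_var_explained": None if body_size is None
        else body_size.var_explained,
        "rng_seed": config.rng_seed,
    }
    return PipelineResult(
        metrics=metrics, exclusions=report, measures=measures,
        ic_score=ic_score, body_size=body_size, correlations=correlations,
        anova=anova, coordinate_tests=coord, mixed_model=mixed,
        mean_paths=mean_paths, summary=summary,
    )
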