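"""Group-level inference for the stop-change task.

* A 2 (Block: trials 1-3 vs 4-6) x 3 (Trial Type: first Go, second Go,
  Change) repeated-measures ANOVA on completion latencies, with each
  effect tested against its own subject-interaction error term and no
  sphericity correction by default (a Greenhouse-Geisser option exists).
* Per-block quadratic trend contrasts (1, -2, 1) and Bonferroni-corrected
  pairwise post hocs (family = the 3 within-block pairs).
* One-sample t-tests of trajectory coordinates against a reference.
* A linear mixed model for IC scores (normal response, REML) with a random
  intercept for enclosure; fixed effects are sex (female reference), body
  size, BWA, TO and trial-4 latency.  The sex x size interaction is fitted
  first and dropped (with a refit) when non-significant.  Reported p-values
  for the mixed model are Wald tests based on the large-sample normal
  approximation.

The ANOVA sums of squares are computed explicitly so the within-subject
decomposition (total = effects + subjects + error strata) can be audited.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("stopchange")

QUADRATIC_CONTRAST = np.array([1.0, -2.0, 1.0])


@dataclass
class AnovaResult:
    table: pd.DataFrame  # effect, F, df1, df2, p
    ss: dict  # full sums-of-squares partition
    cell_means: pd.DataFrame  # block x trial-type means
    posthoc: pd.DataFrame | None = None
    trends: dict = field(default_factory=dict)


@dataclass
class MixedModelResult:
    table: pd.DataFrame  # term, b, SE, t, p
    random_intercept_var: float
    interaction_included: bool
    interaction_p: float | None
    method: str  # "mixedlm" or "ols-fallback"


def _f_p(ss_eff, df_eff, ss_err, df_err):
    if ss_err <= 0:
        # degenerate (e.g. identical cells): no variability to test against
        return 0.0, 1.0
    F = (ss_eff / df_eff) / (ss_err / df_err)
    return float(F), float(sps.f.sf(F, df_eff, df_err))


def _layout(wide: pd.DataFrame) -> np.ndarray:
    """(n, 2, 3) latency array: subject x block x within-block position."""
    cols = [1, 2, 3, 4, 5, 6]
    missing = [c for c in cols if c not in wide.columns]
    if missing:
        raise ValueError(f"incomplete layout: missing trial(s) {missing}")
    if wide[cols].isna().any().any():
        bad = wide.index[wide[cols].isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete layout: missing cells for {bad}")
    return wide[cols].to_numpy(float).reshape(len(wide), 2, 3)


def rm_anova(wide: pd.DataFrame,
             gg_correction: bool = False) -> AnovaResult:
    """Two-way fully within-subjects ANOVA on the 6-trial latency table.

    ``wide`` is indexed by bird with columns 1..6 (trial latencies).
    Block = {1-3, 4-6}; Trial Type = position within block.  Each effect
    uses its own Effect x Subject interaction as the error term.
    """
    Y = _layout(wide)
    n, a, b = Y.shape
    if n < 2:
        raise ValueError("need >= 2 subjects")
    gm = Y.mean()
    subj = Y.mean(axis=(1, 2))
    A = Y.mean(axis=(0, 2))  # block means
    B = Y.mean(axis=(0, 1))  # trial-type means
    AB = Y.mean(axis=0)
    AS = Y.mean(axis=2)  # subject x block
    BS = Y.mean(axis=1)  # subject x type

    ss_subj = a * b * np.sum((subj - gm) ** 2)
    ss_A = b * n * np.sum((A - gm) ** 2)
    ss_B = a * n * np.sum((B - gm) ** 2)
    ss_AB = n * np.sum((AB - A[:, None] - B[None, :] + gm) ** 2)
    ss_AS = b * np.sum((AS - A[None, :] - subj[:, None] + gm) ** 2)
    ss_BS = a * np.sum((BS - B[None, :] - subj[:, None] + gm) ** 2)
    ss_total = np.sum((Y - gm) ** 2)
    ss_ABS = ss_total - (ss_subj + ss_A + ss_B + ss_AB + ss_AS + ss_BS)
    ss_ABS = max(ss_ABS, 0.0)

    df_A, df_B, df_AB = a - 1, b - 1, (a - 1) * (b - 1)
    df_AS, df_BS = df_A * (n - 1), df_B * (n - 1)
    df_ABS = df_AB * (n - 1)

    eff = []
    for name, ss_e, df_e, ss_r, df_r in (
            ("Block", ss_A, df_A, ss_AS, df_AS),
            ("TrialType", ss_B, df_B, ss_BS, df_BS),
            ("Block:TrialType", ss_AB, df_AB, ss_ABS, df_ABS)):
        df1, df2 = df_e, df_r
        if gg_correction and df_e > 1:
            eps = _gg_epsilon(Y, name)
            df1, df2 = eps * df1, eps * df2
        F, p = _f_p(ss_e, df1, ss_r, df2)
        eff.append({"effect": name, "F": F, "df1": df1, "df2": df2, "p": p})

    cell_means = pd.DataFrame(AB, index=pd.Index([1, 2], name="block"),
                              columns=["first_go", "second_go", "change"])
    res = AnovaResult(
        table=pd.DataFrame(eff),
        ss={"subjects": ss_subj, "Block": ss_A, "TrialType": ss_B,
            "Block:TrialType": ss_AB, "Block:subj": ss_AS,
            "TrialType:subj": ss_BS, "residual": ss_ABS,
            "total": ss_total},
        cell_means=cell_means,
    )
    res.posthoc = pd.concat(
        [bonferroni_pairwise(Y[:, i, :], block=i + 1) for i in range(a)],
        ignore_index=True)
    res.trends = {i + 1: quadratic_trend(Y[:, i, :]) for i in range(a)}
    return res


def _gg_epsilon(Y: np.ndarray, effect: str) -> float:
    """Greenhouse-Geisser epsilon for the trial-type stratum."""
    M = Y.mean(axis=1) if effect == "TrialType" else \
        (Y[:, 0, :] - Y[:, 1, :])
    S = np.cov(M, rowvar=False)
    k = S.shape[0]
    D = S - S.mean(axis=0)[None, :] - S.mean(axis=1)[:, None] + S.mean()
    denom = (k - 1) * np.sum(D * D)
    eps = (np.trace(D) ** 2) / denom if denom > 0 else 1.0
    return float(min(max(eps, 1.0 / (k - 1)), 1.0))


def quadratic_trend(block_values: np.ndarray) -> dict:
    """Quadratic contrast (1, -2, 1) across the three trials of one block.

    Applies the contrast per bird and tests the contrast scores against 0
    (one-sample t; F = t^2 with df (1, n-1)).  Also returns the contrast
    of the cell means.
    """
    V = np.asarray(block_values, float)
    if V.ndim != 2 or V.shape[1] != 3:
        raise ValueError("block_values must be (n, 3)")
    n = len(V)
    if n < 2:
        raise ValueError("need >= 2 birds for the trend test")
    scores = V @ QUADRATIC_CONTRAST
    mean_contrast = float(V.mean(axis=0) @ QUADRATIC_CONTRAST)
    sd = scores.std(ddof=1)
    if sd == 0:
        t = 0.0
        p = 1.0
    else:
        t = float(scores.mean() / (sd / np.sqrt(n)))
        p = float(2 * sps.t.sf(abs(t), n - 1))
    return {"contrast": mean_contrast, "t": t, "F": t * t,
            "df1": 1, "df2": n - 1, "p": p}


def bonferroni_pairwise(block_values: np.ndarray,
                        block: int | None = None) -> pd.DataFrame:
    """Paired t-tests for the three within-block trial pairs, Bonferroni
    corrected within that family (adjusted p = min(1, 3 * raw p))."""
    V = np.asarray(block_values, float)
    labels = ["first_go", "second_go", "change"]
    rows = []
    pairs = [(0, 1), (0, 2), (1, 2)]
    for i, j in pairs:
        diff = V[:, i] - V[:, j]
        if np.allclose(diff.std(ddof=1), 0):
            t, p = (0.0, 1.0) if np.allclose(diff.mean(), 0) else \
                (np.inf, 0.0)
        else:
            res = sps.ttest_rel(V[:, i], V[:, j])
            t, p = float(res.statistic), float(res.pvalue)
        rows.append({
            "block": block, "pair": f"{labels[i]} vs {labels[j]}",
            "mean_diff": float(diff.mean()), "t": t, "df": len(V) - 1,
            "p_raw": p, "p_bonferroni": min(1.0, 3.0 * p),
        })
    return pd.DataFrame(rows)


def coordinate_ttest(values: np.ndarray, reference: float = 0.0) -> dict:
    """Two-sided one-sample t-test of per-bird coordinates against a
    reference (e.g. the crossing x-coordinate against the midline)."""
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValueError("need >= 2 values")
    sd = v.std(ddof=1)
    if sd == 0:
        if np.allclose(v.mean(), reference):
            return {"mean": float(v.mean()), "sd": 0.0, "t": 0.0,
                    "df": len(v) - 1, "p": 1.0}
        raise ValueError("zero variance away from the reference")
    res = sps.ttest_1samp(v, reference)
    return {"mean": float(v.mean()), "sd": float(sd),
            "t": float(res.statistic), "df": len(v) - 1,
            "p": float(res.pvalue)}


FIXED_EFFECTS = ["sex_m", "body_size", "bwa", "to", "trial4_rt"]


def fit_ic_model(data: pd.DataFrame, alpha: float = 0.05,
                 ) -> MixedModelResult:
    """Mixed model for IC scores with an enclosure random intercept.

    ``data`` needs columns ic_score, sex (F/M), body_size, bwa, to,
    trial4_rt, enclosure.  Stage 1 includes the sex x body-size
    interaction; when its p >= alpha the model is refitted with main
    effects only and that refit is reported.  With a single enclosure the
    model falls back to ordinary least squares (no random intercept).
    """
    import statsmodels.formula.api as smf

    df = data.copy()
    need = {"ic_score", "sex", "body_size", "bwa", "to", "trial4_rt",
            "enclosure"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = df.dropna(subset=sorted(need))
    df["sex_m"] = (df["sex"] == "M").astype(float)  # female = reference 0

    X = df[FIXED_EFFECTS].to_numpy(float)
    Xc = np.column_stack([np.ones(len(df)), X])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError(
            "rank-deficient design: aliased terms among "
            f"{['intercept'] + FIXED_EFFECTS}"
        )

    base = "ic_score ~ " + " + ".join(FIXED_EFFECTS)
    inter = base + " + sex_m:body_size"
    single_group = df["enclosure"].nunique() < 2

    def _fit(formula):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if single_group:
                return smf.ols(formula, data=df).fit(), "ols-fallback"
            m = smf.mixedlm(formula, data=df, groups=df["enclosure"])
            return m.fit(reml=True), "mixedlm"

    fit1, method = _fit(inter)
    if single_group:
        logger.warning("single enclosure: random intercept dropped, "
                       "fitting fixed effects only")
    p_inter = float(fit1.pvalues["sex_m:body_size"])
    if p_inter < alpha:
        fit, keep = fit1, True
    else:
        fit, method = _fit(base)
        keep = False

    terms = [t for t in fit.params.index if t != "Group Var"]
    table = pd.DataFrame({
        "term": terms,
        "b": [float(fit.params[t]) for t in terms],
        "SE": [float(fit.bse[t]) for t in terms],
        "t": [float(fit.params[t] / fit.bse[t]) for t in terms],
        "p": [float(fit.pvalues[t]) for t in terms],
        "ci_low": [float(fit.conf_int().loc[t, 0]) for t in terms],
        "ci_high": [float(fit.conf_int().loc[t, 1]) for t in terms],
    })
    re_var = float(fit.cov_re.iloc[0, 0]) if method == "mixedlm" else 0.0
    return MixedModelResult(
        table=table, random_intercept_var=re_var,
        interaction_included=keep, interaction_p=p_inter, method=method,
    )
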