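"""Composite scores: the inhibitory-control principal component and the
mass+tarsus body-size component.

Both composites are first principal components of the *correlation* matrix
(the inputs have incommensurate units), with deterministic orientation
rules so scores are reproducible across linear-algebra backends:

* IC score — the three measures (latency difference, correction distance,
  CSRT) all point toward *poor* control, so the first eigenvector is
  oriented with non-negative loadings and the projection is multiplied by
  -1: a high score means strong inhibitory control.
* body size — positive loadings on both mass and tarsus; an exactly
  uncorrelated pair resolves to the (1, 1)/sqrt(2) direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datamodel import BirdCovariates, ValidationError
from .metrics import MEASURE_NAMES, ICMeasures, measures_frame


@dataclass
class ICScore:
    scores: pd.Series  # indexed by bird_id; mean 0; high = strong control
    loadings: pd.Series  # per measure, non-negative orientation
    eigenvalue: float
    var_explained: float  # eigenvalue / 3


@dataclass
class BodySizeScore:
    scores: pd.Series
    loadings: pd.Series  # positive on mass and tarsus
    eigenvalue: float
    var_explained: float  # eigenvalue / 2


def _zscore(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ValidationError(
            f"zero-variance measure(s): {list(zero.index)}"
        )
    return (df - df.mean()) / sd


def measure_correlations(measures: list[ICMeasures] | pd.DataFrame,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations of the three measures with two-sided
    p-values.  Requires at least 4 birds."""
    df = measures if isinstance(measures, pd.DataFrame) \
        else measures_frame(measures)
    df = df[list(MEASURE_NAMES)]
    if len(df) < 4:
        raise ValidationError(
            f"need >= 4 birds for measure correlations, got {len(df)}"
        )
    _zscore(df)  # raises on a constant measure
    names = list(MEASURE_NAMES)
    r = pd.DataFrame(np.eye(3), index=names, columns=names)
    p = pd.DataFrame(np.zeros((3, 3)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = sps.pearsonr(df[a], df[b])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


def _first_component(corr: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eigh(corr)
    return float(vals[-1]), vecs[:, -1]


def ic_pca_score(measures: list[ICMeasures] | pd.DataFrame) -> ICScore:
    """First-PC composite of the three measures, sign-flipped so that a
    high score means strong inhibitory control."""
    df = measures if isinstance(measures, pd.DataFrame) \
        else measures_frame(measures)
    df = df[list(MEASURE_NAMES)].astype(float)
    if len(df) < 5:
        raise ValidationError(
            f"need >= 5 birds for the IC component, got {len(df)}"
        )
    if not np.all(np.isfinite(df.to_numpy())):
        raise ValidationError("non-finite measure values")
    z = _zscore(df)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigval, vec = _first_component(corr)
    # orient: all three measures index poor control, so their loadings
    # should be non-negative; flip by the loading sum if needed
    if vec.sum() < 0:
        vec = -vec
    scores = -(z.to_numpy() @ vec)
    return ICScore(
        scores=pd.Series(scores, index=df.index, name="ic_score"),
        loadings=pd.Series(vec, index=MEASURE_NAMES, name="loading"),
        eigenvalue=eigval,
        var_explained=eigval / 3.0,
    )


def body_size_pc(covariates: list[BirdCovariates] | pd.DataFrame,
                 ) -> BodySizeScore:
    """First PC of (mass, tarsus): the overall body-size axis.

    The eigenvalue of a 2-variable correlation matrix is 1 + |r|, so the
    variance explained is (1 + |r|)/2.  At r = 0 the eigenvalues tie and
    the direction is fixed to (1, 1)/sqrt(2) by convention.
    """
    if isinstance(covariates, pd.DataFrame):
        df = covariates[["mass", "tarsus"]].astype(float)
    else:
        df = pd.DataFrame(
            {"mass": [c.mass for c in covariates],
             "tarsus": [c.tarsus for c in covariates]},
            index=pd.Index([c.bird_id for c in covariates], name="bird_id"),
        )
    if len(df) < 3:
        raise ValidationError(
            f"need >= 3 birds for the body-size component, got {len(df)}"
        )
    z = _zscore(df)
    r = float(np.corrcoef(z["mass"], z["tarsus"])[0, 1])
    if abs(r) < 1e-12:  # equal-eigenvalue tie: fixed direction
        vec = np.array([1.0, 1.0]) / np.sqrt(2.0)
        eigval = 1.0
    else:
        eigval = 1.0 + abs(r)
        # eigenvector of [[1, r], [r, 1]] for 1 + |r| is (1, sign(r))/sqrt(2);
        # mass keeps a positive loading (r < 0 cannot give two positive ones)
        vec = np.array([1.0, np.sign(r)]) / np.sqrt(2.0)
    scores = z.to_numpy() @ vec
    return BodySizeScore(
        scores=pd.Series(scores, index=df.index, name="body_size"),
        loadings=pd.Series(vec, index=["mass", "tarsus"], name="loading"),
        eigenvalue=eigval,
        var_explained=eigval / 2.0,
    )
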