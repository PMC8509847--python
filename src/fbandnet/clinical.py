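"""Exploratory regression of clinical change on brain-network features.

The outcome is the pre-to-post change in the total depression score
(post - pre, negative = improvement); the main regressor is a network
feature (a change or a baseline value) and demographic covariates (age,
sex, IQ) can be partialed out. Fits are ordinary least squares; results
are exploratory and deliberately not corrected for multiple comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["ClinicalTable", "RegressionResult", "regress_outcome", "regress_pooled_sessions"]

MIN_COMPLETE_CASES = 4


@dataclass
class ClinicalTable:
    """Per-subject clinical scores and demographics.

    ``change`` is post - pre (negative = improvement). Subjects with a
    missing session keep NaN there; regressions drop them listwise.
    """

    table: pd.DataFrame  # columns: subject, pre, post, age, sex, iq (some optional)

    def __post_init__(self) -> None:
        t = self.table
        if "change" not in t.columns:
            t = t.assign(change=t["post"] - t["pre"])
        both = t["pre"].notna() & t["post"].notna()
        if not np.allclose(
            t.loc[both, "change"], t.loc[both, "post"] - t.loc[both, "pre"]
        ):
            raise ValueError("change column inconsistent with pre/post scores")
        self.table = t


@dataclass
class RegressionResult:
    slope: float
    p_value: float
    n_used: int
    stderr: float
    r_squared: float


def _fit(outcome: np.ndarray, design: pd.DataFrame) -> RegressionResult:
    X = sm.add_constant(design, has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the offending columns for the caller
        cols = list(X.columns)
        for k in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X.to_numpy()[:, : k + 1]) == np.linalg.matrix_rank(
                X.to_numpy()[:, :k]
            ):
                raise ValueError(
                    f"collinear design: column {cols[k]!r} is linearly dependent "
                    "on the preceding columns"
                )
        raise ValueError("collinear design")
    fit = sm.OLS(outcome, X).fit()
    return RegressionResult(
        slope=float(fit.params["feature"]),
        p_value=float(fit.pvalues["feature"]),
        n_used=int(fit.nobs),
        stderr=float(fit.bse["feature"]),
        r_squared=float(fit.rsquared),
    )


def regress_outcome(
    feature,
    outcome,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> RegressionResult:
    """OLS of outcome on [intercept | feature | covariates].

    Rows with any missing value are dropped listwise; at least
    ``MIN_COMPLETE_CASES`` complete cases are required. With covariates the
    feature coefficient equals the fit of residualized outcome on
    residualized feature (the Frisch-Waugh identity), i.e. the covariates
    are partialed out.
    """
    feature = np.asarray(feature, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    if feature.shape != outcome.shape or feature.ndim != 1:
        raise ValueError("feature and outcome must be 1-D vectors of equal length")
    frame = pd.DataFrame({"feature": feature, "outcome": outcome})
    if covariates is not None:
        cov = pd.DataFrame(np.atleast_2d(np.asarray(covariates, dtype=float)))
        if cov.shape[0] != len(feature):
            cov = cov.T
        cov.columns = [f"cov{k}" for k in range(cov.shape[1])]
        frame = pd.concat([frame, cov.reset_index(drop=True)], axis=1)
    frame = frame.dropna()
    if len(frame) < MIN_COMPLETE_CASES:
        raise ValueError(
            f"only {len(frame)} complete cases; at least {MIN_COMPLETE_CASES} required"
        )
    return _fit(frame["outcome"].to_numpy(), frame.drop(columns="outcome"))


def regress_pooled_sessions(
    feature_pre,
    feature_post,
    outcome_pre,
    outcome_post,
    covariates=None,
) -> RegressionResult:
    """Pooled fit stacking baseline and post-treatment observations.

    Pools the two sessions of each subject as if they were independent
    observations. This inflates the effective sample size and thus the
    false-positive rate; it is provided only to reproduce the pooled
    exploratory analysis style and should be labeled as such in reports.
    """
    f = np.concatenate([np.asarray(feature_pre, float), np.asarray(feature_post, float)])
    y = np.concatenate([np.asarray(outcome_pre, float), np.asarray(outcome_post, float)])
    cov = None
    if covariates is not None:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != len(feature_pre):
            c = c.T
        cov = np.vstack([c, c])
    return regress_outcome(f, y, covariates=cov)
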