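"""Paired pre/post group inference: sign-flip permutation tests, effect
sizes, power, and multiple-comparison control.

The core test randomizes the sign of each subject's pre-to-post change and
compares the observed mean change D against the permutation distribution
of mean changes D'. The reported p-value is the empirical tail probability
in the direction of the observed sign of D, with the observed assignment
counted in the tail (so p is never 0). With n subjects the sign space has
2^n points; whenever 2^n does not exceed the requested realization count
the test enumerates the space exactly instead of sampling, which at n = 12
makes every p an exact multiple of 2^-12 = 0.0002441. Note that because
the tail direction is chosen from the data, the null distribution of this
p-value is uniform on (0, 1/2] rather than (0, 1]; see the methods note.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PairedSample",
    "PermutationResult",
    "Subnetwork",
    "sign_permutation_test",
    "sign_permutation_many",
    "cohens_d_pooled",
    "power_one_sample",
    "bonferroni_threshold",
    "bh_fdr_select",
    "build_fdr_subnetwork",
]

DEFAULT_REALIZATIONS = 1_000_000


@dataclass
class PairedSample:
    """Per-subject pre and post values of one feature."""

    pre: np.ndarray
    post: np.ndarray

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=float)
        self.post = np.asarray(self.post, dtype=float)
        if self.pre.shape != self.post.shape or self.pre.ndim != 1:
            raise ValueError("pre and post must be 1-D vectors of equal length")
        if not (np.isfinite(self.pre).all() and np.isfinite(self.post).all()):
            raise ValueError("paired samples must not contain missing values")

    @property
    def diffs(self) -> np.ndarray:
        return self.post - self.pre

    @property
    def n(self) -> int:
        return len(self.pre)


@dataclass
class PermutationResult:
    observed_d: float
    p: float
    n_realizations: int
    exhaustive: bool
    effect_size_d: float = np.nan
    power: float = np.nan

    @property
    def resolution(self) -> float:
        """Smallest achievable p: 2^-n when exhaustive, 1/realizations sampled."""
        return 1.0 / self.n_realizations


@functools.lru_cache(maxsize=4)
def _exhaustive_signs_cached(n: int) -> np.ndarray:
    codes = np.arange(2 ** n, dtype=np.uint32)
    bits = (codes[:, None] >> np.arange(n, dtype=np.uint32)) & 1
    return bits.astype(np.float64) * 2.0 - 1.0


def _exhaustive_signs(n: int) -> np.ndarray:
    """All 2^n sign vectors as a (2^n, n) float +-1 matrix.

    Cached only for small n; large enumerations are rebuilt on demand to
    keep resident memory bounded."""
    if n <= 16:
        return _exhaustive_signs_cached(n)
    codes = np.arange(2 ** n, dtype=np.uint32)
    bits = (codes[:, None] >> np.arange(n, dtype=np.uint32)) & 1
    return bits.astype(np.float64) * 2.0 - 1.0


def _tail_probabilities(
    observed: np.ndarray, null_means: np.ndarray
) -> np.ndarray:
    """Directional tail probability per column of the null mean matrix.

    ``observed``: (m,), ``null_means``: (R, m). For D > 0 counts D' >= D,
    for D < 0 counts D' <= D; D == 0 gives p = 1.
    """
    r = null_means.shape[0]
    p = np.empty(observed.shape)
    pos = observed > 0
    neg = observed < 0
    # small numerical guard keeps the observed assignment in its own tail
    tol = 1e-12 * np.maximum(1.0, np.abs(observed))
    if pos.any():
        p[pos] = (null_means[:, pos] >= (observed[pos] - tol[pos])).sum(axis=0) / r
    if neg.any():
        p[neg] = (null_means[:, neg] <= (observed[neg] + tol[neg])).sum(axis=0) / r
    p[~(pos | neg)] = 1.0
    return p


def sign_permutation_many(
    diffs: np.ndarray,
    n_realizations: int = DEFAULT_REALIZATIONS,
    seed: int | None = None,
    chunk: int = 65536,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Vectorized sign-flip test over many features sharing the subjects.

    ``diffs`` is (n_subjects, m). Returns (observed means, p-values,
    realization count, exhaustive flag). Enumerates all 2^n sign
    assignments when that does not exceed ``n_realizations``; otherwise
    draws ``n_realizations`` random assignments (seeded).
    """
    diffs = np.atleast_2d(np.asarray(diffs, dtype=float))
    n, m = diffs.shape
    if n < 2:
        raise ValueError("need at least 2 paired subjects")
    observed = diffs.mean(axis=0)
    exhaustive = 2 ** n <= n_realizations
    if exhaustive:
        signs = _exhaustive_signs(n)
        null_means = signs @ diffs / n
        p = _tail_probabilities(observed, null_means)
        return observed, p, 2 ** n, True
    rng = np.random.default_rng(seed)
    counts = np.zeros(m)
    done = 0
    tol = 1e-12 * np.maximum(1.0, np.abs(observed))
    pos = observed > 0
    neg = observed < 0
    while done < n_realizations:
        r = min(chunk, n_realizations - done)
        signs = rng.integers(0, 2, size=(r, n)).astype(np.float64) * 2.0 - 1.0
        null_means = signs @ diffs / n
        counts[pos] += (null_means[:, pos] >= (observed[pos] - tol[pos])).sum(axis=0)
        counts[neg] += (null_means[:, neg] <= (observed[neg] + tol[neg])).sum(axis=0)
        done += r
    p = counts / n_realizations
    p[~(pos | neg)] = 1.0
    # the observed assignment counts as one realization; p is never 0
    p = np.maximum(p, 1.0 / n_realizations)
    return observed, p, n_realizations, False


def sign_permutation_test(
    sample: PairedSample,
    n_realizations: int = DEFAULT_REALIZATIONS,
    seed: int | None = None,
    alpha: float = 0.05,
) -> PermutationResult:
    """Sign-flip permutation test of one paired feature, with Cohen's d
    (pooled) and post-hoc power of the one-sample t-test on the changes."""
    diffs = sample.diffs
    observed, p, n_real, exhaustive = sign_permutation_many(
        diffs[:, None], n_realizations=n_realizations, seed=seed
    )
    sd = diffs.std(ddof=1)
    pooled_sd = _pooled_sd(sample.pre, sample.post)
    d = (sample.post.mean() - sample.pre.mean()) / pooled_sd if pooled_sd > 0 else np.nan
    power = power_one_sample(diffs, alpha=alpha) if sd > 0 else np.nan
    return PermutationResult(
        observed_d=float(observed[0]),
        p=float(p[0]),
        n_realizations=n_real,
        exhaustive=exhaustive,
        effect_size_d=float(d),
        power=float(power) if np.isfinite(power) else np.nan,
    )


def _pooled_sd(pre: np.ndarray, post: np.ndarray) -> float:
    n1, n2 = len(pre), len(post)
    v = ((n1 - 1) * np.var(pre, ddof=1) + (n2 - 1) * np.var(post, ddof=1)) / (
        n1 + n2 - 2
    )
    return float(np.sqrt(v))


def cohens_d_pooled(pre, post) -> float:
    """Cohen's d with pooled SD; negative = decrease after treatment."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) < 2 or len(post) < 2:
        raise ValueError("both sessions need at least 2 values")
    sd = _pooled_sd(pre, post)
    if sd == 0:
        if post.mean() == pre.mean():
            return 0.0
        raise ValueError("pooled standard deviation is zero; d undefined")
    return float((post.mean() - pre.mean()) / sd)


def power_one_sample(diffs, alpha: float = 0.05) -> float:
    """Power of the two-sided one-sample t-test of the changes vs mu0 = 0.

    Uses the noncentral-t distribution with noncentrality sqrt(n) mean/SD
    and n-1 degrees of freedom, at significance level ``alpha``.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = len(diffs)
    if n < 2:
        raise ValueError("need at least 2 changes")
    sd = diffs.std(ddof=1)
    if sd == 0:
        return 1.0 if diffs.mean() != 0 else alpha
    nc = np.sqrt(n) * diffs.mean() / sd
    df = n - 1
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(
        1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
    )


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Per-comparison threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def bh_fdr_select(pvals, alpha: float = 0.05) -> np.ndarray:
    """Indices selected by the Benjamini-Hochberg step-up procedure."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([], dtype=int)
    if (pvals < 0).any() or (pvals > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return np.flatnonzero(reject)


def paired_feature_table(
    pre: np.ndarray,
    post: np.ndarray,
    n_realizations: int = DEFAULT_REALIZATIONS,
    seed: int | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Sign-flip tests of many features at once (subjects x features).

    Returns one row per feature with the observed mean change ``D``, the
    directional permutation ``p``, Cohen's d (pooled over the two
    sessions) and the post-hoc power of the one-sample t-test on the
    changes. Degenerate features (zero spread) get d and power = NaN.
    """
    pre = np.atleast_2d(np.asarray(pre, dtype=float))
    post = np.atleast_2d(np.asarray(post, dtype=float))
    if pre.shape != post.shape:
        raise ValueError("pre and post must have matching subjects x features shape")
    n = pre.shape[0]
    diffs = post - pre
    observed, p, n_real, exhaustive = sign_permutation_many(
        diffs, n_realizations=n_realizations, seed=seed
    )
    pooled = np.sqrt(
        ((n - 1) * pre.var(axis=0, ddof=1) + (n - 1) * post.var(axis=0, ddof=1))
        / (2 * n - 2)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(pooled > 0, (post.mean(axis=0) - pre.mean(axis=0)) / pooled, np.nan)
    sd = diffs.std(axis=0, ddof=1)
    power = np.full(diffs.shape[1], np.nan)
    ok = sd > 0
    if ok.any():
        nc = np.sqrt(n) * observed[ok] / sd[ok]
        tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
        power[ok] = 1 - stats.nct.cdf(tcrit, n - 1, nc) + stats.nct.cdf(-tcrit, n - 1, nc)
    return pd.DataFrame(
        {
            "D": observed,
            "p": p,
            "effect_size": d,
            "power": power,
            "n_realizations": n_real,
            "exhaustive": exhaustive,
        }
    )


@dataclass
class Subnetwork:
    """Connections surviving edgewise BH-FDR in one frequency band."""

    band: int
    edges: pd.DataFrame  # columns: i, j, p, direction
    within_subnetwork_degree: np.ndarray

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def build_fdr_subnetwork(
    edge_table: pd.DataFrame,
    n_nodes: int,
    band: int = 0,
    alpha: float = 0.05,
) -> Subnetwork:
    """BH-FDR selected subnetwork plus within-subnetwork nodal degree.

    ``edge_table`` must have columns ``i``, ``j``, ``p`` and ``D`` (the
    observed mean connectivity change); every unique edge of the band
    should appear exactly once. The within-subnetwork degree of a node is
    the number of selected connections incident to it.
    """
    required = {"i", "j", "p", "D"}
    if not required.issubset(edge_table.columns):
        raise ValueError(f"edge table must have columns {sorted(required)}")
    selected = bh_fdr_select(edge_table["p"].to_numpy(), alpha=alpha)
    sub = edge_table.iloc[selected][["i", "j", "p"]].copy()
    sub["direction"] = np.sign(edge_table["D"].to_numpy()[selected]).astype(int)
    degree = np.zeros(n_nodes, dtype=int)
    for i, j in zip(sub["i"].astype(int), sub["j"].astype(int)):
        degree[i] += 1
        degree[j] += 1
    return Subnetwork(
        band=band,
        edges=sub.reset_index(drop=True),
        within_subnetwork_degree=degree,
    )
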