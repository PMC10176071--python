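"""Core statistical primitives for the two-group TMT design.

Everything here is tuned to the study layout — two groups of four samples —
where exact small-sample procedures are both feasible and preferable:
classical (equal-variance) Student's t, power via the noncentral t,
exact-enumeration Wilcoxon rank-sum and Spearman permutation p-values, and
a single-response OPLS-DA decomposition for the sample-separation plots.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "PowerSpec",
    "RankSumResult",
    "CorrResult",
    "OplsdaModel",
    "t_test_two_sample",
    "power_t_test",
    "wilcoxon_rank_sum",
    "pearson",
    "spearman",
    "cohens_d",
    "oplsda_fit",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def t_test_two_sample(a, b) -> TTestResult:
    """Two-sided equal-variance (classical Student's) two-sample t test.

    Degenerate zero-pooled-variance inputs are resolved by limit: equal
    means give (t=0, p=1), unequal means give p -> 0 with a degeneracy flag.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in t test input")
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, degenerate=True)
        return TTestResult(math.copysign(math.inf, diff), df, 0.0, degenerate=True)
    t = diff / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(min(p, 1.0)), degenerate=False)


@dataclass(frozen=True)
class PowerSpec:
    """Two-sample t-test power problem: Cohen's d, group sizes, alpha."""

    effect_size: float
    n1: int = 4
    n2: int = 4
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be >= 2")


def power_t_test(spec: PowerSpec) -> float:
    """Power of the two-sided two-sample t test, by the noncentral t.

    Noncentrality ncp = d * sqrt(n1*n2/(n1+n2)) on df = n1+n2-2; at d = 0
    the rejection probability is exactly alpha.
    """
    df = spec.n1 + spec.n2 - 2
    ncp = spec.effect_size * math.sqrt(spec.n1 * spec.n2 / (spec.n1 + spec.n2))
    tcrit = sps.t.ppf(1 - spec.alpha / 2, df)
    upper = sps.nct.sf(tcrit, df, ncp)
    lower = sps.nct.cdf(-tcrit, df, ncp)
    # scipy's noncentral t underflows to NaN at large |ncp|, where the
    # corresponding tail is 0 (and the other is 1)
    if math.isnan(upper):
        upper = 1.0 if ncp > tcrit else 0.0
    if math.isnan(lower):
        lower = 1.0 if -ncp > tcrit else 0.0
    return float(min(upper + lower, 1.0))


def cohens_d(a, b) -> float:
    """Pooled-SD Cohen's d of two observed samples."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        return 0.0 if a.mean() == b.mean() else math.inf
    return float((a.mean() - b.mean()) / math.sqrt(sp2))


@dataclass(frozen=True)
class RankSumResult:
    u: float
    p: float
    exact: bool


def wilcoxon_rank_sum(a, b, exact_threshold: int = 10) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact enumeration when both groups have <= ``exact_threshold``
    observations and there are no ties; otherwise a tie-corrected normal
    approximation (no continuity correction, so a dead-central U gives
    p = 1, and fully tied inputs resolve to p = 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("need >= 1 value per group")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    if not has_ties and n1 <= exact_threshold and n2 <= exact_threshold:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return RankSumResult(float(res.statistic), float(res.pvalue), True)
    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts)
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return RankSumResult(float(u1), 1.0, False)
    z = (u1 - mean_u) / math.sqrt(var_u)
    p = 2.0 * sps.norm.sf(abs(z))
    return RankSumResult(float(u1), float(min(p, 1.0)), False)


@dataclass(frozen=True)
class CorrResult:
    r: float
    p: float
    n: int
    exact: bool = False


def pearson(a, b) -> CorrResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired values")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in correlation input")
    res = sps.pearsonr(a, b)
    return CorrResult(float(res.statistic), float(res.pvalue), len(a))


from functools import lru_cache


@lru_cache(maxsize=8)
def _perm_indices(n: int) -> np.ndarray:
    """All n! permutations of range(n) as an (n!, n) index matrix."""
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _spearman_rho(ra: np.ndarray, rb: np.ndarray) -> float:
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = math.sqrt((ra**2).sum() * (rb**2).sum())
    return float((ra * rb).sum() / denom) if denom > 0 else math.nan

def spearman(a, b, exact_threshold: int = 8) -> CorrResult:
    """Spearman rank correlation with an exact permutation p for small n.

    Midranks handle ties; for n <= ``exact_threshold`` the p-value is the
    exact two-sided permutation tail over all n! orderings (coarse but
    honest at the study's n = 4 + 4), otherwise the t approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need >= 3 paired values")
    n = len(a)
    ra, rb = sps.rankdata(a), sps.rankdata(b)
    if ra.std() == 0 or rb.std() == 0:
        raise ValueError("zero rank variance in correlation input")
    rho = _spearman_rho(ra, rb)
    if n <= exact_threshold:
        rb_c = rb - rb.mean()
        ra_c = ra - ra.mean()
        denom = math.sqrt((ra_c**2).sum() * (rb_c**2).sum())
        rhos = ra_c[_perm_indices(n)] @ rb_c / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        return CorrResult(rho, p, n, exact=True)
    if abs(rho) >= 1.0:
        return CorrResult(rho, 0.0, n, exact=False)
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2.0 * sps.t.sf(abs(t), n - 2)
    return CorrResult(rho, float(min(p, 1.0)), n, exact=False)


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class OplsdaModel:
    """Fitted single-response OPLS-DA decomposition.

    One predictive component (scores ``t_pred``) plus ``n_orth`` orthogonal
    components whose scores have, by construction, zero sample covariance
    with the class response.  Inputs are mean-centered and unit-variance
    scaled internally; constant features are dropped with a warning.
    """

    t_pred: np.ndarray
    p_pred: np.ndarray
    w_pred: np.ndarray
    t_orth: np.ndarray  # samples x n_orth
    p_orth: np.ndarray  # features x n_orth
    w_orth: np.ndarray
    r2x: list[float] = field(default_factory=list)  # per component (pred first)
    r2y: float = 0.0
    feature_ids: list[str] | None = None
    sample_ids: list[str] | None = None
    y: np.ndarray | None = None

    def summary(self) -> str:
        lines = [
            "OPLS-DA (1 predictive + %d orthogonal component(s))" % self.t_orth.shape[1],
            f"  R2X per component: {[round(v, 4) for v in self.r2x]}",
            f"  R2Y (predictive):  {self.r2y:.4f}",
        ]
        return "\n".join(lines)


def oplsda_fit(X, y, n_orth: int = 1, feature_ids=None, sample_ids=None) -> OplsdaModel:
    """Fit OPLS-DA on samples x features ``X`` against a +/-1 class vector.

    Orthogonal-signal-correction PLS with a single response: the weight
    direction w ∝ X'y is fixed, each orthogonal component removes the part
    of the loading orthogonal to w, and the final predictive component is
    extracted from the deflated matrix.  Deterministic given input order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be samples x features aligned with y")
    classes = np.unique(y)
    if len(classes) != 2 or np.any(np.sort(classes) != [-1.0, 1.0]):
        raise ValueError("y must be a +/-1 class vector with both classes present")
    if min((y == -1).sum(), (y == 1).sum()) < 2:
        raise ValueError("need >= 2 samples per class")

    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} constant feature(s)")
        X = X[:, keep]
        if feature_ids is not None:
            feature_ids = [f for f, k in zip(feature_ids, keep) if k]
        sd = sd[keep]
    if X.shape[1] == 0:
        raise ValueError("no non-constant features")
    max_orth = min(X.shape[0] - 2, X.shape[1] - 1)
    if n_orth >= max(1, X.shape[0] - 1) or n_orth > max_orth:
        raise ValueError(f"n_orth={n_orth} too large for {X.shape[0]} samples")

    X0 = (X - X.mean(axis=0)) / sd
    y0 = y - y.mean()
    ssx_total = float((X0**2).sum())

    w = X0.T @ y0
    w = w / np.linalg.norm(w)

    t_orths, p_orths, w_orths, r2x_orth = [], [], [], []
    Xd = X0
    for _ in range(n_orth):
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            raise ValueError("orthogonal variation exhausted; reduce n_orth")
        w_o = w_o / norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        t_orths.append(t_o)
        p_orths.append(p_o)
        w_orths.append(w_o)
        r2x_orth.append(float((np.outer(t_o, p_o) ** 2).sum() / ssx_total))

    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    c = float(y0 @ t / (t @ t))
    r2x_pred = float((np.outer(t, p) ** 2).sum() / ssx_total)
    resid = y0 - c * t
    r2y = float(1 - (resid @ resid) / (y0 @ y0))

    return OplsdaModel(
        t_pred=t,
        p_pred=p,
        w_pred=w,
        t_orth=np.column_stack(t_orths) if t_orths else np.empty((X.shape[0], 0)),
        p_orth=np.column_stack(p_orths) if p_orths else np.empty((X.shape[1], 0)),
        w_orth=np.column_stack(w_orths) if w_orths else np.empty((X.shape[1], 0)),
        r2x=[r2x_pred] + r2x_orth,
        r2y=r2y,
        feature_ids=list(feature_ids) if feature_ids is not None else None,
        sample_ids=list(sample_ids) if sample_ids is not None else None,
        y=y,
    )
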