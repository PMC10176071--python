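"""ssGSEA immune-cell enrichment, immune score, and feature correlations.

Single-sample GSEA scores each sample independently: genes are ranked by
abundance (descending, midranks for ties) and the enrichment score is the
sum over the ranked list of the difference between the weighted in-set rank
ECDF (weights = rank^exponent) and the uniform out-of-set ECDF.  The immune
score is the same statistic on an immune-signature set — a rank-based
stand-in for the ESTIMATE immune score whose affine rescaling is irrelevant
to the between-group comparison.  Correlations between glycopeptide levels
and cell scores / enzyme abundances are Spearman with pairwise-complete
observations, exact permutation p-values at small n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glycomodel import QuantMatrix
from . import stats as gstats

__all__ = [
    "GeneSet",
    "ssgsea",
    "immune_score",
    "correlate_features",
    "gene_sets_from_gmt",
]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set; symbols are upper-cased and de-duplicated."""

    name: str
    genes: frozenset[str]
    source: str = ""

    @staticmethod
    def from_list(name: str, genes, source: str = "") -> "GeneSet":
        cleaned = frozenset(str(g).strip().upper() for g in genes if str(g).strip())
        if not cleaned:
            raise ValueError(f"gene set {name!r} is empty")
        return GeneSet(name, cleaned, source)


def gene_sets_from_gmt(gmt: dict) -> list[GeneSet]:
    return [
        GeneSet.from_list(name, body["genes"], body.get("description", ""))
        for name, body in gmt.items()
    ]


def _sample_es(values: np.ndarray, in_set: np.ndarray, exponent: float) -> float:
    """Enrichment score for one sample (no missing values at this point)."""
    n = len(values)
    ranks = sps.rankdata(values)  # midranks; highest abundance -> rank n
    order = np.argsort(-values, kind="stable")
    in_sorted = in_set[order]
    w = ranks[order] ** exponent * in_sorted
    denom_in = w.sum()
    n_out = n - int(in_set.sum())
    p_in = np.cumsum(w) / denom_in
    p_out = np.cumsum(~in_sorted) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea(
    expression: QuantMatrix,
    sets: list[GeneSet],
    exponent: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Per-sample enrichment scores (sets x samples).

    Missing values rank lowest within their sample (an undetected protein
    is treated as least abundant).  ``normalize=True`` min-max rescales
    each set's scores across samples (off by default; row-wise Z scores for
    display are a separate presentation step).
    """
    genes = pd.Index([g.upper() for g in expression.values.index])
    if genes.has_duplicates:
        raise ValueError("duplicate gene ids in expression matrix")
    if len(genes) < 2:
        raise ValueError("need >= 2 genes")
    masks = {}
    for gs in sets:
        mask = genes.isin(gs.genes)
        if not mask.any():
            raise ValueError(f"gene set {gs.name!r} has no genes in the matrix")
        if mask.all():
            raise ValueError(f"gene set {gs.name!r} covers every gene")
        masks[gs.name] = mask

    vals = expression.values.to_numpy(dtype=float)
    es = pd.DataFrame(
        index=[gs.name for gs in sets], columns=expression.sample_ids, dtype=float
    )
    for j, sample in enumerate(expression.sample_ids):
        col = vals[:, j]
        filled = np.where(np.isfinite(col), col, -np.inf)
        if np.all(filled == filled[0]):
            warnings.warn(f"constant expression in sample {sample}")
        for name, mask in masks.items():
            es.loc[name, sample] = _sample_es(filled, mask, exponent)
    if normalize:
        rng = es.max(axis=1) - es.min(axis=1)
        rng = rng.replace(0, 1.0)
        es = es.sub(es.min(axis=1), axis=0).div(rng, axis=0)
    return es


def immune_score(
    expression: QuantMatrix,
    signature: GeneSet,
    case_group: str | None = None,
) -> dict:
    """Per-sample immune score with a Wilcoxon rank-sum group comparison."""
    scores = ssgsea(expression, [signature]).iloc[0]
    groups = expression.group_names
    case = case_group if case_group is not None else groups[0]
    control = [g for g in groups if g != case][0]
    a = scores[expression.samples_in(case)].to_numpy(dtype=float)
    b = scores[expression.samples_in(control)].to_numpy(dtype=float)
    test = gstats.wilcoxon_rank_sum(a, b)
    return {
        "scores": scores,
        "case_group": case,
        "control_group": control,
        "case_mean": float(a.mean()),
        "control_mean": float(b.mean()),
        "u": test.u,
        "p_value": test.p,
        "exact": test.exact,
    }


def correlate_features(
    x: pd.DataFrame,
    y: pd.DataFrame,
    alpha: float = 0.05,
    bh_correct: bool = False,
    min_n: int = 3,
) -> pd.DataFrame:
    """Spearman correlation of every x row against every y row.

    Rows are features, columns are shared samples; missing values are
    handled pairwise-complete.  Pairs with fewer than ``min_n`` complete
    observations are reported with NaN rho and a reason.  Significance is
    raw p < alpha (the study applies no multiplicity correction);
    ``bh_correct`` adds a Benjamini-Hochberg q column.
    """
    samples = [s for s in x.columns if s in y.columns]
    if len(samples) < min_n:
        raise ValueError("fewer than min_n shared samples")
    rows = []
    for xid, xvals in x[samples].iterrows():
        xv = xvals.to_numpy(dtype=float)
        for yid, yvals in y[samples].iterrows():
            yv = yvals.to_numpy(dtype=float)
            ok = np.isfinite(xv) & np.isfinite(yv)
            n = int(ok.sum())
            if n < min_n:
                rows.append({"x_id": xid, "y_id": yid, "rho": np.nan,
                             "p_value": np.nan, "n": n, "significant": False,
                             "reason": f"<{min_n} complete pairs"})
                continue
            try:
                res = gstats.spearman(xv[ok], yv[ok])
            except ValueError as exc:
                rows.append({"x_id": xid, "y_id": yid, "rho": np.nan,
                             "p_value": np.nan, "n": n, "significant": False,
                             "reason": str(exc)})
                continue
            rows.append({"x_id": xid, "y_id": yid, "rho": res.r,
                         "p_value": res.p, "n": n,
                         "significant": bool(res.p < alpha), "reason": ""})
    df = pd.DataFrame(rows)
    if bh_correct and df["p_value"].notna().any():
        from .glycoquant import _benjamini_hochberg

        df["q_value"] = _benjamini_hochberg(df["p_value"])
    return df
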