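"""Glycan classification, microheterogeneity, differential and specificity
calling, and target-decoy FDR utilities.

The glycan classifier buckets a linkage-free composition into the six
classes commonly used for N-glycans (paucimannose, high mannose,
complex/hybrid, sialylated, fucosylated, fucosylated+sialylated).
Differential calling follows the study design: fold change as the ratio of
group medians (RA-like / OA-like) on protein-normalized intensities,
two-sided Student's t on log2 values, thresholds 1.5 / 0.67 at alpha 0.05,
with per-feature post hoc power.  Group-specific glycopeptides are those
detected in >= 75% of one group's samples and in none of the other's.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .glycomodel import (
    GlycanComposition,
    GlycoPeptideRecord,
    QuantMatrix,
)
from . import stats as gstats

__all__ = [
    "GLYCAN_CLASSES",
    "classify_glycan",
    "glycan_class_flags",
    "microheterogeneity",
    "class_cooccurrence",
    "normalize_to_protein",
    "differential",
    "call_specific",
    "gpsm_fdr",
    "threshold_for_fdr",
]

GLYCAN_CLASSES = [
    "paucimannose",
    "high_mannose",
    "complex_hybrid",
    "sialylated",
    "fucosylated",
    "fucosylated_sialylated",
]


def classify_glycan(composition: GlycanComposition) -> str:
    """Assign exactly one of the six glycan classes to a composition.

    Decision table, first rule wins; decoration checks run before core
    checks so decorated high-mannose cores land in the fucosylated /
    sialylated classes:

    1. fuc >= 1 and neuac >= 1  -> fucosylated_sialylated
    2. neuac >= 1               -> sialylated
    3. fuc >= 1                 -> fucosylated
    4. hexnac <= 2 and hex <= 3 -> paucimannose
    5. hexnac == 2 and hex >= 4 -> high_mannose
    6. otherwise                -> complex_hybrid
    """
    if composition.total == 0:  # unreachable for a valid GlycanComposition
        raise ValueError("empty composition")
    if composition.fuc >= 1 and composition.neuac >= 1:
        return "fucosylated_sialylated"
    if composition.neuac >= 1:
        return "sialylated"
    if composition.fuc >= 1:
        return "fucosylated"
    if composition.hexnac <= 2 and composition.hex <= 3:
        return "paucimannose"
    if composition.hexnac == 2 and composition.hex >= 4:
        return "high_mannose"
    return "complex_hybrid"


def glycan_class_flags(composition: GlycanComposition) -> dict[str, bool]:
    """Overlapping per-class flags (a decorated glycan also flags its core).

    Complements the exclusive decision table for summaries where one glycan
    may count toward several classes.
    """
    flags = {c: False for c in GLYCAN_CLASSES}
    flags[classify_glycan(composition)] = True
    if composition.fuc >= 1:
        flags["fucosylated"] = True
    if composition.neuac >= 1:
        flags["sialylated"] = True
    if composition.hexnac == 2 and composition.hex >= 4:
        flags["high_mannose"] = True
    return flags


def microheterogeneity(records: Sequence[GlycoPeptideRecord]) -> dict:
    """Site/glycan multiplicity summaries over unique proteins and sites.

    Returns the sites-per-protein histogram (fraction of glycoproteins),
    the glycans-per-site histogram (fraction of glycosites), and per-class
    site shares where a site counts toward every class it carries.
    """
    if not records:
        raise ValueError("no records")
    sites_by_protein: dict[str, set[int]] = {}
    glycans_by_site: dict[str, set[str]] = {}
    classes_by_site: dict[str, set[str]] = {}
    for rec in records:
        sites_by_protein.setdefault(rec.protein_id, set()).add(rec.site)
        key = rec.site_id
        glycans_by_site.setdefault(key, set()).add(str(rec.composition))
        classes_by_site.setdefault(key, set()).add(classify_glycan(rec.composition))

    sites_per_protein = (
        pd.Series({p: len(s) for p, s in sites_by_protein.items()})
        .value_counts(normalize=True)
        .sort_index()
    )
    glycans_per_site = (
        pd.Series({s: len(g) for s, g in glycans_by_site.items()})
        .value_counts(normalize=True)
        .sort_index()
    )
    n_sites = len(classes_by_site)
    class_share = pd.Series(
        {
            c: sum(c in cs for cs in classes_by_site.values()) / n_sites
            for c in GLYCAN_CLASSES
        }
    )
    return {
        "sites_per_protein": sites_per_protein,
        "glycans_per_site": glycans_per_site,
        "class_share_per_site": class_share,
        "n_proteins": len(sites_by_protein),
        "n_sites": n_sites,
    }


def class_cooccurrence(records: Sequence[GlycoPeptideRecord]) -> dict:
    """Count glycosites where pairs of glycan classes co-occur.

    Returns counts for each of the 15 unordered pairs of distinct classes
    plus singleton counts (sites carrying exactly one class).
    """
    classes_by_site: dict[str, set[str]] = {}
    for rec in records:
        classes_by_site.setdefault(rec.site_id, set()).add(
            classify_glycan(rec.composition)
        )
    pair_counts = {
        frozenset(p): 0 for p in combinations(GLYCAN_CLASSES, 2)
    }
    singleton = {c: 0 for c in GLYCAN_CLASSES}
    for cs in classes_by_site.values():
        if len(cs) == 1:
            singleton[next(iter(cs))] += 1
        for p in combinations(sorted(cs), 2):
            pair_counts[frozenset(p)] += 1
    pairs = pd.Series(
        {" & ".join(sorted(k)): v for k, v in pair_counts.items()}
    ).sort_index()
    return {"pairs": pairs, "singletons": pd.Series(singleton)}


def normalize_to_protein(
    records: Sequence[GlycoPeptideRecord],
    proteins: QuantMatrix,
) -> list[GlycoPeptideRecord]:
    """Divide each glycopeptide intensity by its protein's intensity.

    The protein matrix should be column-normalized first.  The result is
    missing wherever either factor is missing (or the protein intensity is
    zero, with a warning).  Glycopeptides whose protein is absent from the
    proteomics table keep their raw intensities and are flagged
    ``normalized_to_protein=False`` so they can be analyzed separately.
    """
    out = []
    zero_hits = 0
    for rec in records:
        if rec.protein_id in proteins.values.index:
            prot = proteins.values.loc[rec.protein_id].reindex(rec.intensities.index)
            zeros = prot == 0
            if zeros.any():
                zero_hits += int(zeros.sum())
                prot = prot.mask(zeros)
            norm = rec.intensities / prot
            out.append(
                GlycoPeptideRecord(
                    rec.protein_id, rec.peptide, rec.site, rec.composition,
                    rec.intensities, normalized=norm, normalized_to_protein=True,
                )
            )
        else:
            out.append(
                GlycoPeptideRecord(
                    rec.protein_id, rec.peptide, rec.site, rec.composition,
                    rec.intensities, normalized=rec.intensities.copy(),
                    normalized_to_protein=False,
                )
            )
    if zero_hits:
        warnings.warn(f"{zero_hits} zero protein intensities -> missing ratios")
    return out


@dataclass
class DifferentialResult:
    feature_id: str
    fold_change: float
    log2fc: float
    p_value: float
    power: float
    category: str  # up | down | unchanged | insufficient
    n_case: int
    n_control: int
    degenerate: bool = False


def differential(
    matrix: QuantMatrix,
    case_group: str | None = None,
    fc_high: float = 1.5,
    fc_low: float = 0.67,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Per-feature differential abundance between the two groups.

    Fold change is the ratio of group medians (case / control) on the raw
    (already protein-normalized) scale; the p-value is a two-sided
    equal-variance Student's t on log2 values; post hoc power uses the
    observed pooled-SD Cohen's d at the given alpha.  Features with fewer
    than two detected values in either group are reported as
    ``insufficient``.  ``bh_correct`` optionally adds a Benjamini-Hochberg
    q-value column (categories still use the raw p, as in the study).
    """
    groups = matrix.group_names
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    case = case_group if case_group is not None else groups[0]
    control = [g for g in groups if g != case][0]
    case_cols = matrix.samples_in(case)
    ctrl_cols = matrix.samples_in(control)

    rows = []
    for fid in matrix.feature_ids:
        a = matrix.values.loc[fid, case_cols].dropna().to_numpy(dtype=float)
        b = matrix.values.loc[fid, ctrl_cols].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            rows.append(
                DifferentialResult(fid, math.nan, math.nan, math.nan, math.nan,
                                   "insufficient", len(a), len(b))
            )
            continue
        med_a, med_b = float(np.median(a)), float(np.median(b))
        if med_b == 0:
            fc = math.inf if med_a > 0 else math.nan
        else:
            fc = med_a / med_b
        # zeros are below quantification: excluded from the log-scale t test
        la, lb = np.log2(a[a > 0]), np.log2(b[b > 0])
        if len(la) < 2 or len(lb) < 2:
            rows.append(
                DifferentialResult(fid, fc, math.nan, math.nan, math.nan,
                                   "insufficient", len(a), len(b),
                                   degenerate=True)
            )
            continue
        res = gstats.t_test_two_sample(la, lb)
        d = gstats.cohens_d(la, lb)
        power = (
            1.0 if not math.isfinite(d)
            else gstats.power_t_test(
                gstats.PowerSpec(abs(d), len(a), len(b), alpha)
            )
        )
        if math.isnan(fc):
            cat = "insufficient"
        elif fc > fc_high and res.p < alpha:
            cat = "up"
        elif fc < fc_low and res.p < alpha:
            cat = "down"
        else:
            cat = "unchanged"
        rows.append(
            DifferentialResult(
                fid, fc, math.log2(fc) if fc > 0 else math.nan, res.p,
                power, cat, len(a), len(b), degenerate=res.degenerate or not math.isfinite(fc),
            )
        )
    df = pd.DataFrame([vars(r) for r in rows]).set_index("feature_id")
    if bh_correct:
        df["q_value"] = _benjamini_hochberg(df["p_value"])
    return df


def _benjamini_hochberg(p: pd.Series) -> pd.Series:
    mask = p.notna()
    q = pd.Series(np.nan, index=p.index)
    pv = p[mask].to_numpy(dtype=float)
    m = len(pv)
    order = np.argsort(pv)
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[mask] = out
    return q


def call_specific(
    matrix: QuantMatrix,
    case_group: str | None = None,
    min_frac: float = 0.75,
) -> dict:
    """Group-specific features by the detection rule.

    A feature is specific to group G iff it is detected in at least
    ``ceil(min_frac * n_G)`` of G's samples and in zero samples of the
    other group.  The subset detected in *all* of G's samples is reported
    separately.
    """
    groups = matrix.group_names
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    case = case_group if case_group is not None else groups[0]
    control = [g for g in groups if g != case][0]
    mask = matrix.detection_mask()
    n_case_det = mask[matrix.samples_in(case)].sum(axis=1)
    n_ctrl_det = mask[matrix.samples_in(control)].sum(axis=1)
    n_case = len(matrix.samples_in(case))
    n_ctrl = len(matrix.samples_in(control))
    need_case = math.ceil(min_frac * n_case)
    need_ctrl = math.ceil(min_frac * n_ctrl)

    case_specific = matrix.values.index[(n_case_det >= need_case) & (n_ctrl_det == 0)]
    ctrl_specific = matrix.values.index[(n_ctrl_det >= need_ctrl) & (n_case_det == 0)]
    return {
        "case_group": case,
        "control_group": control,
        "case_specific": list(case_specific),
        "control_specific": list(ctrl_specific),
        "case_specific_all_samples": list(
            matrix.values.index[(n_case_det == n_case) & (n_ctrl_det == 0)]
        ),
        "control_specific_all_samples": list(
            matrix.values.index[(n_ctrl_det == n_ctrl) & (n_case_det == 0)]
        ),
    }


# ---------------------------------------------------------------------------
# Target-decoy FDR
# ---------------------------------------------------------------------------

def gpsm_fdr(n_forward: int, n_decoy: int) -> float:
    """Spectrum-level target-decoy FDR as a percentage: 2*n_decoy*100/n_forward.

    The factor 2 reflects the assumption that false forward matches arrive
    at the same rate as decoy matches, and that a decoy hit flags one of an
    estimated pair of errors.
    """
    if n_forward < 1:
        raise ValueError("n_forward must be >= 1 for a defined FDR")
    if n_decoy < 0:
        raise ValueError("n_decoy must be >= 0")
    return 2.0 * n_decoy * 100.0 / n_forward


def threshold_for_fdr(
    scores_forward: Iterable[float],
    scores_decoy: Iterable[float],
    target: float = 1.0,
) -> dict:
    """Find the score cutoff keeping the most forward GPSMs at FDR <= target (%).

    Scores are 'higher is better'; candidate cutoffs are scanned over all
    observed scores, counting matches at or above each cutoff.  Returns the
    chosen threshold with its forward/decoy counts and achieved FDR, or
    ``threshold=None`` if no cutoff meets the target.
    """
    fwd = np.sort(np.asarray(list(scores_forward), dtype=float))
    dec = np.sort(np.asarray(list(scores_decoy), dtype=float))
    if len(fwd) == 0:
        raise ValueError("no forward scores")
    best = None
    for cut in np.unique(np.concatenate([fwd, dec])):
        nf = int(len(fwd) - np.searchsorted(fwd, cut, side="left"))
        nd = int(len(dec) - np.searchsorted(dec, cut, side="left"))
        if nf == 0:
            continue
        fdr = gpsm_fdr(nf, nd)
        if fdr <= target and (best is None or nf > best["n_forward"]):
            best = {"threshold": float(cut), "n_forward": nf, "n_decoy": nd,
                    "fdr_percent": fdr}
    if best is None:
        return {"threshold": None, "n_forward": 0, "n_decoy": 0,
                "fdr_percent": math.nan}
    return best
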