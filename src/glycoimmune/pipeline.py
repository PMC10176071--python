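"""End-to-end orchestration of the downstream glycoproteomics analysis.

Stage order: protein column normalization -> protein differential ->
glycopeptide protein-normalization -> glycan classification /
microheterogeneity / co-occurrence -> glycopeptide differential +
group-specificity -> antigenicity profiling and screening of the
differential/specific candidates -> ssGSEA cell enrichment + immune score
-> glycopeptide x cell-score and glycopeptide x enzyme correlations ->
OPLS-DA score tables -> candidate funnel report.

Identical inputs and parameters produce identical outputs; every written
table carries a provenance header (config hash, seed, version) whose only
run-dependent line is the timestamp.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .glycomodel import (
    GlycoPeptideRecord,
    QuantMatrix,
    normalize_columns,
    read_fasta,
    read_glycopeptide_table,
    read_gmt,
    records_to_matrix,
)
from . import glycoquant as gq
from . import antigenicity as ag
from . import immunoscore as im
from . import stats as gstats

__all__ = ["PipelineParams", "PipelineConfig", "PipelineError", "PipelineResult",
           "run_pipeline", "run_on_tables", "make_report", "write_outputs"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineParams:
    """Analysis thresholds and toggles (defaults follow the study design)."""

    fc_high: float = 1.5
    fc_low: float = 0.67
    alpha: float = 0.05
    min_frac: float = 0.75
    flank: int = 15
    kd_threshold: float = 1.0
    emini_threshold: float = 1.0
    ai_threshold: float = 1.0
    ssgsea_exponent: float = 0.25
    ssgsea_normalize: bool = False
    bh_correct: bool = False
    case_group: str | None = None
    immune_signature_set: str = "immune_signature"
    n_orth: int = 1

    def validate(self) -> None:
        if not (0 < self.fc_low < 1 < self.fc_high):
            raise ValueError("need fc_low < 1 < fc_high with both positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("min_frac", "kd_threshold", "emini_threshold",
                     "ai_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineConfig:
    """File-based pipeline configuration (see also ``run_on_tables``)."""

    glyco_table: str
    protein_table: str
    fasta: str
    gene_sets: str
    groups: str
    enzymes: str | None = None
    out_dir: str = "glycoimmune_out"
    seed: int = 0
    params: PipelineParams = field(default_factory=PipelineParams)

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        params = PipelineParams(**raw.pop("params", {}))
        return PipelineConfig(params=params, **raw)


@dataclass
class PipelineResult:
    tables: dict[str, pd.DataFrame]
    oplsda: dict[str, gstats.OplsdaModel]
    counts: dict[str, int]
    provenance: dict[str, str]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _provenance_hash(params: PipelineParams, records, proteins, seed: int) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(asdict(params), sort_keys=True).encode())
    h.update(str(seed).encode())
    for rec in records:
        h.update(rec.feature_id.encode())
    h.update(",".join(proteins.sample_ids).encode())
    return h.hexdigest()[:16]


def run_on_tables(
    records: Sequence[GlycoPeptideRecord],
    proteins: QuantMatrix,
    sequences: Mapping[str, str],
    gene_sets: Mapping[str, Mapping],
    enzyme_ids: Sequence[str] | None = None,
    params: PipelineParams | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run the full downstream analysis on in-memory inputs."""
    params = params or PipelineParams()
    params.validate()
    groups = proteins.groups
    group_names = proteins.group_names
    case = params.case_group or group_names[0]

    prot_norm = _stage("protein column normalization")(normalize_columns)(proteins)
    prot_diff = _stage("protein differential")(gq.differential)(
        prot_norm, case_group=case, fc_high=params.fc_high,
        fc_low=params.fc_low, alpha=params.alpha, bh_correct=params.bh_correct,
    )

    # Ratios use matched RAW intensities: within a TMT channel the sample
    # loading factor cancels in glyco/protein exactly, whereas dividing by
    # the column-normalized protein matrix would re-introduce a per-sample
    # factor whenever the two layers differ compositionally.
    records_n = _stage("protein normalization of glycopeptides")(
        gq.normalize_to_protein
    )(list(records), proteins)

    @_stage("glycan classification")
    def _classes() -> pd.DataFrame:
        return pd.DataFrame(
            [{"feature_id": r.feature_id, "protein_id": r.protein_id,
              "site": r.site, "composition": str(r.composition),
              "glycan_class": gq.classify_glycan(r.composition),
              "normalized_to_protein": r.normalized_to_protein}
             for r in records_n]
        ).set_index("feature_id")

    class_table = _classes()
    micro = _stage("microheterogeneity")(gq.microheterogeneity)(records_n)
    cooc = _stage("class co-occurrence")(gq.class_cooccurrence)(records_n)

    normalized_recs = [r for r in records_n if r.normalized_to_protein]
    orphan_recs = [r for r in records_n if not r.normalized_to_protein]

    glyco_norm_mat = records_to_matrix(normalized_recs, groups, use_normalized=True)
    glyco_raw_mat = records_to_matrix(records_n, groups, use_normalized=False)

    glyco_diff = _stage("glycopeptide differential")(gq.differential)(
        glyco_norm_mat, case_group=case, fc_high=params.fc_high,
        fc_low=params.fc_low, alpha=params.alpha, bh_correct=params.bh_correct,
    )
    orphan_diff = (
        _stage("orphan glycopeptide differential")(gq.differential)(
            records_to_matrix(orphan_recs, groups), case_group=case,
            fc_high=params.fc_high, fc_low=params.fc_low, alpha=params.alpha,
        )
        if orphan_recs else pd.DataFrame()
    )
    specific = _stage("group specificity")(gq.call_specific)(
        glyco_raw_mat, case_group=case, min_frac=params.min_frac
    )

    diff_ids = set(glyco_diff.index[glyco_diff["category"].isin(["up", "down"])])
    spec_ids = set(specific["case_specific"]) | set(specific["control_specific"])
    candidate_ids = diff_ids | spec_ids

    @_stage("antigenicity screen")
    def _screen() -> tuple[pd.DataFrame, dict]:
        cand_records = [r for r in records_n if r.feature_id in candidate_ids]
        profiles = ag.profile_glycosites(cand_records, sequences,
                                         flank=params.flank)
        rows = []
        for sid, prof in profiles.items():
            verdict = ag.screen_peptide(
                prof, kd_threshold=params.kd_threshold,
                emini_threshold=params.emini_threshold,
                ai_threshold=params.ai_threshold,
            )
            for fid in prof.linked_features:
                rows.append({
                    "feature_id": fid, "site_id": sid, "window": prof.window,
                    "truncated": prof.truncated, "passes": verdict.passes,
                    **{f"criterion_{k}": v for k, v in verdict.flags.items()},
                    **prof.peptide_summary,
                })
        df = (pd.DataFrame(rows).set_index("feature_id")
              if rows else pd.DataFrame())
        return df, profiles

    screen_table, profiles = _screen()
    screened_ids = (
        set(screen_table.index[screen_table["passes"]])
        if len(screen_table) else set()
    )

    @_stage("ssGSEA / immune score")
    def _immune():
        sets = [im.GeneSet.from_list(n, b["genes"], str(b.get("description", "")))
                for n, b in gene_sets.items()
                if n != params.immune_signature_set]
        es = im.ssgsea(prot_norm, sets, exponent=params.ssgsea_exponent,
                       normalize=params.ssgsea_normalize)
        sig_body = gene_sets.get(params.immune_signature_set)
        score = (
            im.immune_score(
                prot_norm,
                im.GeneSet.from_list(params.immune_signature_set,
                                     sig_body["genes"]),
                case_group=case,
            )
            if sig_body else None
        )
        return es, score

    es, score = _immune()

    @_stage("correlation analysis")
    def _correlate():
        # normalized levels where the protein was quantified, raw otherwise
        cand = sorted((r for r in records_n if r.feature_id in screened_ids),
                      key=lambda r: r.feature_id)
        x = (records_to_matrix(cand, groups, use_normalized=True).values
             if cand else pd.DataFrame())
        if not len(x):
            empty = pd.DataFrame(columns=["x_id", "y_id", "rho", "p_value",
                                          "n", "significant", "reason"])
            return empty, empty.copy()
        cells = im.correlate_features(x, es, alpha=params.alpha,
                                      bh_correct=params.bh_correct)
        if enzyme_ids:
            enz = prot_norm.values.loc[
                [e for e in enzyme_ids if e in prot_norm.values.index]]
            enzymes = im.correlate_features(x, enz, alpha=params.alpha,
                                            bh_correct=params.bh_correct)
        else:
            enzymes = pd.DataFrame(columns=cells.columns)
        return cells, enzymes

    corr_cells, corr_enzymes = _correlate()
    correlated_ids = (
        set(corr_cells.loc[corr_cells["significant"].fillna(False), "x_id"])
        if len(corr_cells) else set()
    )

    @_stage("OPLS-DA")
    def _oplsda() -> dict[str, gstats.OplsdaModel]:
        y = np.where(np.array([groups[s] for s in prot_norm.sample_ids]) == case,
                     1.0, -1.0)
        out = {}
        for name, mat in [("proteins", prot_norm), ("glycopeptides", glyco_norm_mat)]:
            complete = mat.values.dropna(axis=0)
            complete = complete[(complete > 0).all(axis=1)]
            if len(complete) < 3:
                continue
            out[name] = gstats.oplsda_fit(
                np.log2(complete.to_numpy(dtype=float)).T, y,
                n_orth=params.n_orth, feature_ids=list(complete.index),
                sample_ids=list(complete.columns),
            )
        return out

    oplsda_models = _oplsda()
    oplsda_tables = {
        f"oplsda_{name}_scores": pd.DataFrame(
            {"sample_id": m.sample_ids, "group": [groups[s] for s in m.sample_ids],
             "t_pred": m.t_pred,
             **{f"t_orth{k + 1}": m.t_orth[:, k]
                for k in range(m.t_orth.shape[1])}}
        ).set_index("sample_id")
        for name, m in oplsda_models.items()
    }

    immune_associated = sorted(screened_ids & correlated_ids)

    counts = {
        "n_glycopeptides": len(records_n),
        "n_glycoproteins": len({r.protein_id for r in records_n}),
        "n_glycosites": len({r.site_id for r in records_n}),
        "n_protein_differential": int(
            prot_diff["category"].isin(["up", "down"]).sum()),
        "n_differential": len(diff_ids),
        "n_up": int((glyco_diff["category"] == "up").sum()),
        "n_down": int((glyco_diff["category"] == "down").sum()),
        "n_case_specific": len(specific["case_specific"]),
        "n_control_specific": len(specific["control_specific"]),
        "n_candidates": len(candidate_ids),
        "n_screen_passing": len(screened_ids),
        "n_significant_cell_correlations": int(
            corr_cells["significant"].fillna(False).sum()) if len(corr_cells) else 0,
        "n_significant_enzyme_correlations": int(
            corr_enzymes["significant"].fillna(False).sum()) if len(corr_enzymes) else 0,
        "n_immune_associated": len(immune_associated),
    }

    spec_table = pd.DataFrame(
        [{"feature_id": fid, "category": "case_specific",
          "in_all_samples": fid in specific["case_specific_all_samples"]}
         for fid in specific["case_specific"]]
        + [{"feature_id": fid, "category": "control_specific",
            "in_all_samples": fid in specific["control_specific_all_samples"]}
           for fid in specific["control_specific"]]
    )
    if len(spec_table):
        spec_table = spec_table.set_index("feature_id")

    micro_table = pd.concat([
        micro["sites_per_protein"].rename("fraction").rename_axis("value")
        .reset_index().assign(statistic="sites_per_protein"),
        micro["glycans_per_site"].rename("fraction").rename_axis("value")
        .reset_index().assign(statistic="glycans_per_site"),
        micro["class_share_per_site"].rename("fraction").rename_axis("value")
        .reset_index().assign(statistic="class_share_per_site"),
    ]).set_index("statistic")

    cooc_table = pd.concat([
        cooc["pairs"].rename("n_sites").rename_axis("classes").reset_index()
        .assign(kind="pair"),
        cooc["singletons"].rename("n_sites").rename_axis("classes").reset_index()
        .assign(kind="singleton"),
    ]).set_index("classes")

    immune_table = pd.DataFrame({"feature_id": immune_associated}).set_index(
        "feature_id") if immune_associated else pd.DataFrame()

    score_table = (
        pd.DataFrame({"sample_id": score["scores"].index,
                      "group": [groups[s] for s in score["scores"].index],
                      "immune_score": score["scores"].values}).set_index("sample_id")
        if score else pd.DataFrame()
    )

    tables = {
        "protein_differential": prot_diff,
        "glyco_differential": glyco_diff,
        "glyco_differential_unnormalized": orphan_diff,
        "glyco_specific": spec_table,
        "glycan_classes": class_table,
        "microheterogeneity": micro_table,
        "class_cooccurrence": cooc_table,
        "antigenicity_screen": screen_table,
        "enrichment_scores": es,
        "immune_score": score_table,
        "correlations_cells": corr_cells,
        "correlations_enzymes": corr_enzymes,
        "immune_associated": immune_table,
        **oplsda_tables,
    }
    provenance = {
        "version": __version__,
        "seed": str(seed),
        "config_hash": _provenance_hash(params, records_n, prot_norm, seed),
    }
    if score:
        counts["immune_score_p"] = score["p_value"]
    return PipelineResult(tables=tables, oplsda=oplsda_models, counts=counts,
                          provenance=provenance)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run from a file-based configuration and write the output tables."""
    config.params.validate()
    records = read_glycopeptide_table(config.glyco_table)
    prot = pd.read_csv(config.protein_table, sep="\t", comment="#",
                       index_col="protein_id")
    groups_df = pd.read_csv(config.groups, sep="\t", comment="#")
    groups = pd.Series(groups_df["group"].values, index=groups_df["sample_id"])
    proteins = QuantMatrix(prot, groups)
    sequences = read_fasta(config.fasta)
    gene_sets = read_gmt(config.gene_sets)
    enzyme_ids = (
        Path(config.enzymes).read_text().split() if config.enzymes else None
    )
    result = run_on_tables(records, proteins, sequences, gene_sets,
                           enzyme_ids=enzyme_ids, params=config.params,
                           seed=config.seed)
    write_outputs(result, config.out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    """Write every result table as TSV with a provenance header."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = "".join(
        [f"# glycoimmune {result.provenance['version']}\n",
         f"# config_hash={result.provenance['config_hash']}\n",
         f"# seed={result.provenance['seed']}\n",
         f"# generated={datetime.now(timezone.utc).isoformat()}\n"]
    )
    paths = {}
    for name, table in result.tables.items():
        path = out_dir / f"{name}.tsv"
        with open(path, "w") as fh:
            fh.write(header)
            table.to_csv(fh, sep="\t", float_format="%.6g")
        paths[name] = path
    report_path = out_dir / "report.txt"
    report_path.write_text(make_report(result))
    paths["report"] = report_path
    return paths


def make_report(result: PipelineResult) -> str:
    """Plain-text candidate-funnel summary of one pipeline run."""
    c = result.counts
    lines = [
        "glycoimmune pipeline report",
        "===========================",
        f"glycopeptides quantified:        {c['n_glycopeptides']}"
        f" ({c['n_glycosites']} sites on {c['n_glycoproteins']} proteins)",
        f"differential proteins:           {c['n_protein_differential']}",
        f"differential glycopeptides:      {c['n_differential']}"
        f" (up {c['n_up']}, down {c['n_down']})",
        f"group-specific glycopeptides:    "
        f"{c['n_case_specific'] + c['n_control_specific']}"
        f" (case {c['n_case_specific']}, control {c['n_control_specific']})",
        f"candidates (differential+spec.): {c['n_candidates']}",
        f"antigenicity screen passing:     {c['n_screen_passing']}",
        f"significant cell correlations:   {c['n_significant_cell_correlations']}",
        f"significant enzyme correlations: {c['n_significant_enzyme_correlations']}",
        f"immune-associated glycopeptides: {c['n_immune_associated']}",
    ]
    if "immune_score_p" in c:
        lines.append(f"immune score group test p:       {c['immune_score_p']:.4g}")
    for name, model in result.oplsda.items():
        lines.append(f"OPLS-DA [{name}]: " + "; ".join(model.summary().splitlines()))
    return "\n".join(lines) + "\n"
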