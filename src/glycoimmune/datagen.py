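"""Synthetic TMT-style glycoproteomics dataset generator with ground truth.

Emulates the structure of a two-group (RA-like vs OA-like), four-samples-
per-group intact N-glycoproteomics experiment: protein sequences with valid
N-X-S|T|C sequons at every simulated glycosite, glycan compositions drawn
from the six-class mixture, log-normal reporter intensities
(log2 intensity = base + group effect + N(0, noise_sd)), completely-at-
random missingness except for planted group-specific features (structurally
absent in the other group), immune-signature and enzyme genes shifted in
the RA-like group, and planted fold changes that survive protein
normalization.  Every planted effect is recorded in a ``GroundTruth`` table
so recovery by the downstream callers can be scored exactly.

One quirk is deliberate: if a *non*-planted feature's random detection mask
happens to satisfy the group-specificity rule, a single detection is added
in the opposite group.  This keeps the ground-truth labels exhaustive — the
specificity caller can be scored with zero tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .glycomodel import (
    AMINO_ACIDS,
    GlycanComposition,
    GlycoPeptideRecord,
    QuantMatrix,
    read_fasta,
    read_glycopeptide_table,
    read_gmt,
    write_fasta,
    write_glycopeptide_table,
    write_gmt,
)
from .glycoquant import GLYCAN_CLASSES, classify_glycan

__all__ = ["SimConfig", "GroundTruth", "Bundle", "ConfigError",
           "simulate_dataset", "write_bundle", "read_bundle", "CELL_TYPES"]

CELL_TYPES = [
    "B_cells", "CD4_T_cells", "CD8_T_cells", "Dendritic_cells", "Macrophages",
    "Mast_cells", "NK_cells", "Plasma_cells", "CD4_TPH_cells",
]

_NON_P = AMINO_ACIDS.replace("P", "")


class ConfigError(ValueError):
    """Raised on an infeasible simulation configuration."""


def _check_dist(name: str, dist: Mapping[int, float]) -> None:
    probs = np.array(list(dist.values()), dtype=float)
    if np.any(probs < 0) or np.any(probs > 1):
        raise ConfigError(f"{name}: probabilities must lie in [0, 1]")
    if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise ConfigError(f"{name}: probabilities must sum to 1")


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic dataset.

    Defaults mirror the emulated design at desk scale: 2 groups x 4
    samples, sites-per-protein mix ~74/15/11% for 1/2/3+ sites, a
    glycans-per-site mix with modes at 2 and >=5, glycan classes dominated
    by high-mannose (32%) and fucosylated (36%) glycans, fold-change
    plantings at |log2 FC| = 2 against log-scale noise of 0.25, and an
    immune-signature shift of 1 log2 unit in the RA-like group.
    """

    n_per_group: int = 4
    group_names: tuple[str, str] = ("RA_like", "OA_like")
    n_glycoproteins: int = 40
    n_glycopeptides: int | None = None  # target feature count; None -> dists decide
    sites_per_protein_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.74, 2: 0.15, 3: 0.11}
    )
    glycans_per_site_dist: dict[int, float] = field(
        default_factory=lambda: {1: 0.15, 2: 0.33, 3: 0.10, 4: 0.08, 5: 0.34}
    )
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "paucimannose": 0.05, "high_mannose": 0.32, "complex_hybrid": 0.12,
            "sialylated": 0.08, "fucosylated": 0.36,
            "fucosylated_sialylated": 0.07,
        }
    )
    motif_mix: dict[str, float] = field(
        default_factory=lambda: {"T": 0.665, "S": 0.33, "C": 0.005}
    )
    n_planted_up: int = 25
    n_planted_down: int = 10
    planted_log2fc: float = 2.0
    n_planted_specific: int = 10
    case_specific_fraction: float = 0.8  # share of specifics in the RA-like group
    n_unquantified_proteins: int = 2  # glycoproteins absent from proteomics
    detection_rate: float = 0.95
    noise_sd: float = 0.25
    n_genes: int = 300
    immune_set_sizes: tuple[int, ...] = (20,) * 9
    immune_signature_size: int = 50
    immune_shift: float = 1.0
    n_enzymes: int = 20
    enzyme_shift: float = 0.8
    protein_shift_fraction: float = 0.1
    protein_shift: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if len(self.immune_set_sizes) != len(CELL_TYPES):
            raise ConfigError(
                f"immune_set_sizes must have {len(CELL_TYPES)} entries"
            )
        for name, dist in [
            ("sites_per_protein_dist", self.sites_per_protein_dist),
            ("glycans_per_site_dist", self.glycans_per_site_dist),
            ("class_mix", self.class_mix),
            ("motif_mix", self.motif_mix),
        ]:
            _check_dist(name, dist)
        if set(self.class_mix) != set(GLYCAN_CLASSES):
            raise ConfigError("class_mix must cover exactly the six glycan classes")
        if not 0 <= self.detection_rate <= 1:
            raise ConfigError("detection_rate must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        reserved = sum(self.immune_set_sizes) + self.immune_signature_size + self.n_enzymes
        if self.n_genes < reserved:
            raise ConfigError(
                f"n_genes={self.n_genes} smaller than immune+signature+enzyme "
                f"genes ({reserved})"
            )
        if self.n_unquantified_proteins >= self.n_glycoproteins:
            raise ConfigError("n_unquantified_proteins must be < n_glycoproteins")


@dataclass
class GroundTruth:
    """Planted-effect labels for recovery scoring.

    ``features``: one row per glycopeptide (label in {up, down,
    case_specific, control_specific, null}, planted log2 FC, glycan class,
    whether its protein is in the proteomics table).  ``genes``: one row
    per protein-table row (role and planted group shift).
    """

    features: pd.DataFrame
    genes: pd.DataFrame


@dataclass
class Bundle:
    """Everything the pipeline consumes, plus the generator's ground truth."""

    config: SimConfig
    sequences: dict[str, str]
    records: list[GlycoPeptideRecord]
    proteins: QuantMatrix
    gene_sets: dict[str, dict]
    groups: pd.Series
    enzyme_ids: list[str]
    truth: GroundTruth


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    return list(rng.choice(list(AMINO_ACIDS), size=length))


def _plant_sequon(seq: list[str], site: int, rng: np.random.Generator,
                  motif_mix: Mapping[str, float]) -> None:
    """Write N-X-[S/T/C] (X != P) at 1-based ``site``."""
    third = rng.choice(list(motif_mix), p=list(motif_mix.values()))
    seq[site - 1] = "N"
    x = seq[site]
    seq[site] = x if x != "P" else "A"
    seq[site + 1] = third


def _sample_composition(rng: np.random.Generator, glycan_class: str) -> GlycanComposition:
    """Draw a composition consistent with the requested class."""
    if glycan_class == "paucimannose":
        return GlycanComposition(hexnac=int(rng.integers(1, 3)),
                                 hex=int(rng.integers(1, 4)))
    if glycan_class == "high_mannose":
        return GlycanComposition(hexnac=2, hex=int(rng.integers(4, 10)))
    hexnac = int(rng.integers(3, 7))
    hx = int(rng.integers(3, 8))
    if glycan_class == "complex_hybrid":
        return GlycanComposition(hexnac=hexnac, hex=hx)
    if glycan_class == "sialylated":
        return GlycanComposition(hexnac=hexnac, hex=hx,
                                 neuac=int(rng.integers(1, 4)))
    if glycan_class == "fucosylated":
        core = rng.random() < 0.4
        if core:
            return GlycanComposition(hexnac=2, hex=int(rng.integers(4, 10)),
                                     fuc=int(rng.integers(1, 3)))
        return GlycanComposition(hexnac=hexnac, hex=hx,
                                 fuc=int(rng.integers(1, 3)))
    if glycan_class == "fucosylated_sialylated":
        return GlycanComposition(hexnac=hexnac, hex=hx,
                                 fuc=int(rng.integers(1, 3)),
                                 neuac=int(rng.integers(1, 4)))
    raise ValueError(f"unknown glycan class {glycan_class!r}")


def simulate_dataset(config: SimConfig) -> Bundle:
    """Generate the full input bundle with planted effects.

    Deterministic: the same config (including seed) yields an identical
    bundle, element for element.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    case, control = config.group_names
    samples = [f"{g}_{i + 1}" for g in config.group_names
               for i in range(config.n_per_group)]
    groups = pd.Series(
        [g for g in config.group_names for _ in range(config.n_per_group)],
        index=samples,
    )
    case_cols = [s for s in samples if groups[s] == case]
    ctrl_cols = [s for s in samples if groups[s] == control]

    # --- protein sequences with planted sequons -------------------------
    site_counts = list(config.sites_per_protein_dist)
    site_probs = list(config.sites_per_protein_dist.values())
    glycan_counts = list(config.glycans_per_site_dist)
    glycan_probs = list(config.glycans_per_site_dist.values())
    classes = list(config.class_mix)
    class_probs = list(config.class_mix.values())

    sequences: dict[str, str] = {}
    features: list[dict] = []  # protein, site, composition, class, peptide
    n_prot = 0
    while True:
        n_prot += 1
        acc = f"GP{n_prot:04d}"
        nsites = int(rng.choice(site_counts, p=site_probs))
        length = 60 + 30 * nsites + int(rng.integers(0, 40))
        seq = _random_sequence(rng, length)
        # sites spaced >= 4 apart, >= 3 from either terminus
        positions = sorted(
            rng.choice(np.arange(4, length - 3, 4), size=nsites, replace=False)
        )
        for site in positions:
            _plant_sequon(seq, int(site), rng, config.motif_mix)
        sequences[acc] = "".join(seq)
        for site in positions:
            site = int(site)
            k = int(rng.choice(glycan_counts, p=glycan_probs))
            seen: set[str] = set()
            lo, hi = max(0, site - 8), min(length, site + 7)
            peptide = sequences[acc][lo:hi]
            for _ in range(k):
                for _attempt in range(50):
                    cls = str(rng.choice(classes, p=class_probs))
                    comp = _sample_composition(rng, cls)
                    if str(comp) not in seen:
                        seen.add(str(comp))
                        features.append({
                            "protein_id": acc, "site": site, "peptide": peptide,
                            "composition": comp, "glycan_class": classify_glycan(comp),
                        })
                        break
        done_by_count = (config.n_glycopeptides is not None
                         and len(features) >= config.n_glycopeptides)
        done_by_proteins = (config.n_glycopeptides is None
                            and n_prot >= config.n_glycoproteins)
        if done_by_count or done_by_proteins:
            break
        if config.n_glycopeptides is None and n_prot >= config.n_glycoproteins:
            break
    if config.n_glycopeptides is not None:
        features = features[: config.n_glycopeptides]
        kept = {f["protein_id"] for f in features}
        sequences = {a: s for a, s in sequences.items() if a in kept}
    n_features = len(features)

    n_planted = (config.n_planted_up + config.n_planted_down
                 + config.n_planted_specific)
    if n_planted > n_features:
        raise ConfigError(
            f"{n_planted} planted features requested but only {n_features} simulated"
        )

    # --- protein-table rows: glycoproteins + gene background ------------
    glyco_accs = list(sequences)
    unquantified = set(
        rng.choice(glyco_accs, size=config.n_unquantified_proteins, replace=False)
    ) if config.n_unquantified_proteins else set()

    gene_rows: list[tuple[str, str, float]] = []  # (id, role, case shift)
    gene_sets: dict[str, dict] = {}
    for cell, size in zip(CELL_TYPES, config.immune_set_sizes):
        ids = [f"IMM_{cell[:6].upper()}_{i + 1:03d}" for i in range(size)]
        gene_sets[cell] = {"description": "synthetic immune cell markers",
                          "genes": ids}
        gene_rows += [(g, f"immune:{cell}", config.immune_shift) for g in ids]
    sig_ids = [f"SIG_{i + 1:03d}" for i in range(config.immune_signature_size)]
    gene_sets["immune_signature"] = {
        "description": "synthetic immune signature", "genes": sig_ids}
    gene_rows += [(g, "signature", config.immune_shift) for g in sig_ids]
    enzyme_ids = [f"ENZ_{i + 1:03d}" for i in range(config.n_enzymes)]
    gene_rows += [(g, "enzyme", config.enzyme_shift) for g in enzyme_ids]
    n_bg = config.n_genes - len(gene_rows)
    gene_rows += [(f"BG_{i + 1:04d}", "background", 0.0) for i in range(n_bg)]

    # glycoprotein-level shifts for a random fraction (exercises
    # protein normalization: these cancel out of the normalized ratios)
    n_shifted = int(round(config.protein_shift_fraction * len(glyco_accs)))
    shifted_accs = list(rng.choice(glyco_accs, size=n_shifted, replace=False))
    prot_shift = {
        acc: float(config.protein_shift * rng.choice([-1.0, 1.0]))
        for acc in shifted_accs
    }

    # --- intensities -----------------------------------------------------
    is_case = np.array([groups[s] == case for s in samples])
    base_log2 = {acc: float(rng.normal(20.0, 1.5)) for acc in glyco_accs}

    def _log2_row(base: float, shift: float) -> np.ndarray:
        return (base + shift * is_case
                + rng.normal(0.0, config.noise_sd, size=len(samples)))

    prot_values = {}
    gene_meta = []
    for acc in glyco_accs:
        row = _log2_row(base_log2[acc], prot_shift.get(acc, 0.0))
        gene_meta.append((acc, "glycoprotein", prot_shift.get(acc, 0.0)))
        if acc not in unquantified:
            prot_values[acc] = 2.0 ** row
    for gid, role, shift in gene_rows:
        prot_values[gid] = 2.0 ** _log2_row(float(rng.normal(18.0, 1.5)), shift)
        gene_meta.append((gid, role, shift))
    proteins = QuantMatrix(
        pd.DataFrame(prot_values, index=samples).T, groups.copy()
    )

    # --- planted labels --------------------------------------------------
    eligible = [i for i, f in enumerate(features)
                if f["protein_id"] not in unquantified]
    if n_planted > len(eligible):
        raise ConfigError("not enough quantified-protein features to plant effects")
    chosen = rng.choice(eligible, size=n_planted, replace=False)
    labels = np.array(["null"] * n_features, dtype=object)
    up_idx = chosen[: config.n_planted_up]
    down_idx = chosen[config.n_planted_up: config.n_planted_up + config.n_planted_down]
    spec_idx = chosen[config.n_planted_up + config.n_planted_down:]
    labels[up_idx] = "up"
    labels[down_idx] = "down"
    n_case_spec = int(round(config.case_specific_fraction * len(spec_idx)))
    labels[spec_idx[:n_case_spec]] = "case_specific"
    labels[spec_idx[n_case_spec:]] = "control_specific"

    need = math.ceil(0.75 * config.n_per_group)

    records: list[GlycoPeptideRecord] = []
    truth_rows = []
    for i, feat in enumerate(features):
        acc = feat["protein_id"]
        label = labels[i]
        glyco_fc = {"up": config.planted_log2fc,
                    "down": -config.planted_log2fc}.get(label, 0.0)
        offset = float(rng.normal(-3.0, 1.0))
        log2row = (base_log2[acc] + prot_shift.get(acc, 0.0) * is_case
                   + offset + glyco_fc * is_case
                   + rng.normal(0.0, config.noise_sd, size=len(samples)))
        values = 2.0 ** log2row

        if label in ("case_specific", "control_specific"):
            own = case_cols if label == "case_specific" else ctrl_cols
            other = ctrl_cols if label == "case_specific" else case_cols
            n_det = int(rng.integers(need, config.n_per_group + 1))
            det_cols = set(rng.choice(own, size=n_det, replace=False))
            detected = np.array(
                [s in det_cols for s in samples]
            )
        else:
            detected = rng.random(len(samples)) < config.detection_rate
            # ground-truth integrity: a null feature must not satisfy the
            # specificity rule by chance
            d_case = detected[is_case].sum()
            d_ctrl = detected[~is_case].sum()
            if d_ctrl == 0 and d_case >= need:
                j = int(np.flatnonzero(~is_case)[rng.integers(0, (~is_case).sum())])
                detected[j] = True
            elif d_case == 0 and d_ctrl >= need:
                j = int(np.flatnonzero(is_case)[rng.integers(0, is_case.sum())])
                detected[j] = True
        intensities = pd.Series(np.where(detected, values, np.nan), index=samples)
        records.append(GlycoPeptideRecord(
            protein_id=acc, peptide=feat["peptide"], site=feat["site"],
            composition=feat["composition"], intensities=intensities,
        ))
        truth_rows.append({
            "feature_id": records[-1].feature_id,
            "label": label,
            "planted_log2fc": glyco_fc,
            "protein_id": acc,
            "site": feat["site"],
            "composition": str(feat["composition"]),
            "glycan_class": feat["glycan_class"],
            "protein_quantified": acc not in unquantified,
        })

    truth = GroundTruth(
        features=pd.DataFrame(truth_rows).set_index("feature_id"),
        genes=pd.DataFrame(gene_meta, columns=["gene_id", "role", "case_shift"])
        .set_index("gene_id"),
    )
    return Bundle(config=config, sequences=sequences, records=records,
                  proteins=proteins, gene_sets=gene_sets, groups=groups,
                  enzyme_ids=enzyme_ids, truth=truth)


# ---------------------------------------------------------------------------
# Bundle IO
# ---------------------------------------------------------------------------

FILENAMES = {
    "glyco": "glycopeptides.tsv",
    "proteins": "proteins.tsv",
    "fasta": "proteins.fasta",
    "gmt": "gene_sets.gmt",
    "groups": "groups.tsv",
    "enzymes": "enzymes.txt",
    "truth_features": "ground_truth_features.tsv",
    "truth_genes": "ground_truth_genes.tsv",
}


def write_bundle(bundle: Bundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as plain-text files; returns the path of each part."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in FILENAMES.items()}
    try:
        write_glycopeptide_table(bundle.records, paths["glyco"])
        prot = bundle.proteins.values.copy()
        prot.insert(0, "protein_id", prot.index)
        prot.to_csv(paths["proteins"], sep="\t", index=False, float_format="%.6g")
        write_fasta(bundle.sequences, paths["fasta"])
        write_gmt(bundle.gene_sets, paths["gmt"])
        pd.DataFrame({"sample_id": bundle.groups.index,
                      "group": bundle.groups.values}).to_csv(
            paths["groups"], sep="\t", index=False)
        paths["enzymes"].write_text("\n".join(bundle.enzyme_ids) + "\n")
        bundle.truth.features.to_csv(paths["truth_features"], sep="\t")
        bundle.truth.genes.to_csv(paths["truth_genes"], sep="\t")
    except OSError as exc:
        raise OSError(f"failed writing bundle file: {exc.filename}") from exc
    return paths


def read_bundle(directory: str | Path) -> dict:
    """Read back a written bundle (data parts + ground truth tables)."""
    directory = Path(directory)
    p = {k: directory / v for k, v in FILENAMES.items()}
    records = read_glycopeptide_table(p["glyco"])
    prot = pd.read_csv(p["proteins"], sep="\t", index_col="protein_id")
    groups_df = pd.read_csv(p["groups"], sep="\t")
    groups = pd.Series(groups_df["group"].values, index=groups_df["sample_id"])
    proteins = QuantMatrix(prot, groups)
    return {
        "records": records,
        "proteins": proteins,
        "sequences": read_fasta(p["fasta"]),
        "gene_sets": read_gmt(p["gmt"]),
        "groups": groups,
        "enzyme_ids": p["enzymes"].read_text().split(),
        "truth_features": pd.read_csv(p["truth_features"], sep="\t",
                                      index_col="feature_id"),
        "truth_genes": pd.read_csv(p["truth_genes"], sep="\t",
                                   index_col="gene_id"),
    }
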