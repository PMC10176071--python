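"""Data model and IO for intact N-glycopeptide analysis.

The unit of analysis is the intact N-glycopeptide: a peptide together with
the glycosite it carries and the monosaccharide composition of its N-glycan
(HexNAc / Hex / Fuc / NeuAc counts, no linkage information).  This module
holds the composition parser, the N-glycosylation sequon rule
(N-X-S|T|C, X != P), site-centered window extraction, the features x samples
quantitation container, and readers/writers for the plain-text exchange
formats (TSV tables, FASTA, GMT gene sets).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GlycanComposition",
    "GlycoPeptideRecord",
    "QuantMatrix",
    "SequonResult",
    "Window",
    "parse_composition",
    "validate_sequon",
    "extract_window",
    "motif_distribution",
    "normalize_columns",
    "read_fasta",
    "write_fasta",
    "read_gmt",
    "write_gmt",
    "read_glycopeptide_table",
    "write_glycopeptide_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: accepted residue spellings -> canonical slot
_RESIDUE_SYNONYMS: dict[str, str] = {
    "HEXNAC": "hexnac",
    "N": "hexnac",
    "HEX": "hex",
    "H": "hex",
    "FUC": "fuc",
    "F": "fuc",
    "DHEX": "fuc",
    "NEUAC": "neuac",
    "S": "neuac",
    "NEUAC5": "neuac",
}

_TOKEN_RE = re.compile(r"([A-Za-z][A-Za-z0-9]*)\((-?\d+)\)")


class CompositionError(ValueError):
    """Raised on a malformed glycan composition string."""


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide counts of an N-glycan, linkage-free.

    ``other`` preserves residues outside the core alphabet (e.g. NeuGc);
    they round-trip through formatting but are ignored by the classifier.
    """

    hexnac: int = 0
    hex: int = 0
    fuc: int = 0
    neuac: int = 0
    other: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        counts = [self.hexnac, self.hex, self.fuc, self.neuac]
        counts += [c for _, c in self.other]
        if any(c < 0 for c in counts):
            raise CompositionError("negative monosaccharide count")
        if self.total == 0:
            raise CompositionError("composition must contain >= 1 monosaccharide")

    @property
    def total(self) -> int:
        return (
            self.hexnac + self.hex + self.fuc + self.neuac
            + sum(c for _, c in self.other)
        )

    def __str__(self) -> str:
        parts = []
        for name, count in (
            ("HexNAc", self.hexnac),
            ("Hex", self.hex),
            ("Fuc", self.fuc),
            ("NeuAc", self.neuac),
        ):
            if count:
                parts.append(f"{name}({count})")
        for name, count in sorted(self.other):
            if count:
                parts.append(f"{name}({count})")
        return "".join(parts)


def parse_composition(text: str) -> GlycanComposition:
    """Parse a ``Residue(count)`` composition string.

    Accepted synonyms: HexNAc|N, Hex|H, Fuc|F|dHex, NeuAc|S|NeuAc5 (case
    insensitive).  Unknown residues are preserved in ``other``.  Order of
    tokens is irrelevant; ``parse_composition(str(c)) == c``.
    """
    if not isinstance(text, str) or not text.strip():
        raise CompositionError("empty composition string")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {"hexnac": 0, "hex": 0, "fuc": 0, "neuac": 0}
    other: dict[str, int] = {}
    for m in _TOKEN_RE.finditer(text):
        if m.start() != pos:
            raise CompositionError(
                f"malformed composition near {text[pos:m.start()]!r} in {text!r}"
            )
        pos = m.end()
        name, count = m.group(1), int(m.group(2))
        if count <= 0:
            raise CompositionError(f"non-positive count in token {m.group(0)!r}")
        slot = _RESIDUE_SYNONYMS.get(name.upper())
        if slot is not None:
            counts[slot] += count
        else:
            other[name] = other.get(name, 0) + count
    if pos != len(text):
        raise CompositionError(f"malformed composition near {text[pos:]!r}")
    return GlycanComposition(other=tuple(sorted(other.items())), **counts)


@dataclass
class GlycoPeptideRecord:
    """One intact N-glycopeptide.

    A unique glycopeptide is keyed by (protein, glycosite, canonical
    composition string, peptide sequence).  ``intensities`` are raw
    per-sample reporter intensities (NaN = not detected); ``normalized``
    holds the intensity divided by the matching protein intensity once
    :func:`glycoimmune.glycoquant.normalize_to_protein` has run.
    """

    protein_id: str
    peptide: str
    site: int  # 1-based position of the modified Asn in the protein
    composition: GlycanComposition
    intensities: pd.Series
    normalized: pd.Series | None = None
    normalized_to_protein: bool = False

    @property
    def feature_id(self) -> str:
        return f"{self.protein_id}|N{self.site}|{self.composition}"

    @property
    def site_id(self) -> str:
        return f"{self.protein_id}|N{self.site}"


@dataclass
class QuantMatrix:
    """Features x samples abundance table with group labels.

    ``values`` is a DataFrame (rows = features, columns = samples) with NaN
    marking missing/undetected entries — absence is deliberately distinct
    from zero so that detection-based rules and t tests see different
    things.  ``groups`` maps each sample to its group label.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        self.groups = self.groups.loc[list(self.values.columns)]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def detection_mask(self) -> pd.DataFrame:
        return self.values.notna()

    def subset(self, feature_ids: Sequence[str]) -> "QuantMatrix":
        return QuantMatrix(self.values.loc[list(feature_ids)], self.groups.copy())


# ---------------------------------------------------------------------------
# Sequon and window rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequonResult:
    valid: bool
    motif_class: str  # "N-X-T" | "N-X-S" | "N-X-C" | "invalid"


def validate_sequon(sequence: str, site: int) -> SequonResult:
    """Check the N-glycosylation sequon N-X-S|T|C (X != P) at ``site``.

    ``site`` is the 1-based position of the candidate Asn.  Sites within two
    residues of the C terminus cannot complete the motif and are invalid.
    """
    if not 1 <= site <= len(sequence):
        raise IndexError(f"site {site} outside sequence of length {len(sequence)}")
    i = site - 1
    if i + 2 >= len(sequence):
        return SequonResult(False, "invalid")
    n, x, third = sequence[i], sequence[i + 1], sequence[i + 2]
    if n != "N" or x == "P" or third not in "STC":
        return SequonResult(False, "invalid")
    return SequonResult(True, f"N-X-{third}")


@dataclass(frozen=True)
class Window:
    """A glycosite-centered subsequence (no terminal padding)."""

    window: str
    center_index: int  # 0-based index of the Asn within ``window``
    truncated: bool


def extract_window(sequence: str, site: int, flank: int = 15) -> Window:
    """Extract up to ``2*flank + 1`` residues centered on the glycosite Asn.

    Windows are truncated at protein termini rather than padded, so scores
    computed on them never see invented residues.
    """
    if not 1 <= site <= len(sequence):
        raise IndexError(f"site {site} outside sequence of length {len(sequence)}")
    if sequence[site - 1] != "N":
        raise ValueError(
            f"residue at site {site} is {sequence[site - 1]!r}, expected 'N'"
        )
    lo = max(0, site - 1 - flank)
    hi = min(len(sequence), site + flank)
    return Window(
        window=sequence[lo:hi],
        center_index=site - 1 - lo,
        truncated=(hi - lo) < 2 * flank + 1,
    )


def motif_distribution(
    records: Iterable[GlycoPeptideRecord],
    sequences: Mapping[str, str],
    groups: pd.Series | None = None,
) -> dict:
    """Sequon-motif proportions over unique glycosites.

    Returns overall proportions of N-X-T / N-X-S / N-X-C (plus the N-T-C
    sub-count, reported separately), and — when intensities carry sample
    columns — per-sample proportions over the sites detected in that sample
    with mean ± SD by group.  Invalid sequons are excluded with a warning.
    """
    site_motif: dict[str, str] = {}
    site_ntc: dict[str, bool] = {}
    site_detect: dict[str, pd.Series] = {}
    invalid: list[str] = []
    for rec in records:
        sid = rec.site_id
        seq = sequences.get(rec.protein_id)
        if seq is None or sid in site_motif or sid in invalid:
            if seq is None:
                invalid.append(sid)
            continue
        res = validate_sequon(seq, rec.site)
        if not res.valid:
            invalid.append(sid)
            continue
        site_motif[sid] = res.motif_class
        i = rec.site - 1
        site_ntc[sid] = seq[i + 1] == "T" and seq[i + 2] == "C"
        det = rec.intensities.notna()
        site_detect[sid] = site_detect.get(sid, det) | det
    if invalid:
        warnings.warn(f"{len(invalid)} sites with invalid/missing sequons excluded")

    classes = ["N-X-T", "N-X-S", "N-X-C"]
    motifs = pd.Series(site_motif)
    overall = (
        motifs.value_counts(normalize=True).reindex(classes).fillna(0.0)
        if len(motifs)
        else pd.Series(0.0, index=classes)
    )
    ntc_fraction = float(np.mean(list(site_ntc.values()))) if site_ntc else 0.0

    out = {
        "overall": overall,
        "ntc_fraction": ntc_fraction,
        "excluded_sites": invalid,
    }
    if site_detect:
        det = pd.DataFrame(site_detect).T  # sites x samples
        per_sample = {}
        for s in det.columns:
            hit = motifs[det[s].reindex(motifs.index).fillna(False)]
            per_sample[s] = (
                hit.value_counts(normalize=True).reindex(classes).fillna(0.0)
                if len(hit)
                else pd.Series(np.nan, index=classes)
            )
        per_sample_df = pd.DataFrame(per_sample).T  # samples x motif classes
        out["per_sample"] = per_sample_df
        if groups is not None:
            g = pd.Series(groups).loc[per_sample_df.index]
            out["group_mean"] = per_sample_df.groupby(g).mean()
            out["group_sd"] = per_sample_df.groupby(g).std(ddof=1)
    return out


def normalize_columns(matrix: QuantMatrix) -> QuantMatrix:
    """Scale every sample so non-missing column totals are equal.

    The common target is the grand mean of the observed column totals, so
    an already-balanced matrix passes through unchanged and the operation
    is idempotent.  Missing entries stay missing.
    """
    totals = matrix.values.sum(axis=0, skipna=True)
    dead = totals[(totals == 0) | matrix.values.isna().all(axis=0)]
    if len(dead):
        raise ValueError(f"all-missing/zero-total sample(s): {list(dead.index)}")
    target = totals.mean()
    return QuantMatrix(matrix.values * (target / totals), matrix.groups.copy())


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA; accession is the first whitespace token of the header."""
    return {
        rec.id.split()[0]: str(rec.seq)
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(seq), id=acc, description="")
        for acc, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read GMT gene sets: name <tab> description <tab> genes..."""
    sets: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line with <3 fields: {line[:60]!r}")
        sets[fields[0]] = {
            "description": fields[1],
            "genes": [g for g in fields[2:] if g],
        }
    return sets


def write_gmt(sets: Mapping[str, Mapping], path: str | Path) -> Path:
    path = Path(path)
    lines = [
        "\t".join([name, str(body.get("description", "")), *body["genes"]])
        for name, body in sets.items()
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


_GLYCO_META_COLS = ["protein_id", "peptide", "site", "composition"]


def read_glycopeptide_table(path: str | Path) -> list[GlycoPeptideRecord]:
    """Read the glycopeptide TSV: meta columns then one column per sample."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str})
    missing = [c for c in _GLYCO_META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"glycopeptide table missing columns {missing}")
    sample_cols = [c for c in df.columns if c not in _GLYCO_META_COLS]
    records = []
    for _, row in df.iterrows():
        records.append(
            GlycoPeptideRecord(
                protein_id=row["protein_id"],
                peptide=row["peptide"],
                site=int(row["site"]),
                composition=parse_composition(row["composition"]),
                intensities=pd.Series(
                    row[sample_cols].astype(float).values, index=sample_cols
                ),
            )
        )
    return records


def write_glycopeptide_table(
    records: Sequence[GlycoPeptideRecord], path: str | Path
) -> Path:
    path = Path(path)
    if not records:
        raise ValueError("no records to write")
    sample_ids = list(records[0].intensities.index)
    rows = []
    for rec in records:
        row = {
            "protein_id": rec.protein_id,
            "peptide": rec.peptide,
            "site": rec.site,
            "composition": str(rec.composition),
        }
        row.update(rec.intensities.reindex(sample_ids).to_dict())
        rows.append(row)
    df = pd.DataFrame(rows, columns=_GLYCO_META_COLS + sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def records_to_matrix(
    records: Sequence[GlycoPeptideRecord],
    groups: pd.Series,
    use_normalized: bool = False,
) -> QuantMatrix:
    """Stack records into a QuantMatrix keyed by feature_id."""
    rows = {}
    for rec in records:
        values = rec.normalized if use_normalized else rec.intensities
        if values is None:
            raise ValueError(f"{rec.feature_id}: normalized values not computed")
        rows[rec.feature_id] = values
    return QuantMatrix(pd.DataFrame(rows).T, pd.Series(groups))
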