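"""Sequence-based antigenicity screening of glycosite-centered peptides.

Five classical B-cell-epitope measures are computed on 31-mer windows
centered on the glycosylated Asn (15 residues of flank either side, no
padding at termini): Kyte-Doolittle hydrophilicity (sign-flipped hydropathy,
window 9), Emini surface probability (hexapeptide product form), Karplus-
Schulz flexibility (normalized B-values, window 7), Garnier-Robson-style
beta-turn assignment (directional information summed over offsets -8..+8,
per-position argmax over four states), and the Jameson-Wolf antigenic index
(weighted sum of the discretized components, maximum 2.4).

A peptide passes the screen iff it has at least one flexible residue, at
least one beta-turn residue, max hydrophilicity >= 1, max surface
probability >= 1 and max antigenic index >= 1.

The per-residue parameter tables ship as TSV data files with literature
citations in their headers and are checksum-pinned at load time.  The
directional-information table is a synthetic stand-in built from
Chou-Fasman propensities (see its header); the published Garnier-
Osguthorpe-Robson parameter set is not redistributed here.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np

from .glycomodel import AMINO_ACIDS, GlycoPeptideRecord, Window, extract_window

__all__ = [
    "ScaleTable",
    "AntigenicityProfile",
    "Verdict",
    "load_scale",
    "load_gor_table",
    "hydrophilicity_kd",
    "surface_emini",
    "flexibility_ks",
    "turns_gr",
    "chou_fasman_turn_track",
    "antigenic_index_jw",
    "compute_profile",
    "screen_peptide",
    "profile_glycosites",
    "DEFAULT_CUTPOINTS",
]

GOR_STATES = ["helix", "extended", "turn", "coil"]
GOR_OFFSETS = np.arange(-8, 9)

_CHECKSUMS = {
    "kyte_doolittle.tsv": "5fff74eacf629a37f53d60f7e29bc129c2e7daa68c50246c02f0e417b2caefd5",
    "emini.tsv": "b349e3bc9121151415320ce516b1e22028ddd16d72ae15d7133b8df727975025",
    "karplus_schulz.tsv": "f0adcd5f6d6c108638af30f69f6104dc56a04e2f42811bc68ed3e63294583eff",
    "chou_fasman_turn.tsv": "560a527406287f3360f3be4d459d3252fa12c8998d19841e7d58da1a37d7a5d8",
    "gor_turn_synthetic.tsv": "be12ca57b64ef5d0199ebffd0e159c2b24c514f3c0b0e7f5fbde0887d29b0e2f",
}

_WINDOWS = {"kyte_doolittle": 9, "emini": 6, "karplus_schulz": 7,
            "garnier_robson": 17, "chou_fasman": 1}


@dataclass(frozen=True)
class ScaleTable:
    name: str
    values: Mapping[str, float]
    window: int
    source: str


def _read_scale_file(filename: str) -> tuple[list[str], str]:
    ref = resources.files("glycoimmune.data.scales").joinpath(filename)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[filename]:
        raise RuntimeError(
            f"scale table {filename} failed its checksum "
            f"({digest[:12]}... != {_CHECKSUMS[filename][:12]}...); refusing "
            "to score with a modified table"
        )
    lines = raw.decode().splitlines()
    source = " ".join(
        l.lstrip("# ").strip() for l in lines if l.startswith("#")
    )
    return [l for l in lines if l and not l.startswith("#")], source


def load_scale(name: str) -> ScaleTable:
    """Load a per-residue scale by name (checksum-verified)."""
    filename = {"kyte_doolittle": "kyte_doolittle.tsv", "emini": "emini.tsv",
                "karplus_schulz": "karplus_schulz.tsv",
                "chou_fasman": "chou_fasman_turn.tsv"}[name]
    body, source = _read_scale_file(filename)
    values = {}
    for line in body[1:]:  # skip header row
        aa, val = line.split("\t")
        values[aa] = float(val)
    if set(values) != set(AMINO_ACIDS):
        raise RuntimeError(f"scale {name} does not cover the 20 residues")
    return ScaleTable(name, values, _WINDOWS[name], source)


def load_gor_table() -> dict[str, dict[str, np.ndarray]]:
    """Directional-information arrays: state -> residue -> offsets -8..+8."""
    body, _ = _read_scale_file("gor_turn_synthetic.tsv")
    table: dict[str, dict[str, np.ndarray]] = {s: {} for s in GOR_STATES}
    for line in body[1:]:
        fields = line.split("\t")
        state, aa = fields[0], fields[1]
        table[state][aa] = np.array([float(v) for v in fields[2:]])
    return table


def _check_sequence(sequence: str) -> None:
    for i, aa in enumerate(sequence):
        if aa not in AMINO_ACIDS:
            raise ValueError(f"unknown residue {aa!r} at position {i}")


def _window_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding mean, truncated (not padded) at the ends."""
    half = window // 2
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def hydrophilicity_kd(sequence: str, window: int = 9) -> np.ndarray:
    """Sign-flipped Kyte-Doolittle hydropathy, centered window mean.

    Positive = hydrophilic, so the screen's "score >= 1" selects strongly
    hydrophilic stretches.  Edge positions use the truncated window.
    """
    _check_sequence(sequence)
    if not sequence:
        raise ValueError("empty sequence")
    scale = load_scale("kyte_doolittle").values
    vals = np.array([scale[aa] for aa in sequence])
    return -_window_mean(vals, window)


def surface_emini(sequence: str, window: int = 6) -> np.ndarray:
    """Emini surface probability per hexapeptide, assigned to its 4th residue.

    S = (product of the six residues' fractional surface probabilities)
    * 0.37^-6, so a random sequence has expectation about 1.  Positions not
    covered by any hexapeptide center are NaN; sequences shorter than the
    window yield an all-NaN track with a warning.
    """
    _check_sequence(sequence)
    n = len(sequence)
    out = np.full(n, np.nan)
    if n < window:
        warnings.warn(f"sequence shorter than Emini window ({n} < {window})")
        return out
    scale = load_scale("emini").values
    vals = np.array([scale[aa] for aa in sequence])
    norm = 0.37 ** (-window)
    for start in range(n - window + 1):
        out[start + 3] = float(np.prod(vals[start:start + window]) * norm)
    return out


def flexibility_ks(sequence: str, window: int = 7) -> dict:
    """Karplus-Schulz flexibility: windowed normalized B-values.

    ``flexible_region[i]`` is True where the windowed mean exceeds 1.0,
    i.e. the backbone is more flexible than average.
    """
    _check_sequence(sequence)
    if not sequence:
        raise ValueError("empty sequence")
    scale = load_scale("karplus_schulz").values
    vals = np.array([scale[aa] for aa in sequence])
    track = _window_mean(vals, window)
    return {"track": track, "flexible_region": track > 1.0}


def turns_gr(sequence: str) -> dict:
    """Beta-turn assignment from summed directional information.

    For each position i and state s, sum I(s; residue at i+d, d) over
    offsets d in -8..+8 (truncated at termini); the predicted state is the
    argmax, with exact ties resolved toward the turn state.  Returns the
    four per-state tracks and the ``beta_turn`` flags.
    """
    _check_sequence(sequence)
    n = len(sequence)
    if n == 0:
        raise ValueError("empty sequence")
    table = load_gor_table()
    tracks = {s: np.zeros(n) for s in GOR_STATES}
    for state in GOR_STATES:
        st = table[state]
        for i in range(n):
            total = 0.0
            for k, d in enumerate(GOR_OFFSETS):
                j = i + d
                if 0 <= j < n:
                    total += st[sequence[j]][k]
            tracks[state][i] = total
    stacked = np.vstack([tracks[s] for s in GOR_STATES])
    turn_idx = GOR_STATES.index("turn")
    best = stacked.max(axis=0)
    beta_turn = tracks["turn"] >= best - 1e-12  # ties go to turn
    return {"tracks": tracks, "beta_turn": beta_turn}


def chou_fasman_turn_track(sequence: str) -> np.ndarray:
    """Per-residue Chou-Fasman beta-turn propensity."""
    _check_sequence(sequence)
    scale = load_scale("chou_fasman").values
    return np.array([scale[aa] for aa in sequence])


#: per-component absolute cut-points mapping raw track values to the five
#: Jameson-Wolf classes {-0.6, -0.3, 0, +0.3, +0.6}; chosen so a random
#: sequence averages a class near 0 on each component.
DEFAULT_CUTPOINTS: dict[str, tuple[float, float, float, float]] = {
    "hydrophilicity": (-2.0, -0.5, 0.5, 2.0),
    "surface": (0.5, 0.8, 1.25, 2.0),
    "flexibility": (0.96, 0.99, 1.01, 1.04),
    "turn_gr": (-200.0, -60.0, 60.0, 200.0),
    "turn_cf": (0.7, 0.9, 1.1, 1.3),
}

_CLASS_VALUES = np.array([-0.6, -0.3, 0.0, 0.3, 0.6])
_JW_WEIGHTS = {"hydrophilicity": 0.3, "surface": 0.15, "flexibility": 0.15,
               "turn_gr": 0.2, "turn_cf": 0.2}


def _discretize(track: np.ndarray, cuts: Sequence[float]) -> np.ndarray:
    """Map track values onto the five JW class values; NaN -> class 0."""
    out = np.zeros(len(track))
    ok = np.isfinite(track)
    out[ok] = _CLASS_VALUES[np.digitize(track[ok], np.asarray(cuts))]
    return out


def antigenic_index_jw(
    hydrophilicity: np.ndarray,
    surface: np.ndarray,
    flexibility: np.ndarray,
    turn_gr: np.ndarray,
    turn_cf: np.ndarray,
    cutpoints: Mapping[str, Sequence[float]] | None = None,
) -> np.ndarray:
    """Jameson-Wolf antigenic index.

    AI[i] = 4 * (0.3 h + 0.15 s + 0.15 f + 0.2 t1 + 0.2 t2) with each
    component first discretized to {-0.6,-0.3,0,+0.3,+0.6} by the
    configured cut-points; the rescaling by 4 makes the maximum attainable
    AI equal to 2.4.
    """
    cutpoints = dict(DEFAULT_CUTPOINTS) | dict(cutpoints or {})
    tracks = {"hydrophilicity": hydrophilicity, "surface": surface,
              "flexibility": flexibility, "turn_gr": turn_gr, "turn_cf": turn_cf}
    n = {len(np.asarray(t)) for t in tracks.values()}
    if len(n) != 1:
        raise ValueError(f"component track lengths differ: {sorted(n)}")
    total = np.zeros(n.pop())
    for name, track in tracks.items():
        total = total + _JW_WEIGHTS[name] * _discretize(
            np.asarray(track, dtype=float), cutpoints[name]
        )
    return 4.0 * total


@dataclass(frozen=True)
class Verdict:
    passes: bool
    flags: dict[str, bool]


@dataclass
class AntigenicityProfile:
    """Per-residue antigenicity tracks over one glycosite-centered window."""

    site_id: str
    window: str
    center_index: int
    truncated: bool
    tracks: dict[str, np.ndarray]       # hydrophilicity, surface_probability,
                                        # flexibility, antigenic_index
    turn_tracks: dict[str, np.ndarray]  # per GOR state
    flags: dict[str, np.ndarray]        # flexible_region, beta_turn (bool)
    peptide_summary: dict[str, float]
    verdict: Verdict | None = None
    linked_features: list[str] = field(default_factory=list)


def compute_profile(
    window: str | Window,
    site_id: str = "",
    cutpoints: Mapping[str, Sequence[float]] | None = None,
) -> AntigenicityProfile:
    """Compute all five tracks and the screen summary for one window."""
    if isinstance(window, Window):
        seq, center, truncated = window.window, window.center_index, window.truncated
    else:
        seq, center, truncated = window, len(window) // 2, False
    h = hydrophilicity_kd(seq)
    s = surface_emini(seq)
    fl = flexibility_ks(seq)
    gr = turns_gr(seq)
    cf = chou_fasman_turn_track(seq)
    ai = antigenic_index_jw(h, s, fl["track"], gr["tracks"]["turn"], cf,
                            cutpoints=cutpoints)
    summary = {
        "max_hydrophilicity": float(np.nanmax(h)),
        "max_surface_probability": float(np.nanmax(s)) if np.isfinite(s).any() else math.nan,
        "max_flexibility": float(np.nanmax(fl["track"])),
        "max_antigenic_index": float(np.nanmax(ai)),
        "n_flexible": int(fl["flexible_region"].sum()),
        "n_beta_turn": int(gr["beta_turn"].sum()),
    }
    profile = AntigenicityProfile(
        site_id=site_id, window=seq, center_index=center, truncated=truncated,
        tracks={"hydrophilicity": h, "surface_probability": s,
                "flexibility": fl["track"], "antigenic_index": ai},
        turn_tracks=gr["tracks"],
        flags={"flexible_region": fl["flexible_region"],
               "beta_turn": gr["beta_turn"]},
        peptide_summary=summary,
    )
    profile.verdict = screen_peptide(profile)
    return profile


def screen_peptide(
    profile: AntigenicityProfile,
    kd_threshold: float = 1.0,
    emini_threshold: float = 1.0,
    ai_threshold: float = 1.0,
) -> Verdict:
    """Apply the conjunctive antigenicity screen to one profile.

    Pass requires all of: >= 1 flexible-region residue, >= 1 beta-turn
    residue, max hydrophilicity >= 1, max surface probability >= 1 and max
    antigenic index >= 1.  Threshold criteria aggregate by the window max
    (an existence claim over residues), matching the flag criteria.
    """
    s = profile.peptide_summary
    flags = {
        "flexible_region": s["n_flexible"] >= 1,
        "beta_turn": s["n_beta_turn"] >= 1,
        "hydrophilicity": s["max_hydrophilicity"] >= kd_threshold,
        "surface_probability": (
            math.isfinite(s["max_surface_probability"])
            and s["max_surface_probability"] >= emini_threshold
        ),
        "antigenic_index": s["max_antigenic_index"] >= ai_threshold,
    }
    return Verdict(all(flags.values()), flags)


def profile_glycosites(
    records: Sequence[GlycoPeptideRecord],
    sequences: Mapping[str, str],
    flank: int = 15,
    cutpoints: Mapping[str, Sequence[float]] | None = None,
) -> dict[str, AntigenicityProfile]:
    """One profile per unique glycosite, linked to all glycoforms on it.

    Sites whose protein is absent from the FASTA (or whose site residue is
    not Asn) are skipped with a warning — the screen must be computed on a
    genuine glycosite-centered window.
    """
    profiles: dict[str, AntigenicityProfile] = {}
    skipped: list[str] = []
    for rec in records:
        sid = rec.site_id
        if sid in profiles:
            if rec.feature_id not in profiles[sid].linked_features:
                profiles[sid].linked_features.append(rec.feature_id)
            continue
        if sid in skipped:
            continue
        seq = sequences.get(rec.protein_id)
        if seq is None:
            skipped.append(sid)
            continue
        try:
            win = extract_window(seq, rec.site, flank=flank)
        except (ValueError, IndexError):
            skipped.append(sid)
            continue
        profile = compute_profile(win, site_id=sid, cutpoints=cutpoints)
        profile.linked_features.append(rec.feature_id)
        profiles[sid] = profile
    if skipped:
        warnings.warn(f"{len(skipped)} site(s) skipped (missing/invalid in FASTA)")
    return profiles
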