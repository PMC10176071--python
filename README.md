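# glycoimmune

Downstream analysis of intact *N*-glycopeptide quantitation for two-group
TMT designs, built around the comparison of rheumatoid-arthritis-like (RA)
and osteoarthritis-like (OA) synovium: which glycopeptides change, which
are group-specific, which of their prototype peptides look antigenic, and
which track immune-cell infiltration.

## Who this is for

Proteomics groups that already have identification-level outputs — a
glycopeptide quantitation table (protein, peptide, glycosite, glycan
composition, per-sample intensities), a protein quantitation table, protein
FASTA, and immune gene sets (GMT) — and want the downstream statistics as a
tested, scriptable pipeline instead of spreadsheet steps.

## What it computes

- **Glycan classes.** A composition `HexNAc(a)Hex(b)Fuc(c)NeuAc(d)` is
  assigned one of six classes by a priority rule: Fuc≥1 ∧ NeuAc≥1 →
  fucosylated+sialylated; NeuAc≥1 → sialylated; Fuc≥1 → fucosylated;
  HexNAc≤2 ∧ Hex≤3 → paucimannose; HexNAc=2 ∧ Hex≥4 → high mannose;
  otherwise complex/hybrid. Microheterogeneity summaries (sites/protein,
  glycans/site, class co-occurrence at shared sites) follow.
- **Differential calling.** Glycopeptide intensities are divided by the
  matching protein intensity per sample; fold change is the ratio of group
  medians (RA/OA) with a two-sided equal-variance Student's *t* on log₂
  values; defaults FC > 1.5 or < 0.67 at *p* < 0.05, with post hoc power
  from the noncentral *t* (Cohen's *d*, pooled SD).
- **Group specificity.** A glycopeptide is RA-specific when detected in
  ≥ 75 % of RA samples and in no OA sample (and vice versa).
- **Target–decoy FDR.** Spectrum-level FDR = 2·n_decoy·100/n_forward, plus
  a score-threshold scan for a target FDR (e.g. ≤ 1 %).
- **Antigenicity screen.** On the 31-mer window centered on each glycosite
  (no terminal padding): Kyte–Doolittle hydrophilicity (sign-flipped
  hydropathy, window 9), Emini surface probability (hexapeptide product ×
  0.37⁻⁶), Karplus–Schulz flexibility (window 7), a Garnier–Robson-style
  β-turn assignment (directional information, offsets −8..+8), and the
  Jameson–Wolf antigenic index AI = 4·(0.3h + 0.15s + 0.15f + 0.2t₁ +
  0.2t₂) over discretized components (max 2.4). A peptide passes when it
  has a flexible region, a β-turn, and max hydrophilicity, surface
  probability and AI all ≥ 1.
- **Immune context.** ssGSEA enrichment scores (rank-weighted ECDF
  difference, exponent 0.25) for nine immune-cell gene sets, an
  immune-signature score compared between groups by exact Wilcoxon
  rank-sum, OPLS-DA sample scores, and Spearman correlations (exact
  permutation *p* at small *n*) of candidate glycopeptides with cell
  scores and glycosylation-enzyme abundances.

A synthetic-data generator (`glycoimmune.datagen`) emulates the 2 × 4
TMT design with planted fold changes, group-specific detection patterns,
six-class glycan mixtures and immune-signature shifts, and writes the
ground truth alongside, so every caller can be scored against known
answers.

## Worked example

```sh
glycoimmune simulate --out data --seed 3
glycoimmune run --config pipe.yaml     # pipe.yaml points at data/, seed 3
```

prints

```
glycoimmune pipeline report
===========================
glycopeptides quantified:        170 (54 sites on 40 proteins)
differential proteins:           77
differential glycopeptides:      38 (up 27, down 11)
group-specific glycopeptides:    10 (case 8, control 2)
candidates (differential+spec.): 48
antigenicity screen passing:     40
significant cell correlations:   161
significant enzyme correlations: 53
immune-associated glycopeptides: 31
immune score group test p:       0.02857
```

Reading it: 170 simulated glycopeptides were quantified; 38 passed the
fold-change + *t*-test thresholds after protein normalization (the bundle
planted 25 up and 10 down); 10 were group-specific by the 75 %/0 detection
rule (all 10 planted ones); 48 candidates went into the antigenicity
screen and 40 passed; 31 of those also correlate significantly with at
least one immune-cell enrichment score — the final "immune-associated
glycopeptide" set. The immune score is higher in the RA-like group at the
smallest *p* an exact rank-sum test on 4 + 4 samples can produce (2/70 ≈
0.0286). Per-table TSVs (differential, specificity, classes,
co-occurrence, antigenicity verdicts, enrichment scores, correlations,
OPLS-DA scores) land in the configured output directory with provenance
headers.

The same analyses are importable: `glycoimmune.pipeline.run_on_tables`
runs everything in memory, and each stage (`glycoquant.differential`,
`antigenicity.compute_profile`, `immunoscore.ssgsea`, `stats.oplsda_fit`,
…) is a plain function or model object.

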