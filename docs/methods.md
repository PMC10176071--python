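# Methods

This note documents the models, rules and numerical choices implemented in
`glycoimmune`, what the synthetic-data generator does and does not emulate,
and the places where the design was genuinely open.

## Data model

The analysis unit is the intact *N*-glycopeptide, keyed by (protein
accession, glycosite, canonical composition string, peptide sequence).
Compositions are monosaccharide counts over {HexNAc, Hex, Fuc, NeuAc} with
unknown residues preserved but ignored by the classifier; the canonical
string order is HexNAc, Hex, Fuc, NeuAc, then others alphabetically, so
`parse ∘ format` is the identity. Positions are 1-based in protein
coordinates (matching `IGSF10_N2147`-style site names); window indices are
0-based. Missing intensities are encoded as absent (NaN), never zero:
detection-based rules and *t* tests must distinguish "not identified" from
"low abundance".

## Sequon and windows

A glycosite is valid iff the protein carries N-X-[S/T/C] with X ≠ P at the
site; sites within two residues of the C terminus cannot complete the
motif. Site-centered windows take up to 15 residues either side and
truncate at termini rather than pad — antigenicity scores are never
computed on invented residues; truncated windows are flagged.

## Quantitative calling

**Protein normalization.** Glycopeptide/protein ratios are computed from
matched raw intensities. Within an isobaric-labelling channel the
sample-loading factor multiplies both layers and cancels in the ratio;
dividing instead by a total-normalized protein matrix re-introduces a
per-sample factor whenever the two layers differ compositionally (e.g.
when immune proteins rise as a group), which measurably inflates the null
false-positive rate. Total (column) normalization is therefore applied
only where a single layer is analyzed on its own: the protein
differential, enrichment scoring and enzyme correlations. Columns are
scaled to the grand mean of column totals, so the operation is idempotent
and a balanced matrix passes through unchanged. Glycopeptides whose
protein is absent from proteomics keep raw intensities, are flagged, and
are analyzed in a separate differential table.

**Differential.** Fold change is the ratio of group medians
(case/control) on the normalized scale — the ratio-of-medians reading of
"median ratio"; the *t* test is the classical equal-variance two-sample
test on log₂ values (Welch available as an option), two-sided, α = 0.05,
FC thresholds 1.5 and 0.67. Zero intensities are treated as below
quantification and excluded from the log-scale test; a zero control median
yields an infinite fold change with the result flagged degenerate.
Features with fewer than two quantified values per group are
`insufficient`. No multiplicity correction is applied by default (raw
*p* < 0.05 mirrors the emulated workflow); Benjamini–Hochberg is available
as a toggle. Per-feature post hoc power uses Cohen's *d* from the observed
pooled SD and the noncentral *t* with ncp = d·√(n₁n₂/(n₁+n₂)) — at d = 0
the returned power is exactly α.

**Specificity.** Detected-in ≥ ⌈0.75·n_G⌉ samples of one group and zero of
the other; the detected-in-all subset is reported separately. Detection
means a non-missing raw intensity; there is no intensity floor.

**Target–decoy FDR.** FDR% = 2·n_decoy·100/n_forward. The threshold scan
assumes higher scores are better matches and returns the cutoff retaining
the most forward matches at the target rate.

## Antigenicity

All five measures are computed from their original published descriptions
(Kyte & Doolittle 1982; Emini 1985; Karplus & Schulz 1985;
Garnier–Osguthorpe–Robson-style directional information; Jameson & Wolf
1988) with windows 9/6/7/17; the commercial implementations of these
scales apply unpublished smoothing, so exact parity with any particular
product is out of scope — the contract here is agreement with naive
re-computations of the documented formulas, which the tests enforce to
1e-9. Scale tables ship as TSV data files with citations in their headers
and are SHA-256-pinned; a modified table refuses to load.

Choices worth knowing:

- "Kyte–Doolittle hydrophilicity" is sign-flipped hydropathy, so the
  screening rule "score ≥ 1" selects hydrophilic stretches. Both the raw
  and flipped readings were defensible; the flipped one makes the
  screening threshold meaningful.
- The Emini score for a hexapeptide is assigned to its 4th residue;
  positions not covered by a full hexapeptide are NaN.
- The directional-information table for the turn assignment is a
  **synthetic stand-in** (`gor_turn_synthetic.tsv`): the published GOR-I
  parameter set is not redistributed here, so the table is constructed
  from Chou–Fasman conformational propensities as
  I(state; residue, d) = 100·ln P_state·(1 − |d|/9) over offsets −8..+8,
  with coil as the zero-information reference. The algorithm around it
  (truncated directional sums, per-position argmax over four states) is
  the standard one, and ties resolve toward the turn state, favouring
  screen sensitivity.
- Jameson–Wolf components are discretized to {−0.6, −0.3, 0, +0.3, +0.6}
  by per-track absolute cut-points (configurable) chosen so a random
  sequence averages near class 0, then combined with weights
  0.3/0.15/0.15/0.2/0.2 and rescaled ×4, giving a maximum AI of 2.4.
- The screen is a conjunction of existence claims over the window:
  ≥ 1 flexible residue, ≥ 1 β-turn residue, and window maxima ≥ 1 for
  hydrophilicity, surface probability and AI. "Anywhere in the window"
  was chosen over "at the same residue"; it is the weaker and more
  screening-friendly reading, and the per-criterion flags are always
  reported so the stricter analysis remains possible downstream.

## Enrichment and correlation

ssGSEA ranks each sample's genes by abundance (midranks for ties; missing
values rank lowest) and sums, down the ranked list, the difference between
the in-set ECDF weighted by rank^0.25 and the uniform out-of-set ECDF.
Scores are rank-invariant under any strictly monotone transform of one
sample's values. Min–max normalization across samples exists but is off by
default; row-scaled Z scores for heatmaps are presentation, not analysis.
The immune score is the same statistic on an immune-signature set — a
rank-based analogue of the ESTIMATE immune score whose affine rescaling is
irrelevant to a rank-sum group comparison. Group comparison uses the
Wilcoxon rank-sum test, exact by enumeration when both groups have ≤ 10
observations and no ties, otherwise a tie-corrected normal approximation
without continuity correction (so a dead-central U and all-tied inputs
give p = 1). Note the granularity at n = 4 + 4: the exact two-sided test's
smallest attainable *p* is 2/70 ≈ 0.0286, and its attainable level at the
0.05 threshold is likewise 2/70 — null rejection rates sit near 0.029, not
0.050.

Correlations are Spearman with pairwise-complete observations: midranks,
then the product-moment correlation of ranks; *p* is the exact two-sided
permutation tail over all n! orderings for n ≤ 8 (coarse but honest at
this design's n) and the *t* approximation above. Significance is raw
*p* < α, with BH optional. The nine cell-type gene sets and the enzyme
panel are user inputs (GMT / accession list); the generator fabricates
both with planted signal.

## OPLS-DA

Single-response orthogonal-projection PLS: features are mean-centered and
unit-variance scaled (constant features dropped with a warning), the
weight direction is w ∝ X'y, each of the n_orth orthogonal components
removes the loading component orthogonal to w, and one predictive
component is extracted from the deflated matrix. Orthogonal scores have
exactly zero sample covariance with the centered class vector by
construction. n_orth defaults to 1 — eight samples cannot support more —
and no cross-validated Q² is computed by default at this n.

## Synthetic-data generator

The generator emulates the *structure* of the emulated study: 2 groups ×
4 samples; protein sequences with valid sequons planted at every simulated
glycosite (third residue T/S/C at 66.5/33/0.5 %); sites per protein
1/2/3 at 74/15/11 %; glycans per site 1/2/3/4/5+ at 15/33/10/8/34 %;
class mix paucimannose 5 %, high mannose 32 %, complex/hybrid 12 %,
sialylated 8 %, fucosylated 36 %, fucosylated+sialylated 7 %. Intensities
are log-normal: log₂ I = base + group effect + N(0, noise_sd), with
noise_sd = 0.25 and planted |log₂ FC| = 2 on top of the protein so the
effect survives protein normalization; a fraction of glycoproteins also
shift at the protein level to exercise the cancellation. Immune-cell
marker sets (9 × 20 genes), a 50-gene immune signature (shifted +1 log₂ in
the RA-like group) and a 20-gene enzyme panel (+0.8) sit in a 300-row
gene background. Missingness is completely at random per cell (detection
rate 0.95) except planted specific features, which are structurally absent
in the other group; if a *null* feature's random mask happens to satisfy
the specificity rule, one detection is added in the opposite group so the
ground-truth labels stay exhaustive and recovery can be scored with zero
tolerance. A single seeded RNG stream generates everything in a fixed
order, so equal seeds give byte-identical bundles.

What it does **not** emulate: spectra, retention times, reporter-ion
interference and co-isolation, intensity-dependent (MNAR) missingness,
correlated protein covariation, isoforms, and real marker-gene biology.
Passing recovery tests on this generator therefore demonstrates that the
callers implement their rules correctly under the stated noise model — not
that the thresholds are well-calibrated for any particular real dataset.

## Problem sizes used in validation

The packaged validation runs use reduced scales chosen to exercise every
code path with comfortable statistics: 500-feature / 120-protein bundles
(10 seeds) for differential recovery, default 40-protein bundles for
specificity and end-to-end runs, 200 seeds for immune-score separation,
and 100,000 simulated *t* tests for the Monte-Carlo power cross-check.

## Known limitations

- With n = 4 per group, exact rank tests are coarse (see above); Spearman
  *p*-values on 4 complete pairs cannot reach 0.05 at all.
- The turn-assignment parameter table is synthetic (documented above);
  turn flags are internally consistent and oracle-tested but not
  numerically comparable to published GOR-I outputs.
- Total-sum column normalization is compositional: a large coordinated
  shift (here, immune infiltration) biases the remaining features'
  apparent changes in the protein-level differential. This mirrors the
  emulated workflow and is left as-is there; the glycopeptide caller
  avoids it by construction (raw ratios).
- The pipeline performs no missing-value imputation and no isoform-level
  protein inference.
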