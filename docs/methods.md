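# Methods

## The screen and its statistic

A mating screen mixes a MATa pool displaying TCR variants with a MATalpha
pool displaying pMHC variants. Binding between a displayed TCR and pMHC
promotes agglutination and therefore mating; the diploid pool is selected
(auxotrophic markers) and sequenced. Two readout geometries are supported:

- **payload amplicons** — the variable region itself is sequenced: the
  27 bp peptide region after a perfect match of the 38 bp anchor
  `GTTTTTCAATATTTTCTGTTATTGCTAGCGTTTTAGCA`, or the 24 bp CDR3 region after
  the 30 bp anchor `GATTCTGCTACTTATTTGTGTGCTGTTAGA`. Used when one side of
  the cross is a library and the other side is a known strain per arm.
- **barcode pairs** — for library-on-library crosses, Cre-loxP
  recombination juxtaposes the two parental 15 bp barcodes on one
  amplicon; the MATa barcode follows `GAAAAGCGGC` on the read and the
  MATalpha barcode follows `CCAGGTATCG` on the reverse-complemented read.

Counting is exact-match throughout: anchors must match perfectly, and
payloads/barcodes must equal a registry entry (a Hamming-1 correction
exists behind a flag, off by default). Reads are accounted exhaustively:
`assigned + low_quality + no_anchor + unassigned_payload = total` per
replicate, and the extraction stage asserts this in its output.

Within each replicate, a variant's count is divided by the count of the
**stop-codon internal control** — a library member whose payload carries a
premature stop (e.g. a stop at the third residue of the SL9 peptide),
cannot display, and hence mates only at the background rate. Ratios are
computed per replicate first and averaged afterwards; the control's own
ratio is identically 1, and ratios are invariant to per-replicate
sequencing depth (the totals cancel), which the tests assert as a scale-
invariance property. For library-on-library tables, pMHC proportions are
computed per MATa barcode clone, averaged across the clones of a TCR
group, then normalized to the control peptide within each group.

Enrichment is tested per variant with an **unpaired pooled-variance
Student t-test** between the experimental-arm and control-arm replicate
ratios (Welch available by flag), and called when fold change of the arm
means exceeds 1 and p < 0.05 (raw p; Benjamini–Hochberg is an opt-in
column). The t statistic is implemented directly rather than delegated,
because the degenerate cases need fixed conventions: zero pooled variance
with equal means yields (t = 0, p = 1), with unequal means p = 0. The
non-degenerate path is cross-checked against `scipy.stats.ttest_ind` in
the tests. The one-tailed variant tests the directional alternative
mean(x) > mean(y).

## Performance evaluation

Ground truth is activation-based: a variant is cognate iff its mean
T-cell activation fraction strictly exceeds 10%. Reports carry the
classical confusion-matrix quantities and, separately, the
**validated-call rate** TP / (TP + FP) — the fraction of screen calls
confirmed by the orthogonal assay. That precision-style number is the
"specificity" convention used when a screen is benchmarked against a
handful of validated interactions (6 of 7 calls validating gives 6/7 ≈
85.7%); the classical TN/(TN+FP) specificity is reported alongside it
under its proper name. ROC curves sweep the mean experimental-arm
normalized ratio descending (ties grouped, trapezoid AUC via
scikit-learn); the ranking variable is a design choice — the upstream
analyses do not pin one down — and the AUC is verified against a
Mann–Whitney pair-counting oracle in the tests.

## The simulator

The simulator is a generative model of the selection, not of yeast
physiology. Per (TCR group g, pMHC variant v) pair, the mating rate is
linear in the planted interaction strength s ∈ [0, 1]:

    e(g, v) = base + (max − base) · s(g, v)

with defaults base = 5·10⁻⁴ (background diploid formation) and max =
2·10⁻² (cognate-pair mating). These defaults are illustrative: the source
experiments report only that cognate pairs mate significantly more than
negative controls, not per-pair efficiencies, so the two rates are exposed
as configuration. The diploid pool of each replicate is one multinomial
draw at the configured read depth over pair probabilities proportional to
`abundance_a · abundance_alpha · e`; stop-codon variants are forced to
strength 0. Reads are then emitted per diploid with a random 0–8 bp 5'
pad, the scheme's invariant core, a 4 bp tail, and i.i.d. substitution
errors at 10⁻³ per base (no indels — extraction matches anchors exactly,
so indel modeling adds no test power; a perfect 38 bp anchor then fails
with probability 1 − (1 − p)³⁸, which the tests check against the
binomial closed form). Qualities are a constant Q37: base-call noise is
modeled on the sequence, not the quality string. The two anchor 10-mers
have no prefix/suffix self-overlap and barcodes are rejected if they
contain an anchor, so a noiseless simulation round-trips exactly: the
extracted count table equals the simulated truth, which is asserted
per-cell in the tests. Not modeled, deliberately: PCR amplification bias
(a single multinomial draw), induction kinetics, growth competition, and
paired-end structure (amplicons are emitted merged). Passing tests
therefore validate the deconvolution and statistics, not robustness to
amplification artifacts.

### Presets

Presets fix the study conditions; they are not tuning knobs.

- `peptide_screen` — SL9 (SLYNTVATL) saturation library at residue 3
  (wild type, 19 substitutions, stop control 3*), mated to the 868 TCR
  (experimental arm) vs A6/2C (control arm); 4 replicates per arm,
  5·10⁴ reads each. The library is unequally distributed (SL9, 3F, 3I
  rare). Planted strengths separate mating from activation: 3K mates but
  does not activate; 3I/3M/3V activate (ground truth cognate) but do not
  mate or are rare — so the simulated screen reproduces the worked
  example's confusion structure (7 calls, 6 validated, 9 cognates)
  structurally rather than by assignment.
- `tcr_screen` — a VαCDR3 octamer library (wild type GAHDYALN — an
  inferred spelling consistent with the named mutants — 12 strong
  mutants, 3 weak ones, stop control GAHDY*LN) mated to SL9 vs TAX/3*
  arms; the sequenced axis is the CDR3.
- `library_on_library` — 868/A6/2C (two barcode clones each) × five
  peptides mixed equally, barcode-pair readout, TAX 8* as control;
  planted: 868–SL9 (1.0) and 868–3L (0.7). A6–TAX is left at background
  because that interaction is too weak to drive mating in library
  conditions.
- `dilution_1e2` / `dilution_1e4` — SL9, 3L and TAX 8* spiked at 10⁻²
  or 10⁻⁴ relative to each abundant negative (3*, TAX); 3 replicates at
  10⁵ and 10⁶ reads respectively, normalized to 3*. Activation ground
  truth uses 75.6% for SL9 (the reported activation of the index
  peptide); other fractions are synthetic stand-ins placed on the correct
  side of the 10% rule.

Replicate counts (4 and 3) and depths are scaled-down analogues of the
original screens' pooled technical × biological replicates, chosen once
as realistic for a simulation study.

## Numerical and design choices

- **Quality filter**: mean Phred ≥ 20, configurable; the upstream
  description states filtering but no criterion.
- **Orientation**: forward search first, reverse-complement fallback on
  by default (`as_is` reproduces strict single-orientation behavior).
  Multiple anchor hits: the 5'-most wins.
- **Pseudocount**: 0 by default (no smoothing in the source analyses); a
  zero control count is an explicit error telling the user to set 0.5.
- **Ratios, not proportions, go into the t-test** — consistent with
  normalizing to the control before comparing arms; within a replicate
  the two differ only by the total-count factor, which the normalization
  cancels.
- **Calls compare arms per variant**; in library-on-library mode the
  experimental sample is the experimental TCR group's replicate ratios
  and the control sample pools the control groups' ratios for the same
  peptide.
- **Type-I calibration**: `null_screen_call_rate` simulates all-equal-
  affinity screens through the real normalization + call path; because a
  call needs both p < 0.05 (two-tailed) and fold change > 1, the null
  call rate sits near 2.5%, comfortably below the 5% bound asserted in
  the tests.
- **Determinism**: every stage is seeded (NumPy `SeedSequence` children);
  manifests store relative paths, outputs carry no timestamps, so two
  same-seed runs are byte-identical — asserted file-by-file in the tests.

## Limitations

Exact matching discards reads with any anchor error (~3.7% at 10⁻³ per
base for the 38 bp anchor) — acceptable at simulation depths, but real
screens with worse chemistry may prefer the Hamming-1 flag. The linear
strength→rate map is a modeling convenience; only its monotonicity is
load-bearing. Library diversity estimation is the plain clones ×
insertion-efficiency product and does not attempt to reconcile diversity
with theoretical NNK capacity.
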