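# matescreen

Analysis toolkit for **yeast-mating interaction screens of TCR–pMHC pairs**.

In these screens, MATa yeast display single-chain T-cell receptors (TCRs)
and MATalpha yeast display peptide–MHC complexes (pMHC). When a displayed
TCR binds its cognate pMHC, agglutination raises the mating rate, so
diploids are enriched for interacting pairs. Sequencing amplicons from the
selected diploid pool — the variable peptide (27 bp) or CDR3 (24 bp)
region behind a conserved anchor, or a Cre-loxP–juxtaposed pair of 15 bp
strain barcodes — reads out which library members were pulled through the
selection. `matescreen` turns those reads into interaction calls and
evaluates how well a screen performed:

- **read_extraction** — FASTQ quality filtering, exact-anchor payload
  extraction, barcode-pair deconvolution, and replicate × variant count
  tables with full read accounting.
- **enrichment_stats** — normalization of each variant's counts to a
  stop-codon internal control (a library member that cannot display its
  payload and therefore mates only at the background rate), per-replicate
  enrichment ratios, unpaired pooled-variance Student *t*-tests between
  experimental and control arms, and calls at fold change > 1, *p* < 0.05.
- **performance_eval** — confusion matrices against activation-based
  ground truth (cognate ⇔ mean T-cell activation > 10%), the
  validated-call rate, and ROC/AUC over enrichment ratios.
- **synthetic_screen** — a seeded forward simulator: per-pair mating rate
  `e = base + (max − base) · strength`, multinomial diploid sampling,
  vectorized amplicon read emission with substitution errors, and five
  ready-made screen presets with planted interactions, so the whole
  pipeline runs end to end with no external data.
- **screen_model** — strain registries, amplicon schemes, screen designs,
  NNK saturation-mutagenesis codon enumeration.

## Worked example

Simulate a peptide screen (an SL9 position-3 saturation library mated
against the 868 TCR, with A6/2C TCRs as the control arm) and run the whole
pipeline on it:

```sh
matescreen run-all --preset peptide_screen --seed 11 --out run/
```

```
called enriched: 3F, 3H, 3K, 3L, 3Q, 3W, SL9
sensitivity 66.7%, validated-call rate 85.7%
```

`run/enrichment.tsv` holds, per peptide variant, the mean normalized
ratio in each arm, the fold change, the *t*-test *p*-value and the call:

```
variant_id  fold_change  p_value   call
3*               1.0000   1.0000  False
3F              33.5836   0.0000   True
3H              31.2267   0.0000   True
...
```

The stop-codon control `3*` has ratio 1 by construction and is never
called. Seven variants pass both cutoffs. Scoring those calls against the
simulated coculture ground truth (`run/performance.json`) gives a
validated-call rate of 6/7 = 85.7% — six of the seven called peptides
really activate T cells (3K binds strongly enough to mate but does not
activate) — and a sensitivity of 6/9 = 66.7%, because three activating
variants (3I, 3M, 3V) mate too weakly or are too rare in the library to
enrich. The same stages are available separately as `matescreen simulate`,
`extract`, `score` and `evaluate`, and as plain Python functions.

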