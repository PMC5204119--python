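# Methods

## Scope

The package implements the dry-lab arm of an oestrogen-response lncRNA
screen as a testable pipeline: microarray DE calling with signal
calibration, qPCR concordance, gene-structure lineage classification from
multi-species alignments, regulatory-evidence tiering, and catalogue
intersection. All inputs are synthetic, produced by `lncestro.simdata`
together with a truth table, so every stage has an exact scoring target.
Wet-lab procedures (transfection, viability assays, imaging, FISH) and
externally trained predictors are out of scope; the ERE scan below is a
documented consensus-motif stand-in for a trained binding-site predictor,
and the interface accepts externally produced motif-hit tables instead.

## Synthetic study generator

### Array model

Per gene *g* and probe *k*, the latent control-channel log2 intensity is
`b_gk ~ U(8,12) + U(-0.5,0.5)`; the treated channel adds the planted log2
fold change. Noise is multiplicative lognormal — additive Gaussian
`N(0, noise_sd)` on the log2 scale, the standard model for two-channel
arrays — applied per measurement, and scanner compression is emulated as

```
observed = (latent · noise)^(1/γ_true)
```

so that the downstream correction `I → I^γ` recovers the truth when
`γ = γ_true`. Spike-in probes carry known nominal log2 ratios (default set
−2…+2, cycled over 20 probes); six non-DE control genes with reference
ratio 0 join them in the calibration set. The configured default exponent
is 1.125, the mild compression typical of this array generation.

### Study conditions

`SimConfig` defaults mirror the full study: 5586 genes with 7 probes each,
44 induced / 83 repressed, duplicate hybridisations, spliced fraction
43/127 and polyadenylated fraction 86/127, a 25-gene validation panel
(top-|FC| DE genes, mirroring a "top 25 most significant" selection) with a
planted 7/15/3 split of ChIP / motif-only / no regulatory evidence and
3 FOXA1 co-bound loci. `benchmark_config()` is the scaled benchmark used by
the tests, the analysis scripts and the acceptance script: 500 genes, 20
up / 30 down with |log2 FC| ∈ [1, 2.5], three replicates, log2 noise 0.25.
This size keeps a full run under a second while leaving every recovery
property (sensitivity, FDP, label recovery, tier partition) statistically
meaningful.

### Genome and elements

Each gene occupies a private locus slot (6 kb; 20 kb for panel genes so the
±5 kb evidence windows never touch a neighbour). Spliced genes (2–3 exons
of 200–400 bp, introns 300–700 bp) get canonical GT/AG intron ends planted
on the transcript strand; polyadenylated genes get one AATAAA or ATTAAA
whose end lies 10–30 nt upstream of the transcript 3′ end — inside the
40-nt search window the extractor uses (canonical signal position is
10–30 nt upstream of cleavage; the extraction window is deliberately a
little wider). The 40-nt window is rejection-sampled so it contains exactly
the planted hexamer (or none), and panel-gene windows are scrubbed of
accidental ERE consensus matches before one exact ERE is planted 2 kb
upstream of motif-positive genes. Scrubbing and the hexamer guarantee can
perturb each other, so the generator alternates the two fixes until stable
and fails loudly if it cannot (never observed in practice; the failure mode
would require an accidental hexamer fully inside a planted element).

### Alignments, peaks, partner catalogue

One MultiZ-style block per element (5 bp context each side) over a
six-species panel: human reference, two non-human primates, treeshrew, and
two outgroup mammals. Species conserved under the element's planted label
copy the human consensus (context bases mutated at 10% for realism);
non-conserved species either carry a single consensus-breaking substitution
(GT→GC, AG→GG, hexamer→…G) or are unaligned — encoded both as an omitted
row and as a gapped row, so the classifier's two unaligned paths are both
exercised. Peaks (ERα, plus FOXA1 on co-bound genes) are placed inside the
gene body of ChIP-tier genes; decoy CTCF peaks sit in non-panel slots. The
partner catalogue re-lists a random 40% of genes under new identifiers with
the first exon extended 50 bp (still overlapping) plus non-overlapping
single-exon decoys.

### Determinism

All randomness flows from one seed through named `SeedSequence` substreams
(truth, array, qPCR, genome, alignments, peaks, partner), so stages are
individually rerunnable and a rerun is byte-identical.

## Statistical choices

* **Probe-level test.** The default is a per-gene fixed-effect two-way
  ANOVA, log2 *I* ~ probe + probe:condition, testing each probe's
  treated−control contrast against the error variance pooled over the
  gene's probes and conditions (df = 2K(R−1)). With seven probes measuring
  one transcript, pooling is the natural reading of a gene-level
  ANOVA/linear-model analysis and gives the contrast 28 error df at three
  replicates instead of the ~4 of an isolated per-probe test — the
  difference between a workable and an underpowered unanimity rule at
  duplicate-scale replication. A per-probe Welch t-test (`probe_pvalue`,
  `probe_pvalues_welch`, CLI `--test welch`) is kept as the
  model-assumption-free alternative.
* **FDR.** Benjamini–Hochberg (statsmodels), verified in tests against an
  independent all-pairs step-up oracle. An empirical-null local-fdr
  estimator (probit transform, central-matching Gaussian null, kernel
  mixture density) is available as `local_fdr` for exploratory use; it is
  deliberately not the default because its null estimation is
  sample-dependent.
* **Fold-change threshold** is applied on the log2 scale, |log2 FC| ≥
  log2 1.4, symmetric in direction. Criteria are applied per probe (the
  unanimity criterion references per-probe significance); the gene-level
  fold change reported is the median probe log2 FC and is not separately
  thresholded.
* **Calibration** is a deterministic grid search over γ ∈ [0.5, 2.0] step
  0.005 (no gradient method; the objective is piecewise-smooth in the
  spike-in noise and the grid guarantees reproducibility). At zero noise
  the recovered γ equals the planted one to grid resolution; at log2 noise
  0.1 with 20 spike-ins it is within ±0.05.
* **qPCR** assumes 100% amplification efficiency (one cycle per doubling);
  no efficiency standard curves or multi-reference normalisation.
  "Validation" is operationalised as sign agreement plus a configurable
  magnitude floor (default log2 1.2) — direction-only confirmation is the
  floor-0 special case.
* **Pearson concordance** is computed on log2 fold changes and reported for
  all tested genes and for the validated subset; with fewer than three
  points or zero variance it is reported as missing (null), not as an
  error, in reports.

## Annotation choices

* **Splice elements** are emitted per intron end independently, only when
  the strand-adjusted dinucleotide is canonical (a GC–AG intron yields an
  acceptor but no donor), from isoforms with cDNA/EST support ≥ 2, and are
  deduplicated across isoforms sharing an intron.
* **polyA search window** is 40 nt upstream of the annotated 3′ end with
  the 3′-most canonical hexamer winning; either hexamer counts as conserved
  in another species even if it differs from the human variant, since both
  are canonical.
* **Presence/absence** in another genome is read directly from the
  alignment: a species is unaligned at an element if any element column
  lacks that species or is a gap; no liftover or synteny check beyond the
  alignment itself. Elements spanning multiple blocks are evaluated per
  base and require every base aligned.
* **Lineage classes** are assigned in precedence order: any non-primate
  non-treeshrew conservation → conserved beyond primates; otherwise
  treeshrew conservation → primate-plus-treeshrew; otherwise ≥1 non-human
  primate conserved → primate-specific (a `strict_all_primates` flag
  requires all primates); otherwise uninformative. "At least one non-human
  primate" is the default because alignment dropout in a single primate
  genome should not disqualify an otherwise primate-wide element.
* **ERE scan.** The consensus `GGTCAnnnTGACC` is its own reverse
  complement, so a match is inherently strand-symmetric; hits are reported
  once on the forward strand of the scanned sequence rather than twice.
  Repeat-masked (lowercase) and N bases never match. The mismatch budget is
  per half-site (default 1) because ERα half-site recognition is largely
  independent.
* **Windows and overlap.** Evidence windows are gene body ±5 kb, clamped at
  position 0, strand-independent (symmetric flanks); all interval overlap
  is half-open with a ≥1 bp criterion; the catalogue intersection exposes a
  configurable minimum-overlap flag.

## Known limitations

* The generator omits array spatial artefacts, dye bias, and
  sequence-dependent probe affinity; dye-swap correction is not modelled
  (the two dye channels are treated as the two conditions). Recovery rates
  on this benchmark therefore bound what the statistics can do under the
  stated noise model, not under real scanner physics.
* Alignment blocks are noise-free around the planted states: the 100%
  lineage-label recovery demonstrates the classifier's correctness, not
  robustness to alignment error.
* The ERE stand-in is a consensus scan, not a trained model; counts of
  motif-only loci on real sequence would differ from a published
  predictor's.
* Set-level fractions printed by the conservation summary (e.g. 33%
  primate-specific polyA signals at the default lineage mixture) reflect
  the configured lineage prior, not an empirical estimate for any genome.
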