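# lncestro

Analysis pipeline for oestrogen-responsive long non-coding RNAs (lncRNAs) in
breast cancer cells: probe-consensus microarray differential-expression (DE)
calling with spike-in signal calibration, TaqMan-style qPCR concordance,
evolutionary lineage classification of gene-structure elements from
multi-species alignments, regulatory-evidence tiering of lncRNA loci, and
strand-/exon-specific catalogue intersection — exercised end to end on
synthetic data with a machine-readable ground truth.

## The problem

Oestrogen (17β-oestradiol, E2) drives proliferation of ER-positive breast
cancer cells through the oestrogen receptor ERα. Custom two-channel
microarrays with **seven strand-specific 60-mer probes per lncRNA gene** can
interrogate the lncRNA transcriptome for E2-responsive genes, but the dry-lab
analysis chains together several non-trivial steps that deserve tested,
reusable code:

1. **Signal calibration.** Scanner compression makes observed fold changes
   underestimate true ones. Spike-in probes with known log2 ratios (plus
   control genes with known zero fold change) anchor a grid search for the
   exponent γ such that correcting intensities as *I* → *I*^γ best restores
   the reference ratios (least squares on log2 fold changes).
2. **Probe-consensus DE calling.** Per probe, the log2 fold change is
   mean log2(treated) − mean log2(control) over replicate hybridisations;
   significance comes from a per-gene fixed-effect ANOVA whose error term is
   pooled across the gene's probes; Benjamini–Hochberg converts p-values to
   q-values. A gene is called DE only if **all** its probes satisfy
   |FC| ≥ 1.4 and q ≤ 0.05 and agree in direction.
3. **qPCR validation.** ΔΔCt fold changes (log2 FC = −ΔΔCt at 100%
   efficiency) validate array calls by sign agreement plus a small magnitude
   floor; platform concordance is the Pearson correlation of log2 fold
   changes, over all tested genes and over the validated subset.
4. **Lineage classification.** A gene's "key structure elements" — canonical
   GT/AG splice-site dinucleotides and AATAAA/ATTAAA polyadenylation
   signals — are located in non-singleton transcript models and looked up in
   MultiZ-style alignment blocks. Per species an element is conserved,
   diverged, or unaligned; the pattern over the clade taxonomy classifies it
   as conserved beyond primates, primate-plus-treeshrew, primate-specific,
   or uninformative. Genes whose elements are all primate-specific have
   *completely primate-specific gene structures*.
5. **Regulatory tiering.** Each locus (gene body ± 5 kb) is scanned for
   ERα/FOXA1 ChIP peaks and for the palindromic oestrogen response element
   consensus `GGTCAnnnTGACC` (≤1 mismatch per 5-bp half-site; masked/N bases
   never match). ChIP evidence outranks motif-only evidence.
6. **Catalogue intersection.** Two gene catalogues match only on the same
   chromosome and strand with ≥1 bp exon-to-exon overlap.

Because the original array scans, alignments and peak sets are not
deposited, every input is generated by the `simdata` module with planted
truth (DE directions and effect sizes, per-element lineage labels, a
25-gene validation panel with a 7/15/3 evidence-tier split, a shared subset
with the partner catalogue), so that each stage's output can be scored
exactly.

## Worked example

Run the numbered analysis scripts (each is a thin driver over the library;
tables land in `results/`):

```bash
cd analysis
python 01_simulate_study.py --seed 1
python 02_differential_expression.py
python 03_qpcr_validation.py
python 04_structure_conservation.py
python 05_regulatory_evidence.py
python 06_catalogue_intersection.py
```

which prints, for seed 1:

```
seed 1: simulated 500 genes (20 up, 30 down), 806 structure elements, 25-gene validation panel
recovered exponent gamma = 1.070
called 19 up / 30 down of 500 genes (10%)
sensitivity 0.980, false discovery proportion 0.000
validated 25/25 panel genes (100%)
Pearson r (all tested)  = +0.995
extracted 806 elements; planted-label recovery 100.0%
evidence tiers over 25 panel genes: 7 ChIP / 15 motif-only / 3 neither
located 200 of 500 genes in the partner catalogue (planted: 200)
```

Reading the numbers: the simulation planted a compression exponent of 1.125
and the calibration recovers 1.07 under log2 noise 0.25 (exact at zero
noise); 49 of the 50 planted DE genes are recalled with no false calls; the
qPCR stage confirms the panel and the two platforms correlate near-perfectly
at this noise level; all 806 planted lineage labels, the 7/15/3 evidence
partition, and the planted 200-gene catalogue overlap are recovered exactly.

The same pipeline is available as a CLI (`lncestro run --config config.yaml
--outdir DIR`, with per-stage subcommands `simulate`, `de`, `validate`,
`conserve`, `regulatory`, `intersect`) and as a library
(`lncestro.pipeline.run_pipeline`).

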