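# accessprior

Prioritization of candidate transcription-factor (TF) regulators from
differential chromatin accessibility, with downstream target nomination and
knockout-transcriptome integration.

## The problem

ATAC-seq on sorted cell populations yields open-chromatin peaks whose
differential accessibility between conditions marks condition-specific
regulatory elements. When a tumor stem-cell population (e.g. glioma stem
cells, GSC) is contrasted both against its developmental counterpart
(neural stem/progenitor cells, NSPC) and against non-stem tumor cells, two
regulatory signatures emerge: a *developmentally shared* one and a
*tumor-specific* one. A TF whose binding motif is overrepresented in
exactly one of those signatures — and whose gene is itself highly and
differentially expressed in the tumor stem cells — is a strong candidate
intrinsic regulator. `accessprior` implements that decision layer as a
reusable, fully tested pipeline:

1. **Differential accessibility** — a negative-binomial (NB) Wald engine
   (median-of-ratios size factors, method-of-moments dispersions with
   empirical-Bayes shrinkage toward the central value, per-feature NB GLM
   with log link, Benjamini–Hochberg FDR) applied under two contrast
   designs: union-of-stem-populations vs. non-stem, and tumor-stem vs.
   everything else.
2. **Motif enrichment with an exclusivity filter** — exhaustive PWM
   scanning of peak sequences with *exact* score p-values (dynamic-
   programming convolution of integer-scaled log-odds columns),
   hypergeometric enrichment of each motif in a differential peak set
   against the all-peaks universe, and retention of motifs significant in
   exactly one of the two analyses.
3. **Expression gating** — the candidate motif's cognate TF gene must sit
   in the top expression quartile genome-wide and be differentially
   overexpressed (NB Wald, p < 0.05, positive fold change) in the tumor
   stem fraction.
4. **Regulatory-domain annotation and target nomination** — basal-plus-
   extension regulatory domains (5 kb upstream / 1 kb downstream of the
   TSS, extended to the nearest neighbouring basal domain or 1000 kb),
   nearest-TSS and promoter-window ([−5 kb, +3 kb]) rules, and ranking of
   strongly overexpressed genes (log2FC > 3) by the number of
   motif-bearing differential peaks in their domains.
5. **Knockout integration** — intersection of genes consistently
   downregulated in two knockout-vs-sham analyses (overall: q < 0.05;
   migratory: q < 0.05 and |log2FC| > 1) with the motif-annotated genes.
6. **ChIP-qPCR quantification** — efficiency-adjusted fold enrichment over
   IgG, `fold = E^(IA−S)_sample / E^(IA−S)_IgG`, where `E` is primer
   efficiency, `S` the sample Ct and `IA` the input-adjusted Ct
   (`IA = Ct_input − log_E(1/input_fraction)`); equals the textbook
   2^(−ΔΔCt) at E = 2.

A seeded synthetic-data module generates a miniature genome, classed peaks,
planted motif instances, expression and knockout count matrices, and qPCR
Ct tables with full ground truth, so the entire pipeline is testable
end-to-end without external data.

## Worked example

Generate a synthetic study with a planted tumor-exclusive motif and run the
discovery and knockout pipelines:

```bash
accessprior simulate --seed 7 --out simtest
accessprior discover --config simtest/pipeline_config.yaml
accessprior integrate-ko --config simtest/pipeline_config.yaml
accessprior chip --table simtest/chip_ct.csv
```

which prints:

```
selected candidate: motif_tumor -> g0560 (rank 1, percentile 96.8, p = 9.76e-08)
tables written to simtest/results
overall DE: 48  migratory DE: 41  downregulated overlap: 40  final (motif-annotated): 12
final targets: g0059, g0108, g0168, g0270, g0297, g0376, g0408, g0448, g0501, g0650, g0805, g0926
locus_id        n       mean    sem     p       tested
negative_control        6       0.906474        0.027196        0.0225164       True
target_locus_1  6       7.68442 0.43678 3.03553e-07     True
target_locus_2  6       8.2727  0.365609        7.2421e-08      True
```

Reading the output: of six motifs scanned, only `motif_tumor` is
exclusively enriched in the tumor-specific peak set (enrichment rank 1) and
its cognate gene `g0560` passes both expression gates (96.8th percentile,
overexpression p = 9.8 × 10⁻⁸) — exactly the TF the generator planted. The
knockout integration recovers all 12 planted motif-bearing knockout
targets. The ChIP summary inverts the synthetic Ct tables to a ~8-fold
enrichment at the two true binding loci (planted fold: 8) and ~0.9 at the
negative-control locus (planted fold: 1). Every intermediate table
(differential peaks, motif hits, enrichment, exclusivity verdicts,
candidate audit trail, nominated targets, Venn membership) is written under
`simtest/results/` with a deterministic run manifest.

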