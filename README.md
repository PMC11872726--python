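# bcrpipe

Analysis toolkit for B-cell receptor (BCR) heavy-chain repertoires from
AIRR-seq experiments, built for case/control cohort studies — for example
comparing patients with myalgic encephalomyelitis/chronic fatigue syndrome
(ME/CFS, mild/moderate and severe), multiple-sclerosis controls and healthy
controls. It takes AIRR Rearrangement TSVs (one row per UMI-consensus
transcript with V/D/J calls, constant region, junction and germline
alignment) plus a subject→group metadata table, and runs the complete
analysis a repertoire study needs:

- **QC**: drop non-productive transcripts; exclude subjects with fewer
  than 1,500 productive UMIs; flag single-gene-dominated repertoires.
- **Diversity/clonality**: Gini index `G = Σᵢ (2i − S − 1) P₍ᵢ₎ / S` and
  Shannon entropy `H = −Σᵢ Pᵢ ln Pᵢ` on unique CDR3s, rarefied to 1,000
  UMIs and averaged over 1,000 iterations; composition bins (top 1, 2–10,
  11–100, 101+ clones).
- **Clonotyping**: cross-subject clustering of records sharing V gene,
  J gene and CDR3 length with CDR3s within 0.15 substitutions/aa
  (single linkage ≡ connected components of the threshold graph), network
  export (GraphML/GEXF/edge list), and the high-IGHV3-30 subset
  comparison at matched depth.
- **Features**: UMI-weighted V/D/J gene usage, somatic hypermutation
  (mismatches to the aligned germline, substitutions only), N-glycosylation
  sequons (N-X-S/T, X ≠ P) in the translated variable region, IgM/IgG
  composition.
- **Group statistics**: Mann–Whitney U + Bonferroni for usage,
  Kruskal–Wallis + Dunn + Holm–Šidák for multi-group comparisons, Cohen's
  d, between-group median-usage R², PCA, and a six-feature logistic
  classifier (IGHV3-30, IGHV3-30-3, IGHV3-49, IGHV1-3, IGHD1-26, IGHJ6)
  with a stratified 60/40 split and ROC/AUC.
- **Synthetic cohorts**: a generator emitting fully annotated AIRR tables
  with a ground-truth ledger — Dirichlet between-subject usage variation,
  heavy-tailed clone sizes, isotype-conditional hypermutation, and planted
  group effects calibrated so the realized Cohen's d matches the
  configured value (default: a 0.70 SD shift of IGHV3-30 usage in the
  mild/moderate group).

## Worked example

Simulate a study-sized cohort (110 subjects: 21 HC, 25 ME_mm, 36 ME_sa,
28 MS) and run the whole pipeline with one call:

```python
from bcrpipe import simulate, pipeline

repertoires, ledger = simulate.simulate_cohort(simulate.default_config(seed=13))
summary = pipeline.run_pipeline(repertoires, "out/", seed=13)
```

or from the shell (`bcrpipe run-all --seed 13 --out out/`). On seed 13
this prints, among other fields:

```
n_subjects_included                110
median_shannon                     6.52
median_gini                        0.178
ighv3_30_cohens_d_memm_vs_hc       1.05
ighv3_30_p_adjusted_memm_vs_hc     0.0006
median_usage_r2.ME_mm_vs_HC        0.936
classifier_ME_mm_auc_train         0.80
classifier_ME_mm_auc_test          0.75
```

Reading these: all 110 subjects clear the 1,500-UMI depth filter; a median
repertoire rarefied to 1,000 UMIs carries ~6.5 nats of CDR3 entropy and a
Gini of ~0.18 (polyclonal, mildly skewed). The planted IGHV3-30 shift —
calibrated so its expected Cohen's d is 0.70 — comes out at 1.05 on this
particular cohort (single-cohort estimates scatter around 0.70 with a
Monte-Carlo SD of ≈0.3; the 500-seed recovery experiment in the test suite
pins the mean) and the Bonferroni-corrected Mann–Whitney test is clearly
significant. Global V-gene usage stays highly correlated between groups
(R² ≈ 0.94) — the effect is confined to one gene, not a repertoire-wide
distortion. The six-feature classifier fits the training split (AUC 0.80)
and, on this strong-effect draw, transfers moderately to held-out subjects
(AUC 0.75). Per-stage tables (QC report, diversity, clonotypes, usage
matrices, SHM summaries, test results, ROC points, network exports) land
in `out/`.

To analyse real data instead, point the same pipeline at files:

```python
pipeline.run_pipeline_from_files("rearrangements.tsv", "metadata.tsv", "out/")
```

## Layout

```
src/bcrpipe/
  io.py           AIRR TSV read/write, QC filters, allele stripping
  diversity.py    Gini/Shannon, rarefaction, composition bins
  clonotyping.py  clonotype clustering, subset selection, networks
  features.py     gene usage, SHM, sequons, isotypes
  stats.py        tests, corrections, effect sizes, PCA, classifier
  simulate.py     synthetic cohort generator + truth ledger
  experiments.py  Monte-Carlo recovery/calibration studies
  pipeline.py     end-to-end assembly
  cli.py          `bcrpipe` command-line interface
```

See `docs/methods.md` for the models, defaults and numerical conventions.
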