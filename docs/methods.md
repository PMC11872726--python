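# Methods

`bcrpipe` analyses B-cell receptor (BCR) heavy-chain repertoires from
AIRR-format rearrangement tables and ships a synthetic cohort generator that
reproduces the statistical structure those analyses assume. This note
records the models, the defaults and why they were chosen, the numerical
conventions, and the limits of what the synthetic experiments demonstrate.

## Quality control

Records are one UMI-consensus transcript each; `duplicate_count` is the UMI
weight and every abundance computation is UMI-weighted. Non-productive
transcripts are removed first. A subject is excluded when their productive
UMI total is *strictly below* 1,500 — a subject with exactly 1,500 is kept.
Depth counts productive UMIs only, which makes the productive and depth
filters commute. A repertoire in which any single V gene exceeds 90% of
productive UMIs (configurable) is flagged for manual review, never
auto-excluded: single-subject dominance of, say, IGHV4-34 can reflect a
genuinely aberrant repertoire, but that judgement is an analyst's call.

Multi-call V/D/J assignments (`IGHV4-34*01,IGHV4-34*02`) resolve to the
first listed call; the `*NN` allele suffix is stripped for all gene-level
analyses, while duplicate-gene suffixes (`IGHV3-30-3`) are part of the gene
name and retained.

## Diversity and clonality

Species are unique CDR3 amino-acid sequences (or pre-clustered clonotypes
for network subsets). With proportions `P_(i)` sorted ascending over the
`S` species present:

- Gini index `G = Σ_i (2i − S − 1) P_(i) / S`, 0 for a perfectly even
  repertoire, approaching `(S−1)/S` under complete dominance;
- Shannon entropy `H = −Σ_i P_i ln P_i` in nats, maximal at `ln S`.

Because both depend on depth, each repertoire is rarefied to 1,000 UMIs
drawn without replacement, and indices are averaged over 1,000 iterations.
A repertoire at exactly the rarefaction depth short-circuits to the exact
single-pass value. Repertoires below the depth raise an error rather than
being skipped silently — upstream QC guarantees 1,500+. Composition bins
(top 1, 2–10, 11–100, 101+ CDR3s) break abundance ties lexicographically by
CDR3 string so outputs are deterministic.

## Clonotyping

A clonotype is the standard heavy-chain definition: identical V gene,
J gene and CDR3 length, with CDR3s within 0.15 substitutions per amino acid.
Since lengths are equal inside a candidate group, the edit distance reduces
to normalized Hamming distance. Clustering is single-linkage agglomeration
cut at the threshold. Single linkage was chosen because at a fixed cut it
is exactly the connected components of the ≤-threshold graph — the usual
clonotype semantics — and that equivalence provides an exact independent
oracle for the test suite. Clustering pools all subjects so shared
clonotypes are visible. Clonotype ids are assigned in (partition key,
smallest member id) order, making exports reproducible and diffable.

Networks have one node per record and clique edges within a clonotype;
clonotypes above 50 members fall back to a star on the most abundant member
(recorded in the export) to avoid quadratic edge counts. The high-usage
subset analysis selects case subjects whose IGHV3-30 usage exceeds the
control mean by more than one control SD (n−1 denominator, strict
inequality), samples the same number of controls at random under the run
seed, and depth-matches both groups by drawing the same number of UMIs
without replacement. When the gene-restricted subset holds fewer UMIs than
the 5,000 default, the depth is lowered to the largest common value —
desk-scale synthetic cohorts are far shallower than real libraries.

## Per-record features

Somatic hypermutation is the count of aligned positions where sequence and
germline both carry unambiguous nucleotides and differ; gap and ambiguity
positions are excluded, so the count covers substitutions only. Mutation
frequency divides by compared positions, not raw length — identical for
clean sequences, and it prevents frequencies above 1 when ambiguity codes
appear. N-glycosylation sequons are N-X-S/T with X any standard amino acid
except proline, counted with overlaps, over the full in-frame translation;
a flag restricts scanning to the junction. Productive records whose
translation contains an internal stop are excluded from sequon counting
with a logged warning. Isotypes map by constant-region prefix to IgM / IgG
(the assay covers only these); anything else is reported as "other" and
excluded from IgM:IgG ratios.

## Group statistics and classifier

Pairwise usage comparisons use two-sided Mann-Whitney U — exact when the
pooled sample is ≤ 20 without ties, otherwise the normal approximation with
tie and continuity correction — with Bonferroni adjustment. The family
size defaults to the number of (gene, comparison) pairs in the call; the
targeted six-gene replication preset uses m = 2 (the two disease-vs-control
comparisons per gene). Multi-group comparisons use Kruskal–Wallis with tie
correction and Dunn's z on pooled mean ranks, Holm–Šidák adjusted.
Effect sizes are Cohen's d with pooled n−1 SD.

The classifier follows the published protocol: six gene-usage features
(IGHV3-30, IGHV3-30-3, IGHV3-49, IGHV1-3, IGHD1-26, IGHJ6), a stratified
60/40 split (round-half-even per label, repaired to the overall 60% target,
at least one subject per label per side), unregularized maximum-likelihood
logistic regression, and AUC on both splits with ties counted ½. Features
enter the model unscaled — they are commensurate proportions — but are
standardized for PCA, whose component signs follow a fixed
largest-loading-positive convention. Perfectly separable training data
trigger a flagged small-ridge (1e-6) fallback. One prose mention of
"IGHV3-39" in the source literature is treated as a typo for IGHV3-49,
which is what the analysis plan and figures use.

## Synthetic cohorts

The generator emits fully annotated AIRR tables plus a truth ledger that
reconciles exactly with the emitted records (record counts, isotype UMIs,
per-record mutation counts, sequon totals).

**Germline panel.** A deterministic toy reference: 34 IGHV, 6 IGHD and 6
IGHJ genes under real gene names, built from random stop-free codons with
germline sequons scrubbed (sequons are rare in real germline V genes and
arise mostly through hypermutation). Sequences are frame 0 from position 1.
Every downstream analysis depends only on names and mismatch counts, so toy
sequences are sufficient; nothing is downloaded.

**Usage.** Each subject's V/D/J usage is a Dirichlet perturbation of
population frequencies (IGHV3-23 highest; the panel includes rare genes
down to ~0.3%). The concentration default of 300 and the clone-size law
(discrete power law, tail exponent 2.7, drawn until the subject's UMI
target is met exactly) were set together so that a default cohort
reproduces the global structure reported for real cohorts: group-median
V-gene usage correlating at R² ≈ 0.95–0.98 between groups, with
substantial subject-to-subject composition spread and occasional large
clones. At desk-scale depth (~2,000–3,200 UMIs per subject) the
clone-weighting noise floor (E[Σw²] ≈ 0.005) keeps R² slightly below the
0.98–0.99 seen at real sequencing depth; the same generator at higher depth
closes that gap.

**Planted case/control effect.** The effect group's (default ME_mm)
IGHV3-30 base frequency is shifted before the Dirichlet draw. The shift is
calibrated empirically: pseudo-cohorts of *measured* usage (Beta marginal
of the Dirichlet thinned through a drawn clone-size vector — the exact
distribution of UMI-weighted usage, without record emission) are drawn at
the configured group sizes, and the shift is rescaled by fixed point until
the mean realized sample Cohen's d equals the configured 0.70. Calibrating
on the sample statistic matters: heavy-tailed clone weighting biases
small-sample SDs low, which a population-SD calibration misses by ~15%.
The calibration RNG is fixed and results are cached per configuration, so
cohorts remain bit-reproducible.

**Isotypes and SHM.** Each subject's IgM fraction is Beta-distributed
around the group mean (concentration 30, i.e. ±9 percentage points SD),
giving the borderline-significance behaviour seen in real group
comparisons rather than an implausibly clean separation. Group means
default to HC 0.55, ME_mm 0.65, ME_sa 0.58, MS 0.50. Isotype is assigned
per clone. Mutation counts are zero-inflated Poisson for IgM (75% zeros,
mean 4 among mutated — naive-dominated) and negative binomial for IgG
(mean 15, shape 5 — overdispersed with positive mean), applied as exact-k
substitutions confined to the V and J segments; CDR3 variation within a
clone is modelled separately as a small per-residue substitution process
(rate 0.015) on members, so clonotype clustering has realistic
near-identical structure to find. With per-mutation probability 0.01 a
mutated record gains a planted sequon at a random in-frame V position.
Ledger mutation counts are re-measured against the emitted germline after
all edits, so reconciliation is exact even when a planted sequon overwrites
a mutated site.

**Depth and attrition.** Per-subject depth is uniform on 2,000–3,200
productive UMIs by default — a desk-scale choice, not an estimate of real
library depth. Non-productive singletons are added at ~2% on top.
`study_attrition_config` plants 14 extra shallow subjects (600–1,400 UMIs)
across groups so the 124 → 110 QC attrition pattern is exercised.

**What the synthetic experiments do and do not show.** They verify the
analysis stack end to end: that planted effects of known size are recovered
through record emission, usage measurement and effect estimation; that the
tests are calibrated under the null; and that every stage is deterministic
and schema-stable. They do not validate biological realism of CDR3
sequence content, hotspot-biased hypermutation, indels, light chains,
class-switch lineages, or allele-level variation — all explicitly out of
scope.

## Monte-Carlo experiment sizes

The recovery study simulates the two groups the replication test involves
(21 HC vs 25 ME_mm — the study's sizes) at 1,000–1,600 UMIs per subject,
500 effect cohorts and 300 matched null cohorts; simulating the other two
groups would not enter the two-group statistic. Type-I error is estimated
from the first 2,000 per-gene Mann-Whitney p-values pooled over null
cohorts and compared with the binomial 99% interval around α = 0.05. The
acceptance script runs a lighter replicate (150/100 cohorts) plus a full
default-cohort pipeline.

## Known limitations

- The Gini/Shannon resampling loop is exact but serial; very deep
  repertoires are better subsampled upstream.
- The edge-capped star fallback changes network topology (not membership)
  for clonotypes above the cap; degree-based statistics on such graphs
  must account for the flag.
- The empirical effect calibration adds ~1–2 s (cached) the first time a
  configuration with a non-zero planted effect is simulated.
- Dunn's test uses the large-sample normal approximation; for very small
  groups the pairwise p-values are approximate even though Kruskal–Wallis
  itself is exact-tie-corrected.
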