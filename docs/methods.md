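# Methods

`repseqx` analyses bulk AIRR-seq clonotype tables (TCRβ or BCR heavy chain)
for a two-group case–control design — here benign versus malignant ovarian
tumours — and ships a synthetic cohort generator so the whole pipeline is
testable end to end without patient data. This note records the models,
parameter choices and numerical conventions, and what the synthetic studies
do and do not demonstrate.

## Clonotype model and identity

A clonotype is keyed by `(V gene, CDR3 nucleotide sequence, J gene)`
throughout, except public-clonotype sharing and differential clonotype
calling, which use the CDR3 amino-acid sequence alone (the sharing analysis
concerns convergent amino-acid clones; the key is configurable back to
V+CDR3nt+J). Allele suffixes (`*01`) are stripped to gene-level names.
Frequencies are always recomputed from read counts — correction,
decontamination and rarefaction all invalidate stored frequencies.

## Preprocessing

Four steps, in fixed order:

1. **Correct** (error-clonotype merging). A child merges into a parent when
   they share V and J genes, their equal-length CDR3s differ at ≤ 2
   nucleotides (Hamming distance; indel variants are never merged), and
   child/parent count ratio is **strictly** < 0.05 on pre-merge counts.
   Children attach to the single highest-count eligible parent, ties broken
   lexicographically by CDR3. Within one pass a clone that is itself being
   absorbed receives no children; passes repeat to a fixpoint. This makes
   the merge deterministic and idempotent.
2. **Decontaminate**. A clonotype is dropped from a sample when any other
   sample carries the identical key at ≥ 20-fold its relative frequency
   (boundary **inclusive**). Frequencies, not raw counts, are compared,
   because depths differ before rarefaction. Both this threshold and the
   0.05 merge ratio are evaluated in exact rational arithmetic (integer
   cross-multiplication), so boundary cases are decided by the stated
   inequality rather than floating-point rounding.
3. **FilterNonFunction**. Clones with a stop codon (`*`) in the CDR3
   amino-acid sequence or an out-of-frame junction (length not divisible by
   3) are removed.
4. **DownSample**. Every sample is rarefied to the minimum per-sample depth
   (or an explicit depth) by drawing reads without replacement — per-clone
   counts are multivariate hypergeometric — under a fixed seed.

## Diversity statistics

With relative abundances $x_i$ (n clones, $\bar x = 1/n$):

- Gini coefficient $G = \sum_i \sum_j |x_i - x_j| \,/\, (2 n^2 \bar x)$,
  evaluated via the sorted closed form $\sum_i (2i - n - 1) x_{(i)} / (n
  \sum_i x_i)$; 0 = perfectly even, → 1 under extreme dominance.
- Chao1 $= S_{obs} + a_1(a_1 - 1) / (2 (a_2 + 1))$ with singleton count
  $a_1$ and doubleton count $a_2$ — the bias-corrected form, finite at
  $a_2 = 0$ and equal to $S_{obs}$ when $a_1 \le 1$.
- Inverse Simpson $= 1 / \sum_i p_i^2$, the effective number of equally
  abundant clones.

Group contrasts use the two-sided Wilcoxon–Mann–Whitney test: exact null
distribution when both groups have ≤ 12 observations and no ties (the
cohort sizes of interest, 12 vs 8, sit inside this range), otherwise the
normal approximation with tie correction. Age trends are Pearson
correlations fitted overall and per group. All three indices are verified
against literal brute-force evaluations (double loop, direct tallies,
direct sum of squares) to 1e-12, and Chao1/inverse Simpson additionally
against scikit-bio.

## Overlap, differential clonotypes, motifs

Sharing matrices count exact key-set intersections between samples;
off-diagonal pairs are partitioned into within-malignant, within-benign and
between, compared by rank test.

Differential clonotype calling works on counts: clones present in ≥ 3
samples (configurable) are transformed to log2 counts-per-million with a
0.5 pseudocount against full library sizes, `log2((c + 0.5)/(L + 1)·1e6)`,
then tested with a moderated two-sample t-statistic: the per-clone pooled
variance (residual df $d$) is shrunk toward the mean per-clone variance
with df-weighted blending, $\tilde s^2 = (d s^2 + d_0 s_0^2)/(d + d_0)$,
and the statistic referred to $t_{d + d_0}$. The prior df $d_0$ defaults to
$d$; $d_0 = 0$ recovers the ordinary pooled t exactly (tested against
scipy). Reported clones satisfy p < 0.01 and |log2 FC| ≥ 2, uncorrected for
multiple testing — a deliberate mirror of the exploratory design; the
permutation studies confirm the false-positive rate stays at or below
nominal under these thresholds.

Motif matrices tally amino-acid frequencies per 1-based CDR3 position over
the sequences long enough to cover each position (columns normalised to 1);
the dominant k-mer over a fixed window (default positions 6–9) is the most
frequent contiguous substring among covering sequences, ties broken
lexicographically.

## Gene usage

Usage matrices give each sample's fractional use of every V, J or V-J
segment in the cohort-wide universe (absent segments are 0, keeping vectors
fixed-length). Default weighting is by reads (clone-frequency weighted);
clonotype weighting is available. Per-segment group tests are uncorrected
Mann–Whitney at α = 0.05; inter-sample Spearman correlations of usage
vectors are partitioned by group pairing.

## Clonal-space homeostasis

Each clone's frequency falls in one of five bins — Rare (< 1e-5), Small
(1e-5–1e-4), Medium (1e-4–1e-3), Large (1e-3–1e-2), Hyperexpanded
(> 1e-2) — and the bin mass is the summed frequency of its clones, so
masses partition 1. Bins are `[lower, upper)` with the last bin closed at
1: a clone at exactly 1e-4 is Medium. (Strict inequalities on both sides
would orphan boundary values; this half-open convention is the minimal fix
and is recorded in the output metadata.) Which bins are populated depends
on depth: frequencies below 1/depth are unobservable, so rarefied synthetic
cohorts at ~3×10⁴ reads leave the Rare bin empty while the group contrast
(malignant mass shifted into Large/Hyperexpanded) is unaffected.

## Screening model

Features are V-J usage fractions. Pairs with uncorrected Mann–Whitney
p < 0.01 are selected, columns are mean-centred without scaling, samples
split 70/30 stratified by group (per class `round(0.7·n)` to training — a
12/8 cohort yields exactly 8+6 training and 4+2 test), stratified 3-fold CV
runs on the training portion, and three classifiers are fit at pinned
defaults: logistic regression (L2, C = 1), random forest (500 trees,
seeded), RBF SVM (C = 1, gamma = scale, decision-function scores).
Performance is ROC-AUC per fold, on the held-out test set, and averaged
across the three models.

By default feature selection and centring see training samples only; a
perturbation probe verifies that changing test-sample values changes
nothing about the fitted models. `paper_mode=True` instead selects features
on all samples before splitting — the order the original analysis appears
to have used — and is provided for fidelity comparison only, since it leaks
selection information into the test AUC.

PCA on the selected, centred features uses orthonormal loadings with
non-increasing component variances; full-rank coordinates reproduce the
centred input.

## Synthetic cohort generator

The generator emulates the statistical structure the group comparisons
rest on. Defaults (the study conditions; one global RNG seeded per run,
sub-steps drawing in documented order, so output is byte-reproducible):

| parameter | default | role |
|---|---|---|
| cohort | 12 benign / 8 malignant | the case–control design |
| base richness | 5000 vs 1500 clones | malignant richness loss |
| Zipf exponent | 0.8 vs 1.2 (±0.05 jitter) | heavier malignant tail |
| forced hyper-expanded clones | 5 per malignant sample at freq 0.012–0.05 | clonal dominance |
| depth | 30–60k reads/sample | desk-scale sequencing depth |
| V/J universe | 25 TRBV × 13 TRBJ | gene-usage axes |
| usage shifts | 4 pairs ×5 up, 2 pairs ×0.2 down in malignant | differential V-J usage |
| usage dispersion (Dirichlet conc.) | 1500 benign / 400 malignant | higher malignant heterogeneity |
| public pool | 800 clonotypes; 8% benign / 3% malignant draw | benign share more clones |
| error rate | 2% of reads as 1–2-nt variants, ratio < 0.05 | exercises Correct |
| contamination | 0.2% of clones at ≥ 20–80× donor/recipient ratio | exercises Decontaminate |
| non-functional rate | 5% of clones (stop or frameshift) | exercises FilterNonFunction |
| ages | benign U(25, 60), malignant U(40, 70) | older malignant patients |
| age-richness slope | −0.02 per year (log scale) | diversity declines with age |

CDR3s are built from the 61 sense codons, 8–20 codons (24–60 nt) long;
non-functional clones are created explicitly by stop-codon substitution or
single-nucleotide deletion. Forced hyper-expanded clones carry the
malignant-enriched V-J pairs (round-robin), tying clonal dominance to the
usage shift — the antigen-driven-expansion mechanism the design emulates —
which also makes the planted pairs recoverable despite the dominance noise
that read-weighted usage suffers in low-diversity repertoires. Every
injected truth (variant→parent map, contaminant list with realised fold
ratios, non-functional keys, group profiles, ages) is returned in a ledger.

What the generator does **not** model: biophysically realistic VDJ
recombination and junctional biology, somatic hypermutation lineages,
isotypes, sequencing depths of 10⁷ reads (desk-scale depths leave the
Rare/Small homeostasis bins sparsely populated), batch effects, or any
cohort-specific biology. Passing recovery studies therefore demonstrate
that the pipeline's statistics detect the *kinds* of structure claimed —
not that real-cohort effect sizes or the published headline numbers
(reproducible only from the deposited accession) are recovered.

The no-effect configuration (`null_config`) sets both groups to identical
parameters at reduced scale (richness 1000, depth 8–15k, no shifts, no
forced expansions, shared age range, zero age slope) and backs the
calibration studies: the Wilcoxon rejection rate at α = 0.05 must sit
inside the binomial 95% CI of 0.05, and the age-richness correlation must
centre on 0. Fresh independent-age cohorts are used for the age null
because permuting ages within a fixed cohort has E[r] = −1/(n−1) ≠ 0, which
would bias the check at these replicate counts.

## Validation studies and problem sizes

`repseqx.validation` packages the replicated studies run by the test suite
and `scripts/acceptance.py`: formula parity on 1000 random abundance
vectors; preprocessing recovery on 5 ledgered cohorts plus a 2000-draw
rarefaction-expectation check; 50 default-condition replicates for
direction-of-effect, usage-shift sensitivity and screening AUC; 200
no-effect replicates for null calibration; 100 label permutations for the
differential false-positive rates; 25 permutations for the null-AUC check;
and a 500-sequence motif-planting recovery. These sizes balance
Monte-Carlo error (binomial SE ≈ 0.03–0.04 at 50 replicates) against a
single-CPU desk-scale budget.

## Known limitations

- The moderated-t variance prior (mean of per-clone variances, prior df =
  residual df) is a deliberately simple limma-style empirical-Bayes
  moderation; coefficient-level parity with limma/voom is not claimed, only
  calibration and threshold/sign behaviour.
- Decontamination can legitimately remove public clonotypes whose
  frequencies differ ≥ 20-fold between samples; with heavy-tailed
  abundances this is common and mirrors the real filter's behaviour on
  shared clones.
- The exact Mann–Whitney cutoff (both groups ≤ 12) is tuned to this
  cohort scale; larger cohorts silently switch to the tie-corrected normal
  approximation.
- `paper_mode` feature selection is intentionally leaky and must not be
  used for performance claims.
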