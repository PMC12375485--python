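# repseqx

Immune-repertoire (AIRR-seq) analysis for two-group case–control designs —
built around the question of whether peripheral-blood TCRβ/BCR-heavy
repertoire features separate benign from malignant ovarian tumours.
`repseqx` takes per-sample clonotype tables (AIRR Rearrangement TSV: CDR3
nucleotide/amino-acid sequence, V/J calls, read count) plus a sample
metadata table, and provides:

- **Preprocessing** — the four clonotype-table refinement steps: merge
  sequencing-error clonotypes (≤ 2 nt, abundance ratio < 0.05, same V/J),
  remove cross-sample contaminants (≥ 20-fold frequency in another
  sample), drop non-functional clones (stop codon / out-of-frame), and
  rarefy all samples to a common depth (hypergeometric subsampling).
- **Diversity** — per-sample unique clonotypes, Gini coefficient
  `G = ΣᵢΣⱼ|xᵢ−xⱼ| / (2n²x̄)`, bias-corrected Chao1
  `S_obs + a₁(a₁−1)/(2(a₂+1))`, inverse Simpson `1/Σpᵢ²`; group contrasts
  by two-sided Wilcoxon–Mann–Whitney (exact at these cohort sizes) and
  Pearson age correlations per group and overall.
- **Overlap & differential clonotypes** — shared-CDR3 count matrices,
  within/between-group sharing comparison, differential clonotype calling
  (log2 CPM, moderated t, p < 0.01 and |log2FC| ≥ 2, uncorrected), and
  CDR3 positional motif matrices with dominant window k-mer.
- **Gene usage** — V / J / V-J usage matrices (read- or
  clonotype-weighted), per-segment Wilcoxon tests, inter-sample Spearman
  usage correlations by group pairing.
- **Clonal-space homeostasis** — frequency mass in Rare / Small / Medium /
  Large / Hyperexpanded bins with group tests.
- **Screening model** — V-J-usage feature selection (p < 0.01), stratified
  70/30 split and 3-fold CV, logistic regression / random forest / RBF SVM
  at pinned defaults, ROC-AUC reporting and PCA projection, with strict
  train-only feature selection by default.
- **Synthetic cohorts** — a seeded generator producing AIRR TSVs with
  heavy-tailed clone abundances, group-dependent expansion, shifted V-J
  usage, public clonotypes, planted sequencing errors, contaminants and
  non-functional clones — every injected truth returned in a ledger, so
  the whole pipeline is testable without patient data.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Run the full pipeline on a bundled synthetic cohort (12 benign, 8
malignant):

```bash
repseqx run --config examples/pipeline.yaml     # or, equivalently, in Python:
```

```python
from repseqx.pipeline import PipelineConfig, run_pipeline
run_pipeline(PipelineConfig(out_dir="demo_out", seed=42))
```

With seed 42 this simulates the cohort, preprocesses it (2437 error
variants merged, 529 contaminant records removed, 3497 non-functional
clones dropped, every sample rarefied to 31 951 reads) and writes one
TSV/JSON per stage. `demo_out/diversity.tsv` starts:

```
sample_id  group     age   unique_clonotypes   gini     chao1      inv_simpson
B01        benign    36.3  4875               0.659    5523.1     177.3
B02        benign    42.3  4438               0.659    4911.5     173.4
B03        benign    52.4  3897               0.600    4040.8     290.3
```

and `demo_out/diversity_tests.json` reports the group comparisons: all
four metrics separate the groups at the exact-test floor for 12-vs-8
samples (p = 1.59e-05 — malignant repertoires have fewer unique clones,
higher Gini, lower Chao1 and lower inverse Simpson), and the age
correlation of unique clonotypes is negative overall (r = −0.76,
p = 9.8e-05). The screening stage selects 94 differential V-J pairs on the
training samples and reaches test AUC 1.0 for all three models on this
strongly separated synthetic cohort; `demo_out/homeostasis_tests.json`
shows the Hyperexpanded-bin mass higher in the malignant group
(p = 1.59e-05).

Individual stages are also exposed as subcommands
(`repseqx simulate|preprocess|diversity|overlap|differential|motif|usage|homeostasis|screen`),
each reading/writing plain TSV/JSON.

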