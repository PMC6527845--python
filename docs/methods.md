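# Methods

This note documents the models and procedures implemented in
`cmapminer`, the assumptions behind them, the constants a user may want
to change, and what the synthetic-data tests do and do not demonstrate.

## Literature scoring

Abstracts are segmented into sentences by a deterministic rule:
sentence-terminal punctuation followed by whitespace and an uppercase
letter or digit ends a sentence, except after tokens in a packaged,
user-extensible abbreviation list (`e.g.`, `vs.`, `al.`, …) or
single-initial tokens (`J.`). A title, when present, is treated as
sentence 0. Term matching is dictionary lookup: case-insensitive,
delimited by non-alphanumeric characters (so `EGFR-positive` matches
`EGFR`), longest synonym wins at each position and shorter overlapping
matches are suppressed. A synonym shared by several canonical entities
produces one hit per entity — ambiguity is preserved for the curator
rather than resolved by the machine.

Per abstract, sentences are classified exclusively with respect to the
disease: a sentence with a disease term and a gene-or-drug term is a
co-occurrence sentence (N_c); with a disease term only, disease-context
(N_hnc); gene-only and drug-only counts (N_gene, N_drug) require the
absence of a disease term but tolerate other categories, since a strict
"only this category" reading would zero most counts in practice. The
flags (FLAG_gene, FLAG_drug, FLAG_hnc) record category presence
anywhere in the abstract; the disease flag's definition is a
convention and can be switched to "a counted disease sentence exists"
(`flag_hnc_from_any_disease=False`).

The association scores are weighted sums of these counts (see README).
Weights are not identifiable from data — they encode how much one
co-mention is worth relative to context sentences — and default to
w_c = 10, w_hnc = w_gene = w_drug = 1: the co-occurrence sentence is
the evidence of interest and the context terms only break ties among
candidates with equal co-mention counts. Only the relative order of
scores matters for ranking; scaling all weights rescales all scores.
The candidate threshold defaults to min_score = 1 (anything with any
flagged context survives to curation — the pipeline is deliberately
recall-oriented because a human reviews the output), applied per entity
by default or per abstract (`threshold_level="abstract"`). An optional
fourth lexicon category, `event`, is highlighted in curation HTML but
never scored.

## Probe reannotation

Input is BLAT's 21-column PSL (0-based half-open coordinates, kept
throughout; GTF input is converted at the parser boundary). Alignment
filtering keeps records with mismatches ≤ 1, gaps ≤ 0 and similarity
strictly greater than 90, where similarity is defined as
100·matches/query_size — the simplest score monotone in alignment
quality; any other 0–100 definition can be supplied as a callable.

Affymetrix probe sets collapse to one synthetic feature per locus: the
set is retained iff at least 3 perfectly matching probes (no
mismatches, no gaps, same chromosome and strand) form a run whose
consecutive starts differ by at most 200 bp. The 200 bp default
reflects that 25-mer probes of one set tile a short target region;
"adjacent" has no canonical definition, so the window is configurable.
The emitted record spans the longest qualifying run.

Gene assignment is strand-aware interval overlap (relaxable via
`ignore_strand`): exactly one overlapping gene wins; a coding gene
beats any number of lncRNAs; two or more coding genes (or two or more
lncRNAs without a coding gene) make the feature ambiguous and it is
dropped; features aligning at more than one surviving locus are dropped
entirely, since a probe that maps to two places measures neither
cleanly. Every decision is recorded per feature (candidate count,
whether coding priority decided the call, drop reason).

## Expression processing

Quantile normalization replaces the value at rank r of every sample
column with the mean over columns of the r-th order statistics; tied
values within a column receive the mean of their tied targets. Rows
containing missing values have no well-defined rank in every column;
they are excluded from the target computation and returned as missing,
the simplest contract that preserves the defining property (identical
post-normalization value multisets) on complete rows. A single-column
matrix is returned unchanged with a warning.

Whether a matrix is already log-scale is decided by a heuristic: a
maximum above 50 marks raw intensities (log2 microarray values rarely
exceed ~20), which are transformed as log2(x + ε) with ε = 1 guarding
zeros; both constants are configurable and the decision is reported.
Probe-level rows mapping to one gene are averaged (arithmetic mean per
sample); RMA summarization of raw Affymetrix CEL files is out of scope
— the package consumes already-summarized matrices.

## Moderated t and meta-ranking

Differential expression is a two-group comparison on log2 data:
log2 fold change is the difference of group means, and the statistic is
a pooled-variance t whose per-gene variance is shrunk toward a prior
fitted across genes. Writing d = n1 + n2 − 2 and s² the pooled sample
variance, the prior (d0, s0²) is estimated by moment-matching the log
sample variances to a scaled F distribution (digamma/trigamma moment
equations, trigamma inverted by Newton iteration); then

    s̃² = (d0·s0² + d·s²) / (d0 + d),   t = Δmean / (s̃·√(1/n1+1/n2))

referred to a t distribution on min(d0 + d, G·d) degrees of freedom
(G = number of genes; the cap keeps the reference finite when the
variances carry no excess spread and d0 → ∞, in which case s0² is the
mean variance). Zero sample variances are floored at 1e-5 times the
median variance before taking logs. With prior_df = 0 the statistic is
exactly the classical equal-variance two-sample t (tested), and the
whole estimator agrees with limma's `lmFit`/`eBayes` to near machine
precision on identical input (cross-checked against limma in the test
suite). Raw p-values are thresholded at p < 0.05 (strict) to match the
recall-oriented design; a Benjamini–Hochberg FDR column is emitted for
users but not used for selection. Samples whose label is neither
contrast level (e.g. "unknown" HPV status) are excluded with a logged
count. Genes with zero moderated variance get t = 0, p = 1.

Cross-dataset integration uses robust rank aggregation. Per dataset,
genes are ranked by log2 fold change (descending for the "up" list,
ascending for "down"; ties get average ranks) and normalized by the
dataset's gene count. For a gene measured in n datasets with sorted
normalized ranks r(1) ≤ … ≤ r(n), the aggregation score is the
Bonferroni-corrected minimum over k of the Beta(k, n−k+1) CDF at r(k) —
the probability that the k-th smallest of n uniforms is this small.
n is per-gene, so genes absent from some platforms are not penalized.
The displayed "meta-score" is −log10(ρ) signed by direction; this is a
labeled display convention, the raw ρ is always stored.

## Connectivity map

θ_gd (README) combines abstract-level co-occurrence counts — presence
anywhere in the abstract, not sentence-level, and unweighted by
SGD/SDD — with the mean absolute Pearson correlation between the gene
and the drug's annotated targets, taken as a flat mean over all
(target, dataset) pairs where both genes are measured with nonzero
variance (per-dataset averaging first is available as an option). A
target identical to the gene contributes |r| = 1, capturing the
direct-target case; a drug with no annotated targets gets Corr_gd = 0.
All samples of each dataset are used by default (tumor-only is a
configurable alternative). λ = 1 regularizes the zero-count cases. The
score is not clamped: a pair co-occurring less often than independence
predicts has a negative log term, which the (1 + Corr) factor makes
more negative.

A caveat inherent to the log-odds form: a rare gene and rare drug
co-mentioned once by chance can receive a very large θ, because the
denominator df_g·df_d is tiny. The full gene × drug table is therefore
kept unfiltered (every component is stored per cell for audit), while
the human-readable shortlist in the pipeline report requires support
df_gd ≥ 2.

## Synthetic data

The generators produce every input the pipeline consumes, each from its
own labeled substream of the seed (so adding one generator call never
perturbs another), and re-running with the same seed reproduces
byte-identical files.

- **Corpus**: 200 abstracts of 3–6 template sentences; 5 planted
  disease genes among 50 background genes and 10 drugs; a planted gene
  co-occurs with a disease term in 20% of abstracts, as does the single
  planted drug–gene pair; background genes and drugs appear in
  disease-free sentences at rate 30%. Sentence realism is deliberately
  minimal — subject–verb–object templates with entity slots — because
  dictionary matching, not NER difficulty, is the test target.
- **Expression**: 5 datasets × 200 genes × 10+10 samples; baseline
  values i.i.d. N(8, 1) on the log2 scale; planted genes shifted by
  ±2 log2 units in tumor samples (alternating sign); one designated
  gene pair generated as y = x + N(0, σ²) with σ = 0.5, giving
  population correlation 1/√(1+σ²); HPV and smoking labels random
  (null contrasts).
- **Probe fixture**: a hand-laid toy chromosome containing one probe
  per assignment rule and one decoy per filtering rule (2 mismatches;
  a gap; similarity exactly 90; a probe set with only 2 perfect probes;
  one with 3 perfect probes spaced 400+ bp apart; coding–coding
  ambiguity; coding-over-lncRNA priority; a multi-mapper; a strand
  mismatch), with the intended assignment or drop reason recorded as
  truth.

What passing these tests shows: the formulas are computed correctly,
the filters drop exactly what they should, the statistics are
calibrated under the model that generated the data, and planted signal
of realistic effect size is recovered end to end. What they do not
show: robustness to real abstracts (parenthetical sentence structure,
synonym noise, negation), real microarray artifacts (batch effects,
intensity-dependent variance, probe cross-hybridization), or
correlated gene–gene structure beyond the planted pairs. Problem sizes
(200 abstracts, 5 × 200-gene datasets, 2,000-gene null simulations)
were chosen so the full suite runs in well under a minute while keeping
Monte-Carlo standard errors small relative to the tested tolerances.

## Numerical and degenerate-input choices

- Ranks and ties: average ranks everywhere (order-independent).
- Candidate ranking ties: broken by abstract count, then id.
- Empty corpus → empty ranking; no overlapping genes across DE tables
  → empty result with a warning; empty probe→gene intersection →
  error.
- RRA ranks must lie in (0, 1]; ρ is capped at 1.
- p-values are clipped to (tiny, 1]; θ validation enforces
  0 ≤ df_gd ≤ min(df_g, df_d) ≤ P, Corr ∈ [0, 1], λ > 0.
- All internal genomic coordinates are 0-based half-open; GTF (1-based
  closed) is converted at the parser boundary only.
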