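# Methods

## Problem

Differential-expression studies of the same disease rarely agree: they use
different platforms (from ~100-probe boutique arrays to genome-wide
sequencing), different sample sizes, and report ranked lists of different
lengths. `mirmeta` integrates such per-study ranked miRNA lists into a single
signature by robust rank aggregation, and provides the statistics typically
used to validate that signature in independent expression data (relative
qPCR quantification, paired tests, ROC analysis, published linear risk
scores, and optimal-cutpoint survival analysis).

## Rank aggregation model

Each study contributes an ordered list of significantly up-regulated miRNAs
and one of down-regulated miRNAs (rank 1 = strongest evidence; within a
source table, ordering is by |fold change| descending, falling back to
p-value ascending where fold changes are absent). Ranks are normalized by
the list length, giving values in (0, 1]. Up- and down-regulated lists are
aggregated separately; a combined single-matrix representation centred at
0.5 (above 0.5 = up-regulated, 0.5 = unreported) is available for
inspection and export.

Under the null hypothesis that the M input lists are uncorrelated, an
item's normalized ranks behave like independent Uniform(0,1) draws. With
the ranks sorted, r(1) <= ... <= r(M), the k-th *Beta score* is the
probability that the k-th order statistic of M uniforms falls at or below
r(k) — the Beta(k, M−k+1) CDF at r(k). The *rho score* is the minimum Beta
score over k, and p = min(1, rho · M) is a Bonferroni bound over the M
minima considered. Across items, a second Bonferroni correction is applied
with N_tests equal to the number of aggregated miRNAs by default; N_tests
is configurable upward (e.g. to a platform-universe probe count) because
the appropriate universe is a modelling choice, not a property of the data.

### Missing entries

Published lists are partial: most studies do not report most miRNAs. Two
policies are implemented:

* **drop** (default): an item's order statistics are computed over only the
  n lists that report it, and the per-item bound is p = min(1, rho · n).
  Conditioning on the reporting pattern keeps the p-value valid — an
  unreported list carries no rank information under the null — and this is
  the behavior of the robust-rank-aggregation implementations in common
  use. It is the only policy under which strong but partially-reported
  signals (reported by, say, half the studies at top ranks) reach the very
  small p-values this kind of meta-analysis is expected to produce.
* **bottom**: unreported entries count as worst-ranked (normalized rank
  1.0) and order statistics run over all M lists. This reads absence as
  evidence against the item and is strictly more conservative; it is kept
  for sensitivity analysis.

Null calibration of the default policy is verified by simulation: on an
exchangeable null corpus (26 studies, 500-miRNA universe) the fraction of
analytic p-values below 0.05 stays under the nominal level (measured
~0.03).

### Permutation p-values

`mc_pvalue` estimates P(score_null <= score_observed) by independently
permuting each study column (preserving each study's multiset of
normalized ranks and its reported/unreported pattern) and recomputing the
target item's score; the estimate uses the add-one rule
(1 + #hits)/(B + 1). Since columns are permuted independently and only one
row is scored, each null replicate row is drawn directly as one uniform
pick per column — distributionally identical to permuting the whole matrix
and far cheaper.

### Leave-one-out stability

Stability resampling repeats the aggregation B times (default 10,000),
each time excluding one uniformly chosen study, and averages each miRNA's
p-value across rounds (an item absent from a reduced corpus contributes
p = 1). Only M distinct sub-corpora exist, so the implementation computes
the M per-drop p-vectors once and averages them with multinomial weights —
exactly equivalent to the naive loop. An exhaustive mode (each study
dropped once, uniform mean) is available for fully deterministic output.

## Signature selection and annotation

An item enters the integrated signature when its Bonferroni-corrected p is
strictly below alpha (default 0.05) and it is reported by at least
min_fraction of the studies (default 1/3, compared without rounding, so 26
studies require at least 26/3 ≈ 8.67, i.e. 9 reporters). Subgroup
reanalysis (e.g. HBV-only etiologies) reruns the entire pipeline on the
matching sub-corpus with its own test count. Genomic clusters are
annotated by scanning same-chromosome loci in coordinate order and
chaining same-strand neighbours separated by less than 50 kb; any
opposite-orientation locus breaks the chain. The published cluster rule
also breaks chains at intervening transcription units; without a
transcript annotation input this is approximated by the orientation rule
alone — a documented limitation.

## Validation statistics

* **ddCt**: fold = 2^−[(Ct_target − Ct_ref)_tumor − (Ct_target − Ct_ref)_normal].
  The per-miRNA summary fold across patients is the geometric mean
  (equivalently 2^−mean ddCt), matching the averaging convention of the
  ddCt method. Deregulation calls use inclusive thresholds: fold ≥ 2 up,
  ≤ 0.5 down.
* **Missing-data filter**: a miRNA is excluded when its missing fraction
  *exceeds* 10% (exactly 10% is kept); remaining values are
  log2(x + pseudocount), pseudocount 1.0 by default for count-like
  abundances such as reads-per-million, 0 for strictly positive
  continuous values.
* **Paired test**: Wilcoxon signed-rank by default — robust at the small n
  (~11 pairs) typical of qPCR validation cohorts — with a paired t-test
  option.
* **AUC** is the Mann–Whitney rank statistic (ties counted half), verified
  in tests against brute-force pair counting; ROC curve points come from
  scikit-learn.
* **Risk scores** apply published LASSO coefficients to log2 expression;
  the shipped models are the four-miRNA tissue-classification score
  (0.180·E_miR-221 + 0.0262·E_miR-21 − 0.007·E_miR-223 − 0.185·E_miR-130a)
  and the five-miRNA grade score. Coefficients are applied, never refit.
* **Survival**: Kaplan–Meier estimation and the two-group log-rank test are
  delegated to lifelines. The optimal cutpoint scans all midpoints between
  consecutive distinct marker values whose groups each exceed 10% of the
  cohort and returns the split maximizing the log-rank chi-square. The
  returned p is the unadjusted minimum over the scan and is therefore
  anti-conservative under the null — a property demonstrated by a
  simulation test, and the reason the cutpoint p should be treated as
  descriptive.

## Synthetic data

The corpus generator emulates the structure of a literature meta-analysis
corpus: 26 studies by default; per-direction list lengths uniform on
10–100; platform sizes log-uniform on 114–208,818; sample sizes log-normal
around a median of 21 pairs, clipped to 8–241; an etiology mix of 8
HBV-only studies, 1 HCV study and 17 unrestricted. A planted signature
(default 5 up, 8 down) enters each study's list with probability
detect_prob = 0.5 at a normalized rank drawn from Beta(1, 19) — top ~5% in
expectation, strong but not degenerate — and every other slot is a uniform
draw without replacement from the non-planted universe (500 miRNAs by
default), which makes the null exchangeable, exactly what the aggregation
null assumes. The generator records planted memberships and realized ranks
so recovery can be scored without re-reading the parameters.

Expression tables are log-normal with per-patient baselines and planted
tumor/normal log2 fold changes; Ct tables use a constant reference assay
per tissue with Gaussian Ct noise (sd 0.25); survival times are
exponential with hazard = baseline · exp(logHR · marker) and independent
exponential censoring. What these generators do **not** emulate: platform-
specific detection biases, correlated miRNAs (clusters co-reported by
biology), inter-study rank correlation induced by shared samples, and
heavy-tailed expression. Passing recovery tests therefore demonstrates
correctness of the pipeline under its own null/alternative model, not
performance guarantees on any particular real corpus.

## Numerical choices and problem sizes

Ties in ranked lists are removed upstream (name standardization keeps the
best rank of merged duplicates and re-ranks densely). Sorting and
selection tie-breaks are lexicographic by miRNA name for determinism. All
randomness flows from a single integer seed through NumPy's SeedSequence;
per-operation child seeds are derived deterministically. Test and
acceptance simulations use 50 corpus replicates for recovery, 100
replicates for power/accuracy rates, 100,000 draws for Monte-Carlo
order-statistic checks, and B = 10,000 for leave-one-out averaging —
sizes at which the reported rates have standard errors well below the
margins being asserted.
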