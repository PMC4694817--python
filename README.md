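# mirmeta

Meta-analysis of miRNA differential-expression lists by robust rank
aggregation, with the downstream statistics used to validate an integrated
signature in independent data.

`mirmeta` is for researchers integrating published tumor-vs-normal miRNA
profiling results (e.g. hepatocellular carcinoma studies spanning
114-probe arrays to genome-wide sequencing). It answers: *which miRNAs are
ranked consistently near the top of many independent studies' up- or
down-regulated lists, more than chance would allow?* — and then supports
validating the answer with qPCR ddCt fold changes, paired tests, ROC/AUC,
published linear risk scores, and Kaplan–Meier / log-rank survival
analysis with an optimal marker cutpoint.

## The statistic

Each study's ranked list is normalized by its length, so an item's ranks
across M uncorrelated studies behave like Uniform(0,1) draws. With sorted
normalized ranks r(1) ≤ … ≤ r(M), the k-th Beta score is
P(U(k) ≤ r(k)) = I_{r(k)}(k, M−k+1) (the regularized incomplete Beta
function, i.e. the Beta(k, M−k+1) CDF), the aggregation score is

    rho = min_k I_{r(k)}(k, M−k+1)

and p = min(1, rho·n) bounds its significance, where n is the number of
lists that report the item (unreported lists are uninformative and are
dropped by default; a conservative bottom-ranked policy is available).
Across items, Bonferroni correction uses the number of aggregated miRNAs
(configurable to a platform universe). The integrated signature keeps
items with corrected p < 0.05 reported by at least one third of the
studies. Leave-one-out resampling (drop one random study, re-aggregate,
average p over 10,000 rounds) quantifies the stability of each p-value.

## Worked example

Generate a synthetic 26-study corpus with a planted signature (5 up, 8
down, each entering a study's list with probability 0.5 near the top),
aggregate the up-regulated lists, and select the signature:

```python
from mirmeta import CorpusSimParams, aggregate, select_signature, simulate_corpus

corpus, truth = simulate_corpus(CorpusSimParams(seed=3))
res = aggregate(corpus, "up")          # rho, p, Bonferroni p, support
print(res.head(3).to_string(index=False))
sig = select_signature(res, alpha=0.05, min_fraction=1/3, n_studies=26)
print(sorted(sig["mirna"]), sorted(truth["planted_up"]))
```

```
    mirna direction          rho      p_value  corrected_p  n_reporting
miR-s0001        up 3.301691e-15 4.292198e-14 2.013041e-11           13
miR-s0000        up 1.552331e-12 2.018030e-11 9.464563e-09           13
miR-s0002        up 2.372931e-10 3.084810e-09 1.446776e-06           13
['miR-s0000', 'miR-s0001', 'miR-s0002', 'miR-s0003', 'miR-s0004'] ['miR-s0000', 'miR-s0001', 'miR-s0002', 'miR-s0003', 'miR-s0004']
```

The three strongest items are planted miRNAs reported by 13 of the 26
studies at top ranks; their corrected p-values are far below 0.05, and
the selected signature recovers the planted set exactly. The same
pipeline is exposed on the command line:

```bash
mirmeta simulate corpus --seed 3 --out corpus/
mirmeta aggregate corpus/ --direction up --out agg.tsv
mirmeta signature select agg.tsv --n-studies 26
```

Validation statistics follow the same pattern — for example, ddCt fold
changes and deregulation calls from a qPCR Ct table:

```python
from mirmeta import classify_deregulated, ddct_fold_change, summarize_folds
from mirmeta.simulate import CtSimParams, simulate_ct

ct, _ = simulate_ct(CtSimParams(seed=1))
folds = summarize_folds(ddct_fold_change(ct))
print(classify_deregulated(folds).to_dict())
```

```
{'miR-x1': 'up', 'miR-x2': 'down'}
```

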