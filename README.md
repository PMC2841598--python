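# granet

Temporal-precedence clustering for time-course gene expression data.

`granet` builds a **gene association network** by testing Granger causality
between every ordered pair of expression profiles (nested OLS
autoregressions, F test, per-pair AIC lag selection), symmetrizes the
directed strengths with a max rule, thresholds the network at an empirical
quantile of the edge weights, and extracts candidate functional modules as
dense regions (k-core-weighted greedy seed expansion with a 2-core
post-filter). A seeded simulator for multivariate autoregressive systems
with known causal structure and a network-statistics suite make every stage
verifiable without external data.

## Layout

| module               | purpose                                                               |
| -------------------- | --------------------------------------------------------------------- |
| `granet.simulate`    | VAR simulator; benchmark systems `dataset1/2/3`, `combined_system`    |
| `granet.preprocess`  | expression matrix type, first differencing, flat-gene filter, FFT ranking |
| `granet.granger`     | restricted/unrestricted OLS fits, F statistic, AIC lag selection, all-pairs scan |
| `granet.assoc`       | max-symmetrization, quantile thresholding, correlation/Euclidean baselines |
| `granet.modules`     | k-cores, vertex weighting, greedy complex detection and scoring       |
| `granet.netstats`    | degree/shared-neighbor distributions, closeness, topological coefficient, summary |
| `granet.io` / `granet.pipeline` / `granet.cli` | file formats, config, end-to-end pipeline, CLI |

## CLI

```bash
# simulate a benchmark system to an expression TSV (genes x time points)
granet simulate --dataset combined --T 1000 --seed 7 --out expr.tsv

# individual stages
granet preprocess --in expr.tsv --out prepped.tsv --diff --flat-filter-k 2.0
granet test-pairs --in prepped.tsv --out directed.tsv --alpha 0.05 --full-matrix
granet network    --in directed.tsv --out network.tsv -q 0.975
granet find-complexes --in network.tsv --out complexes.tsv --vwp 0.2 --min-core 2
granet stats      --in network.tsv --out stats.json

# or everything at once (YAML config optional; flags override it)
granet run --in expr.tsv --out-dir results/ --no-diff --quantile 0.975
```

Expression matrices are TSV/CSV with the gene id in the first column and one
ordered time point per remaining column. Networks are written as weighted
edge-list TSV, GraphML or SIF (chosen by extension).

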