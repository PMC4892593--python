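# comarker

Cross-cohort consensus discovery of **common marker genes** from
case-control expression studies.

## The problem

Differential-expression screens of the same disease in different
tissues and on different microarray platforms rarely agree: each
cohort has its own platform, sample type, and sample size, and a gene
that tops the list in purified monocytes may barely move in whole
blood, where the responding cell type is diluted.  For translational
work (diagnostic panels, blood-based markers) the interesting genes
are the ones that survive *all* of that: markers significant across
cohorts, sample types, and analytical strategies.  The motivating use
case is systemic lupus erythematosus (SLE), screened in four
case-control cohorts covering monocytes, peripheral blood mononuclear
cells (PBMC), and whole blood, with case/control sizes 5/5, 61/20,
99/30, and 157/20 — but nothing in the package is specific to lupus.

## The method

Given cohorts $d = 1..n$ with probe-level matrices:

1. **Harmonize.**  Map probes to official gene symbols, collapse
   multi-probe genes (default: keep the probe with the highest mean
   intensity), and restrict every cohort to the commonly profiled
   genes $\bigcap_d \text{panel}_d$.
2. **Marginal screen** (per cohort, per gene): linear-scale fold
   change $\mathrm{FC} = 2^{\bar x_{case} - \bar x_{ctrl}}$ on log2
   data; Welch two-sample t-test; Benjamini–Hochberg q-values.  Three
   selections per cohort: top 100 by FC, top 100 by t-test p, and all
   genes with $q \le 0.001$.
3. **Cross-cohort vote.**  For each marginal method keep the genes
   selected in at least $m$ of $n$ cohorts (default 3 of 4); the union
   of the three filtered sets is the **marginal pool**.
4. **Joint screen**: per cohort, L1-penalized logistic regression of
   case/control on all standardized gene columns
   $\min_{\beta_0,\beta}\; \tfrac1n \sum_i \log(1+e^{-\tilde y_i(\beta_0 + x_i^\top\beta)}) + \lambda \lVert\beta\rVert_1$
   over a descending λ grid from $\lambda_{max}$, with λ chosen by
   stratified cross-validated binomial deviance (1-SE rule by
   default).  The **joint pool** aggregates the per-cohort supports
   (default: union across cohorts; a 3-of-4 vote is configurable).
5. **Common markers** = marginal pool ∩ joint pool, reported with a
   per-gene, per-cohort statistics table and min–max fold-change
   ranges per sample type.

A synthetic multi-cohort generator with planted, sample-type-attenuated
markers makes the whole pipeline testable offline, and local
hypergeometric gene-set enrichment plus a PPI cross-set summary cover
the downstream annotation steps without any web service.

## Worked example

```sh
comarker simulate --out study/ --seed 3 --n-genes 500 --n-planted 8
comarker -v run --data study/ --out results/ --seed 3
```

The `run` command prints one line of accounting (values for this seed):

```
marginal_fc_top_k=20  marginal_t_top_k=20  marginal_fdr_threshold=5  marginal_pool=23  joint_pool=23  union=37  common_markers=9
```

Read: 20, 20 and 5 genes passed the 3-of-4 vote for the FC, t-test
and FDR selections; their union (the marginal pool) has 23 genes; the
pooled lasso supports also contain 23 genes; 9 genes sit in both
pools and are reported as common markers — all 8 planted genes plus
one false positive (`results/consensus.json`, compare
`study/truth.json`; at this toy scale the top-100 rules cover 20% of
the 500-gene panel, so a by-chance consensus gene is expected).
`results/marker_report.tsv` tabulates FC, p and q per marker per
cohort, with fold changes largest in the monocyte cohort and smallest
in whole blood, mirroring the attenuation the generator plants.

In Python the same run is:

```python
import comarker as cm

cfg = cm.default_study_config(n_genes=500, n_planted=8, seed=3)
datasets, probe_maps, truth = cm.generate_multidataset(cfg)
result = cm.run_pipeline(datasets, probe_maps, cm.AnalysisConfig(seed=3))
print(sorted(result.consensus.common_markers))
```

## Layout

| module | role |
| --- | --- |
| `io_formats` | TSV/GMT/edge-list readers and writers, domain types |
| `synthetic_data` | multi-cohort generator with planted markers |
| `harmonize` | probe collapse, log-scale heuristic, panel intersection |
| `marginal_selection` | FC, Welch/Student t, BH, the three selection rules |
| `joint_selection` | L1-logistic path solver + cross-validated selection |
| `consensus` | vote counting, m-of-n filter, pool algebra, marker report |
| `annotation` | hypergeometric enrichment, PPI cross-set summary |
| `pipeline` / `cli` | orchestration, manifests, `comarker` command |

See `docs/methods.md` for the statistical details and design
decisions.
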