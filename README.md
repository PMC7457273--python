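# methtriad

Base-resolution estimation of three cytosine-modification signals — 5mC,
5hmC and pooled 5fC/5caC — from triple bisulfite sequencing count data
(BS-seq, oxBS-seq and MAB-seq), and integration of the resulting gene-body
methylation changes with gene expression. The package is aimed at
epigenomics analysts who have per-CpG C/T count tables from the three
chemistries and want per-site modification estimates, bin- and gene-level
summaries, methylation-stratified expression tests, and cross-cohort
validation of methylation trends — plus a synthetic-data generator that
emulates the full measurement chain with known ground truth.

## The model

**Joint 5mC/5hmC estimation.** In BS-seq both 5mC and 5hmC protect a
cytosine from conversion, while in oxBS-seq only 5mC does. For a CpG with
true fractions (p_m, p_h), the two libraries' C-counts are

    k_bs ~ Binomial(n_bs, p_m + p_h),   k_ox ~ Binomial(n_ox, p_m)

and the per-site estimate maximises the product likelihood over the
simplex {p_m ≥ 0, p_h ≥ 0, p_m + p_h ≤ 1}. The interior solution is
p̂_m = k_ox/n_ox, p̂_h = k_bs/n_bs − k_ox/n_ox; when the observed
proportions invert (k_bs/n_bs < k_ox/n_ox) the constrained maximum lies on
the p_h = 0 edge and equals the pooled proportion (k_bs+k_ox)/(n_bs+n_ox).
Sites require depth ≥ 10 in both libraries at matched coordinates.

**5fC/caC calling.** In MAB-seq, M.SssI methylates all unmodified CpGs, so
only 5fC/5caC read as T apart from a small non-conversion inefficiency e
(default e = 0.0164, measured for the assay). Under the null the T-count
is Binomial(n, e); each site gets the exact upper-tail p-value P(X ≥ t),
the corrected level max(0, (t/n − e)/(1 − e)), and Benjamini–Hochberg
q-values across depth-passing sites. A site is retained when depth ≥ 10,
p < 0.01 and q < 0.01.

**Aggregation and integration.** Signals are normalised in non-overlapping
1000-bp bins and over gene bodies: depth-weighted means for 5mC/5hmC (the
deconvolved form of TNC/(TNC+TNT)), unweighted means over retained sites
for 5fC/caC. Genes are split by the sign of their case-minus-control
gene-body change (gain vs loss) and their expression log2 fold-changes are
compared with a two-sided Wilcoxon rank-sum test. Differential expression
uses RPKM with strict fold-change > 1.5 and p < 0.05 cutoffs. Trend
concordance against an independent cohort is the fraction of genes whose
methylation delta keeps its sign.

## Worked example

Run the six-stage pipeline on its built-in synthetic demo (150 genes, 20
with planted 5mC gain and 20 with loss at delta 0.2, expression coupled
gain→up / loss→down):

```sh
methtriad all --seed 1 --outdir results
```

`results/report.json` then contains, among other stage summaries:

```
"call":      { "n_estimates": 28801, "n_fcac_retained": 48, ... }
"aggregate": { "n_gain_5mC": 78, "n_loss_5mC": 72, ... }
"express":   { "n_significant_tissue": 40, "n_significant_model": 34 }
"integrate": { "stratification": { "n_gain": 78, "n_loss": 72,
               "p_value": 2.24e-06, "stars": "***" },
               "n_signature_up": 13, "n_signature_down": 17 }
"validate":  { "concordance": { "n_consistent": 92, "n_tested": 150,
               "fraction": 0.613 } }
```

Reading: 28,801 site/group pairs got joint 5mC/5hmC estimates and 48 sites
passed the three-way 5fC/caC retention rule; 78 genes gained and 72 lost
gene-body 5mC; the gain and loss strata differ in expression fold-change
at p = 2.2e-06 in the planted direction (gain genes higher); 13 + 17 genes
form the direction-matched DE signature shared by the two simulated
cohorts; and 92/150 genes (61%) keep their methylation sign in a
validation cohort simulated at a 57% concordance rate. Identical seed and
config reproduce every output byte for byte; stages can equally be run one
at a time (`simulate`, `call`, `aggregate`, `express`, `integrate`,
`validate`). `examples/demo.yaml` lists every tunable with its default.

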