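# Methods

## Measurement model

A CpG site carries true fractions (p_m, p_h, p_f) of 5mC, 5hmC and pooled
5fC+5caC, with p_m + p_h + p_f ≤ 1. The three bisulfite chemistries read
out different sums of these fractions per sequenced cytosine:

| library | C-readout probability | rationale |
|---------|----------------------|-----------|
| BS      | p_m + p_h + eps_bs·(1 − p_m − p_h) | 5mC and 5hmC resist conversion; unmodified C, 5fC and 5caC convert to T |
| oxBS    | p_m + eps_ox·(1 − p_m)             | chemical oxidation turns 5hmC into 5fC, leaving only 5mC protected |
| MAB     | 1 − [p_f + e·(1 − p_f)]            | M.SssI methylates unmodified CpGs first, so only 5fC/caC read T, plus non-conversion e |

5fC and 5caC are treated as one pooled species throughout: the chemistry
cannot separate them and the downstream analyses never need to. Sites are
represented at the plus-strand cytosine of the CpG dyad; merging strand
pairs of real data is an ingest concern, not a modelling one.

## Estimation

**5mC/5hmC.** The joint likelihood Binom(k_bs; n_bs, p_m + p_h) ·
Binom(k_ox; n_ox, p_m) is maximised over the simplex. Because the interior
stationary point is (k_ox/n_ox, k_bs/n_bs − k_ox/n_ox) and both candidate
coordinates are proportions, the only reachable constraint violation is
p_h < 0; there the likelihood factorises into two binomials sharing one
parameter, whose MLE is the pooled proportion. The implementation is this
closed form (no iterative optimiser), flagged per site when the boundary
is taken, and is verified in the test suite against an exhaustive 10⁻³
grid search of the joint log-likelihood. The likelihood assumes ideal
BS/oxBS conversion; error-rate parameters exist in the simulator but the
estimator deliberately omits them, matching standard practice for this
estimator class. Counts are pooled across replicates per site, group and
library before estimation.

**5fC/caC.** Under the null every MAB read is protected and reads T only
through non-conversion, so T ~ Binomial(n, e) with e = 0.0164 by default
(the assay's measured inefficiency; configurable). The p-value is the
exact upper tail P(X ≥ t) *including* the observed count — the
conventional, conservative choice; the corrected level inverts the mixing
t/n ≈ p_f + e(1 − p_f). Benjamini–Hochberg is computed across
depth-passing sites only, since sites failing the depth ≥ 10 filter never
reach downstream analysis; retention requires depth ≥ 10, p < 0.01 and
q < 0.01, all strict.

## Aggregation

Bins are half-open [k·1000, (k+1)·1000) anchored at 0. For 5mC/5hmC the
bin (and gene-body) signal is the depth-weighted mean of site estimates —
the exact generalisation of TNC/(TNC+TNT) from raw counts to deconvolved
proportions, to which it reduces for a single-library signal; the weights
are the depths of the library that directly measures each signal (oxBS
for 5mC, BS for 5hmC). For 5fC/caC the signal is the unweighted mean over
retained sites, reflecting the far lower genomic density of those sites.
Gene bodies are the full gene interval (no TSS exclusion). A gene-body
delta is defined only with ≥ 3 passing sites in both groups (min_sites,
configurable; chosen to stabilise gene means). The delta is an arithmetic
difference — stable near 0, unlike a ratio — and drives the gain/loss
direction; a pseudo-counted ratio is reported alongside.

## Expression and integration

RPKM = count/((length/10³)·(lib_size/10⁶)); RPKM and FPKM are treated as
synonymous for these count matrices. The builtin DE test is a two-sided
Welch t-test on log2(RPKM + 0.5) — an explicit stand-in chosen for having
no tuning parameters; the `external` method accepts any per-gene
(log2fc, p) table so a dedicated count-model DE engine can be slotted in,
with only the strict fold-change > 1.5 and p < 0.05 thresholds applied
here. Pseudo-count 0.5 is used for every log transform and fold change.
Profile correlations are Pearson r on log2(value + 0.5) over genes
expressed above 1 (strict) in at least one member of the pair.

The gain/loss stratification test is the two-sided Wilcoxon rank-sum:
exact enumeration when both strata have ≤ 20 genes and no ties, exact
permutation of the U statistic when ties occur at that size, and the
tie-corrected normal approximation with continuity correction otherwise.
No-change genes (delta exactly 0) join neither stratum. Trend concordance
is sign-only agreement of per-gene deltas — no magnitude threshold — so
cohorts measured on different platforms can be compared; genes with zero
or undefined delta in either cohort are excluded from the denominator.

## Synthetic data: what it does and does not emulate

The generator draws a toy genome of non-overlapping genes, scatters CpGs
as per-bp Bernoulli(density), draws control-group levels from Beta
baselines (defaults: 5mC Beta(2,2), 5hmC Beta(2,5), 5fC/caC Beta(1,60) —
mean ≈ 1.6%, matching the scale of the caller's null rate), plants ±delta
5mC shifts on designated gain/loss genes with simplex re-projection, and
draws per-library counts with negative-binomial depth (mean 30,
dispersion 5 — WGBS-typical; the source data state only a total data
volume, not a depth distribution). Expression counts are negative
binomial with group means separated by the planted |log2FC| and direction
tied to the methylation flag through the coupling map (default gain→up,
loss→down); dispersion 0 is the deterministic limit (counts equal the
rounded mean), which makes boundary tests exact. Validation cohorts keep
each discovery sign with probability rho and perturb magnitudes
lognormally, so the realised concordance is exactly Binomial(n, rho).

Not emulated: read-level errors and mapping, sequence context beyond CpG
positions, strand asymmetry, copy-number or genotype artefacts (a variant
mask BED is accepted but never generated), library-composition biases in
expression, and batch structure. Passing tests therefore demonstrate
correctness of the estimators and pipeline under the stated sampling
model, not robustness to alignment or genotyping artefacts in real data.

## Numerical and design choices

- Seeds are explicit in every stochastic operation; the pipeline derives
  per-stage seeds from the global seed by fixed offsets, so one stage's
  draw count never perturbs another's.
- p-value validation for BH is (0, 1]; exact tails are computed with the
  binomial survival function, never by 1 − cdf.
- Simplex projection in the simulator is sequential (5mC keeps its draw,
  then 5hmC, then 5fC/caC yield), deterministic and order-stable.
- Degenerate DE genes with zero variance in both groups get p = 1.
- Bin/gene means are permutation-invariant by construction (grouped
  sums); conservation of the depth-weighted mean is exact to float
  round-off and asserted at 10⁻¹² in the tests.
- Problem sizes in the test and acceptance runs (20,000 sites for
  recovery, 50,000 sites for caller calibration, 200 replicates for the
  null-uniformity check, a 150-gene demo genome) were chosen as the
  smallest sizes at which the binomial standard errors make the stated
  tolerances meaningful.
- The p_h recovery bound scales the p_m bound by √2: p̂_h is a difference
  of two independent proportions, so its sampling sd is √2 times that of
  a single proportion at equal depth.

## Known limitations

- The 5mC/5hmC estimator ignores conversion errors in its likelihood;
  with strongly non-ideal chemistry the estimates inherit that bias.
- The non-conversion inefficiency is applied per read, uniformly across
  sites; site-specific inefficiency would need a hierarchical null.
- The builtin Welch-on-log-RPKM DE test is less powerful than count-model
  tests at small n and low counts; use the external path for production
  DE calls.
- Gene-body averaging ignores within-gene heterogeneity (promoter vs
  body); the bin track exists for finer-grained follow-up.
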