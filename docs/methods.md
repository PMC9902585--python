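# Methods

`miscreen` reimplements, as a tested pipeline, an in-silico screen for
signaling receptors whose expression is simultaneously associated with two
tumor programs — epithelial–mesenchymal transition (EMT) and cell-cycle
(mitotic) activity — together with a cross-dataset conserved-correlation
procedure for mapping the neighborhood of one focal gene. All statistics
operate on gene × sample expression matrices; everything is exercised on
synthetic data with planted structure, so the whole chain is testable
without any download.

## Activity scores

For each sample, the activity of a program (EMT or mitotic) is the
differential mean expression of the program genes versus rank-matched
control genes:

1. counts are normalized to counts-per-million (every sample column sums to
   10⁶);
2. all genes are ranked by mean expression and split into `n_bins = 25`
   contiguous rank intervals of near-equal size (sizes differ by at most
   one; ties in the mean break by gene symbol, so the binning is
   deterministic);
3. from every interval containing at least one program gene, the
   `n_control_per_bin = 100` top-ranked non-program genes (all of them if
   fewer) join the control pool;
4. score(sample) = mean log₂(CPM+1) of program genes − mean log₂(CPM+1) of
   the control pool.

Scores are computed on log₂(CPM+1) rather than raw CPM because differential
means on the raw scale are dominated by a handful of high expressors; the
log scale is the community norm for module scores. Matching controls on
expression rank removes the abundance component, so adding a constant to
every gene of a sample (on the scoring scale) leaves the score unchanged —
a property the tests assert. Control selection is deterministic given
(matrix, program); a seeded resampled-control variant exists for
uncertainty checks and is off by default.

If the program genes exhaust their bins (no eligible control remains), the
scorer falls back to a matrix-wide background excluding the program, with a
warning — preferable to failing on tiny matrices.

Variable-gene selection (used when the caller wants to restrict a program
to its most variable members) ranks genes by the residual of their
coefficient of variation above a rolling-median mean–CV trend computed in
20 mean-rank windows (windows shrink on small matrices so each holds ≥10
genes). This is deterministic and dependency-light; a LOESS fit would serve
equally.

## Entropy, mutual information, co-information

Expression vectors are prepared for entropy estimation by replacing zeros
with 1, dividing by the total, and taking log₂. The map is monotone, so it
does not move quantile-bin boundaries except where the zero→1 replacement
merges ties; activity scores are signed and are binned directly. Each
variable is then discretized into `n_levels = 10` equal-frequency bins
(ties share a bin; a constant variable collapses to one level and is
flagged). Quantile bins are robust to the heavy right tail of expression
data and give every gene a comparable marginal entropy.

All information quantities are plugin estimates in bits. The k-variable
mutual information is assembled by inclusion–exclusion over joint
entropies,

    MI(X₁..X_k) = − Σ_{S≠∅} (−1)^{|S|} H(S),

which for two variables is I(X;Y) = H(X)+H(Y)−H(X,Y) and for three the
co-information H(X)+H(Y)+H(Z)−H(XY)−H(XZ)−H(YZ)+H(XYZ). Pairwise plugin MI
is non-negative; co-information is signed — negative for synergy, positive
for redundancy. Normalized MI divides by √(∏ᵢ H(Xᵢ)) and is defined as 0
when any marginal entropy vanishes. The test suite checks the
inclusion–exclusion estimator against an independent oracle that computes
MI (and, for three variables, I(X;Y) − I(X;Y|Z)) straight from the
empirical joint distribution, over hundreds of random and degenerate joint
tables, to 10⁻¹² bits. No bias-corrected entropy estimators are used: the
statistic of interest is the plugin quantity, and significance is assessed
by permutation, which carries the same bias under the null.

### Permutation significance

For each gene, the sample labels of the gene (the target) are permuted
`n_perm` times against the fixed score anchors, the statistic is recomputed
and `p = (1 + #{perm ≥ obs}) / (1 + n_perm)`. Pairwise MI is tested
one-sided (larger MI = more dependence).

The triple statistic needs care: the permutation null of the plugin
co-information is **not centred at zero**. Breaking the target–anchor
dependence leaves I(E;C) intact while the estimated conditional dependence
I(E;C | target) carries a positive finite-sample bias that grows with the
table size, so permuted co-informations concentrate around a substantial
negative value. A magnitude test against that null has essentially no power
for synergy and inverts for redundancy. The triple test is therefore
two-sided on the deviation from the null centre, where the centre pools the
observed value with the permuted ones — a symmetric function of the
exchangeable set, so the p-value remains exact under the null. Both
synergistic and redundant dependence count as joint association, which is
what the screen needs: a receptor tracking both programs can appear either
way depending on how the programs co-vary.

One seeded set of permutations is shared across all genes of a screen, so a
whole matrix is reproducible under a single master seed.

### Multiple testing and the screen

The screen computes, for every gene, pairwise MI against the EMT score,
pairwise MI against the mitotic score, and the triple co-information with
both. Benjamini–Hochberg correction is applied separately within each of
the three families; the three significant sets (q ≤ 0.05 by default)
intersect to give the co-associated genes, and a ligand–receptor annotation
filters the intersection to receptors. Directionality comes from the
Spearman correlation of the untransformed per-sample values against each
score; receptors are ranked most-negative-first on the EMT correlation
(ties by the mitotic correlation, then symbol). Screening is performed on
the CPM matrix so library-size variation does not leak into every gene's
statistic.

## Conserved correlation and ORA

Given several independent datasets (bulk samples or single cells alike —
no pseudobulking), the focal gene is Spearman-correlated against every
other gene within each dataset (vectorized midrank Pearson with the
t-approximation p-value, verified against `scipy.stats.spearmanr` row by
row). Significance is called per dataset on BH-adjusted q ≤ α (a raw-p
switch exists, BH is the default so the k-of-N rule has interpretable
specificity); a gene is conserved-associated when significant in ≥ k
datasets (defaults k = 2, α = 0.05). The conserved set is tested for
pathway over-representation with the one-sided hypergeometric tail within a
stated universe, BH-corrected across pathways.

## Synthetic data

The generator emulates the statistical structure the screen assumes, not
any particular cohort:

- **Latent activities.** Each sample carries an EMT-like and a mitotic-like
  activity, lognormal with σ = 0.4, correlated at 0.35 by default. The
  correlation reflects that proliferation and mesenchymal programs co-vary
  across tumors; it also gives a receptor tracking both programs a
  redundancy component in its triple statistic, which is the association
  structure the screen is designed to find.
- **Counts.** Negative binomial (gamma–Poisson) with dispersion 0.3 for all
  genes; lognormal library sizes (σ = 0.3, mean 2×10⁵) and lognormal
  relative abundances. The NB discreteness exposes the quantile binning to
  realistic ties and zeros.
- **Program genes** (30 + 30 by default): mean proportional to
  (latent/mean)^γ with γ ~ U(0.8, 1.6), so expression increases with the
  matching activity at gene-specific steepness.
- **Receptors.** Mean = exp(direction · b · g(latent)), with g(x) =
  x/(x+median) a saturating (monotone, nonlinear) link — nonlinear
  monotone dependence is exactly the regime where MI is preferable to
  linear correlation. For target "both", g is averaged over the two
  latents. The strength b is calibrated by bisection so the realized
  Spearman correlation between the receptor's *counts* and the driving
  latent hits ρ_target (±0.1 at n ≥ 300, averaged over seeds). Calibration
  draws include NB noise and library-size variation — omitting the latter
  systematically undershoots the realized correlation. ρ_target = 1 with
  positive dispersion is rejected as impossible (counting noise bounds the
  attainable rank correlation).
- **Null genes**: independent of both latents.
- **Multi-dataset simulation**: dataset d uses seed (master + d); in the
  designated signal datasets, module genes follow a calibrated monotone
  link of the focal gene's own latent driver, elsewhere they are null.

What the generator does **not** emulate: batch structure, tumor purity,
subtype mixtures, single-cell dropout beyond NB zeros, gene–gene
correlation beyond the planted programs. Passing tests therefore
demonstrate the statistics behave correctly under the assumed model, not
that the screen's biological discoveries replicate on real cohorts.

## Validation experiments and problem sizes

`miscreen.benchmarks` holds the self-contained experiments the test suite
asserts on and `scripts/acceptance.py` reports:

- estimator-vs-oracle equivalence over ≥500 random joint tables (≤3
  variables, ≤4 levels) plus degenerate cases, at 10⁻¹² bits;
- closed-form checkpoints (uniform 4-level entropy = 2 bits; identical
  binary MI = NMI = 1; XOR co-information = −1 bit);
- permutation-null calibration: a structureless 4000-gene × 300-sample
  dataset, scores built from designated pseudo-program genes, 200 tested
  genes chosen disjoint from the program and control pools (a control gene
  is a summand of the score, so its dependence on the score is real, not a
  calibration error), 499 permutations; type-I error at α = 0.05 and KS
  uniformity, pooled over the three statistic families;
- screen power: replicates of a 570-gene × 300-sample dataset with 10
  dual-program receptors at ρ_target = 0.5 (alternating sign) among 500
  null genes, n_perm = 1499; detection requires intersection membership
  with both Spearman signs matching the planted direction (20 replicates in
  the test suite, 10 in the acceptance script);
- activity-score recovery of a +1 log₂-unit planted shift in half of 200
  samples, and a 200-program null ensemble;
- conserved-module recovery: 4 datasets × 150 samples, 20-gene module
  planted in 3, ρ_target = 0.5 (50 runs in the test suite, 30 in the
  acceptance script);
- ORA vs exhaustive enumeration on universes ≤ 12 genes and the
  closed-form 1/C(20,5) case;
- two pipeline runs of the bundled 200-gene configuration compared by
  output checksum.

`n_perm = 1499` for the screen is chosen so the smallest attainable p-value
(1/1500) sits below the BH threshold a 10-true-signal, ~570-gene family
implies (≈ 10/570 × 0.05); fewer permutations would make discoveries
impossible regardless of effect size.

## Numerical choices and degenerate inputs

- log base 2 throughout; 0·log 0 = 0.
- Equal-frequency binning with `searchsorted` on interior quantiles;
  duplicate quantile edges (heavy ties) collapse levels, which is recorded
  in the variable's provenance.
- Ties everywhere break by gene-symbol lexicographic order.
- All-zero samples, all-zero entropy inputs, empty gene sets, missing focal
  genes and sample mismatches are rejected with messages naming the
  offender; a constant variable yields entropy 0 and NMI 0 rather than
  NaN.
- Seeds: one master seed per run; per-dataset seeds are master + index;
  permutation indices derive from the screen seed and are shared across
  genes.

## Known limitations

- Plugin MI on 10-level bins at n ≈ 300 is strongly biased; the permutation
  test absorbs the bias for testing, but the reported MI values themselves
  are not bias-corrected and should be compared only within a screen.
- The per-dataset BH-then-count conservation rule controls false positives
  per dataset, not family-wise over the k-of-N decision.
- The triple statistic conflates synergy and redundancy by design; callers
  who need the distinction should inspect the sign of the co-information.
- The generator's calibration targets the Spearman correlation against the
  latent, not against the realized activity score; the score is a noisy
  estimate of the latent, so realized gene–score correlations run slightly
  below ρ_target.
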