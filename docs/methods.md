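# Methods

## Model and estimands

Trait values X_ik, k = 1..n_i, in genotype groups i = 1, 2, 3 (ordered by
risk-allele count) are independent with arbitrary distributions F_i; no
moments are required, and all distribution functions are taken in the
normalized (mid) form F(x) = P(X < x) + ½P(X = x), so ties — ordered
categorical scores, detection-limit data coded as a shared constant — are
part of the model rather than a nuisance. The estimands are the unweighted
relative effects p_i = ∫ G dF_i with G = (F₁ + F₂ + F₃)/3. They satisfy
Σ p_i = 3/2, lie in [0, 1], are invariant under strictly increasing
transformations of the trait and are reflected (p ↦ 1 − p) by decreasing
ones. Genetic effects are contrasts δ_q = c_q′p with the Marcus rows
(dominant pools {aA, AA} with sample-size weights against aa; additive
compares AA with aa; recessive pools {aa, aA} against AA) or the all-pairs
rows. Rows are oriented so that positive δ means higher trait values with
more copies of the declared risk allele; two-sided inference is unaffected
by this convention, and the CLI's `--risk-allele` flag makes the
orientation explicit.

## Estimation

Placements F̂_j(X_ik) are evaluated by binary search in the sorted group j
(equivalently, pooled mid-rank minus within-group mid-rank over n_j); p̂
comes from pseudo-ranks 1/2 + N·Ĝ(X_ik). In balanced designs pseudo-ranks
equal pooled mid-ranks, and the implementation computes them as such so the
identity holds bitwise. Because every quantity is a function of counts of
strict inequalities and ties, all downstream statistics are *bit-identical*
under strictly increasing transformations — not merely equal to tolerance.

The covariance of √N(p̂ − p) is estimated through the asymptotic influence
decomposition p̂_m − p_m ≈ Σ_g n_g⁻¹ Σ_k u⁽ᵐ⁾_gk with

* u⁽ᵐ⁾_mk = ⅓ Σ_{j≠m} (F̂_j(X_mk) − ŵ_jm)  (own group), and
* u⁽ᵐ⁾_gk = −⅓ (F̂_m(X_gk) − ŵ_mg)  (g ≠ m),

where ŵ_jm = ∫ F̂_j dF̂_m. The estimator V̂[m, m′] =
N Σ_g [n_g(n_g−1)]⁻¹ Σ_k u⁽ᵐ⁾_gk u⁽ᵐ′⁾_gk is a sum of scaled Gram
matrices, hence symmetric PSD by construction, reduces to the standard
two-sample Brunner-type variance for a single pair, and is tie-robust. It
is validated against a nonparametric bootstrap (2,000 resamples,
n = (50, 50, 50), all entries within 15% relative error) and against
fresh-replicate Monte Carlo (mean of 200 estimates vs the empirical
covariance of 5,000 replicate p̂ at n = (30, 30, 30), within 3 combined
Monte-Carlo standard errors); each group needs n_g ≥ 2 or estimation
refuses with an explicit error. The same decomposition, restricted to the
pairwise empirical distributions, supplies the covariance of the
pairwise-rankings effects.

## Inference

Statistics T_q = δ̂_q / ŝe_q with ŝe_q = √(c_q′V̂c_q/N) are referred to a
central multivariate t with the estimated correlation matrix R̂ and a
common Welch-Satterthwaite degree of freedom: per contrast
ν_q = (Σ_g λ_gq)² / Σ_g λ_gq²/(n_g−1), λ_gq the group-g share of the
contrast variance, with the minimum over contrasts (floored at 2) used for
both the quantile and the adjusted p-values. The common-minimum choice is
deliberate: it keeps the single-quantile construction and errs
conservative; a contrast-specific df would break the "one threshold for
all contrasts" structure of the simultaneous intervals. `approx="normal"`
replaces t by the normal limit for large samples.

Box probabilities P(max_q |T_q| ≤ b) are computed by randomized
quasi-Monte-Carlo integration (scipy's multivariate t) with a fixed,
configurable seed, making p-values and quantiles reproducible across runs;
observed integration noise is below 1e-5, well inside the 1e-4 design
tolerance. Equicoordinate quantiles are found by Brent root search
(xtol 1e-5) inside a bracket spanned by the perfectly-correlated
(univariate) and Šidák-style quantiles. A singular R̂ (perfectly
correlated contrasts) is shrunk by 1e-8 toward the identity before
integration, perturbing probabilities by less than 1e-4. Adjusted p-values
are p_q = 1 − P(max_r |T_r| ≤ |T_q|); the global test rejects iff
min_q p_q < α, equivalently iff some interval δ̂_q ∓ z·ŝe_q excludes the
null value — the two decision rules are compatible by construction.

Two reporting scales exist and are treated as two procedures:

* **plain** — statistics and intervals on the effect scale; bounds can
  leave [−1, 1];
* **fisher** (default) — the delta method on the Fisher z scale:
  statistics atanh(δ̂)·(1−δ̂²)/ŝe and intervals
  tanh(atanh(δ̂) ∓ z·ŝe/(1−δ̂²)), always inside (−1, 1). Computing the
  statistic on the same transformed scale (rather than only transforming
  the interval) is what keeps interval and p-value decisions compatible
  for this variant too; the two scales agree to first order as δ̂ → 0.
  Pairwise effects π ∈ (0, 1) are rescaled to 2π − 1 before the transform
  and mapped back.

**Degenerate contrasts.** When a contrast variance estimate falls below
1e-12 the data carry no usable information on that scale (total ties — or
complete separation, where the placement-based variance estimate is
exactly zero). Such contrasts are flagged and report statistic 0, p-value
1 and the uninformative maximal interval ([−1, 1] on the contrast scale,
[0, 1] for pairwise effects); a point interval at the estimate would
falsely claim infinite precision and could contradict the p-value. Effects
at the boundary |δ̂| = 1 are clamped to 1 − 1e-12 before the Fisher
transform, with a warning.

**Pairwise variant.** π_dom = (n₁ŵ₁₃ + n₂ŵ₂₃)/(n₁+n₂),
π_add = ŵ₁₃, π_rec = (n₂ŵ₁₂ + n₃ŵ₁₃)/(n₂+n₃), each tested against ½.
The n-weighted combination is used because the pooled comparison sample is
formed by pooling observations. Pairwise effects can be intransitive
(cyclic stochastic dominance); every result carries a transitivity flag,
and the global-ranking version is the default and recommended procedure.
One-sided tests and logit/probit interval scales are out of scope.

## Simulation model

Each subject receives two haplotypes drawn independently from the two-locus
haplotype distribution (q₁q₂+δ, q₁(1−q₂)−δ, (1−q₁)q₂−δ, (1−q₁)(1−q₂)+δ) —
random mating, HWE — giving a trait-locus genotype and a marker genotype;
tests only ever see the marker. Genotypic values are (0, a, 2a), (0, a, a)
or (0, 0, a) for the additive/dominant/recessive mode, with a solving
V_g/(V_g + σ²) = h² under HWE at the trait locus (σ² = 1 by default).
Phenotypes are Y = μ_g + N(0, σ²); log-normal traits apply the standard
log-normal quantile transform Q_LN(Φ(Y)). Since that map is strictly
increasing, rank-based decisions are bit-identical between the normal and
log-normal versions of the same draws — the suite asserts this per
replicate, which is the distribution-free property in its sharpest form.

`run_study` redraws (and counts) replicates in which a marker genotype
class has fewer than 2 subjects, rather than dropping them silently: level
estimates stay interpretable while the count records how pathological the
design is. Rare marker alleles (q₂ = 0.1 at N = 100) make such draws
common and the separate-variance max-T visibly liberal — the expected
failure mode of Behrens-Fisher procedures in extreme unbalance, which the
validation suite checks as a directional property rather than hiding.

Comparators: tie-corrected Kruskal-Wallis, one-way ANOVA, trend regression
on 0/1/2 scores (all scipy), and parametric mean-contrast max-T tests —
pooled-variance with df = N − 3, and heteroscedastic with per-contrast
Satterthwaite plug-in. The balanced pooled-variance all-pairs version is
cross-checked in the tests against the studentized-range (Tukey)
distribution, an independent oracle.

Default grids (all configurable): N ∈ {100, 500}, q₁ = q₂ ∈ {0.1, 0.3,
0.5}, δ ∈ {0, δ_max/2, δ_max}, h² ∈ {0, 0.01, 0.05, 0.1}, α = 0.05,
spanning near-balanced to extremely unbalanced designs. The validation
suite and the acceptance script use 1,000–2,000 replicates per setting
(Monte-Carlo s.e. ≈ 0.005–0.007 at the 5% level) and 500–1,000 replicates
for power comparisons, with fixed seeds throughout; `Scenario.reps`
defaults to 10,000 for production-scale studies.

What the generator does *not* emulate: covariates and population
stratification (no adjustment is implemented — a genuinely open problem
for this class of procedures), missing genotypes, genotyping error,
departures from HWE, multi-locus effects, and genome-wide multiplicity.
Passing tests therefore support the procedure's level, power ordering and
invariance properties under this generating model, not performance under
confounding.

## Known limitations

* Exactly three groups (di-allelic markers); k-group generalization is out
  of scope.
* Liberal under extreme unbalance (smallest group ≲ 5): a consequence of
  separate variance estimation, documented and simulated rather than
  patched.
* Not intended for routine genome-wide scans; per-SNP runtime is dominated
  by the QMC quantile search (~50 ms).
* The pairwise variant can be intransitive; it is off by default.
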