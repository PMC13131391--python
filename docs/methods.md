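# Methods

## Scope and model

`ordidrift` analyses equal-interval ordinal scoring of a Gaussian latent
trait y = μ + u + e (u ~ N(0, σ²ᵤ) additive genetic, e ~ N(0, σ²ₑ)
residual, σ²_y = σ²ᵤ + σ²ₑ). A threshold system is k ordered categories cut
by interior thresholds τ₁ < … < τ_{k−1} with open-ended extremes; an offset
Δ ≥ 0 models a system whose thresholds lag the current mean (implemented as
τ_j − Δ applied to phenotypes, provably identical to μ + Δ applied to the
mean — both code paths exist and are tested against each other).

Binning convention: lower-closed, upper-open (`τ_{j−1} ≤ y < τ_j`); exact
boundary values take the upper score. Non-Gaussian latent distributions and
unequal interior bin widths are out of scope.

### Units

Thresholds and latent models carry a unit tag (`in` or `cm`, fixed factor
2.54). Stature scoring mixes both in practice (1-inch bins, cm-scale
evaluations), so every operation validates unit agreement and refuses mixed
calls rather than converting silently; `to_unit()` converts explicitly. The
BLP slope is therefore reported in score per *working* unit — 0.382/cm
equals 0.970/in for the default grid.

### Marginal vs conditional probabilities

Unconditional category probabilities integrate the *full* phenotypic
distribution (σ_y in the probit argument); probabilities conditional on a
breeding value use σ_e around μ + u. The distinction matters: the marginal
form reproduces the observed score distribution, the conditional form
drives the exact projection integrals.

## Projection

The BLP slope uses the closed Stein/convolution form
β = (1/σ_y) Σ φ((τ_j − μ − Δ)/σ_y). Projected components come in three
routes sharing that β and the analytic Var(s):

- `approx`: σ²ᵤₛ = β²σ²ᵤ, σ²ₑₛ = Var(s) − β²σ²ᵤ (the linearization of
  Var(g(u)); accurate when k is not small and thresholds not extreme);
- `quadrature`: exact Var(g(u)) and E[Var(s|u)] by Gauss–Hermite
  quadrature over u ~ N(0, σ²ᵤ), 64 nodes by default (physicists' nodes
  with the change of variable u = √2 σ t; the law of total variance
  Var(g) + E Var(s|u) = Var(s) is satisfied to < 1e−12 at the defaults,
  tested at 1e−8). The quadrature route is authoritative when the two
  disagree; for the 9-category stature grid they differ by under 1%.
- `monte_carlo`: the same expectations by simulation, used as a cross-check.

A negative approximate residual variance (possible only numerically) is
clamped to zero with a warning. E(s²|u) uses the tail-sum identity
E(s²|u) = k² − Σ (2j+1) Φ((τ_j − μ − Δ − u)/σ_e), which avoids forming all
k conditional probabilities. Rescaling scores by c multiplies β by c and
variances by c²; heritability is invariant exactly (both components carry
the same factor), not merely approximately.

The BLP intercept α equals E(s) because E(u) = 0; it is carried in the
result but plays no further role.

## Worked-example parameterization

Two presets are deliberately distinct:

- `paper_projection_model`: μ = 147.32 cm, σ_y = 4.75 cm, σ²ᵤ = 10.0 cm²
  (h² = 0.443) — the parameterization of the published projection table,
  which uses the baseline animal-model *estimate* of the genetic variance;
- `simulation_model`: σ_y = 4.75 cm with h² = 0.43 exactly — the
  simulation truth.

Threshold presets: `EI1` centres the 9-point, 1-inch grid at 58 in
(147.32 cm); `EI0` at 56 in (142.24 cm, the pre-recalibration system). The
closed forms are translation-invariant, so EI0 with μ = 56 reproduces EI1
with μ = 58 exactly (tested).

## Synthetic pedigree and phenotypes

The reference data set behind the published study (a proprietary
Brown Swiss pedigree of 12,909 animals, 5,141 with records) is not public;
the generator *emulates its size and depth*, never its structure:

- three discrete generations of 4,303 (12,907 ids): each female of the
  current generation is mated once to a male drawn with replacement
  (paternal half-sib families, as under artificial insemination), two
  offspring per mating; sexes by balanced random split;
- phenotypes on the whole final generation plus 19.5% of the middle one
  (≈ 5,141 records);
- breeding values simulated down the pedigree with Mendelian-sampling
  variance σ²ᵤ(0.5 − 0.25(F_s + F_d)); inbreeding coefficients by
  memoized recursive kinship (exact; negligible cost at depth 3, and
  essentially zero under random mating at this size, but tracked so that
  deliberately inbred test pedigrees are handled exactly);
- trait: N(147.32, 4.75²) cm with h² = 0.43; scores on the EI1 grid,
  rescaled ×5 to the 1–50 evaluation scale.

Equal generation sizes are a choice — the source states only totals. What
the generator does *not* emulate: overlapping generations, selection
history, assortative mating, herd/season fixed effects, and the real
pedigree's family-size distribution. Passing simulation tests therefore
demonstrate internal consistency of the estimation machinery under the
stated design, not agreement with any particular field data set.

## Gibbs sampler

Single-site updates for all pedigree members' u using the sparse rows of
A⁻¹ (Henderson's rules with inbreeding), a flat prior on μ, and scaled
inverse-χ² priors on both variances; variance draws use the full
conditionals (u'A⁻¹u + ν S²)/χ²_{ν+q}. Hyperparameters are unstated in the
source: defaults are ν = 4 with both prior scales at half the response
variance (prior h² of 0.5) — proper but weak next to ~5,000 records.
Initial values: half the response variance for each component.

Heritability is summarized as the posterior mean of the per-draw ratio
σ²ᵤ/(σ²ᵤ+σ²ₑ) (the ratio of posterior means is also reported; they differ
by < 0.01 in practice). The inner loop is compiled with numba; a chain on
the reference-size pedigree costs ≈ 0.8 ms/iteration.

Chain presets: the library default is 20,000 iterations (4,000 burn-in,
thin 10). The scenario study and test suite use 8,000 iterations (1,500
burn-in, thin 5) with 10 replicates — at ~5,000 records the posterior mean
of h² is stable well before that (block means of a 30,000-iteration
diagnostic chain wander by < 0.01), and the full five-scenario,
ten-replicate study completes in about six minutes on one core. Scores are
modelled *linearly*, exactly as in routine evaluations — measuring what
that mis-specification does under threshold drift is the object of study,
so no threshold-model link is fitted (a deliberate non-goal).

Degenerate inputs: constant phenotypes are rejected (variances
unidentifiable); degenerate priors (huge ν) pin the variances and are used
in tests to verify that posterior-mean EBVs converge to the BLUP solutions
of the mixed-model equations (solved directly, sparse LU, as the oracle).

## Scenarios and selection metrics

M0 continuous y; M1A group means of y within Δ=0 score classes; M1B ×5
scores at Δ=0; M2 at Δ=2 in; M3 at Δ=4 in. All five reanalyze the same
simulated records per replicate with matched chain seeds, so cross-scenario
contrasts are paired. ρ_y and ρ_u are Spearman correlations (average ranks;
scores are heavily tied) over phenotyped animals.

RSA: the published definition ("ratio of rank correlation between the
ordinal-scale and baseline evaluations") is ambiguous about the pairing, so
two readings are implemented: the default benchmark framing — rank
correlation of test vs baseline EBVs within the subset selected on baseline
EBVs (top-q, symmetric middle-q around the median, bottom-q) — and, when a
truth vector is supplied (simulations), the ratio
Spearman(test, truth | subset) / Spearman(baseline, truth | subset).
"Intermediate animals" are the symmetric central fraction, a definition the
source leaves open. The dilution pattern (larger RSA loss at top-5% than at
top-50%) holds under both readings; the absolute loss magnitudes are
pedigree-dependent and not comparable across data sets.

Selection intensity uses the exact normal-tail form φ(z_{1−α})/α; expected
response R = i_α r σᵤ is implemented literally. The published response
example pairs "1.35 (SD = 4.29)" with inputs whose literal product is
≈ 4.30; the package reproduces the product and leaves the unexplained 1.35
alone.

## Known numerical caveats

- Printed probability vectors and the Δ=0 projection column in the source
  carry visible rounding of intermediate quantities (normal quantiles at 2
  decimals; a threshold-density sum printed as 1.82 vs the exact 1.8132).
  Package output is exact; tests compare to printed values with tolerances
  of ≤ 0.002 (probabilities) and ≤ 1.5% (components) to absorb exactly
  that rounding, never implementation error.
- The M1B–M2 heritability contrast is small (≈ 0.01–0.02 truth gap) and
  its paired replicate noise is of the same order; occasional inversions in
  individual replicates are expected behaviour, not estimator failure.
- Spearman correlations from Monte Carlo at n = 10⁶ are reproducible to
  ±0.003 under the fixed seeds used in tests.
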