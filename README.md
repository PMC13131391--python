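# ordidrift

Quantitative-genetics toolkit for **threshold drift in ordinal trait
scoring**: what happens to phenotypic distributions, heritability, breeding
values and selection decisions when the bin boundaries of an equal-interval
ordinal scale lag behind a shifting population mean.

The worked case throughout is stature in dairy cattle. Stature is a
continuous trait, routinely recorded on a 1–9 linear score where each unit
spans one inch and the central score 5 straddles the population mean. As
cattle have grown taller, scoring systems calibrated decades ago place
today's mean two or more score classes above the intended midpoint, piling
records into the open-ended top category (a ceiling effect). `ordidrift`
provides the analytic machinery to quantify that distortion, and a
simulation + Bayesian-estimation pipeline to measure its consequences for
genetic evaluation.

## The model

A Gaussian latent trait y = μ + u + e, with additive genetic u ~ N(0, σ²ᵤ)
and residual e ~ N(0, σ²ₑ), is discretized by interior thresholds
τ₁ < … < τ_{k−1} (τ₀ = −∞, τ_k = +∞): the score is s = j iff
τ_{j−1} ≤ y < τ_j. An outdated system lags the mean by an offset Δ ≥ 0,
equivalent to shifting every interior threshold down by Δ. Key quantities:

- **Category probabilities** p_j = Φ((τ_j − μ − Δ)/σ_y) − Φ((τ_{j−1} − μ − Δ)/σ_y),
  with exact score mean/variance from the weighted sums.
- **Best linear projection (BLP)** of scores on breeding values,
  s = α + βu + r. By Stein's lemma the slope is a Gaussian convolution over
  the thresholds: β = (1/σ_y) Σ_j φ((τ_j − μ − Δ)/σ_y).
- **Projected score-scale components** σ²ᵤₛ ≈ β²σ²ᵤ,
  σ²ₑₛ ≈ Var(s) − β²σ²ᵤ, h²ₛ ≈ β²σ²ᵤ/Var(s) — with exact Gauss–Hermite
  counterparts Var(g(u)) and E[Var(s|u)], where g(u) = E(s|u). Rescaling
  scores by a constant multiplies variances by c² and leaves h² invariant.
- **Animal model** fitted by single-site Gibbs sampling (flat prior on the
  mean, scaled inverse-χ² priors on variances, pedigree A⁻¹ by Henderson's
  rules with inbreeding) to continuous phenotypes, group means, or rescaled
  ordinal scores generated under lagged thresholds.
- **Selection theory**: intensity i_α = φ(z_{1−α})/α, accuracy r = √h²ₛ,
  response R = i_α·r·σᵤ, and relative selection accuracy (RSA) — the rank
  correlation between an ordinal-scale evaluation and the continuous-scale
  baseline within the top/middle/bottom fraction a breeder would select.

## Worked example

```python
import ordidrift as od

model = od.report.paper_projection_model("cm")   # N(147.32, 4.75²), σ²u = 10 cm²
ts = od.report.stature_thresholds("EI1", "cm")   # 9 bins, 1 in wide, centred 58 in

for d_in in (0, 2, 4):
    ts_d = ts.with_delta(d_in * od.CM_PER_INCH)
    res = od.projected_components(model, ts_d)
    print(f"Δ={d_in} in: beta={res.beta:.3f}/cm  Var(s)={res.var_s:.2f} "
          f"σ²us={res.sigma_us2:.2f} σ²es={res.sigma_es2:.2f} h²s={res.h_s2:.3f}")
```

prints

```
Δ=0 in: beta=0.382/cm  Var(s)=3.39 σ²us=1.46 σ²es=1.93 h²s=0.430
Δ=2 in: beta=0.339/cm  Var(s)=2.80 σ²us=1.15 σ²es=1.65 h²s=0.410
Δ=4 in: beta=0.197/cm  Var(s)=1.25 σ²us=0.39 σ²es=0.86 h²s=0.311
```

— as the thresholds fall 2 and then 4 inches behind the mean, the score
distribution compresses into the ceiling, the regression of scores on
breeding values flattens, and score-scale heritability drops from 0.43 to
0.31. Selection accuracy √h²ₛ drops accordingly (e.g. 0.640 at h² = 0.409,
0.582 at 0.339), shrinking expected response under top-5% selection
(i₀.₀₅ = 2.063).

The simulation pipeline (`ordidrift all`, or `od.run_scenarios`) generates
a three-generation pedigree (~12,900 animals, ~5,100 phenotyped), simulates
the latent trait at h² = 0.43, and re-estimates variance components by
Gibbs sampling under five response codings (continuous, group means, and
rescaled scores at Δ = 0/2/4 in), reproducing the degradation pattern and
the RSA loss under intense selection.

There is also a CLI: `ordidrift bins`, `project`, `simulate`, `evaluate`,
`select`, `response`, `all` (see `--help`).

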