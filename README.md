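# tweediemix

Bayesian **Tweedie compound-Poisson partial linear mixed models** for
longitudinal *semicontinuous* outcomes — nonnegative responses with a point
mass at exactly zero, such as repeated WOMAC pain scores in an osteoarthritis
cohort — when both the response and some covariates are **missing not at
random (MNAR)**.

## The model

For subject *i* at visit *j*, conditional on a random effect
*b<sub>i</sub>* ~ N<sub>r</sub>(0, Σ),

> Y<sub>ij</sub> | b<sub>i</sub> ~ Tw<sub>p</sub>(μ<sub>ij</sub>, φ), 1 < p < 2,
> log μ<sub>ij</sub> = x<sub>ij</sub>ᵀβ + z<sub>ij</sub>ᵀb<sub>i</sub> + g(t<sub>ij</sub>)

The Tweedie law with power index p ∈ (1, 2) is a Poisson-many sum of gamma
variables: Y = Σ<sub>k≤U</sub> X<sub>k</sub> with U ~ Poisson(λ),
X<sub>k</sub> ~ Gamma(α, γ), giving E Y = μ, Var Y = φμ<sup>p</sup> and
P(Y = 0) = e<sup>−λ</sup> > 0 — a single integrated model for the zeros and
the positive part.  Its marginal density has an intractable normalizing
series, so inference augments each outcome with its latent count
U<sub>ij</sub>, whose joint density with Y<sub>ij</sub> is closed-form.

The smooth time trend g is a Bayesian P-spline: g(t) = Σ<sub>h</sub> ξ<sub>h</sub>B<sub>h</sub>(t)
with a first-order random-walk prior ξ<sub>h</sub> = ξ<sub>h−1</sub> + v<sub>h</sub>,
v<sub>h</sub> ~ N(0, τ²<sub>ξ</sub>/δ<sub>h</sub>), where τ²<sub>ξ</sub> is a
global and δ<sub>h</sub> are locally adaptive smoothing parameters.

Missingness of the response and of the first *m* covariates is modelled by
logistic selection models whose predictors include the possibly unobserved
values themselves (two variants: lagged-outcome logits, or logits sharing the
outcome across response and covariate indicators), which is what makes the
mechanisms nonignorable.  Missing continuous covariates get a sequential
conditional-normal model x<sub>k</sub> | x<sub>1..k−1</sub>, x<sub>obs</sub> ~ N(α<sub>k</sub>ᵀw, σ²<sub>k</sub>).

Everything is fitted jointly by an MH-within-Gibbs sampler that alternates
exact draws of the latent counts, data augmentation of the missing values,
random-walk Metropolis for (β, ξ, b, p, φ) and the selection coefficients,
and conjugate draws for Σ, τ²<sub>ξ</sub>, δ, α, σ².

## Worked example

```python
import numpy as np
import tweediemix as tm

design = tm.sim1()                      # 150 subjects x 4 visits, MNAR masks
data = tm.generate_dataset(design, seed=7)
print(f"missing: y {data.y_missing.mean():.1%}, "
      f"x1 {data.x_missing[:,0].mean():.1%}, x2 {data.x_missing[:,1].mean():.1%}")

summary = tm.run_chain(data, tm.prior_spec(design, "I"), design.mechanism(),
                       config=tm.MCMCConfig(iterations=2000, burnin=2000, seed=7))
print(summary.table().head(6).to_string(index=False))
```

prints (the missing rates of this draw, then posterior means/SDs against the
generating values β = (1, 1, −1), p = 1.5, φ = 0.5, Σ = 0.64):

```
missing: y 8.5%, x1 6.2%, x2 12.7%
parameter      mean       sd
    beta1  1.053293 0.094241
    beta2  0.914427 0.067201
    beta3 -0.939952 0.098451
        p  1.527931 0.021986
      phi  0.532542 0.044794
    Sigma  0.593747 0.099594
```

Every posterior mean is within ~1.3 posterior SDs of its generating value.
`summary.curve(grid)` returns the pointwise posterior mean and 95% credible
band of g for plotting against sin(2πt).

The same pipeline is scriptable:

```bash
tweediemix simulate --design sim1 --seed 3 --out sim.csv
tweediemix fit --data sim.csv --mechanism A --iterations 2000 --burnin 2000 --out fitdir
tweediemix replicate --design sim2 --prior-type I --reps 10 --seed 1 --out table.csv
```

`replicate` writes the Bias / SD / RMS parameter-recovery table across
replications (Bias = mean estimate − truth, SD = spread of the estimates,
RMS = root-mean-square deviation from truth).

## Layout

| module | contents |
|---|---|
| `tweediemix.tweedie` | Tweedie distribution: parameterizations, sampling, augmented and marginal densities |
| `tweediemix.pspline` | B-spline bases, locally adaptive random-walk penalty and prior |
| `tweediemix.model` | data container, linear predictor, complete-data log-likelihood |
| `tweediemix.missingness` | selection mechanisms (both variants), sequential covariate model, mask generation |
| `tweediemix.sampler` | priors, MH-within-Gibbs engine, posterior summaries |
| `tweediemix.simstudy` | stock designs, replication engine, Bias/SD/RMS tables, curve estimates |
| `tweediemix.io` / `tweediemix.cli` | long-format CSV schema + `simulate`/`fit`/`replicate` commands |

See `docs/methods.md` for the modelling and algorithmic details, numerical
choices, and known limitations.
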