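# eramed

Bayesian extended redundancy analysis (ERA) with multiple mediators and
mixed continuous/ordinal outcomes.

Blocks of predictors are reduced to unit-variance weighted composites
(components) that drive both a multivariate-t mediator regression and a
mixed-outcome response regression with correlated multivariate-t errors.
Ordinal outcomes are handled through latent variables whose t distribution
(df 7.3, variance-matched scale) approximates the logistic law, so their
identified coefficients read as log odds ratios.  All parameters — weights,
direct effects, mediator effects, covariances, cutpoints, degrees of
freedom — are estimated jointly by a Gibbs sampler with Metropolis steps
for precisions and df, truncated-normal data augmentation for the ordinal
latents, and parameter-expansion moves for the covariances.  Indirect
(mediated) effects are computed per posterior draw as products of path
coefficients.

## Layout

| module | contents |
|---|---|
| `eramed.mvt` | t/logistic approximation constants, scale-mixture helpers |
| `eramed.model` | `ModelSpec`, `Dataset`, parameter containers, validation |
| `eramed.simulate` | synthetic-data generator incl. `default_scenario` |
| `eramed.sampler` | the MCMC engine (`fit`, update operations) |
| `eramed.effects` | indirect/direct/total effects, posterior summaries |
| `eramed.diagnostics` | trace extraction, ESS, Geweke z |
| `eramed.io` | CSV/YAML/JSON I/O, run manifests |
| `eramed.cli` | `eramed simulate | fit | summarize | diagnose` |

## Quick start (Python)

```python
import numpy as np
from eramed import default_scenario, fit, McmcSettings, indirect_effects, summarize

spec, data, true = default_scenario(300, np.random.default_rng(7))
draws = fit(data, spec, settings=McmcSettings(n_iter=30_000, burn_in=2_000,
                                              thin=5, seed=1))
for s in summarize(indirect_effects(draws).reshape(draws.n_draws, -1)):
    print(s.label, round(s.mean, 3), (round(s.lo, 3), round(s.hi, 3)))
```

## Quick start (CLI)

```bash
eramed simulate --n 300 --seed 7 --out sim/
eramed fit --data sim/ --iters 30000 --burnin 2000 --thin 5 --seed 1 \
           --out sim/draws.csv
eramed summarize --draws sim/draws.csv --config sim/model.yaml \
                 --out sim/effects.csv
eramed diagnose --draws sim/draws.csv --config sim/model.yaml --params "w[0,0],nu_c"
```

`fit` writes a wide CSV of retained draws (one row per draw, columns like
`a3[1,0]`) plus a JSON run manifest with settings, seed, wall time and
Metropolis acceptance rates.  Runs are bit-for-bit reproducible at a fixed
seed.

## Notes

- Ordinal outcomes use 1-based category codes `1..J`; cutpoints are
  strictly increasing with the first fixed at 0.
- Component standardization uses ddof=1 sample variance; the first weight
  of each block is constrained nonnegative for sign identifiability.
- Ordinal-outcome draws are stored on the identified scale
  (latent residual variance 1); `identified_rescale` is idempotent there.
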