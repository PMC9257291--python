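# wingcontrast

Tools for asking whether conspicuously contrasting ventral wings in birds
track ecological proxies of in-flight collision risk. The package covers the
full analysis chain: objective contrast scoring of wing images, aggregation
of a multi-scorer classification panel, assembly of an ecological predictor
table, and Bayesian phylogenetic mixed models averaged over a set of
candidate trees — plus a synthetic-data generator that emulates every input
with known ground truth, so the whole pipeline is testable without any
museum images, field observations, or downloaded phylogenies.

## The statistics

**RMS contrast.** After background removal and greyscale conversion, an
image's contrast is the sample standard deviation of its wing-pixel grey
values x_i (0–255 scale):

    RMS = [ 1/(n-1) · Σ (x_i − x̄)² ]^{1/2}

Uniform wings score 0. Species values are the mean over images, then
log-transformed.

**Manual score.** S = 30 scorers each classify every image as contrasting /
non-contrasting; an image's manual score is its count of contrasting votes
(0–30) and a species' score is the mean over its images.

**Phylogenetic mixed model.** For species-level response y,

    y = Xβ + u + e,   u ~ N(0, σ²_p A),   e ~ N(0, σ²_e I)

with A the unit-height phylogenetic covariance (shared root-to-tip path
lengths under Brownian motion). Predictors: log body mass, log flock size,
coloniality, sqrt predator richness, activity time, and a coloniality×mass
interaction, continuous terms centred. The model is Gibbs-sampled with a
parameter-expanded prior on σ²_p (V = 1, ν = 1, α ~ N(0, 1000)) and an
almost-flat inverse-Wishart on σ²_e (V = 1, ν = 0.002); chains run 75 000
sweeps, 7 500 burn-in, thinned by 40. The phylogenetic signal is reported as
λ = σ²_p / (σ²_p + σ²_e) per draw, and posterior summaries (mean, 95% HPD
interval, pMCMC, ESS) are averaged over models fitted on many candidate
trees. A profiled-GLS maximum-likelihood fit over a λ grid serves as an
independent oracle for the sampler.

## Worked example

The numbered scripts under `analysis/` run the full chain on a reduced-scale
synthetic study (400 species, 140 with museum images, 10 trees) and write
tables under `results/`:

```
python analysis/01_simulate_dataset.py
python analysis/02_score_images.py
...
python analysis/07_recovery_experiments.py
```

`02` prints the imaging/scoring link — truly contrasting wings score far
higher RMS contrast than non-contrasting ones:

```
280 museum images scored, 140 species
mean RMS contrast: contrasting wings 89.1, non-contrasting 20.0
```

`05` fits the mixed model over 5 trees and prints the averaged coefficient
table (posterior mean, s.e., pMCMC, ESS) next to the generator's truth, and
`07` runs the parameter-recovery experiments:

```
lambda: truth 0.77, recovered median 0.819
validation slope: truth 0.676, recovered median 0.677
validation R^2: truth 0.891, recovered median 0.891
```

i.e. data simulated with phylogenetic variance fraction 0.77 return a
posterior-mean λ close to 0.77, and simulated manual/RMS score pairs with
slope 0.676 and population R² 0.891 are recovered by the validation
regression. The same functions are importable directly:

```python
from wingcontrast.phylo import simulate_yule, vcv_from_tree
from wingcontrast.pcmm import fit_mcmc, MCMCSchedule
from wingcontrast.synth import simulate_response
import numpy as np

tree = simulate_yule(300, 1.0, seed=1)
V = vcv_from_tree(tree, scale=True)
X = np.ones((300, 1))
y = simulate_response(X, V.matrix, [10.0], 0.77, 25.0, seed=2)
fit = fit_mcmc(y, X, V, schedule=MCMCSchedule(15_000, 1_500, 10, seed=3))
print(fit.lambda_mean)        # ~0.77
```

There is also a CLI (`wingcontrast synth / image-score / manual-score /
prep / run`) wrapping the same functions for shell use.

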