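# Methods

## Imaging

Images are 8-bit RGB or RGBA rasters. The wing mask comes either from the
alpha channel (alpha > 0) or, for key-colour backdrops, from Euclidean RGB
distance to the key exceeding a tolerance (default 10 on the 0–255 scale;
museum-style backdrops are near-uniform, so a small tolerance is enough).
Greyscale conversion uses the ITU-R BT.601 luma weights 0.299/0.587/0.114 —
the common imaging default; the weights are a function argument, and grey
values are kept real-valued (never re-quantised) because the contrast
statistic is computed on them. RMS contrast is the sample standard
deviation (n−1 denominator) of the masked grey values; it is
scale-dependent, so the 0–255 convention is fixed and stated here. Species
with several images get the arithmetic mean of per-image RMS *before* the
log transform, mirroring the species-level averaging of the manual scores.
A perfectly uniform wing has RMS 0; its log is taken as log(RMS + 1e-6)
with a warning, so such species stay in downstream models instead of being
dropped silently.

## Manual scoring

The scorer panel is a complete design: every scorer classifies every image,
and ragged panels are rejected rather than imputed. The canonical score is
the *count* of contrasting votes (0..S; 0–30 for the default 30-scorer
panel), with a proportion accessor for convenience; species scores are
means of image scores, so count vs proportion averaging is equivalent up to
the factor S.

## Trait table

Transforms: natural log for body mass and flock size, square root for
predator richness; binary coloniality (non-colonial baseline) and activity
(diurnal baseline); interaction = coloniality × centred log mass.
Continuous predictors are centred after the missing-data filter, and the
centering offsets, transforms and log base are recorded in the design
metadata (slope scales are meaningless without them). Any unparseable or
empty cell in the five trait columns — or a missing response — drops the
species. VIFs are computed on main-effect columns only, each from an
intercept-included auxiliary regression, because interactions built from
centred components inflate VIF mechanically; the conventional < 1.5
threshold is reported, not enforced.

## Phylogenetic covariance

V[i, j] is the shared root-to-tip path length of tips i and j, built
edge-by-edge (each edge adds its length to all pairs of descendant tips),
which handles polytomies without special cases. Trees are scaled to unit
height before inference so variance components are comparable across trees
of different depths. Pagel's λ transform multiplies off-diagonals by λ and
is exactly multiplicative under composition. Pruning an ultrametric tree to
a tip subset leaves the remaining shared path lengths intact up to the
constant root shift, so covariance sub-matrices double as pruned-tree
covariances; species present in the table but absent from a tree are an
error, never silently dropped.

## The mixed model and its sampler

The model is y = Xβ + u + e with u ~ N(0, σ²_p A) and e ~ N(0, σ²_e I),
Gaussian response. Priors: scalar inverse-Wishart IW(V=1, ν=0.002) on σ²_e
(almost flat), and a parameter-expanded IW(V=1, ν=1) on σ²_p with working
location α ~ N(0, 1000): the phylogenetic effect is written u = α·v,
v ~ N(0, σ²_v A), so σ²_p = α²σ²_v. Parameter expansion keeps the chain
mixing when σ²_p is near zero, where the plain conjugate sampler sticks.
Fixed effects take an improper flat prior.

A single eigendecomposition A = Q D Qᵀ (eigenvalues floored at 1e-10)
rotates data and design into a basis where every full conditional is
diagonal; each Gibbs sweep then costs O(np) and the samplers for β, v, α,
σ²_v, σ²_e are all exact conjugate draws. Chains are deterministic
functions of a single integer seed (numpy Generator). Draws are retained at
sweeps burn_in + thin, burn_in + 2·thin, …, giving exactly
floor((n_iter − burn_in)/thin) draws — 1687 under the default
75 000 / 7 500 / 40 schedule.

Conventions for the summaries:

- **λ** is the per-draw variance fraction σ²_p/(σ²_p + σ²_e), posterior
  mean — the heritability-style quantity mixed-model users report as
  Pagel's λ. A separately profiled GLS λ̂ (grid of 101 values on [0, 1],
  β and σ² profiled analytically) is exposed as an independent estimate
  and serves as the sampler's oracle in tests.
- **pMCMC** = 2·min(P(>0), P(<0)), floored at 2/n and capped at 1.
- **95% CI** is the highest-posterior-density (shortest) interval; a
  central quantile interval is available by flag.
- **ESS** = n/(1 + 2Στ̂) with Geyer initial-positive-sequence truncation of
  the autocorrelation (consecutive pair sums kept while positive); a
  constant chain reports ESS 0 with a warning.
- **Model averaging** over k trees sampled without replacement: arithmetic
  means of per-tree posterior means, pMCMC, ESS and λ; the reported "s.e."
  is the mean of per-model posterior standard deviations. Per-tree chain
  seeds derive from the master seed through a numpy SeedSequence, so runs
  are reproducible end to end; any single-tree failure aborts with the tree
  index.
- **Bayesian R²** (validation regression) is per-draw
  var(Xβ)/(var(Xβ) + σ²_p + σ²_e) — the marginal R² with both non-fixed
  components counted as residual — averaged over draws. The validation
  regression z-scores its predictor, so the slope is per SD of log-RMS.

## Synthetic data

The generator's defaults mirror the study scale: 1980 species, 200 with at
least one missing trait, 682 museum-imaged species of which 17 carry
missing traits (so 1780 and 665 survive the filter), 30 scorers, Table-2-
scale fixed effects, λ = 0.77 and total variance 25 for the latent
contrast. Trees are pure-birth (Yule): starting from the root's two
lineages, splits arrive at rate k·b with k extant lineages, plus a final
Exp(n·b) stretch after the last split, giving expected height
Σ_{k=2..n} 1/(k·b); trees are exactly ultrametric and deterministic under
seed. Log body mass evolves by Brownian motion on the tree so predictors
themselves carry phylogenetic signal — the confounding the real analysis
faces (an independent-predictor mode exists for clean unit tests, and the
coloniality–mass logit slope defaults to 0 so recovery tests are
unconfounded). Flock size is log-normal, predator richness Poisson(20),
nocturnality Bernoulli(0.05), coloniality Bernoulli(≈0.15).

The measurement channel: each species gets 1–3 images whose
contrasting/non-contrasting truth is Bernoulli with probability
clip(latent/S, 0, 1), and each of S scorers votes the truth flipped
independently with probability 0.1 (a realistic panel error; the scorer
protocol itself reports no rate). The expected species score equals the
latent trait wherever the latent lies inside [0, S], so end-to-end
coefficient recovery is unbiased — but the image-level Bernoulli sampling
adds substantial independent measurement noise, so the variance fraction λ
of the *measured* score is genuinely attenuated relative to the latent
λ = 0.77 (visible in the analysis drivers). Real museum photo panels are
far less noisy per image than an independent Bernoulli per image; this is
the main respect in which the generator is harsher than real data, and it
is why the λ-recovery experiments draw the response directly from the
generative model rather than through the vote channel. The generator also
does not attempt real wing shapes, taxonomic structure, or the empirical
score distribution.

Synthetic wing images are ellipses on a magenta key-colour background (or
alpha-masked), tiled by a patch grid in up to two colours; the truth label
is "contrasting" iff both colours each cover more than 5% of the wing's
patches, and non-contrasting images carry the second colour on at most 5%.

## Problem sizes and numerical choices

Tests and analysis drivers run at reduced scale chosen to keep the default
suite fast while leaving the estimators in their asymptotic regime:
recovery experiments use 15 000-sweep chains (burn-in 1 500, thin 10; 1 350
draws) on 300–682 tips, where the retained draws put the Monte-Carlo error
of a posterior mean an order of magnitude below the reported tolerances;
the credible-interval calibration check runs 200 simulations at 60 tips
with 2 500-sweep chains; the end-to-end dataset recovery check uses 8
replicates of 200 species with error-free scorers (isolating the
evolutionary signal from panel noise). Eigenvalues of A are floored at
1e-10; the design matrix must be full rank (singular XᵀX is an error, as is
a perfectly collinear VIF column, which reports ∞ with a warning).

## Limitations

Gaussian responses only (scores are treated as continuous, as in the
analysis this mirrors); single random effect (phylogeny); no non-Gaussian
families, multi-response models, or information-criterion comparison. The
manual score's bounded 0–30 scale is modelled as unbounded Gaussian, which
is adequate away from the bounds but misspecified for species pinned at 0
or 30. Tree uncertainty is absorbed by averaging over candidate trees, not
by joint inference.
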