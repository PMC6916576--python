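# Methods

This note documents the model implemented by the package, the choices made
where the design was genuinely open, the numerics, and the limits of what the
synthetic-data tests demonstrate.

## Model

### Calibration stage

Pollen counts at basin `i` are Dirichlet-multinomial, `y_i ~ DM(n_i, φ_i)`,
with per-taxon concentrations

    φ_{i,k} = γ_k φ̂_k r_{s(i),k} + (1/C_i) (1 − γ_k) φ̂_k Σ_{j≠s(i)} r_{s_j,k} W[s(i), s_j]

- `γ_k ∈ (0,1)`: fraction of taxon-k pollen of local (own grid cell) origin.
- `φ̂_k > 0`: pollen productivity. The concentration total `Σ_k φ_{i,k}`
  sets the overdispersion (large total → multinomial limit), so the absolute
  scale of `φ̂` is identified by the data through the count variance; `φ̂` is
  therefore sampled freely (lognormal prior) rather than normalized to a
  fixed sum. Fixing the sum would misspecify the model against its own
  forward simulations.
- `W` is the dispersal kernel density times cell area, diagonal excluded;
  `C_i` is the off-diagonal row sum for the focal cell. Computing `C` per
  focal cell makes the non-local term a proper weighted average and treats
  edge cells consistently with interior ones. On a single-cell grid the
  non-local term vanishes (only `γ_k φ̂_k r` remains).
- Kernels (normalized to integrate to 1 over the plane):
  inverse power-law `k(d) = (b−2)(b−1)/(2π a²) (1 + d/a)^(−b)` (default;
  requires `b > 2` for a finite 2-D normalization) and Gaussian
  `k(d) = exp(−(d/a)²)/(π a²)`. Distances are planar Euclidean on projected
  km coordinates; the kernel is shared across taxa by default (per-taxon
  parameters are a constructor option).

Priors (overridable): `γ_k ~ Beta(2,2)`; `log φ̂_k ~ N(log 10, 3²)`;
`a ~ half-Normal(domain diameter / 4)`; `b − 2 ~ half-Normal(2)`. The
posterior (dimension `2K + 2`) is sampled with an affine-invariant ensemble
sampler (emcee; differential-evolution moves, walkers initialized near a
Nelder-Mead posterior mode), default 4,000 steps × 48 walkers, half
discarded, thinned by 10. Acceptance fractions and integrated autocorrelation
times are reported on the results object.

As printed, the mixing equation's non-local sum carries the focal-cell
composition; context (a weighted sum of *other* cells' composition) requires
`r_{s_j,k}`, which is what is implemented. The per-taxon `γ_k` of the
calibration stage is retained in prediction.

### Prediction stage

Latent fields `g_{s,t,k} ~ N(μ^g_{s,t,k}, σ²_{s,t,k})` map to proportions by
softmax over taxa. The process mean is

    μ^g_{s,1,k} = μ_k + ν^s_{s,k}
    μ^g_{s,t,k} = μ_k + ν^s_{s,k} + μ^t_{t,k} + ν^st_{s,t,k},   t ≥ 2

- `μ_k ~ N(0, μ_scale²)` (default scale 1): overall ALR-scale adjustment.
  The softmax location non-identifiability is resolved by these zero-mean
  priors (a sum-to-zero constraint across taxa is not imposed).
- `μ^t_{t,k}`: spatially invariant temporal mean; `N(0, ξ²)` at `t = 2`, then
  a random walk `N(μ^t_{t−1,k}, ξ²)`. A damped AR(1) variant
  (`mean = ω_t μ^t_{t−1,k}`) is selectable via
  `SpatialHyperparams(temporal_model="ar1")`.
- `ν^s = c C*⁻¹ α^s`: modified predictive process with exponential
  covariance `η_k² exp(−d/ρ_k)` evaluated at knots (a regular subgrid, every
  m-th cell, default m = 2), `α^s ~ MVN(0, C*)`.
- `ν^st`: innovations with the same projection; knot coefficients are AR(1),
  `α^t_t ~ MVN(ω α^t_{t−1}, (1−ω²) C*)`, initialized at stationarity
  (`α^t_2 ~ MVN(0, C*)`), so the prior variance is constant across time.
  The innovation covariance is implemented with `C*` (not its inverse): the
  stationary-variance identity `Σ = ω²Σ + (1−ω²)C* ⇒ Σ = C*` and the
  variance-correction formula both require it. A consequence of stationary
  initialization is that the first innovation (bin 2) is a full-amplitude
  field relative to the bin-1 mean; with `ω → 1` composition freezes across
  innovation bins (t ≥ 2).
- Process variance: `σ² = η² − (c C*⁻¹ c′)_ss + τ²` at `t = 1`, with the
  same correction added once more scaled by `(1 − ω²)` for `t > 1`, i.e. the
  marginal variance minus what the low-rank projection explains, plus a
  nugget `τ² = 1e-5` that keeps the variance positive at knot-coincident
  cells. Negative values from round-off are clipped at `τ²` with a warning.
- `(η_k, ρ_k)` are estimated a priori from the settlement-era composition:
  each taxon's centered log-ratio field is fitted with the
  predictive-process marginal likelihood (Woodbury form) by multistart
  Nelder-Mead maximum likelihood. Point estimates were chosen over posterior
  medians because, on single fields at desk scale, the weak log-range prior
  pulled the median up by factors above two while the ML estimate recovers a
  100-km range within a factor of two in 10/10 replicates on a 20×20 grid.
  Note the settlement-era field carries both the time-invariant component
  and the accumulated innovations, so `η` estimated this way is an estimate
  of the *total* field scale — the same convention the procedure implies.
- `ω` and `ξ` are fixed configuration values (defaults 0.8 and 0.1), not
  sampled.

### Sampling

The posterior over `(μ, μ^t, α^s, α^t, g)` — roughly `K(1 + M + (T−1)(1+M)
+ NT)` dimensions, about 5,000 at the small size — is sampled with adaptive
Hamiltonian Monte Carlo (`stepps.hmc`) using analytically coded gradients on
a non-centered parameterization: each block is a deterministic transform of
standard-normal coordinates (Cholesky factors for the knot fields, scan
recursions for the AR chains, `σ`-scaled residuals for `g`), so the prior is
isotropic and the only non-trivial gradient is the Dirichlet-multinomial
likelihood propagated by the chain rule through the softmax, the mixing
operator, the kriging projection, and the AR recursions. Warm-up adapts the
step size by dual averaging (target acceptance 0.8) and a diagonal mass
matrix from an intermediate window; trajectories jitter the leapfrog count
(±20% around 24) to avoid resonances; transitions with energy error > 1000
count as divergences and are reported, as are split-R̂ and effective sample
sizes (via arviz) on tracked scalar series. Runs are exactly reproducible
given the seed. The gradient is verified against finite differences, and the
whitened density against an independently coded natural-parameterization
log posterior, in the test suite.

Dating uncertainty: each run bins the records under one joint age-model
posterior draw set and pairs them with one calibration-posterior draw;
posteriors are pooled across runs with provenance retained. Defaults are 4
age-draw sets at desk scale (the published configuration — 40 sets, warm-up
250, 2,000 iterations, every 40th retained — is available as
`PipelineConfig.paper_scale()`). Failed member runs are reported and pooling
proceeds over the successes.

### Change classification

Differences are computed within each posterior draw on the composition
implied by the smooth process mean `μ^g` (a full-field option uses `g`
including the nugget-scale heterogeneity). For a cell/taxon/time-pair:
significant change if the larger directional probability is ≥ 0.85 and the
posterior-mean abundance exceeds 3% at either time (the estimator for the 3%
ecological filter is the posterior mean); large change if
`P(|Δ| > 0.05) ≥ 0.85`; stable if `P(|Δ| < 0.03) ≥ 0.85`. The large-change
test is two-sided on `|Δ|`. Community level: any large-change taxon makes a
large-change cell (dominant = large-changer with the greatest posterior-mean
`|Δ|`); a cell is stable only if every taxon is. Exact ties `Δ = 0` count
toward neither direction. No multiple-comparison correction is applied
across the time-pair lattice. The most recent bin can be excluded from
analysis by configuration (as done for the 200 YB1950 bin in the published
analysis).

### Ecotone analysis

The cells × (taxon·time) matrix of posterior-mean composition is
column-centered and decomposed by SVD. The first spatial mode is oriented so
its mean over the northern half of the domain is positive. Stacking all time
bins yields one time-invariant spatial mode; per-time score fields are
obtained by projecting each bin's centered composition onto the first mode's
(unit-normalized) taxon loadings for that bin, so the score field — and its
zero line — moves as composition changes. Zero lines are marching-squares
contours (scikit-image) with the longest connected component retained;
default transects are 10 equally spaced lines perpendicular to the
reference-time ecotone (normals averaged over a 5-vertex window), and
displacement is the signed km along each transect from the reference-time
intersection (nearest-to-anchor on multiple intersections; missing
intersection → NaN). The EOF input (raw proportions, all taxa) and transect
layout are package defaults; both are explicit parameters.

## Synthetic data

The generator draws every latent block from the model priors and the counts
from the mixed Dirichlet-multinomial — it is the model run forward, plus an
age-error process: AR(1)-correlated noise down-core (marginal sd 60 yr by
default, matching decadal-to-centennial age-model uncertainty) projected to
monotone age-depth relations by pool-adjacent-violators, per joint draw set.
Sites are uniform over the domain (a density-gradient option emulates uneven
record networks). The fossil network defaults to 30 sites with ~300 grains
per sample; the settlement-era calibration pair has its own denser network
(200 sites, ~500 grains), mirroring the structure of real applications where
the calibration dataset is much larger than the fossil one. Default truth:
γ = 0.85 for all taxa, productivities spread 3–15, inverse power-law kernel
(a = 40 km, b = 4), η = 1, ρ = 100 km, ω = 0.8, ξ = 0.1 on a 10×10 grid of
24-km cells with 8 centennial bins ending at 150 YB1950.

What passing recovery tests show — and what they do not: the pipeline is
internally consistent (simulating from the model and refitting recovers γ,
the composition fields, and interval calibration at nominal rates). They do
not validate the model against real vegetation: real pollen–vegetation
relationships involve taphonomy, basin-size effects, surveyor biases and
non-stationary dispersal that the generator deliberately omits. A practical
ceiling at desk scale: the truth field includes nugget-scale cell-level
noise that no estimator can predict at unobserved cells, which bounds the
attainable posterior-mean/truth correlation (≈ 0.78–0.82 across seeds at the
default size) independently of sampler quality.

## Numerics and conventions

- Time is YB1950 (years before AD 1950; larger = older). Bins are 100-yr,
  half-open `[lower, upper)`, ordered oldest first; `t = 1` is the oldest
  bin. Bin labels are midpoints (the 350–250 bin is "300 YB1950").
  Postsettlement samples (younger than 150 YB1950 or a per-site settlement
  horizon) are excluded; samples older than the oldest edge are dropped with
  a logged count; same-site same-bin samples are summed.
- Sites map to cells by nearest cell center, ties to the lowest index.
- Covariance Cholesky factorizations fall back to a 1e-8 diagonal jitter,
  logged; a failure after jitter raises.
- Softmax uses max-subtraction; concentrations are floored at 1e-12 inside
  the likelihood to keep gradients finite in extreme corners.
- NetCDF output uses xarray's scipy backend (NetCDF-3) with the seed and a
  config hash embedded; identical config + seed reproduce byte-identical
  files.
- All random streams derive from explicit seeds; derived seeds stay below
  2³¹.

## Limitations

- The HMC uses fixed-length jittered trajectories, not a dynamic no-U-turn
  criterion; at the sizes exercised here effective sample sizes per minute
  are adequate, but very large grids would warrant the dynamic sampler and
  sparse/partitioned gradient evaluation.
- `ω` and `ξ` are fixed rather than estimated by default.
- The EOF ecotone is a single dominant-mode proxy; domains with multiple
  ecotones would need per-component handling beyond the longest-contour
  rule.
- No geographic reprojection: all coordinates are grid-local km.
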