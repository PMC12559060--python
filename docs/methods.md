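# Methods

## The model

`marapop` implements a hierarchical Bayesian integrated state-space model of
an age- and sex-structured large-herbivore population observed at a monthly
time step, motivated by the Mara–Serengeti topi (*Damaliscus lunatus
jimela*): a seasonally breeding resident grazer with an 8-month gestation, a
3-month lactation pause, and therefore an ~11-month conception cycle.

### Latent state

The population each month is a 34-component integer vector:

* `N` — newborns, age [0, 1) month;
* `G(k)`, k = 2..19 — juvenile monthly cohorts of age [k−1, k); quarters are
  cohorts 2–6, half-yearlings 7–19;
* `P(ℓ)`, ℓ = 1..12 — adult females that last gave birth ℓ months ago
  (ℓ = 12 means ≥ 12); only `P(11) + P(12)` can conceive;
* `Fa` — females newly recruited to adulthood this month (they join the
  breeding cycle at `P(4)` the following month, giving birth 8 months after
  recruitment);
* `Ma`, `Mb` — newly recruited and surviving adult males.

Transitions are binomial thinning along the cohort conveyor, a trinomial
split of the oldest juvenile cohort into female recruits, male recruits and
deaths, and a binomial birth draw `N(t) ~ Bin(P(t,11) + P(t,12), r(t))`
taken *after* the adult female classes advance (the within-month order is:
adult females, recruitment and male survival, juvenile cohorts, births).
The exact transition log-pmf is the sum of all factor log-pmfs and is the
likelihood the samplers use; `tests` verify it is a proper pmf by exhaustive
enumeration on tiny states.

### Vital rates

Natural (predation-free) rates come from logit-linear models on a monthly
covariate table: a cubic month polynomial, lagged rainfall and moving
averages (the pre-birth window `rain(7–11)` is the mean over lags 6–10),
lag-1 seasonal rainfall totals, temperatures, and lagged population indices
(`Npop` at lag 7 ≈ conception time, `Apop` at lag 1) for density dependence.
Month and season enter the survival and sex-ratio models as indicator-
selected intercepts.  Continuous covariates are z-scored (the scaling
constants are stored for back-transformation); indicator columns never are.

Predation is a fixed, tuned multiplicative factor, not an estimated
parameter: survival = natural survival × (1 − risk), with the risk reduced
to 70% of its wet-season value during the dry season (July–October, when
migratory prey flood the system), and adult male survival fixed at 99.7% of
adult female survival.  Baseline risks default to (newborn 0.10, quarter
0.05, half-yearling 0.03, adult 0.02) and are exposed in `PredationConfig`.

### Observation layer

Ground counts per class are gamma–Poisson: an intensity
`λ ~ Gamma(Y²/σ², Y/σ²)` (mean Y, variance σ²) with a Poisson count, so
counts are unbiased for the latent class total with variance `Y + σ²`.  In
the likelihood the intensity is marginalized analytically (negative-binomial
form); the equivalence to the two-stage formulation is tested by quadrature
and by Monte-Carlo moments.  A latent class total of zero cannot explain a
positive count (−∞), which the samplers must and do respect.

Sparse aerial surveys estimate the ecosystem-wide total.  At each survey
month, a ratio `K > 1` (prior `1/K ~ Beta(1,1)`, i.e. density ∝ K⁻² on
K > 1) links the reserve total `B` to an ecosystem intensity
`λ_T ~ Gamma(mean K·B, var σ_T²)`, the true ecosystem total
`℧ ~ Poisson(λ_T)`, and the published estimate `Ψ ~ N(℧, σ_Ψ²)`.  `K`,
`λ_T`, `℧` are latent per survey month and independent across surveys.

The ×1.7 newborn sightability correction is a screening-stage device for
deriving starting values only; it never enters the MCMC likelihood.  The
×1.33 aerial display correction is likewise excluded from the likelihood.

### Priors and initial state

Coefficients: independent normals, variance 10,000 (mean 0 by default; a
pilot run can re-center).  Observation variances: flat on (0, ∞), sampled
by log-scale random walks with the log-Jacobian.  Initial states: normal
with variance 20,000 around data-derived means — average June class shares
applied to the early ground-count total, split uniformly within the
quarter, half-yearling and pregnancy classes — except `N(0)`, which keeps
its binomial model given `P(0,11) + P(0,12)` (using the normal there too
would double-count a prior on the same quantity).

## Inference

Metropolis-within-Gibbs with:

* **Transformation MCMC** for each coefficient block: one scalar innovation
  `ε = |N(0,1)|` and independent random signs `b`.  Early in burn-in the
  move is `γ + (b ∘ scales)·ε` with per-coordinate scales proportional to
  starting magnitudes; once burn-in has accumulated enough draws the move
  becomes `γ + ε·m·(L b)` where `L` is the Cholesky factor of the block's
  estimated posterior covariance and `m` a per-block multiplier adapted
  toward ~30% acceptance.  Either form is additive and self-inverse
  (flip every sign) with unit Jacobian, so acceptance is
  `min(1, exp(Δ log-joint))`.  The covariance preconditioning matters:
  block coefficients span two orders of magnitude and the z-scored cubic
  month polynomial is strongly collinear, so un-preconditioned coordinate
  moves explore the posterior ridge extremely slowly.  Adaptation stops at
  the end of burn-in.
* **Latent trajectory**: symmetric integer random walks (sign × geometric
  step, per-component step means adapted in burn-in) over every
  (month, component) site.  Every update evaluates the exact local change
  in the reconstructed log-joint; constraint violations get −∞ and are
  rejected, so feasibility is invariant.  The hot path is a numba kernel
  that consumes pre-drawn randomness and is verified draw-for-draw against
  a pure-Python reference; a T = 2 miniature model is checked against the
  exhaustively enumerated posterior.
* **Aerial latents**: `λ_T` by its exact conjugate full conditional
  (`Gamma(α + ℧, β + 1)` — the gamma intensity is conjugate to the Poisson
  count); `℧` by an independence proposal around the Gaussian-product
  optimum of its Poisson and Normal factors; `K` by a 50/50 mix of local
  random walks and independence proposals centred on `λ_T / B`, all with
  exact Metropolis corrections.  Plain random walks here mix so slowly
  that the three-way chase between `K·B`, `λ_T` and `℧` inflates the
  realized residuals, which in turn inflates `σ_T²` (see below).

Two identifiability repairs in the aerial layer, both documented
deviations from flat-prior defaults:

* `σ_Ψ²` is held at the survey-SE value (mean of `se²`) rather than
  sampled: with both aerial variances free, either can absorb the
  `K·B`-vs-`Ψ` mismatch and the pair is jointly unidentified.
* `σ_T²` gets a half-Cauchy prior on `σ_T` (scale 1,000 animals) instead
  of a flat prior.  Because the per-survey ratio `K` can zero the gamma
  residual at *any* `σ_T²`, the marginal likelihood for `σ_T²` is flat and
  a flat prior leaves the chain drifting into a regime (`σ_T` ~ thousands)
  where the aerial data no longer inform `K` at all — an effect easy to
  demonstrate with the trajectory clamped at its generating values.

Desk-scale runs use 50,000-80,000 iterations after one-fifth as much
burn-in (thinned by 10); the published analysis scale is two orders of
magnitude larger.  A full fit of the 174-month scenario at 80,000
iterations takes about ten minutes on one CPU, which is the problem size
used throughout the tests and the acceptance script.

Diagnostics: split-free Gelman–Rubin from multiple chains, an
initial-positive-sequence autocorrelation ESS (truncated at the chain
length), and two-sample Kolmogorov–Smirnov prior-vs-posterior tests as an
estimability screen (a small p-value means the data moved the posterior).

### IRMCMC

To refit many related datasets cheaply, the reference chain stores a
thinned pool of (parameters, trajectory, data log-likelihood) snapshots.
For a new dataset, importance weights ∝ exp(ℓ_new − ℓ_ref) over the pool
select a restart (zero-weight draws are allowed; an error advises full MCMC
if all vanish).  The starting trajectory is rebuilt for the new data by
guided forward simulation: candidate transitions are drawn each month and
the one closest to the smoothed observed total kept, with a proportional
feedback boost on the rates and the resampled pool state (an equilibrated
age/breeding composition) as the seed — plain forward simulation starts
several percent off the new data's level, and the single-site latent
sampler relaxes level errors only diffusively.  After a latent-only
warm-up, a short chain runs the standard kernels while mixing in
independence proposals for the coefficient blocks drawn from a Gaussian
moment-match of the weighted pool.  The Gaussian has a computable density,
so the Metropolis correction is exact and the short chain targets the new
dataset's own posterior; the literal weighted-pool proposal has no density
once the chain leaves the pool.

### Linear-Gaussian approximation

A generalized Leslie matrix gives `E[Y_t | Y_{t−1}] = L Y_{t−1}` exactly
(the newborn row carries `r·s_a_f` on the `P(10..12)` columns and
`−r·s_a_f` on the `N` column because births draw from the *updated* pool).
Process noise is assembled from the binomial/multinomial variances and the
observation variances from the `Y + σ²` law, both evaluated along the
deterministic mean trajectory — not the filtered means — so the
approximating model is exactly linear-Gaussian and the Kalman-filter
log-likelihood equals the directly marginalized multivariate-normal
density (asserted to 1e−6 on a T = 3 toy).

## Validation machinery

* **Balanced bootstrap**: concatenate R copies of the unit indices, permute,
  split into R blocks — every unit is selected exactly R times overall.
* **Jolly's Method 2** for transects of unequal area:
  `R = Σy/Σz`, estimate `Z·R`, variance
  `N(N−n)/n · (s_y² − 2R s_zy + R² s_z²)` floored at 0, with the frame size
  `N` defaulting to `Z / mean unit area`.
* **Hypothetical series**: bootstrap ecosystem totals are interpolated to
  monthly resolution, scaled to the reserve by 1/K, allocated to the five
  observable classes by multinomial draws around the monthly class-share
  profile of the ground data, and pushed through the gamma–Poisson
  observation layer.  This recipe is a reconstruction; the coverage check
  compares each series' totals with the refitted 95% limits of `K·B`.
* **Predation scan**: forward simulation under scaled class-specific risks;
  the reserve total is far more sensitive to adult risk than to the same
  relative change in any juvenile class.

## The synthetic-data generator

All study conditions live in `ScenarioConfig` / `default_parameters()`:
174 months anchored at a June (t = 0), ~annual aerial surveys, an initial
reserve total of 6,000, overdispersion σ² = (100, 400, 400, 900, 900),
ecosystem/reserve ratio 2.4, and transect frames of 6,665.6 km² sampled by
180 units of 12.5/25/50 km².  The generating coefficients were chosen once
to encode the documented biology — births rare January–July rising to a
sharp October–November peak (the cubic month polynomial is a least-squares
fit to that target curve), natural monthly survival ≈ 0.98 (quarters) /
0.99 (half-yearlings) / 0.998 (adults), mild density dependence, a
female-biased recruitment ratio ≈ 0.58 — and give a deterministic annual
growth factor ≈ 0.92, a slow decline.

The density-dependence covariate (`Npop`/`Apop`) is an exogenous smooth
index carried with the bundle, so generation and fitting see identical
covariates; with real data the same column can be built by linearly
interpolating the aerial estimates (`monthly_population_series`).

What the generator does **not** emulate: spatial zone structure, real
rainfall records, survey-effort variation, migration, premature pregnancy
termination, and newborn-sightability dynamics.  Passing tests therefore
demonstrate internal correctness and recoverability under the model's own
assumptions, not robustness to the misspecifications real data would add.

## Numerical choices

* Probabilities are clamped to (1e−12, 1 − 1e−12); degenerate-rate identities
  hold to ~1e−6 over hundreds of trials.
* Fast gammaln-based log-pmf kernels replace `scipy.stats` calls in the hot
  path (they are checked against `scipy.stats` in the tests).
* Ties/degenerate inputs: a zero mean in the gamma–Poisson law is a point
  mass at zero; Jolly variance is undefined (NaN) for single-unit samples
  and floored at zero otherwise; ESS is capped at the chain length.
* Equal-tailed (2.5%, 97.5%) credible intervals throughout.

## Free-coefficient subset for recovery experiments

The default recovery experiment frees the birth-recruitment block (γR, 9
coefficients) and the sex-ratio block (γS, 9), 18 in all, fixing the
remaining blocks at their generating values.  The choice is about interval
calibration at desk scale: γR carries the strongest signal in the data
(newborn seasonality), and γS sits far from any boundary, so its weakly
informed coefficients get honestly wide intervals.  The survival blocks
are poor candidates for a desk-scale interval check for a structural
reason: the fixed predation factor caps realized survival below 1, so
natural-survival intercepts become likelihood-flat above a logit of ~7
and their marginals mix on prior time scales (γQ's 12 per-month dummies,
with ~15 observations each, drift visibly along this ridge at desk
scale).  The experiment uses 80,000 iterations after 16,000 burn-in
(about ten minutes on one CPU); a five-fold longer gold-standard run
shifts the freed coefficients' interval coverage from roughly 78% to 94%,
i.e. the residual error at desk scale is Monte-Carlo, not model, error.

## Known limitations

* Single-site integer random walks mix slowly for large latent counts;
  desk-scale interval widths for weakly identified month intercepts are
  wide and occasionally drift (survival near 1 is a soft boundary).
* `σ_Ψ²` is one scalar; per-survey standard errors only initialize it.
* The full conditional distributions are never used analytically; every
  update pays a log-joint evaluation (correct, slower than Gibbs).
* Coverage validation at 3 bootstrap series is a smoke-scale analogue of
  the 10-series design; run `analysis/03_validate.py --n-series 10` for a
  release check.
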