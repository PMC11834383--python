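# Methods

## Descriptors of breeding demographic structure

Every identified breeding bird is assigned an integer age. Birds whose hatch
year is known (first marked as chicks or subadults) get `age = year −
hatch_year` exactly; birds first trapped as breeding adults are assigned age 2
in their first capture year and aged forward deterministically. The age-2
convention is justified by the species' high (>50%) annual mortality: a bird
first seen as an adult is most likely in its second year, and the
subadult/adult dichotomy — the quantity the analysis actually uses — is
correct for such birds regardless. A record carrying both an adult first
capture and a hatch year is contradictory; the hatch year wins and a warning
is logged. Computed ages below 1 are rejected.

Per population-year the package reports: `prop_subadult` (share of aged
breeders with age 1 — the primary descriptor), `mean_age`, `prop_senescent`
(age ≥ `senescent_age_threshold`), and each descriptor's change against the
mean of the previous `running_mean_window` observed years (missing until two
prior observed years exist). Individuals breeding twice in a season count
once; parents of unknown identity count toward the population size
`n_breeders` but can never be aged. A population-year enters downstream
analyses only if `n_breeders ≥ 20` and the aged fraction strictly exceeds
0.25 — both boundaries exclusive of the filter (19 breeders fail; an aged
fraction of exactly 0.25 fails).

Defaults chosen here and exposed as configuration: `senescent_age_threshold =
4` (senescent declines in this species are reported from roughly that age)
and `running_mean_window = 5` observed years (observed, not calendar, so gaps
in a series do not empty the window). Both are assumptions of this package,
not settled constants, which is why they are knobs.

## Covariates

Thirteen variables per population-year *t*, all referring to the year leading
into the focal breeding season:

* `clutch_size_lag1`: mean eggs per breeding attempt in *t−1*; second
  clutches included by default (`first_clutches_only` restricts them).
* Seasonal means of daily mean temperature (°C) and daily precipitation (mm):
  summer = Jun–Aug (*t−1*), autumn = Sep–Nov (*t−1*), winter = Dec (*t−1*) –
  Feb (*t*), spring = Mar–May (*t*). The four windows exactly partition
  June 1 (*t−1*) – May 31 (*t*). A window with more than 10% of its calendar
  days missing yields a missing value (the 10% is an implementation
  tolerance, configurable).
* `n_cold_ece` / `n_hot_ece`: counts of days in June (*t−1*) – May (*t*)
  whose daily minimum falls strictly below the 5th percentile of the
  population's **entire** daily minimum record, or whose maximum strictly
  exceeds the 95th percentile of its entire maximum record. Percentiles use
  the empirical quantile with linear interpolation; the source wording
  specifies strict inequalities, so a constant series yields zero events.
  The event window is taken to be the same June–May year as the seasonal
  covariates.
* `mast_lag1`: beech mast value in *t−1* from the geographically nearest
  collection site (missing beyond 1500 km — the scale at which masting stays
  synchronised); `mast_lag1_local` additionally requires the site within
  100 km and the population inside the beech distribution. Mast values pass
  through untransformed. Distance ties resolve to the lowest site index and
  are logged.

All distances are haversine great-circle distances with Earth radius
6371.0 km (sub-0.5% error at these scales).

## Covariate regression

For each covariate separately, a Gaussian hierarchical model with population
random intercepts and random slopes (assumed mutually independent;
`allow_correlated=True` frees the covariance) is fitted to the z-normalised
descriptor and covariate. Normalisation is over the pooled population-years,
so fixed slopes are comparable across covariates. The marginal likelihood is
maximised directly (statsmodels `MixedLM`, ML rather than REML, so the fit is
a deterministic optimum of the same likelihood a Bayesian fit under flat
priors would centre on) and the fixed slope carries a Wald 95% interval.
One covariate at a time is deliberate: the climate variables are strongly
intercorrelated and a joint model would be uninterpretable. A variance
component estimated at the zero boundary flags the result as singular rather
than raising; a zero-variance covariate is an error ("degenerate covariate").
Rows with a missing covariate are dropped per model, not globally.

## Synchrony estimator

Within each population the descriptor series is centred and scaled to sample
standard deviation 1 (ddof = 1) over its observed years — required by the
unit diagonal of the yearly correlation matrices. Years observing fewer than
two populations carry no cross-population information and are dropped; a
population with fewer than two usable years cannot be normalised and drops
out entirely.

The likelihood is evaluated by grouping years with identical observation
patterns (one Cholesky factorisation serves all years in a group) in a
numba-compiled kernel; a plain numpy path computing the same sum year by year
with explicit inverses is retained and tested against it to 1e−8. The
constrained domain 0 ≤ ρ∞ ≤ ρ0 < 1, l ∈ [1, 20000] km is enforced by
optimising over (logit ρ0, logit ρ∞/ρ0, log l) with L-BFGS-B, 8 jittered
multi-starts (seeded), and a log-likelihood tolerance of 1e−10 (1e−8 inside
the bootstrap). The kernel family is positive definite by construction on
this domain; a numerical Cholesky failure triggers one 1e−8 diagonal jitter,
then the evaluation is abandoned (a large penalty, so the optimiser retreats).
Solutions at the transformed-coordinate bounds are flagged `at_boundary` —
e.g. a perfectly synchronous degenerate panel drives ρ0 to its upper bound.

The parametric bootstrap re-simulates every year's observed-population vector
from MVN(0, Σ_t) at the point estimate, independent across years with the
observation pattern preserved, re-normalises per population, and refits each
replicate from the point estimate plus one jittered start. 2000 replicates
are the production default; replicate refits that fail are dropped and
counted, with a warning beyond 5%. Reported synchrony at the reference
distances (100/500/1000/2500 km) is the per-replicate ρ(d) summarised by
median and 2.5/97.5 percentiles; plug-in values at the point estimate are
emitted alongside because the two legitimately differ (the median of a
nonlinear function is not the function of the median — at 1000 km the
difference is visible at the second decimal).

Covariate-adjusted synchrony regresses the descriptor on the covariate
within each population by OLS, z-normalises the residuals per population,
and refits the synchrony model to the residual panel. A population with a
constant covariate passes through un-adjusted (flagged); one with numerically
zero residuals is dropped. Year-subset analyses (e.g. 2000–2022) are a panel
filter, not a separate code path.

## Synthetic data

The generator draws the latent descriptor field from the estimator's own
generative model — that is deliberate: recovery and coverage tests need a
well-posed truth. Default design mirrors the motivating study: 32 populations
uniform over 35–65° N × 4° W–33° E (~3500 km extent), candidate years
1956–2022, one contiguous observation window per population with length
uniform on 10–35 years (total ≈ 700 population-years), truth
(ρ0, ρ∞, l) = (0.35, 0, 650 km) in the tests. Latent values map to subadult
proportions through an inverse-logit link p = expit(μ + σ·y) with defaults
μ = 0 (central proportion 0.5) and σ = 0.9, giving roughly the 0–0.9 range of
observed proportions. Individual records are drawn so the ingest stage
reproduces the realised binomial fractions exactly: subadult counts are
Binomial(n_aged, p); adult ages follow a geometric tail with survival 0.5
(echoing >50% annual mortality) truncated at age 6; population sizes are
lognormal (median ≈ 150, clipped at 25) with an aged fraction uniform on
0.30–0.85. Clutch sizes are Normal(9, 2) rounded and clipped at 1, with an
optional linear link to the next year's latent value to create a
reproductive covariate with a genuine effect. The covariate-driver generator
adds β × (its own spatial field) to an independent residual field sharing
the same windows.

What the generator does **not** emulate: density dependence, dispersal,
temporal autocorrelation within populations (years are exchangeable),
observation error in ageing, and non-Gaussian tails. Passing recovery tests
therefore demonstrate the estimator is correct under its own assumptions —
not that real demographic series satisfy them.

## Problem sizes in the packaged checks

Parameter recovery aggregates 20 independent panels at the full study design;
bootstrap coverage uses 200 replicates per trial over 20 trials; regression
interval coverage uses 200 replicates of a 30-population × 30-year design;
the worked example bootstraps 500 replicates. These sizes put Monte Carlo
noise comfortably below the tolerances being checked (e.g. binomial sd of a
95% coverage estimate at n = 200 is ≈ 1.5 percentage points) while the whole
suite stays in the low minutes.

## Known limitations

* The synchrony model constrains average correlation to be non-negative and
  isotropic; panels generated with genuinely negative average correlation or
  directional structure will be mis-fit by construction.
* ρ∞ and l are weakly identified when the site network's spatial extent is
  not much larger than l; bootstrap intervals for l are wide and ρ∞ piles up
  near 0 (its boundary) on null-ish panels.
* The ML-with-Wald-intervals regression matches a Bayesian random-slope fit
  only to the extent posteriors are near-Gaussian; with few populations the
  random-slope sd can collapse to the boundary where an MCMC posterior would
  not.
* Ages for birds first captured as adults are conventions, not observations;
  descriptors that weight older ages (mean age, proportion senescent) inherit
  that approximation more strongly than the subadult proportion does.
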