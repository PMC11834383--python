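# demosync

Spatial synchrony of breeding demographic structure in territorial songbird
populations — from individual nest-box capture records to a distance-decay
estimate of how synchronously the age composition of separate populations
fluctuates, and how much of that synchrony reproductive and environmental
variables explain.

## Who this is for

Population ecologists with multi-population, multi-decade individual breeding
records (the great tit *Parus major* nest-box networks are the motivating
system) who want to:

1. build annual **demographic-structure descriptors** — primarily the
   proportion of breeding subadults (first-year breeders) among aged parents,
   plus mean age, proportion senescent, and each descriptor's change against a
   trailing running mean;
2. relate descriptor fluctuations to **reproductive and environmental
   covariates** (lagged mean clutch size, seasonal temperature and
   precipitation, extreme-event counts, beech masting) with a random-slope
   hierarchical regression; and
3. estimate the **spatial scale of synchrony** of those fluctuations, with and
   without adjusting for the covariates.

## The model

Per-population normalised descriptor series are assumed jointly Gaussian each
year, `y_t ~ MVN(0, Σ_t)`, where `Σ_t` has unit diagonal and off-diagonal
entries given by the Gaussian autocorrelation function

    ρ(d) = ρ∞ + (ρ0 − ρ∞) · exp(−d² / 2l²)

with `d` the great-circle distance (km) between two populations, `ρ0` the
synchrony as distance → 0, `ρ∞` the synchrony at infinite distance, and `l`
(km) the kernel's standard deviation — the characteristic spatial scale of
synchrony. The total log-likelihood is the sum of the annual terms, so
population pairs with longer overlapping series weigh more, in direct
proportion to their shared years. Parameters are constrained to
`0 ≤ ρ∞ ≤ ρ0 < 1`, `l > 0` and estimated by numerical maximum likelihood;
uncertainty comes from a parametric bootstrap (simulate panels from the
fitted `Σ_t` on the observed yearly population sets, re-normalise, refit),
reported as medians and 95% percentile intervals.

The covariate regression is the hierarchical model

    y_ij = β_int + u_int,i + (β_expl + u_expl,i) · Z_ij + ε_ij

with population-level random intercepts and slopes and both variables
z-normalised over the pooled population-years; one model per covariate.

## Worked example

Simulate a panel at the design scale the estimator targets (32 populations
across Europe, staggered windows inside 1956–2022, true ρ0 = 0.35, ρ∞ = 0,
l = 650 km), fit, and bootstrap:

```python
from demosync import SimulationConfig, simulate_latent_field, SpatialSynchrony

sim = simulate_latent_field(SimulationConfig(seed=3))
res = SpatialSynchrony(sim.panel, sim.geometry).fit(seed=3)
boot = res.bootstrap(n_reps=500, seed=3)
print(boot.summary())
```

```
Spatial synchrony: parametric bootstrap (500 replicates, 0 dropped)
parameter       median            95% interval
rho0             0.450      [0.355, 0.560]
rho_inf          0.040      [0.000, 0.148]
l              713.298      [498.228, 978.559]
rho_100          0.446      [0.353, 0.550]
rho_500          0.361      [0.286, 0.445]
rho_1000         0.201      [0.112, 0.296]
rho_2500         0.044      [0.000, 0.150]
point estimate: rho0=0.448 rho_inf=0.040 l=726 km
```

This single seed-3 panel reads as: near-zero-distance synchrony ρ0 ≈ 0.45
[0.36, 0.56], decaying over a characteristic scale l ≈ 713 km [498, 979] to
effectively nothing beyond ~2500 km. The generating values (0.35, 0, 650 km)
sit inside or near the intervals; a single 67-year panel estimates ρ0 with
sampling scatter of roughly ±0.1, which is why the packaged recovery tests
aggregate 20 independent panels. `rho_100` … `rho_2500` are bootstrap medians
of ρ(d) at fixed reference distances; plug-in evaluations at the point
estimate are also emitted (`res.rho_at()`) and differ slightly because the
median of a nonlinear function is not the function of the median.

The same objects run from the shell:

```
demosync simulate --config sim.yaml --output-dir data/
demosync run --config cfg.yaml
demosync fit-synchrony --summaries s.csv --sites sites.csv --b 2000 --seed 1 \
    [--covariate cov.csv --covariate-name mast_lag1] [--years 2000:2022]
```

`demosync run` writes annual summaries, the 13-covariate table, one
random-slope fit per covariate, the raw synchrony fit with bootstrap
replicates and curve data, covariate-adjusted synchrony fits, and a manifest
(seed, config hash, record counts through every filter) that fully determines
the outputs.

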