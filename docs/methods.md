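# Methods

## Data model

A removal experiment is a sequence of events per site.  Event `t` records
`n_removed` (fish taken, equal to the new vacancies created), `n_remaining`
(`D_t`, the density immediately after the removal) and `n_immigrants`
(`I_t`, untagged arrivals before the next census).  Immigrants join the
population and are removable later, so consecutive events obey

```
next.n_remaining = this.n_remaining + this.n_immigrants − next.n_removed
```

chained from the initial abundance `N0`.  Validation enforces this identity
exactly; fractional counts are rejected rather than rounded, since silent
rounding would mask recording errors.  Event index 0 is reserved for
pre-removal census visits (no catch, no immigration — saturated sites admit
no immigrants); a site that ends with one uncatchable individual is simply a
terminal plateau at `n_remaining = 1`, no special field.  `n_initial` is
read from an optional JSON sidecar or inferred as `remaining + removed` of
the first row, which is exact because no immigrant can precede the first
census.

## Scalings

* `per_site`: response `I_t` at every event, including pre-removal and
  zero-density events.
* `per_new_vacancy`: `I_t / n_removed`; events without a catch (pre-removal
  visits and post-extinction observations) are excluded as 0/0.  Scaling to
  *new* rather than cumulative vacancies reflects that in the motivating
  system ~92% of immigrants settled on territories vacated at the
  immediately preceding event.
* `per_capita`: `I_t / D_t`; zero-density events excluded.  This scaling is
  `Y/X` against `X` and is carried for completeness, with the spurious-trend
  caveat built into the validation experiments.

Densities can be re-expressed as proportions of `N0` (no clamping if
immigration pushed the population above `N0`), and zero-density points can
be dropped for sensitivity re-analyses.  The +0.001 Gamma offset is *not*
applied here: scaled values stay interpretable rates, and the offset lives
in the likelihood where it belongs.

## Likelihoods and fitting

Counts (per-site) use NB(mean `μ`, dispersion `k`), variance `μ + μ²/k` —
the ecological ("NB2") convention.  The log-pmf is computed with
`log Γ(y+k) − log Γ(k) = Σ_{i<y} log(k+i)` (a cumulative sum over integer
counts), which remains accurate through the Poisson limit `k → ∞` where
differencing two `gammaln` values loses digits.  Rates (per-new-vacancy,
per-capita) use Gamma(shape `s`, scale `μ/s`) with 0.001 added to both
response and mean so exact-zero rates keep finite density.

Wherever a candidate formula goes non-positive (PDD beyond its root, EDD
with extreme decay) the mean is floored at `ε = 1e−6` inside the likelihood
and at 0 for prediction; unguarded formulas crash optimizers and predict
impossible negative immigration.

Maximisation is a deterministic multi-start scheme: four moment-based
starting points per function (e.g. for the Ricker, `b0 = 1/D̂*` with `D̂*`
the centre of the best of three density bins, `a0 = max(y)·e·b0`) crossed
with two nuisance starts, each run through bounded L-BFGS-B (objective
tolerance 1e−12, nuisance log-transformed, bounds `a ≥ 0` for EDD/SDD/PDD/
RDD and `b ≥ 0` for DI/SDD/RDD so LDD and EDD keep a free sign and each
covers both directions of density dependence), followed by a Nelder-Mead
polish (`xatol 1e−10`) of the best start for tight parameter accuracy —
this is what lets the DI+NB estimate match the sample mean to 1e−6.
Determinism means identical data give identical fits on every platform.
`K` counts the nuisance parameter (2 for DI, 3 otherwise) and `n` is the
number of points actually entering the fit under that scaling, so AICc's
requirement `n > K + 1` is checked per scaling.

## Model comparison

Akaike weights are computed from AICc differences against the set minimum
(invariant to constant shifts; sums to 1 by construction).  The best
function is the AICc argmin; exact ties break toward fewer parameters, then
the canonical order DI, LDD, EDD, SDD, PDD, RDD.  Evidence ratios with a
zero denominator weight (possible when weights are rounded) propagate as
flagged infinities and are excluded from cross-site means with a warning,
never dropped silently.  Peak diagnostics use the closed forms `D* = 1/b`
(Ricker) and `D* = b/(2a)` (quadratic); monotone functions and degenerate
hump fits (`b ≤ 0`, `a ≤ 0`) report no peak.  The binned combined-data
summary uses half-open 0.1-wide proportion bins with exactly-zero density
as its own bin and SE = 0 for singleton bins.  The vacancy-fill summary
reports a percentile-bootstrap 95% CI of the median fill (10,000 seeded
resamples); the CI method for a median is a genuine choice and the
percentile bootstrap was picked for transparency and reproducibility.

## Synthetic experiments

The generator emulates the study design and its defaults are those
conditions: `n_initial = 60`, a constant `round(0.15·N0) = 9` fish removed
per event, five pre-removal census visits (biweekly observation at 2–3-day
intervals), NB noise with dispersion `k = 5` (counts of ~0–7 per event with
variance a few times the mean — realistic overdispersion for settlement
counts), and termination only after two consecutive events with zero fish
and zero immigration (cessation confirmed over ~6 days at the field
cadence).  Immigrants are drawn around the configured candidate function of
the current density, join the population, and are removable — so
`Σ removed = N0 + Σ immigrants` holds on every completed series.
Configurations whose immigration outpaces the removal rate can never be
depleted; the simulator detects the divergence (population exceeding 50×
`N0`) and refuses them rather than looping forever.

What the generator does *not* emulate: spatial territory structure,
neighbour expansion, mutual defence, species identity, or source-area
depletion.  Passing tests therefore demonstrate the statistical machinery
under the assumed count-generating model, not the behavioural ecology of
real reefs.

A second generator implements the finite-pool vacancy-filling model: each
new vacancy is filled independently with probability `fill_probability`
(default 0.25, matching the observed median fill), capped by a finite pool
of potential immigrants.  Because post-extinction vacancies are limited to
just-arrived immigrants, immigration collapses within the stop window after
density first reaches zero even when most of the pool remains — the model's
point: cessation of immigration does not imply immigrant depletion.

## Validation experiments

`selection_frequency`, `parameter_recovery` and
`pseudo_density_dependence_demo` run simulate → scale → fit-six → compare
many times, with per-rep seeds derived from the master seed as
`(seed + 1_000_003·rep) mod 2³¹` so single reps replay in isolation.  These
experiments set `n_pre_observations = 0`: pre-removal rows carry zero
immigration by construction (a saturation effect none of the candidate
functions model), so including them would measure model mismatch rather
than estimator behaviour.  "Decreasing function" in the artifact demo means
LDD with `â < 0` or EDD with `b̂ > 0` winning the AICc comparison.

Problem sizes used by the shipped experiments: recovery uses 100 simulated
sites (one ~10–20-event site per fit), the artifact demo 200 reps × two
scalings × six functions, selection-frequency checks 15–50 reps; these are
the sizes at which the Monte-Carlo summaries (median bias, win fractions)
are stable enough to assert directions and coarse magnitudes.

## Known limitations

* The NB dispersion and Gamma shape are point-estimated jointly with the
  mean parameters; no confidence intervals are reported.
* With ≤ ~8 informative density levels per site, individual-site estimates
  of the Ricker parameters are noisy (relative RMSE ~0.2–0.4 at the default
  design even though median bias is small); cross-site evidence ratios are
  the more stable summary.
* Quadratic (PDD) fits can tie with Ricker on strongly humped data; the two
  are reported separately and both count as "hump-shaped" in validation
  summaries.
* The published study's per-site AICc values themselves cannot be
  reproduced here because the per-event counts were never deposited; the
  package instead recomputes everything downstream of the printed AICc
  columns and validates the fitting machinery on synthetic data.
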