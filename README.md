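# densimm

Tools for detecting **density-dependent immigration** in staged removal
(depletion) experiments.

## The problem

When a local population of territorial animals — the motivating system is
Caribbean damselfish holding ~1 m² reef territories — is harvested a constant
number of individuals at a time, the arrival of immigrants between removal
events traces out how immigration responds to density over the full range
from saturation to extinction.  Theory suggests a *hump*: positive density
dependence at low density (conspecific attraction, limited immigrant supply)
and negative density dependence at high density (competition for space), so
immigration peaks at intermediate density.  Detecting that hump, and not
being fooled by the spurious trend that ratio scalings introduce, takes some
statistical care.  This package provides the full pipeline for researchers
running such experiments: data model, scalings, likelihood fits, information-
theoretic model comparison, a simulator, and validation experiments.

## The method

Immigration after each removal event `t` is expressed under three scalings
of the immigrant count `I_t` against the post-removal density `D_t`:
**per site** (`I_t`, defined everywhere), **per new vacancy**
(`I_t / n_removed`, undefined before the first removal), and **per capita**
(`I_t / D_t`, undefined at zero density).  Six candidate mean functions are
fit to each site by maximum likelihood:

| name | formula | pattern |
|------|---------|---------|
| DI   | `I = b` | density independent |
| LDD  | `I = aD + b` | linear (± slope) |
| EDD  | `I = a·exp(−bD)` | exponential (± decay) |
| SDD  | `I = a·(1 − exp(−bD))` | saturating positive |
| PDD  | `I = −aD² + bD` | quadratic hump through origin |
| RDD  | `I = aD·exp(−bD)` | Ricker hump (peak at `D* = 1/b`) |

Counts use a negative-binomial likelihood (mean `μ`, dispersion `k`,
variance `μ + μ²/k`); rates use a Gamma likelihood (mean/shape form, with
0.001 added to responses and means so zero rates stay finite).  Fits are
compared by AICc, `−2 logL + 2K + 2K(K+1)/(n−K−1)`, normalized Akaike
weights `w_i`, and evidence ratios `w_i/w_j`, averaged across sites.
Per-capita scaling regresses `Y/X` on `X` and can manufacture negative
density dependence out of nothing ("pseudo-density dependence");
`densimm.validation_experiments.pseudo_density_dependence_demo` quantifies
that artifact on simulated data.

The fitting surface is sklearn-style: `CandidateModelRegressor` (one
function, `fit`/`predict`, fitted attributes `a_`, `b_`, `aicc_`, ...) and
`DensityDependenceSelector` (all six functions, `best_function_`,
`weights_`), with plain functions (`fit_mle`, `fit_site`, `compare_site`)
layered on top.

## Worked example

Simulate seven 60-fish sites with Ricker-truth immigration
(`a=1.5, b=0.08`, NB dispersion 5 — peak immigration ≈ 6.9 fish/event at
`D* = 12.5`), fit all six functions per site under per-site scaling, and
summarize:

```python
import densimm as dm
from densimm.model_selection import fit_site, cross_site_summary, format_comparison_tables
from densimm.scaling import per_site

cfgs = [dm.SimConfig(function="RDD", a=1.5, b=0.08, dispersion=5.0, seed=s) for s in range(7)]
study = dm.simulate_study(cfgs)
tables = [fit_site(per_site(site)) for site in study]
print(format_comparison_tables(tables))

s = cross_site_summary(tables, "RDD", "DI")
best = tables[0].fits[tables[0].best]
pk = dm.peak_location(best, n_initial=60)
print(f"site01 best={tables[0].best} peak at D*={pk.density:.1f} "
      f"({100*pk.proportion:.0f}% of start), height {pk.value:.1f}")
```

prints (AICc and Akaike weight per cell, `*` marks the best function):

```
function              site01            site02     ...
DI            180.94  0.000      77.70  0.000
LDD           158.76  0.002      64.46  0.000
EDD           169.08  0.000      71.53  0.000
SDD           176.23  0.000      76.44  0.000
PDD           149.49  0.231      50.70  0.082
RDD           147.09  0.767*     45.87  0.918*
site01 best=RDD peak at D*=9.7 (16% of start), height 9.6
```

A hump-shaped function wins every site (Ricker in six, the quadratic in
one), and the recovered peak sits near the true `D* = 12.5` — the behaviour
the selection procedure is supposed to have when the truth really is
hump-shaped.  The same machinery applied to field data reads a CSV of
events instead (`densimm.read_events`).

The same flows are available from a shell:

```bash
densimm simulate --config sim.json --seed 42 --out events.csv
densimm fit --input events.csv --scaling per_site --out tables/
densimm summarize --tables tables/ --num RDD --den DI
densimm recover --experiment artifact --config sim.json --reps 200 --seed 1 --out report.json
```

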