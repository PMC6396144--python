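# tafsim

Stochastic population models and statistical analyses of
**telomere-associated DNA-damage foci (TAF)** accumulation in rarely
dividing cardiomyocytes.

Adult heart muscle cells are essentially post-mitotic, yet the number of
DNA-damage foci that co-localise with telomeres rises steadily with age,
while the *total* number of γH2A.X damage foci stays flat. Two mechanisms
could in principle produce that rise:

* **stress** — irreparable telomeric damage arises in non-dividing cells as
  a Poisson process with rate λ_T per cell per month, so per-cell TAF at age
  *t* is Poisson(λ_T·t) and the TAF-positive fraction is 1 − e^(−λ_T·t);
* **proliferation** — the rare divisions (rate δ_c per cell per month) each
  deposit Poisson(μ_d) new TAF, a compound-Poisson law with mean δ_c·μ_d·t
  and Fano factor 1 + μ_d.

The decisive observation is an inequality: under proliferation alone, the
fraction of TAF-positive cells can never exceed the fraction of cells that
have *ever divided*,

    P(TAF ≥ 1) ≤ 1 − exp(−δ_c·t),

whatever μ_d is. Plausible lifetime division fractions for cardiomyocytes
(4–15% over a 27-month window) therefore cap the TAF-positive fraction at
~15%, far below what aged cohorts show — so division cannot account for the
age-dependent TAF rise, while the division-independent stress model fits it
closely. `tafsim` packages that argument as testable code: an exact
Gillespie simulator, closed-form oracles, synthetic cohort generators,
model fitting with a feasibility verdict, rank and survival statistics, and
SBML exchange.

## Modules

| module | contents |
| --- | --- |
| `tafsim.models` | `ModelSpec` and closed-form observables (mean TAF, TAF-positive fraction, non-TAF immigration–death mean, the proliferation cap) |
| `tafsim.gillespie` | exact stochastic simulation (direct method) of a cell population over the lifespan |
| `tafsim.synthetic` | synthetic mouse cohorts (ages 3–30 months, 4–7 mice × ~100 cells), focus-lifetime track sets with right-censoring, telomere-intensity sets |
| `tafsim.inference` | stress / proliferation fits, feasibility verdict, model comparison, bootstrap CIs |
| `tafsim.cohort_stats` | per-age summaries (mouse as unit, mean ± SEM), % telomere signal loss, Mann–Whitney U from first principles |
| `tafsim.survival` | Kaplan–Meier product-limit estimator and Gehan–Breslow test for focus persistence |
| `tafsim.sbml_io` | SBML L3V1 export/import of any `ModelSpec` as a mass-action network |

## Worked example

Generate a cohort under the stress model (λ_T chosen so roughly 60% of
cells are TAF-positive at 30 months), summarise it, and ask which mechanism
explains it:

```python
from tafsim import (ModelSpec, CohortDesign, generate_cohort,
                    summarize_cohort, compare_models, observed_from_cohort)

model = ModelSpec(mechanism="stress", lambda_T=0.0305,
                  lambda_N=7.0, rho=2.0, horizon_months=30.0)
cohort = generate_cohort(CohortDesign(seed=1), model)

for s in summarize_cohort(cohort):
    print(f"age {s.age_months:4.0f} mo: mean TAF {s.mean_taf:.2f} ± {s.sem_taf:.2f}, "
          f"TAF-positive {100*s.frac_positive:.0f}%, total foci {s.mean_total_foci:.2f}")

cmp_ = compare_models(observed_from_cohort(cohort))
print("verdict:", cmp_.verdict)
```

Output:

```
age    3 mo: mean TAF 0.10 ± 0.02, TAF-positive 9%, total foci 3.55
age   15 mo: mean TAF 0.47 ± 0.06, TAF-positive 38%, total foci 3.92
age   22 mo: mean TAF 0.65 ± 0.07, TAF-positive 48%, total foci 4.32
age   30 mo: mean TAF 0.71 ± 0.13, TAF-positive 48%, total foci 4.10
verdict: stress
```

Mean TAF rises roughly linearly with age while total foci stay near their
stationary level (λ_N/ρ = 3.5 plus the TAF), and the TAF-positive fraction
climbs far past the ~15% ceiling that any admissible division rate could
produce: the proliferation fit is flagged infeasible
(`cmp_.fits["proliferation"].feasible == False`) and the stress fit
recovers the rate with Pearson r ≈ 0.97.

The same pipeline is scriptable from the shell:

```bash
tafsim cohort --model stress --rate 0.0305 --seed 1 -o cohort.csv
tafsim stats --cohort cohort.csv -o summary.csv
tafsim fit --cohort cohort.csv --mechanism both -o fit.json
tafsim sbml export --config model.json -o model.xml
```

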