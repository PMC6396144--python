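# Methods

## Models

Cells are statistically identical and the population size is constant: a
division "renews" a cell in place, the daughter inheriting the parent's TAF
count plus a Poisson(μ_d) increment. Time is measured in months, with birth
at 0, so a 3-month-old animal has accrued damage for 3 months and the
modelled window runs to 30 months (a 27-month horizon past the earliest
sampling age). TAF are never removed — telomeric damage is treated as
irreparable, which is what the focus-persistence experiments motivate —
while non-telomeric foci follow an immigration–death process (gain λ_N,
first-order repair ρ) whose mean relaxes to λ_N/ρ and is therefore flat in
age.

Per-cell TAF at age *t*:

* stress: Poisson(m₀ + λ_T·t), m₀ the Poisson mean of the initial count;
* proliferation: compound Poisson — divisions D ~ Poisson(δ_c·t), TAF | D ~
  Poisson(μ_d·D); mean δ_c·μ_d·t, Fano factor 1 + μ_d;
* hybrid: independent sum of the two.

The TAF-positive probability uses Poisson thinning: a division leaves at
least one TAF with probability 1 − e^(−μ_d), so positive cells follow
1 − exp(−[m₀ + λ_T·t + δ_c·t(1 − e^(−μ_d))]). Taking μ_d → ∞ gives the
mechanism-free ceiling 1 − e^(−δ_c·t): the fraction of cells that have ever
divided. Published lifetime division fractions f for adult cardiomyocytes
are mapped to rates by δ_c = −ln(1 − f)/H with H = 27 months; the admissible
range f ∈ [0.04, 0.15] is a configurable constraint, not a fitted quantity.
This "fraction dividing at least once over the window" reading is the most
generous possible to the proliferation hypothesis, which makes the
resulting infeasibility verdict conservative.

## Stochastic engine

The simulator is the exact direct method over aggregated state: occupancy
counts n_k of cells with k TAF (k = 0..cap, default cap 50 with an
absorbing top bin; a warning is logged if more than 0.1% of cells reach the
cap) plus the pooled non-TAF total. All four channels — stress gain,
division, non-TAF gain, non-TAF repair — have propensities linear in these
counts, so aggregation is exact and a 10⁴-cell, 30-month run takes seconds.
Division increments are drawn at event time from the same seeded generator;
a fixed seed reproduces a trajectory bit for bit. Non-TAF are initialised
at their stationary Poisson level unless told otherwise, matching the
flat-in-age observation the model encodes. Per-cell identities are
materialised only on demand (`end_state_cells`), which is valid because
cells are exchangeable.

## Synthetic data

The cohort generator mirrors the cross-sectional study design it emulates:
ages {3, 15, 22, 30} months, 5 mice per age, 100 cells per mouse by
default. Mouse-to-mouse variability is a unit-mean gamma multiplier on the
damage-accrual rates (λ_T, δ_c); the default shape 20 gives a ~22%
between-mouse coefficient of variation, a typical magnitude for per-animal
scatter in such cohorts, and shape → ∞ recovers the homogeneous model
exactly. Non-TAF per cell are stationary Poisson(λ_N/ρ) draws; the defaults
λ_N = 7, ρ = 2 per month put mean total foci near 3.5 plus the TAF count.
Focus-lifetime tracks mix a persistent class (probability 0.2, censored at
the 24-h window) with exponential transients (mean 60 min); intensity sets
are log-normal with an optional log-shift for the TAF-labelled telomeres,
zero shift encoding length-independent damage.

What the generator does **not** emulate: measurement error in focus
counting, correlation between TAF and cell size or ploidy, non-exponential
repair kinetics, litter effects, or attrition of old animals. Passing tests
therefore demonstrate internal consistency of the inference machinery under
the stated sampling design, not robustness to those real-data features.

## Fitting and the verdict

Both mechanisms predict a linear mean, so mean TAF alone cannot separate
them; the positive-fraction channel can. The stress fit is least squares of
per-mouse mean TAF on age with slope and intercept clipped at zero. The
proliferation fit constrains δ_c to the admissible interval and minimises a
combined objective (grid over δ_c × μ_d, then Nelder–Mead polish) in which
each observable is standardised by its pooled between-mouse SD so the two
channels carry comparable weight. Proliferation is declared infeasible when
the observed positive fraction at any age exceeds the μ_d-independent
ceiling at the largest admissible δ_c by more than 3 between-mouse standard
errors. `compare_models` returns the feasible fit with the smaller
objective, ties going to the model with fewer free parameters.

Bootstrap intervals resample mice within age groups. Plain percentile
intervals are systematically anti-conservative here: each group holds only
~5 mice, resampling m items shrinks variance by (m−1)/m, and the bootstrap
SE is itself noisy at that size. The default is therefore the expanded
percentile interval (Hesterberg 2015, *Am Stat* 69:371–386), which widens
the percentile levels to Φ(−√(m/(m−1))·t₀.₀₂₅,ₘ₋₁) with m the smallest
group size; measured coverage at the default design is ≈0.92 versus ≈0.82
unadjusted. `expand=False` restores the plain percentile interval.

## Statistics implemented from formulas

The Mann–Whitney U uses midrank tie credit. The exact two-sided p-value
builds the null distribution of U by the standard counting recurrence and
is used automatically for tie-free samples of at most 8 per group
(configurable); the tests verify it against full enumeration of labelings.
Larger or tied samples use the normal approximation with tie-corrected
variance and a 0.5 continuity correction. The Kaplan–Meier estimator uses
the simultaneous-death convention for tied event times — sampling every 10
min guarantees heavy ties — and censoring at an event time leaves the track
in the risk set for that event. The Gehan–Breslow statistic scores all
cross-pairs (+1 / −1 / 0 by definite ordering under censoring); its p-value
comes from label permutation by default (10,000 permutations, add-one
estimator) or from the normal approximation with Gehan's permutation
variance n₁n₂ Σh_i² / (n(n−1)).

## SBML

Export writes Level 3 Version 1 with mass-action kinetic laws only, so any
standard stochastic simulator can run the documents. The compound-Poisson
division increment is unrolled into channels C_k → C_{k+j} weighted by the
Poisson pmf, truncated where the omitted tail mass is below 10⁻⁶; export
fails if the chosen cap would truncate over 1% of the initial TAF
distribution. Import reconstructs a `ModelSpec` only from documents that
carry this package's parameter naming convention; anything else — for
instance an external repository deposit — is returned as a structured
report of species, reactions and rate constants rather than being silently
coerced. Validation is structural (namespace, level/version, declared
compartments and species, mass-action rate references, nonnegative rate
parameters); the test suite additionally re-simulates an exported document
with a generic network SSA that knows nothing of the package's models and
checks the analytic mean.

## Numerical choices and problem sizes

Closed forms use `expm1`/`log1p` where cancellation threatens. Simulation
checks run at 10⁴ cells (3 Monte-Carlo SEs discriminate means to ~1%);
replicate-based checks use 100 seeds for the verdict rate, 200 cohorts for
recovery and coverage, 500 simulations for test calibrations — sizes at
which the binomial error of the measured rates is comfortably inside the
asserted bands and the whole suite runs in well under a minute per check on
one CPU. Degenerate inputs are contracts, not surprises: zero total
propensity freezes a trajectory, an all-censored track set yields S ≡ 1,
identical samples give U = n₁n₂/2 with p = 1, and a zero-rate model
round-trips through SBML as a document with zero-valued parameters.

## Known limitations

The engine tracks non-TAF as a pooled total, so the joint per-cell
(TAF, non-TAF) law is only available through the stationary approximation
in the cohort generator. The division model keeps the population constant
and ignores cell death and senescent-cell clearance. Lifetimes observed on
the 10-min imaging grid are treated as exact right-continuous times rather
than interval-censored. Telomere-length dynamics and shelterin biology are
out of scope throughout.
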