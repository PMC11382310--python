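# ril-mediation

Causal mediation analysis for right-censored survival outcomes with a binary
mediator, built around the question it was designed for: how much of the
overall-survival benefit of proton over photon chemoradiation in esophageal
cancer flows through the reduced risk of grade-4 radiation-induced
lymphopenia (G4RIL)?

The package is aimed at biostatisticians and radiation-oncology researchers
who want the full analysis chain as tested, reusable code: a synthetic
confounded-cohort generator (the motivating single-center cohort is not
publicly deposited), propensity-score construction with optimal 1:1
matching, censored-data regression, and a closed-form natural-effect
decomposition with delta-method or bootstrap confidence intervals.

## The model

Let A ∈ {0 = photons (IMRT), 1 = protons (PBT)} be the exposure,
M ∈ {0, 1} the mediator (G4RIL), T the overall-survival time, and C the
adjustment covariates (after matching, the propensity score). Two
regressions are combined:

* mediator model — logistic:
  `logit P(M = 1 | A, C) = β₀ + β₁ A + β₂′C`
* outcome model — Weibull accelerated failure time with shape fixed at 1
  (exponential): `log T = θ₀ + θ₁ A + θ₂ M + θ₃ AM + θ₄′C + ε`,
  where exp(ε) is standard exponential.

Because M is Bernoulli, the counterfactual mean survival times integrate in
closed form. With `L_x = β₀ + β₁x + β₂′c` and `k_x = θ₂ + θ₃x`:

    TR_NIE = (1 + e^{L_a + k_a})(1 + e^{L_a*}) / [(1 + e^{L_a* + k_a})(1 + e^{L_a})]
    TR_NDE = e^{θ₁(a − a*)} (1 + e^{L_a* + k_a}) / (1 + e^{L_a* + k_a*})

are time ratios; with shape 1 every time ratio converts to a hazard ratio
by `log HR = −log TR`, and the total effect decomposes exactly as
`TE = NDE × NIE` on the hazard-ratio scale. The proportion mediated is
computed on the excess-relative-hazard scale,

    PM = exp(NDE)·[exp(NIE) − 1] / [exp(NDE)·exp(NIE) − 1],

with NDE/NIE as log hazard ratios, and the indirect effect converts to
months of median survival by scaling a reference-arm exponential hazard λ:
`Δmedian = (ln 2 / λ)(1/HR_NIE − 1)`.

Matching solves the bipartite assignment problem minimizing the total
absolute propensity-score distance (logit scale by default) — optimal
matching, with a greedy benchmark available for comparison.

## Worked example

```python
from ril_mediation import (default_paper_params, simulate_cohort,
                           fit_ps_model, optimal_match, mediate)
from ril_mediation.propensity import matched_cohort

cohort = simulate_cohort(default_paper_params(n=2000, seed=1))
ps = fit_ps_model(cohort, ["age", "baseline_alc", "ptv", "ecog", "location",
                           "stage", "chemo_cycles", "barretts", "histology",
                           "surgery"])
matches = optimal_match(ps, cohort)
result = mediate(matched_cohort(cohort, matches), ps.scores)
```

prints, when formatted:

```
matched pairs: 709
TE  HR 0.696  (95% CI 0.613-0.792)
NDE HR 0.786  (95% CI 0.691-0.895)
NIE HR 0.886  (95% CI 0.855-0.917)
proportion mediated 0.296
median survival gain via mediator 5.07 months
```

Reading: in this synthetic cohort protons reduce the death rate by ~30%
overall (TE). Holding each patient's mediator at its photon-arm
distribution, protons alone would reduce it by ~21% (NDE); the remaining
~11% reduction (NIE) travels through the lower G4RIL risk, accounting for
~30% of the total effect and about 5 months of median survival. The
generator's default calibration targets the published marginals of the
motivating cohort (G4RIL incidence 45.2% photons vs 22.6% protons,
photon-arm median OS 40.9 months, mediator death-hazard ratio 1.49, direct
modality hazard ratio 0.79); see `docs/methods.md` for what these synthetic
results do and do not say about real data.

The same pipeline runs from a shell:

```sh
ril-mediation run --config examples/config.yaml --out out/
ril-mediation simulate --seed 7 --n 734 --out cohort.csv
ril-mediation mediate --csv cohort.csv --out mediation.json
ril-mediation report --results out/mediation.json
```

`run` writes the cohort summary, screening report, match pairs, balance
table, odds-ratio and hazard-ratio tables, Kaplan-Meier step functions,
the mediation decomposition (JSON), surgical-subgroup results, and a
manifest with the seed, config hash and per-file checksums; the same config
and seed reproduce every artifact byte for byte.

## Cohort CSV schema

One row per patient, UTF-8, header row, "." decimal separator; times in
months. Columns: `id, age, sex {female,male}, baseline_alc (10³ cells/µL),
ptv (cm³), ecog {0,1-2}, location {upper-middle,lower}, stage {I,II,III},
chemo_cycles (≥1), barretts {0,1}, histology {adeno,scc}, surgery {0,1},
modality {0=IMRT,1=PBT}, g4ril {0,1}, os_months (>0), event {0,1}`.
Common synonyms (e.g. `PBT`, `Adenocarcinoma`, `F`) are normalized on read;
rows failing validation are rejected and counted. A `column_map` argument
renames arbitrary external headers.

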