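# meqherit

Chronotype questionnaire scoring and family-based heritability estimation.

Diurnal preference (chronotype) — whether a person is a "morning type" or an
"evening type" — is commonly measured with the 19-item Horne–Östberg
Morningness–Eveningness Questionnaire (MEQ), whose total score runs from 16
(extreme evening) to 86 (extreme morning). In family cohorts the score's
narrow-sense heritability can be estimated from the resemblance of
relatives with a polygenic variance-components model. `meqherit` implements
that pipeline end to end for epidemiologists and statistical geneticists
working with pedigree-structured cohorts:

- **MEQ scoring** — the canonical instrument shipped as a data file, strict
  (non-imputing) scoring, the five-band typology, preferred wake/bed times;
- **pedigrees** — PED-style file parsing with validation, the additive
  relationship matrix 2Φ by the tabular kinship recursion, relative-degree
  classification;
- **heritability** — maximum-likelihood estimation of the polygenic model
  Ω = 2Φσ²ₐ + Iσ²ₑ, h² = σ²ₐ/σ²ₚ, via spectral decomposition and a profiled
  1-D likelihood in h² ∈ [0, 1], with curvature standard errors and
  boundary-corrected (½χ²₀ + ½χ²₁) likelihood-ratio p-values, under a
  configurable suite of covariate models;
- **descriptives** — exact pooling of subgroup summaries, two-sample
  t-tests and Cohen's d (noncentral-t confidence intervals) from summary
  statistics, age trends, histogram and normal Q-Q figure data;
- **synthetic cohorts** — a gene-dropping generator producing pedigrees and
  phenotypes with exactly the covariance structure the model assumes, used
  to validate every estimator without any external data.

## Worked example

Simulate a 112-family cohort (~820 adults with ages 46 ± 16 truncated to
18–89, 60% female, ~12% rural residence, score mean 63.5) and run the full
analysis:

```sh
meqherit simulate --seed 11 --out cohort
meqherit run --pedigree cohort/pedigree.ped --phenotypes cohort/phenotypes.csv \
             --seed 11 --out results
```

`results/table1.tsv` summarizes the cohort by residence zone:

```
    group   n  age_mean  pct_female  meq_mean   meq_sd
municipal 729   47.4752     58.9849   63.0864 10.30190
    rural  88   47.7016     61.3636   69.6477  9.25506
    total 817   47.4995     59.2411   63.7931 10.39030
```

`results/table2.tsv` holds the heritability estimates under the four
standard covariate models:

```
              model   n       h2    se_h2      p_value
         unadjusted 817 0.395251 0.064541 3.496623e-13
            sex_age 817 0.455210 0.062990 1.081370e-16
sex_age_age2_sexage 817 0.455512 0.063215 1.345316e-16
  sex_age_residence 817 0.468522 0.063108 2.738013e-17
```

Reading the output: the unadjusted h² is diluted because covariate effects
(here a true age slope of 0.26 points/year plus sex and residence effects)
inflate the phenotypic variance; adjusting for them raises h² toward the
generating residual-scale value (0.438 realized in this cohort, inside one
standard error of the 0.455 estimate). Adding age² and the sex×age
interaction to data generated without them leaves the estimate essentially
unchanged (0.4552 vs 0.4555). All p-values test h² = 0 with the
boundary-corrected likelihood-ratio mixture. The bundle also contains
figure data (`fig1_hist.tsv` score histogram by zone, `fig3_age.tsv`
age–score pairs — the fitted slope here is 0.218 points/year,
p ≈ 7·10⁻¹⁸ — and `fig4_qq.tsv` normal Q-Q coordinates, which show the
ceiling flattening above ~80) and a provenance-stamped `report.json` that is
byte-identical across reruns with the same seed and configuration.

The same steps are available as library calls (`meqherit.simulate_cohort`,
`meqherit.fit_table2_suite`, …); see the module docstrings and
`docs/methods.md` for the model details.

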