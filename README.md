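# msrefcurve

Disease-specific normative reference curves for brain volume in multiple
sclerosis (MS), and the statistical machinery to ask whether they explain
clinical severity better than the healthy-control (HC) curves that commercial
volumetric-reporting tools ship with.

Brain atrophy in people with MS starts earlier and runs faster than normal
aging, so judging a patient's normalized brain volume (NBV, % of intracranial
volume) against age/sex-matched healthy controls mostly restates that they
have MS. A *disease-specific* reference instead asks: is this brain smaller
than expected *for a patient with these characteristics*? This package is for
biostatisticians and imaging researchers who want to build, stress-test or
extend that kind of normative model on cohort data.

## The model

The reference curve is a linear normative model fitted on patients and
controls jointly,

    NBV_i = β₀ + β_age·age_i + β_M·1[male_i] + β_dur·duration_i
            + β_RRMS·1[RRMS_i] + β_SPMS·1[SPMS_i] + β_PPMS·1[PPMS_i] + ε_i,

with phenotype contrasts versus HC and ε ~ N(0, σ²). Beta-regression and
natural-cubic-spline refits are available as assumption checks, and
coefficient uncertainty comes from a case-resampling bootstrap (default
B = 2500). Each patient is scored **out of their own fit**: leave-one-out
prediction gives a deviation `NBV_obs − NBV_pred`, mapped to a percentile
`100·Φ(deviation/σ̂)` (or a midrank ECDF percentile) and cut at 25/50/75 into
quartiles — quartile 1 is the most atrophy relative to peers. Severity is
measured by the MS severity score (MSSS: EDSS ranked among duration-matched
peers, scaled to 0–10), SDMT, 9HPT and T25FW; the *added value* of the
MS-specific quartiles beyond HC-based ones is a partial F-test between nested
linear models, with multinomial/logistic models for 5-year EDSS change and
reliable-change cognitive decline.

Because the source cohort is not public, the package ships a first-class
synthetic-cohort generator calibrated to the published group composition,
covariate distributions and generative coefficients; all analyses run
end-to-end on it.

## Worked example

```sh
python examples/05_added_value.py
```

```
 MS-specific quartiles: F=33.2, p=4.6e-20, eta^2=0.123  (Q1=6.34 Q2=5.37 Q3=4.64 Q4=3.57)
    HC-based quartiles: F=38.5, p=5e-23, eta^2=0.140  (Q1=5.85 Q2=4.22 Q3=3.92 Q4=2.82)

added value of MS-specific over HC-based quartiles: F=3.6, p=0.013, partial eta^2=0.015

cognitive decline: OR per MS-quartile increment = 0.77 (95% CI 0.48-1.24, p=0.28)
```

Reading this: MSSS falls monotonically across the MS-specific quartiles —
patients whose volume is below the *disease-specific* expectation are more
severely affected than duration-matched peers — and adding the MS-specific
coding to a model that already contains the HC-based coding still explains
significantly more MSSS variance (the added-value F-test). The decline OR
below 1 means each quartile step toward "more volume than expected" lowers
the odds of reliable cognitive decline over five years. (In this synthetic
emulation the HC-based quartiles are themselves informative, because both
references are fitted on the same cohort; see `docs/methods.md`.)

The other examples cover cohort simulation, model fitting and bootstrap CIs,
deviation scoring, severity scores, and the one-command pipeline. A thin CLI
wraps the same functions:

```sh
msrefcurve run-all --seed 1 --out results/demo
msrefcurve simulate --seed 2 --out cohort.csv
msrefcurve fit --cohort cohort.csv --family linear --reference ms --out fit.json
```

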