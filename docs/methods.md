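# Methods

## Normative model and deviation scoring

The reference curve is an ordinary least-squares model of normalized brain
volume (NBV, % of intracranial volume) on age (years), sex (male vs female),
disease duration (years; 0 for healthy controls so one design matrix serves
the whole cohort) and phenotype contrasts versus HC (RRMS/SPMS/PPMS). Fitting
on patients and controls jointly anchors the phenotype contrasts; the model
assumes residual normality, linear covariate effects and no interactions.
Three checks probe those assumptions and are reported, never used for
scoring: a beta-regression refit (logit mean link, constant precision φ, AIC
on the (0,1) scale), a natural-cubic-spline refit of age and duration (4 df
each, AIC comparison), and a joint AIC screen of all two-way interactions.
The interaction screen deliberately replaces heavier hierarchical shrinkage
machinery: with ~15 extra columns on ~970 rows a plain AIC comparison is
adequate for a yes/no nonlinearity verdict.

Patients are scored against two references:

* **MS-specific** — the full model, with leave-one-out (LOO) predictions so a
  subject never influences their own expected value. LOO refits the
  *coefficients* per fold; the covariate set is selected once on the full
  sample, because per-fold selection would make quartile membership depend on
  unstable variable sets. The fold-refit implementation is checked against
  the hat-matrix closed form `e_i/(1−h_ii)` to 1e-8.
* **HC-based** — age + sex fitted on the HC arm only, emulating commercial
  normative tools. Patients are out-of-sample by construction.

A deviation (observed − predicted) becomes a percentile either as
`100·Φ(deviation/σ̂)` with σ̂ the full-sample residual scale (default; this is
how normative tools report centiles, and residuals are close to normal) or as
a midrank ECDF percentile among the scored patients (kept as a switch because
real NBV residuals are mildly left-skewed). Percentiles are cut at 25/50/75
into quartiles with half-open bins: a percentile exactly at a cutoff goes to
the *upper* quartile, and 100 is in quartile 4. Quartile 1 = most atrophy
relative to peers.

Covariate selection is bidirectional and AIC-guided from the full candidate
model (phenotype's three contrasts move as one block); a p-value mode
(enter 0.05 / remove 0.10) exists for sensitivity analyses. Bootstrap CIs are
nonparametric case resampling with percentile-method 95% intervals (B = 2500
by default; BCa is not implemented — percentile intervals are what "95% CI
from 2,500 resamples" means operationally, and coverage is verified by
simulation at B = 500). Rank-deficient resamples are redrawn with a capped
retry count; rank-deficient *designs* fail loudly with the offending column
names. All randomness flows through explicit seeded `numpy` generators.

## Severity scores

**MSSS.** EDSS ranked among duration-matched peers: patients are binned by
integer duration year, bins pooled with their neighbours until each stratum
holds ≥ 5 patients, and within a stratum of size n the patient with midrank R
scores `10·(R−0.5)/n`. The stratum mean is exactly 5 and the score depends on
EDSS only through ranks (both are tested). The published global MSSS lookup
is external data; the cohort-local construction above is the default, and a
loader applies a user-supplied `duration_year × EDSS → MSSS` table when one
is available. Distributionally the two agree in simulation because the
generator's EDSS is itself rank-calibrated within duration strata.

**EDSS change.** Worsening/improvement needs a 1.5-point change from
baseline 0.0, 1.0 point from baselines up to 4.5, and 0.5 point above 4.5;
the classifier is verified against a brute-force restatement over all 441
half-point grid pairs.

**Cognitive decline.** Per-test reliable change `RCI_t = (Δ_patient −
mean Δ_HC)/SD(Δ_HC)`; centering on the HC mean absorbs average practice
effects, and no further practice correction is applied. Timed tests (9HPT,
T25FW), where higher is worse, are sign-flipped so negative always means
decline. A test declines below −1.645 (90% one-sided); a patient declines on
≥ 2 tests.

## Evaluation battery

One-way ANOVA relates each quartile coding to MSSS (η² = SS_between/SS_total,
checked against a direct decomposition to 1e-10); Tukey HSD post hocs run
only when the omnibus p < 0.05. SDMT/9HPT/T25FW use ANCOVA with age, sex,
duration and phenotype; type-II sums of squares because the model has no
interactions and type-II is invariant to predictor order. The added value of
the MS-specific quartiles is the partial F-test of `outcome ~ C(q_HC) +
C(q_MS)` against `outcome ~ C(q_HC)`; aliased codings report F = 0 rather
than erroring. Longitudinal models keep baseline value and follow-up time as
covariates. EDSS change uses a multinomial logit (stable as reference) and
cognitive decline a binary logit, both with quartile as a single *ordinal*
predictor — matching a single odds ratio "per quartile increment" — plus
follow-up time; separation and non-convergence are reported with category
diagnostics, never silently. DMT use/efficacy get plain (uncorrected)
contingency χ² with listwise exclusion of unknowns and a flag when an
expected cell falls below 1. Demographics tables pick ANOVA+Tukey vs
Kruskal-Wallis+Dunn (Holm-adjusted; Dunn is implemented in-package with tie
correction) by a Lilliefors normality check and a Levene variance check.
α = 0.05 throughout; missing outcomes are dropped listwise per analysis.

If covariates reproduce an outcome exactly (zero residual SS), the quartile
F would be a ratio of rounding noise; the ANCOVA reports F = 0, p = 1 with a
degenerate-input note instead.

## Synthetic cohort generator

The generator emulates a single-centre cross-sectional MS cohort:
259 HC / 503 RRMS / 134 SPMS / 76 PPMS; ages and durations from per-group
truncated normals matching the published means, SDs and ranges; sex from the
published per-group proportions. NBV follows the linear model with
coefficients (age −0.077, male −0.758, duration −0.083, PPMS −1.038, RRMS
−1.076, SPMS −1.787 %ICV) and residual SD 2.8 %ICV, chosen so the population
R² lands in the reported 0.26–0.28 band; coefficient recovery is insensitive
to this choice. The intercept is not a published quantity: it is computed so
the *expected* HC-arm mean NBV (truncated-normal age mean, 67.2% female)
equals 82.7 %ICV, giving ≈ 86.67.

Clinical outcomes hang off a latent severity
`L = c·(−ε/σ) + drift·duration + noise`, where ε is the generative NBV
residual — severity is driven by how far the brain falls below the
*disease-specific* expectation, not the HC expectation. EDSS is obtained by
quantile-mapping L within phenotype × duration strata onto the 0–8.5
half-point grid around a mean that rises with duration and progressive
phenotype; this guarantees the rank-based MSSS inherits the intended
coupling exactly (tested in the noiseless limit). The coupling c defaults to
0.6 latent units per residual SD — a free parameter, set once so the
added-value comparison at the full cohort size is adequately powered (≥ 80%;
measured ≈ 95%) — with unit latent noise. SDMT and 9HPT couple to the same
latent with realistic intercepts and noise; T25FW's coupling defaults to 0,
mirroring the observed absence of quartile effects for walking speed. DMT
fields are drawn from the published per-phenotype frequencies independently
of deviation.

Follow-up (default n = 297, time ~ N(4.93, 0.72²) truncated positive) evolves
EDSS with worsening probability `logit⁻¹(−0.85 + 0.3·(−ε/σ))`, a small
constant improvement probability, and stable jitter inside the
classification band; 23 of the worst-deviating RRMS patients are relabelled
SPMS at follow-up (labels only). All HC rows and the follow-up patients
receive five abstract cognitive change scores, HC ~ N(0.5, 3²) (the RCI
reference), patients shifted by −0.8 plus 0.3·(ε/σ), calibrated to put the
per-quartile decline OR in the 0.7–0.8 range at realistic decline rates
(~5–10%).

What the generator does **not** emulate: scanner/software variability,
pseudoatrophy under treatment initiation, measurement error distinct from
biological residual variation, informative follow-up dropout, lesion or
spinal-cord metrics, and any external HC population. Consequently, passing
tests show that the *pipeline* recovers the structure it assumes — unbiased
coefficient recovery, calibrated CIs, correctly gated tests — not that the
published effect sizes would replicate in new patient data.

One structural consequence deserves emphasis: because the HC-based reference
is fitted on the *same* synthetic cohort's HC arm, a patient's HC-based
deviation equals the MS-model residual plus modest systematic
duration/phenotype terms (SD ≈ 0.8 vs 2.8 %ICV), so the two deviations
correlate at ≈ 0.96 and the HC-based quartiles are almost as predictive of
severity as the MS-specific ones in this emulation. The MS-specific coding
still adds significant explanatory value on top (the added-value test), but
the emulation cannot make the HC quartiles *uninformative*, as an external,
independently calibrated HC reference can be. Analyses comparing the two
references are therefore internally consistent rather than a re-enactment of
the external-tool comparison.

## Numerical choices and problem sizes

Fit-comparison tolerance 1e-8 relative on coefficients; LOO-vs-hat-matrix
tolerance 1e-8 absolute on cohorts of n ≤ 200. Percentile ties use midranks;
quartile cutoffs are half-open upward. The test suite runs its simulations at
the sizes the analysis actually uses — 200 cohorts of n = 972 for coefficient
recovery, 200 cohorts at B = 500 for bootstrap coverage, 50 full-size
replicates for added-value power, 25 seeds for the headline quartile
contrast — which keeps the default `pytest` run at a few minutes on one CPU.
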