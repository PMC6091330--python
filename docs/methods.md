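# Methods

## The descriptor grammar

An IMPeTUs string is a comma-separated token list over a closed vocabulary:
`BM(n)[A]` (diffuse marrow uptake, Deauville 1–5, optional appendicular
flag), `F<g>` with optional site flags `.S`/`.SP`/`.ExtraSP` and an
optional `(n)` Deauville score of the hottest focal lesion, `L<g>` (lytic
grade), `Fr` (fracture), `PM` (paramedullary disease), and `EM` with site
flags `N`/`EN` each carrying an optional per-site score (`EM.N(5)EN(4)` is
valid; positivity takes the maximum across sites). Lesion-count grades
mean: 1 = no lesions, 2 = 1–3, 3 = 4–10, 4 = >10; the two middle anchors
are fixed by the published grade descriptions and the outer two follow the
same convention; the mapping ships as editable `GradeSemantics`
configuration rather than constants.

Parsing is strict by design: unknown or malformed tokens are errors (with
token and character offset), never warnings, because stage assignment must
not run on partially understood input. The `A` suffix after `BM(n)` is
stored as an uninterpreted boolean — no published semantics exist for it.
Serialization emits a canonical token order (BM, F, L, Fr, PM, EM) and is
exactly inverted by the parser (`parse(serialize(d)) == d`), which is
enforced by a property test over the full descriptor space.

PET positivity cutoffs: a focal bone lesion is positive at Deauville ≥ 4,
or ≥ 3 for a diffuse lytic lesion of 0.5–1 cm — the lesion size is an
optional side input, since descriptor strings carry no sizes. An EM site
without a recorded score is treated as non-assessable (negative) and
logged.

## Staging engines

All three engines are pure functions of a `LabPanel` and/or parsed
descriptor, parameterized by a `StagingRules` config (YAML-serializable,
shipped with defaults). Each returns the assignment plus a rule trace of
the clauses that fired.

**DSS.** Stage I requires all of: Hb > 10 g/dL, Ca ≤ 10.5 mg/dL, a normal
or solitary-lesion skeletal survey, and low M-component production
(IgG < 5 g/dL, IgA < 3 g/dL, Bence Jones < 4 g/24 h). Stage III fires on
any of: Hb < 8.5 g/dL, Ca > 12 mg/dL, advanced lytic lesions, IgG > 7,
IgA > 5, or Bence Jones > 12. Stage II is exactly the complement
(verified by grid enumeration in the tests). Subgroup B at
creatinine ≥ 2.0 mg/dL. M-component clauses that reference an isotype the
patient does not secrete simply do not trigger. The stage-III calcium
trigger is implemented in the hypercalcemia direction (> 12 mg/dL); both
threshold and direction sit in the config.

**RISS.** Stage I: albumin ≥ 3.5 g/dL, β₂M < 3.5 mg/L, normal LDH, no
t(4;14)/t(14;16)/del17p. Stage III: β₂M > 5.5 mg/L and (elevated LDH or
high-risk cytogenetics). Stage II otherwise. No renal subgroup.

**DS Plus.** Two components, combined by maximum severity: focal burden
(grade 1–2 → I, 3 → II, 4 → III, demoted one level when the focal
Deauville score is below the bone-positivity cutoff) and diffuse marrow
disease (BM ≤ 2 → I, 3 → II, ≥ 4 → III). Subgroup B when
creatinine > 2.0 mg/dL and/or PET-positive EMD. The focal lesion-count
grades (1–3, 4–10, >10) straddle the system's nominal boundaries (0–4,
5–20, >20), so no descriptor-only mapping can be exact; the default table
above is an explicit, documented choice exposed as configuration, and the
package reports engine-vs-reference agreement (`agreement_report`, with
rule traces for every mismatch) instead of pretending determinism. The
packaged cohort itself contains a pair of patients with identical focal
patterns but different recorded DS Plus stages, so its printed stage
columns — not engine re-derivations — feed all concordance and survival
statistics. For statistics, stage IA/IB are collapsed to I (and so on):
subgroups are combined within the main numerical grouping; the A/B letter
is kept as the renal/EMD axis.

## Concordance statistics

Cross-tabs are k×k counts over paired labels; percent agreement is
100·trace/n. Shift summaries count, per column-system stage, how many
patients the row system moves down, keeps, or moves up. Weighted kappa
uses linear weights by default (they are the standard choice for ordinal
three-level scales; quadratic and unweighted are options), with the
Fleiss–Cohen–Everitt (1969) asymptotic variance for the 95% normal CI and
the null-variance version for the p-value against κ = 0. The
implementation is validated against a termwise brute-force enumeration on
random tables and against `statsmodels.stats.inter_rater.cohens_kappa`
(point estimate and both variances agree to machine precision). CIs from
small tables are asymptotic and should be read accordingly; an exact or
bootstrap CI is a possible extension.

Internally everything is kept at full precision; reports round to two
decimals.

## Survival analysis

Overall survival runs from the baseline PET/CT to death, censored at last
follow-up. Kaplan–Meier estimation and the log-rank test are delegated to
lifelines; a median the curve never crosses is reported as the
distinguished value `NR`, never as infinity or NaN. The Cox
proportional-hazards model is fitted in-package by Newton–Raphson with
step-halving on the log partial likelihood; **Breslow** tie handling is
the default (the common default of the statistical packages of the era
this kind of analysis is run in), with **Efron** selectable. Inference is
Wald: SEs from the inverse observed information, 95% CIs and p-values on
the log-hazard scale. Convergence uses a relative log-likelihood criterion
(1e-9); constant covariates are dropped with a warning, singular
information raises, and |coef| > 15 triggers a separation warning.
Correctness is checked three ways: grid maximization of the written-out
partial likelihood on micro-examples (≤ 1e-6 agreement), lifelines on
tie-free data where Breslow and Efron coincide, and simulation (CI
coverage ≈ 95% at n = 500 over 200 replicates; unbiased log-HR within
Monte-Carlo error).

Known structural caveat: a model containing both an EMD indicator and the
DS Plus subgroup-B indicator is near-collinear, because subgroup B is
defined partly *by* EMD; the fitter allows it but such fits should be read
with care.

## Synthetic cohorts

The generator emulates the baseline table's structure with known ground
truth. Sampling order: demographics → isotype-consistent laboratory panel
→ descriptor from categorical distributions over the observed token
vocabulary → stage labels **derived by the actual engines** (so labels are
internally consistent by construction; no label noise) → survival from a
proportional-hazards model given the derived DS Plus stage and PET flags →
administrative censoring.

Defaults, chosen to mirror the baseline cohort's frequencies: marrow
scores concentrated at 2–3 with ~30% ≥ 4; EM tokens in ~65% of patients;
creatinine as a two-component log-normal mixture putting ~1/3 of patients
above 2 mg/dL; β₂M log-normal around 4 mg/L; elevated LDH 30%, high-risk
cytogenetics 25%. The survival model defaults to an exponential baseline
(0.006 events/month for a stage-I reference patient, i.e. a multi-year
median) with stage hazard ratios 1 / 4.818 / 11.539 and flag effects 3.487
(marrow Deauville ≥ 4) and 1.463 (EMD) — presets on the scale reported
for this disease setting so demonstration runs look clinically plausible;
they are inputs, never estimates. Censoring is uniform accrual over a
72-month window before a single data cut-off. A Weibull baseline is
available. Everything is reproducible from one integer seed
(`numpy.random.default_rng`), and stage-targeted descriptor generation
uses rejection sampling against the DS Plus engine (simple, and provably
consistent with the rules).

What the generator does *not* emulate: correlations among labs beyond
those the staging rules induce, treatment effects, PET image formation, or
informative censoring. Passing simulation tests therefore demonstrates the
correctness and calibration of the machinery, not clinical performance on
real cohorts.

## The packaged baseline cohort

The 33-patient table ships verbatim (descriptor strings, three stage
labels, demographics, treatment). Two provenance notes are recorded rather
than silently edited: patient 1's DSS cell prints only the subgroup letter
`B`, stored as `IIIB` — the unique completion consistent with the
published DSS stage marginals 1/2/30 (`fixture_table2(raw=True)` restores
the printed cell); and the published univariate table counts 17
paramedullary-positive patients while the PM token appears in 18 strings —
PM counts are therefore excluded from quantitative checks. The table
carries no per-patient follow-up times, so survival routines are validated
by simulation, not against published medians or hazard ratios.

## Problem sizes used in validation

Simulation-based checks run at sizes chosen to make Monte-Carlo error
small relative to the tolerance being asserted: log-rank type-I
calibration uses 3 × 40 patients × 1000 replicates (binomial SE ≈ 0.7% at
the nominal 5%); Cox recovery uses n = 500 with 200 replicates for CI
coverage; generator marginals use n = 4000 with censoring off.
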