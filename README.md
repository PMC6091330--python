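# mmstage

Staging newly diagnosed multiple myeloma from standardized FDG-PET/CT
reads, and comparing staging systems statistically.

Multiple myeloma is staged in the clinic by three competing systems: the
laboratory-based **Durie–Salmon system (DSS)**, the **Revised International
Staging System (RISS)** built on β₂-microglobulin, albumin, LDH and
high-risk cytogenetics, and the imaging-based **Durie–Salmon Plus
(DS Plus)**, which grades focal-lesion burden and diffuse marrow disease.
The **IMPeTUs** notation (Italian Myeloma criteria for PET USe) makes
PET/CT reads reproducible enough to drive DS Plus mechanically: a string
such as `BM(3), F3.SP.ExtraSP(4), L2, PM, EM.N(2)` encodes the marrow
Deauville score, focal-lesion count grade and sites, lytic lesions, and
paramedullary/extramedullary disease with per-site Deauville scores.

`mmstage` is aimed at nuclear-medicine and hematology researchers who want
to run this comparison on their own cohorts. It provides:

- a validating **parser/serializer** for IMPeTUs descriptor strings, with
  the PET positivity cutoffs (Deauville ≥ 4; ≥ 3 for small lytic lesions
  given a 0.5–1 cm size);
- **rule engines** for DSS, RISS and DS Plus, with every threshold in an
  editable YAML config and per-patient rule traces;
- **concordance statistics**: 3×3 cross-tabs, percent agreement,
  up/down-staging summaries, and Cohen's weighted kappa

  κ = (P₀ − Pₑ)/(1 − Pₑ),  P₀ = Σ wᵢⱼ pᵢⱼ,  Pₑ = Σ wᵢⱼ pᵢ. p.ⱼ,

  with linear weights wᵢⱼ = 1 − |i−j|/(k−1) by default and
  Fleiss–Cohen–Everitt asymptotic errors;
- **survival analysis**: Kaplan–Meier, log-rank, and a Cox
  proportional-hazards fitter (Newton–Raphson on the partial likelihood,
  Breslow or Efron ties);
- a **synthetic-cohort generator** whose stage labels are derived by the
  actual engines and whose survival follows a configurable
  proportional-hazards model — every analysis step is testable against
  known ground truth;
- a packaged **33-patient baseline cohort** of newly diagnosed myeloma
  patients with verbatim IMPeTUs strings and all three printed stage labels.

## Worked example

```sh
$ mmstage parse --fixture
parsed 33 descriptor(s) without error
marrow Deauville >= 4: 10; PET-positive EMD: 16

$ mmstage concord --fixture          # DS Plus (rows) vs DSS (columns)
DSPLUS (rows) vs DSS (columns)
            I    II   III  total
      I     0     1     8      9
     II     1     1     8     10
    III     0     0    14     14
  total     1     2    30     33
percent agreement: 45.45%
       I: n=1, down 0 (0.00%), same 0 (0.00%), up 1 (100.00%)
      II: n=2, down 1 (50.00%), same 1 (50.00%), up 0 (0.00%)
     III: n=30, down 16 (53.33%), same 14 (46.67%), up 0 (0.00%)
 overall: n=33, down 17 (51.52%), same 15 (45.45%), up 1 (3.03%)
linear-weighted kappa = 0.07 (95% CI, -0.02 to 0.16; p = 0.333; n = 33)
```

Reading: only 45% of patients keep their stage when moving from the
radiograph-based DSS to the PET-based DS Plus — more than half of DSS
stage-III patients are downstaged — and the chance-corrected agreement
(κ = 0.07) is essentially nil, i.e. the two systems classify patients
almost independently. Against RISS (`--col-b stage_riss`) agreement is
fair: κ = 0.37, 57.58% concordant.

The same works from Python:

```python
from mmstage import fixture_table2, build_crosstab, weighted_kappa

cohort = fixture_table2()
ct = build_crosstab(cohort.stage_labels("dsplus"), cohort.stage_labels("riss"))
print(weighted_kappa(ct).to_text())
# linear-weighted kappa = 0.37 (95% CI, 0.13 to 0.60; p = 0.004; n = 33)
```

A full synthetic pipeline — simulate, re-stage, concordance, survival —
composes from one seed:

```sh
mmstage simulate --n 200 --seed 7 --out syn.csv --truth-out truth.csv
mmstage stage syn.csv --out staged.csv
mmstage concord staged.csv --col-a stage_dsplus --col-b stage_riss
mmstage survive staged.csv --group-col stage_dsplus --plot km.png
```

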