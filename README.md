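# aabarray

Serum **a**uto**a**nti**b**ody protein-**array** analysis for grading pancreatic
intraductal papillary mucinous neoplasms (IPMN).

IPMN are cystic pancreatic lesions that can progress from low-grade to
high-grade dysplasia and on to invasive carcinoma. Deciding whom to
operate on hinges on separating low-risk (low-grade, IPMN-LR) from
high-risk (high-grade or with associated invasive carcinoma, IPMN-HR)
disease without surgery. One candidate readout is the autoantibody
repertoire: patient IgG/IgM/IgA binding to tumour-associated
self-antigens printed on a protein microarray. This package implements
the complete analysis for such a study — from per-spot fluorescence
tables to a ranked marker panel — and ships a synthetic-data generator
that emulates the reference cohort design (378 sera: 54 healthy
controls, 91 IPMN-LG, 66 IPMN-HG, 30 IPMN-CA, 137 early-stage PDAC, on
a 249-antigen array), so every stage is testable without access to the
original sera.

## The method

1. **Per-patient regional background.** For each antigen spot, the
   negative-control spots within a radius *r* are combined with
   inverse-distance weights `w_j = 1/(d_j + 1)^p`, giving a local mean
   `mu_r` and weighted SD `sigma_r` per spot, per serum. Per-patient
   estimation absorbs both the spatial structure of each slide and the
   serum-specific baseline.
2. **Seropositivity calling.** An antigen is immunoreactive when its
   median fluorescence intensity (MFI) reaches
   `T = mu_r + 5 * sigma_r`; the fold change is `f = MFI / T`, so a call
   is exactly `f >= 1`. Replicate spots aggregate by the median fold
   change. Both `T` and `MFI` scale with any per-sample intensity
   factor, so calls are invariant to serum brightness.
3. **Design matrix.** Binary calls (binding / no binding) — not
   intensities — enter the model. Antigens never called, or whose call
   pattern duplicates another antigen's, are dropped; class-balancing
   weights `w_i = n /(K * n_class(i))` equalize the weighted class totals;
   an age-percentile window can force the class age distributions into
   overlap.
4. **Marker selection.** A weighted multinomial lasso over the five
   disease classes, with age and sex unpenalized (penalty factor 0):

   minimize over β:  `(1/Σw) Σ_i w_i [log Σ_k exp(η_ik) − η_i,y(i)] + λ Σ_j pf_j Σ_k |β_jk|`

   solved by proximal gradient (FISTA) along a λ path, with λ chosen by
   inner stratified cross-validation on the weighted deviance (one-SE
   rule by default). Selected markers are the antigens with any nonzero
   class coefficient.
5. **Evaluation.** Hand–Till pairwise AUCs `A(i|j)` via midranks, their
   average — the multiclass **M-value** — apparent and under an outer
   stratified 10-fold cross-validation that refits the whole model per
   fold; confusion matrices; and per-marker / panel sensitivity and
   specificity for the IPMN-LR vs IPMN-HR dichotomy, where a panel
   (markers above a strict specificity gate, default >90%) calls a
   sample positive if at least one member does.

## Worked example

Simulate the reference-size study with 14 planted discriminative
antigens (seropositivity probability 0.30 in one class, 0.01 elsewhere),
call seropositivity, fit the model, and evaluate the panel:

```python
from aabarray import simulate_study, call_cohort, build_design, fit_design
from aabarray.arrays import cohort_frame
from aabarray.evaluation import marker_table, panel_evaluate
from aabarray.experiments import planted_config

cfg, planted = planted_config(seed=1)
layout, records, truth, tables = simulate_study(cfg)
calls = call_cohort(tables, layout)
design = build_design(calls, cohort_frame(records), trim=False)
est, markers = fit_design(design, random_state=1)
tbl = marker_table(design.X, design.y, markers)
panel = panel_evaluate(design.X, design.y, markers, specificity_gate_pct=90.0, table=tbl)
```

This prints (at seed 1):

```
samples: 378   antigens: 249
design: (378, 234)
selected markers: ['AG096', 'AG232', 'AG130', 'AG113', 'AG079', ...]   # 17 antigens
lambda: 0.00873
panel sens/spec: 71.9 97.8
```

All 14 planted antigens are among the 17 selected (3 false selections);
the ten selected HR-direction markers with specificity above 90% form a
panel that captures 71.9% of high-risk IPMN sera at 97.8% specificity
on this synthetic cohort. On real sera the corresponding published
panel of 7 markers reaches about one third sensitivity at comparable
specificity — synthetic signal is planted far cleaner than biology
provides (see `docs/methods.md`).

A command-line interface mirrors the stages:

```sh
aabarray simulate --seed 1 --out study/
aabarray call --spots study/spots --out study/calls.tsv
aabarray run-all --seed 1 --out report/
```

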