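# embryostack

Stacked embryo-implantation modelling and twin-rate-constrained embryo
selection for IVF cohorts.

## The problem

After ovarian stimulation and day-3 culture, an IVF clinic must decide how
many embryos to transfer and which ones. A double embryo transfer (DET)
raises the chance of clinical pregnancy but carries twin risk, with its
well-known perinatal complications; a single embryo transfer (SET) avoids
twins but may lower the success rate, especially for patients without a
top-quality embryo. The outcomes of the two embryos of a DET are not
independent — they share the same uterus and cycle — so the twin rate cannot
be obtained from per-embryo implantation probabilities alone.

`embryostack` is aimed at methodologists and embryology decision-support
developers. It provides:

* a **two-level stacked model**: a gradient-boosted per-embryo implantation
  scorer over 19 clinical and morphology features, feeding two DET-level
  scorers that read the 16 patient features plus the engineered pair
  features P1 + P2 and P1 × P2, and predict DET pregnancy and twin risk;
* a **selection rule**: among all single-embryo and pair plans, recommend the
  one maximizing predicted pregnancy subject to predicted twin risk ≤ τ, the
  clinic's acceptable twin-rate threshold, with sequential re-planning after
  a failed transfer;
* a **synthetic cohort generator** whose per-embryo implantation probability
  is a known function of the features plus a shared-patient latent
  receptivity term u ~ N(0, σ²) on the log-odds scale — conditional on u the
  two embryos implant independently, marginally they are positively
  dependent — so the whole pipeline is testable against exact oracles
  without patient data;
* **evaluation machinery**: rank-based AUC, repeated stratified train/test
  evaluation, calibration tables, and a three-algorithm comparison (boosted
  trees vs logistic regression vs a single classification tree) using Dunn's
  rank test with Benjamini–Hochberg FDR correction.

### Model sketch

For embryo *i* of a patient with feature vector *x*:

    logit P(implant_i | u) = f(x_patient, x_embryo_i) + u,   u ~ N(0, σ²)

Level 1 estimates the marginal of that quantity per embryo (P1, P2). For a
DET, level 2 models

    P(pregnancy) = g(x_patient, P1 + P2, P1 × P2)
    P(twin)      = h(x_patient, P1 + P2, P1 × P2)

and the recommendation solves  max pregnancy  s.t.  twin ≤ τ  over all
candidate plans. Label attribution for level 1: SET embryos take the
transfer outcome; both embryos of a 0- or 2-implantation DET take 0 or 1;
embryos of one-implantation DETs are excluded (attribution unobservable).

## Worked example

```
$ embryostack simulate --n 5828 --seed 1 --out cohort.csv
wrote 5828 transfer records to cohort.csv

$ embryostack train --cohort cohort.csv --seed 2 --out model.json
trained on 5828 transfers (406 embryos excluded from level 1); model at model.json
```

The 406 exclusions are the embryos of one-implantation DETs. Now score a
34-year-old patient with three embryos of decreasing quality (8-cell
fragment-free, 7-cell light fragmentation, 6-cell heavy fragmentation) at an
acceptable twin rate of 20%:

```
$ printf 'embryo_id,blastomere_number,fragment,equality\nE1,8,0,0\nE2,7,1,1\nE3,6,2,3\n' > embryos.csv
$ embryostack recommend --model model.json \
    --patient "age=34,attempt_times_ivf=1,antral_follicle_count=12,fsh=8.1,lh=4.0,\
e2_hcg_day=2600,endometrial_thickness=11.2,mii=9,two_pn=6,oocyte_number=10,\
two_pn_mii_ratio=0.67,agonist_protocol=1,endometrial_type_a=1,endometrial_type_c=0,\
secondary_infertility=0,icsi=0" \
    --embryos embryos.csv --tau 0.2
```

Abridged output (all six plans are printed, with the feasibility frontier):

```
"plans": [
  {"embryo_ids": ["E1","E2"], "pregnancy": 0.978, "twin": 0.970, "feasible": false},
  {"embryo_ids": ["E1"],      "pregnancy": 0.633, "twin": 0.0,   "feasible": true},
  {"embryo_ids": ["E1","E3"], "pregnancy": 0.505, "twin": 0.047, "feasible": true},
  {"embryo_ids": ["E2"],      "pregnancy": 0.448, "twin": 0.0,   "feasible": true},
  ...
],
"recommendation": {"embryo_ids": ["E1"], "pregnancy": 0.633, "twin": 0.0}
```

Reading it: transferring the two best embryos together would give the
highest predicted pregnancy (0.978) but a predicted twin risk of 0.970, far
above the 0.2 ceiling, so the model recommends transferring E1 alone
(predicted pregnancy 0.633, twin risk 0 by definition for a single embryo).
Raising τ above 0.970 would flip the recommendation to the pair — that
trade-off is exactly what the feasibility frontier in the report tabulates.
DET-level probabilities are trained on the cohort's ~560 double transfers
and are in-sample calibrated; at that sample size they can be extreme for
atypical feature combinations (see `docs/methods.md` on stacking leakage).
`--sequential` prints the full re-planning sequence instead.

Other commands: `evaluate` (repeated stratified train/test AUCs for the
three tasks), `compare` (boosted trees vs logistic regression vs single
tree, Dunn + FDR), `regress` (multivariable logistic companion analysis per
outcome). Every command is a thin wrapper over the library API
(`embryostack.generate_cohort`, `fit_hierarchical_model`, `recommend`,
`repeated_evaluation`, ...), which is the recommended interface for
programmatic use.

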