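# lgeviab

Late gadolinium enhancement (LGE) cardiovascular MR viability analysis:
from short-axis scar quantification to the prediction of global left
ventricular (LV) functional recovery after surgical revascularisation.

In patients with coronary disease and impaired LV function, bypass surgery
(CABG) improves ejection fraction (EF) only when enough myocardium is
still viable. On LGE-CMR, scar is bright and its **transmural extent**
per segment (graded 0, 1–25, 26–50, 51–75, >75 %LGE) predicts whether that
segment recovers contraction. This package implements the patient-level
question built on top of that: counting, over the AHA 16-segment model,
the segments that are either *viable* (dysfunctional, scar below a
transmural cutoff — default <50%) or *normal* (normally contracting), and
using that **viable+normal count N** to predict a global EF response
(responder: ΔEF ≥ 3 points at follow-up). The statistical chain is

* segmental recovery vs transmurality grade by **logistic GEE** with an
  AR1 (or independence) working correlation, patients as clusters;
* ΔEF model building: per-variable simple regression screen at p < 0.1,
  then one multiple linear regression over the retained variables;
* **ROC analysis** of N against responder status — AUC by the
  Mann–Whitney pair-counting identity, operating threshold by Youden's
  J = sens + spec − 1 (ties broken toward sensitivity), positivity
  N ≥ threshold — plus PPV/NPV from sensitivity, specificity and
  prevalence;
* paired t / χ² / Fisher / Mann–Whitney group comparisons and Cohen's
  kappa for grading agreement.

No patient images ship with the package. A first-class synthetic module
generates (a) annular short-axis LV **phantoms** (7 mm slices, 3 mm gap)
with subendocardial scar wedges of known angular span and transmural
depth, exact masks, and nulled remote myocardium, and (b) tabular patient
**cohorts** with known generative truth: recovery probability monotone
decreasing in grade, and ΔEF = β0 + β1·N + ε with the expected response
crossing the 3-point criterion just below N = 10 segments.

## Worked example

Run the whole chain on the bundled demo cohort (33 patients, seed 1):

```sh
$ lgeviab report --seed 1 --out demo_run
33 patients; responders 24; ROC threshold >= 10 (sens 0.88, spec 0.89, AUC 0.944); report in demo_run/report.json
```

The report says: 24 of 33 synthetic patients improved EF by ≥3 points;
the ROC analysis of the viable+normal count selected ≥10 segments as the
operating threshold (sensitivity 0.88, specificity 0.89, AUC 0.944) —
i.e. the analysis recovered the cohort's generative change-point of 10.
Inside `demo_run/report.json`, the segmental GEE (AR1) gives a grade
coefficient of −0.95 (p ≈ 2e−18): each additional transmurality grade
multiplies the odds of segmental recovery by exp(−0.95) ≈ 0.39. The
model-building stage retains the viable+normal count among the screened
baseline variables, and the remodeling table shows the ≥10-segment group
improving EF by 7.8 points and shrinking ESVI by 15.9 ml·m⁻² while the
<10 group is flat.

The image path works the same way from the shell:

```sh
lgeviab synth-phantom --out ph --wedge 2,0,90,0.6   # scar wedge on slice 2
lgeviab quantify --in ph --out sectors.csv           # 2SD threshold + sectors
lgeviab register --sectors sectors.csv --rings 0,2,4 --out segments.csv
```

or from Python:

```python
import lgeviab as lv

spec = lv.PhantomSpec(wedges=(lv.ScarWedge(2, 0.0, 90.0, 0.4),))
stack = lv.generate_phantom(spec)
table, mass, (mean, sd) = lv.quantify_stack(stack)
print(table.query("slice == 2 and sector < 2")["pct_lge"])  # ~35.2 vs 35.6 analytic
```

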