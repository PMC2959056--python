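# Methods

## Scar quantification

Scar is segmented by intensity thresholding: a voxel is enhanced when it
lies inside the myocardium and its signal is strictly greater than
mean + 2·SD of a remote-myocardium ROI (sample SD, n−1 denominator; the
multiplier k is a parameter). Scar mass assumes a myocardial specific
gravity of 1.05 g/cm³ over the imaged slab (7 mm slice thickness; the 3 mm
gap contributes no signal, so a voxel is pixel-area × 7 mm).

Per-sector transmural extent (%LGE) is, by default, the **area fraction**:
enhanced area over myocardial area within the sector's angular span. The
original reading of "transmural extent" could equally have been a radial
depth; a **chord** method (maximum, over 5°-wide radial chords, of the
scar's radial extent over the wall thickness) is available via
`method="chord"`. Area fraction is the default because it is the
reproducible, automatable statistic; the chord maximum carries an upward
discretization bias of roughly half a pixel per wall edge, visible in its
wider test tolerance. Note that for a subendocardial wedge of
thickness-fraction d the two disagree by geometry alone: the area fraction
is ((r_endo + d·t)² − r_endo²)/(r_epi² − r_endo²) with t the wall
thickness, which is below d (the inner wall contributes less area).

Grades bin the rounded integer percent: 0 (rounds to 0), 1–25 → 1,
26–50 → 2, 51–75 → 3, >75 → 4. Rounding half away from zero makes the
25/26, 50/51, 75/76 boundaries exact.

## Segment registration

Angles are measured from the anterior insertion of the right ventricle
(segment 1's edge), increasing counter-clockwise as viewed from the apex;
this convention is defined once in `phantom.Geometry` and used everywhere.
Two basal-slice rules coexist and are both implemented: volumetry uses the
most basal slice with ≥50% myocardial circumference; segment registration
uses the first slice without LV outflow tract. The mid ring sits 20 mm
(two 10-mm increments) below the base conditional on papillary muscle
without trabeculation, the apical ring 20 mm further with trabeculation
and no papillary muscle; when the nominal slice fails, the search falls
back in the order +1, −1, +2, −2 increments (apex-ward preferred), and an
unsatisfiable condition is an error naming the failed ring.

The AHA 16-segment model uses 6 × 60° basal, 6 × 60° mid and 4 × 90°
apical segments; the apical ring is rotated 45° from the basal anchor per
the standard AHA diagram (the rotation is a convention choice; sources
differ). The 48-segment model is 6 slices × 8 × 45° sectors. Segments
aggregate finer sectors by **myocardial-area-weighted mean %LGE, then
re-grade**; a majority vote over sector grades was rejected because the
grade is defined on extent, not on votes. The fine sector grid must
subdivide segment boundaries exactly (24 sectors/slice works for every
scheme); misalignment is an error rather than a silent approximation.

## Function, viability, counting

Volumes use disc summation at 10-mm increments with no gap interpolation;
EF = 100·(EDV − ESV)/EDV; EDVI/ESVI index by body surface area. Regional
wall motion is graded 1 (normal) to 5 (dyskinetic); a segment *recovers*
when it improves by ≥1 grade except the 5→4 transition, which does not
count as recovery.

Viability labels are function-first: a segment with pre-op grade 1 is
**normal** regardless of scar; otherwise it is **viable** when %LGE is
strictly below the cutoff (25/50/75; default 50) and **nonviable** when at
or above it. How a normally-contracting-but-heavily-scarred segment should
count is genuinely underdetermined; the function-first rule follows the
construct "all segments able to contribute to the endpoint", and such
segments are rare in realistic cohorts. Missing segments count as neither
and are logged. Responders are defined inclusively: ΔEF ≥ 3 (or ≥ 5) EF
points.

## Statistics

* **ROC**: AUC by the Mann–Whitney identity with ties counting ½ —
  identical, on these integer scores, to the trapezoid under the
  threshold-swept curve (asserted in tests). The curve is evaluated at all
  integer thresholds spanning 0–16; the operating point maximises
  Youden's J, with ties resolved toward higher sensitivity. Positivity is
  count ≥ threshold.
* **GEE**: logistic, clusters = patients, robust (sandwich) SEs, AR1 or
  independence working correlation (statsmodels). AR1 orders segments
  within a patient by segment index 1–16 — an assumption, since spatial
  adjacency around the ring is not an order; the independence structure is
  the check that conclusions do not hinge on it. Apparent separation or
  non-convergence is reported in the fit object (`converged=False` with a
  diagnostic), never raised.
* **Model building**: stage 1 screens each baseline variable by simple
  linear regression against ΔEF at p < 0.1 (the slope t-test; with one
  regressor this is equivalent to the Pearson-r test); stage 2 enters all
  retained variables simultaneously in one OLS. No multiple-testing
  correction is applied at the screen, deliberately; with ~12 candidates
  the screen admits a null variable about 10% of the time (tested).
  Rank deficiency of the retained design is flagged, not hidden.
* **Kappa**: unweighted Cohen's kappa, undefined (error) when both raters
  use a single category.
* **Group comparisons**: paired t (with an explicit t=0, p=1 convention
  for identical vectors, where the 0/0 statistic is otherwise undefined),
  χ² falling back to Fisher's exact test when any expected cell is < 5,
  and Mann–Whitney for non-normal continuous data.

## Synthetic data

The phantom is an annular myocardium (default endo 22 mm / epi 32 mm,
129² grid at 1 mm, 6 slices) with subendocardial scar wedges growing
radially outward from the endocardium by a transmural depth fraction.
Remote myocardium is nulled near 15 a.u., scar near 90 a.u.; noise is
Gaussian on the magnitude image by default (adequate at these SNRs) with
a Rician option. The remote ROI is myocardium ≥30° from any wedge on its
slice — clean by construction; contaminated ROIs are a test fixture, not
a default. Ground truth (exact masks and the analytic per-sector depth
and area fraction) is carried beside the intensities. Not emulated: MR
physics (inversion recovery, surface-coil shading), partial-volume
blurring at boundaries, papillary muscles and trabeculation in the image
(they exist only as slice annotations), or respiratory/cardiac motion —
so passing phantom tests demonstrates correctness of the planimetry
given masks and intensities, not robustness to acquisition artifacts.

The cohort generator draws, per patient, a nonviable-segment count from a
clipped normal (mean 5, SD 3, so the viable+normal count is ~11 ± 3 of
16), a Poisson(3) number of low-grade (1–2) scarred segments, scar %LGE
uniform within the grade's bin, and dysfunction for 25% of unscarred
segments — so that "normal" ≠ "unscarred" and roughly two-thirds of
segments are dysfunctional while about half are scarred. Dysfunctional
segments recover with probability (0.73, 0.65, 0.50, 0.25, 0.10) by
grade — monotone non-increasing, anchored at 73% for unscarred segments.
Baseline EF is N(38, 11) clipped to [12, 75]; EDVI is N(118, 33); ESV
derives from EDV and EF so the volume identities hold exactly; scar mass
is 0.066 g per summed segment-%LGE point plus noise, centring near 28 g.

ΔEF = β0 + β1·N + ε with slope β1 = 1.298 EF points per viable+normal
segment. The intercept is set so the expected ΔEF equals the 3-point
responder criterion **at N = 9** (β0 = 3 − 9·β1): patients at N = 9 are
coin-flip responders and from N = 10 up clearly respond, making 10 the
population-optimal Youden threshold of the counting rule. Placing the
knife-edge at N = 10 instead would make the N = 10 bin 50/50 and — with a
responder prevalence above one half — push the population Youden optimum
to 11 for *any* noise level; the generative change-point would then not
be recoverable even in infinite samples. The noise SD defaults to 2.0 EF
points, the largest round value that preserves p(responder | N=9) <
prevalence < p(responder | N=10), the condition under which threshold 10
is population-optimal. A consequence worth knowing: the synthetic
count–ΔEF correlation (~0.88) and AUC (~0.94) run somewhat higher than
is typical of observed cohorts; the generator targets the recoverable
change-point, not any particular observational correlation (likewise it
guarantees the monotone EF–wall-motion association without targeting a
specific r). Follow-up EDVI shrinks by 1.6 ml·m⁻² per ΔEF point plus
N(0, 5) noise, producing the expected reverse-remodeling pattern in the
≥10-segment group.

With noise SD 0 the ΔEF model is exactly linear (clips on EF are
unreachable there), so regression recovers β0 and β1 to machine
precision — used as an oracle in the tests.

## Problem sizes and tolerances

Tests run phantoms at 129² (convergence checked against 257² at halved
pixel spacing: discretization error at least halves), cohorts at n = 33
(the analysis size) and n = 200 (for per-grade rates and GEE power), and
200 replicate cohorts for threshold-recovery; the whole suite completes
in well under a minute. Planimetry on the noise-free default wedge is
within 0.4 percentage points of the closed-form area ratio (tests assert
2.0); area conservation and scheme-agreement identities are exact to
float round-off; GEE-independence on singleton clusters matches ordinary
logistic regression to 1e−6.

## Known limitations

* The chord transmurality reading is max-biased at coarse resolution (see
  above); the area method is the default for a reason.
* The pipeline's tabular path does not simulate the image path per
  patient (phantom → sectors → segments is exercised separately); wiring
  full image cohorts through the pipeline is straightforward but slow and
  adds nothing to the statistics.
* Operator override of automatic grading is replaced by deterministic
  rules; inter-observer variability enters only through the kappa
  utility.
* No FWHM or alternative thresholding beyond k·SD, no partial-volume
  modelling, no DICOM ingestion.
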