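# Methods

This note documents the models, estimators and numerical choices behind
`mcakscreen`, and what the synthetic-data validation does and does not
demonstrate.

## Image-based polymer quantification

### Processing chain

Both quantification variants share one code path:

1. **Sharpen** — 3×3 high-pass kernel (−1 ring, center 12, divided by
   the kernel sum 4), replicate padding at the borders, output clamped
   to the bit-depth range (12-bit images use the camera convention of
   4094 usable gray levels). A constant image is unchanged; a lone
   pixel of value *v* becomes 3*v*.
2. **Edge detection** — Sobel gradient magnitude √(Gx²+Gy²), clamped.
   An ideal step of height *h* reads 4*h* in the two columns adjacent
   to the step.
3. **Binary threshold** — IsoData auto-threshold (deterministic) or a
   fixed value; polarity is handled internally so foreground always
   means particles. **Holes are filled** after thresholding: edge
   detection turns solid objects into outlines, and measuring filled
   shapes is what makes (a) the perimeter-to-length conversion coherent
   (the perimeter of a solid elongated particle is ≈ 2·length +
   2·width, whereas an annulus has no such relation) and (b) the
   circularity filter meaningful (a filled aggregate disc has
   circularity ≈ 1 and is rejected; the annular outline of the same
   disc would have deceptively low circularity and slip through).
4. **Particle analysis** — 8-connected component labeling; per-particle
   pixel area (scaled by `pixel_size²` for calibrated units), boundary
   perimeter, circularity 4π·area/perimeter², and derived length.

For well time series, the threshold is estimated **once on the t = 0
(pre-enzyme) baseline image and reused at the later timepoints**.
Auto-thresholding each image independently is unstable in exactly the
interesting regime: when the enzyme has removed most polymer, the
IsoData split lands inside the noise distribution and segments large
parts of the background (we measured "percent remaining" above 400%
without anchoring). Anchoring keeps the segmentation operating point
fixed within a well, which is what a ratio of timepoints assumes.

### Perimeter estimator

The perimeter is the length of the closed outer boundary chain through
boundary-pixel centers, obtained by Moore-neighbor tracing with
diagonal steps weighted √2 (a 10×6 solid rectangle has perimeter
2·(9+5) = 28). Holes do not contribute (masks are hole-filled in the
pipeline). Two details matter:

* the deterministic trace can include a short transient before its
  recurrent cycle on some concave shapes, so the chain length is
  accumulated around the recurrent cycle only;
* a single-pixel particle is assigned its pixel outline, 4, so
  circularity stays finite. Chain-through-centers perimeters are
  meaningless for particles of a few pixels (a two-pixel domino would
  read circularity 2π); all such particles lie far below the size
  filters of both variants, so this never affects reported metrics.

The test suite checks the implementation against an independently
written brute-force flood-fill and *counterclockwise* boundary walk,
requiring exact agreement of counts, areas and perimeters on random
masks.

### Size bands, calibration and the length formula

* **Screen variant** — size band 0.0015–0.1 in calibrated area units,
  circularity 0–0.7 (closed intervals), metric = polymer level =
  count × mean area ≡ total area. The calibrated unit is set by
  `pixel_size`, default 0.003 units/px, so the band corresponds to
  ≈167–11 111 px². This calibration passes single filaments of
  ≈20–1300 px length, keeps clusters of a few crossing filaments
  inside the band (dropping merged clusters at t = 0 would bias the
  percent-remaining ratio upward), and rejects noise specks.
* **Sedimentation variant** — size band 110 px²–∞ (raw pixels),
  circularity 0–0.7, metric = total polymer length normalized to the
  pooled FCP control condition.
* **Length formula** — *L = (P − 2w)/2*, clamped at 0. The constant is
  twice the effective post-processing width *w*, which is **not** the
  nominal 6 px filament width: the sharpen/edge halo widens filled
  particles to ≈8 px, and the boundary chain overestimates the
  perimeter of digitized strips at intermediate orientations by up to
  ≈8% (the classic chain-code staircase bias). Calibrated on noiseless
  single-filament renders over lengths 30–300 px at five orientations,
  `RunConfig.mt_width_px` defaults to 12, which keeps single-filament
  length recovery within 10% across that range. The bare
  `particle_length` function keeps the conventional default of 6 for
  direct use; both are configurable for re-calibration against other
  imaging setups.

Hit calling uses percent polymer remaining, 100 × level(t60)/level(t0);
wells with zero baseline polymer are flagged and excluded rather than
divided by.

## Synthetic image generator

Filaments are anti-aliased bright segments with a flat-top cross
profile out to w/2 − 0.5 px and a Gaussian shoulder of σ = 0.4 px, so
the half-maximum width equals the nominal 6 px width and the foreground
area tracks Σ(length × width) within a few percent on noiseless
renders. Aggregates are filled discs (default radius 8 px, 5% of
objects) to exercise the circularity filter. Noise is Poisson shot
noise on (background + signal) plus Gaussian read noise; defaults are
background 150 ADU, read noise 5 ADU, and amplitude SNR 30 ×
background-noise scale — bright, high-contrast rhodamine-labeled
microtubules on a 12-bit camera. All generators are pure functions of
(parameters, seed); plate simulators derive per-well sub-seeds so wells
are independent but reproducible.

Depolymerization time series model all-or-none removal of individual
microtubules: the t = 60 field keeps filaments (in sampling order)
until the target residual fraction of total length is reached, with the
crossing filament shortened so the truth is exact; t = 30 sits at the
geometric mean of the t = 0 and t = 60 totals. Active-enzyme wells
default to a residual fraction of 0.1 (90% depolymerization);
enzyme-free and inhibited controls to 1.0.

**What this does not emulate:** uneven illumination, focus drift,
well-edge vignetting, filament curvature, bundling, and the
well-to-well variability of microtubule surface attachment that
dominates the real assay's CV. Passing recovery tests on these images
demonstrates that the quantification chain is unbiased and internally
consistent, not that it is robust to every real-world artifact.

## FRET model

Per-well true ratios are Normal(mean, SD) by role — uninhibited enzyme
1.64 ± 0.02, antibody-inhibited 1.34 ± 0.03, Aurora-B-phosphorylated
1.10 ± 0.01, and the enzyme-free donor–acceptor fusion (FCP) set to
4.0 ± 0.08 to represent its qualitatively "very high" FRET (the exact
value is configurable; only its separation from the enzyme ratios
matters). Compound wells behave like uninhibited-enzyme wells times an
optional multiplicative effect. The donor signal (1000 reader units)
and per-channel backgrounds (40, 50) are deterministic reader
constants, so the generated well ratio is exactly recoverable by
background-corrected division — with zero SDs the pipeline reproduces
the generator truth bit-for-bit and Z′ is exactly 1.

Analysis: ratio = (I_F − B_F)/(I_D − B_D) with backgrounds from the
mean of same-plate buffer blanks ((0, 0) with a warning when a plate
has none). A non-positive corrected donor flags the well invalid (NaN)
rather than raising; invalid wells are excluded from baselines and
reported. Hit calling compares each compound well to the mean of the
same-plate uninhibited-enzyme control wells — per-plate normalization,
the HTS norm. Replicate readings are averaged at the ratio level.

A note on classification margins: with per-well SD 0.03, an
antibody-inhibited well sits only ≈1.8 SD beyond the −15% cutoff, so
single readings of individual control wells occasionally fall short;
condition-level control ratios (means over the role's wells, as control
values are conventionally reported) classify with ≈3.6 SD of margin.

## Screen analytics

Z′ uses sample SDs (n − 1) — with as few as four control wells per
plate this choice visibly matters — and returns NaN when the control
means coincide. CV is reported over the positive-control wells by
default. Image-assay thresholds are strict (>50, <10, following
"greater than"/"less than"); the FRET threshold is inclusive (≥15,
following "or more"). Duplicate hits require the same non-NONE class in
both replicates; a compound is confirmed iff it is a primary hit,
scores non-NONE in the rescreen, and is not flagged by the FCP counter
screen (which detects compounds perturbing the fluorophores rather than
the enzyme). Hit rates round half-away-from-zero to one decimal;
dilution concentrations to two decimals; the substrate:enzyme molar
ratio reports its integer part.

## Dose–response

The three-parameter log-logistic model fixes the Hill slope at unity —
that is precisely what distinguishes it from the four-parameter fit and
is the appropriate option when few dose levels are available. MTT
preprocessing subtracts the 650 nm reading from the 570 nm reading,
averages duplicate wells, and normalizes to the mean zero-dose (DMSO)
delta; the zero dose never enters the log-dose fit. Fitting is
least-squares via trust-region optimization with Bottom bounded below
at 0, initialized at Top = max, Bottom = min, and logIC50 interpolated
at the half-range crossing.

Because normalized viability carries an approximately constant
coefficient of variation, the default objective minimizes log-scale
(relative) residuals; this roughly halves the logIC50 standard error at
10% CV compared with unweighted residuals and is exactly equivalent for
noiseless data (recovered to ≥10 significant digits). Plain residuals
are available via `weighting="none"`. Flat data and optimizer failures
return flagged fits; fold-changes propagate the flag as NaN. The IC50
fold-change IC50(reference)/IC50(treated) is reported to one decimal;
values above 1 indicate sensitization. In paired experiments (reference
and co-treated condition simulated or measured together), fold-change
recovery at 10% CV with duplicate wells and 8 dose levels is accurate
to well under 10% on a five-experiment mean.

## Cell-assay statistics

Proportion assays score a fixed number of cells (100 by convention) per
biological repeat; tests operate on replicate-level percentages, never
pooled counts, so the experimental n is the number of repeats. The
two-condition comparison is the two-sided equal-variance Student's
t-test (configurable in principle to Welch, but equal-variance is the
stated convention); degenerate zero-variance inputs are handled
explicitly (equal means → p = 1, distinct constant groups → p = 0).
Under a binomial null with three repeats per arm, the test's type-I
error at α = 0.05 is calibrated within binomial error over 10 000
simulations. Colony counting is strictly greater-than-50 cells;
normalized clonogenic fractions are compared to the theoretical control
value 1.0 with a one-sample two-sided t-test.

## Problem sizes in the test suite

The suite validates the particle oracle on 500 random ≤32×32 masks,
image recovery on one 4-well plate of 512×672 px time series, FRET
recovery on 96-well plates, fold-change recovery on 5 paired
experiments (with a 60-experiment median-bias check), and type-I
calibration on 10 000 simulated assays — sizes chosen to give stable
statistics while the whole suite runs in well under a minute.

## Known limitations

* The perimeter → length conversion is calibrated for straight,
  non-overlapping filaments; heavily bundled or curved polymer will
  bias lengths (the area-based screen metric is less sensitive to
  this).
* The screen-variant size band depends on the pixel-size calibration;
  other acquisition settings require re-deriving `pixel_size` and
  `mt_width_px` (both are single config values).
* The FRET model treats reader background as deterministic;
  plate-position effects and crosstalk between channels are not
  modeled.
* The image assay's dominant real-world noise source — variable
  microtubule attachment between wells — is not simulated, so measured
  Z′ on synthetic plates is optimistic relative to the wet assay.
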