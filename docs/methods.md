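# Methods

This note documents the models implemented in `microdomain`, the defaults
that matter, what the synthetic-data generator does and does not emulate,
and the design choices made where the methodology was genuinely open.

## Image formation model (simulator)

Fields are rendered on a pixel grid (0-based row/col, origin top-left)
with a physical pixel size in µm. Point emitters are drawn with an
isotropic 2-D Gaussian PSF whose mass is integrated analytically over
pixel areas (error-function differences), truncated beyond 5σ from the
centre; the truncation discards < 10⁻⁶ of the flux, and the test suite
verifies total-flux conservation against the closed-form Gaussian mass
inside the field to 10⁻³ relative.

Noise models: `poisson` (shot noise on signal + background),
`gaussian` (additive, SD `gaussian_noise_sd`), `poisson_gaussian`
(both — the EM-CCD-like default), or `none`. Images are clipped at zero
after noise. Every generator takes a mandatory integer seed and is
bit-reproducible; there is no global random state.

### DSLB TIRF fields

* Single fluorophore: integrated intensity drawn per emitter from
  Normal(`single_intensity_mean` = 1000 ADU, CV = 0.1), floored at 5% of
  the mean to stay physical.
* Trimer: one emitter with exactly 3 molecules (3× a single-intensity
  draw) — the small-oligomer species.
* Cluster: molecule count drawn from lognormal(ln 25, 0.9154), redrawn
  below `cluster_min_molecules` = 11. The untruncated law has median 25
  and arithmetic mean 38 molecules, matching a high-cholesterol bilayer;
  truncation raises the realized sample mean above 38, which is why
  distribution-level checks are phrased against the law, not the sample
  mean. Each molecule is an individual emitter placed uniformly in a disc
  of radius 0.05 µm × √N (constant areal density, sub-µm footprints).
* Defaults `background_level` = 100 ADU/px and read noise SD 10 give a
  single-molecule peak SNR of ≈ 5–7 — detectable but noisy, as in real
  single-fluorophore TIRF.

Truth tables record every emitter (position, molecule count, cluster id,
flux) plus per-field totals. Molecule counts are integers; because
rounding continuous lognormal draws to integers measurably distorts the
empirical CDF at a scale of ~25 molecules, the sampler also exposes its
continuous pre-rounding draws
(`sample_cluster_molecule_counts(..., integer=False)`), and
distribution-fidelity tests (KS against the truncated generating law) use
those.

### GUV equatorial sections

Liposomes are laid out on a jittered grid (no overlaps, none touching the
border), radius uniform in 1.5–2.5 µm; as many 480×480 px fields as
needed are generated. The membrane ring has a Gaussian radial profile
(σ = 1.5 px); the protein channel carries the same ring profile at the
diffuse-protein level plus clusters. Per-liposome cluster counts are
Poisson(`lambda_clusters`); cluster footprint areas are lognormal
(median 0.25 µm²).

Clusters are rendered as **hard discs** (pixels whose centre falls inside
the radius), not PSF-convolved blobs. This is a deliberate choice: the
analysis measures cluster area on a thresholded mask without
deconvolution, and for a smooth-edged profile the 2×median threshold sits
far below the cluster plateau, placing the measured boundary well outside
the nominal edge and inflating areas by 25–45%. With hard-edged discs the
thresholded area agrees with the recorded truth area to within pixel
quantization, keeping the area measurement and its ground truth mutually
consistent. Angular positions on the ring are drawn with a minimum
separation so discs stay disjoint (counts remain exactly the Poisson
draws; the rendering never merges clusters).

Intensity defaults (background 80, diffuse ring 400, cluster +1200,
membrane 800 ADU) put the per-liposome threshold (2× the median ring
intensity, ≈ 560 ADU) about 4 shot-noise SDs above the brightest diffuse
ring pixels and far below the cluster plateau, so false-positive and
false-negative cluster calls are both negligible at the default noise.

### Colocalization pairs and FRAP traces

Channel-B puncta are co-positioned exactly on distinct channel-A puncta
at the requested fraction (`round(overlap_fraction × n_B)` — exact in
truth); the remaining B puncta are kept ≥ 6 PSF σ from every A punctum so
that the 1.5×mean threshold masks of distinct puncta are disjoint and the
truth overlap is recoverable from masks. Puncta are bright extended
objects (integrated intensity 20 000 ADU — cellular junction puncta, not
single fluorophores). FRAP traces follow the closed form
`1` (pre-bleach) → `(1−d) + d·m·(1−e^(−t/τ))` with bleach depth d, mobile
fraction m, and additive Gaussian noise.

## Quantification

**Background.** Field background is the median pixel value (robust to
sparse bright spots); per-spot local background is the median of a
3-px-wide annulus offset 2 px from the spot, falling back to the field
median when the annulus touches another spot.

**Calibration.** Candidate spots above
`background + max(4·σ_bg, 2% of dynamic range)` (σ_bg from the MAD) are
kept if they are ≥ 5 PSF σ from the border and have no neighbour within
6 PSF σ; intensities are integrated over the component dilated by ~2σ
(recovering sub-threshold PSF tails); values above 1.5× the cohort median
and then the top 5% are discarded as multi-fluorophore contaminants.
Fewer than 10 survivors is a calibration error. On noise-free simulated
singles the calibrated mean is within a fraction of a percent of truth;
with CV 0.2 and shot noise, within a few percent (slight upward bias from
preferentially missing the dimmest spots).

**Detection.** The spot threshold is expressed in molecule units:
`background + threshold_molecules × A₁`, `A₁ = I₁/(2πσ²)`. The stated
"intensity level of five molecules" criterion is ambiguous between a
peak and an integrated reading; thresholding operates on pixels, so the
peak-amplitude form is used — it is calibration- and PSF-consistent, and
σ is an explicit parameter (`QuantParams.psf_sigma_px`, default 1.3).
Components are 8-connected, ties at the threshold included, components
smaller than `min_spot_area_px` = 2 discarded. Note that with the default
threshold (5 molecules) singles and trimers are intentionally
sub-threshold; oligomer-counting analyses lower `threshold_molecules`
(the trimer recovery tests use 1.0). Molecule counts are kept unrounded.

**Clustered fraction.** Total protein intensity is
Σ max(pixel − background, 0) — deliberately including diffuse
sub-threshold fluorescence — and the clustered fraction divides the
summed intensity of >10-molecule spots by it. Two opposing small biases
exist: in sparse fields, zero-flooring rectifies noise into the
denominator (underestimating the fraction); in very dense fields the
median background absorbs diffuse signal (overestimating it). At a
realistic fluid-bilayer density (~2.3 emitters/µm²; the default test
condition uses 600 singles + 120 trimers + 48 thirty-molecule clusters in
a 25.6 µm square) both effects stay within ±0.03 of truth. This is a
property of the estimator on any data, not of the simulator.

## GUV analysis

The membrane channel is thresholded at mean + 2 SD, closed and
hole-filled; components touching the border are excluded (censored
counts), circularity (4πA/P²) must reach 0.6, and the radius is the mean
distance of thresholded ring pixels from the component centroid (an
unbiased ring-radius estimator; recovered radii are within a few percent
of truth). Clusters are protein pixels above
`cluster_threshold_factor` (default 2.0) × the median intensity on the
ring annulus (half-width 0.35 µm), 8-connected, ≥ 5 px; a component is
assigned to the liposome whose ring band contains its centroid, and its
full (unclipped) component area is converted to µm². The blinded-observer
"cluster-positive" call of manual scoring is replaced by this explicit,
configurable criterion; results should always be reported together with
the threshold factor used. Because both SEM and 95% CI conventions are
common for cluster areas, the dataset summary reports both.

## Statistics

* **Poisson fit**: λ̂ = mean (MLE); exact 95% CI from the chi-square
  (gamma) bounds on the total count; χ² GOF with right-tail pooling to
  expected ≥ 5 and one df spent on λ̂ (reported as NaN when fewer than
  three pooled bins remain).
* **C-test**: conditional binomial with two-sided p by the
  minimum-likelihood method (sum of outcomes no more probable than
  observed, capped at 1). Exact, symmetric under group swap; verified
  against exhaustive exact-rational enumeration for all totals ≤ 30. The
  type-I error at α = 0.05 under equal rates (λ = 0.5, n = 200/group) is
  5% ± 2% (mild conservatism from discreteness is expected and accepted).
* **E-test**: standardized rate difference with per-outcome variance
  estimates; p by summation of the joint Poisson probability (under the
  pooled null rate) over all outcomes at least as extreme, lattice
  truncated at 10⁻¹³ marginal tail mass. Typically slightly less
  conservative than the C-test.
* The exposures n₁, n₂ are liposome counts (rates per liposome), not
  membrane areas.
* **Lognormal fit**: MLE on log data (biased-sd form); KS against the
  fitted normal *without* Lilliefors correction — anti-conservative, and
  flagged in the result metadata rather than silently corrected, because
  that is the standard field practice being reproduced. Zero log-spread
  samples are flagged degenerate with σ at the boundary.
* **Histograms**: half-open bins `[edge, edge + width)`, width 2
  molecules by default, edges anchored at an integer multiple of the
  width; out-of-range samples are dropped.
* **Group comparisons** are delegated to scipy: Student's t (equal
  variances), one-way ANOVA post hoc via `tukey_hsd`, Dunnett via
  `dunnett`; multiplicity-adjusted p-values are returned per comparison.

## FRAP

Double normalization: subtract background, divide frame-wise by the
reference ROI scaled to its pre-bleach mean (acquisition-bleaching
correction), divide by the pre-bleach mean, then map affinely so
pre-bleach = 1 and the first post-bleach value = 0. The recovery model is
a single exponential with time re-zeroed at the first post-bleach frame —
a well-mixed approximation chosen over a diffusion-type model because
only the plateau is interpreted, and the plateau is robust to the kinetic
model (the choice is recorded in the result metadata). `y_max` is not
constrained ≤ 1, so complete recovery can fit marginally above 1;
`immobile_fraction` clips to [0, 1]. Flat traces (no recovery) return
y_max = 0 flagged degenerate, since τ is unidentifiable.

## What the simulator does not emulate

Physically realistic membrane optics and 3-D PSFs; fluorophore
photobleaching during acquisition (other than the FRAP bleach event
itself); liposome polydispersity beyond a uniform radius range;
out-of-focus light and camera fixed-pattern noise; manual curation of
bilayer defects (an exclusion mask can be supplied instead). Passing
tests therefore demonstrate correctness of the estimators under the
stated image-formation model, not robustness to every artefact of real
microscopy — in particular, thresholded-area and clustered-fraction
measurements on real data inherit PSF broadening and background structure
that the tolerances here do not cover.

## Problem sizes and numerical choices

Test and acceptance runs use 512×512 px calibration/counting fields,
~200-liposome GUV datasets (the two experimental sample sizes, 194 and
201), 2000 replicates for the type-I calibration, 1000 (tests) or 200
(acceptance script) replicates for lognormal-fit calibration at n = 500,
and 100 noisy FRAP traces per mobility level — sizes at which the
sampling error of each check is several times smaller than its tolerance.
Curve fits use analytic starting values (plateau from the trace tail, τ
from the half-recovery time); thresholds use strict `>` comparisons
except the calibrated spot threshold, where ties are included by design;
all per-stage seeds derive deterministically from a single master seed.
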