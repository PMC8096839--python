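# Methods

This note records the models behind `forcefret`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions made where the design was open.

## Spring calibration

The sensor is modelled as a linear spring in series with a constant
linker: F = (r − b·n − c)/(a·n), with the fluorophore separation r tied
to the FRET efficiency by E = 1/(1 + (r/R₀)⁶). Defaults describe the
29-residue flagelliform construct labelled with an AF555/AF647 pair:
a = 0.0122 nm/pN, b = 0.044 nm, n = 29, R₀ = 5.1 nm. The linker
constant c is not a free parameter of the model but is inferred at run
time from a zero-force measurement (`calibrate_linker`): the collapsed
sensor on a cell-free bilayer shows E₀ = 0.87, giving c ≈ 2.439 nm.
c is carried unrounded internally (display rounds to 2.4 nm); rounding
before use would shift the derived force anchors (10 pN ↔ E = 0.11,
0.9 pN ↔ E = 0.8) by several percent.

Forces below zero (separations below the collapsed length, as produced
by symmetric measurement noise around E₀) are reported as-is with a
flag rather than clamped, so zero-force noise stays symmetric and does
not bias population fits.

`propagate_peak_to_force` converts a fitted Gaussian FRET peak into a
force-distribution summary by deterministic quadrature: the Gaussian is
truncated to the sensor's dynamic range, evaluated on ≥ 2001
equidistant nodes, and pushed through the (convex, decreasing) E→F map.
Because of the convexity the transformed mean exceeds the point
conversion F(peak mean) — e.g. a peak at 0.42 ± 0.22 yields ≈ 4.8 pN
versus F(0.42) = 4.71 pN. Monte-Carlo sampling is used only as an
independent oracle in the tests; quadrature keeps results exactly
reproducible.

Two readouts of "peak force" are deliberately exposed: the point
conversion `fret_to_force(mean E)` and the truncated-distribution mean.
Which one a study reports is a convention; both are available and the
tests pin both.

## Synthetic movies

`simulate.render_movie` emulates the imaging physics of a two-color
ALEX TIRF/EMCCD experiment. Per frame doublet, a green exposure yields
the DD and DA images and the following red exposure the AA image. For
a 1:1 sensor with donor-channel photon budget N per frame (at unit
laser intensity) and correction factors (α, δ, γ, β):

    f_DD = N (1 − E)
    f_DA = γ N E + α f_DD + δ f_AA
    f_AA = β γ N

This parametrization makes the standard accurate-FRET identities exact
in expectation: the corrected efficiency recovers the scheduled E and
the stoichiometry of intact pairs is exactly 0.5 regardless of γ.
Multiplicity classes (donor-only, acceptor-only, double-donor at
S = 2/3, double-acceptor at S = 1/3) scale the budgets accordingly.

Rendering: expected photons are spread with an integrated Gaussian PSF
(error-function integration per pixel, σ default 1 px), multiplied by
the laser profile at the molecule position, Poisson shot noise applied
per pixel, then converted to camera counts (counts = photons ×
gain/ppc, defaults 300 and 15.7) with Gaussian read noise (20 counts)
and a constant offset (100 counts). EM-gain excess noise is *not*
modelled: the count↔photon conversion is treated as the deterministic
scale used in calibration. Coordinates are 0-based pixel indices with
positions at pixel centers; physical lengths convert via the 160 nm
pixel size. The DD channel is rendered in donor geometry (positions
mapped through the inverse channel transform) so that registration is
a real processing step, not a no-op.

Defaults were chosen once as realistic study conditions: photon budget
N = 1500/frame (a bright organic dye at 5 ms illumination on an EMCCD),
background 3 photons/px/frame, diffusion 0.001 µm²/s for gel-phase
anchors versus 0.72 µm²/s for fluid bilayers, frame doublets at 50 fps
(t_ill = 5 ms, t_delay = 15 ms), 300 frame pairs per movie. Acceptor
bleach times are drawn uniformly inside the movie so that every intact
sensor exhibits the single bleaching step the QC chain demands.

Not emulated: fluorophore blinking kinetics (blinking can only be
mimicked as configured gaps), vesicle/microcluster morphology, TIRF
evanescent-depth effects, and EM excess noise. Passing tests therefore
demonstrate correctness of the analysis chain under idealized
single-emitter photophysics, not robustness to every artifact of real
recordings.

## Detection, tracking, brightness

Spots are detected on the registered sum image T(Im_DD) + Im_DA (green
frames) and on Im_AA (red frames) after a σ = 1 px Gaussian blur: local
maxima above the image median plus k = 4 robust noise standard
deviations, refined by 2D Gaussian least squares (fallback: intensity
centroid). Using the sum image makes detection independent of the FRET
state. Localizations are interlaced in recording order and linked by
globally optimal frame-to-frame assignment (Hungarian algorithm) with a
hard gate of 800 nm between consecutive frames, growing with the square
root of the gap during memory (≤ 3 frames); gaps are filled by linear
interpolation and flagged. Trajectories need ≥ 4 true observations.

Brightness: the blurred image is summed over the pixels whose centers
lie within 4.5 px of the rounded position (9 px diameter foreground
circle) minus the mean of a 4.5–7.5 px annulus; annulus pixels within
a foreground radius of any neighbor are excluded, and a fully occluded
annulus falls back to the image median with a flag. The 3 px annulus
width is a package choice — wide enough for a stable mean at the
densities simulated. Values are divided by the laser profile at the
position (profile: stained-sample image, σ = 10 px blur, scaled to a
maximum of exactly 1). Records whose annulus would leave the image are
dropped.

## Quality-control chain

Canonical order: laser region (≥ 50% of peak intensity) → overlap
(trajectories with > 25% overlapping foreground circles dropped, other
overlapping records removed) → first-frame presence → photobleaching →
E/S computation → stoichiometry (> 25% of records outside S ∈
[0.35, 0.6] drops the trajectory) → optional cell mask.

Step detection is greedy binary segmentation of the intensity trace
with a BIC stopping rule (two parameters per changepoint) followed by
an amplitude-significance filter at 3 local noise standard deviations.
Photon noise is heteroscedastic, so each step is judged against the
noise of its own two plateaus (difference-based robust estimate), not a
global scale; plateaus shorter than 2 samples are not offered as
segments. On 5σ single steps the detector is ≥ 99% accurate to ±1
frame with ~0% false positives on flat traces.

The bleach filter accepts a trajectory iff f_AA shows exactly one
downward step and f_DD + f_DA shows no *partial* bleach — a mid-trace
downward step whose post-step level stays significantly above
background indicates multiple donors. A terminal drop of the total to
background is an ordinary donor bleach and defines the truncation
point; otherwise truncation is the acceptor-bleach frame. Records from
the bleach frame on are discarded. One caveat: for γ noticeably above
1 an acceptor bleach itself lowers the donor-excitation total, which
the rule would read as partial bleach; the chain is intended for γ ≲ 1
as in the calibration here.

The cell mask uses local-mean adaptive thresholding (block 51 px by
default — choose a block larger than the cell diameter, e.g. 101 px for
10 µm cells at 160 nm pixels; offset defaults to three robust noise
standard deviations so a featureless image yields an empty mask).

## Correction factors

α = median(f_DA/f_DD) over donor-only records, δ = median(f_DA/f_AA)
over acceptor-only records. γ comes from acceptor-bleach events of a
high-FRET control sensor: per event, the drop of the α/δ-corrected DA
signal divided by the rise of the DD signal across the step (plateaus
of ≥ 5 frames averaged, one guard frame around the step), aggregated by
the median. High-FRET controls are preferred because they maximize both
intensity contrasts — the estimator's spread on low-FRET controls is
measurably larger. β solves median S = 0.5 on a known 1:1 calibration
sample by monotone root finding. The median was chosen as the robust
location throughout: ratio estimators are outlier-prone.

## Population fits

The (E, S) cloud is fitted with a variational Bayesian Gaussian
mixture (scikit-learn), ≤ 2 components, weight-concentration prior
1/2, 10 restarts, tolerance 1e-4, ridge-regularized refit on degenerate
covariances. Fallback to a single Gaussian when the stretched (lower
E) component has weight < 0.1 or its mean exceeds E_max: a stretched
peak outside the sensor's dynamic range is not interpretable.
"Collapsed" is the component with the higher E mean. Standard errors
are nonparametric bootstrap (100 resamples of equal size), with
label switching resolved by matching components to the full-data fit
by proximity of the E means.

## Kinetics and mobility

*Ergodicity ratio*: over trajectories with ≥ 5 efficiency records
below 0.6 (unambiguously force-loaded sensors), the mean per-trajectory
force standard deviation divided by the standard deviation of all
pooled low-FRET force values. Frozen per-molecule force levels give a
ratio near 0; i.i.d. sampling of the full force distribution gives ≈ 1.

*Loading rate*: traces are aligned so their force peaks (argmax of a
3-point median-filtered trace) coincide; the rising phase — from the
last local minimum before the peak to the peak, where minima qualify
only within 25% of the pre-peak span above the baseline so ramp-noise
dips do not truncate the phase — is pooled across traces and fitted
with one straight line. Measured bias at the study conditions
(7 ramps, 1.5 pN/s, σ_E = 0.05 at 10 fps) is about +4%, within the 5%
design bound; the residual bias stems from noise-driven peak/minimum
selection. The visual ramp selection of a human analyst is replaced by
this documented automatic criterion.

*MSD*: squared displacements pooled per lag 1–10 (only between frames
exactly lag apart, so gaps never contaminate), fitted per bootstrap
round with MSD = 4·D·t_lag + 4ε². The bootstrap resamples whole
trajectories by default rather than individual displacements:
overlapping displacements of one molecule are strongly correlated, and
element-wise resampling understates the standard error about two-fold
on Brownian test data (replicate sd 0.043 vs element-wise bootstrap se
0.019 µm²/s at 300 tracks × 12 frames, D = 0.72 µm²/s); with
trajectory resampling the bootstrap se matches the replicate sd and
±2 se is an honest 95% interval. `resample="displacements"` restores
the element-wise variant. Negative fitted intercepts clamp ε to 0.

*Mobility*: the smallest enclosing circle of a trajectory is computed
exactly with Welzl's move-to-front algorithm (deterministically
shuffled; collinear triples fall back to the widest two-point circle),
verified against brute-force enumeration over point pairs and triples.
The statistic r_c/√t_d separates immobilized from mobile sensors at
0.35 µm s⁻⁰·⁵; t_d is the spanned observation time.

## DRAAP and statistics

E_bulk = (f_post − f_pre)/f_post from ROI-averaged donor images before
and after complete acceptor photobleaching, with a configurable
background subtracted from both averages (uncorrected background
biases E_bulk toward zero). Acceptor bleaching is modelled as
complete; incomplete bleaching can be emulated in the generator to
study the bias but is outside the correction model. ΔE_bulk differences
a cell ROI against the matched cell-free ROI. Group comparisons use the
two-sided, tie-corrected Mann–Whitney U test with significance at
p < 0.01.

## Dynamic range

E_min = force_to_fret(10 pN) ≈ 0.11: the spring is trusted to respond
linearly up to 10 pN. E_max is simulated: mixture samples
(collapsed peak 0.87 ± 0.12, stretched peak scanned, weight 0.15 or
0.25, n = 2300) are tested against pure collapsed samples with a
two-sample KS test; E_max is the largest stretched mean (at sd 0.12)
whose median p over 50 replicates stays below α = 0.05. The replicate
median (rather than a single draw per grid point) stabilizes the
threshold; α is config-exposed since the original analysis reports a
p-value map without naming a cut. The default conditions give
E_max = 0.80, i.e. F_min ≈ 0.9 pN.

## Problem sizes and determinism

The test suite runs everything on desk-scale problems chosen as the
package's own study conditions: movies of 40–50 molecules × 120–160
frame pairs on 112–128 px fields, 300 × 12-frame tracks for diffusion,
7 ramps for the loading rate, 500 simulations for the step detector,
n = 2300 for the KS scan. Every stochastic component takes an explicit
seed; fixed seeds reproduce movies bit-identically and analyses
byte-identically, which the tests assert.

## Known limitations

* Single-emitter photophysics only; no blinking kinetics model, no EM
  excess noise, no spectral crosstalk beyond the α/δ/γ/β model.
* The bleach-filter's partial-bleach rule assumes γ ≲ 1 (see above).
* Linking is nearest-neighbor with gap closing; it will split tracks
  when a diffusive step exceeds the 800 nm gate and is not designed
  for high-density fields.
* The loading-rate estimator retains a small positive selection bias
  (~4% at the study conditions).
* Adaptive-threshold cell masking needs a block size larger than the
  cell; the default (51 px) suits sub-8 µm objects at 160 nm pixels.
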