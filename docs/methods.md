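# Methods

This note documents the models, parameter choices and known limitations of
`fluomux`. It covers what the synthetic-data generator emulates, the numerical
choices inside each stage, and what the simulation benchmarks do and do not
demonstrate about real data.

## Measurement space

The spectral grid models a multiplexed confocal acquisition: six excitation
lasers (405, 488, 514, 561, 594, 639 nm) by 34 emission bins, i.e. 204
channels per fingerprint. Bin edges are one wide multialkali bin at
350–400 nm, 32 uniform interior bins partitioning 400–695 nm (width
(695−400)/32 ≈ 9.22 nm), and one wide bin at 695–750 nm. Real spectral
detectors use slightly wider bins at long wavelengths; the uniform interior is
an approximation that changes no algorithm, and empirical edges can be loaded
from a table instead (`SpectralGrid` accepts arbitrary strictly increasing
edges).

## Parametric fingerprints

Real reference fingerprints are measured from single-fluorophore-expressing
cells. As a stand-in, each fluorophore is modelled with unit-peak Gaussian
excitation and emission curves; channel (laser l, bin b) of a fingerprint is

    brightness · power_l · T(λ_l) · Ex(λ_l) · ∫_bin Em(λ) dλ

with the emission integral evaluated in closed form (erf). Bins overlapping
±10 nm of a laser line are zeroed, emulating beam-splitter rejection of
scattered excitation light. Default peaks (ex/em, nm): mTagBFP2 399/454,
mTurquoise2 434/474, T-Sapphire 399/511, GCaMP6s 497/515, mVenus 515/528,
mOrange2 549/565, mCyRFP1 528/594, mScarlet 569/594, FusionRed 580/608,
mNeptune2.5 599/643; default widths 18 nm (excitation SD) and 22 nm
(emission SD); relative brightness 1 (a per-fluorophore knob emulates dim
reporters). The resulting 204-channel library is full rank with condition
number ≈ 6.

**Limitation.** Gaussian curves preserve the *relative positions* of the real
spectra but are cleaner than empirical fingerprints (no vibronic shoulders,
no detector roll-off, no bleed measured through a GRIN lens). Conclusions
that depend on fine spectral overlap — notably how fast accuracy collapses
when a second fluorophore contaminates an ROI — are optimistic relative to
empirical libraries; see “Benchmark behaviour” below.

## Lens models

The axial chromatic focal shift versus wavelength is fit with a second-order
polynomial and reported with R² (computed as 1 − SS_res/SS_tot); it is
informational for acquisition planning — the computational correction for the
focal shift is the summed z-projection. Transmission versus wavelength is fit
with a sixth-order polynomial (degree configurable), clipped to (0, 1] on
evaluation, with an extrapolation warning outside the fitted wavelength
domain. The power plan scales each laser by T(reference)/T(laser), so the
plan is invariant to rescaling all transmissions; individual lasers can be
pinned to an absolute power fraction (the 639 nm line is conventionally fixed
at 40% because only the furthest-red fluorophore responds to it).

## Stack processing

Each laser's (z, bin, y, x) stack is background-subtracted per plane with a
rolling ball (radius 30 µm converted to pixels via the configured pixel size;
Sternberg's algorithm as implemented in scikit-image), clipped at zero, then
summed over a configurable z-crop. The summed projection flattens the
wavelength-dependent focal shift; the z-crop must be identical for every
laser of a subject. ROI fingerprints are the *mean* over mask pixels, so ROI
area does not scale fingerprints.

## Registration

Both modalities are reduced to vessel maps: Gaussian denoise (σ 1 px
miniscope / 2 px confocal), subtraction of a large-σ Gaussian background
(50 / 100 px), then a morphological black-hat with a square window
(11 / 21 px) that turns dark vessels into bright ridges. The similarity
transform (tx, ty, rotation, scale) is applied as scale → rotate → translate
about the image centre, mapping miniscope into confocal coordinates; the
convention is serialized with every result. The score is Pearson correlation
over the valid overlap (≥ 25% of the fixed frame, else the candidate is
rejected), which makes it invariant to affine intensity rescaling.

The coarse search is exhaustive over a grid (defaults: translations ±60 px
step 5, rotation ±15° step 5, scale 1.8–2.0 step 0.05 — 21,875 nodes; the
scale interval encodes a specific miniscope/confocal pixel-size ratio and
must be widened for other optics), with a deterministic first-best
tie-break. Refinement is gradient ascent with central finite differences
(probe steps 0.5 px, 0.25°, 0.005; learning rate 0.5; backtracking on failed
steps), followed by a coordinate-wise polish at shrinking steps, because the
correlation surface couples rotation and scale to the translations and can
stall a joint gradient step. The returned score never falls below the
starting score; a NaN objective returns the starting transform with a
warning.

Two practical points surfaced by the synthetic pipeline and worth knowing on
real data: (1) rolling-ball subtraction is an opening and therefore erases
dark-vessel contrast, so the registration reference is taken from the
*unsubtracted* z-sum; (2) a single ~9 nm emission bin can be noise-limited —
the pipeline can average an emission band (`reference.band_nm`) instead.

## Unmixing and identity assignment

Betas are nonnegative least squares (active-set NNLS; an unconstrained mode
exists behind a flag for comparison). `beta_norm` refits the max-one-
normalized spectrum against max-one-normalized references. No intercept is
fit: constant background is absorbed by the per-subject baseline, which is
the point of the baseline design. Baselines use the population SD
(deterministic at any ROI count; negligible difference from the sample SD at
realistic ROI counts). A hit requires beta_raw OR beta_norm above
mean + k·SD (k = 1.5); the primary is the hit with the largest z-score,
using max(z_raw, z_norm) since neither channel is privileged. The indicator
(GCaMP6s) is always fit, but whether it is an *assignable* identity is a
classifier option: in vivo it is expressed in every neuron and is excluded
from assignment; in cell-culture-style validation datasets where it is a
class, it is assignable.

The dual pass re-evaluates only pass-1 no-hits. For each fluorophore the
over-representation ratio r is its experimental beta share (over all ROIs,
as a percent of total) divided by its theoretical equal share; when r > 1
the cutoff becomes mean + k·SD/r, otherwise it is unchanged. The exact
proportionality of "lowered thresholds" is an open design choice; this
realization is isolated in `adjusted_cutoffs` for substitution. The
theoretical equal-share profile is exact (an ideal equal-count dataset of
pure fingerprints yields identical per-fluorophore totals under NNLS), so no
reference simulation is needed.

## The synthetic-data generator

`simulate_roi_dataset` draws, per ROI: a class from the configured
distribution; an amplitude from a log-normal with unit median and log-SD 0.5
(standing in for the brightness spread of sampled cells); then builds

    spectrum = A·ref_class [+ A₂·ref_class2 if dual-label]
             + g·Ā·ref_GCaMP
             + b·Ā·mixture  (uniform mean of the nine non-GCaMP references)
             + N(0, (Ā/snr)²)  clipped at 0

where Ā is the realized mean amplitude. SNR is defined as mean peak signal
over noise SD (references are unit-peak, so amplitudes are peak signal);
`snr=inf` disables noise, and the low-noise default for conditions that do
not sweep noise is SNR = 20. Zero-clipping is a mild departure from unbounded
Gaussian noise, required by fingerprint nonnegativity. In the
spatial-overlap variant (`second_fluor_background`) the mixture is replaced
by one randomly chosen different fluorophore scaled to b × the ROI's own
amplitude. GCaMP is excluded from the uniform mixture (it is modelled
separately by g). Dual-label rosters contain every unordered pair plus
single-label controls in equal numbers.

Presets encode the study conditions: `realistic_config` uses an
empirical-like distribution over the nine injected fluorophores (T-Sapphire
and mVenus most frequent, FusionRed and mCyRFP1 least; exact values in
`EMPIRICAL_DISTRIBUTION`), g = 0.30, b = 0.30, SNR = 6; the four-fluorophore
preset restricts the library to mTagBFP2/mVenus/mOrange2/mNeptune2.5 plus
GCaMP with the analogous distribution.

`simulate_image_pair` renders an end-to-end fixture: dark random-walk vessel
trees on a bright field, disk somata carrying per-class fingerprints plus
30% GCaMP, a broad violet-excited autofluorescence term modulated by the
vessel map (so vessels appear as shadows in the confocal reference channel),
per-channel white noise, and a miniscope view produced by inverse-warping a
padded world (both views are centred crops of the same canvas, so the
similarity transform about the crop centre is exact and no empty border ring
leaks into registration). Somata are placed with a minimum separation; if the
density cap prevents placement a warning is issued.

**What passing tests show.** The generator reproduces the *mechanisms* the
classifier must survive — class imbalance, indicator background, spectral
background, noise, dual labels — under a separable reference library. It
does not reproduce empirical fingerprint overlap, neuropil structure,
segmentation errors, motion, or photobleaching, so passing benchmarks bound
ideal-case behaviour, not in vivo performance.

## Benchmark behaviour

At the study scale (460 ROIs × 100 replicates) the suite reproduces: beta
shares ≈ 10% per fluorophore under equal classes; dual-pass recovery > 90%
of an 80%-prevalent fluorophore (single-pass recovery collapses to < 20%,
matching the intended failure mode); accuracy ≈ 89% with errors exclusively
false negatives at GCaMP background equal to signal; ≈ 98–99% at-least-one
detection on clean dual labels; and false-positive rates ≪ 5% under the
realistic presets. One benchmark does not transfer to the parametric
library: a second fluorophore at 50% of the ROI amplitude leaves accuracy
near 99% here, because the Gaussian references are separable enough that
NNLS attributes the two components correctly; the sharp accuracy loss seen
with empirical libraries arises from baseline-SD inflation under strong
spectral overlap. The generator's conditions were not tuned to force that
collapse.

## Behavioral selectivity

For each cell × behavior, each onset contributes a (pre, post) pair of mean
ΔF/F over 2.5 s windows (50 samples per side at 20 Hz); a two-sided paired
t-test across epochs is compared against α/m with m the number of behaviors
tested for that cell (Bonferroni). Pairing is the natural reading of
before-versus-after comparisons; an unpaired Welch alternative is available
behind a flag. Onsets without full windows inside the trace are dropped and
counted; overlapping epochs are retained but reported so users can filter.
Fewer than two usable epochs yields an "untestable" result rather than an
exception. Under an i.i.d. null the fraction of selective calls stays at or
below the Bonferroni-corrected α (verified by simulation in the test suite).

## Reproducibility and problem sizes

All randomness flows through explicit seeds; replicate streams are spawned
from a `SeedSequence` so adding conditions never perturbs other conditions'
draws. The benchmark script runs every condition at 460 ROIs × 100
replicates (~1 minute on one CPU); the registration property suite uses 100
seeded 64×64 vessel pairs (~1 minute); the end-to-end image fixture uses a
96×96 field with 24 somata at SNR 10 (~5 s). These sizes were chosen to make
Monte-Carlo error small relative to every decision band while keeping the
full suite inside a few minutes.
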