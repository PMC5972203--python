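# Methods

This note documents the models, estimators and numerical conventions behind
`chemotrack`, the assumptions they rest on, and the design choices made where
more than one convention was defensible.

## The measurement problem

Chemokine-scale proteins (~10 kDa) diffuse at tens to hundreds of µm²/s in
aqueous media. Tracking single fluorophore-labelled molecules at these speeds
requires sub-millisecond frame intervals, which leaves so few photons per
frame that localization error is no longer negligible against the distance a
molecule moves between frames, and tracks survive only a handful of frames
before photobleaching. The package implements an analysis stack built for
exactly this regime — short, noisy tracks of a mixed mobile/immobile
population — together with a simulator that generates the same kind of data
with known ground truth, so every stage can be validated end to end.

## Image simulation

Emitters are rendered as pixel-integrated symmetric 2D Gaussians (erf form,
exact photon conservation; support truncated at 5σ, discarding < 6e-7 of the
flux) at continuous positions on a 128×128 px frame, 120 nm/px. Positions
evolve by Brownian steps of per-axis variance 2·D·Δt. Each focus is
destroyed with per-frame probability 0.1 (default) and re-created at a
uniform random position as a *new* ground-truth track, emulating
photobleaching and other truncation effects; intensity and width are
resampled on re-creation and held constant within a track segment. Motion
blur within a frame is deliberately not rendered; each focus appears at one
instantaneous position per frame.

Default samplers reflect the target regime: summed spot intensities
~N(2500, 250) counts (clipped to 1,200–4,500; the observed initial
intensities fall in the 2,000–3,000 count range), PSF σ ~N(1.95, 0.08) px
(HWHM 250–300 nm at 120 nm/px), frame interval 0.65 ms (camera cycle time,
not exposure).

Readout noise is zero-mean Gaussian with per-pixel SD

    sd(x, y) = base_sd + intensity_coefficient · I_noise_free(x, y)

an affine stand-in for the (unspecified) intensity dependence of a real
EMCCD; pixel values are clipped at zero afterwards because a detector cannot
report negative counts. No gain-register stochastics, no camera calibration
files, no axial PSF. The default "noisy" condition is
`NoiseModel(base_sd=16, intensity_coefficient=0.08)` over a 100-count
background offset, chosen once so that the immobilized-calibration
localization precision lands near 30 nm at 2,500-count spots — inside the
25–60 nm band that brackets the ~40 nm precision quoted for this kind of
instrument, and consistent with the effective per-localization error implied
by reference simulation results at 0.65 ms. Tissue-like runs use
`NoiseModel(25, 0.1)` over a 60-count offset with bright static
matrix-shaped regions (+140 counts), which puts the calibration precision
near 40 nm at 2 ms frames.

What the simulator does *not* emulate: photophysical blinking and intensity
decay within a track, spatially varying illumination, aberrated or
anisotropic PSFs, axial defocus, sample drift, and Poisson photon statistics
(noise is additive-Gaussian). Tests passing on simulated data therefore
validate the estimator chain under idealized imaging physics, not the full
complexity of tissue acquisitions.

## Detection and linking

Candidate peaks are found on a Gaussian-smoothed copy of each frame (kernel
σ = half the PSF σ — a matched filter, so pixel noise does not flood the
detector at a 3.5 σ threshold), against robust background statistics
(median, and 84th-percentile-minus-median for the SD, which survives
zero-clipped noise where a MAD estimate collapses). Candidates closer than
2 σ_PSF merge to the brighter one. Each candidate is refined by iterative
Gaussian-masked centroiding on the raw image; groups of spots whose windows
overlap (separation < 6 σ_PSF) are re-fitted jointly as a sum of Gaussians
with a shared width and background, because a neighbour inside the centroid
window otherwise drags the centroid's fixed point by several tenths of a
pixel. Accepted foci must pass an integrated-signal test (aperture intensity
above 3.5× the aperture-pooled noise) and lie ≥ 2 σ_PSF from the frame edge.
Isolated noise-free spots localize to < 0.01 px; at the default noisy
condition the per-track error is ~25–30 nm.

Linking is greedy mutual-nearest-neighbour between consecutive frames within
5 px (≈3 SD of a 10 µm²/s step at 0.65 ms plus precision), ties broken by
distance then candidate index; no gap closing (a missed frame ends the
track, appropriate when only the first four steps are analysed anyway).

Localization precision is calibrated from immobilized (D = 0) emitters. Two
statistics are reported from one calibration run: the **pooled** per-axis SD
about each track's mean (after rejecting tracks whose scatter exceeds 3× the
median track scatter — such spots are unresolved overlaps of two emitters,
not single-emitter data), which sets the diffusion-histogram bin width; and
the **median per-track RMS**, the typical single-emitter error, which is
what the MSD plateau correction (below) needs, since pooling is still
inflated by rare multi-emitter residue.

## Microscopic diffusion coefficients

For each track with ≥ 5 localizations, the MSD is computed at lags Δt..4Δt
from the first four steps, averaging all overlapping windows at each lag
(the 4Δt point is the single end-to-end displacement). The per-track
coefficient is the weighted least-squares gradient of MSD against lag
through the origin with weights ∝ 1/lag² — equivalently, the mean of the
per-lag apparent coefficients MSD(kΔt)/(4kΔt) — divided by 4 for 2D motion.

Two properties drove this choice. First, variance: the SD of an MSD value
grows linearly with its lag, so 1/lag² is the inverse-variance weighting;
the resulting estimator has an effective shape (mean²/variance) of ≈ 2.1,
matching the expectation that only two of the four overlapping steps are
statistically independent. An ordinary least-squares slope with a free
intercept has effective shape ≈ 0.6 — the extra parameter more than triples
the variance and produces frequent negative estimates — and no
free-intercept variant can produce the shape-2 population distributions this
analysis is built on. Plain OLS remains available as `method="ols"`.
Second, the localization plateau: position noise of SD σ adds 4σ² to every
MSD value, which a through-origin fit converts into a positive bias of
0.52·σ²/Δt on D (0.52 = mean of 1/k over the four lags). Instead of a free
intercept, the plateau is subtracted explicitly using the
immobilized-calibration σ (`precision_um`); this keeps the estimator's shape
while restoring offset immunity. Negative corrected estimates are retained
and pooled into the first histogram bin — discarding them would bias the
immobile fraction.

Histograms use bin width σ_pooled²/Δt (in µm²/s): the apparent-diffusion
scale of the localization precision, the only dimensionally consistent
reading of "bin width given by the localization precision", and the one that
places a truly immobile population inside the first bin. The first bin is
anchored at zero.

## Gamma-mixture model

The sampling distribution of an MSD-based estimate from N independent steps
is gamma with mean D and shape N:

    F(x; D, N) = (N/D)^N x^(N-1) exp(-N x / D) / Γ(N)

with (N−1)! generalized to Γ(N) because fitted shapes are non-integer.
Populations are modelled as mixtures of such components with weights on the
unit simplex (unit total area).

**Single-component fits** (used for the simulation studies) work on the raw
per-track estimates: the fitted mean D is anchored at the sample mean — the
maximum-likelihood estimate of a gamma's mean, unbiased whatever the true
shape — and the shape N is found by weighted least squares against a
boundary-corrected kernel density estimate of the data (Gaussian kernel,
robust Silverman bandwidth 0.9·min(SD, IQR/1.349)·n^(-1/5), reflected at
x = 0). Two subtleties matter here. The candidate gamma is convolved with
the KDE's own kernel (and reflected identically) before comparison, so the
data-side smoothing cancels and does not bias the shape — fitting a sharp
density to a smoothed one otherwise misreads both parameters. And the
bandwidth uses the robust spread because the estimate distribution is
heavy-tailed (rare tracking artifacts), which would inflate an SD-based
bandwidth and over-smooth the peak. Weights follow the KDE's sampling error
(∝ √density). The fit grid runs to the 99.5th percentile.

**Mixture fits** (immobile + mobile decomposition) are weighted least
squares on the histogram densities, with Poisson counting errors and
empty bins given one-count weight — the histogram's first-bin structure is
precisely what identifies the immobile component. The refined constraint
scheme, arrived at by simulating immobile data and refitting: the immobile
component's D is confined to the first bin with a free shape below 1
(immobile steps share localization error, hence strongly dependent), and
the mobile shape is fixed at 2 (two non-overlapping steps among the first
four). The unconstrained scheme (all D, N free, N ≤ 4) is available for the
1/2/3-component model comparison; model order is chosen by reduced
χ² = χ²/(occupied bins − free parameters), computed in count space on the
histogram.

`iterative_refine` closes the loop the method prescribes: fit the data,
simulate at the fitted parameters through the full image pipeline, refit the
simulation under the same constraints, and accept once each simulated-fit D
matches its input within 5% relative (components whose D lies below one bin
width are only resolvable to the bin, and are accepted when the refit stays
below it). Non-convergence is flagged, never raised.

Parameter errors come from fitting ten random 80% subsamples (without
replacement) and taking the SD of each parameter across repeats.

## Stoichiometry

A track's initial intensity is the straight line through its first three
intensity values extrapolated to the frame before the first observation; the
characteristic single-dye intensity is the mode of the kernel density
(Silverman) of initial intensities; their ratio is the apparent
stoichiometry. Photobleaching steps are counted by an edge-preserving
Chung–Kennedy filter (forward/backward running means, lower-variance side)
followed by recursive change-point search: candidate split positions come
from the filtered trace, but significance is judged by a two-sample t test
on the *raw* trace (the filter's correlated noise would wildly inflate a t
statistic computed on its output), Bonferroni-corrected within segments at
α = 1e-4; adjacent plateaus whose means do not differ at p < 0.01 are
merged, and downward transitions are counted. On three-step staircases with
noise at 10% of the step size the detector finds exactly three steps in at
least nine of ten seeded runs, with a < 5% false-positive rate on flat
traces.

The random-overlap null assumes spatially Poisson emitters at density
ρ = (max foci per frame)/(frame area): a focus is a chance coincidence with
probability 1 − exp(−ρπr²) for coincidence radius r (default 300 nm, the
upper PSF HWHM; configurable — the printed 18% overlap figure for this
geometry depends on a radius convention that is not fully specified, so it
is documented rather than asserted). Apparent stoichiometry under the null
is 1 + Poisson(ρπr²), truncated and renormalized; the predicted intensity
density shifts the single-dye density to mean s·µ and widens it by √s per
stoichiometry s. Observed-vs-predicted comparisons use Pearson's χ² with
dof = bins − 1.

## Segmentation

Tissue stacks are segmented on their temporal mean: white top-hat with a
radius-4 px disk, Otsu threshold, then small-hole filling with a radius-2
disk. The hole filling applies erosion-then-dilation on the inverted (hole)
topology, which on the foreground is a binary closing; a `closing` switch
applies the foreground closing directly (the two coincide here — the switch
exists because erosion-first on the foreground itself is an opening and
cannot fill holes). A constant image has no Otsu threshold and returns an
empty mask with a warning. Note the top-hat passes only structures narrower
than about twice its radius: broad bright plateaus are treated as
background, so validation fixtures use structures inside the passband
(fibre-like strands a few px wide). Tracks are classified matrix-bound vs
interstitial by majority vote of their localizations against the mask, ties
conservatively to the matrix; a one-sided rank-sum test compares
matrix-track mobility between conditions.

## FCS and FRAP

The autocorrelation model is the standard triplet × 3D-translational form

    G(τ) = 1 + [1 + T/(1−T)·e^(−τ/τ_T)] · A · (1 + τ/τ_D)^(−1) · (1 + τ/(s²τ_D))^(−1/2)

with the effective confocal volume and mean concentration folded into one
amplitude A (not separately identifiable from a single trace), the
structural parameter s fixed at 6.6 from calibration against a reference
diffusion coefficient of 59 µm²/s, and D = r0²/(4τ_D) with r0 = 0.322 µm.
Fitting is unweighted least squares; non-decaying traces are rejected.
Traces contaminated by multimeric clumps are a manual exclusion in the
input, not an automatic filter. FRAP recovery is the single exponential
I(t) = I0 − I1·e^(−t/τ1) with D = ω²/(8τ1); the bleach-spot half-width ω is
fitted as a Gaussian intensity deficit (1/e radius convention), invariant to
constant offsets. Neither model accounts for axially thin samples or 2D/3D
reaction–diffusion corrections.

## Hydrodynamic theory

Stokes–Einstein D = k_B·T/(6πηr) at T = 293 K (room temperature; this value
reproduces the 12.3 µm²/s reference for a 3.48 nm sphere in 0.005 Pa·s to
three figures). Globular radii from mass at 1.35 g/cm³. Faxén's near-wall
correction η(h) = η(∞)(1 + P(r/h))^(−1) is provided in two fifth-order
forms behind a mode switch: the published polynomial with exponents on whole
bracketed factors, and the conventional wall-drag series
−(9/16)γ + (1/8)γ³ − (45/256)γ⁴ − (1/16)γ⁵; they differ in the γ⁴/γ⁵ terms,
and the ambiguity is why combined near-wall predictions are documentation
examples rather than asserted values. Mixture averages weight component D
by particle number (e.g. a 15:2 monomer:dimer blend), with the dimer radius
taken as exactly twice the monomer's.

## Validation studies and problem sizes

The package's quantitative self-checks re-run four simulation studies
end-to-end (simulate → detect → link → estimate → fit):

- noise-free D = 1.6 µm²/s, ≥ 1,500 tracks (≥ 2,500 in the acceptance
  script), free-shape single-gamma fit;
- noisy D = 10 µm²/s, ≥ 450 tracks, same fit;
- a 50:50 immobile + 9 µm²/s noisy mixture, ≥ 900 tracks, constrained
  two-component fit reporting the mobile D;
- a 1,000-frame tissue-like acquisition at D = 6.6 µm²/s and 2 ms frames
  with segmentation-gated mobile-population fit.

Problem sizes (frames per batch, foci per frame: 5–6 in vitro, 12 in
tissue-like fields) were chosen so each study completes in one to a few
minutes on one CPU while keeping parameter uncertainties a few percent.
Free-shape fits across these conditions return N ≈ 2–2.6, the
overlapping-window signature; the known residual biases are percent-level
(tracking artifacts from close encounters inflate the raw mean slightly;
the least-squares shape fit is exact only if the estimator distribution
were exactly gamma, which it is not).

## Known limitations

- The estimator chain is tuned for short tracks; no long-lag MSD analysis,
  anomalous-diffusion exponents, or confinement models.
- The gamma-shape interpretation (N as effective independent steps) is an
  approximation for overlapping windows; the shape is fitted, not derived.
- Segmentation assumes static bright structures within the top-hat passband.
- Additive Gaussian noise underestimates the excess noise of EM-gain
  cameras; absolute localization precisions on real data will be somewhat
  worse at equal counts.
- Greedy nearest-neighbour linking can swap identities when two emitters
  pass within the search radius; rare bridged death/birth events produce
  outlier coefficients, which the robust fitting conventions are designed to
  tolerate rather than remove.
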