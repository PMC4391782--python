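# Methods

This note documents the models implemented in `mineralmap`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## Hounsfield scaling and calibration

Raw detector intensities are mapped to Hounsfield units by the affine map
anchored at the air and water reference intensities, with **air = 0 HU and
water = 1000 HU** (the standard clinical convention shifted by +1000). This
convention is recorded in every file sidecar; standard-HU data can be
imported by supplying references that realize `HU_std = HU − 1000`. Values
outside the reference bracket extrapolate linearly, so mineralized voxels
land in the 10⁴ HU range.

The calibration line is fitted by unweighted ordinary least squares of
nominal phantom density on mean phantom HU — MD-on-HU, the direction in
which the line is applied. An inverse-variance weighting option
(`sd_hu²/n`) exists but is off by default since phantom ROIs are large and
homogeneous. Negative densities produced below the intercept (air, soft
tissue) are preserved and counted in `meta['negative_md_voxels']`, never
clamped: clamping would bias segment means near interfaces.

The gravimetric comparison fits an ash-density line over the same phantom
HU values and evaluates both lines on a common HU grid. The "correlation"
between the curves is reported as the Pearson r of the two lines'
predictions over that grid (for two straight lines this is ±1 by affine
invariance; the residual curve carries the substantive information, and the
implementation keeps working if either curve becomes non-linear). The
alternative reading — correlating residuals — was not adopted because the
residual of two fitted lines is itself a line and carries no extra
information; both the residual curve and the prediction correlation are
returned.

## Gradient, histogram and seed loci

The gradient magnitude is the Euclidean norm of per-axis central
differences with edge replication (exact on linear ramps, which keeps the
operator testable against closed forms); a normalized Sobel operator is
available as an option. Neither choice changes watershed boundaries on
blurred interfaces in practice.

Seed selection works on the joint (intensity, gradient) histogram. The
low-gradient band is taken as the smallest gradient-bin prefix holding a
configurable fraction (default 0.5) of the histogram mass. Intensity peaks
are detected on the **log-scaled**, 3-bin-smoothed low-gradient profile:
material modes can differ by orders of magnitude in height, because a
homogeneous tissue concentrates its voxels into a few bins while a
heterogeneous one (e.g. a carious lesion) spreads the same mass over
hundreds of HU — linear prominence would silently drop the heterogeneous
mode. Two guards reject spurious peaks: a minimum separation (8 bins) and a
minimum mass per peak bin (3·10⁻⁴ of the masked voxels), the latter
filtering log-scale wiggles in sparse tails. Each peak is widened to where
its profile falls below 20% of the peak height, clipped at midpoints
between neighboring peaks so loci stay disjoint.

## Watershed

The watershed is a marker-based priority flood of the gradient-magnitude
landscape with face (6-neighbor) connectivity. Determinism contract: the
queue pops by `(landscape value, insertion index)`; marker voxels are
scanned in raster order at initialization; neighbors are visited in fixed
axis order (−z, +z, −y, +y, −x, +x). Any re-implementation of this contract
(the test suite carries a heap-free linear-scan flood) reproduces the
labels bit-for-bit; on tie-free (continuous-valued) landscapes the result
is determined by values alone. Markers are all voxels whose (intensity,
gradient) pair falls inside a locus box; with a single locus the flood is
skipped and every masked voxel receives its label. Masked voxels
unreachable from any marker (disconnected under the mask) retain label 0.

The manual refine-and-rerun workflow is exposed as `iterate_segmentation`:
after each pass, Welch t-tests compare all segment pairs (subsampled to
20 000 voxels) and any pair not significant after Bonferroni correction has
its loci merged before re-flooding — the automatic counterpart of accepting
a segmentation only when its mineral zones are statistically distinct.

## Segment statistics

Per-segment statistics are computed in HU and converted through the affine
calibration: the mean converts exactly; the standard deviation converts as
`|slope|·sd_HU` (identical to converting per-voxel first, since the map is
affine); the MD range is the converted HU extrema. Segment volume is
`n_voxels · voxel_size³` with the default 3.84 µm voxel. Dentin zone
classes use HU cutoffs 3 545–13 475 (hypomineralized), 13 755–14 740
(near-normal), >15 000 (hypermineralized); segment means falling in the
gaps between intervals are flagged `unclassified` rather than forced into a
class.

## XRF quantification

Counts divide by the thin-film-standard gain (counts per mmol/cm²) to give
area concentration. The self-absorption model is a single-layer uniform
matrix under Beer–Lambert attenuation of both the incident beam and the
outgoing fluorescence, integrated over depth:

    A = C · t_eff,  t_eff = (1 − e^{−µt})/µ,
    µ = (1/L_in)/sin θ_in + (1/L_f)/sin θ_out.

`t_eff` is monotone in t, bounded by min(t, 1/µ), and equals t within 1%
when µt < 0.02 (the thin-sample limit). Geometry defaults to 45°/45°
incidence/takeoff, a common microprobe arrangement, and is configurable.
Absorption lengths are **inputs** (defaults: 110 µm at the 10 keV incident
energy; 9, 4 and 75 µm at the Ca, P and Zn Kα lines — representative 1/e
depths for a hydroxyapatite-dominated matrix); computing them from matrix
stoichiometry is out of scope. Pixels with non-positive thickness are
flagged invalid (NaN) and excluded from all downstream statistics, and a
per-element detection floor (config) marks below-detection pixels — P sits
closest to its floor because of its soft fluorescence line.

## Ratios and masked statistics

Ratio maps are per-pixel molar ratios of same-unit maps; pixels whose
denominator is at or below the floor are invalid and excluded from every
statistic. The default masked statistic is the **mean of per-pixel ratios**
(the map-math-then-average reading); the ratio-of-means is always available
and co-reported where relevant, because the two differ on heterogeneous
regions and the convention behind printed ratio means is not always stated.
Both agree exactly on constant-ratio fields.

Joint-density plots detect concentration peaks as strict local maxima
(8-neighborhood) holding ≥5% of the masked counts, with peaks closer than
3 bins merged; two or more surviving peaks classify the distribution as
"localized" (distinct zones), otherwise "spread". These thresholds are
configurable; the 5%-of-mass criterion makes the classification scale with
ROI size but also makes it sensitive to the bin count — coarse binning
(≈8–12 bins per axis) is appropriate when zones are broad. Overlays,
density plots and line profiles are pure views: they never modify stored
data, and statistics are invariant to color normalization.

## Statistics

Unpaired comparisons default to the Welch unequal-variance t-test (a
pooled-variance option exists for strict replication); paired comparisons
require equal n. Bonferroni adjustment is `min(1, m·p)` with m computed
from the number of comparisons actually run, never hard-coded. The
median-based ANOVA is implemented as Mood's median test — counts above/
below the grand median (ties counted "below" by default) — which is the
closest standard test to a "median-based ANOVA" over masked pixel
populations; with exactly two groups the p-value is the two-sided Fisher
exact probability of the 2×2 table (exact at small n), with more groups the
chi-square form. Kruskal–Wallis is available behind a switch as a
rank-based alternative.

## The synthetic generator

The generator emulates the acquisition chain, not the physics of
reconstruction: volumes are synthesized post-reconstruction (no projection
or beam-hardening model), and geometry is limited to axis-aligned boxes and
z-cylinders since specimen shape enters no recovered quantity.

Micro-CT forward model: per-region voxel MD ~ Normal(md_mean, md_sd),
optionally modulated by a linear ramp or step; MD → HU through the
instrument line (slope 0.11 mg/cc per HU, intercept −48.6 mg/cc); Gaussian
PSF blur (σ = 1 voxel default); additive Gaussian HU noise (sd = 50 HU
default); HU → raw intensities under the (air, water) affine convention.
Blur precedes noise — the PSF acts on the physical signal, counting noise
on the recorded one; the order is an assumption recorded here and in the
config, as is the Gaussian noise character. All stochastic operations
require an explicit integer seed (numpy PCG64) and are bit-reproducible.

Tissue parameter rows (packaged in `data/tissues.json`): the mean is the
study mean where one is printed (cementum 1290, diseased cementum 1150,
alveolar bone 1115, calculus 1525 mg/cc), otherwise the midrange of the
printed range; the voxel-level sd is (range width)/4 so that ±2 sd spans
the printed range; the sd of the tissue mean (`sem`) is kept where printed
(15, 50, 30, 40 mg/cc respectively). XRF ratio rows
(`data/xrf.json`) carry the printed mean ± sd for Ca/P (dentin 1.49 ± 0.21,
bone 1.68 ± 0.20, cementum 1.51 ± 0.22, lesion zones 0.32 ± 0.05 and
0.46 ± 0.04) and Ca/Zn (acellular cementum 595 ± 50, cellular 1155 ± 165,
bone 2765 ± 905, bone interface 855 ± 125, cementum overall 990 ± 430).

XRF forward model: per-pixel ratio fields ~ Normal(mean, sd) floored at a
small positive value; Ca from a base volume concentration (default
10 mmol/cm³, the order of magnitude of Ca in mineralized dentin) scaled by
lesion depletion factors; P = Ca/ratio and Zn = Ca/ratio; volume → area
concentration through the same t_eff the quantifier inverts (a thin-limit
flag bypasses self-absorption for tests); area → counts through per-element
gains; multiplicative log-normal measurement noise with mean 1 and cv 10%
by default, plus optional Poisson counting noise. The mean-1 log-normal
noise on the denominator gives the mean-of-ratios a known upward bias of
about (1 + cv²) ≈ 1% at cv = 10%; recovery checks use tolerance bands (2×
the configured sd) far wider than this bias.

What the generator does **not** emulate: irregular specimen geometry,
partial-volume composition mixing, beam hardening and scatter, spatially
correlated detector noise, secondary fluorescence, and the anatomical
micro-structure (tubules, lacunae, incremental line curvature). Passing
recovery tests therefore demonstrates that the pipeline's inference chain
is self-consistent and unbiased under the stated noise models — not that
it is robust to every artifact of real tomograms.

## Fixture and problem sizes

Validation fixtures use 128³ voxels for volumes (the scale at which the
blurred-interface band is a negligible fraction of a region) and 256² for
XRF maps; the tissue-mean fixtures fill the whole volume with one tissue,
emulating an analysis ROI interior to a tissue, so segment means carry no
partial-volume bias, while the two-region lesion fixture exercises the
watershed on a genuine noisy interface (Dice ≥ 0.95 required). The
brute-force watershed oracle runs on volumes up to 10³ voxels, where
exhaustive linear-scan flooding is tractable.

## Known limitations

* The watershed flood is single-threaded Python (heap-based); 128³ volumes
  with two or more loci take tens of seconds. Single-locus volumes bypass
  the flood.
* Absorption lengths are user inputs; no fundamental-parameters XRF physics,
  no spectral fitting of raw detector spectra.
* `ratio-of-means` without stashed denominator values falls back to the
  harmonic mean of per-pixel ratios, which is exact only for a spatially
  constant numerator; use `ratio_with_denominator` when exactness matters.
* Trabecular morphometrics, XANES speciation, crystallography and texture
  analysis are out of scope.
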