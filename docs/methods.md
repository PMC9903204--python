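# Methods

This note documents the models, numerical choices and defaults behind
each analysis, what the synthetic-data generators do and do not emulate,
and the known limitations.

## Gel densitometry and median-Rf kinetics

A lane is reduced to intensity vs relative migration Rf (0 at the well,
1 at the bottom of the crop) by summing pixel rows across the lane's
columns. Background is the mean intensity over Rf ≥ 0.97 — the deep-gel
region below the smallest fragments — subtracted pointwise with
negatives clipped to zero; the 0.97 bound is configurable.

The lane summary is the **Rf of median band intensity**: the cumulative
signal is accumulated from the gel bottom, normalised to the lane total
(so lanes with different DNA loadings are directly comparable), and the
smallest Rf at which it falls to 0.5 is taken, linearly interpolating
between the bracketing samples. On a plateau exactly at 0.5 the smallest
Rf is used, a deterministic tie-break.

Digestion time courses of median Rf are fitted by least squares to a
log-normal-in-time curve. Because the median migration of a digested
array can only move toward smaller fragments, the default shape is the
saturating CDF form

    rf(t) = baseline + amplitude · Φ((ln t − μ)/σ),    rf(0) = baseline,

with amplitude constrained non-negative so the fitted curve is monotone
by construction; a peak-normalised density shape is selectable for
non-monotone series. The fit uses bounded Levenberg–Marquardt
(`scipy.optimize.curve_fit`) with up to 8 perturbed restarts from a
data-driven initial guess; non-convergence is reported as an absent fit,
never an exception. Zero-noise series are recovered to ≤ 1e-6 relative
error (tested), which is the practical identifiability check for the
4-parameter model on ≥ 4 time points.

## Ladder calibration and repeat-length estimation

Fragment sizing uses the standard semi-log electrophoresis
approximation: migration is linear in log₁₀(size). The standard curve
interpolates (Rf, log₁₀ size) **piecewise-linearly** through the ladder
bands rather than fitting a single global line — this matches how gels
are actually read, is exact at every ladder band, and makes a query
midway (in Rf) between two bands return the geometric mean of their
sizes. Each band's Rf is the mean of the two flanking ladder lanes, so a
symmetric tilt of the gel cancels. Queries outside the ladder range are
linearly extrapolated from the end segments and flagged.

MNase digestion peaks are local maxima of the moving-average-smoothed
lane profile (window 5 samples, prominence ≥ 5% of the profile range by
default). Orders are assigned 1..k from the largest Rf (the
mononucleosome) upward; non-monotone interpolated sizes raise an error
rather than silently mis-assigning orders.

The nucleosomal repeat length is reported as **mean ± sample s.d. of
sizeₙ/n over fragments n = 2…7**. The mononucleosome is excluded because
exonucleolytic trimming biases its size low relative to the arithmetic
ladder. Two alternative estimators are available behind a flag: a
through-origin regression of sizeₙ on n, and the mean of successive band
differences; all three agree exactly on noise-free arithmetic ladders
(tested).

## Melt-curve transition detection

Thermal-stability curves (environment-sensitive dye fluorescence vs
temperature) rise in sigmoidal steps as nucleosomes fall apart.
Transitions are maxima of dF/dT: the fluorescence is moving-average
smoothed (default window 1.5 °C), differentiated by centred differences,
and the derivative smoothed with the same window. Peaks are kept if
their prominence exceeds an adaptive floor — the larger of 5% of the
derivative range and 8 robust (MAD-based) standard deviations of the
derivative's residual noise. The noise term is what makes detection
stable on realistic curves: with a fixed small percentage alone,
measurement noise at a few percent of the step amplitude sprouts dozens
of spurious "transitions".

The reported Tm is not the raw argmax sample but the intensity-weighted
centroid of the derivative peak's above-half-prominence region. For a
symmetric peak this equals the centre exactly — including on a constant
or linear fluorescence baseline, whose derivative contribution is
constant — and it cuts the noise-limited Tm scatter about five-fold
relative to the argmax (0.13 °C vs 0.66 °C s.d. at 2% noise, 0.3 °C
sampling, width-2 °C transition; measured over 200 seeds in the test
suite's Monte-Carlo check).

Classification follows the biology of mononucleosome disassembly: the
highest-Tm transition is DNA release (the terminal event); the most
prominent remaining transition is H2A-H2B dimer dissociation; any others
are reported unlabelled. A curve with a single transition yields DNA
release only. A transition-width output (°C between 25% and 75% of the
step) is provided as a quantitative handle on "more progressive"
dissociation, though no reference value is asserted for it.

## Nuclei image quantification

The thresholding recipes are implemented from the 256-bin histogram up,
because they — not a library call — are the measurement:

- **Kapur maximum entropy**: the threshold maximises the sum of Shannon
  entropies of the background (bins ≤ t) and foreground (bins > t)
  classes of the normalised histogram; ties go to the lower threshold.
  The vectorised implementation is tested for exact equality against a
  naive exhaustive search over all 256 bins.
- **Isodata (iterative intermeans)**, the ImageJ default: iterate
  t ← round((mean_below + mean_above)/2) to its fixed point. Tested
  against the fixed-point property directly and cross-checked against
  scikit-image's reference implementation.

Touching nuclei are separated by a distance-transform watershed: seeds
are the regional maxima of the Euclidean distance transform (lightly
Gaussian-smoothed, σ = 1 px, to merge the near-equal ridge maxima a
digitised ellipse produces, which would otherwise over-split single
convex objects) after 3×3 maximum suppression, with connected plateau
maxima fused into one marker; flooding the inverted distance map with
watershed lines leaves a one-pixel background cut between catchments.
Objects are the relabelled catchment basins — re-running 8-connected
component labelling after the cut would re-merge diagonal neighbours
across a one-pixel line, so it is deliberately avoided. Particle
counting drops objects below a caller-supplied minimum area
(noise-derived specks); the count is monotone non-increasing in that
threshold (tested).

Manually outlined nuclear areas are **pixel counts**: the number of
integer pixel centres inside or on the polygon (boundary counts as
inside — a deterministic rule), converted to µm² by pixel_size².
Self-intersecting polygons are rejected. Agreement with the shoelace
area is within half the perimeter, the expected rasterisation
discrepancy.

ATAC-see quantitation thresholds both channels (DNA stain and
transposase signal) by maximum entropy and reports
|DNA ∧ ATAC| / |DNA| for the whole field plus per-nucleus fractions over
the watershed-split DNA objects, excluding sub-`min_size` (default
50 px²) specks. A perfectly flat ATAC channel is treated as an empty
mask (fraction 0) rather than an error, since "no accessible signal
anywhere" is a meaningful biological outcome for sperm chromatin.

## Motif scanning

The core SPKK family is S-P-[KR]-[KR]; SPAKK is counted as a separate
family. Matching is left-to-right greedy and non-overlapping within each
family (families independent), case-insensitive. SPRR is accepted by the
SP(K/R)(K/R) definition by default, with a flag restricting to the
commonly named SPKK/SPKR/SPRK. Long ACGTU-only inputs trigger a warning
that a nucleotide sequence was probably passed.

## Statistics

The unpaired t-test defaults to the pooled-variance (Student) form with
a Welch flag; one-way ANOVA is the classical between/within
mean-squares F. Degenerate inputs are handled deterministically: two
zero-variance groups with equal means give t = 0, p = 1 (unequal means
raise, as the statistic is undefined), and an all-identical dataset
gives F = 0, p = 1. Quartiles use the linear-interpolation convention
(numpy's default), whiskers are the extreme data points within 1.5×IQR
of the quartiles, and points beyond the fences are listed as outliers.
Mean ± spread summaries use the n−1 sample s.d. and s.e.m. = s.d./√n.
p-values map to stars through a configurable legend defaulting to
0.1 / 0.01 / 0.001 / 0.0001.

## Synthetic data: what it emulates, and what it does not

Every generator is deterministic given a seed and produces ground truth
alongside its output.

- **Gels**: bands are Gaussian ridges in Rf centred at a − b·log₁₀(size)
  with integrated intensity proportional to mass × size (mass-weighted
  intercalating-dye staining); a and b default to spanning the ladder
  across Rf 0.05–0.95. Flanking lanes carry the ladder with band masses
  ∝ 1/size, i.e. equal band brightness, as commercial ladders are
  balanced. Noise is additive Gaussian clipped at zero — Poisson
  statistics are unnecessary at gel-scanner intensities. MNase lanes
  place bands at n·NRL with masses ∝ decayⁿ (default 0.7, a mild
  digestion). Default lane sampling is 1200 rows for sizing work.
- **Time courses** invert the fitted kinetic model exactly, with t = 0
  mapped to the undigested baseline.
- **Melt curves** are sums of logistic steps plus a constant baseline.
  The reference conditions used in validation — width 2 °C, noise 2% of
  step amplitude, 0.3 °C sampling — represent a plate-reader melt at
  typical dye signal-to-noise.
- **Nuclei fields** are filled rotated ellipses (aspect 0.7–1.0) on a
  dark background (foreground 180, background 20, default noise s.d. 8 —
  about 5% of the dynamic range), placed disjointly except for a
  requested number of overlapping pairs at 0.6–0.9 of the sum of radii.
  Default mean area 600 px² on a 512×512 field.
- **Sequences** plant non-overlapping SPKK-family motifs into a random
  peptide background whose alphabet omits proline, which guarantees —
  not merely makes unlikely — that neither the background nor any
  motif/background junction contains an accidental match.

Not emulated: gel smiling and lane distortion, optical point-spread and
z-structure in micrographs, FISH chemistry, intensity vignetting, and
the mitochondrial ATAC-see foci seen in real sperm images. Passing the
recovery tests therefore demonstrates correctness of the measurement
chain under the stated statistical structure, not robustness to every
artefact of real acquisitions; the thresholds and watershed are the
standard remedies but their failure modes on heavily distorted real
images are outside what the synthetic suite can certify.

## Validation operating points

The end-to-end recovery checks run at the biologically meaningful
values: repeat lengths of 207 bp (somatic-like) and 225 bp (sperm-like);
dimer-dissociation temperatures of 70 °C (canonical H2B) and 78 °C
(spH2B) with DNA release 19 °C higher; and nucleus populations of 20
whose median areas differ by the 1.5× diploid:haploid ratio (area s.d.
5% of the mean). `scripts/acceptance.py` recomputes these from scratch;
problem sizes (1200-row gel lanes, ~200-sample melt curves, 512×512
fields) are chosen so the whole validation runs in seconds on one core.
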