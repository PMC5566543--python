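# Methods

## The counting model

`objcoloc` treats colocalisation as a property of segmented objects, not
of pixel intensities. An image contributes, per nucleus: the number of
red objects, green objects, and (red, green) object pairs whose pixel
sets overlap by at least a criterion minimum. Pairs are counted, not
object unions: a green object overlapped by two red objects yields two
colocalisations. For users who want Manders-style per-channel object
counts instead, the report also exposes the number of *distinct* red and
green objects involved in at least one pair (`n_red_colocalised`,
`n_green_colocalised`); this is an extension, and the pair count is the
primary statistic.

## ROI-local thresholding

The background threshold inside each ROI is T = ⌈μ⌉ + M·⌈σ⌉, with μ and σ
the mean and standard deviation of the ROI's (filtered) intensities and M
a user multiplier. Numerical choices:

- **σ is the population standard deviation** (1/n). ROIs contain
  thousands of pixels, so the 1/(n−1) alternative differs negligibly; the
  population form is also what array-oriented environments compute by
  default. The unit test pins this with a 4-pixel hand computation where
  the two differ visibly.
- **Ceiling is applied to μ and σ separately**, then M multiplies the
  ceiled σ: a region with mean 25 and σ 3 at M = 2 thresholds at
  25 + 2·3 = 31, not ⌈25 + 6⌉ computed jointly. With fractional M the
  threshold may be non-integral; the background rule is always
  "intensity < T", so equality with T is foreground.
- **Degenerate ROI (σ = 0):** T = ⌈μ⌉, so the whole ROI is candidate
  foreground. This is the faithful limit of the rule; realistic images
  never hit it because signal pixels contribute variance.
- Thresholds are computed on **filtered** intensities when denoising is
  enabled (denoising exists to stabilise exactly this statistic), while
  object intensity sums always use raw values.

Monotonicity in M (larger M ⇒ never more foreground) holds by
construction and is asserted over random scenes.

## Denoising filters

Two optional filters run before thresholding, median first (impulse
removal should precede variance estimation), both with zero padding at
the borders and odd window sizes (defaults 3×3 median, 5×5 Wiener):

- **Median**: window middle value; removes salt-and-pepper outliers.
- **Adaptive Wiener**: with local window mean μ and population variance
  σ², and noise variance v² estimated as the mean of all local variances
  over the whole channel (not per ROI — the estimate is a property of the
  detector, not of a nucleus), the output is
  b = μ + ((σ² − v²)/σ²)(a − μ). Where σ² < v² the gain is clamped to
  zero so b = μ (the formula's behaviour there is otherwise undefined;
  clamping matches the classical wiener2 construction and scipy's
  implementation, which the tests use as an independent cross-check).
  σ² = 0 likewise yields b = μ. Output is real-valued for thresholding,
  clipped to the input dtype's range, and rounded half-up only on export.

Zero padding makes border pixels systematically darker (their windows
include synthetic zeros); this is documented rather than corrected, so
results are interpretable and reproducible across reimplementations.

## ROI detection

Nuclei come from the blue channel via Otsu's threshold computed on the
exact integer histogram (one bin per intensity level, for 8- and 16-bit
data alike), which makes the detected mask invariant to a constant
intensity shift. Components are 8-connected; labels are assigned in
raster-scan order of first encounter. Defaults chosen here (both
configurable): `min_roi_area_px = 500`, far below any nucleus at typical
pixel sizes (a 10 µm nucleus at 0.14 µm/pixel covers ~4000 px) but enough
to drop debris; `fill_holes = True`, since nuclei are solid and chromatin
texture can punch spurious holes through the threshold. A constant blue
channel raises an error ("no ROI separable") rather than guessing.
External label masks are accepted in place of auto-detection; labels are
compacted to 1..n and non-connected labels are split with a warning.

## Monte Carlo significance

Each iteration translates every detected object to a uniformly random
position fully inside its *originating* ROI (preserving per-nucleus
object density, which the per-ROI counting semantics require), with no
rotation or reflection. Same-channel objects may land on each other; the
union is left merged and re-segmented, so a merged pair becomes one
larger object — the null mimics what the detector would actually see.
Uniformity is achieved by rejection sampling over the ROI bounding box
(capped at `max_placement_attempts`, default 1000) with an exhaustive
enumeration of valid anchors as fallback, so even an object with a single
legal position terminates correctly.

The test is a one-sample Student's t-test of the randomised counts
against the observed count as hypothesised mean:
t = (mean_random − observed)/(sd/√n), p from the t distribution with
n − 1 degrees of freedom, two-sided by default (a one-sided "observed
greater" option exists for enrichment questions). If the null counts
have zero variance the test is degenerate: p = 1 when their mean equals
the observed count, else p = 0, with a warning. Reproducibility: one
master seed spawns independent per-iteration child generators
(`numpy.random.SeedSequence`), so iterations are order-independent and
the whole result is bit-stable for a fixed seed.

This randomisation null is only calibrated when objects are small
relative to their ROI; the library warns whenever an object exceeds
1/600 of its ROI's area. In that sparse regime the suite verifies
calibration empirically: over 200 scenes drawn from the null itself, the
two-sided test rejects at the 5% level in roughly 1–12% of scenes.

## Synthetic scenes

The generator emulates the target imaging situation: elliptical nuclei
(semi-axes 18–26 px) at high blue intensity on a dark background; 2–4
compact objects of 10–15 px per channel per nucleus; per-nucleus,
per-channel background offsets drawn from 10–40 intensity levels
(background genuinely varies between cells and channels); objects at a
fixed offset (default 160) above their nucleus' background; optional
additive truncated-Gaussian noise and salt-and-pepper impulse noise.
Gaussian rather than Poisson noise is the default because the threshold
model is mean/σ-based, not photon-statistical; the noise level is a free
parameter.

A configurable fraction of green objects (default 0.5) is planted to
overlap a red object by an **exact** pixel count (default 4): the overlap
region is carved from the red object's pixels near a random boundary
extreme and the green object is grown outward from it, never entering
any other red object. All other object placements keep ≥2 px Chebyshev
separation from every other object. Consequences used by the tests:
non-planted pairs overlap by exactly 0 pixels, planted pairs by exactly
the requested count (so the 2-vs-3-pixel criterion boundary is directly
testable), and same-channel objects never merge.

What the generator does **not** emulate: PSF blur (object edges are
hard), photon statistics, chromatic shift, uneven illumination within a
nucleus, and touching nuclei. Passing the recovery tests therefore shows
the pipeline is exact on well-separated, well-resolved objects; it does
not certify performance on images where signal and background tails
genuinely mix, which is precisely where the multiplier M and the filters
need tuning by the user.

Recovery conditions used by the test suite: 10 scenes of 5 nuclei at
noise_sd = 0 must reproduce per-nucleus (n_red, n_green, n_coloc)
exactly; at noise_sd = 8 (object contrast 160 ≈ 5× the 2σ background
tail plus threshold margin) the total colocalisation count must stay
within ±5% of planted. Both run with denoising disabled: the filters are
edge-eroding by design (a 3×3 median shaves convex corners off 10–15 px
objects), which is desirable on noisy real data but would deliberately
perturb exact planted overlaps; on noise-free synthetic data there is
nothing to denoise.

## Batch interface

The CLI processes a glob of images with one configuration and writes a
tab-delimited file: one row per ROI (image, roi_id, roi_area_px, n_red,
n_green, n_coloc, per-channel pixel and raw-intensity sums), one summary
row per image (`roi_id = ALL`), and — when the significance stage is on —
observed/mean_random/t/p/n_iterations/seed columns on the summary row.
The effective configuration is echoed as `#` comment lines so any output
file doubles as a reproducibility record. Per-image failures are logged,
the batch continues, and the exit status is non-zero iff any image
failed. Configuration files are flat `key=value` text; command-line
flags override file values.

Problem sizes throughout the suite (256² images, ≤5 nuclei, ≤10⁴ Monte
Carlo iterations on ≤100-px ROIs) were chosen as the smallest scales at
which every contract — exactness, calibration, determinism — is
meaningfully exercised.

## Known limitations

- Touching nuclei are not split (no watershed); they count as one ROI.
- Objects clipped by the ROI boundary lose their outside pixels by
  construction; counting is strictly per-nucleus.
- The t-test compares the null's mean against a single observed draw; for
  dense scenes (large objects, many per ROI) it is anti-conservative,
  hence the 1/600 spatial-ratio warning.
- Channel order R,G,B is taken on faith from the file; no colour-space
  inference.
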