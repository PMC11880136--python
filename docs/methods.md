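# Methods

This note documents the statistical procedures, their assumptions, the
default parameters and why they were chosen, what the synthetic generators
do and do not emulate, and the numerical edge cases.

## 1. ISH area quantification

Pipeline (all steps on a single-channel image with known pixel size):

1. min–max rescale to the 8-bit range [0, 255] — this makes the whole
   measurement invariant under affine intensity rescaling of the input;
2. invert, so chromogenic stain (dark) becomes bright;
3. Gaussian blur with σ = `blur_radius` / pixel size (default 4 µm, valid
   range ~3–5 µm — large enough that stain-sized particles vanish into the
   blurred background estimate);
4. subtract the blurred image from the inverted one and clip at zero — a
   high-pass step that removes smooth illumination and tissue-level
   intensity trends;
5. binarise (Otsu by default; a fixed value can be supplied per probe);
6. 8-connected particle labelling, discarding particles below
   `min_particle_area` (default: area of a 1-µm-radius circle — specks of a
   pixel or two are noise, and no biologically meaningful stain particle is
   smaller than a fraction of a nucleus);
7. report the particle area inside the ROI divided by the ROI area.

Numerical details that matter: the blur uses odd-reflection border padding,
which continues a linear ramp exactly across the border, so a pure intensity
gradient produces a strictly zero difference image rather than spurious edge
bands; and the difference image is quantised to the 8-bit integer grid (the
behaviour of an integer image calculator), so sub-unit float residue can
never be picked up by the automatic threshold. A fully zero difference image
yields ratio 0 with a warning, not an error.

## 2. Cell detection and positive calling

Nuclei are localised with a difference-of-Gaussians band-pass, σ₁ =
radius/√2 and σ₂ = √2·σ₁ (the standard blob-detector scale pairing), local
maxima above an intensity threshold, and non-maximum suppression within one
cell radius — two responses closer than a cell radius merge into the
stronger one. Detection count is monotone non-increasing in the threshold.

Per-cell intensities are disk means (the disk is the detection radius).
Whether the original measurement used mean, sum, or max over the cell is not
determinable; the mean is used because it is insensitive to the disk area
and robust to partial clipping. Delta intensity is divided by DAPI intensity
("rectification"): staining efficiency and section thickness vary across a
slide but affect both channels, so their ratio is comparable across cells.
Positives are called on the ratio histogram — Otsu by default, which
separates a bimodal histogram without a hand-picked cutoff; a degenerate
(single-valued) histogram yields zero positives with a warning. Cells with
non-positive DAPI are excluded and logged.

## 3. Spatial statistics

**Relative nearest-neighbour distance.** For each positive cell i,
ratio_i = (distance to the nearest other positive cell) / (distance from
cell i to its nearest neighbour of any label). The per-cell denominator
makes the statistic scale-free (invariant under translation, rotation, and
uniform scaling). The summary is the CV (sample sd / mean) of the ratios.
Interpretation caveat: on an idealised CSR substrate the denominator can be
arbitrarily small, giving the ratio a heavy right tail and inflating the
sample CV well above the Rayleigh nearest-neighbour CV √(4/π − 1) ≈ 0.523.
Real epithelium has an exclusion radius (cells cannot overlap), which keeps
the denominator near the typical cell spacing; on the jittered-grid
substrate the CV of randomly labelled positives is ≈ 0.49, the regime the
statistic was designed for.

**Ripley K / L.** K̂(r) = A/(n(n−1)) · Σ_{i≠j} e_ij · 1(d_ij ≤ r). The
default edge correction is the translation correction, e_ij =
A/((Lx−|dx|)(Ly−|dy|)), which makes K̂ unbiased for CSR on a rectangle
(without it, K̂ at r = 10 in a 100×100 µm window is ~8% low, because circles
near the boundary are clipped); `edge_correction="none"` gives the plain
count estimator. L(r) = √(K(r)/π) — the "linear solution" convention whose
CSR reference is the line L = r; classification against an envelope is
identical under the L − r convention. K̂ is asserted non-decreasing on
every call.

**Radius grid.** 100 radii, equally spaced from span/100 to span/2, where
span is the smaller side of the window (by default the bounding box of the
cell coordinates). The upper limit span/2 keeps the translation weights
finite and the estimator meaningful.

**Envelopes.** The null model is random *relabelling*: the positive label is
redrawn uniformly without replacement over the observed cell positions
(default 80 simulations). This conditions on the tissue's own cell
arrangement — the right null when positives inherit the substrate's spatial
structure — rather than resampling positions in continuous space. Pointwise
bounds are the (1−level)/2 and 1−(1−level)/2 empirical quantiles (linear
interpolation between order statistics; at the default 99% level with 80
simulations this sits just inside the min/max). Each radius is classified
clustered (observed L above the upper bound), regular (below the lower
bound), or random. With interpolated quantiles of 80 simulations the
per-radius two-sided exceedance under the null is ≈ 2.5%, so a null pattern
is typically called random at ≥ 95–97% of radii. If every cell is positive
the simulations equal the observation; the result is all-random with a
warning.

## 4. Trace correction and features

Traces are two channels on a uniform grid, default dt = 5 min over 5 h (60
frames). Steps:

* **Normalize**: mCherry/GFP pointwise. Cancels multiplicative bias common
  to both channels (laser exposure, focus drift). GFP must be positive; the
  synthetic generator floors GFP at 1% of its mean for the same reason.
* **Detrend**: subtract a centred moving mean with a 100-min window (21
  samples at dt = 5), shrinking symmetrically at the boundaries. The
  shrinking centred filter reproduces a line exactly, so linear
  photobleaching is removed completely; a 60-min oscillation loses only
  ~13% amplitude.
* **Smooth**: centred moving mean, 20-min window (5 samples); white noise
  sd shrinks by √5.
* **Peak calling**: local maxima of the smoothed signal with topographic
  prominence ≥ 0.1 × dynamic range; endpoints are never peaks; plateaus
  report their leftmost sample. *Dynamic range* is the max − min of the
  normalized signal — the full excursion of the recording including its
  slow trend. This choice is deliberate: a threshold relative to the
  band-passed signal's own range is scale-free with respect to noise, so it
  fires on any non-oscillatory trace (~9 spurious "peaks" per flat cell in
  simulation, independent of the noise level); anchoring the threshold to
  the recording's full dynamic range suppresses noise peaks on
  non-oscillatory cells while leaving genuine oscillation peaks (which are
  large on that scale) untouched. The prominence reading of "threshold" is
  used because a neighbour-difference threshold would reject almost all
  smooth peaks.
* **Autocorrelation**: r(k) = Σ(x_t−x̄)(x_{t+k}−x̄)/Σ(x_t−x̄)², k = 1..n−1
  (biased normalisation; 59 lags from 60 points), computed on the smoothed
  signal. A constant series raises a degenerate-input error.
* **Features** (larger = more robust oscillator): completed cycles
  (peaks − 1, floored at 0), mean squared ACF over all lags, ACF range
  (max − min), mean peak-to-peak interval (0 with < 2 peaks), mean peak
  prominence (0 with no peaks). ACF coefficients with |r| < 0.3 are zeroed
  before the two ACF features are formed — below that magnitude the
  coefficient is indistinguishable from no correlation at these series
  lengths, and squaring would otherwise accumulate it. The cutoff is not
  applied to peak calling, which operates in the time domain.
* **Alignment**: traces are shifted so the first peak sits at pseudo-time 0;
  peakless traces cannot be aligned and are reported separately.

"Number of completed cycles" and "amplitude" have no unique operational
definition; peaks − 1 and mean prominence are used and exposed as such.

## 5. Clustering

Features are z-scored per column (sample sd; constant columns are dropped
with a warning) because they mix counts, minutes, and dimensionless
quantities spanning orders of magnitude. k-means is Lloyd's algorithm with
the iteration cap ("epochs", default 50) and early stop on unchanged
assignments; 10 random restarts, best inertia kept; empty clusters re-seed
at the worst-fit point; inertia is asserted non-increasing across
iterations. The group count is selected by the elbow rule: fit k = 1..6 and
take the k in 2..5 maximising the second difference of the inertia curve
(ties to the smallest k). The curve and the second differences are attached
to the result so the automatic choice can be audited or overridden — on
data without planted structure the rule still returns *some* k, and the
flat second-difference profile is the evidence that no sharp elbow exists.

Group summaries report per-group feature means ± sd, counts and fractions,
mean aligned waveforms on the common pseudo-time grid, and Student
two-sample t-tests of each feature between group pairs.

## 6. Synthetic data: what it emulates, what it does not

**Cell fields**: binomial (CSR) or jittered-grid (epithelium-like) point
patterns; positive labels planted at random (null), as a focal cell plus its
nearest neighbours (maximal clustering), or by greedy farthest-point
sampling seeded with the most distant pair (maximal regularity — on a
square grid with 4 positives it selects the corners).

**ISH images**: bright background, linear gradient, non-overlapping dark
disks, optional Gaussian noise, with the ground-truth disk mask returned.

**Traces**: mCherry(t) = baseline + drift·t + A·sin(2πt/T + φ) + ε,
GFP(t) = mean + ε′ (floored positive). Defaults: baseline 100 a.u., drift
−0.15 a.u./min (≈ 45% photobleaching over the 5-h recording — strong but
realistic confocal bleaching), GFP 100 ± 2 a.u., uniform random phase.

The `mixed_default` population mixes three classes:

| class  | fraction | amplitude | noise sd | period |
|--------|----------|-----------|----------|--------|
| robust | 1/3      | 25        | 2        | 60 min |
| noisy  | 1/2      | 15        | 8        | 40 min |
| flat   | 1/6      | 0         | 2        | —      |

The mixture is designed so the three classes are genuinely distinguishable
as three clusters in standardized feature space: robust cells lead on ACF
power and amplitude; noisy cells oscillate faster, so they lead on cycle
count with shorter intervals but weak ACF; flat cells sit at the origin of
every feature. Intermediate oscillators form the largest class and
non-oscillatory cells the smallest. Two structural facts are worth knowing:
with z-scored features the total between-class variance is fixed, so
three-group recoverability by the second-difference elbow requires the
class centroids to be near-equidistant — an equal-thirds mixture with a
purely "intermediate" noisy class is provably always split into two groups,
whichever parameters are chosen.

What the generator does **not** emulate: cell movement and tracking errors,
photobleaching beyond a linear trend, correlated (non-white) measurement
noise, spatial correlation between neighbouring cells' phases
(synchronisation), 3D tissue structure, and ISH stain texture within
particles. Tests passing on this synthetic data therefore certify the
*estimators and the pipeline plumbing* — closed-form CSR behaviour, oracle
equivalence, planted-structure recovery — not robustness to every artefact
of real microscopy.

## 7. Problem sizes and determinism

Defaults used by the test-suite and the acceptance script: spatial checks
use 200-cell fields (2 000 and 10 000 points for the CSR closed forms),
80-simulation envelopes at 100 radii; trace checks use 60-cell populations
of 60-frame traces, 20 populations for the cluster-count study. All
generators and every stochastic algorithm take explicit integer seeds;
identical seeds give bitwise-identical outputs.

## 8. Known limitations

* The translation edge correction assumes a rectangular window; irregular
  ROIs are approximated by their bounding box.
* The envelope classification is pointwise, not a global test: with 100
  radii, a few flagged radii are expected under the null (≈ 2–3), so
  single-radius excursions should not be over-read. The extreme-control
  plantings are the calibration for what real clustering/regularity looks
  like.
* The per-cell relative-distance CV is only comparable across slices with
  similar substrate regularity (see §3).
* k-means with z-scoring weights every feature equally; a different
  feature weighting (or a model-based clusterer) could merge or split the
  groups differently. The inertia curve is exported precisely so that the
  automatic k is never a black box.
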