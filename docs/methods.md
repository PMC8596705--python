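# Methods note

This note records the data model, the measurement chain, the parameter
defaults and why they were chosen, and the known limits of the approach.
All quantitative statements here are recomputed by the test suite or by
`scripts/acceptance.py`; none are asserted from memory.

## 1. Field geometry

A slab is a 10° × 5° en-face extraction at 288 µm per degree
(`FieldGeometry`, defaults: `um_per_deg = 288`, `um_per_px = 3`), i.e.
2880 × 1440 µm sampled on a 960 × 480 pixel grid. Pixel (i, j) has its
centre at ((j + 0.5)·p, (i + 0.5)·p) µm; all centroids and distances use
this pixel-centre convention. The nominal slab depth (14 µm below the
ellipsoid zone) is metadata only — the model is purely 2-D.

## 2. Synthetic data model

**Dot placement** (`plant_dots`) is a hard-core rejection process: centres
uniform over the field, a dot fully inside the field (centre at least d/2
from every edge), and every pair of centres at least `min_separation` apart.
Diameters are uniform on [`d_min`, `d_max`] = [10, 20] µm. A per-dot attempt
budget turns an overcrowded request into an explicit `PlacementError` rather
than a hang.

**Rendering** (`render_slab`) adds one isotropic Gaussian per dot on a
uniform background, with FWHM equal to the dot diameter
(σ = FWHM / 2.355) and peak `amplitude` above background. Speckle is
multiplicative unit-mean gamma noise, `pixel ∗ Gamma(k, 1/k)`; with the
default shape k = 30 the per-pixel contrast is 1/√30 ≈ 18%, a plausible
magnitude for averaged OCT frames. Dots whose FWHM falls below ~2 pixels
are flagged in the image metadata (`undersampled_dots`), not rejected.

**Cohort model** (`simulate_cohort`). Per subject i of group g a positive
baseline `B_i ~ Normal(μ_g, σ_g)` truncated at zero; the recorded baseline is
`round(B_i)`. At each post-baseline timepoint t the count is
`round(B_i · (1 + δ_gt + e_it))`, `e_it ~ Normal(0, σ_gt)`, clamped at zero
(numpy round, half to even). By construction δ and σ are zero at baseline,
so the per-subject percent change at baseline is exactly 0. Default
parameters (`hrdquant.study`) are the published group summary statistics of
a 2 × 10-subject experiment: group-1 mean fractional changes
(−0.133, −0.251, −0.085, −0.001) and group-2 changes near zero, plus the
per-group baseline means/SDs (898.2 ± 162.9 and 909.0 ± 203.2 dots).

**Imaging cohorts** (`simulate_imaging_cohort`) render one slab per subject
× timepoint whose planted dot count equals the cohort count exactly; image
substreams are spawned from the cohort seed via `SeedSequence`, so the whole
bundle is reproducible from one integer.

## 3. Detection chain

`detect_hrds` = white top-hat → fixed threshold → small-object removal →
8-connected labelling.

* **White top-hat**: image minus its grey-scale opening by a disc of radius
  `tophat_radius_um`, clipped at zero. Removes background and any structure
  larger than the disc while passing dots intact.
* **Threshold**: strict `> threshold` on the residue (absolute units; the
  generator's background is already removed by the top-hat).
* **Small-object removal**: binary erosion by a disc of radius
  `min_size_radius_um` followed by morphological reconstruction by dilation;
  a component survives, with its exact pixel set, iff its erosion is
  non-empty (verified against a brute-force per-component oracle).
* **Measurement**: 8-connected labelling; centroid, area, and equivalent
  diameter per dot.

### Calibrated defaults

The detection defaults are pinned by calibration tests against the
generator (noise-free exactness plus ≤2% count error under default speckle):

| parameter | default | rationale |
| --- | --- | --- |
| `tophat_radius_um` | 18 | must exceed the largest dot radius by a margin: a Gaussian of FWHM 20 µm still has visible tails at r = 10 µm, and a 12 µm disc clips its peak to ~0.63 of the amplitude, pushing large dots under threshold. 18 µm passes all dot sizes at full amplitude while still flattening ramps. |
| `threshold` | 100 | half the default dot amplitude (200): equidistant from the zero background residue and the dot peaks, so it tolerates speckle fluctuations in both directions. |
| `min_size_radius_um` | 3 | one pixel of erosion at the default pitch; kills isolated speckle pixels, keeps every ≥10 µm dot. |
| generator `min_separation` | 28 µm | two 20 µm dots merge at the half-max threshold when their centres are closer than ~24 µm; 28 µm keeps all planted dots resolvable, which is what makes "detected = planted" a meaningful calibration target. |

With these defaults: noise-free detection is exact on 100/100 random
fields, and under default speckle the count error stays within 2%
(`tests/test_detection.py`, `tests/test_acceptance.py`).

## 4. Spatial statistics

**Influence zones.** The skeleton-by-influence-zones (SKIZ) of the dot mask
— the watershed of the Euclidean distance function seeded by the labelled
objects — is computed exactly via the Euclidean feature transform
(`scipy.ndimage.distance_transform_edt(..., return_indices=True)`): each
pixel takes the label of its nearest object pixel. This is the discrete
Voronoi tessellation of extended objects; a flooding watershed on the
quantised distance image was found to disagree with the exact partition on
~3% of pixels and was therefore not used.

**Nearest-neighbour distances** are edge-to-edge in the pixel-centre
metric. On the grid, the ridge minimum is read as `dt(p) + dt(q) + 1`
pixels over 4-adjacent pixel pairs (p, q) straddling a cell boundary; the
+1 compensates the half-pixel offset on either side of the ridge and makes
the estimator exact for single-pixel objects. Against an O(n²) pairwise
oracle the estimator agrees within 1.5 px on 100-dot fields. Cells touching
the field border are flagged and excluded from the per-image mean/SD (their
true nearest neighbour may lie outside the field).

**Poisson sanity check.** For a binomial (no hard core) process the mean
nearest-centre distance of interior dots — 40 µm guard zone for edge
correction — matches the Poisson closed form 0.5/√λ within 3 standard
errors over 200 replicate fields. The guard zone matters: the raw estimator
is biased upward by edge effects, and minus-sampling that conditions on the
measured NN distance is biased downward by selection.

**Column profile.** Dot counts in half-open 0.5° bins along x; bins tile
the field exactly, so counts sum to the total.

## 5. Cohort statistics

**Percent change** is per subject relative to the first timepoint; a zero
baseline yields a missing value, never a division error.

**Split-plot ANOVA** (`rm_anova`) uses the classical balanced-design sum of
squares decomposition: group is tested against subject-within-group; time
and group × time against the subject × time residual. The decomposition is
exact (SS identity to 1e-8 relative, tested) and F/p values agree with an
independent mixed-ANOVA implementation. Sphericity is handled by reporting
both uncorrected and Greenhouse–Geisser-corrected p values; ε is computed
from the double-centred covariance of the within-group residuals (the
split-plot-appropriate residual covariance) and clamped to
[1/(k−1), 1]. Degenerate inputs (zero residual or zero subject variance)
raise instead of returning misleading F values. On the null generator
(δ = 0, homoscedastic σ = 0.10) the uncorrected interaction test's type-I
error is 0.05 ± 0.02 over 1000 simulated cohorts.

**Wilcoxon signed-rank** (`paired_wilcoxon`) uses Pratt handling of zero
differences and average ranks for ties; for n ≤ 25 the null distribution is
built exactly by dynamic-programming convolution over doubled ranks
(verified against full 2ⁿ enumeration and against scipy's exact method on
tie-free data), with the normal approximation above.

**Normality** is Shapiro–Wilk with its valid range 3 ≤ n ≤ 5000 enforced;
constant input returns an undefined (NaN) statistic rather than a spurious
rejection.

## 6. Numerical and reproducibility choices

* All randomness flows from integer seeds through `numpy.random.Generator`;
  nested streams are spawned with `SeedSequence`, so cohorts, images and the
  acceptance targets are bit-reproducible. Derived integer seeds are kept
  below 2³¹.
* Counts are rounded half-to-even (numpy default), which avoids a +0.5 bias
  in the cohort means.
* Images are stored as 16-bit TIFF with a JSON sidecar carrying geometry
  and metadata; pixel values are rounded, not rescaled, on write.
* The acceptance targets are Monte-Carlo estimates with fixed problem
  sizes: 50 imaging cohorts × 10 subjects for the baseline-count target and
  200 count-level cohorts for the percent-change targets, chosen so that
  the Monte-Carlo standard error is well inside the stated tolerances
  (±15 dots, ±1.0 percentage point).

## 7. Limitations

* The generator is a stylised model: uniform background, isotropic Gaussian
  dots, pixel-wise gamma speckle. Real en-face slabs have vessel shadows,
  segmentation-induced banding, spatially correlated speckle and motion
  artefacts; detection performance here is an upper bound.
* The hard-core placement (28 µm) means truly overlapping or abutting dots
  are never generated, so the detector's merging behaviour at small
  separations is untested territory by design.
* The cohort model treats per-subject change as a single multiplicative
  factor per timepoint; it does not model spatially heterogeneous loss
  within a slab, repeat-scan measurement error at fixed state, or any
  axial (depth) dependence.
* The 2-D model ignores the axial extent of dots and the choice of slab
  depth; both strongly affect absolute counts in real data.
* NN distances are reported in the pixel-centre metric on a 3 µm grid;
  sub-pixel dot boundaries are not modelled, so distances carry an
  irreducible quantisation error of order one pixel.
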