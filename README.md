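# hrdquant

Quantification of hyperreflective dots (HRDs) on en-face OCT slabs, with a
fully synthetic data model of a two-group light-stimulation experiment.

## Scientific problem

Small (~10–20 µm) hyperreflective dots populate the hyporeflective band
between the ellipsoid and interdigitation zones of the outer retina. On an
en-face ("C-scan") slab extracted ~14 µm below the ellipsoid zone, a healthy
eye shows on the order of 900 such dots over a 10° × 5° field. Their count
drops transiently after dark adaptation and even more after an intense
photobleach, recovering within ~30 minutes — a light-dependent signal thought
to reflect the RPE apical processes / photoreceptor outer-segment interface.

Raw scans for such experiments are typically not deposited, so this package
pairs the measurement chain with a calibrated synthetic generator:

* **Generator** (`hrdquant.synthetic`) — hard-core random dot placement,
  Gaussian-profile dot rendering on a uniform background, multiplicative
  gamma speckle, and a longitudinal two-group cohort model: per subject a
  positive baseline count `B_i ~ N(μ_g, σ_g)` truncated at zero, and at each
  post-baseline timepoint `count = round(B_i · (1 + δ_gt + e_it))` with
  `e_it ~ N(0, σ_gt)`.
* **Detection** (`hrdquant.detection`) — white top-hat (image minus opening
  by a disc), fixed absolute threshold, small-object removal by erosion plus
  morphological reconstruction, 8-connected labelling with centroid and size
  measurements.
* **Spatial statistics** (`hrdquant.spatial`) — watershed influence zones
  (SKIZ / discrete Voronoi tessellation of extended objects) via the exact
  Euclidean feature transform, edge-to-edge nearest-neighbour distances read
  off the ridge minima, and a 0.5° column profile.
* **Cohort statistics** (`hrdquant.cohort_stats`) — per-subject percent
  change from baseline, split-plot (between–within) repeated-measures ANOVA
  with Greenhouse–Geisser correction, exact paired Wilcoxon signed-rank
  (Pratt zero handling), Shapiro–Wilk normality check, subgroup medians.
* **Orchestration** (`hrdquant.pipeline`, `hrdquant.cli`) — a YAML-configured
  end-to-end pipeline and a `hrdquant` command-line tool.

See `docs/methods.md` for the model, parameter defaults and their rationale.

## Worked example

Simulate the default 2 × 10-subject cohort and run the statistics layer:

```bash
python analysis/01_simulate_cohort.py
python analysis/04_cohort_stats.py
```

Actual output (seed 1):

```
 group  timepoint       mean        sd  n
group1         T0   0.000000  0.000000 10
group1   T20_dark -15.675517  7.389998 10
group1 T22_bleach -27.355518  9.713599 10
group1        T37  -5.953015 21.102168 10
group1        T52  -0.637272 11.596329 10
group2         T0   0.000000  0.000000 10
group2   T20_dark  -0.034127  2.015946 10
group2 T22_bleach  -3.115535  8.658759 10
group2        T37  -6.088225  7.169781 10
group2        T52   3.587115  4.385239 10

group x time interaction: F = 4.56, p = 2.43e-03 (Greenhouse-Geisser p = 1.72e-02)
```

The stimulated group loses ~16% of its dots after dark adaptation and ~27%
right after the bleach, then recovers; the control group stays flat; the
group × time interaction is significant for this single replicate.

Rendering and detection work end to end as well
(`python analysis/02_render_detect.py`, seed 1):

```
   subject timepoint  planted  detected  error
group1_s01        T0      954       950     -4
group1_s02        T0     1032      1024     -8
group1_s03        T0      952       946     -6
group2_s01        T0      644       641     -3
group2_s02        T0     1093      1085     -8
group2_s03        T0     1000       995     -5
```

i.e. under default speckle the detector recovers planted counts to well
within 1%.

The same functionality is available from the command line:

```bash
hrdquant run-all --seed 1 --out results/run
hrdquant simulate-image --seed 2 --out results/img --n-dots 900
hrdquant detect --out results/det results/img/slab.tiff
```

## Reproduction

All randomness is seeded; every artefact below is regenerated from scratch.

```bash
# numbered analysis drivers (write under results/)
python analysis/01_simulate_cohort.py
python analysis/02_render_detect.py
python analysis/03_spatial_stats.py
python analysis/04_cohort_stats.py

# quantitative acceptance targets (a few minutes; 100 imaging cohorts and
# 200 count-level cohorts)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`results/acceptance.json` reports the Monte-Carlo estimates of the mean
detected baseline count for the stimulated group (target 898.2 ± 15 dots)
and the group-mean percent changes after dark adaptation (−13.3 ± 1.0) and
after the bleach (−25.1 ± 1.0).

## Layout

```
src/hrdquant/    library (geometry, study constants, synthetic, detection,
                 spatial, cohort_stats, config, io, pipeline, cli)
analysis/        numbered thin driver scripts writing to results/
scripts/         acceptance-target recomputation
tests/           pytest suite incl. property tests and acceptance criteria
docs/methods.md  methods note
```
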