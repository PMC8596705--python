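"""Synthetic en-face OCT slabs and light-stimulation cohorts.

Real en-face slabs from the study are not publicly deposited, so every
downstream stage (morphological detection, watershed Voronoi statistics,
cohort ANOVA) is exercised against synthetic data with exact ground truth.
The generator emulates:

* a 10 x 5 degree macular slab sampled 14 um below the ellipsoid zone,
  containing on the order of 900 hyperreflective dots of 10-20 um diameter,
  homogeneously distributed (hard-core uniform process) over multiplicative
  gamma speckle, and
* a two-group, 10-subjects-per-group, five-timepoint cohort whose group and
  time effect structure follows the published summary tables.

All randomness flows from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import study
from .geometry import FieldGeometry, DEFAULT_GEOMETRY

#: Default intensity of the flat background (arbitrary units on a 16-bit scale).
DEFAULT_BACKGROUND: float = 100.0
#: Default dot peak amplitude above background.
DEFAULT_AMPLITUDE: float = 200.0
#: Default gamma-speckle shape parameter (mean 1, SD = 1/sqrt(shape)).
DEFAULT_SPECKLE_SHAPE: float = 30.0
#: Default hard-core separation between dot centres, um.  Chosen above the
#: largest dot diameter so that the half-maximum contours of rendered dots
#: never coalesce and each dot is individually resolvable, as in the slabs
#: the generator emulates.
DEFAULT_MIN_SEPARATION: float = 28.0
#: Default dot diameter range, um.
DEFAULT_D_MIN: float = 10.0
DEFAULT_D_MAX: float = 20.0


class PlacementError(RuntimeError):
    """Raised when the rejection-sampling budget for dot placement runs out."""


@dataclass(frozen=True)
class DotPlacement:
    """One planted dot: centre position (um from the top-left field corner),
    diameter (um, equals the rendered full width at half maximum) and peak
    amplitude above background."""

    x_um: float
    y_um: float
    diameter_um: float
    amplitude: float


@dataclass
class CScanImage:
    """A single 2-D en-face intensity slab with its geometry and provenance.

    ``pixels`` is float64 row-major with row 0 at the top of the field;
    ``meta`` carries subject/group/timepoint labels and generator warnings.
    """

    pixels: np.ndarray
    geometry: FieldGeometry
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("CScanImage pixels must be 2-D")
        if np.any(self.pixels < 0):
            raise ValueError("CScanImage intensities must be non-negative")


def plant_dots(
    n: int,
    geometry: FieldGeometry = DEFAULT_GEOMETRY,
    d_min: float = DEFAULT_D_MIN,
    d_max: float = DEFAULT_D_MAX,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    amplitude: float = DEFAULT_AMPLITUDE,
    seed: int | np.random.Generator = 0,
    max_attempts_per_dot: int = 1000,
) -> list[DotPlacement]:
    """Place ``n`` dots uniformly over the field with a hard-core constraint.

    Each dot receives a diameter uniform in [d_min, d_max] and a centre
    uniform over the region where the dot lies fully inside the field (at
    least one radius from every edge).  Centres of distinct dots are at least
    ``min_separation`` um apart (hard-core process); ``min_separation=0``
    recovers a binomial (conditional Poisson) process.

    Raises
    ------
    PlacementError
        If ``n * max_attempts_per_dot`` rejection draws do not suffice, i.e.
        the field is too crowded for the requested separation.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if d_min <= 0 or d_max < d_min:
        raise ValueError("need 0 < d_min <= d_max")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    width, height = geometry.width_um, geometry.height_um
    if d_max > min(width, height):
        raise ValueError("dot diameter exceeds field size")

    placements: list[DotPlacement] = []
    xs = np.empty(n)
    ys = np.empty(n)
    budget = n * max_attempts_per_dot
    k = 0
    while k < n:
        if budget <= 0:
            raise PlacementError(
                f"placed {k}/{n} dots before exhausting the rejection budget; "
                "field too crowded for the requested min_separation"
            )
        budget -= 1
        d = rng.uniform(d_min, d_max)
        r = d / 2.0
        x = rng.uniform(r, width - r)
        y = rng.uniform(r, height - r)
        if k and min_separation > 0:
            if np.min((xs[:k] - x) ** 2 + (ys[:k] - y) ** 2) < min_separation**2:
                continue
        xs[k], ys[k] = x, y
        placements.append(DotPlacement(x_um=x, y_um=y, diameter_um=d, amplitude=amplitude))
        k += 1
    return placements


_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def render_slab(
    dots: list[DotPlacement],
    geometry: FieldGeometry = DEFAULT_GEOMETRY,
    background_level: float = DEFAULT_BACKGROUND,
    speckle_model: str = "none",
    speckle_shape: float = DEFAULT_SPECKLE_SHAPE,
    seed: int | np.random.Generator = 0,
    meta: dict | None = None,
) -> CScanImage:
    """Render planted dots onto a flat background, optionally under speckle.

    Each dot is an isotropic Gaussian bump whose full width at half maximum
    equals its diameter and whose peak adds ``amplitude`` to the background.
    Speckle ``"gamma"`` multiplies every pixel by an i.i.d. unit-mean gamma
    variate of the given shape (intensity speckle of an incoherently averaged
    OCT slab); ``"none"`` is deterministic.

    Dots narrower than two pixels are rendered anyway but a
    ``"undersampled_dots"`` warning count is recorded in the image metadata.
    """
    if speckle_model not in ("none", "gamma"):
        raise ValueError(f"unknown speckle_model {speckle_model!r}")
    nrows, ncols = geometry.shape
    img = np.full((nrows, ncols), float(background_level))
    p = geometry.um_per_px
    undersampled = 0
    for dot in dots:
        if not (0 <= dot.x_um <= geometry.width_um and 0 <= dot.y_um <= geometry.height_um):
            raise ValueError("dot centre outside the field")
        if dot.diameter_um < 2 * p:
            undersampled += 1
        sigma_px = dot.diameter_um * _FWHM_TO_SIGMA / p
        # pixel centre of pixel (i, j) is at ((j + 0.5) p, (i + 0.5) p)
        cx = dot.x_um / p - 0.5
        cy = dot.y_um / p - 0.5
        half = max(2, int(math.ceil(4.0 * sigma_px)))
        i0 = max(0, int(math.floor(cy)) - half)
        i1 = min(nrows, int(math.ceil(cy)) + half + 1)
        j0 = max(0, int(math.floor(cx)) - half)
        j1 = min(ncols, int(math.ceil(cx)) + half + 1)
        ii = np.arange(i0, i1)[:, None]
        jj = np.arange(j0, j1)[None, :]
        r2 = (ii - cy) ** 2 + (jj - cx) ** 2
        img[i0:i1, j0:j1] += dot.amplitude * np.exp(-r2 / (2.0 * sigma_px**2))
    if speckle_model == "gamma":
        if speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        img *= rng.gamma(speckle_shape, 1.0 / speckle_shape, size=img.shape)
    m = dict(meta or {})
    m["n_planted"] = len(dots)
    if undersampled:
        m["undersampled_dots"] = undersampled
    return CScanImage(pixels=img, geometry=geometry, meta=m)


def _default_delta() -> dict:
    return {g: dict(study.DELTA[g]) for g in study.GROUPS}


def _default_sigma() -> dict:
    return {g: dict(study.SIGMA[g]) for g in study.GROUPS}


@dataclass
class CohortParams:
    """Parameters of the simulated two-group longitudinal cohort.

    Per subject i of group g, a positive baseline count B_i is drawn from a
    Normal(baseline_mean_g, baseline_sd_g) truncated at zero; the count at a
    post-baseline timepoint t is round(B_i * (1 + delta_gt + e_it)) with
    e_it ~ Normal(0, sigma_gt), clamped at zero, rounding half to even.
    Baseline itself is round(B_i) (delta and sigma are zero at baseline by
    construction).  Defaults reproduce the published group baselines and
    per-timepoint mean fractional changes.
    """

    n_per_group: int = study.N_PER_GROUP
    baseline_mean: dict = field(
        default_factory=lambda: dict(study.BASELINE_MEAN)
    )
    baseline_sd: dict = field(default_factory=lambda: dict(study.BASELINE_SD))
    delta: dict = field(default_factory=_default_delta)
    sigma: dict = field(default_factory=_default_sigma)
    timepoints: tuple = study.TIMEPOINTS
    groups: tuple = study.GROUPS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        for g in self.groups:
            if self.baseline_sd[g] < 0:
                raise ValueError("baseline_sd must be non-negative")
            for t in self.timepoints[1:]:
                if self.sigma[g][t] < 0:
                    raise ValueError("sigma must be non-negative")


def simulate_cohort(params: CohortParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort; returns (cohort table, ground-truth trajectories).

    The cohort table is a tidy DataFrame with columns ``subject``, ``group``,
    ``timepoint``, ``count`` (complete balanced design).  The ground-truth
    frame additionally carries the unrounded baseline and the realised
    fractional change ``delta + e`` per subject x timepoint.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    truth = []
    for g in params.groups:
        mu, sd = params.baseline_mean[g], params.baseline_sd[g]
        for i in range(params.n_per_group):
            subject = f"{g}_s{i + 1:02d}"
            b = rng.normal(mu, sd)
            while b <= 0:  # truncate the baseline distribution at zero
                b = rng.normal(mu, sd)
            for t in params.timepoints:
                if t == params.timepoints[0]:
                    frac = 0.0
                else:
                    frac = params.delta[g][t] + rng.normal(0.0, params.sigma[g][t])
                count = max(0, int(np.round(b * (1.0 + frac))))
                rows.append((subject, g, t, count))
                truth.append((subject, g, t, b, frac, count))
    cohort = pd.DataFrame(rows, columns=["subject", "group", "timepoint", "count"])
    truth_df = pd.DataFrame(
        truth,
        columns=["subject", "group", "timepoint", "baseline_true", "frac_change_true", "count"],
    )
    return cohort, truth_df


def simulate_imaging_cohort(
    params: CohortParams,
    geometry: FieldGeometry = DEFAULT_GEOMETRY,
    d_min: float = DEFAULT_D_MIN,
    d_max: float = DEFAULT_D_MAX,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    amplitude: float = DEFAULT_AMPLITUDE,
    background_level: float = DEFAULT_BACKGROUND,
    speckle_model: str = "gamma",
    speckle_shape: float = DEFAULT_SPECKLE_SHAPE,
    timepoints: tuple | None = None,
) -> tuple[dict, pd.DataFrame, dict]:
    """Simulate the cohort and render one slab per subject x timepoint.

    Returns ``(images, cohort, dots)`` where ``images`` and ``dots`` map
    ``(subject, timepoint)`` to the rendered :class:`CScanImage` and the list
    of planted :class:`DotPlacement`.  The planted dot count of every image
    equals the corresponding cohort-table count exactly.  ``timepoints`` may
    restrict rendering to a subset of the protocol (e.g. baseline only).
    """
    cohort, truth = simulate_cohort(params)
    render_tps = params.timepoints if timepoints is None else tuple(timepoints)
    # independent, reproducible substreams per image, all derived from the seed
    ss = np.random.SeedSequence(params.seed, spawn_key=(1,))
    images: dict = {}
    dots: dict = {}
    subset = cohort[cohort["timepoint"].isin(render_tps)]
    children = ss.spawn(len(subset))
    for child, (_, row) in zip(children, subset.iterrows()):
        rng = np.random.default_rng(child)
        placements = plant_dots(
            int(row["count"]), geometry, d_min, d_max, min_separation, amplitude, seed=rng
        )
        img = render_slab(
            placements,
            geometry,
            background_level=background_level,
            speckle_model=speckle_model,
            speckle_shape=speckle_shape,
            seed=rng,
            meta={
                "subject": row["subject"],
                "group": row["group"],
                "timepoint": row["timepoint"],
            },
        )
        key = (row["subject"], row["timepoint"])
        images[key] = img
        dots[key] = placements
    return images, cohort, dots
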