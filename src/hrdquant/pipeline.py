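"""End-to-end orchestration of the simulated light-stimulation experiment.

One call (or the ``run-all`` CLI subcommand) performs, from a single seed:
cohort simulation, slab rendering per subject and timepoint, morphological
dot detection, watershed nearest-neighbour statistics, and the cohort
statistics on the *detected* counts.  Everything is written to the output
directory: images (optional), dot and NN CSVs, the true and detected cohort
tables, summary/percent-change CSVs, ANOVA JSON, the effective config and a
log with the seed and package versions.  Outputs are deterministic given the
seed.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cohort_stats, io
from .config import RunConfig
from .detection import detect_hrds
from .spatial import (
    column_profile,
    group_timepoint_nn,
    nn_distances,
    nn_summary,
    voronoi_watershed,
)
from .detection import DotMask
from .synthetic import CohortParams, simulate_imaging_cohort

log = logging.getLogger("hrdquant")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - tag and re-raise
                raise PipelineError(name, e) from e
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full simulated protocol; returns the result bundle paths.

    Requires ``config.seed`` to be set.  Stage failures abort with a
    stage-tagged :class:`PipelineError`.
    """
    if config.seed is None:
        raise ValueError("a seed is mandatory (set it in the config or via --seed)")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if config.verbosity else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )
    config.save(out / "config.yaml")
    (out / "run.log").write_text(
        f"hrdquant {__version__}\nnumpy {np.__version__}\npandas {pd.__version__}\n"
        f"seed {config.seed}\n"
    )

    gen = config.generator
    kwargs = {}
    if gen.baseline_mean is not None:
        kwargs["baseline_mean"] = gen.baseline_mean
    if gen.baseline_sd is not None:
        kwargs["baseline_sd"] = gen.baseline_sd
    params = CohortParams(n_per_group=gen.n_per_group, seed=config.seed, **kwargs)

    images, true_cohort, planted = _stage("simulate")(simulate_imaging_cohort)(
        params,
        geometry=config.geometry,
        d_min=gen.d_min,
        d_max=gen.d_max,
        min_separation=gen.min_separation,
        amplitude=gen.amplitude,
        background_level=gen.background_level,
        speckle_model=gen.speckle_model,
        speckle_shape=gen.speckle_shape,
    )
    io.cohort_to_csv(true_cohort, out / "cohort_true.csv")

    img_dir = out / "images"
    dots_dir = out / "dots"
    nn_dir = out / "nn"
    for d in (dots_dir, nn_dir):
        d.mkdir(exist_ok=True)
    if config.save_images:
        img_dir.mkdir(exist_ok=True)

    detected_rows = []
    nn_results = {}
    for (subject, timepoint), image in images.items():
        tag = f"{subject}_{timepoint}"
        if config.save_images:
            _stage("write-images")(io.save_image)(img_dir / f"{tag}.tiff", image)
            io.placements_to_csv(planted[(subject, timepoint)], img_dir / f"{tag}_truth.csv")
        dots = _stage("detect")(detect_hrds)(image, config.detection)
        io.dotset_to_csv(dots, dots_dir / f"{tag}_dots.csv")
        detected_rows.append((subject, image.meta["group"], timepoint, dots.count))
        if dots.count >= 2:
            mask = DotMask(mask=dots.labels > 0, geometry=image.geometry)
            cells = _stage("spatial")(voronoi_watershed)(mask, dots)
            res = nn_distances(mask, dots, cells)
            res.table.to_csv(nn_dir / f"{tag}_nn.csv", index=False)
            nn_results[(subject, image.meta["group"], timepoint)] = res
        profile = column_profile(dots, image.geometry, config.spatial.bin_deg)
        profile.to_csv(nn_dir / f"{tag}_profile.csv", index=False)
    detected = pd.DataFrame(
        detected_rows, columns=["subject", "group", "timepoint", "count"]
    )
    io.cohort_to_csv(detected, out / "cohort_detected.csv")

    per_image_nn = nn_summary(nn_results)
    per_image_nn.to_csv(out / "nn_per_image.csv", index=False)
    group_timepoint_nn(per_image_nn).to_csv(out / "nn_group_timepoint.csv", index=False)

    stats = _stage("stats")(compute_cohort_stats)(detected)
    io.write_json(stats["anova"], out / "anova.json")
    stats["summary"].to_csv(out / "summary.csv", index=False)
    stats["percent_change"].to_csv(out / "percent_change.csv", index=False)

    log.info("pipeline complete: %s", out)
    return {
        "out_dir": out,
        "cohort_true": true_cohort,
        "cohort_detected": detected,
        "nn_per_image": per_image_nn,
        "stats": stats,
    }


def compute_cohort_stats(cohort: pd.DataFrame) -> dict:
    """Summary, percent change and ANOVA layer over one cohort table."""
    rm = cohort_stats.rm_anova(cohort)
    ow = cohort_stats.one_way_time_anova(cohort)
    counts = cohort["count"].to_numpy(dtype=float)
    w, p, flagged = cohort_stats.normality_check(counts)
    return {
        "summary": cohort_stats.summarize(cohort),
        "percent_change": cohort_stats.percent_change_summary(cohort),
        "anova": {
            "between_within": rm.table.to_dict(orient="records"),
            "epsilon_gg": rm.epsilon_gg,
            "one_way_time": ow.table.to_dict(orient="records"),
            "shapiro": {"W": w, "p": p, "non_normal": flagged},
        },
    }
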