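"""Published group-level statistics of the light-stimulation cohort study.

These are the study's printed summary tables for the two 10-subject groups
(Group 1: dark adaptation + photobleach protocol; Group 2: constant ambient
illumination) at the five acquisition timepoints.  They serve two roles:

* defaults for the synthetic cohort generator (the simulated study
  conditions), and
* inputs to analytic identities, e.g. equal-n pooling of the two group means
  reproduces the whole-population means quoted in the study's results.
"""

from __future__ import annotations

import numpy as np

#: Ordered timepoint labels: baseline, after 20 min dark adaptation, after the
#: 2 min photobleach (T = 22 min), then 15 and 30 min post-bleach.
TIMEPOINTS: tuple[str, ...] = ("T0", "T20_dark", "T22_bleach", "T37", "T52")

#: Timepoints after baseline, in protocol order.
POST_BASELINE: tuple[str, ...] = TIMEPOINTS[1:]

GROUPS: tuple[str, ...] = ("group1", "group2")

#: Subjects per group in the study.
N_PER_GROUP: int = 10

#: Baseline HRD counts, mean and SD per group.
BASELINE_MEAN = {"group1": 898.2, "group2": 909.0}
BASELINE_SD = {"group1": 162.9, "group2": 203.2}

#: Mean HRD counts per group x timepoint (mean, SD).
GROUP_TIMEPOINT_MEAN_SD = {
    "group1": {
        "T0": (898.2, 162.9),
        "T20_dark": (784.6, 215.1),
        "T22_bleach": (669.5, 140.5),
        "T37": (819.7, 240.3),
        "T52": (892.2, 169.0),
    },
    "group2": {
        "T0": (909.0, 203.2),
        "T20_dark": (921.5, 217.5),
        "T22_bleach": (910.0, 247.8),
        "T37": (918.1, 232.1),
        "T52": (910.7, 241.9),
    },
}

#: Mean per-subject fractional change from baseline (Group x post-baseline
#: timepoint), and the SD of the per-subject change, as fractions (not %).
DELTA = {
    "group1": {"T20_dark": -0.133, "T22_bleach": -0.251, "T37": -0.085, "T52": -0.001},
    "group2": {"T20_dark": 0.001, "T22_bleach": 0.005, "T37": -0.006, "T52": 0.004},
}
SIGMA = {
    "group1": {"T20_dark": 0.128, "T22_bleach": 0.122, "T37": 0.213, "T52": 0.111},
    "group2": {"T20_dark": 0.039, "T22_bleach": 0.103, "T37": 0.087, "T52": 0.089},
}


def pooled_timepoint_means() -> dict[str, float]:
    """Equal-n pooled mean HRD count per timepoint over both groups.

    With balanced groups the whole-population mean at each timepoint is the
    unweighted average of the two group means.
    """
    return {
        t: float(
            np.mean(
                [GROUP_TIMEPOINT_MEAN_SD[g][t][0] for g in GROUPS]
            )
        )
        for t in TIMEPOINTS
    }
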