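"""Spatial statistics of detected dots: watershed Voronoi tessellation,
nearest-neighbour distances and the binned column profile.

The tessellation is the skeleton-by-influence-zones (SKIZ) of the dot mask:
a watershed of the Euclidean distance-to-nearest-object function seeded by
the labelled objects, which assigns every background pixel to the nearest
object and generalises the point Voronoi diagram to extended objects.  Along
the ridge between two influence zones the distance function attains half the
edge-to-edge gap between the objects, so the minimum of the distance
function on a cell's internal boundary recovers the dot's edge-to-edge
nearest-neighbour distance.

Distances are edge-to-edge in the pixel-centre metric: the distance between
two objects is the minimum Euclidean distance between centres of their
pixels, the same convention as an exhaustive pairwise computation on the
label image.  On the discrete grid the ridge minimum is read as
``dt(p) + dt(q) + 1`` pixels over 4-adjacent pixel pairs (p, q) on opposite
sides of a cell boundary, which compensates the half-pixel offset on each
side of the ridge and is exact for point-like (single-pixel) objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .detection import DotMask, DotSet
from .geometry import FieldGeometry


@dataclass
class InfluenceMap:
    """Per-pixel assignment of the field to dot influence zones (Voronoi
    cells of extended objects).  Labels match the DotSet labels."""

    labels: np.ndarray
    geometry: FieldGeometry


@dataclass
class NNResult:
    """Per-dot nearest-neighbour distances of one slab.

    ``table`` columns: ``label``, ``nn_um`` (edge-to-edge distance, NaN when
    undefined), ``border`` (cell touches the field border).  ``mean_um`` and
    ``sd_um`` summarise the defined, non-border distances; ``reason`` is set
    when no distance is defined (e.g. fewer than two dots).
    """

    table: pd.DataFrame
    mean_um: float
    sd_um: float
    reason: str | None = None


def voronoi_watershed(mask: DotMask, dots: DotSet) -> InfluenceMap:
    """Influence zones (SKIZ) of the labelled dots.

    Watershed of the background's Euclidean distance-to-nearest-object
    function, realised exactly through the Euclidean feature transform: each
    pixel is assigned the label of its nearest object pixel, so the zone
    boundaries are the watershed ridges of the distance function.  Ties on
    the discrete ridge are broken deterministically by the feature
    transform's scan order.
    """
    if dots.count == 0:
        raise ValueError("cannot tessellate an empty dot set")
    _, (inds_i, inds_j) = ndi.distance_transform_edt(
        ~mask.mask, sampling=1.0, return_indices=True
    )
    labels = dots.labels[inds_i, inds_j]
    return InfluenceMap(labels=labels, geometry=mask.geometry)


def _boundary_minima(mask: DotMask, cells: InfluenceMap) -> tuple[np.ndarray, np.ndarray]:
    """Per-label minimum of ``dt(p) + dt(q) + 1`` (pixels) over 4-adjacent
    pixel pairs straddling an internal cell boundary, plus a per-label flag
    for cells touching the image border (the border itself contributes no
    pair)."""
    lab = cells.labels
    dist = ndi.distance_transform_edt(~mask.mask, sampling=1.0)
    nlab = lab.max()
    minima = np.full(nlab + 1, np.inf)
    for axis in (0, 1):
        a = np.take(lab, range(lab.shape[axis] - 1), axis=axis)
        b = np.take(lab, range(1, lab.shape[axis]), axis=axis)
        da = np.take(dist, range(dist.shape[axis] - 1), axis=axis)
        db = np.take(dist, range(1, dist.shape[axis]), axis=axis)
        diff = a != b
        pair = da[diff] + db[diff] + 1.0
        np.minimum.at(minima, a[diff], pair)
        np.minimum.at(minima, b[diff], pair)
    border_labels = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    )
    touches = np.zeros(nlab + 1, dtype=bool)
    touches[border_labels] = True
    return minima, touches


def nn_distances(mask: DotMask, dots: DotSet, cells: InfluenceMap) -> NNResult:
    """Edge-to-edge nearest-neighbour distance per dot.

    For each dot, the ridge minimum of the background distance function
    along its cell's boundary with other cells (the image border is not a
    neighbour).  Dots whose cell has no internal boundary get NaN.  The
    summary mean/SD covers dots with a defined distance whose cell does not
    touch the field border.
    """
    empty = pd.DataFrame(columns=["label", "nn_um", "border"])
    if dots.count < 2:
        return NNResult(
            table=empty, mean_um=float("nan"), sd_um=float("nan"),
            reason="fewer than two dots",
        )
    minima, touches = _boundary_minima(mask, cells)
    p = mask.geometry.um_per_px
    labels = dots.table["label"].to_numpy()
    nn = minima[labels] * p
    nn[~np.isfinite(nn)] = np.nan
    border = touches[labels]
    table = pd.DataFrame({"label": labels, "nn_um": nn, "border": border})
    interior = table.loc[~table["border"], "nn_um"].dropna()
    mean = float(interior.mean()) if len(interior) else float("nan")
    sd = float(interior.std(ddof=1)) if len(interior) > 1 else float("nan")
    reason = None if len(interior) else "no interior dot has a defined distance"
    return NNResult(table=table, mean_um=mean, sd_um=sd, reason=reason)


def column_profile(
    dots: DotSet, geometry: FieldGeometry | None = None, bin_deg: float = 0.5
) -> pd.DataFrame:
    """Dot counts summed along x in half-open bins of ``bin_deg`` degrees.

    Bins [k*bin, (k+1)*bin) tile the full field width; the sum over bins
    equals the total dot count.  Returns columns ``bin_start_deg``, ``count``.
    """
    if bin_deg <= 0:
        raise ValueError("bin_deg must be positive")
    geometry = geometry or dots.geometry
    nbins = int(np.ceil(geometry.width_deg / bin_deg - 1e-9))
    edges = np.arange(nbins + 1) * bin_deg
    x_deg = dots.table["x_um"].to_numpy() / geometry.um_per_deg
    idx = np.floor(x_deg / bin_deg).astype(int)
    idx = np.clip(idx, 0, nbins - 1)  # centroids sit strictly inside the field
    counts = np.bincount(idx, minlength=nbins) if len(x_deg) else np.zeros(nbins, int)
    return pd.DataFrame({"bin_start_deg": edges[:-1], "count": counts})


def nn_summary(results: dict) -> pd.DataFrame:
    """Aggregate per-image NN means over a keyed image set.

    ``results`` maps metadata tuples ``(subject, group, timepoint)`` to
    :class:`NNResult`; returns one row per image plus group x timepoint
    aggregates in long form (columns ``subject``, ``group``, ``timepoint``,
    ``mean_nn_um``, ``sd_nn_um``).
    """
    rows = [
        {
            "subject": subject,
            "group": group,
            "timepoint": timepoint,
            "mean_nn_um": res.mean_um,
            "sd_nn_um": res.sd_um,
        }
        for (subject, group, timepoint), res in results.items()
    ]
    return pd.DataFrame(rows)


def group_timepoint_nn(per_image: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of per-image mean NN distances per group x timepoint."""
    return (
        per_image.groupby(["group", "timepoint"], sort=False)["mean_nn_um"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
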