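"""Morphological detection of hyperreflective dots on an en-face slab.

The chain is the classical mathematical-morphology spot detector:

1. white top-hat (image minus its opening by a disc) to flatten the
   background and keep bright structures smaller than the disc;
2. a fixed absolute threshold on the top-hat residue;
3. small-object removal by an erosion followed by morphological
   reconstruction, which deletes components that vanish under the erosion
   and restores the surviving ones to their exact original pixel sets;
4. 8-connected component labelling and per-component measurement.

All arithmetic is in floating point regardless of the input bit depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import morphology

from .geometry import FieldGeometry
from .synthetic import CScanImage, DEFAULT_AMPLITUDE


def disc_footprint(radius_px: float) -> np.ndarray:
    """Discrete disc: pixels whose centre lies within the Euclidean radius
    (ties at the exact radius included)."""
    if radius_px < 0:
        raise ValueError("radius must be non-negative")
    r = int(np.floor(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius_px**2 + 1e-9


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the detection chain (all distances in um).

    ``tophat_radius_um`` must exceed the radius of the largest dot of
    interest by a comfortable margin, since the opening clips the tails of
    dots comparable in size to the disc.  ``threshold`` is an absolute
    intensity in top-hat units; the default is half the default rendered dot
    amplitude.  ``min_size_radius_um`` is the erosion disc radius of the
    small-object filter; 0 disables it.
    """

    tophat_radius_um: float = 18.0
    threshold: float = 0.5 * DEFAULT_AMPLITUDE
    min_size_radius_um: float = 3.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.min_size_radius_um < 0:
            raise ValueError("min_size_radius_um must be non-negative")
        if self.tophat_radius_um <= 0:
            raise ValueError("tophat_radius_um must be positive")


@dataclass
class DotMask:
    """Binary dot mask aligned to its source slab."""

    mask: np.ndarray
    geometry: FieldGeometry

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.geometry.shape:
            raise ValueError("mask shape does not match geometry")


@dataclass
class DotSet:
    """Labelled, measured dots of one slab.

    ``table`` has one row per dot with columns ``label`` (consecutive
    positive integers), ``x_um``/``y_um`` (area-weighted centroid),
    ``area_um2`` and ``eq_diameter_um``; ``labels`` is the corresponding
    label image.
    """

    table: pd.DataFrame
    labels: np.ndarray
    geometry: FieldGeometry

    @property
    def count(self) -> int:
        return len(self.table)


def white_tophat(image: CScanImage, radius_um: float) -> CScanImage:
    """White top-hat: image minus its grey-scale opening by a disc.

    Non-negative everywhere; flat regions map to zero; bright structures
    narrower than the disc survive with their local contrast.
    """
    radius_px = image.geometry.um_to_px(radius_um)
    if radius_px < 1:
        raise ValueError(
            f"top-hat radius {radius_um} um maps to {radius_px:.2f} px (< 1 px)"
        )
    fp = disc_footprint(radius_px)
    pix = image.pixels
    opened = ndi.grey_dilation(ndi.grey_erosion(pix, footprint=fp), footprint=fp)
    out = pix - opened
    # opening is anti-extensive, so the residue is >= 0 up to float round-off
    np.clip(out, 0.0, None, out=out)
    return CScanImage(pixels=out, geometry=image.geometry, meta=dict(image.meta))


def binarize(tophat_image: CScanImage, threshold: float) -> DotMask:
    """Fixed absolute threshold on the top-hat residue (strictly greater)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return DotMask(mask=tophat_image.pixels > threshold, geometry=tophat_image.geometry)


def remove_small(mask: DotMask, radius_um: float) -> DotMask:
    """Remove components that vanish under an erosion; keep survivors intact.

    Erodes the mask by a disc of the given radius, then reconstructs by
    dilation inside the original mask.  A connected component survives iff
    its erosion is non-empty, and a surviving component is returned with its
    exact original pixel set.  Radius 0 is the identity.
    """
    if radius_um < 0:
        raise ValueError("radius must be non-negative")
    radius_px = mask.geometry.um_to_px(radius_um)
    if radius_px < 1:
        return DotMask(mask=mask.mask.copy(), geometry=mask.geometry)
    fp = disc_footprint(radius_px)
    eroded = ndi.binary_erosion(mask.mask, structure=fp, border_value=0)
    if not eroded.any():
        return DotMask(mask=np.zeros_like(mask.mask), geometry=mask.geometry)
    recon = morphology.reconstruction(
        eroded.astype(np.uint8), mask.mask.astype(np.uint8), method="dilation"
    )
    return DotMask(mask=recon.astype(bool), geometry=mask.geometry)


def label_and_measure(mask: DotMask, geometry: FieldGeometry | None = None) -> DotSet:
    """8-connected labelling with per-component centroid, area and equivalent
    diameter in physical units.

    Pixel (row i, col j) has its centre at ((j + 0.5) p, (i + 0.5) p) um for
    pixel pitch p; components touching the image border are kept.
    """
    geometry = geometry or mask.geometry
    if mask.mask.shape != geometry.shape:
        raise ValueError("mask dimensions do not match geometry")
    labels, n = ndi.label(mask.mask, structure=np.ones((3, 3), dtype=int))
    p = geometry.um_per_px
    if n == 0:
        table = pd.DataFrame(
            columns=["label", "x_um", "y_um", "area_um2", "eq_diameter_um"]
        )
        return DotSet(table=table, labels=labels, geometry=geometry)
    idx = np.arange(1, n + 1)
    centroids = ndi.center_of_mass(mask.mask, labels, idx)
    areas = ndi.sum_labels(mask.mask, labels, idx)
    cy = np.array([c[0] for c in centroids])
    cx = np.array([c[1] for c in centroids])
    table = pd.DataFrame(
        {
            "label": idx,
            "x_um": (cx + 0.5) * p,
            "y_um": (cy + 0.5) * p,
            "area_um2": areas * p * p,
            "eq_diameter_um": np.sqrt(4.0 * areas / np.pi) * p,
        }
    )
    return DotSet(table=table, labels=labels, geometry=geometry)


def detect_hrds(image: CScanImage, params: DetectionParams = DetectionParams()) -> DotSet:
    """Full detection chain: top-hat, threshold, small-object removal,
    labelling.  Deterministic given the image and parameters."""
    th = white_tophat(image, params.tophat_radius_um)
    mask = binarize(th, params.threshold)
    mask = remove_small(mask, params.min_size_radius_um)
    return label_and_measure(mask)
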