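"""File formats: 16-bit grayscale TIFF slabs with JSON geometry sidecars,
CSV tables for dots, nearest-neighbour distances and cohorts, JSON summaries.

CSV files are UTF-8, comma-separated with a header row and '.' decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detection import DotSet
from .geometry import FieldGeometry
from .synthetic import CScanImage, DotPlacement


def save_image(path, image: CScanImage) -> Path:
    """Write a slab as 16-bit TIFF with a ``.json`` geometry/metadata sidecar."""
    path = Path(path)
    pix = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, pix)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(
        json.dumps(
            {"geometry": image.geometry.to_dict(), "meta": image.meta}, indent=1
        )
    )
    return path


def load_image(path) -> CScanImage:
    """Read a TIFF slab and its JSON sidecar back into a :class:`CScanImage`."""
    path = Path(path)
    pix = tifffile.imread(path).astype(float)
    sidecar = path.with_suffix(".json")
    info = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    geometry = (
        FieldGeometry.from_dict(info["geometry"])
        if "geometry" in info
        else FieldGeometry(
            width_deg=pix.shape[1] / 96.0, height_deg=pix.shape[0] / 96.0
        )
    )
    return CScanImage(pixels=pix, geometry=geometry, meta=info.get("meta", {}))


def dotset_to_csv(dots: DotSet, path) -> Path:
    path = Path(path)
    dots.table.to_csv(path, index=False)
    return path


def placements_to_csv(placements: list[DotPlacement], path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(d.x_um, d.y_um, d.diameter_um, d.amplitude) for d in placements],
        columns=["x_um", "y_um", "diameter_um", "amplitude"],
    ).to_csv(path, index=False)
    return path


def cohort_to_csv(cohort: pd.DataFrame, path) -> Path:
    path = Path(path)
    cohort.to_csv(path, index=False)
    return path


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject", "group", "timepoint", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV lacks columns {sorted(missing)}")
    return df


def write_json(obj, path) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=1, default=default, allow_nan=True))
    return path
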