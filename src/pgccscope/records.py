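"""Per-nucleus record table schema.

Detected nuclei are carried through the pipeline as a :class:`pandas.DataFrame`
with one row per nucleus (the convention of high-content screening tools such
as CellProfiler).  Columns:

===========  ==================================================================
column       meaning
===========  ==================================================================
field_id     identifier of the image field the nucleus came from
label        positive integer label in the field's label image
row, col     centroid in pixels, 0-based, origin at the top-left corner
area_px      number of member pixels of the nucleus mask
area_um2     physical area, ``area_px * pixel_size_um**2`` (NaN if pixel size
             is unknown)
solidity     area / convex-hull area of the mask, in (0, 1]
mean_nuclei  mean nuclear-stain (Hoechst/DAPI) intensity over the mask dilated
             by 2 px, raw camera units
mean_live    mean live-stain (Calcein AM / FITC) intensity, same mask
mean_dead    mean dead-stain (Ethidium homodimer / TRITC) intensity, same mask
mean_ros     mean ROS-probe (CellROX / Cy5) intensity, NaN if channel absent
viability    'live' | 'dead' | 'unassigned'
ploidy_class 'non_pgcc' | 'pgcc' | 'debris' | 'unassigned'
===========  ==================================================================

Intensities are never normalized at load time, so gating thresholds stay
interpretable against the raw stains.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RECORD_COLUMNS = [
    "field_id",
    "label",
    "row",
    "col",
    "area_px",
    "area_um2",
    "solidity",
    "mean_nuclei",
    "mean_live",
    "mean_dead",
    "mean_ros",
    "viability",
    "ploidy_class",
]

VIABILITY_CLASSES = ("live", "dead", "unassigned")
PLOIDY_CLASSES = ("non_pgcc", "pgcc", "debris", "unassigned")

_DTYPES = {
    "field_id": str,
    "label": np.int64,
    "row": float,
    "col": float,
    "area_px": np.int64,
    "area_um2": float,
    "solidity": float,
    "mean_nuclei": float,
    "mean_live": float,
    "mean_dead": float,
    "mean_ros": float,
    "viability": str,
    "ploidy_class": str,
}


def empty_records() -> pd.DataFrame:
    """Return an empty record table with the canonical columns and dtypes."""
    return pd.DataFrame({c: pd.Series(dtype=_DTYPES[c]) for c in RECORD_COLUMNS})


def validate_records(records: pd.DataFrame) -> None:
    """Raise ``ValueError`` if *records* is missing canonical columns or holds
    out-of-vocabulary class labels."""
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"record table missing columns: {missing}")
    bad_v = set(records["viability"]) - set(VIABILITY_CLASSES)
    if bad_v:
        raise ValueError(f"unknown viability labels: {sorted(bad_v)}")
    bad_p = set(records["ploidy_class"]) - set(PLOIDY_CLASSES)
    if bad_p:
        raise ValueError(f"unknown ploidy labels: {sorted(bad_p)}")
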