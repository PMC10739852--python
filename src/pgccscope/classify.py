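"""Viability gating and nuclear-area ploidy classification.

A detected nucleus is first gated live/dead from the viability stains
(live cells are Calcein-bright and Ethidium-dim), then live cells are split
into PGCCs and non-PGCCs by nuclear area.  The reference thresholds are
300 px at a 4x objective and 1875 px at 10x, equivalently a physical area of
817 µm² (a circle of ~32 µm diameter); a nucleus is a PGCC when its area
STRICTLY exceeds the threshold.  Dead cells are a terminal class: their
nuclear size is never interpreted as ploidy.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

PGCC_AREA_PX_4X = 300
PGCC_AREA_PX_10X = 1875
PGCC_AREA_UM2 = 817.0
MIN_RECORDS_FOR_AUTO_GATES = 20


@dataclasses.dataclass
class GatingParams:
    """Live/dead intensity gates in raw camera units.

    A cell is live iff ``mean_live > live_threshold`` and
    ``mean_dead <= dead_threshold`` (high Live intensity AND low Dead
    intensity), the standard quadrant gate.
    """

    live_threshold: float
    dead_threshold: float
    mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "auto"):
            raise ValueError("mode must be 'fixed' or 'auto'")
        if self.mode == "fixed" and (self.live_threshold <= 0 or self.dead_threshold <= 0):
            raise ValueError("fixed gates must be positive")


@dataclasses.dataclass
class ClassificationParams:
    """PGCC area threshold, in pixels at a reference magnification or in µm².

    ``pixels`` mode reproduces the objective-dependent defaults (300 px @4x,
    1875 px @10x); ``physical`` mode uses the magnification-independent
    817 µm² definition and needs a pixel size.
    """

    threshold_mode: str = "pixels"
    area_threshold_px: int = PGCC_AREA_PX_4X
    reference_magnification: float = 4.0
    area_threshold_um2: float = PGCC_AREA_UM2

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("pixels", "physical"):
            raise ValueError("threshold_mode must be 'pixels' or 'physical'")
        if self.area_threshold_px <= 0 or self.area_threshold_um2 <= 0:
            raise ValueError("area thresholds must be positive")
        if self.reference_magnification <= 0:
            raise ValueError("reference_magnification must be positive")


def threshold_for_magnification(base_px: int, base_mag: float, target_mag: float) -> int:
    """Rescale a pixel-area threshold between objective magnifications.

    Area scales with the square of linear magnification:
    ``round(base_px * (target_mag / base_mag) ** 2)``.
    E.g. 300 px at 4x becomes 1875 px at 10x.
    """
    if base_px <= 0 or base_mag <= 0 or target_mag <= 0:
        raise ValueError("all arguments must be positive")
    return round(base_px * (target_mag / base_mag) ** 2)


def threshold_area_to_diameter(area_um2: float) -> float:
    """Diameter (µm) of the circle with the given area: ``2 * sqrt(A / pi)``.

    The 817 µm² threshold corresponds to a ~32 µm circle.
    """
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    return 2.0 * math.sqrt(area_um2 / math.pi)


def auto_gates(records: pd.DataFrame) -> GatingParams:
    """Derive live/dead gates from the record population, per channel.

    The population is split by Otsu on log10(intensity + 1); the gate is then
    placed midway (in log space) between the medians of the two resulting
    classes, which keeps it clear of the tails when the classes are very
    unbalanced (e.g. 5 dead cells among hundreds of live ones).

    Deterministic for fixed input.  Requires at least 20 records; raises on
    degenerate (single-valued) intensity distributions.
    """
    usable = records[records["ploidy_class"] != "debris"]
    if len(usable) < MIN_RECORDS_FOR_AUTO_GATES:
        raise ValueError(
            f"auto gating needs >= {MIN_RECORDS_FOR_AUTO_GATES} records "
            f"(got {len(usable)}); supply fixed gates instead"
        )
    thresholds = {}
    for ch in ("live", "dead"):
        values = np.log10(usable[f"mean_{ch}"].to_numpy(dtype=float) + 1.0)
        if np.ptp(values) == 0:
            raise ValueError(
                f"all mean_{ch} intensities identical: no gate exists; use fixed gates"
            )
        split = threshold_otsu(values, nbins=256)
        lo, hi = values[values <= split], values[values > split]
        if len(lo) == 0 or len(hi) == 0:
            gate_log = split
        else:
            # midpoint of the class medians: keeps the gate clear of either
            # population's tail even when class sizes are very unbalanced
            gate_log = 0.5 * (np.median(lo) + np.median(hi))
        thresholds[ch] = 10.0**gate_log - 1.0
    return GatingParams(
        live_threshold=thresholds["live"],
        dead_threshold=thresholds["dead"],
        mode="auto",
    )


def gate_viability(records: pd.DataFrame, gates: GatingParams) -> pd.DataFrame:
    """Assign viability: live iff Calcein-bright AND Ethidium-dim.

    Debris records are left untouched.  Raises if the live/dead intensities
    are absent (time-lapse data has no viability stains; use the time-lapse
    path, which treats all non-debris nuclei as live).
    """
    if records["mean_live"].isna().all() or records["mean_dead"].isna().all():
        raise ValueError(
            "records carry no live/dead intensities; for RFP time-lapse data "
            "use timelapse.count_frames, which skips viability gating"
        )
    out = records.copy()
    non_debris = out["ploidy_class"] != "debris"
    is_live = (out["mean_live"] > gates.live_threshold) & (
        out["mean_dead"] <= gates.dead_threshold
    )
    out.loc[non_debris, "viability"] = np.where(is_live[non_debris], "live", "dead")
    return out


def resolve_area_threshold(
    params: ClassificationParams,
    magnification: Optional[float] = None,
    pixel_size_um: Optional[float] = None,
) -> float:
    """Resolve the PGCC threshold into pixels for the acquisition at hand."""
    if params.threshold_mode == "pixels":
        if magnification is None:
            raise ValueError("pixels-mode threshold needs the objective magnification")
        return float(
            threshold_for_magnification(
                params.area_threshold_px, params.reference_magnification, magnification
            )
        )
    if pixel_size_um is None:
        raise ValueError("physical-mode threshold needs pixel_size_um")
    return params.area_threshold_um2 / pixel_size_um**2


def classify_pgcc(
    records: pd.DataFrame,
    params: Optional[ClassificationParams] = None,
    magnification: Optional[float] = None,
    pixel_size_um: Optional[float] = None,
    assume_live: bool = False,
) -> pd.DataFrame:
    """Split live cells into PGCC / non-PGCC by nuclear area.

    A live, non-debris nucleus is a PGCC iff its area strictly exceeds the
    resolved threshold ("larger than"); an area exactly at the threshold is
    non-PGCC.  Dead and debris records keep their classes.  With
    ``assume_live=True`` (time-lapse mode, no viability stains) every
    non-debris record is treated as live.
    """
    if params is None:
        params = ClassificationParams()
    out = records.copy()
    if assume_live:
        out.loc[out["ploidy_class"] != "debris", "viability"] = "live"
    thr_px = resolve_area_threshold(params, magnification, pixel_size_um)
    live = (out["viability"] == "live") & (out["ploidy_class"] != "debris")
    is_pgcc = out["area_px"] > thr_px
    out.loc[live, "ploidy_class"] = np.where(is_pgcc[live], "pgcc", "non_pgcc")
    return out
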