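"""Time-lapse population dynamics: per-frame PGCC/non-PGCC counts from a
nuclear-RFP channel, greedy nearest-neighbor track linking, and detection of
non-PGCC -> PGCC transitions.

Viability stains perturb live-cell imaging, so time-lapse acquisitions carry
only a transfected nuclear-RFP marker; every non-debris nucleus is treated as
live and classified by area alone.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import ClassificationParams, classify_pgcc, resolve_area_threshold
from .io import MultiChannelField
from .segmentation import SegmentationParams, segment_field

DEFAULT_PERSISTENCE_FRAMES = 3


@dataclasses.dataclass
class TimeSeries:
    """Framewise counts; times in minutes since the start, strictly increasing."""

    times: np.ndarray
    n_non_pgcc: np.ndarray
    n_pgcc: np.ndarray
    field_id: str = "timelapse"
    frame_records: Optional[list[pd.DataFrame]] = dataclasses.field(
        default=None, repr=False
    )

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.n_non_pgcc = np.asarray(self.n_non_pgcc, dtype=int)
        self.n_pgcc = np.asarray(self.n_pgcc, dtype=int)
        if not (len(self.times) == len(self.n_non_pgcc) == len(self.n_pgcc)):
            raise ValueError("times and count arrays must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "n_non_pgcc": self.n_non_pgcc,
                "n_pgcc": self.n_pgcc,
            }
        )


@dataclasses.dataclass
class Track:
    """One nucleus followed across frames.

    ``points`` rows: (frame_index, time_min, row, col, area_px).
    """

    track_id: int
    points: list[tuple[int, float, float, float, int]] = dataclasses.field(
        default_factory=list
    )
    status: str = "ongoing"

    @property
    def frames(self) -> list[int]:
        return [p[0] for p in self.points]

    @property
    def areas(self) -> np.ndarray:
        return np.array([p[4] for p in self.points])


@dataclasses.dataclass
class TransitionEvent:
    track_id: int
    frame_index: int
    time_min: float


def count_frames(
    frames: Sequence[MultiChannelField],
    seg_params: Optional[SegmentationParams] = None,
    class_params: Optional[ClassificationParams] = None,
) -> TimeSeries:
    """Count non-PGCCs and PGCCs per frame of an RFP time-lapse.

    Segmentation runs on the ``rfp`` channel; there is no viability gating
    (all non-debris nuclei count as live).  Frames must be time-ordered with
    strictly increasing timestamps.
    """
    if not frames:
        return TimeSeries(np.array([]), np.array([], int), np.array([], int))
    times = []
    for i, f in enumerate(frames):
        if "rfp" not in f:
            raise ValueError(f"frame {i} ({f.field_id!r}) has no 'rfp' channel")
        t = f.timestamp_min if f.timestamp_min is not None else float(i)
        times.append(t)
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("frame timestamps are not strictly increasing")

    n_non, n_pgcc, per_frame = [], [], []
    for f in frames:
        records, _ = segment_field(f, seg_params, nuclear_channel="rfp")
        records = classify_pgcc(
            records,
            class_params,
            magnification=f.magnification,
            pixel_size_um=f.pixel_size_um,
            assume_live=True,
        )
        n_non.append(int((records["ploidy_class"] == "non_pgcc").sum()))
        n_pgcc.append(int((records["ploidy_class"] == "pgcc").sum()))
        per_frame.append(records)
    return TimeSeries(
        times=times,
        n_non_pgcc=np.array(n_non),
        n_pgcc=np.array(n_pgcc),
        field_id=frames[0].field_id,
        frame_records=per_frame,
    )


def link_tracks(
    frame_records: Sequence[pd.DataFrame],
    times: Sequence[float],
    max_disp: float = 20.0,
    max_gap_frames: int = 1,
    pixel_size_um: Optional[float] = None,
) -> list[Track]:
    """Greedy nearest-neighbor linking of nuclei across frames.

    Candidate links are sorted by centroid distance and accepted greedily;
    links farther than ``max_disp`` (µm when ``pixel_size_um`` is given, else
    pixels) are rejected.  Unmatched previous nuclei persist for up to
    ``max_gap_frames`` frames, then their track is marked ``lost``; unmatched
    current nuclei start new tracks.  Ties break on lower nucleus label, so
    the result is deterministic.
    """
    max_disp_px = max_disp / pixel_size_um if pixel_size_um else max_disp
    tracks: list[Track] = []
    # active: list of (track, last_frame_index)
    active: list[Track] = []
    next_id = 0
    for fi, records in enumerate(frame_records):
        t = float(times[fi])
        recs = records[records["ploidy_class"] != "debris"]
        recs = recs.sort_values("label")
        cur = [
            (int(r.label), float(r.row), float(r.col), int(r.area_px))
            for r in recs.itertuples()
        ]
        # build candidate links (distance, track_idx, cur_idx)
        candidates = []
        for ti, trk in enumerate(active):
            pr, pc = trk.points[-1][2], trk.points[-1][3]
            for ci, (lab, r, c, a) in enumerate(cur):
                d = np.hypot(r - pr, c - pc)
                if d <= max_disp_px:
                    candidates.append((d, trk.track_id, lab, ti, ci))
        candidates.sort()
        used_tracks: set[int] = set()
        used_cur: set[int] = set()
        for d, _, _, ti, ci in candidates:
            if ti in used_tracks or ci in used_cur:
                continue
            used_tracks.add(ti)
            used_cur.add(ci)
            lab, r, c, a = cur[ci]
            active[ti].points.append((fi, t, r, c, a))
        # unmatched current -> new tracks
        for ci, (lab, r, c, a) in enumerate(cur):
            if ci in used_cur:
                continue
            trk = Track(track_id=next_id)
            next_id += 1
            trk.points.append((fi, t, r, c, a))
            tracks.append(trk)
            active.append(trk)
        # expire tracks that have not been matched within the gap allowance
        still_active = []
        for trk in active:
            if fi - trk.points[-1][0] > max_gap_frames:
                trk.status = "lost"
            else:
                still_active.append(trk)
        active = still_active
    return tracks


def detect_transitions(
    tracks: Sequence[Track],
    area_threshold_px: Optional[float] = None,
    class_params: Optional[ClassificationParams] = None,
    magnification: Optional[float] = None,
    pixel_size_um: Optional[float] = None,
    persistence_frames: int = DEFAULT_PERSISTENCE_FRAMES,
) -> list[TransitionEvent]:
    """Detect non-PGCC -> PGCC transitions along tracks.

    A transition is recorded at the first frame where a track's area crosses
    from at-or-below to strictly above the PGCC threshold and stays above for
    at least ``persistence_frames`` consecutive observations (debouncing
    single-frame flicker at the boundary).  At most one event per track;
    transitioned tracks get ``status='transitioned'``.
    """
    if area_threshold_px is None:
        area_threshold_px = resolve_area_threshold(
            class_params or ClassificationParams(),
            magnification=magnification,
            pixel_size_um=pixel_size_um,
        )
    events: list[TransitionEvent] = []
    for trk in tracks:
        areas = trk.areas
        if len(areas) < persistence_frames + 1:
            continue
        above = areas > area_threshold_px
        if above[0]:
            continue  # already a PGCC at track start: no transition to record
        for i in range(1, len(areas) - persistence_frames + 1):
            if not above[i - 1] and above[i] and above[i : i + persistence_frames].all():
                fi, t = trk.points[i][0], trk.points[i][1]
                events.append(TransitionEvent(trk.track_id, fi, t))
                trk.status = "transitioned"
                break
    return events
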