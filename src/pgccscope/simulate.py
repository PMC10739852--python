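"""Synthetic fluorescence-microscopy simulator with exact ground truth.

Renders fields of elliptical nuclei with class-dependent size distributions
(non-PGCC, PGCC, dead, debris), class-dependent live/dead and ROS stain
amplitudes, a smooth background (plane plus low-frequency blobs), Gaussian
PSF blur, and Poisson shot / Gaussian read noise.  Every rendered object is
reported in a ground-truth table, so the whole analysis pipeline can be
validated without real data.

Ground-truth ploidy class is the operational, area-based definition used by
the classifier: class-conditional diameters are sampled from log-normals
truncated away from the 32 µm threshold diameter (non-PGCC below, PGCC
above), emulating the clearly separated populations of treated cultures.
The truncation bounds are parameters, so threshold-overlap studies remain
possible.

Determinism: all randomness flows from ``SimParams.seed`` through
``numpy.random.default_rng`` (PCG64); per-well and per-frame substreams are
derived by hashing the master seed with the well id / frame index, so plate
output does not depend on iteration order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

from .classify import threshold_for_magnification
from .io import MultiChannelField

DEFAULT_PIXEL_SIZE_10X = 0.66  # µm per pixel at 10x: 1875 px ~= 817 µm²


@dataclasses.dataclass
class SimParams:
    """Simulation parameters for one field.

    Sizes are physical (µm) so the same scene description renders at any
    magnification; the default pixel size of 0.66 µm at 10x makes the
    1875 px and 817 µm² PGCC thresholds coincide.  Intensity amplitudes are
    (median, sigma_log) log-normal pairs in raw camera units.
    """

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_10X
    magnification: float = 10.0
    n_non_pgcc: int = 90
    n_pgcc: int = 10
    n_dead: int = 5
    n_debris: int = 10
    non_pgcc_diameter_um: tuple[float, float] = (15.0, 0.15)
    pgcc_diameter_um: tuple[float, float] = (40.0, 0.10)
    non_pgcc_diameter_range_um: tuple[float, float] = (6.0, 28.0)
    pgcc_diameter_range_um: tuple[float, float] = (36.0, 80.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.6)
    min_separation_um: float = 4.0
    nuclei_amplitude: tuple[float, float] = (3000.0, 0.1)
    live_amplitude_live: tuple[float, float] = (2000.0, 0.2)
    live_amplitude_dead: tuple[float, float] = (60.0, 0.3)
    dead_amplitude_dead: tuple[float, float] = (2000.0, 0.2)
    dead_amplitude_live: tuple[float, float] = (60.0, 0.3)
    ros_amplitude_non_pgcc: tuple[float, float] = (500.0, 0.25)
    ros_fold_pgcc: float = 3.0
    include_ros: bool = False
    debris_amplitude_factor: float = 3.0
    debris_diameter_um: tuple[float, float] = (1.8, 3.5)
    psf_sigma_px: float = 1.5
    background_level: float = 80.0
    background_slope: tuple[float, float] = (0.005, 0.003)
    n_background_blobs: int = 3
    blob_amplitude: float = 30.0
    blob_sigma_px: float = 150.0
    read_noise_sd: float = 8.0
    shot_noise: bool = True
    gain: float = 1.0
    sensor_max: float = 65535.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_non_pgcc", "n_pgcc", "n_dead", "n_debris"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.min_separation_um < 0:
            raise ValueError("min_separation_um must be >= 0")

    @property
    def pgcc_threshold_px(self) -> int:
        """Pixel-area PGCC threshold at this field's magnification."""
        return threshold_for_magnification(300, 4.0, self.magnification)


TRUTH_COLUMNS = [
    "id", "class", "row", "col", "true_area_px", "true_area_um2",
    "amp_nuclei", "amp_live", "amp_dead", "amp_ros",
]


def _derive_seed(master_seed: int, *tokens) -> int:
    """Deterministic 31-bit substream seed from the master seed and tokens."""
    key = ":".join([str(master_seed), *map(str, tokens)]).encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)


def _sample_lognormal(
    rng: np.random.Generator,
    median: float,
    sigma_log: float,
    n: int,
    bounds: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Log-normal samples, rejection-truncated to *bounds* when given."""
    out = median * np.exp(rng.normal(0.0, sigma_log, size=n))
    if bounds is not None:
        lo, hi = bounds
        bad = (out < lo) | (out > hi)
        attempts = 0
        while bad.any():
            out[bad] = median * np.exp(rng.normal(0.0, sigma_log, size=int(bad.sum())))
            bad = (out < lo) | (out > hi)
            attempts += 1
            if attempts > 1000:
                raise RuntimeError("truncated log-normal sampling did not converge")
    return out


class _Placer:
    """Rejection-sampled non-overlapping placement with a border margin."""

    def __init__(self, shape: tuple[int, int], min_sep_px: float, rng: np.random.Generator):
        self.shape = shape
        self.min_sep_px = min_sep_px
        self.rng = rng
        self.rows = np.empty(0)
        self.cols = np.empty(0)
        self.radii = np.empty(0)

    def place(self, radius_px: float, margin_px: float = 3.0, max_attempts: int = 2000):
        H, W = self.shape
        m = radius_px + margin_px
        if 2 * m >= H or 2 * m >= W:
            raise ValueError("object too large for the image")
        for _ in range(max_attempts):
            r = self.rng.uniform(m, H - m)
            c = self.rng.uniform(m, W - m)
            if len(self.rows):
                d = np.hypot(self.rows - r, self.cols - c)
                if np.any(d < self.radii + radius_px + self.min_sep_px):
                    continue
            self.rows = np.append(self.rows, r)
            self.cols = np.append(self.cols, c)
            self.radii = np.append(self.radii, radius_px)
            return r, c
        raise RuntimeError(
            "could not place all objects at the requested separation; "
            "use a larger image or fewer objects"
        )


def _ellipse_axes(
    diameter_px: float, eccentricity: float
) -> tuple[float, float]:
    """Semi-axes of an ellipse with the area of a *diameter_px* circle."""
    r_eq = diameter_px / 2.0
    # area preserved: a*b = r_eq^2, b/a = sqrt(1 - e^2)
    ratio = np.sqrt(1.0 - eccentricity**2)
    a = r_eq / np.sqrt(ratio)
    b = r_eq * np.sqrt(ratio)
    return a, b


def _render_scene(
    shape: tuple[int, int],
    objects: pd.DataFrame,
) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray]:
    """Rasterize object amplitudes into ideal (noise-free, unblurred) channel
    images.  Returns (channel -> ideal image, label image, area_px array)."""
    H, W = shape
    channels = {
        col[len("amp_"):]: np.zeros((H, W))
        for col in objects.columns
        if col.startswith("amp_")
    }
    labels = np.zeros((H, W), dtype=np.int32)
    areas = np.zeros(len(objects), dtype=int)
    for i, obj in enumerate(objects.itertuples()):
        rr, cc = draw_ellipse(
            obj.row, obj.col, obj.semi_a, obj.semi_b,
            shape=(H, W), rotation=obj.theta,
        )
        areas[i] = len(rr)
        labels[rr, cc] = i + 1
        for ch, img in channels.items():
            img[rr, cc] += getattr(obj, f"amp_{ch}")
    return channels, labels, areas


def _background(shape, params: SimParams, rng: np.random.Generator) -> np.ndarray:
    H, W = shape
    r = np.arange(H)[:, None]
    c = np.arange(W)[None, :]
    bg = params.background_level + params.background_slope[0] * r + params.background_slope[1] * c
    for _ in range(params.n_background_blobs):
        br, bc = rng.uniform(0, H), rng.uniform(0, W)
        amp = params.blob_amplitude * rng.uniform(0.5, 1.0)
        bg = bg + amp * np.exp(
            -((r - br) ** 2 + (c - bc) ** 2) / (2 * params.blob_sigma_px**2)
        )
    return bg


def _apply_camera(
    ideal: np.ndarray, params: SimParams, rng: np.random.Generator
) -> np.ndarray:
    img = params.gain * ideal
    if params.shot_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if params.read_noise_sd > 0:
        img = img + rng.normal(0.0, params.read_noise_sd, size=img.shape)
    return np.clip(img, 0.0, params.sensor_max)


def _build_objects(params: SimParams, rng: np.random.Generator) -> pd.DataFrame:
    """Sample classes, sizes, shapes, positions and amplitudes for one field."""
    px = params.pixel_size_um
    classes = (
        ["non_pgcc"] * params.n_non_pgcc
        + ["pgcc"] * params.n_pgcc
        + ["dead"] * params.n_dead
        + ["debris"] * params.n_debris
    )
    n = len(classes)
    med_np, sig_np = params.non_pgcc_diameter_um
    med_p, sig_p = params.pgcc_diameter_um
    diam_px = np.empty(n)
    k = 0
    for cls, count in (
        ("non_pgcc", params.n_non_pgcc),
        ("pgcc", params.n_pgcc),
        ("dead", params.n_dead),
        ("debris", params.n_debris),
    ):
        if count == 0:
            continue
        if cls == "pgcc":
            d = _sample_lognormal(rng, med_p, sig_p, count, params.pgcc_diameter_range_um) / px
        elif cls == "debris":
            d = rng.uniform(*params.debris_diameter_um, size=count) / px
        else:  # non_pgcc and dead share the non-PGCC size distribution
            d = (
                _sample_lognormal(rng, med_np, sig_np, count, params.non_pgcc_diameter_range_um)
                / px
            )
        diam_px[k : k + count] = d
        k += count

    ecc = rng.uniform(*params.eccentricity_range, size=n)
    theta = rng.uniform(0, np.pi, size=n)
    semi = np.array([_ellipse_axes(d, e) for d, e in zip(diam_px, ecc)]).reshape(n, 2)

    placer = _Placer(params.image_shape, params.min_separation_um / px, rng)
    rows = np.empty(n)
    cols = np.empty(n)
    for i in range(n):
        rows[i], cols[i] = placer.place(semi[i, 0])

    def amps(dist, count):
        return _sample_lognormal(rng, dist[0], dist[1], count)

    amp_nuclei = amps(params.nuclei_amplitude, n)
    amp_live = np.empty(n)
    amp_dead = np.empty(n)
    amp_ros = np.zeros(n)
    cls_arr = np.array(classes)
    is_live = np.isin(cls_arr, ("non_pgcc", "pgcc"))
    is_dead = cls_arr == "dead"
    is_debris = cls_arr == "debris"
    amp_live[is_live] = amps(params.live_amplitude_live, int(is_live.sum()))
    amp_live[is_dead] = amps(params.live_amplitude_dead, int(is_dead.sum()))
    amp_dead[is_dead] = amps(params.dead_amplitude_dead, int(is_dead.sum()))
    amp_dead[is_live] = amps(params.dead_amplitude_live, int(is_live.sum()))
    amp_live[is_debris] = 0.0
    amp_dead[is_debris] = 0.0
    amp_nuclei[is_debris] *= params.debris_amplitude_factor
    if params.include_ros:
        med_r, sig_r = params.ros_amplitude_non_pgcc
        npgcc = cls_arr == "non_pgcc"
        pgcc = cls_arr == "pgcc"
        amp_ros[npgcc | is_dead] = amps(
            (med_r, sig_r), int((npgcc | is_dead).sum())
        )
        amp_ros[pgcc] = amps((med_r * params.ros_fold_pgcc, sig_r), int(pgcc.sum()))

    objects = pd.DataFrame(
        {
            "id": np.arange(n),
            "class": cls_arr,
            "row": rows,
            "col": cols,
            "semi_a": semi[:, 0],
            "semi_b": semi[:, 1],
            "theta": theta,
            "amp_nuclei": amp_nuclei,
            "amp_live": amp_live,
            "amp_dead": amp_dead,
        }
    )
    if params.include_ros:
        objects["amp_ros"] = amp_ros
    return objects


def simulate_field(
    params: SimParams,
    channel_names: Optional[Sequence[str]] = None,
    return_labels: bool = False,
):
    """Render one multichannel field with its ground-truth table.

    Returns ``(field, truth)`` — or ``(field, truth, label_image)`` with
    ``return_labels=True``, where the label image is the exact pre-blur,
    pre-noise object raster (``true_area_px`` is its per-object pixel count).
    Identical parameters (including seed) give bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    objects = _build_objects(params, rng)
    ideal_channels, labels, areas = _render_scene(params.image_shape, objects)
    if channel_names is not None:
        ideal_channels = {ch: ideal_channels[ch] for ch in channel_names}

    noise_rng = np.random.default_rng(_derive_seed(params.seed, "camera"))
    channels = {}
    for ch, ideal in ideal_channels.items():
        blurred = gaussian_filter(ideal, params.psf_sigma_px)
        bg = _background(params.image_shape, params, noise_rng)
        channels[ch] = _apply_camera(blurred + bg, params, noise_rng)

    px2 = params.pixel_size_um**2
    truth = pd.DataFrame(
        {
            "id": objects["id"],
            "class": objects["class"],
            "row": objects["row"],
            "col": objects["col"],
            "true_area_px": areas,
            "true_area_um2": areas * px2,
            "amp_nuclei": objects["amp_nuclei"],
            "amp_live": objects["amp_live"],
            "amp_dead": objects["amp_dead"],
            "amp_ros": objects.get("amp_ros", pd.Series(np.zeros(len(objects)))),
        }
    )
    field = MultiChannelField(
        channels=channels,
        magnification=params.magnification,
        pixel_size_um=params.pixel_size_um,
        field_id=f"sim-{params.seed}",
    )
    if return_labels:
        return field, truth, labels
    return field, truth


# ---------------------------------------------------------------------------
# Plates
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class PlateCondition:
    """One plate condition: count multipliers applied to the base SimParams."""

    name: str
    compound: str = ""
    concentration: float = 0.0
    n_replicates: int = 3
    non_pgcc_mult: float = 1.0
    pgcc_mult: float = 1.0
    dead_mult: float = 1.0

    def __post_init__(self) -> None:
        if not self.compound:
            self.compound = self.name


def _well_ids(n: int) -> list[str]:
    ids = []
    for row in "ABCDEFGHIJKLMNOP":
        for col in range(1, 25):
            ids.append(f"{row}{col:02d}")
            if len(ids) == n:
                return ids
    raise ValueError("plate layouts above 384 wells are not supported")


def simulate_plate(
    base_params: SimParams,
    conditions: Sequence[PlateCondition],
    control_condition: str,
    out_dir: str | Path,
    seed: int,
) -> dict:
    """Write a simulated plate: per-well TIFF channels, a layout YAML that
    :func:`pgccscope.io.read_plate` accepts, and a JSON manifest with
    per-well ground-truth counts.

    Well counts are Poisson-sampled around ``base counts x condition
    multiplier`` (replicate-to-replicate biological variability).  Per-well
    seeds derive from the master seed and the well id, so output is
    independent of iteration order.
    """
    if control_condition not in {c.name for c in conditions}:
        raise ValueError(f"control condition {control_condition!r} not in conditions")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_wells = sum(c.n_replicates for c in conditions)
    ids = _well_ids(n_wells)

    layout_wells = {}
    manifest_wells = {}
    i = 0
    for cond in conditions:
        for rep in range(1, cond.n_replicates + 1):
            well_id = ids[i]
            i += 1
            wseed = _derive_seed(seed, "well", well_id)
            wrng = np.random.default_rng(wseed)
            expected = {
                "n_non_pgcc": base_params.n_non_pgcc * cond.non_pgcc_mult,
                "n_pgcc": base_params.n_pgcc * cond.pgcc_mult,
                "n_dead": base_params.n_dead * cond.dead_mult,
                "n_debris": float(base_params.n_debris),
            }
            realized = {k: int(wrng.poisson(v)) for k, v in expected.items()}
            wparams = dataclasses.replace(base_params, seed=wseed, **realized)
            field, truth = simulate_field(wparams)
            images = {}
            for ch, img in field.channels.items():
                fname = f"{well_id}_{ch}.tif"
                tifffile.imwrite(
                    out / fname, np.clip(img, 0, 65535).astype(np.uint16)
                )
                images[ch] = fname
            layout_wells[well_id] = {
                "condition": cond.name,
                "compound": cond.compound,
                "concentration": cond.concentration,
                "replicate": rep,
                "images": images,
            }
            manifest_wells[well_id] = {
                "condition": cond.name,
                "replicate": rep,
                "expected": expected,
                "realized": realized,
            }

    layout = {
        "magnification": base_params.magnification,
        "pixel_size_um": base_params.pixel_size_um,
        "control_condition": control_condition,
        "wells": layout_wells,
    }
    with open(out / "layout.yaml", "w") as fh:
        yaml.safe_dump(layout, fh, sort_keys=True)
    manifest = {"seed": seed, "wells": manifest_wells}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def simulate_count_screen(
    n_compounds: int,
    n_replicates: int,
    control_mean_non_pgcc: float,
    control_mean_pgcc: float,
    seed: int,
    non_pgcc_mults: Optional[Sequence[float]] = None,
    pgcc_mults: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Simulate per-well counts for a screen without rendering images.

    Counts are Poisson around the condition means.  With no multipliers all
    compounds are inactive (null calibration); per-compound multipliers plant
    effects.  Returns a well-summary table for :func:`compare_conditions`.
    """
    rng = np.random.default_rng(seed)
    non_m = non_pgcc_mults if non_pgcc_mults is not None else [1.0] * n_compounds
    pgcc_m = pgcc_mults if pgcc_mults is not None else [1.0] * n_compounds
    rows = []
    for rep in range(1, n_replicates + 1):
        rows.append(
            {
                "well_id": f"CTRL-{rep}", "condition": "control", "compound": "control",
                "concentration": 0.0, "replicate": rep,
                "n_non_pgcc": int(rng.poisson(control_mean_non_pgcc)),
                "n_pgcc": int(rng.poisson(control_mean_pgcc)),
                "n_dead": 0, "n_debris": 0,
            }
        )
    for ci in range(n_compounds):
        name = f"compound-{ci:04d}"
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "well_id": f"{name}-{rep}", "condition": name, "compound": name,
                    "concentration": 1.0, "replicate": rep,
                    "n_non_pgcc": int(rng.poisson(control_mean_non_pgcc * non_m[ci])),
                    "n_pgcc": int(rng.poisson(control_mean_pgcc * pgcc_m[ci])),
                    "n_dead": 0, "n_debris": 0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Time-lapse
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TimelapseKinetics:
    """Population kinetics for a simulated time-lapse.

    Transitioning nuclei grow exponentially in area (``growth_area_factor``
    per frame) along a trajectory phased so the true threshold crossing falls
    midway between two frames, giving a symmetric area margin at the
    adjacent frames.  ``death_frames`` maps nucleus id -> frame after which
    the nucleus disappears (RFP loss on death).
    """

    n_frames: int = 48
    interval_min: float = 30.0
    motion_sigma_um: float = 1.0
    n_transitions: int = 0
    transition_frames: Optional[Sequence[int]] = None
    growth_area_factor: float = 1.15
    pgcc_target_diameter_um: float = 45.0
    death_frames: dict[int, int] = dataclasses.field(default_factory=dict)


def simulate_timelapse(
    params: SimParams, kinetics: TimelapseKinetics
) -> tuple[list[MultiChannelField], list[pd.DataFrame], pd.DataFrame]:
    """Simulate a nuclear-RFP time-lapse sequence.

    Returns ``(frames, per-frame truth tables, transition table)``.  Truth
    class per frame is area-based (PGCC iff rendered area strictly exceeds
    the pixel threshold at this magnification); the transition table holds,
    for each scheduled transition, the first frame whose rendered area is
    above threshold.
    """
    rng = np.random.default_rng(params.seed)
    base = dataclasses.replace(params, n_dead=0, n_debris=0)
    objects = _build_objects(base, rng)
    n = len(objects)
    thr_px = params.pgcc_threshold_px
    thr_diam_px = 2.0 * np.sqrt(thr_px / np.pi)

    n_tr = kinetics.n_transitions
    if n_tr > params.n_non_pgcc:
        raise ValueError("more transitions scheduled than non-PGCCs available")
    non_idx = np.flatnonzero(objects["class"].to_numpy() == "non_pgcc")
    trans_idx = rng.choice(non_idx, size=n_tr, replace=False) if n_tr else np.array([], int)
    if kinetics.transition_frames is not None:
        sched = np.asarray(kinetics.transition_frames, dtype=int)
        if len(sched) != n_tr:
            raise ValueError("transition_frames length must equal n_transitions")
    else:
        # keep scheduled crossings away from both ends so growth is visible
        # before the crossing and persistence frames exist after it
        lo = max(1, min(6, kinetics.n_frames // 3))
        hi = max(lo + 1, kinetics.n_frames - 5)
        sched = np.sort(rng.integers(lo, hi, size=n_tr))
    if n_tr and (sched.min() < 1 or sched.max() >= kinetics.n_frames):
        raise ValueError("transition frames must lie inside the sequence")

    growth_d = np.sqrt(kinetics.growth_area_factor)  # per-frame diameter factor
    target_d_px = kinetics.pgcc_target_diameter_um / params.pixel_size_um
    base_a = objects["semi_a"].to_numpy().copy()
    base_b = objects["semi_b"].to_numpy().copy()
    base_d = 2.0 * np.sqrt(base_a * base_b)  # area-equivalent diameter

    # re-place every nucleus using its maximal (end-of-growth) radius so grown
    # cells never clip at the border or collide with stationary neighbors
    max_scale = np.ones(n)
    max_scale[trans_idx] = np.maximum(target_d_px / base_d[trans_idx], 1.0)
    placer = _Placer(
        params.image_shape, params.min_separation_um / params.pixel_size_um, rng
    )
    for i in range(n):
        objects.loc[i, ["row", "col"]] = placer.place(base_a[i] * max_scale[i])

    positions = objects[["row", "col"]].to_numpy().copy()
    step_px = kinetics.motion_sigma_um / params.pixel_size_um
    H, W = params.image_shape
    min_sep_px = params.min_separation_um / params.pixel_size_um

    frames: list[MultiChannelField] = []
    truths: list[pd.DataFrame] = []
    rendered_areas = np.zeros((kinetics.n_frames, n), dtype=int)
    alive = np.ones(n, dtype=bool)
    # the background structure (illumination plane + blobs) is a property of
    # the optics and stays fixed across the sequence; only noise is per-frame
    static_bg = _background(
        params.image_shape, params,
        np.random.default_rng(_derive_seed(params.seed, "background")),
    )

    for k in range(kinetics.n_frames):
        for oid, death_frame in kinetics.death_frames.items():
            if k >= death_frame:
                alive[oid] = False
        # diameters this frame
        diam = base_d.copy()
        for j, (oi, f) in enumerate(zip(trans_idx, sched)):
            d = thr_diam_px * growth_d ** (k - (f - 0.5))
            diam[oi] = float(np.clip(d, base_d[oi], target_d_px))
        scale = diam / base_d
        # motion with soft-core rejection: nuclei jostle but never touch
        if k > 0 and step_px > 0:
            for i in range(n):
                if not alive[i]:
                    continue
                for _ in range(10):
                    cand = positions[i] + rng.normal(0, step_px, size=2)
                    m = base_a[i] * max_scale[i] + 3.0
                    if not (m <= cand[0] <= H - m and m <= cand[1] <= W - m):
                        continue
                    others = np.flatnonzero(alive)
                    others = others[others != i]
                    if len(others):
                        d2 = np.hypot(
                            positions[others, 0] - cand[0],
                            positions[others, 1] - cand[1],
                        )
                        # separation against maximal radii: growth can never
                        # push two placed nuclei into contact
                        lim = (
                            base_a[others] * max_scale[others]
                            + base_a[i] * max_scale[i]
                            + min_sep_px
                        )
                        if np.any(d2 < lim):
                            continue
                    positions[i] = cand
                    break

        frame_objects = objects.copy()
        frame_objects["row"] = positions[:, 0]
        frame_objects["col"] = positions[:, 1]
        frame_objects["semi_a"] = base_a * scale
        frame_objects["semi_b"] = base_b * scale
        frame_objects = frame_objects.rename(columns={"amp_nuclei": "amp_rfp"})[
            ["id", "class", "row", "col", "semi_a", "semi_b", "theta", "amp_rfp"]
        ]
        frame_objects = frame_objects[alive].reset_index(drop=True)
        ideal, labels, areas = _render_scene(params.image_shape, frame_objects)
        noise_rng = np.random.default_rng(_derive_seed(params.seed, "frame", k))
        blurred = gaussian_filter(ideal["rfp"], params.psf_sigma_px)
        rfp = _apply_camera(blurred + static_bg, params, noise_rng)
        frames.append(
            MultiChannelField(
                channels={"rfp": rfp},
                magnification=params.magnification,
                pixel_size_um=params.pixel_size_um,
                field_id=f"sim-{params.seed}-t{k}",
                timestamp_min=k * kinetics.interval_min,
            )
        )
        ids_alive = frame_objects["id"].to_numpy()
        rendered_areas[k, ids_alive] = areas
        truths.append(
            pd.DataFrame(
                {
                    "id": ids_alive,
                    "class": np.where(areas > thr_px, "pgcc", "non_pgcc"),
                    "row": frame_objects["row"],
                    "col": frame_objects["col"],
                    "true_area_px": areas,
                    "true_area_um2": areas * params.pixel_size_um**2,
                }
            )
        )

    trans_rows = []
    for oi, f in zip(trans_idx, sched):
        above = rendered_areas[:, oi] > thr_px
        first = int(np.argmax(above)) if above.any() else -1
        trans_rows.append(
            {
                "id": int(oi),
                "scheduled_frame": int(f),
                "true_frame": first,
                "true_time_min": first * kinetics.interval_min if first >= 0 else np.nan,
            }
        )
    transitions = pd.DataFrame(
        trans_rows, columns=["id", "scheduled_frame", "true_frame", "true_time_min"]
    )
    return frames, truths, transitions


# ---------------------------------------------------------------------------
# Robustness harness
# ---------------------------------------------------------------------------


def robustness_sweep(
    params: SimParams,
    amplitude_factors: Sequence[float] = (0.5, 1.0, 2.0),
    gain_factors: Sequence[float] = (0.5, 1.0, 2.0),
) -> pd.DataFrame:
    """Recovered class counts under staining-amplitude and exposure-gain
    perturbations.

    Staining factors scale the per-class stain amplitude medians (emulating
    staining concentration); gain factors scale the camera gain (emulating
    exposure time).  One row per combination with the recovered counts, for
    checking that classification is insensitive to experimental conditions.
    """
    from .quantify import analyze_field  # local import: avoids a module cycle

    rows = []
    for af in amplitude_factors:
        for gf in gain_factors:
            p = dataclasses.replace(
                params,
                nuclei_amplitude=(params.nuclei_amplitude[0] * af, params.nuclei_amplitude[1]),
                live_amplitude_live=(params.live_amplitude_live[0] * af, params.live_amplitude_live[1]),
                dead_amplitude_dead=(params.dead_amplitude_dead[0] * af, params.dead_amplitude_dead[1]),
                gain=params.gain * gf,
            )
            field, _ = simulate_field(p)
            records = analyze_field(field)
            rows.append(
                {
                    "amplitude_factor": af,
                    "gain_factor": gf,
                    "n_non_pgcc": int((records["ploidy_class"] == "non_pgcc").sum()),
                    "n_pgcc": int((records["ploidy_class"] == "pgcc").sum()),
                    "n_dead": int(
                        (
                            (records["viability"] == "dead")
                            & (records["ploidy_class"] != "debris")
                        ).sum()
                    ),
                }
            )
    return pd.DataFrame(rows)
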