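"""Reading multichannel fields and plate layouts; writing tabular outputs.

Images are single-plane grayscale TIFFs, one file per channel.  A plate layout
is a YAML file mapping wells to experimental conditions and channel images::

    magnification: 10
    pixel_size_um: 0.66
    control_condition: DMSO
    wells:
      B02:
        condition: DMSO
        compound: DMSO
        concentration: 0.0
        replicate: 1
        images: {nuclei: B02_dapi.tif, live: B02_fitc.tif, dead: B02_tritc.tif}

Channel names are normalized to the fixed vocabulary
``{nuclei, live, dead, ros, rfp}`` (common stain/filter aliases such as
``dapi``/``hoechst``, ``fitc``/``calcein``, ``tritc``/``ethidium``, ``cy5``
are accepted).  Pixel values are loaded at native bit depth and converted to
float without any rescaling.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterator, Mapping, Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .records import RECORD_COLUMNS, validate_records

CHANNEL_NAMES = ("nuclei", "live", "dead", "ros", "rfp")

_CHANNEL_ALIASES = {
    "nuclei": "nuclei", "nucleus": "nuclei", "hoechst": "nuclei", "dapi": "nuclei",
    "live": "live", "fitc": "live", "calcein": "live", "green": "live",
    "dead": "dead", "tritc": "dead", "ethidium": "dead", "red": "dead",
    "ros": "ros", "cy5": "ros", "cellrox": "ros",
    "rfp": "rfp", "nls-rfp": "rfp", "nuclear_rfp": "rfp",
}


def normalize_channel_name(name: str) -> str:
    key = name.strip().lower()
    if key not in _CHANNEL_ALIASES:
        raise ValueError(
            f"unknown channel name {name!r}; expected one of {sorted(set(_CHANNEL_ALIASES))}"
        )
    return _CHANNEL_ALIASES[key]


@dataclasses.dataclass
class MultiChannelField:
    """Co-registered single-plane channel images plus acquisition metadata.

    All channel rasters share one height x width; intensities are raw camera
    units as floats.
    """

    channels: dict[str, np.ndarray]
    magnification: float
    pixel_size_um: Optional[float] = None
    field_id: str = "field"
    timestamp_min: Optional[float] = None

    def __post_init__(self) -> None:
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        shapes = {name: img.shape for name, img in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        self.channels = {
            name: np.asarray(img, dtype=float) for name, img in self.channels.items()
        }

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def __contains__(self, channel: str) -> bool:
        return channel in self.channels

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]


@dataclasses.dataclass
class WellInfo:
    well_id: str
    condition: str
    compound: str
    concentration: float
    replicate: int
    images: dict[str, str]


@dataclasses.dataclass
class PlateLayout:
    """Well -> condition/compound/concentration and channel -> file mapping."""

    wells: dict[str, WellInfo]
    control_condition: str
    magnification: float
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        conditions = {w.condition for w in self.wells.values()}
        if self.control_condition not in conditions:
            raise ValueError(
                f"control condition {self.control_condition!r} appears in no well"
            )
        for w in self.wells.values():
            if w.concentration < 0:
                raise ValueError(f"well {w.well_id}: negative concentration")


def read_field(
    paths: Mapping[str, str | Path],
    magnification: float,
    pixel_size_um: Optional[float] = None,
    field_id: str = "field",
    timestamp_min: Optional[float] = None,
) -> MultiChannelField:
    """Load one multichannel field from per-channel TIFF files.

    The nuclear channel (or ``rfp`` for time-lapse data) must be present.
    Raises ``ValueError`` on a missing nuclear channel or mismatched raster
    shapes, ``IOError`` on unreadable files.
    """
    channels: dict[str, np.ndarray] = {}
    for name, path in paths.items():
        cname = normalize_channel_name(name)
        try:
            img = tifffile.imread(str(path))
        except (OSError, ValueError) as exc:
            raise IOError(f"cannot read TIFF for channel {cname!r}: {path}") from exc
        img = np.asarray(img)
        if img.ndim != 2:
            raise IOError(f"channel {cname!r} ({path}) is not a single-plane image")
        channels[cname] = img.astype(float)
    if "nuclei" not in channels and "rfp" not in channels:
        raise ValueError("missing nuclear channel: provide 'nuclei' (Hoechst) or 'rfp'")
    ref_name = next(iter(channels))
    ref_shape = channels[ref_name].shape
    for name, img in channels.items():
        if img.shape != ref_shape:
            raise ValueError(
                f"channel {name!r} shape {img.shape} does not match "
                f"{ref_name!r} shape {ref_shape}"
            )
    return MultiChannelField(
        channels=channels,
        magnification=magnification,
        pixel_size_um=pixel_size_um,
        field_id=field_id,
        timestamp_min=timestamp_min,
    )


def read_layout(layout_path: str | Path) -> PlateLayout:
    """Parse a plate-layout YAML file (see module docstring for the dialect)."""
    with open(layout_path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "wells" not in raw:
        raise ValueError(f"layout {layout_path}: expected a mapping with a 'wells' key")
    wells: dict[str, WellInfo] = {}
    seen_paths: set[str] = set()
    for well_id, entry in raw["wells"].items():
        well_id = str(well_id)
        if well_id in wells:
            raise ValueError(f"duplicate well id {well_id!r} in layout")
        images = {
            normalize_channel_name(ch): str(p)
            for ch, p in entry.get("images", {}).items()
        }
        for ch, p in images.items():
            key = p
            if key in seen_paths:
                raise ValueError(
                    f"well {well_id}, channel {ch}: image path {p!r} referenced twice"
                )
            seen_paths.add(key)
        wells[well_id] = WellInfo(
            well_id=well_id,
            condition=str(entry["condition"]),
            compound=str(entry.get("compound", entry["condition"])),
            concentration=float(entry.get("concentration", 0.0)),
            replicate=int(entry.get("replicate", 1)),
            images=images,
        )
    return PlateLayout(
        wells=wells,
        control_condition=str(raw["control_condition"]),
        magnification=float(raw.get("magnification", 10.0)),
        pixel_size_um=(
            float(raw["pixel_size_um"]) if raw.get("pixel_size_um") is not None else None
        ),
    )


def read_plate(
    layout_path: str | Path, image_root: str | Path
) -> Iterator[tuple[str, WellInfo, MultiChannelField]]:
    """Yield ``(well_id, info, field)`` in sorted well-id order.

    All referenced images are checked for existence before the first field is
    loaded, so a missing file fails fast without partial iteration.
    """
    layout = read_layout(layout_path)
    root = Path(image_root)
    for well_id in sorted(layout.wells):
        info = layout.wells[well_id]
        for ch, rel in info.images.items():
            if not (root / rel).exists():
                raise FileNotFoundError(
                    f"well {well_id}, channel {ch}: image {root / rel} not found"
                )
    for well_id in sorted(layout.wells):
        info = layout.wells[well_id]
        paths = {ch: root / rel for ch, rel in info.images.items()}
        field = read_field(
            paths,
            magnification=layout.magnification,
            pixel_size_um=layout.pixel_size_um,
            field_id=well_id,
        )
        yield well_id, info, field


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write a per-nucleus record table to CSV (full float precision).

    ``read_records(write_records(x))`` reproduces ``x``.
    """
    validate_records(records)
    records.to_csv(path, index=False, columns=RECORD_COLUMNS)


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"field_id": str})
    validate_records(df)
    return df


def write_summaries(summaries: pd.DataFrame, path: str | Path) -> None:
    summaries.to_csv(path, index=False)


def read_summaries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"well_id": str, "condition": str, "compound": str})


def write_run_metadata(metadata: dict, path: str | Path) -> None:
    """Write run metadata (parameters, seed, software version) as sorted JSON
    so identical runs produce byte-identical files."""
    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
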