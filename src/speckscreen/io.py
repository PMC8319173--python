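"""File-format glue: TIFF fields, manifests and result tables.

Field images travel as single-plane grayscale TIFFs, one file per
channel, named ``<plate>_<well>_<field>_<channel>.tif`` with channel
``dapi`` (nuclear stain) or ``dsred`` (reporter).  A manifest CSV
(``plate_id, well, field, channel, path``) indexes them for analysis.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

from .imaging import FieldImagePair, WellResult

__all__ = [
    "field_filename",
    "save_field_pair",
    "load_field_pair",
    "build_manifest",
    "load_manifest_fields",
    "well_results_to_frame",
    "write_json",
]

CHANNELS = ("dapi", "dsred")
_NAME_RE = re.compile(r"(?P<plate>[^_]+)_(?P<well>[^_]+)_(?P<field>\d+)_(?P<channel>dapi|dsred)\.tif$")


def field_filename(plate_id: str, well: str, field: int, channel: str) -> str:
    if channel not in CHANNELS:
        raise ValueError(f"channel must be one of {CHANNELS}, got {channel!r}")
    return f"{plate_id}_{well}_{field}_{channel}.tif"


def save_field_pair(
    pair: FieldImagePair, out_dir: Path | str, plate_id: str, well: str, field: int
) -> tuple[Path, Path]:
    """Write the two channels as float32 grayscale TIFFs; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for channel, img in (
        ("dapi", pair.nuclear_channel),
        ("dsred", pair.reporter_channel),
    ):
        p = out / field_filename(plate_id, well, field, channel)
        tifffile.imwrite(p, np.asarray(img, dtype=np.float32))
        paths.append(p)
    return paths[0], paths[1]


def load_field_pair(dapi_path: Path | str, dsred_path: Path | str,
                    pixel_size_um: float) -> FieldImagePair:
    return FieldImagePair(
        nuclear_channel=tifffile.imread(dapi_path),
        reporter_channel=tifffile.imread(dsred_path),
        pixel_size_um=pixel_size_um,
    )


def build_manifest(image_dir: Path | str) -> pd.DataFrame:
    """Index a directory of generator-named TIFFs into a manifest table."""
    rows = []
    for p in sorted(Path(image_dir).glob("*.tif")):
        m = _NAME_RE.match(p.name)
        if m:
            rows.append(
                (m["plate"], m["well"], int(m["field"]), m["channel"], str(p))
            )
    return pd.DataFrame(rows, columns=["plate_id", "well", "field", "channel", "path"])


def load_manifest_fields(
    manifest: pd.DataFrame, pixel_size_um: float
) -> dict[tuple[str, str], list[FieldImagePair]]:
    """Group manifest rows into per-well lists of channel pairs."""
    out: dict[tuple[str, str], list[FieldImagePair]] = {}
    for (plate, well), grp in manifest.groupby(["plate_id", "well"], sort=True):
        pairs = []
        for fld, fgrp in grp.groupby("field", sort=True):
            by_channel = dict(zip(fgrp["channel"], fgrp["path"]))
            missing = set(CHANNELS) - set(by_channel)
            if missing:
                raise ValueError(
                    f"manifest: {plate}/{well} field {fld} missing channels {sorted(missing)}"
                )
            pairs.append(
                load_field_pair(by_channel["dapi"], by_channel["dsred"], pixel_size_um)
            )
        out[(str(plate), str(well))] = pairs
    return out


def well_results_to_frame(results: Iterable[WellResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def write_json(obj, path: Path | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)
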