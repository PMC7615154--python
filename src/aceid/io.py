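"""File formats: plate maps (CSV), well images (TIFF + sidecar JSON),
ground truth (JSON), feature tables (CSV/Parquet).

All tabular outputs are UTF-8 CSV with '.' decimal separator; floats are
written with 17 significant digits so that identical runs produce
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from aceid.design import parse_well
from aceid.simulate import ImageSet, WellGroundTruth

__all__ = [
    "read_plate_map",
    "write_plate_map",
    "write_well_tiff",
    "read_well_tiff",
    "write_truth",
    "read_truth",
    "write_table",
    "read_table",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.17g"

PLATE_MAP_COLUMNS = ["plate", "well", "condition_id", "role", "replicate_id", "seeded_cells"]


def write_plate_map(df: pd.DataFrame, path) -> None:
    missing = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate map missing columns: {missing}")
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_plate_map(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate map {path} missing columns: {missing}")
    for w in df["well"]:
        parse_well(str(w))
    return df


def write_well_tiff(image_set: ImageSet, path, *, assay: str = "") -> None:
    """Single-plane two-channel 16-bit TIFF (channel order nuclei, marker)
    with a sidecar ``<name>.json`` recording pixel size and assay."""
    path = Path(path)
    stack = np.stack([image_set.nuclei, image_set.marker]).astype(np.uint16)
    tifffile.imwrite(path, stack)
    sidecar = {"pixel_size_um": image_set.pixel_size_um, "assay": assay, "channels": ["nuclei", "marker"]}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_well_tiff(path) -> tuple:
    """Read a well TIFF; returns ``(ImageSet, sidecar dict)``."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValueError(f"{path}: expected a 2-channel single-plane image, got {stack.shape}")
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    return (
        ImageSet(
            nuclei=stack[0],
            marker=stack[1],
            pixel_size_um=float(sidecar.get("pixel_size_um", 1.0)),
        ),
        sidecar,
    )


def write_truth(truth: WellGroundTruth, path) -> None:
    Path(path).write_text(truth.to_json())


def read_truth(path) -> WellGroundTruth:
    return WellGroundTruth.from_json(Path(path).read_text())


def write_table(df: pd.DataFrame, path, *, parquet: bool = False) -> None:
    path = Path(path)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    if parquet:
        df.to_parquet(path.with_suffix(".parquet"))


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)
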