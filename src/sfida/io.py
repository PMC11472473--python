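"""File formats: multi-page 16-bit TIFF stacks, plate-layout CSVs, and
JSON serialisation of calibration results.

Layout CSV columns (fixed schema): well_id, sample_id, sample_kind,
nominal_concentration_fM, replicate_group.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .calibration import CalibrationCurve, LodEstimate
from .errors import DataError
from .images import TirfmImage

__all__ = [
    "write_stack",
    "read_stack",
    "write_layout",
    "read_layout",
    "write_calibration_json",
]

LAYOUT_COLUMNS = [
    "well_id",
    "sample_id",
    "sample_kind",
    "nominal_concentration_fM",
    "replicate_group",
]


def write_stack(path: str | Path, images: Sequence[TirfmImage]) -> None:
    """Write a well's frames as a multi-page 16-bit grayscale TIFF."""
    arr = np.stack([im.pixels for im in images]).astype(np.uint16)
    tifffile.imwrite(str(path), arr, photometric="minisblack")


def read_stack(path: str | Path, well_id: str = "", bit_depth: int = 14) -> list[TirfmImage]:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise DataError(f"{path}: expected a 2-D or 3-D grayscale TIFF")
    return [
        TirfmImage(pixels=page, well_id=well_id, position_index=i + 1, bit_depth=bit_depth)
        for i, page in enumerate(arr)
    ]


def write_layout(path: str | Path, layout: pd.DataFrame) -> None:
    missing = [c for c in LAYOUT_COLUMNS if c not in layout.columns]
    if missing:
        raise DataError(f"layout is missing columns: {missing}")
    layout[LAYOUT_COLUMNS].to_csv(path, index=False)


def read_layout(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: layout is missing columns: {missing}")
    return df


def write_calibration_json(
    path: str | Path, curve: CalibrationCurve | None, lod: LodEstimate | None
) -> None:
    payload: dict = {"calibration": None, "lod": None}
    if curve is not None:
        payload["calibration"] = curve.to_dict()
    if lod is not None:
        payload["lod"] = {
            "bc_mean_pixel_count": lod.bc_mean_pixel_count,
            "bc_sd": lod.bc_sd,
            "n_bc_replicates": lod.n_bc_replicates,
            "lod_pixel": lod.lod_pixel,
            "lod_fM": lod.lod_fM,
        }
    Path(path).write_text(json.dumps(payload, indent=2))
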