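"""File formats: grayscale rasters, label rasters, boundary CSVs, models."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import BoundaryCurve, BScanImage
from .graphcut import LabelMap
from .mixture import LabelMask, MixtureModel

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_labelmap",
    "write_labelmap",
    "read_boundary_csv",
    "write_boundary_csv",
    "read_model",
    "write_model",
]


def read_image(path: str | Path, **kwargs) -> BScanImage:
    """Read a grayscale B-scan raster (TIFF/PNG, 8/16-bit or float)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse an RGB(A) raster to one channel
        arr = arr[..., 0]
    return BScanImage(arr.astype(float), **kwargs)


def write_image(path: str | Path, image: BScanImage) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image.pixels.astype(np.float32))
    else:
        arr = np.clip(image.pixels, 0, np.iinfo(np.uint16).max)
        iio.imwrite(path, arr.astype(np.uint16))


def read_mask(path: str | Path) -> LabelMask:
    """Read a {0,1,2,3}-valued label raster."""
    return LabelMask(np.asarray(iio.imread(path)))


def write_mask(path: str | Path, mask: LabelMask) -> None:
    iio.imwrite(Path(path), mask.labels.astype(np.uint8))


def read_labelmap(path: str | Path) -> LabelMap:
    return LabelMap(np.asarray(iio.imread(path)).astype(np.int64))


def write_labelmap(path: str | Path, labels: LabelMap) -> None:
    iio.imwrite(Path(path), labels.labels.astype(np.uint8))


def read_boundary_csv(path: str | Path) -> BoundaryCurve:
    """Read a boundary curve stored as ``column,row`` CSV."""
    df = pd.read_csv(path)
    df = df.sort_values("column")
    return BoundaryCurve(df["row"].to_numpy())


def write_boundary_csv(path: str | Path, curve: BoundaryCurve) -> None:
    pd.DataFrame(
        {"column": np.arange(curve.n_cols), "row": curve.rows}
    ).to_csv(path, index=False)


def read_model(path: str | Path) -> MixtureModel:
    return MixtureModel.from_json(Path(path).read_text())


def write_model(path: str | Path, model: MixtureModel) -> None:
    Path(path).write_text(model.to_json())
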