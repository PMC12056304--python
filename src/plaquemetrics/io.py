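"""Calibrated image and table I/O.

Conventions used throughout the package:

* raster coordinates are (row, col), 0-based, origin at the top-left;
* physical quantities are always micron-based (`pixel_size_um` carries the
  calibration; areas in µm², distances in µm, densities per mm² of *region*
  area, not field area);
* tables are plain CSV, UTF-8, '.' decimal separator, stable column order,
  floats written with 9 significant digits.
"""

from __future__ import annotations

import datetime as _dt
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import DataError

MODALITIES = ("brightfield", "fluorescence", "mask")

#: CSV float format — repr with 9 significant digits survives a write/read
#: roundtrip for every value the pipeline emits.
FLOAT_FORMAT = "%.9g"


@dataclass
class ImagePlane:
    """A calibrated raster: 2D (single channel) or 2D×C pixel array.

    Parameters
    ----------
    data:
        ``(H, W)`` or ``(H, W, C)`` array; unsigned 8/16-bit or floating.
    pixel_size_um:
        Physical side length of one pixel in µm (must be > 0).
    modality:
        One of ``brightfield``, ``fluorescence``, ``mask``.
    channel_names:
        One name per channel; defaults to ``ch0..chN``.
    """

    data: np.ndarray
    pixel_size_um: float
    modality: str
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise DataError(f"image must be 2D or 2D×C, got ndim={self.data.ndim}")
        if not self.pixel_size_um > 0:
            raise DataError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.modality not in MODALITIES:
            raise DataError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise DataError(
                f"{len(self.channel_names)} channel names for {self.n_channels} channels"
            )
        if self.modality == "mask" and not (
            self.data.dtype == bool or np.issubdtype(self.data.dtype, np.integer)
        ):
            raise DataError("mask modality requires a boolean or integer-labelled raster")

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[2]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def channel(self, name: str) -> np.ndarray:
        """Return the 2D plane for a named channel."""
        if name not in self.channel_names:
            raise DataError(f"no channel {name!r}; have {self.channel_names}")
        if self.data.ndim == 2:
            return self.data
        return self.data[:, :, self.channel_names.index(name)]

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2


@dataclass
class RegionLabelMap:
    """Integer label raster naming anatomical regions (0 = background)."""

    labels: np.ndarray
    names: dict[int, str]
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise DataError("region labels must be integers")
        if self.labels.min() < 0:
            raise DataError("region labels must be >= 0 (0 = background)")
        present = set(np.unique(self.labels)) - {0}
        unnamed = present - set(self.names)
        if unnamed:
            raise DataError(f"unnamed region labels: {sorted(unnamed)}")

    def region_area_um2(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.pixel_size_um**2

    def region_area_mm2(self, label: int) -> float:
        return self.region_area_um2(label) / 1e6


def read_image(path: str | os.PathLike, pixel_size_um: float, modality: str) -> ImagePlane:
    """Load a TIFF or PNG image with its calibration attached.

    Bit depth is preserved (16-bit stays 16-bit; no silent downcast).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise DataError(f"image file not found: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        data = tifffile.imread(path)
        # multi-page TIFFs come back (C, H, W); move channels last
        if data.ndim == 3 and data.shape[0] <= 4 and data.shape[0] < data.shape[2]:
            data = np.moveaxis(data, 0, 2)
    elif ext == ".png":
        data = iio.imread(path)
    else:
        raise DataError(f"unsupported image format {ext!r} for {path} (TIFF or PNG)")
    return ImagePlane(data=data, pixel_size_um=pixel_size_um, modality=modality)


def write_image(image: ImagePlane | np.ndarray, path: str | os.PathLike) -> None:
    """Write an image as TIFF (multi-page if multi-channel) or PNG."""
    data = image.data if isinstance(image, ImagePlane) else np.asarray(image)
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in (".tif", ".tiff"):
        if data.ndim == 3:
            tifffile.imwrite(path, np.moveaxis(data, 2, 0), photometric="minisblack")
        else:
            tifffile.imwrite(path, data, photometric="minisblack")
    elif ext == ".png":
        iio.imwrite(path, data)
    else:
        raise DataError(f"unsupported image format {ext!r} for {path}")


def write_table(records, path: str | os.PathLike, columns: list[str] | None = None) -> None:
    """Write records (DataFrame or list of dicts) as a stable CSV.

    An empty record list with known columns yields a header-only file; records
    missing an optional field get an empty cell rather than being dropped.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if columns is None:
            seen: dict[str, None] = {}
            for r in records:
                for k in r:
                    seen.setdefault(k)
            columns = list(seen)
        df = pd.DataFrame.from_records(records, columns=columns)
    if columns is not None:
        df = df.reindex(columns=columns)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT, encoding="utf-8")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise DataError(f"table not found: {path}")
    return pd.read_csv(path)


class RunLog:
    """Minimal plain-text run log with timestamps."""

    def __init__(self, path: str | os.PathLike | None):
        self.path = os.fspath(path) if path is not None else None
        self.lines: list[str] = []

    def info(self, msg: str) -> None:
        stamp = _dt.datetime.now().isoformat(timespec="seconds")
        line = f"[{stamp}] {msg}"
        self.lines.append(line)
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(line + "\n")
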