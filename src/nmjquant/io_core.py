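"""Calibrated image and results-table I/O.

Geometry conventions used throughout the package:

* arrays are row-major, 0-based; a coordinate is ``(row, col)`` with the
  origin at the top-left pixel;
* the physical length of a k-pixel horizontal run is ``k * pixel_size_um``
  micrometres and one pixel covers ``pixel_size_um ** 2`` µm²;
* reading never rescales intensities — integer input is preserved
  bit-exactly, and conversion to floating point happens only inside
  filtering operations.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .errors import DimensionError, FormatError, ParameterError

#: Fixed vocabulary of measurement units used in results tables.
UNITS = frozenset(
    {"px", "px2", "um2", "mm2", "percent", "count", "count_per_mm2", "index", "au"}
)


@dataclass
class CalibratedImage:
    """A single-channel 2D fluorescence image with pixel-size calibration.

    Parameters
    ----------
    pixels
        2D array of non-negative intensities in arbitrary fluorescence
        units. Integer dtypes are kept as-is.
    pixel_size_um
        Physical edge length of one pixel in micrometres (> 0).
    channel
        Free-text channel label, e.g. ``"DAPI"``, ``"S100b"``, ``"aBTX"``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise DimensionError(
                f"expected a non-empty 2D image, got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels.astype(float, copy=False))):
            raise ParameterError("image intensities must be finite")
        if np.min(self.pixels) < 0:
            raise ParameterError("image intensities must be non-negative")
        if not (float(self.pixel_size_um) > 0):
            raise ParameterError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        self.pixel_size_um = float(self.pixel_size_um)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def as_float(self) -> np.ndarray:
        """Floating-point view of the intensities (filtering entry point)."""
        return self.pixels.astype(np.float64, copy=False)


@dataclass
class ResultsTable:
    """Long-format measurement table: one row per (condition, replicate, metric)."""

    rows: list[dict] = field(default_factory=list)

    def add(
        self,
        condition: str,
        replicate: str,
        metric: str,
        value: float,
        units: str,
    ) -> None:
        if units not in UNITS:
            raise ParameterError(f"unknown units {units!r}; allowed: {sorted(UNITS)}")
        value = float(value)
        if not math.isfinite(value):
            raise ParameterError(f"non-finite value for metric {metric!r}")
        self.rows.append(
            {
                "condition": str(condition),
                "replicate": str(replicate),
                "metric": str(metric),
                "value": value,
                "units": units,
            }
        )

    def extend(self, other: "ResultsTable") -> None:
        self.rows.extend(other.rows)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.rows, columns=["condition", "replicate", "metric", "value", "units"]
        )

    def __len__(self) -> int:
        return len(self.rows)


def read_image(
    path: str | Path,
    pixel_size_um: float | None,
    channel: str = "",
    page: int | None = None,
) -> CalibratedImage:
    """Read a single-plane grayscale TIFF or PNG as a :class:`CalibratedImage`.

    ``pixel_size_um`` supplied by the caller always wins; if ``None``, TIFF
    resolution tags are consulted and an error is raised when they are absent.
    Intensities are preserved bit-exactly for integer inputs.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    tag_pixel_size: float | None = None

    if suffix in {".tif", ".tiff"}:
        import tifffile

        with tifffile.TiffFile(path) as tif:
            n_pages = len(tif.pages)
            if n_pages > 1 and page is None:
                raise FormatError(
                    f"{path} has {n_pages} pages; pass an explicit page selector"
                )
            tiff_page = tif.pages[page or 0]
            data = tiff_page.asarray()
            res = tiff_page.tags.get("XResolution")
            unit = tiff_page.tags.get("ResolutionUnit")
            if res is not None and unit is not None:
                num, den = res.value
                if num > 0 and den > 0:
                    px_per_unit = num / den
                    unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit.value))
                    if unit_um is not None:
                        tag_pixel_size = unit_um / px_per_unit
    elif suffix == ".png":
        import imageio.v3 as iio

        data = iio.imread(path)
    else:
        raise FormatError(f"unsupported image format {suffix!r} for {path}")

    if data.ndim == 3:
        if data.shape[2] == 1:
            data = data[:, :, 0]
        else:
            raise FormatError(
                f"{path} has {data.shape[2]} samples per pixel; expected grayscale"
            )

    if pixel_size_um is None:
        pixel_size_um = tag_pixel_size
        if pixel_size_um is None:
            raise ParameterError(
                f"{path} carries no resolution tags; pixel_size_um is required"
            )
    return CalibratedImage(pixels=data, pixel_size_um=pixel_size_um, channel=channel)


def write_image(image: CalibratedImage, path: str | Path) -> None:
    """Write a calibrated image as TIFF (with resolution tags) or PNG."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        import tifffile

        px_per_cm = 10000.0 / image.pixel_size_um
        tifffile.imwrite(
            path,
            image.pixels,
            resolution=(px_per_cm, px_per_cm),
            resolutionunit=3,  # centimetre
        )
    elif suffix == ".png":
        import imageio.v3 as iio

        iio.imwrite(path, image.pixels)
    else:
        raise FormatError(f"unsupported image format {suffix!r} for {path}")


def write_table(table: ResultsTable, path: str | Path) -> None:
    """Write a results table as UTF-8 CSV, rows in input order.

    Floats are serialised with :func:`repr` (shortest round-trip form), so a
    written table re-read with :func:`read_table` reproduces every value
    exactly and repeated writes of the same table are byte-identical.
    """
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["condition", "replicate", "metric", "value", "units"])
        for row in table.rows:
            writer.writerow(
                [
                    row["condition"],
                    row["replicate"],
                    row["metric"],
                    repr(float(row["value"])),
                    row["units"],
                ]
            )


def read_table(path: str | Path) -> ResultsTable:
    """Read a CSV written by :func:`write_table`."""
    table = ResultsTable()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            table.add(
                row["condition"],
                row["replicate"],
                row["metric"],
                float(row["value"]),
                row["units"],
            )
    return table


def check_same_shape(*arrays: Iterable[np.ndarray]) -> None:
    shapes = {np.asarray(a).shape for a in arrays}
    if len(shapes) > 1:
        raise DimensionError(f"shape mismatch: {sorted(shapes)}")
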