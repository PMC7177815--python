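"""GeoTIFF raster I/O and the in-memory scene-stack container.

Single-band GeoTIFF files are written through tifffile with the three
georeferencing tags GDAL and QGIS expect (ModelPixelScale,
ModelTiepoint, GeoKeyDirectory) plus the GDAL_NODATA ASCII tag.  Stacks
of per-date rasters are addressed by a manifest CSV (doy -> file),
matching how per-date satellite products arrive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .crop import CANONICAL_DOYS
from .errors import InvalidInputError

NODATA = -9999.0

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class GeoRef:
    """Axis-aligned georeferencing: map origin of the top-left pixel corner,
    pixel sizes in map units, and an EPSG code (default UTM zone 49N,
    which covers the subtropical rice region the defaults emulate)."""

    origin_x: float = 500000.0
    origin_y: float = 3090000.0
    pixel_width: float = 10.0
    pixel_height: float = 10.0
    epsg: int = 32649


def _geokeys(epsg: int) -> tuple[int, ...]:
    # GeoKeyDirectory: version 1.1.0, 3 keys:
    #   GTModelType = projected, GTRasterType = pixel-is-area, ProjectedCSType = epsg
    return (
        1, 1, 0, 3,
        1024, 0, 1, 1,
        1025, 0, 1, 1,
        3072, 0, 1, epsg,
    )


def write_geotiff(
    path: str | Path,
    array: np.ndarray,
    georef: GeoRef | None = None,
    nodata: float | None = NODATA,
) -> None:
    """Write a single-band raster; NaN cells are stored as the nodata value."""
    arr = np.asarray(array)
    if arr.ndim != 2:
        raise InvalidInputError("write_geotiff expects a 2-D array")
    if np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(np.float32)
        if nodata is not None:
            out = np.where(np.isnan(out), np.float32(nodata), out)
    else:
        out = arr
    georef = georef or GeoRef()
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (georef.pixel_width, georef.pixel_height, 0.0), True),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, georef.origin_x, georef.origin_y, 0.0), True),
        (_TAG_GEOKEYS, "H", 16, _geokeys(georef.epsg), True),
    ]
    if nodata is not None:
        nd = str(int(nodata)) if float(nodata).is_integer() else str(nodata)
        extratags.append((_TAG_GDAL_NODATA, "s", 0, nd, True))
    tifffile.imwrite(str(path), out, extratags=extratags)


def read_geotiff(path: str | Path) -> tuple[np.ndarray, GeoRef, float | None]:
    """Read a single-band raster; float nodata cells come back as NaN."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        tags = page.tags
        scale = tags[_TAG_PIXEL_SCALE].value if _TAG_PIXEL_SCALE in tags else (1.0, 1.0, 0.0)
        tie = tags[_TAG_TIEPOINT].value if _TAG_TIEPOINT in tags else (0, 0, 0, 0.0, 0.0, 0)
        epsg = 0
        if _TAG_GEOKEYS in tags:
            keys = tags[_TAG_GEOKEYS].value
            for k in range(4, len(keys), 4):
                if keys[k] == 3072:
                    epsg = int(keys[k + 3])
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    georef = GeoRef(
        origin_x=float(tie[3]),
        origin_y=float(tie[4]),
        pixel_width=float(scale[0]),
        pixel_height=float(scale[1]),
        epsg=epsg,
    )
    if nodata is not None and np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
        arr[arr == np.float32(nodata)] = np.nan
    return arr, georef, nodata


@dataclass
class SceneStack:
    """One growing season of per-pixel LAI series on a raster grid.

    ``lai`` has shape (20, rows, cols) on the canonical DOY grid;
    non-rice cells are NaN.  Georeferencing is carried through every
    downstream surface untouched.
    """

    year: int
    lai: np.ndarray
    rice_mask: np.ndarray
    doys: tuple[int, ...] = CANONICAL_DOYS
    georef: GeoRef = field(default_factory=GeoRef)
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.lai = np.asarray(self.lai, dtype=float)
        self.rice_mask = np.asarray(self.rice_mask, dtype=bool)
        if tuple(self.doys) != CANONICAL_DOYS:
            raise InvalidInputError("SceneStack must use the canonical DOY grid")
        if self.lai.ndim != 3 or self.lai.shape[0] != len(CANONICAL_DOYS):
            raise InvalidInputError(
                f"lai must be (20, rows, cols), got {self.lai.shape}"
            )
        if self.rice_mask.shape != self.lai.shape[1:]:
            raise InvalidInputError("rice_mask shape must match the raster grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.lai.shape[1:]

    def pixel_series(self) -> np.ndarray:
        """(n_rice, 20) matrix of the masked pixels' series, row-major order."""
        return self.lai[:, self.rice_mask].T


def write_scene(directory: str | Path, stack: SceneStack) -> None:
    """Write a stack as per-date GeoTIFFs plus manifest.csv and mask.tif."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, doy in enumerate(stack.doys):
        name = f"lai_{stack.year}_doy{doy:03d}.tif"
        band = np.where(stack.rice_mask, stack.lai[k], np.nan)
        write_geotiff(directory / name, band, stack.georef, stack.nodata)
        rows.append({"doy": doy, "file": name})
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)
    write_geotiff(
        directory / "mask.tif",
        stack.rice_mask.astype(np.uint8),
        stack.georef,
        nodata=None,
    )


def read_scene(directory: str | Path, year: int) -> SceneStack:
    """Read a stack written by :func:`write_scene` (or laid out the same way)."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    if sorted(manifest["doy"]) != list(CANONICAL_DOYS):
        raise InvalidInputError(
            f"manifest in {directory} must list exactly the canonical DOYs"
        )
    manifest = manifest.sort_values("doy")
    bands, georef = [], None
    for _, row in manifest.iterrows():
        arr, georef, _ = read_geotiff(directory / row["file"])
        bands.append(arr.astype(float))
    mask_arr, _, _ = read_geotiff(directory / "mask.tif")
    return SceneStack(
        year=year,
        lai=np.stack(bands),
        rice_mask=mask_arr.astype(bool),
        georef=georef,
    )
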