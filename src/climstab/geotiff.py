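"""Single-band GeoTIFF input/output.

Writes plain georeferenced TIFFs carrying the three tags a GIS needs to
place the raster (ModelPixelScale, ModelTiepoint, a minimal GeoKey
directory declaring a geographic CRS) plus the widely understood
GDAL_NODATA ASCII tag.  Only axis-aligned, north-up, single-band rasters
are supported: this package never resamples, so anything more exotic is
out of scope.

Value layers are stored as 32-bit float with a float sentinel at NoData;
mask and category layers as 8-bit unsigned with sentinel 255.
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import numpy as np
import tifffile

from .errors import GeoTiffError
from .raster import DEFAULT_NODATA, Grid, RasterLayer

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEOKEYS = 34735
_TAG_GDAL_NODATA = 42113

#: Sentinel for uint8 mask / category rasters.
MASK_NODATA = 255


def write_geotiff(layer: RasterLayer, path: str | os.PathLike, *,
                  dtype: str = "float32") -> None:
    """Write ``layer`` as a single-band georeferenced TIFF.

    Parameters
    ----------
    layer : RasterLayer
        Values with NaN at NoData; the grid supplies georeferencing and
        the disk sentinel.
    path : path-like
        Output path; the parent directory must exist.
    dtype : {"float32", "uint8"}
        Storage type.  ``uint8`` is for mask / category layers whose
        values are small non-negative integers; NoData becomes 255.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise GeoTiffError(f"parent directory does not exist: {path.parent}")
    grid = layer.grid
    t = grid.transform
    if t[2] != 0.0 or t[4] != 0.0:
        raise GeoTiffError("rotated geotransforms are not supported")

    nan = np.isnan(layer.values)
    if dtype == "float32":
        nodata = float(np.float32(grid.nodata_value))
        data = layer.values.astype(np.float32, copy=True)
        data[nan] = np.float32(nodata)
        nodata_str = repr(nodata)
    elif dtype == "uint8":
        nodata = MASK_NODATA
        data = np.where(nan, nodata, layer.values).astype(np.uint8)
        nodata_str = str(nodata)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")

    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (abs(t[1]), abs(t[5]), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t[0], t[3], 0.0)),
        (_TAG_GEOKEYS, "H", 16, _geokeys_for(grid.crs_tag)),
        (_TAG_GDAL_NODATA, "s", 0, nodata_str),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def read_geotiff(path: str | os.PathLike, *,
                 band: int | None = None) -> RasterLayer:
    """Read a single-band georeferenced TIFF into a :class:`RasterLayer`.

    The file's NoData value (GDAL_NODATA tag) is mapped to NaN in
    memory and kept as the grid's disk sentinel.  ``variable_id`` and
    ``period_id`` are parsed from the file name when it follows the
    ``sd_past_<bio>`` / ``<bio>_<period>`` conventions, else left as the
    stem.
    """
    path = Path(path)
    if not path.is_file():
        raise GeoTiffError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) > 1 and band is None:
            raise GeoTiffError(
                f"{path.name}: multi-band file ({len(tf.pages)} bands); "
                f"pass band= to select one")
        page = tf.pages[band or 0]
        if page.samplesperpixel > 1:
            raise GeoTiffError(f"{path.name}: multi-sample pixels are not "
                               f"supported")
        values = page.asarray()
        tags = page.tags
        scale = tags.get(_TAG_PIXEL_SCALE)
        tiepoint = tags.get(_TAG_TIEPOINT)
        if scale is None or tiepoint is None:
            raise GeoTiffError(f"{path.name}: missing geotransform tags")
        sx, sy = float(scale.value[0]), float(scale.value[1])
        tp = tiepoint.value
        # tie the raster-space point (tp[0], tp[1]) to model (tp[3], tp[4])
        origin_x = float(tp[3]) - float(tp[0]) * sx
        origin_y = float(tp[4]) + float(tp[1]) * sy
        crs_tag = _crs_from_geokeys(tags.get(_TAG_GEOKEYS))
        nodata_tag = tags.get(_TAG_GDAL_NODATA)

    values = np.asarray(values)
    if nodata_tag is not None:
        nodata = float(str(nodata_tag.value).strip())
    else:
        nodata = DEFAULT_NODATA

    if values.dtype.kind in "ui":
        nodata_cells = values == int(nodata)
    else:
        nodata_cells = values == np.asarray(nodata, dtype=values.dtype)
    out = values.astype(np.float32)
    out[nodata_cells] = np.nan

    grid = Grid(values.shape[0], values.shape[1],
                (origin_x, sx, 0.0, origin_y, 0.0, -sy),
                crs_tag=crs_tag, nodata_value=nodata)
    variable_id, period_id = _ids_from_name(path.stem)
    return RasterLayer(grid, out, variable_id=variable_id,
                       period_id=period_id)


def _geokeys_for(crs_tag: str) -> tuple[int, ...]:
    """Minimal GeoKey directory: geographic model, area pixels, EPSG code."""
    m = re.fullmatch(r"EPSG:(\d+)", crs_tag)
    epsg = int(m.group(1)) if m else 4326
    return (1, 1, 0, 3,          # version, revision, minor, key count
            1024, 0, 1, 2,       # GTModelType = geographic
            1025, 0, 1, 1,       # GTRasterType = PixelIsArea
            2048, 0, 1, epsg)    # GeographicType


def _crs_from_geokeys(tag) -> str:
    if tag is None:
        return "unknown"
    vals = list(tag.value)
    for i in range(4, len(vals) - 3, 4):
        if vals[i] == 2048:
            return f"EPSG:{vals[i + 3]}"
    return "unknown"


def _ids_from_name(stem: str) -> tuple[str, str]:
    m = re.fullmatch(r"(bio\d+|template|csi)[._-](.+)", stem)
    if m:
        return m.group(1), m.group(2)
    return stem, ""
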