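"""Grid data model, raster I/O, distance transforms, resampling, reclassification.

Coordinate convention: row-major, 0-based, row 0 at the map top.  The centre
of cell ``(r, c)`` sits at ``(origin_x + (c + 0.5) * cellsize,
origin_y - (r + 0.5) * cellsize)`` where ``(origin_x, origin_y)`` is the
outer corner of the top-left cell.  All coordinates are planar metres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "GridSpec",
    "RasterLayer",
    "CovariateStack",
    "RasterFormatError",
    "COVARIATE_ROLES",
    "read_raster",
    "write_raster",
    "distance_to_features",
    "resample",
    "reclassify",
]

DEFAULT_NODATA = -9999.0

#: the seven predictor roles every covariate stack must carry
COVARIATE_ROLES = (
    "dist_wells",
    "dist_water",
    "dist_roads",
    "ndvi",
    "fence",
    "landcover",
    "topo_position",
)


class RasterFormatError(ValueError):
    """Raised for malformed raster files or unsupported dialects."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry shared by every raster in one analysis."""

    nrows: int
    ncols: int
    cellsize: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must contain at least one cell")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer grid boundary."""
        return (
            self.origin_x,
            self.origin_y - self.nrows * self.cellsize,
            self.origin_x + self.ncols * self.cellsize,
            self.origin_y,
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.origin_x + (col + 0.5) * self.cellsize,
            self.origin_y - (row + 0.5) * self.cellsize,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (xs, ys) of every cell centre, shaped like the grid."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        xs = self.origin_x + (cols + 0.5) * self.cellsize
        ys = self.origin_y - (rows + 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Containing cell of map coordinates (clipped to the grid)."""
        col = np.clip(((np.asarray(x) - self.origin_x) // self.cellsize).astype(int), 0, self.ncols - 1)
        row = np.clip(((self.origin_y - np.asarray(y)) // self.cellsize).astype(int), 0, self.nrows - 1)
        return row, col

    def aggregated(self, factor: int) -> "GridSpec":
        if self.nrows % factor or self.ncols % factor:
            raise ValueError("grid shape must be divisible by the aggregation factor")
        return GridSpec(
            self.nrows // factor,
            self.ncols // factor,
            self.cellsize * factor,
            self.origin_x,
            self.origin_y,
            self.nodata,
        )


@dataclass
class RasterLayer:
    """A single grid of values with a validity mask.

    ``kind`` is one of ``continuous``, ``categorical`` or ``binary``;
    categorical/binary layers hold integer codes.
    """

    spec: GridSpec
    values: np.ndarray
    kind: str = "continuous"
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.spec.shape:
            raise ValueError(f"values shape {self.values.shape} != grid {self.spec.shape}")
        if self.kind not in ("continuous", "categorical", "binary"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.mask is None:
            self.mask = np.ones(self.spec.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.spec.shape:
                raise ValueError("mask shape mismatch")
        if self.kind in ("categorical", "binary") and not np.issubdtype(self.values.dtype, np.integer):
            if not np.allclose(self.values[self.mask], np.round(self.values[self.mask])):
                raise ValueError(f"{self.kind} layer must hold integer codes")
            self.values = np.round(self.values).astype(np.int64)

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def filled(self, fill: float | None = None) -> np.ndarray:
        out = self.values.astype(float).copy()
        out[~self.mask] = self.spec.nodata if fill is None else fill
        return out

    def copy_with(self, values: np.ndarray, kind: str | None = None, mask: np.ndarray | None = None) -> "RasterLayer":
        return RasterLayer(
            self.spec,
            values,
            kind if kind is not None else self.kind,
            self.mask.copy() if mask is None else mask,
        )


@dataclass
class CovariateStack:
    """The seven predictor layers on one shared grid."""

    layers: dict[str, RasterLayer]

    def __post_init__(self) -> None:
        missing = set(COVARIATE_ROLES) - set(self.layers)
        extra = set(self.layers) - set(COVARIATE_ROLES)
        if missing or extra:
            raise ValueError(f"stack roles invalid: missing={sorted(missing)} extra={sorted(extra)}")
        specs = {(lyr.spec.nrows, lyr.spec.ncols, lyr.spec.cellsize) for lyr in self.layers.values()}
        if len(specs) != 1:
            raise ValueError("covariate layers are not grid-aligned")
        if self.layers["fence"].kind != "binary":
            raise ValueError("fence layer must be binary")
        for role in ("landcover", "topo_position"):
            if self.layers[role].kind != "categorical":
                raise ValueError(f"{role} layer must be categorical")

    @property
    def spec(self) -> GridSpec:
        return next(iter(self.layers.values())).spec

    def __getitem__(self, role: str) -> RasterLayer:
        return self.layers[role]

    def roles(self) -> tuple[str, ...]:
        return COVARIATE_ROLES

    def shared_mask(self) -> np.ndarray:
        mask = np.ones(self.spec.shape, dtype=bool)
        for lyr in self.layers.values():
            mask &= lyr.mask
        return mask


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_raster(layer: RasterLayer, path: str | Path, dialect: str = "esri_ascii") -> Path:
    path = Path(path)
    if dialect == "esri_ascii":
        _write_ascii(layer, path)
    elif dialect == "geotiff":
        _write_geotiff(layer, path)
    else:
        raise RasterFormatError(f"unknown raster dialect {dialect!r}")
    return path


def read_raster(path: str | Path, dialect: str = "esri_ascii", kind: str | None = None) -> RasterLayer:
    path = Path(path)
    if dialect == "esri_ascii":
        return _read_ascii(path, kind)
    if dialect == "geotiff":
        return _read_geotiff(path, kind)
    raise RasterFormatError(f"unknown raster dialect {dialect!r}")


def _write_ascii(layer: RasterLayer, path: Path) -> None:
    spec = layer.spec
    xll = spec.origin_x
    yll = spec.origin_y - spec.nrows * spec.cellsize
    body = layer.filled()
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.ncols}\n")
        fh.write(f"nrows {spec.nrows}\n")
        fh.write(f"xllcorner {xll!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {spec.cellsize!r}\n")
        fh.write(f"NODATA_value {spec.nodata!r}\n")
        for row in body:
            fh.write(" ".join(repr(v) for v in row.tolist()) + "\n")
    # layer kind kept in a sidecar so categorical round-trips are faithful
    Path(str(path) + ".meta.json").write_text(json.dumps({"kind": layer.kind}))


def _read_ascii(path: Path, kind: str | None) -> RasterLayer:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if len(parts) == 2 and key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
                header[key] = float(parts[1])
            else:
                try:
                    rows.append([float(p) for p in parts])
                except ValueError as exc:
                    raise RasterFormatError(f"bad data line in {path}: {line!r}") from exc
    required = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")
    if any(k not in header for k in required):
        raise RasterFormatError(f"missing header fields in {path}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if len(rows) != nrows or any(len(r) != ncols for r in rows):
        raise RasterFormatError(f"ragged or wrong-sized grid body in {path}")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    spec = GridSpec(
        nrows,
        ncols,
        header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nrows * header["cellsize"],
        nodata=nodata,
    )
    values = np.array(rows, dtype=float)
    mask = values != nodata
    if kind is None:
        meta = Path(str(path) + ".meta.json")
        kind = json.loads(meta.read_text())["kind"] if meta.exists() else "continuous"
    if kind in ("categorical", "binary"):
        vals = np.zeros(values.shape, dtype=np.int64)
        vals[mask] = np.round(values[mask]).astype(np.int64)
        return RasterLayer(spec, vals, kind, mask)
    return RasterLayer(spec, values, kind, mask)


_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _write_geotiff(layer: RasterLayer, path: Path) -> None:
    import tifffile

    spec = layer.spec
    desc = json.dumps({"kind": layer.kind})
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (spec.cellsize, spec.cellsize, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.origin_x, spec.origin_y, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(spec.nodata)),
    ]
    tifffile.imwrite(path, layer.filled(), description=desc, extratags=extratags)


def _read_geotiff(path: Path, kind: str | None) -> RasterLayer:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        try:
            sx, sy, _ = tags[_TAG_PIXEL_SCALE].value
            tie = tags[_TAG_TIEPOINT].value
        except KeyError as exc:
            raise RasterFormatError(f"{path} lacks georeferencing tags") from exc
        if abs(sx - sy) > 1e-9:
            raise RasterFormatError(f"{path} has non-square cells ({sx} x {sy})")
        nodata = float(tags[_TAG_GDAL_NODATA].value) if _TAG_GDAL_NODATA in tags else DEFAULT_NODATA
        if kind is None:
            try:
                kind = json.loads(tags["ImageDescription"].value).get("kind", "continuous")
            except Exception:
                kind = "continuous"
    nrows, ncols = values.shape
    spec = GridSpec(nrows, ncols, float(sx), origin_x=float(tie[3]), origin_y=float(tie[4]), nodata=nodata)
    mask = values != nodata
    if kind in ("categorical", "binary"):
        vals = np.zeros(values.shape, dtype=np.int64)
        vals[mask] = np.round(values[mask]).astype(np.int64)
        return RasterLayer(spec, vals, kind, mask)
    return RasterLayer(spec, values, kind, mask)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def distance_to_features(spec: GridSpec, feature_cells: Iterable[tuple[int, int]]) -> RasterLayer:
    """Euclidean distance (m) from each cell centre to the nearest feature-cell centre."""
    cells = list(feature_cells)
    if not cells:
        raise ValueError("feature cell set is empty")
    occupied = np.zeros(spec.shape, dtype=bool)
    for r, c in cells:
        if not (0 <= r < spec.nrows and 0 <= c < spec.ncols):
            raise ValueError(f"feature cell {(r, c)} outside grid")
        occupied[r, c] = True
    dist = ndimage.distance_transform_edt(~occupied, sampling=spec.cellsize)
    return RasterLayer(spec, dist, "continuous")


def resample(layer: RasterLayer, factor: int, method: str) -> RasterLayer:
    """Block-aggregate a layer by an integer factor (mean or majority)."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    if method not in ("mean", "majority"):
        raise ValueError(f"unknown resample method {method!r}")
    if method == "mean" and layer.kind != "continuous":
        raise ValueError("mean resampling requires a continuous layer")
    spec = layer.spec.aggregated(int(factor))
    f = int(factor)
    vals = layer.values.reshape(spec.nrows, f, spec.ncols, f)
    mask = layer.mask.reshape(spec.nrows, f, spec.ncols, f)
    counts = mask.sum(axis=(1, 3))
    out_mask = counts > 0
    if method == "mean":
        totals = np.where(mask, vals, 0.0).sum(axis=(1, 3))
        out = np.divide(totals, counts, out=np.zeros_like(totals, dtype=float), where=out_mask)
        return RasterLayer(spec, out, "continuous", out_mask)
    out = np.zeros((spec.nrows, spec.ncols), dtype=np.int64)
    blocks = vals.transpose(0, 2, 1, 3).reshape(spec.nrows, spec.ncols, f * f)
    bmask = mask.transpose(0, 2, 1, 3).reshape(spec.nrows, spec.ncols, f * f)
    for i in range(spec.nrows):
        for j in range(spec.ncols):
            if not out_mask[i, j]:
                continue
            codes, n = np.unique(blocks[i, j][bmask[i, j]], return_counts=True)
            out[i, j] = codes[np.argmax(n)]  # np.unique sorts, so ties favour the lowest code
    return RasterLayer(spec, out, layer.kind, out_mask)


def reclassify(layer: RasterLayer, rule: Sequence[float] | Mapping[int, float]) -> RasterLayer:
    """Bin a continuous layer into classes, or score a categorical layer.

    A sequence ``rule`` is interpreted as ordered bin edges producing
    left-closed / right-open classes ``[-inf, e0), [e0, e1), ..., [e_last, inf)``
    coded 0..len(rule).  A mapping scores each categorical code; unmapped
    codes raise rather than silently masking.
    """
    if isinstance(rule, Mapping):
        if layer.kind not in ("categorical", "binary"):
            raise ValueError("code map reclassification requires a categorical layer")
        codes = np.unique(layer.values[layer.mask])
        unmapped = [int(c) for c in codes if int(c) not in rule]
        if unmapped:
            raise ValueError(f"unmapped category codes: {unmapped}")
        out = np.zeros(layer.spec.shape, dtype=float)
        for code, score in rule.items():
            out[layer.values == code] = score
        out[~layer.mask] = 0.0
        return layer.copy_with(out, kind="continuous")
    edges = np.asarray(list(rule), dtype=float)
    if edges.ndim != 1 or len(edges) < 1:
        raise ValueError("bin edges must be a non-empty 1-D sequence")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if layer.kind != "continuous":
        raise ValueError("bin-edge reclassification requires a continuous layer")
    # right=False => value == edge falls in the upper class (right-open bins)
    out = np.digitize(layer.values, edges, right=False).astype(np.int64)
    out[~layer.mask] = 0
    return layer.copy_with(out, kind="categorical")
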