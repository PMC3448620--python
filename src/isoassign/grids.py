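"""Raster isoscapes: I/O, calibration transfer functions, alignment, zonal stats.

Conventions
-----------
Grids are north-up and row-major: row 0 is the northernmost row.  ``origin``
is the (west longitude, north latitude) of the *corner* of the top-left cell;
coordinate queries use cell-center registration, so the center of cell
(r, c) lies at ``(origin[0] + (c + 0.5) * cell_size,
origin[1] - (r + 0.5) * cell_size)``.  Cells are square.

Two file formats are supported: ESRI ASCII grid (text, exact round-trip,
used for all fixtures) and GeoTIFF (via tifffile, float32 payload with
ModelPixelScale / ModelTiepoint / GDAL_NODATA tags).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IsoscapeGrid", "TransferFunction", "ClusterSummary", "IsoscapeStack",
    "read_grid", "write_grid", "apply_transfer", "align_stack",
    "zonal_summaries", "GridFormatError", "AlignmentError",
    "D2H_CALIBRATION", "D13C_DISCRIMINATION", "D15N_DISCRIMINATION",
]


class GridFormatError(ValueError):
    """Malformed raster file or unsupported georeferencing."""


class AlignmentError(ValueError):
    """Grids cannot be placed on a common cell lattice."""


DEFAULT_NODATA = -9999.0

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclasses.dataclass
class IsoscapeGrid:
    """A georeferenced single-layer raster of isotope values (‰)."""

    values: np.ndarray
    nodata: float = DEFAULT_NODATA
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        valid = self.values != self.nodata
        if not np.all(np.isfinite(self.values[valid])):
            raise ValueError("non-nodata cells must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def same_geometry(self, other: "IsoscapeGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.origin, other.origin)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def cell_center_lons(self) -> np.ndarray:
        """Longitudes of cell centers, one per column."""
        west, _ = self.origin
        return west + (np.arange(self.shape[1]) + 0.5) * self.cell_size

    def cell_center_lats(self) -> np.ndarray:
        """Latitudes of cell centers, one per row (north to south)."""
        _, north = self.origin
        return north - (np.arange(self.shape[0]) + 0.5) * self.cell_size

    def with_values(self, values: np.ndarray) -> "IsoscapeGrid":
        return dataclasses.replace(self, values=np.asarray(values, dtype=float))


@dataclasses.dataclass(frozen=True)
class TransferFunction:
    """Affine map from an environmental isoscape to the feather-tissue scale.

    ``kind='linear'`` applies ``slope * v + intercept``; ``kind='offset'``
    is the slope-1 special case used for diet-to-tissue discrimination.
    """

    kind: str
    intercept: float
    slope: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "offset"):
            raise ValueError(f"unknown transfer kind {self.kind!r}")
        if self.kind == "offset" and self.slope != 1.0:
            raise ValueError("offset transfer must have slope 1")
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("transfer coefficients must be finite")
        if self.slope == 0:
            raise ValueError("zero slope is not invertible")

    def __call__(self, v):
        return self.slope * np.asarray(v, dtype=float) + self.intercept

    def invert(self, v):
        return (np.asarray(v, dtype=float) - self.intercept) / self.slope


# Published precipitation-to-feather δ²H calibration from known-source birds,
# and the diet-to-tissue discrimination offsets for δ¹³C / δ¹⁵N.
D2H_CALIBRATION = TransferFunction("linear", intercept=-6.77, slope=1.42)
D13C_DISCRIMINATION = TransferFunction("offset", intercept=2.0)
D15N_DISCRIMINATION = TransferFunction("offset", intercept=5.0)


@dataclasses.dataclass
class IsoscapeStack:
    """Aligned multi-layer raster: shape (n_layers, rows, cols).

    A cell is valid only where it is valid in *every* layer (intersection
    mask); all layer-wise statistics use that shared mask.
    """

    layers: np.ndarray
    mask: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    labels: tuple[str, ...]

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers.shape[1:]

    def valid_matrix(self) -> np.ndarray:
        """Valid cells as an (n_valid, n_layers) matrix."""
        return self.layers[:, self.mask].T

    def as_grid(self, layer: int, nodata: float = DEFAULT_NODATA) -> IsoscapeGrid:
        vals = np.where(self.mask, self.layers[layer], nodata)
        return IsoscapeGrid(vals, nodata=nodata, origin=self.origin,
                            cell_size=self.cell_size, label=self.labels[layer])


@dataclasses.dataclass
class ClusterSummary:
    """Per-cluster zonal summaries: mean, SD (population divisor) and cell
    count for each layer.  ``means``/``sds`` have shape (K, n_layers)."""

    cluster_ids: np.ndarray
    layer_labels: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.cluster_ids = np.asarray(self.cluster_ids, dtype=int)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts <= 0):
            raise ValueError("cluster cell counts must be positive")
        if not np.all(np.isfinite(self.means)):
            raise ValueError("cluster means must be finite")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)

    def mean_vectors(self) -> np.ndarray:
        return self.means

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, cid in enumerate(self.cluster_ids):
            for j, lab in enumerate(self.layer_labels):
                rows.append({"cluster": int(cid), "layer": lab,
                             "mean": self.means[i, j], "sd": self.sds[i, j],
                             "n_cells": int(self.counts[i])})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ClusterSummary":
        layers = tuple(dict.fromkeys(df["layer"]))
        clusters = sorted(df["cluster"].unique())
        means = np.empty((len(clusters), len(layers)))
        sds = np.empty_like(means)
        counts = np.empty(len(clusters), dtype=int)
        for i, cid in enumerate(clusters):
            sub = df[df["cluster"] == cid].set_index("layer")
            counts[i] = int(sub["n_cells"].iloc[0])
            for j, lab in enumerate(layers):
                means[i, j] = sub.loc[lab, "mean"]
                sds[i, j] = sub.loc[lab, "sd"]
        return cls(np.array(clusters), layers, means, sds, counts)

    @classmethod
    def from_csv(cls, path) -> "ClusterSummary":
        return cls.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# I/O

def _read_ascii(path: Path, label: str) -> IsoscapeGrid:
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value", "dx", "dy",
        ):
            try:
                header[parts[0].lower()] = float(parts[1])
            except ValueError as exc:
                raise GridFormatError(f"bad header line {lines[i]!r}") from exc
            i += 1
        else:
            break
    required = {"ncols", "nrows", "xllcorner", "yllcorner"}
    if not required.issubset(header):
        raise GridFormatError(f"missing header keys in {path}")
    if "cellsize" in header:
        cell = header["cellsize"]
    elif "dx" in header and "dy" in header:
        if not np.isclose(header["dx"], header["dy"]):
            raise GridFormatError("non-square cells are unsupported")
        cell = header["dx"]
    else:
        raise GridFormatError(f"missing cellsize in {path}")
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    body = "\n".join(lines[i:])
    try:
        values = np.fromstring(body, sep=" ")  # noqa: NPY201 - fast flat parse
    except Exception as exc:  # pragma: no cover
        raise GridFormatError(f"unparseable data block in {path}") from exc
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.size != nrows * ncols:
        raise GridFormatError(
            f"{path}: expected {nrows * ncols} values, found {values.size}")
    values = values.reshape(nrows, ncols)
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return IsoscapeGrid(values, nodata=nodata, origin=origin,
                        cell_size=cell, label=label)


def _write_ascii(grid: IsoscapeGrid, path: Path) -> None:
    nrows, ncols = grid.shape
    yll = grid.origin[1] - nrows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _read_geotiff(path: Path, label: str) -> IsoscapeGrid:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise GridFormatError(f"{path}: missing GeoTIFF georeferencing tags")
        sx, sy = tags[_TAG_MODEL_PIXEL_SCALE].value[:2]
        if not np.isclose(sx, sy):
            raise GridFormatError("non-square cells are unsupported")
        tie = tags[_TAG_MODEL_TIEPOINT].value
        # tiepoint maps raster (i, j, k) -> model (x, y, z); anchor at (0, 0)
        west = tie[3] - tie[0] * sx
        north = tie[4] + tie[1] * sy
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
    if values.ndim != 2:
        raise GridFormatError(f"{path}: expected a single-band raster")
    return IsoscapeGrid(values, nodata=nodata, origin=(west, north),
                        cell_size=float(sx), label=label)


def _write_geotiff(grid: IsoscapeGrid, path: Path) -> None:
    import tifffile

    s = grid.cell_size
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, grid.origin[0], grid.origin[1], 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(grid.nodata)),
    ]
    tifffile.imwrite(path, grid.values.astype(np.float32), extratags=extratags)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    return "ascii"


def read_grid(path, fmt: str | None = None, label: str = "") -> IsoscapeGrid:
    """Read a raster isoscape from an ESRI ASCII grid or a GeoTIFF.

    Format is inferred from the suffix (.tif/.tiff → geotiff, else ascii)
    unless ``fmt`` is given.  Nodata cells are preserved as the sentinel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "ascii":
        return _read_ascii(path, label)
    if fmt == "geotiff":
        return _read_geotiff(path, label)
    raise ValueError(f"unknown format {fmt!r}")


def write_grid(grid: IsoscapeGrid, path, fmt: str | None = None) -> None:
    """Write a grid; ASCII round-trips values exactly, GeoTIFF as float32."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "ascii":
        _write_ascii(grid, path)
    elif fmt == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Transforms

def apply_transfer(grid: IsoscapeGrid, tf: TransferFunction) -> IsoscapeGrid:
    """Apply a calibration/discrimination transfer cellwise; nodata untouched."""
    out = grid.values.copy()
    m = grid.valid_mask
    out[m] = tf(grid.values[m])
    return grid.with_values(out)


def align_stack(grids: Sequence[IsoscapeGrid]) -> IsoscapeStack:
    """Stack grids on a common lattice with an intersection validity mask.

    Grids whose extents overlap but differ are cropped to the common window;
    origins must sit on the same cell lattice.  A cell is valid only if it is
    valid (non-nodata) in every layer.
    """
    if len(grids) == 0:
        raise ValueError("need at least one grid")
    cell = grids[0].cell_size
    for g in grids[1:]:
        if not np.isclose(g.cell_size, cell):
            raise AlignmentError("cell sizes differ")
    # common extent
    wests = [g.origin[0] for g in grids]
    norths = [g.origin[1] for g in grids]
    easts = [g.origin[0] + g.shape[1] * g.cell_size for g in grids]
    souths = [g.origin[1] - g.shape[0] * g.cell_size for g in grids]
    west, north = max(wests), min(norths)
    east, south = min(easts), max(souths)
    if east - west < cell / 2 or north - south < cell / 2:
        raise AlignmentError("grid extents do not overlap")
    ncols = int(round((east - west) / cell))
    nrows = int(round((north - south) / cell))
    layers = np.empty((len(grids), nrows, ncols))
    mask = np.ones((nrows, ncols), dtype=bool)
    for i, g in enumerate(grids):
        c0 = (west - g.origin[0]) / cell
        r0 = (g.origin[1] - north) / cell
        if abs(c0 - round(c0)) > 1e-6 or abs(r0 - round(r0)) > 1e-6:
            raise AlignmentError("grid origins are not on a common cell lattice")
        c0, r0 = int(round(c0)), int(round(r0))
        window = g.values[r0:r0 + nrows, c0:c0 + ncols]
        layers[i] = window
        mask &= window != g.nodata
    labels = tuple(g.label or f"layer{i}" for i, g in enumerate(grids))
    return IsoscapeStack(layers, mask, (west, north), cell, labels)


def zonal_summaries(stack: IsoscapeStack, clusters) -> ClusterSummary:
    """Per-cluster, per-layer mean and SD over valid cells (zonal statistics).

    ``clusters`` is a ClusterMap aligned with the stack; label 0 and cells
    invalid in the stack are excluded.  SD uses the population (n) divisor —
    the zone is the full cell population, not a sample.
    """
    labels = np.asarray(clusters.labels)
    if labels.shape != stack.shape:
        raise AlignmentError("cluster map shape does not match stack")
    ids = np.unique(labels[labels > 0])
    if ids.size == 0:
        raise ValueError("cluster map has no labelled cells")
    means = np.empty((ids.size, stack.n_layers))
    sds = np.empty_like(means)
    counts = np.empty(ids.size, dtype=int)
    for i, cid in enumerate(ids):
        sel = (labels == cid) & stack.mask
        counts[i] = int(sel.sum())
        if counts[i] == 0:
            raise ValueError(f"cluster {cid} has no valid cells")
        cells = stack.layers[:, sel]
        means[i] = cells.mean(axis=1)
        sds[i] = cells.std(axis=1, ddof=0)
    return ClusterSummary(ids, stack.labels, means, sds, counts)
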