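"""Grid definitions, raster stacks and regridding.

All stages of the analysis operate on a single shared grid convention:
row-major arrays, origin at the top-left corner, pixel-centre registration.
Internally nodata is always represented as NaN; the ``GridDef.nodata``
sentinel is only applied when writing files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["GridDef", "RasterStack", "regrid"]


@dataclass(frozen=True)
class GridDef:
    """Definition of a regular raster grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid shape.
    pixel_area : float
        Area of one pixel in km^2 (uniform; 16 km^2 for a 4-km grid).
    x_origin, y_origin : float
        Map coordinates of the top-left corner of the top-left pixel.
    dx, dy : float
        Pixel spacing in map units (positive; rows increase downward).
    nodata : float
        Sentinel written to files in place of NaN.
    """

    n_rows: int
    n_cols: int
    pixel_area: float = 16.0
    x_origin: float = 0.0
    y_origin: float = 0.0
    dx: float = 4.0
    dy: float = 4.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple[float, float]:
        """(height, width) of the grid in map units."""
        return (self.n_rows * self.dy, self.n_cols * self.dx)

    def coarsen(self, factor: int) -> "GridDef":
        """Grid covering the same extent at ``factor``-times coarser resolution."""
        if factor < 1 or self.n_rows % factor or self.n_cols % factor:
            raise ValueError(
                f"factor {factor} does not divide grid shape {self.shape}"
            )
        return replace(
            self,
            n_rows=self.n_rows // factor,
            n_cols=self.n_cols // factor,
            pixel_area=self.pixel_area * factor * factor,
            dx=self.dx * factor,
            dy=self.dy * factor,
        )

    def same_extent(self, other: "GridDef", rtol: float = 1e-9) -> bool:
        return bool(
            np.isclose(self.extent[0], other.extent[0], rtol=rtol)
            and np.isclose(self.extent[1], other.extent[1], rtol=rtol)
        )


@dataclass
class RasterStack:
    """An ordered set of named 2-D layers sharing one grid and one units tag.

    ``data`` has shape ``(n_layers, n_rows, n_cols)``; ``labels`` names each
    layer (a timestamp string, a trait name, ...). NaN marks nodata.
    """

    grid: GridDef
    data: np.ndarray
    labels: list[str]
    units: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.shape[1:] != self.grid.shape:
            raise ValueError(
                f"layer shape {self.data.shape[1:]} != grid shape {self.grid.shape}"
            )
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per layer required")
        if not self.units:
            raise ValueError("units tag required")

    @property
    def n_layers(self) -> int:
        return self.data.shape[0]

    def layer(self, name: str) -> np.ndarray:
        return self.data[self.labels.index(name)]


def _check_block_factor(source: GridDef, target: GridDef) -> int:
    if not source.same_extent(target):
        raise ValueError(
            f"incompatible extents: source {source.shape} spans {source.extent}, "
            f"target {target.shape} spans {target.extent}"
        )
    if source.n_rows % target.n_rows or source.n_cols % target.n_cols:
        raise ValueError(
            f"block regrid needs an integer resolution ratio: "
            f"source {source.shape} vs target {target.shape}"
        )
    fr = source.n_rows // target.n_rows
    fc = source.n_cols // target.n_cols
    if fr != fc:
        raise ValueError(
            f"anisotropic block factor ({fr} x {fc}) between source "
            f"{source.shape} and target {target.shape}"
        )
    return fr


def _blocks(arr: np.ndarray, factor: int) -> np.ndarray:
    r, c = arr.shape
    return arr.reshape(r // factor, factor, c // factor, factor).swapaxes(1, 2)


def _resample_indices(source: GridDef, target: GridDef) -> tuple[np.ndarray, np.ndarray]:
    """Fractional source indices of target pixel centres (same extent)."""
    if not source.same_extent(target):
        raise ValueError(
            f"incompatible extents: source {source.shape} spans {source.extent}, "
            f"target {target.shape} spans {target.extent}"
        )
    rows = (np.arange(target.n_rows) + 0.5) * target.dy / source.dy - 0.5
    cols = (np.arange(target.n_cols) + 0.5) * target.dx / source.dx - 0.5
    return rows, cols


def _bilinear(layer: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    nr, nc = layer.shape
    r0 = np.clip(np.floor(rows).astype(int), 0, nr - 1)
    c0 = np.clip(np.floor(cols).astype(int), 0, nc - 1)
    r1 = np.clip(r0 + 1, 0, nr - 1)
    c1 = np.clip(c0 + 1, 0, nc - 1)
    wr = np.clip(rows - r0, 0.0, 1.0)[:, None]
    wc = np.clip(cols - c0, 0.0, 1.0)[None, :]
    # NaN in any contributing corner propagates to the target cell.
    top = layer[np.ix_(r0, c0)] * (1 - wc) + layer[np.ix_(r0, c1)] * wc
    bot = layer[np.ix_(r1, c0)] * (1 - wc) + layer[np.ix_(r1, c1)] * wc
    return top * (1 - wr)[:, :] + bot * wr


def _nearest(layer: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    nr, nc = layer.shape
    ri = np.clip(np.round(rows).astype(int), 0, nr - 1)
    ci = np.clip(np.round(cols).astype(int), 0, nc - 1)
    return layer[np.ix_(ri, ci)]


def regrid(source: RasterStack, target: GridDef, method: str) -> RasterStack:
    """Resample a stack onto a target grid covering the same extent.

    Methods
    -------
    ``bilinear``
        Pixel-centre bilinear interpolation; nodata if any contributing
        source cell is nodata. Used for fine-to-analysis-grid moisture maps.
    ``nearest``
        Nearest pixel centre; used for trait rasters.
    ``block_mean`` / ``block_sum``
        Integer-factor aggregation ignoring nodata cells; nodata only where
        the whole block is nodata. ``block_sum`` conserves the global sum
        (burned area in km^2).
    ``any_overlap``
        Boolean aggregation: target true where >= 1 source cell is truthy
        (wildland-urban-interface masks).
    """
    out = np.empty((source.n_layers, target.n_rows, target.n_cols))
    if method in ("block_mean", "block_sum", "any_overlap"):
        factor = _check_block_factor(source.grid, target)
        for k in range(source.n_layers):
            blocks = _blocks(source.data[k], factor)
            if method == "any_overlap":
                valid = np.isfinite(blocks)
                hit = np.nansum(np.where(valid, blocks, 0.0) != 0.0, axis=(2, 3)) > 0
                out[k] = hit.astype(float)
                out[k][~valid.any(axis=(2, 3))] = np.nan
            else:
                import warnings

                with warnings.catch_warnings(), np.errstate(invalid="ignore"):
                    warnings.simplefilter("ignore", RuntimeWarning)
                    agg = np.nansum if method == "block_sum" else np.nanmean
                    res = agg(blocks, axis=(2, 3))
                res = np.where(np.isfinite(blocks).any(axis=(2, 3)), res, np.nan)
                out[k] = res
    elif method in ("bilinear", "nearest"):
        rows, cols = _resample_indices(source.grid, target)
        fn = _bilinear if method == "bilinear" else _nearest
        for k in range(source.n_layers):
            out[k] = fn(source.data[k], rows, cols)
    else:
        raise ValueError(f"unknown regrid method: {method!r}")
    return RasterStack(grid=target, data=out, labels=list(source.labels), units=source.units)
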