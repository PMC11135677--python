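"""Composite urban-intensity axis from co-registered environmental layers.

Several urbanization proxies (night-time lights, impervious surface,
anthropogenic noise, ...) are aligned to the analysis grid, standardized,
and reduced by PCA; the first principal component is retained as the single
spatial index of urban intensity.  Because the input layers carry
incommensurate units, the decomposition is of the correlation matrix
(layers are z-scored over the included cells before eigendecomposition).

The PC1 axis is oriented so that it correlates non-negatively with a
designated reference layer (by default the impervious-surface-like layer),
making "larger = more urban" a guaranteed convention rather than an
accident of eigenvector sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (DegenerateLayerError, ExtentError, GridMismatchError,
                     MetadataError, ParameterError)
from .grid import GridSpec, Raster

__all__ = ["UrbanIntensityRaster", "align_layers", "composite_pca"]

logger = logging.getLogger(__name__)

#: PC1 must explain more than this share of total variance for the
#: single-axis summary to be considered adequate.
RETENTION_THRESHOLD = 0.70


@dataclass
class UrbanIntensityRaster:
    """PC1 urban-intensity scores on the analysis grid plus PCA diagnostics.

    ``values`` holds the PC1 score per cell (NaN where any input layer was
    missing); ``variance_explained`` the per-axis variance shares (summing
    to 1); ``loadings`` the layer-by-axis eigenvector matrix; ``retained_ok``
    whether PC1 passed the variance-share retention check.
    """

    grid: GridSpec
    values: np.ndarray
    variance_explained: np.ndarray
    loadings: pd.DataFrame
    reference_layer: str
    retained_ok: bool

    def to_raster(self, name: str = "pc1") -> Raster:
        return Raster(self.grid, self.values, name=name)

    def report(self) -> pd.DataFrame:
        """Loadings and variance explained, one row per axis."""
        rep = self.loadings.T
        rep.insert(0, "variance_explained", self.variance_explained)
        return rep


def align_layers(layers: list[Raster], grid: GridSpec,
                 resampling: str = "mean") -> list[Raster]:
    """Bring source rasters onto the analysis grid.

    Supported resampling: ``mean`` (average of source cells whose centers
    fall in each target cell — the right choice when aggregating finer
    data), ``nearest`` and ``bilinear`` (sampling at target cell centers).
    Source layers must share the target grid's projected frame; arbitrary
    reprojection between unrelated CRSs is not supported — co-register
    inputs upstream.  Target cells with no source coverage come out NaN.
    """
    if resampling not in {"mean", "nearest", "bilinear"}:
        raise ParameterError(f"unknown resampling {resampling!r}")
    out = []
    for layer in layers:
        g = layer.grid
        if g.crs is None and grid.crs is not None:
            raise MetadataError(f"layer {layer.name!r} has no CRS")
        if not g.same_frame(grid):
            raise MetadataError(
                f"layer {layer.name!r} frame {g.crs_id!r} != grid frame {grid.crs_id!r}; "
                "reproject upstream")
        sxmin, symin, sxmax, symax = g.extent
        txmin, tymin, txmax, tymax = grid.extent
        if sxmax <= txmin or txmax <= sxmin or symax <= tymin or tymax <= symin:
            raise ExtentError(f"layer {layer.name!r} does not overlap the target grid")
        if (g.shape == grid.shape and g.origin == grid.origin
                and g.cell_size == grid.cell_size):
            out.append(layer.copy())
            continue
        out.append(_resample(layer, grid, resampling))
    return out


def _resample(layer: Raster, grid: GridSpec, how: str) -> Raster:
    src = layer.grid
    vals = np.full(grid.shape, np.nan)
    if how == "mean":
        # aggregate source cell centers into target cells
        sx, sy = src.cell_centers()
        row, col = grid.cell_index(sx.ravel(), sy.ravel())
        ok = (row >= 0) & np.isfinite(layer.flat)
        if ok.any():
            idx = row[ok] * grid.n_cols + col[ok]
            sums = np.bincount(idx, weights=layer.flat[ok], minlength=grid.n_cells)
            cnts = np.bincount(idx, minlength=grid.n_cells)
            with np.errstate(invalid="ignore"):
                cellmean = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
            vals = cellmean.reshape(grid.shape)
    else:
        tx, ty = grid.cell_centers()
        # fractional position of target centers in source cell units
        fx = (tx - src.origin[0]) / src.cell_size - 0.5
        fy = (ty - src.origin[1]) / src.cell_size - 0.5
        if how == "nearest":
            c = np.rint(fx).astype(int)
            r = np.rint(fy).astype(int)
            ok = (r >= 0) & (r < src.n_rows) & (c >= 0) & (c < src.n_cols)
            vals[ok] = layer.values[r[ok], c[ok]]
        else:  # bilinear
            c0 = np.clip(np.floor(fx).astype(int), 0, src.n_cols - 1)
            r0 = np.clip(np.floor(fy).astype(int), 0, src.n_rows - 1)
            c1 = np.clip(c0 + 1, 0, src.n_cols - 1)
            r1 = np.clip(r0 + 1, 0, src.n_rows - 1)
            wx = np.clip(fx - c0, 0.0, 1.0)
            wy = np.clip(fy - r0, 0.0, 1.0)
            inside = (fx >= -0.5) & (fx <= src.n_cols - 0.5) & \
                     (fy >= -0.5) & (fy <= src.n_rows - 0.5)
            v = ((1 - wy) * ((1 - wx) * layer.values[r0, c0] + wx * layer.values[r0, c1])
                 + wy * ((1 - wx) * layer.values[r1, c0] + wx * layer.values[r1, c1]))
            vals = np.where(inside, v, np.nan)
    return Raster(grid, vals, name=layer.name)


def composite_pca(stack: list[Raster], reference_layer: int | str = 1,
                  retention_threshold: float = RETENTION_THRESHOLD,
                  ) -> UrbanIntensityRaster:
    """Standardize aligned layers and extract an oriented PC1.

    Cells missing in any layer are excluded from the decomposition
    (complete-case PCA) and carry NaN scores.  Layers are z-scored
    (population sd, ddof=0) so the decomposition is of the correlation
    matrix.  The PC1 sign is flipped if needed so scores correlate
    non-negatively with ``reference_layer`` (index or name; default the
    second layer, the impervious-surface slot in the canonical ordering).

    Emits a warning (never an error) when PC1's variance share does not
    exceed ``retention_threshold``: the single-axis summary is then a poor
    compression of the inputs.
    """
    if len(stack) < 2:
        raise ParameterError("need at least 2 layers for a composite")
    grid = stack[0].grid
    for r in stack[1:]:
        if r.grid.shape != grid.shape or r.grid.origin != grid.origin:
            raise GridMismatchError("layers are not on a common grid; align first")
    names = [r.name or f"layer_{i}" for i, r in enumerate(stack)]
    if isinstance(reference_layer, str):
        ref_idx = names.index(reference_layer)
    else:
        ref_idx = int(reference_layer) if len(stack) > int(reference_layer) else 0
    X = np.column_stack([r.flat for r in stack])
    complete = np.all(np.isfinite(X), axis=1)
    n_ok = int(complete.sum())
    if n_ok < 3:
        raise ParameterError(f"only {n_ok} complete cells; need >= 3")
    Xc = X[complete]
    mu = Xc.mean(axis=0)
    sd = Xc.std(axis=0)  # ddof=0: (1/n) Z'Z is then exactly the correlation matrix
    for j, s in enumerate(sd):
        if s == 0:
            raise DegenerateLayerError(f"layer {names[j]!r} is constant over included cells")
    Z = (Xc - mu) / sd

    # SVD route; the eigendecomposition of Z'Z/n is the independent cross-check
    U, svals, Vt = np.linalg.svd(Z, full_matrices=False)
    var = svals**2
    var_share = var / var.sum()
    loadvecs = Vt  # rows = axes
    scores1 = Z @ loadvecs[0]
    # orientation: non-negative correlation with the reference layer
    ref_corr = float(np.dot(scores1, Z[:, ref_idx]))
    if ref_corr < 0:
        scores1 = -scores1
        loadvecs = loadvecs.copy()
        loadvecs[0] = -loadvecs[0]

    retained_ok = bool(var_share[0] > retention_threshold)
    if not retained_ok:
        logger.warning(
            "PC1 explains %.1f%% of variance (<= %.0f%%); single-axis urban "
            "intensity may be a poor summary", 100 * var_share[0],
            100 * retention_threshold)

    values = np.full(grid.n_cells, np.nan)
    values[complete] = scores1
    loadings = pd.DataFrame(
        loadvecs.T, index=names,
        columns=[f"PC{k + 1}" for k in range(loadvecs.shape[0])])
    return UrbanIntensityRaster(
        grid=grid, values=values.reshape(grid.shape),
        variance_explained=var_share, loadings=loadings,
        reference_layer=names[ref_idx], retained_ok=retained_ok)
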