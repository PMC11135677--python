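"""Community Urban Tolerance Index (CUTI): aggregation, binning, testing.

The per-cell, per-group CUTI is the mean UAI of the group's scored
species detected in the cell, weighted by each species' thinned temporal
occurrence (the number of years, 1–11, it was recorded there).  Raw
scores are rebinned to a reversed 5-point scale::

    (-inf, -0.5) -> 5    [-0.5, -0.25) -> 4    [-0.25, 0) -> 3
    [0, 0.25)    -> 2    [0.25, 0.5)   -> 1    [0.5, inf) -> 0

so high scores mark natural-area-associated communities and low scores
urban-tolerant ones.  Group grids are averaged into a composite, citywide
means are reported per group and overall, and the association between
urban intensity and binned CUTI level is tested by one-way ANOVA with
Tukey HSD pairwise contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DegenerateDesignError, ParameterError
from .grid import GridSpec, Raster

__all__ = [
    "BIN_EDGES",
    "CUTIGrid",
    "bin_cuti",
    "cell_cuti",
    "composite",
    "citywide_summary",
    "intensity_association",
]

#: Breakpoints of the reversed 5-point scale (left-closed on the interior).
BIN_EDGES = (-0.5, -0.25, 0.0, 0.25, 0.5)


def bin_cuti(raw):
    """Map raw CUTI value(s) to the reversed 5-point scale.

    Scalar in, scalar int out; array in, int array out.  Non-finite
    values raise :class:`ParameterError`.
    """
    arr = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ParameterError("raw CUTI values must be finite")
    score = 5 - np.digitize(arr, BIN_EDGES, right=False)
    if np.isscalar(raw) or arr.ndim == 0:
        return int(score)
    return score.astype(int)


def _bin_nan(arr: np.ndarray) -> np.ndarray:
    """bin_cuti over an array with NaN passthrough."""
    out = np.full(arr.shape, np.nan)
    ok = np.isfinite(arr)
    if ok.any():
        out[ok] = 5 - np.digitize(arr[ok], BIN_EDGES, right=False)
    return out


@dataclass
class CUTIGrid:
    """Raw and binned CUTI per cell for one group (or the composite).

    Arrays are grid-length (cell_id order); NaN marks no-data cells —
    cells outside the focal region or with no scored species detected.
    For single groups ``binned`` holds integers (as floats); for the
    composite it holds means of group bins in [0, 5].
    """

    group: str
    grid: GridSpec
    raw: np.ndarray
    binned: np.ndarray
    n_species: np.ndarray

    @property
    def data_cells(self) -> np.ndarray:
        return np.nonzero(np.isfinite(self.raw))[0]

    def raw_raster(self) -> Raster:
        return Raster(self.grid, self.raw.reshape(self.grid.shape),
                      name=f"cuti_raw_{self.group}")

    def binned_raster(self) -> Raster:
        return Raster(self.grid, self.binned.reshape(self.grid.shape),
                      name=f"cuti_binned_{self.group}")

    def frame(self) -> pd.DataFrame:
        cells = self.data_cells
        return pd.DataFrame({
            "cell_id": cells,
            "group": self.group,
            "raw": self.raw[cells],
            "binned": self.binned[cells],
            "n_species": self.n_species[cells].astype(int),
        })


def cell_cuti(uai_table: pd.DataFrame, occurrences: pd.DataFrame,
              group: str, grid: GridSpec,
              focal_cells=None) -> CUTIGrid:
    """Per-cell weighted-mean UAI for one detection group.

    ``occurrences`` carries the thinned temporal occurrence per species and
    cell (columns species_id, cell_id, k with k >= 1).  Only species with
    ``status == "fitted"`` in ``uai_table`` contribute, each weighted by
    its k.  ``focal_cells`` restricts scoring to a cell subset (e.g. the
    city); other cells are no-data.
    """
    scored = uai_table[(uai_table["status"] == "fitted")
                       & (uai_table["group"] == group)]
    occ = occurrences[occurrences["species_id"].isin(set(scored["species_id"]))]
    occ = occ[occ["k"] >= 1]
    if focal_cells is not None:
        focal = np.zeros(grid.n_cells, dtype=bool)
        focal[np.asarray(list(focal_cells), dtype=int)] = True
        occ = occ[focal[occ["cell_id"].to_numpy()]]
    raw = np.full(grid.n_cells, np.nan)
    nsp = np.zeros(grid.n_cells)
    if len(occ):
        uai_by_sp = scored.set_index("species_id")["uai"]
        w = occ["k"].to_numpy(dtype=float)
        u = uai_by_sp.reindex(occ["species_id"]).to_numpy(dtype=float)
        cells = occ["cell_id"].to_numpy()
        wsum = np.bincount(cells, weights=w, minlength=grid.n_cells)
        wu = np.bincount(cells, weights=w * u, minlength=grid.n_cells)
        cnt = np.bincount(cells, minlength=grid.n_cells)
        has = wsum > 0
        raw[has] = wu[has] / wsum[has]
        nsp = cnt.astype(float)
    return CUTIGrid(group=group, grid=grid, raw=raw,
                    binned=_bin_nan(raw), n_species=nsp)


def composite(group_grids: list[CUTIGrid]) -> CUTIGrid:
    """Average group grids cell-wise into the cross-taxa composite.

    Per cell, the composite raw (binned) value is the available-case mean
    of the per-group raw (binned) values; cells with no data in any group
    stay no-data.  The composite of a single group equals that group's
    grid.
    """
    if not group_grids:
        raise ParameterError("need at least one group grid")
    grid = group_grids[0].grid
    for g in group_grids[1:]:
        if g.grid.shape != grid.shape:
            raise ParameterError("group grids live on different lattices")
    raws = np.stack([g.raw for g in group_grids])
    bins = np.stack([g.binned for g in group_grids])
    nsp = np.stack([g.n_species for g in group_grids])
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells stay NaN
        raw = np.nanmean(raws, axis=0)
        binned = np.nanmean(bins, axis=0)
    return CUTIGrid(group="composite", grid=grid, raw=raw, binned=binned,
                    n_species=np.nansum(nsp, axis=0))


def citywide_summary(group_grids: list[CUTIGrid],
                     path: str = "group-first",
                     weight_by_cells: bool = False) -> pd.DataFrame:
    """Citywide mean raw and binned CUTI per group plus the composite.

    ``path`` selects how the composite citywide score is averaged:

    * ``group-first`` (default): mean over groups of the per-group
      citywide means (each group one vote);
    * ``cell-first``: citywide mean of the per-cell composite grid.

    ``weight_by_cells`` (group-first only) weights each group's mean by
    its number of data cells instead of equally.
    """
    if path not in {"group-first", "cell-first"}:
        raise ParameterError(f"unknown averaging path {path!r}")
    rows = []
    for g in group_grids:
        cells = g.data_cells
        rows.append({
            "group": g.group,
            "n_cells": len(cells),
            "raw_cuti": float(np.mean(g.raw[cells])) if len(cells) else np.nan,
            "binned_cuti": float(np.mean(g.binned[cells])) if len(cells) else np.nan,
        })
    per_group = pd.DataFrame(rows)
    if path == "group-first":
        w = per_group["n_cells"].to_numpy(float) if weight_by_cells else None
        ok = per_group["n_cells"] > 0
        comp_raw = float(np.average(per_group.loc[ok, "raw_cuti"],
                                    weights=None if w is None else w[ok]))
        comp_bin = float(np.average(per_group.loc[ok, "binned_cuti"],
                                    weights=None if w is None else w[ok]))
        n_cells = int(per_group["n_cells"].max()) if len(per_group) else 0
    else:
        comp = composite(group_grids)
        cells = comp.data_cells
        comp_raw = float(np.mean(comp.raw[cells]))
        comp_bin = float(np.mean(comp.binned[cells]))
        n_cells = len(cells)
    out = pd.concat([per_group, pd.DataFrame([{
        "group": "composite", "n_cells": n_cells,
        "raw_cuti": comp_raw, "binned_cuti": comp_bin}])],
        ignore_index=True)
    return out


@dataclass
class AssociationResult:
    """One-way ANOVA of urban intensity on binned CUTI level + Tukey HSD."""

    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    level_means: pd.DataFrame      # level, n, mean_pc1
    tukey: pd.DataFrame | None     # pairwise contrasts (None if only 2 obs/level edge)
    infinite_f: bool = False


def intensity_association(pc1_values, binned_values,
                          alpha: float = 0.05) -> AssociationResult:
    """Test whether urban intensity differs across binned CUTI levels.

    ``pc1_values`` and ``binned_values`` are per-cell arrays (NaN cells
    dropped).  The factor is the binned level rounded to the nearest
    integer.  Requires at least two levels with at least two cells each.
    Within-group sum of squares of zero with non-zero between-group sum
    flags an infinite F (p = 0); identical responses everywhere give
    F = 0.
    """
    pc1 = np.asarray(pc1_values, dtype=float).ravel()
    binned = np.asarray(binned_values, dtype=float).ravel()
    ok = np.isfinite(pc1) & np.isfinite(binned)
    pc1, level = pc1[ok], np.rint(binned[ok]).astype(int)
    levels, counts = np.unique(level, return_counts=True)
    usable = levels[counts >= 2]
    if len(usable) < 2:
        raise DegenerateDesignError(
            "need >= 2 binned levels with >= 2 cells each "
            f"(got levels {dict(zip(levels.tolist(), counts.tolist()))})")
    keep = np.isin(level, usable)
    pc1, level = pc1[keep], level[keep]

    grand = pc1.mean()
    ss_between = ss_within = 0.0
    means = []
    for lv in usable:
        x = pc1[level == lv]
        means.append({"level": int(lv), "n": len(x), "mean_pc1": float(x.mean())})
        ss_between += len(x) * (x.mean() - grand) ** 2
        ss_within += float(((x - x.mean()) ** 2).sum())
    df_b = len(usable) - 1
    df_w = len(pc1) - len(usable)
    if ss_within == 0.0:
        if ss_between == 0.0:
            f = 0.0
            p = 1.0
            infinite = False
        else:
            f = np.inf
            p = 0.0
            infinite = True
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
        infinite = False

    tukey = None
    if ss_within > 0:
        res = pairwise_tukeyhsd(pc1, level, alpha=alpha)
        tukey = pd.DataFrame(res.summary().data[1:],
                             columns=res.summary().data[0])
    return AssociationResult(
        f_stat=float(f), df_between=df_b, df_within=df_w, p_value=p,
        level_means=pd.DataFrame(means).sort_values("level").reset_index(drop=True),
        tukey=tukey, infinite_f=infinite)
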