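"""Spatiotemporal thinning and taxon-group effort grids.

Presence-only records are reduced to at most one presence per species per
grid cell per year; the per-species count of presence-years in a cell
(``k``, 0–11 for an 11-year study) is the binomial success count.  The
matching trial count is the detection-group effort ``E``: the number of
years in which *any* retained species of the group was recorded in the
cell.  A record of one bird indexes search effort for all birds — the
detection-group assumption that converts presence-only data into a
presence / non-detection design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError
from .grid import GridSpec, Raster

__all__ = [
    "EffortGrid",
    "assign_cells",
    "thin",
    "build_effort",
    "build_binomial",
]


@dataclass
class EffortGrid:
    """Years-with-any-group-record per cell (integers, 0..n_years)."""

    group: str
    grid: GridSpec
    values: np.ndarray  # int, shape grid.shape

    def to_raster(self) -> Raster:
        return Raster(self.grid, self.values.astype(float), name=f"effort_{self.group}")

    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()


def assign_cells(records: pd.DataFrame, grid: GridSpec) -> tuple[pd.DataFrame, int]:
    """Project record coordinates and attach ``cell_id`` (and ``year``).

    Records falling outside the grid extent are excluded; the count of
    exclusions is returned alongside.  Cell membership follows the grid's
    half-open convention (south/west edges inclusive).
    """
    if grid.crs is not None:
        x, y = grid.crs.forward(records["longitude"].to_numpy(),
                                records["latitude"].to_numpy())
    else:
        x, y = records["longitude"].to_numpy(), records["latitude"].to_numpy()
    row, col = grid.cell_index(x, y)
    cell = grid.cell_id(row, col)
    inside = cell >= 0
    out = records[inside].copy()
    out["cell_id"] = cell[inside]
    out["year"] = pd.to_datetime(out["observed_on"]).dt.year
    return out.reset_index(drop=True), int((~inside).sum())


def thin(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse to unique (species_id, group, cell_id, year) presences.

    Idempotent: thinning already-thinned presences is the identity.
    """
    if "cell_id" not in records.columns:
        raise ParameterError("records need cell_id; run assign_cells first")
    cols = ["species_id", "group", "cell_id", "year"]
    return (records[cols].drop_duplicates()
            .sort_values(cols, kind="mergesort").reset_index(drop=True))


def occurrence_counts(presences: pd.DataFrame) -> pd.DataFrame:
    """Per (species_id, cell_id): k = number of distinct presence-years."""
    k = (presences.groupby(["species_id", "group", "cell_id"], sort=True)["year"]
         .nunique().rename("k").reset_index())
    return k


def build_effort(presences: pd.DataFrame, grid: GridSpec,
                 years=None) -> dict[str, EffortGrid]:
    """Group effort grids: distinct years with >= 1 presence of any species.

    ``years`` (optional) bounds the admissible range; presences outside it
    raise.  Effort is computed from the thinned presences that survived
    filtering, so excluded species do not mark effort.
    """
    if years is not None:
        years = set(int(y) for y in years)
        bad = set(presences["year"].unique()) - years
        if bad:
            raise ParameterError(f"presence years outside study window: {sorted(bad)}")
    out: dict[str, EffortGrid] = {}
    for group, sub in presences.groupby("group", sort=True):
        e = sub.drop_duplicates(["cell_id", "year"]).groupby("cell_id").size()
        vals = np.zeros(grid.n_cells, dtype=int)
        vals[e.index.to_numpy()] = e.to_numpy()
        out[group] = EffortGrid(group=group, grid=grid,
                                values=vals.reshape(grid.shape))
    return out


def build_binomial(presences: pd.DataFrame, effort: dict[str, EffortGrid],
                   species_by_group: dict[str, list[str]] | None = None,
                   ) -> pd.DataFrame:
    """Assemble the per-(species, cell) binomial table.

    One row per retained species of a group per effort-positive cell of
    that group — including explicit zeros (k = 0) for cells where the
    group was searched but the species never recorded.  Returns columns
    ``species_id``, ``group``, ``cell_id``, ``k``, ``E`` with
    ``1 <= E`` and ``0 <= k <= E`` guaranteed.
    """
    if species_by_group is None:
        species_by_group = {
            g: sorted(s["species_id"].unique())
            for g, s in presences.groupby("group", sort=True)}
    counts = occurrence_counts(presences)
    frames = []
    for group, species in species_by_group.items():
        if group not in effort:
            raise ParameterError(f"no effort grid for group {group!r}")
        e_flat = effort[group].flat
        cells = np.nonzero(e_flat > 0)[0]
        if len(cells) == 0 or len(species) == 0:
            continue
        base = pd.DataFrame({
            "species_id": np.repeat(species, len(cells)),
            "cell_id": np.tile(cells, len(species)),
        })
        base["group"] = group
        base["E"] = e_flat[base["cell_id"].to_numpy()]
        frames.append(base)
    if not frames:
        return pd.DataFrame(columns=["species_id", "group", "cell_id", "k", "E"])
    table = pd.concat(frames, ignore_index=True)
    table = table.merge(counts[["species_id", "cell_id", "k"]],
                        on=["species_id", "cell_id"], how="left")
    table["k"] = table["k"].fillna(0).astype(int)
    if (table["k"] > table["E"]).any():
        bad = table[table["k"] > table["E"]].iloc[0]
        raise AssertionError(
            f"internal consistency violation: k > E for species "
            f"{bad['species_id']!r} in cell {bad['cell_id']}")
    return table[["species_id", "group", "cell_id", "k", "E"]]
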