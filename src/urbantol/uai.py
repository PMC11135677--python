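"""Species-level Urban Association Index (UAI).

For each species the thinned presence-years ``k`` out of group effort
``E`` per grid cell are modeled as a binomial GLM with logit link and a
single covariate, the cell's urban intensity (PC1)::

    k_i ~ Binomial(E_i, expit(alpha + beta * PC1_i))

The fitted logit-linear slope ``beta`` is the species' UAI: positive
slopes indicate urban tolerance, negative slopes urban intolerance, zero
no relationship.  A species is scored only when it has at least 25
thinned annual occurrences (sum of k) across the study region; fits that
fail to converge or show complete separation are flagged degenerate and
carry no UAI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ParameterError
from .grid import Raster

__all__ = ["SpeciesUAI", "fit_uai", "fit_all", "group_summary"]

#: Minimum summed thinned occurrences for a fit to be attempted.
MIN_OCCURRENCES = 25

#: |beta| beyond this is treated as separation / a diverging fit.
_BETA_DIVERGED = 20.0


@dataclass
class SpeciesUAI:
    """Fit result for one species.

    ``status`` is ``fitted`` (uai/se valid), ``insufficient_data``
    (fewer than ``min_occurrences`` thinned occurrences; no fit attempted)
    or ``degenerate`` (separation or non-convergence; no usable slope).
    """

    species_id: str
    group: str = ""
    uai: float = np.nan
    intercept: float = np.nan
    se_beta: float = np.nan
    n_thinned: int = 0
    n_cells: int = 0
    status: str = "insufficient_data"

    def ci95(self) -> tuple[float, float]:
        """95% Wald interval for the slope."""
        half = 1.959963984540054 * self.se_beta
        return (self.uai - half, self.uai + half)


def fit_uai(rows: pd.DataFrame, pc1_by_cell,
            min_occurrences: int = MIN_OCCURRENCES) -> SpeciesUAI:
    """Fit one species' binomial urban-association regression.

    Parameters
    ----------
    rows
        Binomial table rows for a single species: columns ``species_id``,
        ``cell_id``, ``k``, ``E`` (and optionally ``group``).
    pc1_by_cell
        Urban intensity per cell: a :class:`~urbantol.grid.Raster`, a
        mapping/Series indexed by cell_id, or an array indexed by cell_id.
        Cells with missing PC1 are excluded from the fit.
    """
    if len(rows) == 0:
        raise ParameterError("empty row set")
    sp = rows["species_id"].iloc[0]
    group = rows["group"].iloc[0] if "group" in rows.columns else ""
    cells = rows["cell_id"].to_numpy()
    if isinstance(pc1_by_cell, Raster):
        pc1 = pc1_by_cell.sample_cells(cells)
    elif isinstance(pc1_by_cell, pd.Series):
        pc1 = pc1_by_cell.reindex(cells).to_numpy(dtype=float)
    else:
        pc1 = np.asarray(pc1_by_cell, dtype=float)[cells]
    k = rows["k"].to_numpy(dtype=float)
    E = rows["E"].to_numpy(dtype=float)
    if np.any(k > E) or np.any(E < 1):
        raise ParameterError("rows must satisfy 0 <= k <= E and E >= 1")
    ok = np.isfinite(pc1)
    k, E, pc1 = k[ok], E[ok], pc1[ok]

    res = SpeciesUAI(species_id=sp, group=group,
                     n_thinned=int(k.sum()), n_cells=int(len(k)))
    if res.n_thinned < min_occurrences:
        res.status = "insufficient_data"
        return res
    # complete separation in the trivial direction: every trial a success
    # (or every one a failure) leaves the slope unidentified/unbounded
    if np.all(k == E) or np.all(k == 0):
        res.status = "degenerate"
        return res
    exog = sm.add_constant(pc1)
    model = sm.GLM(np.column_stack([k, E - k]), exog,
                   family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = model.fit(maxiter=100)
    except Exception:
        res.status = "degenerate"
        return res
    beta = float(fit.params[1])
    if not fit.converged or not np.isfinite(beta) or abs(beta) > _BETA_DIVERGED:
        res.status = "degenerate"
        return res
    res.uai = beta
    res.intercept = float(fit.params[0])
    res.se_beta = float(fit.bse[1])
    res.status = "fitted"
    return res


def fit_all(binomial: pd.DataFrame, pc1_by_cell,
            min_occurrences: int = MIN_OCCURRENCES) -> pd.DataFrame:
    """Fit every species in a binomial table.

    Returns the UAI table: one row per species with columns species_id,
    group, uai, intercept, se_beta, n_thinned, n_cells, status.  Fit
    failures are recorded in ``status``, never raised.
    """
    results = []
    for _, rows in binomial.groupby("species_id", sort=True):
        results.append(fit_uai(rows, pc1_by_cell, min_occurrences))
    cols = ["species_id", "group", "uai", "intercept", "se_beta",
            "n_thinned", "n_cells", "status"]
    if not results:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([vars(r) for r in results])[cols]


def group_summary(uai_table: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean and range of UAI over fitted species.

    Mirrors the conventional reporting format
    ``mean (min to max)`` per higher-order grouping.
    """
    fitted = uai_table[uai_table["status"] == "fitted"]
    if len(fitted) == 0:
        return pd.DataFrame(columns=["group", "n_fitted", "mean_uai",
                                     "min_uai", "max_uai", "formatted"])
    g = fitted.groupby("group")["uai"]
    out = pd.DataFrame({
        "n_fitted": g.size(),
        "mean_uai": g.mean(),
        "min_uai": g.min(),
        "max_uai": g.max(),
    }).reset_index()
    out["formatted"] = [
        f"{m:.2f} ({lo:.2f} to {hi:.2f})"
        for m, lo, hi in zip(out["mean_uai"], out["min_uai"], out["max_uai"])]
    return out
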