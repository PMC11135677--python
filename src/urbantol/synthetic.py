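"""Synthetic study system: environment, species pool, and biased observations.

This module generates the three ingredients the analysis pipeline consumes,
with known ground truth so the whole chain can be validated by parameter
recovery:

* **Environment** — correlated urbanization layers (stand-ins for night
  lights, impervious surface, noise) sharing a latent "urbanness" surface
  with a high-intensity core and quieter periphery.
* **Species pool** — species in higher-order detection groups whose
  per-cell-year occurrence probability is logit-linear in urban intensity
  with a known slope (the quantity the downstream index estimates).
  The pool deliberately contains non-native, non-terrestrial,
  heavily-geoobscured and otherwise-excluded species plus subspecies
  aliases, so every downstream filter has work to do.
* **Observations** — presence-only records produced by an uneven observer
  process: observation events per cell-year follow a Poisson law whose
  mean is a group-specific effort field (optionally correlated with urban
  intensity); each event independently detects each present species of
  the group.  Records carry the metadata the filters use (quality grade,
  geoprivacy, dates, lon/lat coordinates).

Observer identity effects, weekend pulses and occupancy persistence across
years are intentionally not modeled: years are exchangeable trials, which
is exactly the assumption of the downstream binomial model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .errors import GridMismatchError, ParameterError
from .grid import GridSpec, LocalEquirectangular, MILE_QUARTER_M, Raster, write_ascii_grid

__all__ = [
    "DEFAULT_GROUPS",
    "DEFAULT_SLOPE_RANGE",
    "DEFAULT_YEARS",
    "EffortField",
    "SyntheticConfig",
    "default_grid",
    "generate_environment",
    "generate_species_pool",
    "make_curation_table",
    "make_effort_field",
    "generate_observations",
    "simulate",
]

DEFAULT_GROUPS = ("birds", "mammals", "butterflies")

#: Default span of true logit-linear slopes (urban association), matching the
#: range observed across real multi-taxon urban gradients.
DEFAULT_SLOPE_RANGE = (-2.93, 0.62)

DEFAULT_YEARS = tuple(range(2011, 2022))  # 11 study years


def default_grid(n_rows: int = 60, n_cols: int = 60,
                 center: tuple[float, float] = (34.0317, -118.2417)) -> GridSpec:
    """The default synthetic study grid: 60x60 quarter-mile cells.

    Centered (by default) on downtown Los Angeles purely to give records
    plausible lon/lat values.
    """
    crs = LocalEquirectangular(lat0=center[0], lon0=center[1])
    half_x = n_cols * MILE_QUARTER_M / 2.0
    half_y = n_rows * MILE_QUARTER_M / 2.0
    return GridSpec(n_rows=n_rows, n_cols=n_cols, cell_size=MILE_QUARTER_M,
                    origin=(-half_x, -half_y), crs=crs)


def _smooth_standard_field(shape, rng, sigma=4.0):
    """Smoothed white noise, standardized to zero mean / unit sd (ddof=0)."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")
    z = z - z.mean()
    sd = z.std()
    if sd == 0:  # pathological tiny grid
        return np.zeros(shape)
    return z / sd


def _latent_urbanness(grid: GridSpec, rng) -> np.ndarray:
    """Latent urban surface: a dense core decaying outward, plus smooth texture."""
    xx, yy = grid.cell_centers()
    xmin, ymin, xmax, ymax = grid.extent
    cx, cy = (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    scale = 0.35 * max(xmax - xmin, ymax - ymin)
    core = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * scale**2))
    z = core + 0.25 * _smooth_standard_field(grid.shape, rng) * core.std()
    z = z - z.mean()
    return z / z.std()


# nominal affine units for successive layers (radiance-, percent-, dB-like)
_LAYER_AFFINES = [(18.0, 4.0), (30.0, 35.0), (12.0, 48.0)]


def generate_environment(grid: GridSpec, n_layers: int = 3,
                         correlation: float = 0.85, seed: int = 0) -> list[Raster]:
    """Generate ``n_layers`` urbanization rasters sharing a latent surface.

    Each layer is an affine transform of ``sqrt(c)*latent + sqrt(1-c)*noise``
    with its own nominal units, so pairwise correlations between layers are
    approximately ``correlation`` (exactly 1 when ``correlation == 1``).

    Parameters
    ----------
    correlation
        Target pairwise correlation between layers, in [0, 1].
    """
    if not (0.0 <= correlation <= 1.0):
        raise ParameterError(f"correlation must be in [0, 1], got {correlation}")
    if n_layers < 2:
        raise ParameterError("n_layers must be >= 2")
    rng = np.random.default_rng(seed)
    latent = _latent_urbanness(grid, rng)
    a = np.sqrt(correlation)
    b = np.sqrt(1.0 - correlation)
    layers = []
    for i in range(n_layers):
        noise = _smooth_standard_field(grid.shape, rng, sigma=2.0)
        z = a * latent + b * noise
        scale, offset = _LAYER_AFFINES[i % len(_LAYER_AFFINES)]
        layers.append(Raster(grid, offset + scale * z, name=f"layer_{i}"))
    return layers


def generate_species_pool(n_per_group: dict[str, int] | None = None,
                          slope_range: tuple[float, float] = DEFAULT_SLOPE_RANGE,
                          seed: int = 0,
                          *,
                          nonnative_fraction: float = 0.15,
                          high_obscured_fraction: float = 0.10,
                          nonterrestrial_fraction: float = 0.05,
                          not_effort_proxy_fraction: float = 0.03,
                          exclude_other_fraction: float = 0.03,
                          subspecies_fraction: float = 0.15,
                          intercept_range: tuple[float, float] = (-2.5, -0.5),
                          detectability_range: tuple[float, float] = (0.2, 0.6),
                          ) -> pd.DataFrame:
    """Draw a species pool with known urban-association slopes.

    Returns a DataFrame with one row per species: ``species_id``, ``group``,
    ``intercept`` and ``slope`` (logit scale), ``native``, ``terrestrial``,
    ``effort_proxy_ok``, ``include``, ``obscured_fraction``,
    ``baseline_detectability`` and ``n_aliases`` (number of subspecies
    names the species' records may appear under).

    Category memberships (non-native, high-obscuration, etc.) are assigned
    by deterministic counts — ``ceil(fraction * n)``, at least one when the
    fraction is positive — so small pools still contain every filter's
    victims.
    """
    if slope_range[0] > slope_range[1]:
        raise ParameterError(f"slope_range lo > hi: {slope_range}")
    if n_per_group is None:
        n_per_group = {g: 30 for g in DEFAULT_GROUPS}
    if any(n < 0 for n in n_per_group.values()):
        raise ParameterError("species counts must be >= 0")

    rng = np.random.default_rng(seed)
    rows = []
    for group in n_per_group:
        n = n_per_group[group]
        if n == 0:
            continue
        slopes = rng.uniform(slope_range[0], slope_range[1], size=n)
        intercepts = rng.uniform(*intercept_range, size=n)
        detect = rng.uniform(*detectability_range, size=n)
        obscured = rng.uniform(0.0, 0.15, size=n)

        def pick(fraction):
            if fraction <= 0 or n == 0:
                return np.zeros(n, dtype=bool)
            k = min(n, max(1, int(np.ceil(fraction * n))))
            mask = np.zeros(n, dtype=bool)
            mask[rng.permutation(n)[:k]] = True
            return mask

        high_obs = pick(high_obscured_fraction)
        obscured[high_obs] = rng.uniform(0.65, 0.95, size=high_obs.sum())
        nonnative = pick(nonnative_fraction)
        nonterr = pick(nonterrestrial_fraction)
        notproxy = pick(not_effort_proxy_fraction)
        exclother = pick(exclude_other_fraction)
        subspp = pick(subspecies_fraction)

        for i in range(n):
            rows.append({
                "species_id": f"{group}_sp{i:03d}",
                "group": group,
                "intercept": intercepts[i],
                "slope": slopes[i],
                "native": not nonnative[i],
                "terrestrial": not nonterr[i],
                "effort_proxy_ok": not notproxy[i],
                "include": not exclother[i],
                "obscured_fraction": obscured[i],
                "baseline_detectability": detect[i],
                "n_aliases": int(subspp[i]) * int(rng.integers(1, 3)),
            })
    return pd.DataFrame(rows)


def _alias_names(species_id: str, n_aliases: int) -> list[str]:
    return [f"{species_id} ssp{chr(ord('a') + j)}" for j in range(n_aliases)]


def make_curation_table(pool: pd.DataFrame) -> pd.DataFrame:
    """Build the expert-curation table implied by a species pool.

    One row per species carrying the four expert-review flags, plus one row
    per subspecies alias mapping it to its parent species.
    """
    rows = []
    for sp in pool.itertuples(index=False):
        rows.append({
            "taxon_name": sp.species_id,
            "native": bool(sp.native),
            "terrestrial": bool(sp.terrestrial),
            "effort_proxy_ok": bool(sp.effort_proxy_ok),
            "include": bool(sp.include),
            "parent_species": "",
        })
        for alias in _alias_names(sp.species_id, sp.n_aliases):
            rows.append({
                "taxon_name": alias,
                "native": bool(sp.native),
                "terrestrial": bool(sp.terrestrial),
                "effort_proxy_ok": bool(sp.effort_proxy_ok),
                "include": bool(sp.include),
                "parent_species": sp.species_id,
            })
    return pd.DataFrame(rows)


@dataclass
class EffortField:
    """Expected observation events per cell-year, per detection group."""

    rasters: dict[str, Raster]

    def __post_init__(self) -> None:
        for group, r in self.rasters.items():
            if np.nanmin(r.values) < 0:
                raise ParameterError(f"effort for group {group!r} has negative cells")

    @property
    def groups(self) -> list[str]:
        return list(self.rasters)

    def __getitem__(self, group: str) -> Raster:
        return self.rasters[group]


def make_effort_field(grid: GridSpec, groups, mean_events: float = 1.5,
                      urban_correlation: float = 0.5,
                      env_pc1: Raster | None = None, seed: int = 0,
                      spread: float = 0.8) -> EffortField:
    """Build group-specific effort surfaces.

    Effort is log-linear in a field that mixes standardized urban intensity
    (weight ``urban_correlation``) with group-specific smooth noise, then
    rescaled so the spatial mean equals ``mean_events``.  This mimics the
    empirical pattern that community scientists concentrate where people
    live, with taxon-specific idiosyncrasies.
    """
    if not (0.0 <= urban_correlation <= 1.0):
        raise ParameterError("urban_correlation must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if env_pc1 is not None:
        if env_pc1.grid.shape != grid.shape:
            raise GridMismatchError("env_pc1 grid differs from target grid")
        z = env_pc1.values - np.nanmean(env_pc1.values)
        sd = np.nanstd(z)
        z = z / sd if sd > 0 else np.zeros(grid.shape)
        z = np.where(np.isfinite(z), z, 0.0)
    else:
        z = np.zeros(grid.shape)
    w = urban_correlation
    rasters = {}
    for group in groups:
        noise = _smooth_standard_field(grid.shape, rng, sigma=3.0)
        f = w * z + np.sqrt(max(0.0, 1.0 - w**2)) * noise
        e = np.exp(spread * f)
        e *= mean_events / e.mean()
        rasters[group] = Raster(grid, e, name=f"effort_{group}")
    return EffortField(rasters)


def generate_observations(pool: pd.DataFrame, env_pc1: Raster,
                          effort: EffortField, years=DEFAULT_YEARS,
                          seed: int = 0, *,
                          research_grade_prob: float = 0.95,
                          alias_prob: float = 0.25,
                          n_users: int = 500,
                          obscure_offset_km: float = 0.0,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate presence-only records and return (records, truth_table).

    For every (cell, year, group): the number of observation events is
    Poisson with mean equal to the group's effort surface; each event
    independently detects each species of the group that is present with
    the species' baseline detectability.  Presence per (species, cell,
    year) is Bernoulli with probability ``expit(a + b * PC1)``, redrawn
    independently each year.

    Records for species with subspecies aliases appear under an alias name
    with probability ``alias_prob``.  Geoprivacy-obscured records keep
    their true coordinates unless ``obscure_offset_km > 0`` (they are
    dropped downstream either way).

    Returns
    -------
    records : DataFrame
        Columns taxon_name, group, latitude, longitude, observed_on,
        quality_grade, geoprivacy, user_id — the iNaturalist-export-like
        dialect the filtering stage reads.
    truth : DataFrame
        species_id, group, intercept, slope (the true urban association),
        native, obscured_fraction.
    """
    grid = env_pc1.grid
    for group in effort.groups:
        if effort[group].grid.shape != grid.shape:
            raise GridMismatchError(f"effort grid for {group!r} differs from PC1 grid")
    missing = set(pool["group"]) - set(effort.groups)
    if missing:
        raise GridMismatchError(f"no effort raster for groups: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    years = np.asarray(sorted(years))
    n_years = len(years)
    n_cells = grid.n_cells
    pc1 = env_pc1.flat
    pc1_ok = np.isfinite(pc1)

    frames = []
    for group in effort.groups:
        sub = pool[pool["group"] == group].reset_index(drop=True)
        n_sp = len(sub)
        lam = effort[group].flat
        # events per (cell, year)
        events = rng.poisson(np.broadcast_to(lam[:, None], (n_cells, n_years)))
        if n_sp == 0 or events.sum() == 0:
            continue
        a = sub["intercept"].to_numpy()[:, None]
        b = sub["slope"].to_numpy()[:, None]
        p_occ = np.where(pc1_ok[None, :], expit(a + b * np.where(pc1_ok, pc1, 0.0)[None, :]), 0.0)
        # presence: (species, cell, year)
        present = rng.random((n_sp, n_cells, n_years)) < p_occ[:, :, None]
        det = sub["baseline_detectability"].to_numpy()
        # detections | events, presence
        p_det = present * det[:, None, None]
        counts = rng.binomial(events[None, :, :], p_det)

        sp_idx, cell_idx, yr_idx = np.nonzero(counts)
        reps = counts[sp_idx, cell_idx, yr_idx]
        sp_idx = np.repeat(sp_idx, reps)
        cell_idx = np.repeat(cell_idx, reps)
        yr_idx = np.repeat(yr_idx, reps)
        n_rec = len(sp_idx)
        if n_rec == 0:
            continue

        row, col = grid.cell_rowcol(cell_idx)
        x = grid.origin[0] + (col + rng.random(n_rec)) * grid.cell_size
        y = grid.origin[1] + (row + rng.random(n_rec)) * grid.cell_size
        obs_frac = sub["obscured_fraction"].to_numpy()[sp_idx]
        obscured = rng.random(n_rec) < obs_frac
        if obscure_offset_km > 0:
            theta = rng.uniform(0, 2 * np.pi, n_rec)
            rad = rng.uniform(0, obscure_offset_km * 1000.0, n_rec)
            x = x + np.where(obscured, rad * np.cos(theta), 0.0)
            y = y + np.where(obscured, rad * np.sin(theta), 0.0)
        if grid.crs is not None:
            lon, lat = grid.crs.inverse(x, y)
        else:
            lon, lat = x, y

        names = sub["species_id"].to_numpy()[sp_idx].astype(object)
        n_ali = sub["n_aliases"].to_numpy()[sp_idx]
        use_alias = (n_ali > 0) & (rng.random(n_rec) < alias_prob)
        if use_alias.any():
            pick = rng.integers(0, np.maximum(n_ali, 1))
            for i in np.nonzero(use_alias)[0]:
                names[i] = _alias_names(names[i], n_ali[i])[pick[i] % n_ali[i]]

        day = rng.integers(0, 365, n_rec)
        year_starts = np.array([np.datetime64(f"{y}-01-01") for y in years])
        observed_on = year_starts[yr_idx] + day.astype("timedelta64[D]")

        frames.append(pd.DataFrame({
            "taxon_name": names,
            "group": group,
            "latitude": lat,
            "longitude": lon,
            "observed_on": observed_on,
            "quality_grade": np.where(rng.random(n_rec) < research_grade_prob,
                                      "research", "casual"),
            "geoprivacy": np.where(obscured, "obscured", "open"),
            "user_id": rng.integers(1, n_users + 1, n_rec),
        }))

    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = pd.DataFrame(columns=["taxon_name", "group", "latitude", "longitude",
                                        "observed_on", "quality_grade", "geoprivacy",
                                        "user_id"])
    records = records.sort_values(
        ["observed_on", "group", "taxon_name", "latitude", "longitude"],
        kind="mergesort").reset_index(drop=True)
    truth = pool[["species_id", "group", "intercept", "slope", "native",
                  "obscured_fraction"]].copy()
    return records, truth


@dataclass
class SyntheticConfig:
    """Declarative configuration for :func:`simulate` (JSON-serializable)."""

    n_rows: int = 60
    n_cols: int = 60
    center: tuple[float, float] = (34.0317, -118.2417)
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_species_per_group: int = 30
    slope_range: tuple[float, float] = DEFAULT_SLOPE_RANGE
    layer_correlation: float = 0.85
    n_layers: int = 3
    mean_events: float = 1.5
    urban_correlation: float = 0.5
    years: tuple[int, ...] = DEFAULT_YEARS
    research_grade_prob: float = 0.95

    @classmethod
    def from_file(cls, path) -> "SyntheticConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def to_file(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def simulate(config: SyntheticConfig, seed: int, outdir) -> dict:
    """Run the full generator and write CSV/raster outputs to ``outdir``.

    Writes records.csv, truth.csv, curation.csv, layer_*.asc and the grid
    description grid.json; returns the in-memory objects as a dict.
    """
    from .urban_intensity import composite_pca

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    s_env, s_pool, s_eff, s_obs = rng.integers(0, 2**31 - 1, size=4)

    grid = default_grid(config.n_rows, config.n_cols, config.center)
    layers = generate_environment(grid, config.n_layers, config.layer_correlation,
                                  seed=int(s_env))
    pc1 = composite_pca(layers).to_raster()
    pool = generate_species_pool(
        {g: config.n_species_per_group for g in config.groups},
        config.slope_range, seed=int(s_pool))
    effort = make_effort_field(grid, config.groups, config.mean_events,
                               config.urban_correlation, env_pc1=pc1,
                               seed=int(s_eff))
    records, truth = generate_observations(
        pool, pc1, effort, years=config.years, seed=int(s_obs),
        research_grade_prob=config.research_grade_prob)
    curation = make_curation_table(pool)

    records.to_csv(outdir / "records.csv", index=False)
    truth.to_csv(outdir / "truth.csv", index=False)
    curation.to_csv(outdir / "curation.csv", index=False)
    for layer in layers:
        write_ascii_grid(outdir / f"{layer.name}.asc", layer)
    (outdir / "grid.json").write_text(json.dumps({
        "n_rows": grid.n_rows, "n_cols": grid.n_cols,
        "cell_size": grid.cell_size, "origin": list(grid.origin),
        "crs": {"lat0": grid.crs.lat0, "lon0": grid.crs.lon0},
    }, indent=2))
    return {"grid": grid, "layers": layers, "pc1": pc1, "pool": pool,
            "effort": effort, "records": records, "truth": truth,
            "curation": curation}
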