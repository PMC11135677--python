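"""Record-quality, geoprivacy, taxonomy and expert-curation filters.

Raw presence-only records (iNaturalist-export-like CSV) pass through four
stages, in a fixed order:

1. **quality** — research-grade only, finite coordinates, date inside the
   study window, point inside the study region (boundary-inclusive);
2. **geoprivacy** — species whose share of coordinate-obscured records
   exceeds 60% (strictly) are removed wholesale, then every remaining
   obscured record is dropped.  The share must be computed *before* the
   obscured records are removed — afterwards it is identically zero;
3. **subspecies reclassification** — records identified below species
   rank are lifted to their parent species, merging record sets;
4. **curation** — expert flags (native, terrestrial, usable as an effort
   proxy, no other exclusion reason) are applied as a conjunction.

Every stage reports per-reason drop counts so that
``len(input) == len(output) + sum(drops)`` holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .errors import CurationGapError, ParameterError

__all__ = [
    "CurationTable",
    "FilterResult",
    "filter_quality",
    "filter_geoprivacy",
    "reclassify_subspecies",
    "filter_curation",
    "apply_filters",
    "DEFAULT_OBSCURED_THRESHOLD",
]

#: Species with strictly more than this share of obscured records are removed.
DEFAULT_OBSCURED_THRESHOLD = 0.6

_CURATION_FLAGS = ("native", "terrestrial", "effort_proxy_ok", "include")


class CurationTable:
    """Expert-review flags plus the subspecies → species map.

    Wraps a DataFrame with columns ``taxon_name``, the four boolean flags
    ``native``, ``terrestrial``, ``effort_proxy_ok``, ``include``, and
    ``parent_species`` (empty/NaN for species-rank taxa).
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing = {"taxon_name", *_CURATION_FLAGS} - set(frame.columns)
        if missing:
            raise ParameterError(f"curation table missing columns: {sorted(missing)}")
        if "parent_species" not in frame.columns:
            frame["parent_species"] = ""
        frame["parent_species"] = frame["parent_species"].fillna("")
        for flag in _CURATION_FLAGS:
            frame[flag] = frame[flag].astype(bool)
        if frame["taxon_name"].duplicated().any():
            dups = frame.loc[frame["taxon_name"].duplicated(), "taxon_name"]
            raise ParameterError(f"duplicate curation entries: {sorted(set(dups))}")
        self.frame = frame.set_index("taxon_name")

    @classmethod
    def from_csv(cls, path) -> "CurationTable":
        return cls(pd.read_csv(path))

    def __contains__(self, name: str) -> bool:
        return name in self.frame.index

    def parent_of(self, name: str) -> str:
        """Canonical species name for ``name`` (itself if species-rank)."""
        parent = self.frame.at[name, "parent_species"]
        return parent if parent else name

    def flags(self, name: str) -> pd.Series:
        return self.frame.loc[name, list(_CURATION_FLAGS)]


@dataclass
class FilterResult:
    """A filtered record table plus per-reason drop counts."""

    records: pd.DataFrame
    dropped: dict[str, int]

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


def _is_obscured(records: pd.DataFrame) -> pd.Series:
    return records["geoprivacy"].fillna("open").str.lower().eq("obscured")


def filter_quality(records: pd.DataFrame,
                   window: tuple = ("2011-01-01", "2021-12-31"),
                   region=None) -> FilterResult:
    """Research-grade, georeferenced, in-window, in-region records only.

    ``region`` is a shapely geometry in the same lon/lat frame as the
    record coordinates; containment is boundary-inclusive (``covers``).
    Drop reasons are assigned with precedence quality → coordinates →
    window → region, one reason per dropped row.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if start > end:
        raise ParameterError(f"empty study window: {window}")
    dates = pd.to_datetime(records["observed_on"])
    good_quality = records["quality_grade"].str.lower().eq("research")
    lon = pd.to_numeric(records["longitude"], errors="coerce")
    lat = pd.to_numeric(records["latitude"], errors="coerce")
    good_coords = np.isfinite(lon) & np.isfinite(lat)
    in_window = (dates >= start) & (dates <= end)
    if region is not None:
        pts = shapely.points(np.where(good_coords, lon, 0.0),
                             np.where(good_coords, lat, 0.0))
        shapely.prepare(region)
        in_region = shapely.covers(region, pts) & good_coords.to_numpy()
    else:
        in_region = np.ones(len(records), dtype=bool)

    keep = good_quality & good_coords & in_window & in_region
    dropped = {
        "not_research_grade": int((~good_quality).sum()),
        "bad_coordinates": int((good_quality & ~good_coords).sum()),
        "outside_window": int((good_quality & good_coords & ~in_window).sum()),
        "outside_region": int((good_quality & good_coords & in_window & ~in_region).sum()),
    }
    return FilterResult(records[keep].reset_index(drop=True), dropped)


def filter_geoprivacy(records: pd.DataFrame,
                      threshold: float = DEFAULT_OBSCURED_THRESHOLD) -> FilterResult:
    """Two-stage geoprivacy filter.

    Stage 1 computes, per taxon, the share of records flagged obscured
    over *all* of that taxon's records in the input, and removes taxa with
    share strictly greater than ``threshold`` (an exactly-at-threshold
    species survives).  Stage 2 drops the remaining obscured records.
    """
    if not (0.0 < threshold <= 1.0):
        raise ParameterError(f"threshold must be in (0, 1], got {threshold}")
    obscured = _is_obscured(records)
    share = obscured.groupby(records["taxon_name"]).mean()
    bad_taxa = set(share.index[share > threshold])
    in_bad = records["taxon_name"].isin(bad_taxa)
    stage2 = obscured & ~in_bad
    keep = ~in_bad & ~stage2
    dropped = {
        "species_over_obscured_threshold": int(in_bad.sum()),
        "obscured_record": int(stage2.sum()),
    }
    return FilterResult(records[keep].reset_index(drop=True), dropped)


def _looks_infraspecific(name: str) -> bool:
    # Genus + epithet = 2 tokens; anything longer is below species rank.
    return len(str(name).split()) > 2


def reclassify_subspecies(records: pd.DataFrame,
                          curation: CurationTable) -> pd.DataFrame:
    """Lift subspecies-rank records to their parent species.

    Adds/overwrites a ``species_id`` column: the curation table's
    ``parent_species`` when the taxon is mapped, otherwise the taxon name
    itself.  Taxa that look infraspecific (more than two name tokens) but
    have no mapping raise :class:`CurationGapError` listing the names.
    No records are dropped.
    """
    names = records["taxon_name"]
    mapped = names.map(
        lambda n: curation.parent_of(n) if n in curation else n)
    unmapped = sorted(
        n for n in names.unique()
        if _looks_infraspecific(n) and (n not in curation or curation.parent_of(n) == n))
    if unmapped:
        raise CurationGapError(unmapped, "unmapped subspecies names")
    out = records.copy()
    out["species_id"] = mapped
    return out


def filter_curation(records: pd.DataFrame, curation: CurationTable,
                    strict: bool = True,
                    default_include: bool = False) -> FilterResult:
    """Apply the four expert flags as a conjunction.

    Records are matched by ``species_id`` (falling back to ``taxon_name``).
    A taxon absent from the table raises :class:`CurationGapError` under
    ``strict``; otherwise the ``default_include`` policy applies.  The
    drop reason per record is the first failing flag, in the order native
    → terrestrial → effort-proxy → other.
    """
    key = records["species_id"] if "species_id" in records.columns else records["taxon_name"]
    present = key.map(lambda n: n in curation)
    if strict and not present.all():
        raise CurationGapError(sorted(key[~present].unique()),
                               "taxa missing from curation table")
    reason_names = {"native": "non_native", "terrestrial": "non_terrestrial",
                    "effort_proxy_ok": "not_effort_proxy", "include": "excluded_other"}
    flag_frame = pd.DataFrame(
        {f: key.map(lambda n, f=f: bool(curation.frame.at[n, f]) if n in curation
                    else default_include)
         for f in _CURATION_FLAGS})
    keep = flag_frame.all(axis=1) & (present | default_include)
    dropped: dict[str, int] = {}
    blamed = pd.Series(False, index=records.index)
    if not strict:
        miss = ~present & ~default_include
        dropped["missing_curation"] = int(miss.sum())
        blamed |= miss
    for f in _CURATION_FLAGS:
        fails = ~flag_frame[f] & ~blamed
        dropped[reason_names[f]] = int(fails.sum())
        blamed |= fails
    return FilterResult(records[keep].reset_index(drop=True), dropped)


def apply_filters(records: pd.DataFrame, curation: CurationTable,
                  window: tuple = ("2011-01-01", "2021-12-31"),
                  region=None,
                  obscured_threshold: float = DEFAULT_OBSCURED_THRESHOLD,
                  strict: bool = True) -> FilterResult:
    """Run the full filter chain in the canonical order.

    quality → geoprivacy → subspecies reclassification → curation.
    The returned drop counts concatenate all stages (keys prefixed by
    stage) and satisfy exact row bookkeeping.
    """
    dropped: dict[str, int] = {}
    q = filter_quality(records, window=window, region=region)
    dropped.update({f"quality:{k}": v for k, v in q.dropped.items()})
    g = filter_geoprivacy(q.records, threshold=obscured_threshold)
    dropped.update({f"geoprivacy:{k}": v for k, v in g.dropped.items()})
    r = reclassify_subspecies(g.records, curation)
    c = filter_curation(r, curation, strict=strict)
    dropped.update({f"curation:{k}": v for k, v in c.dropped.items()})
    assert len(records) == len(c.records) + sum(dropped.values())
    return FilterResult(c.records, dropped)
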