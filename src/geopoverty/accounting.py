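"""Zonal population accounting on the land classification.

Tabulates rural populations per country on degrading/improving and
remote/accessible agricultural land, computes the four spatial shares
(d1: all DAL, d2: remote DAL, i1: all IAL, i2: remote IAL, each as a
percent of the country's rural population), aggregates countries into
regions and world totals, and summarises between-epoch changes in counts
and in population density on classified land.

"Rural" is the complement of the urban-extent mask. Regional share
columns are recomputed from the summed populations, never averaged over
country shares. Reported tables round populations to 0.1 million and
shares to 0.1 percent; internal values stay unrounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import LandClass, LandClassGrid
from .grids import ConfigurationError, GridLayer

__all__ = [
    "CountryTabulation",
    "tabulate_country",
    "compute_region_table",
    "epoch_change",
    "density_change",
    "region_table_to_frame",
]

DEVELOPING_REGIONS = ("EAP", "ECA", "LAC", "MENA", "SA", "SSA")


@dataclass
class CountryTabulation:
    """Rural population of one country by land class, with the four shares (%)."""

    zone_id: int
    epoch: int
    rural_pop: float
    pop_dal: float
    pop_dal_remote: float
    pop_ial: float
    pop_ial_remote: float
    d1: float = np.nan
    d2: float = np.nan
    i1: float = np.nan
    i2: float = np.nan
    shares_defined: bool = True

    def __post_init__(self) -> None:
        if self.rural_pop > 0:
            self.d1 = 100.0 * self.pop_dal / self.rural_pop
            self.d2 = 100.0 * self.pop_dal_remote / self.rural_pop
            self.i1 = 100.0 * self.pop_ial / self.rural_pop
            self.i2 = 100.0 * self.pop_ial_remote / self.rural_pop
            self.shares_defined = True
        else:
            self.d1 = self.d2 = self.i1 = self.i2 = np.nan
            self.shares_defined = False


def tabulate_country(
    labels: LandClassGrid,
    population: GridLayer,
    urban_mask: GridLayer,
    country_zone: GridLayer,
    epoch: int = 2000,
) -> list[CountryTabulation]:
    """Sum rural population by land class within each country zone."""
    for layer in (population, urban_mask, country_zone):
        if layer.shape != labels.labels.shape:
            raise ValueError("all layers must share the label grid's shape")
    pop_ok = population.valid_mask()
    rural = (urban_mask.values != 1) & urban_mask.valid_mask() & pop_ok
    rural &= country_zone.valid_mask()

    zone = country_zone.values.astype(int).ravel()
    pop = np.where(pop_ok, population.values, 0.0).ravel()
    lab = labels.labels.ravel()
    sel = rural.ravel()

    df = pd.DataFrame({"zone": zone[sel], "pop": pop[sel], "label": lab[sel]})
    out: list[CountryTabulation] = []
    all_zones = np.unique(zone[country_zone.valid_mask().ravel()])
    grouped = df.groupby("zone")
    for z in all_zones:
        if z in grouped.groups:
            g = grouped.get_group(z)
            bylab = g.groupby("label")["pop"].sum()
            get = lambda c: float(bylab.get(int(c), 0.0))
            out.append(
                CountryTabulation(
                    zone_id=int(z),
                    epoch=epoch,
                    rural_pop=float(g["pop"].sum()),
                    pop_dal=get(LandClass.DAL_ACC) + get(LandClass.DAL_REM),
                    pop_dal_remote=get(LandClass.DAL_REM),
                    pop_ial=get(LandClass.IAL_ACC) + get(LandClass.IAL_REM),
                    pop_ial_remote=get(LandClass.IAL_REM),
                )
            )
        else:
            out.append(CountryTabulation(int(z), epoch, 0.0, 0.0, 0.0, 0.0, 0.0))
    return out


@dataclass
class RegionAggregate:
    """Populations summed over a region's member countries, shares recomputed."""

    region: str
    epoch: int
    rural_pop: float
    pop_dal: float
    pop_dal_remote: float
    pop_ial: float
    pop_ial_remote: float
    d1: float = field(init=False)
    d2: float = field(init=False)
    i1: float = field(init=False)
    i2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.rural_pop > 0:
            self.d1 = 100.0 * self.pop_dal / self.rural_pop
            self.d2 = 100.0 * self.pop_dal_remote / self.rural_pop
            self.i1 = 100.0 * self.pop_ial / self.rural_pop
            self.i2 = 100.0 * self.pop_ial_remote / self.rural_pop
        else:
            self.d1 = self.d2 = self.i1 = self.i2 = np.nan


_POP_FIELDS = ("rural_pop", "pop_dal", "pop_dal_remote", "pop_ial", "pop_ial_remote")


def compute_region_table(
    tabs: list[CountryTabulation], region_map: dict[int, str]
) -> list[RegionAggregate]:
    """Aggregate country tabulations into region, Developing, Developed and World rows."""
    unmapped = sorted({t.zone_id for t in tabs} - set(region_map))
    if unmapped:
        raise ConfigurationError(f"zones missing from region_map: {unmapped}")

    def agg(region: str, members: list[CountryTabulation], epoch: int) -> RegionAggregate:
        sums = {f: float(sum(getattr(t, f) for t in members)) for f in _POP_FIELDS}
        return RegionAggregate(region=region, epoch=epoch, **sums)

    epoch = tabs[0].epoch if tabs else 0
    by_region: dict[str, list[CountryTabulation]] = {}
    for t in tabs:
        by_region.setdefault(region_map[t.zone_id], []).append(t)

    rows = [
        agg(region, by_region[region], epoch)
        for region in DEVELOPING_REGIONS
        if region in by_region
    ]
    developing = [t for t in tabs if region_map[t.zone_id] in DEVELOPING_REGIONS]
    developed = [t for t in tabs if region_map[t.zone_id] == "DEV"]
    rows.append(agg("Developing", developing, epoch))
    rows.append(agg("Developed", developed, epoch))
    rows.append(agg("World", tabs, epoch))
    return rows


def region_table_to_frame(rows: list[RegionAggregate], scale: float = 1.0) -> pd.DataFrame:
    """Rows as a display DataFrame; populations divided by ``scale`` (e.g. 1e6)."""
    rec = []
    for r in rows:
        rec.append(
            {
                "region": r.region,
                "epoch": r.epoch,
                **{f: getattr(r, f) / scale for f in _POP_FIELDS},
                "d1": r.d1,
                "d2": r.d2,
                "i1": r.i1,
                "i2": r.i2,
            }
        )
    return pd.DataFrame(rec)


def epoch_change(
    tabs_2000: list[CountryTabulation], tabs_2010: list[CountryTabulation]
) -> pd.DataFrame:
    """Percent change 2000->2010 per zone for every population column.

    Changes from a zero base are flagged undefined (NaN) rather than raising.
    """
    z0 = {t.zone_id: t for t in tabs_2000}
    z1 = {t.zone_id: t for t in tabs_2010}
    if set(z0) != set(z1):
        raise ValueError("epoch tabulations cover different zone sets")
    rec = []
    for z in sorted(z0):
        row: dict[str, float | int | bool] = {"zone_id": z}
        defined = True
        for f in _POP_FIELDS:
            a, b = getattr(z0[z], f), getattr(z1[z], f)
            if a == 0:
                row[f"pct_change_{f}"] = np.nan
                defined = False
            else:
                row[f"pct_change_{f}"] = 100.0 * (b - a) / a
        row["all_defined"] = defined
        rec.append(row)
    return pd.DataFrame(rec)


def density_change(
    pop_2000: GridLayer,
    pop_2010: GridLayer,
    labels: LandClassGrid,
    cell_area: float = 1.0,
    bins: int = 10,
) -> pd.DataFrame:
    """Summary of per-cell population-density change on DAL and IAL cells.

    Returns one row per class with count, mean, median and histogram
    (counts and bin edges) of (pop2010 - pop2000) / cell_area.
    """
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")
    ok = pop_2000.valid_mask() & pop_2010.valid_mask()
    delta = (pop_2010.values - pop_2000.values) / cell_area
    rows = []
    for name, mask in (("DAL", labels.dal_mask), ("IAL", labels.ial_mask)):
        vals = delta[mask & ok]
        if vals.size:
            hist, edges = np.histogram(vals, bins=bins)
            rows.append(
                {
                    "land_class": name,
                    "n_cells": int(vals.size),
                    "mean": float(vals.mean()),
                    "median": float(np.median(vals)),
                    "hist_counts": hist.tolist(),
                    "hist_edges": edges.tolist(),
                }
            )
        else:
            rows.append(
                {"land_class": name, "n_cells": 0, "mean": np.nan, "median": np.nan,
                 "hist_counts": [], "hist_edges": []}
            )
    return pd.DataFrame(rows)
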