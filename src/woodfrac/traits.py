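"""Structural and growth traits from raw field measurements.

SLA, Huber value and wood density are simple ratios with unit bookkeeping;
relative basal area increment annualises dendrometer readings; leaf lifespan
is estimated demographically from repeated twig censuses as standing leaf
count over turnover rate, averaging the birth-based and shedding-based
estimates.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "LeafSample",
    "DendrometerSeries",
    "TwigCensus",
    "specific_leaf_area",
    "huber_value",
    "wood_density",
    "volume_by_displacement",
    "relative_bai",
    "leaf_lifespan",
]

DAYS_PER_YEAR = 365.25
WATER_DENSITY_20C_G_CM3 = 0.9982


@dataclass(frozen=True)
class LeafSample:
    total_area_cm2: float
    dry_mass_g: float
    n_leaves: int = 1

    def __post_init__(self):
        if self.total_area_cm2 <= 0 or self.dry_mass_g <= 0 or self.n_leaves <= 0:
            raise ValueError("leaf sample fields must be positive")


@dataclass(frozen=True)
class DendrometerSeries:
    """Chronological diameter-at-breast-height readings (cm)."""

    dates: tuple[dt.date, ...]
    dbh_cm: tuple[float, ...]

    def __post_init__(self):
        if len(self.dates) != len(self.dbh_cm) or len(self.dates) < 2:
            raise ValueError("need >= 2 paired readings")
        if list(self.dates) != sorted(self.dates):
            raise ValueError("dates must be chronological")
        if min(self.dbh_cm) <= 0:
            raise ValueError("diameters must be positive")


@dataclass(frozen=True)
class TwigCensus:
    """Repeated per-twig leaf counts: standing green leaves, cumulative
    births between censuses, and cumulative shed (senescent + dry) leaves."""

    dates: tuple[dt.date, ...]
    standing: tuple[float, ...]  # green leaves present at each census
    births: tuple[float, ...]  # new leaves appearing in each inter-census gap
    shed: tuple[float, ...]  # leaves lost in each inter-census gap

    def __post_init__(self):
        n = len(self.dates)
        if n < 2:
            raise ValueError("need >= 2 censuses")
        if len(self.standing) != n or len(self.births) != n - 1 or len(self.shed) != n - 1:
            raise ValueError("births/shed must have one entry per census gap")
        if list(self.dates) != sorted(self.dates):
            raise ValueError("census dates must be ordered")
        if min(min(self.standing), min(self.births), min(self.shed)) < 0:
            raise ValueError("counts must be non-negative")


def specific_leaf_area(sample: LeafSample) -> float:
    """SLA = leaf area / dry mass (cm^2 g^-1)."""
    return sample.total_area_cm2 / sample.dry_mass_g


def huber_value(sapwood_area_cm2: float, leaf_area_cm2: float) -> float:
    """HV = sapwood cross-sectional area per unit distal leaf area (cm^2 cm^-2).

    Sapwood area excludes bark and pith.
    """
    if leaf_area_cm2 <= 0:
        raise ValueError("leaf area must be positive")
    if sapwood_area_cm2 < 0:
        raise ValueError("sapwood area must be non-negative")
    return sapwood_area_cm2 / leaf_area_cm2


def volume_by_displacement(submerged_mass_g: float,
                           water_density_g_cm3: float = WATER_DENSITY_20C_G_CM3) -> float:
    """Fresh volume (cm^3) from the mass of water displaced (Archimedes)."""
    if submerged_mass_g <= 0:
        raise ValueError("displaced mass must be positive")
    return submerged_mass_g / water_density_g_cm3


def wood_density(dry_mass_g: float, fresh_volume_cm3: float) -> float:
    """Basic wood density = oven-dry mass / fresh volume (g cm^-3)."""
    if fresh_volume_cm3 <= 0:
        raise ValueError("volume must be positive")
    if dry_mass_g <= 0:
        raise ValueError("mass must be positive")
    wd = dry_mass_g / fresh_volume_cm3
    if not 0.1 <= wd <= 1.4:
        log.warning("wood density %.3f g cm^-3 outside plausible range 0.1-1.4", wd)
    return wd


def relative_bai(series: DendrometerSeries) -> float:
    """Relative basal area increment, % yr^-1, annualised over the series span.

    Basal area BA = pi d^2 / 4; relative BAI = 100 (BA_end - BA_start)/BA_start
    scaled by 365.25 / elapsed days.
    """
    days = (series.dates[-1] - series.dates[0]).days
    if days < 28:
        raise ValueError("series must span at least one month")
    ba = np.pi * np.asarray(series.dbh_cm, dtype=float) ** 2 / 4.0
    rel = 100.0 * (ba[-1] - ba[0]) / ba[0]
    return rel * DAYS_PER_YEAR / days


def leaf_lifespan(census: TwigCensus) -> float:
    """Leaf lifespan (years) = mean of birth-based and shedding-based estimates.

    Each estimate is mean standing leaf count divided by the annualised flux
    (births or sheddings per year); at demographic steady state both agree and
    equal the true mean residence time.
    """
    days = (census.dates[-1] - census.dates[0]).days
    if days <= 0:
        raise ValueError("census interval must be positive")
    years = days / DAYS_PER_YEAR
    standing_mean = float(np.mean(census.standing))
    birth_rate = sum(census.births) / years
    shed_rate = sum(census.shed) / years
    if birth_rate == 0 and shed_rate == 0:
        raise ValueError("no leaf turnover observed: lifespan undefined")
    estimates = []
    for rate, label in ((birth_rate, "birth"), (shed_rate, "shedding")):
        if rate > 0:
            estimates.append(standing_mean / rate)
        else:
            warnings.warn(f"zero {label} rate; using single-flux estimate",
                          stacklevel=2)
    return float(np.mean(estimates))
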