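"""Packaged species-level tables: site soil chemistry, tissue N/P, structural traits.

The tables ship as UTF-8 CSV fixtures transcribed cell-by-cell from the printed
species tables of the field study (16 Australian evergreen tree species, 8 on
nutrient-poor sandstone plateau soil and 8 on nutrient-rich gully soil).
Numeric cells are stored as the printed strings so that serialisation
round-trips bit-exactly; parsed views convert to float on access.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

__all__ = [
    "TISSUES",
    "ELEMENTS",
    "SoilRecord",
    "SpeciesRecord",
    "FixtureError",
    "fixture_path",
    "read_raw",
    "load_soil_table",
    "load_species",
    "load_tissue_nutrients",
    "load_trait_table",
    "load_packaged_tables",
    "tissue_nutrient_lookup",
]

#: Tissue compartments sampled per tree, outermost leaf pool to bark.
TISSUES = (
    "fresh_leaves",
    "senescent_leaves",
    "twig_wood",
    "outer_sapwood",
    "inner_wood",
    "bark",
)
ELEMENTS = ("N", "P")  # N in mg g^-1, P in mg kg^-1

_FILES = {
    "soil": "site_soil.csv",
    "species": "species.csv",
    "nutrients": "tissue_nutrients.csv",
    "traits": "structural_traits.csv",
}


class FixtureError(ValueError):
    """A packaged fixture failed validation; message names file and row."""


@dataclass(frozen=True)
class SoilRecord:
    site_id: str
    nutrient_class: str  # low | high | greenhouse
    C: float  # %
    N_total: float  # mg g^-1
    P_total: float  # mg kg^-1
    K_total: float  # mg kg^-1
    Ca_total: float  # mg kg^-1
    P_extractable: float  # mg kg^-1


@dataclass(frozen=True)
class SpeciesRecord:
    species_name: str
    abbreviation: str
    family: str
    soil_class: str  # low | high

    @property
    def genus(self) -> str:
        return self.species_name.split()[0]


def fixture_path(key: str):
    return resources.files("woodfrac.data") / _FILES[key]


def read_raw(key: str) -> pd.DataFrame:
    """Read a fixture with every cell kept as its printed string."""
    with resources.as_file(fixture_path(key)) as path:
        return pd.read_csv(path, dtype=str, keep_default_na=False)


def _as_float(df: pd.DataFrame, cols, key: str) -> pd.DataFrame:
    df = df.copy()
    for col in cols:
        try:
            df[col] = pd.to_numeric(df[col].replace("", None))
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & (df[col] != "")]
            row = int(bad.index[0]) + 2 if len(bad) else "?"
            raise FixtureError(
                f"{_FILES[key]}: non-numeric value in column {col!r} at line {row}"
            ) from exc
    return df


def load_soil_table() -> list[SoilRecord]:
    """Site soil chemistry: 6 low + 6 high field sites + 1 greenhouse soil."""
    df = _as_float(
        read_raw("soil"),
        ["C_percent", "N_total_mg_g", "P_total_mg_kg", "K_total_mg_kg",
         "Ca_total_mg_kg", "P_extractable_mg_kg"],
        "soil",
    )
    records = [
        SoilRecord(r.site_id, r.nutrient_class, r.C_percent, r.N_total_mg_g,
                   r.P_total_mg_kg, r.K_total_mg_kg, r.Ca_total_mg_kg,
                   r.P_extractable_mg_kg)
        for r in df.itertuples()
    ]
    counts = {c: sum(1 for r in records if r.nutrient_class == c)
              for c in ("low", "high", "greenhouse")}
    if counts != {"low": 6, "high": 6, "greenhouse": 1}:
        raise FixtureError(f"{_FILES['soil']}: expected 6 low + 6 high + 1 "
                           f"greenhouse site, found {counts}")
    for i, r in enumerate(records):
        if min(r.C, r.N_total, r.P_total, r.K_total, r.Ca_total,
               r.P_extractable) < 0:
            raise FixtureError(f"{_FILES['soil']}: negative concentration at "
                               f"line {i + 2} ({r.site_id})")
    return records


def load_species() -> list[SpeciesRecord]:
    """The 16 study species, in the printed order (increasing soil fertility)."""
    df = read_raw("species")
    records = [SpeciesRecord(r.species_name, r.abbreviation, r.family,
                             r.soil_class) for r in df.itertuples()]
    if len(records) != 16:
        raise FixtureError(f"{_FILES['species']}: expected 16 species, "
                           f"found {len(records)}")
    for cls in ("low", "high"):
        n = sum(1 for r in records if r.soil_class == cls)
        if n != 8:
            raise FixtureError(f"{_FILES['species']}: expected 8 {cls}-soil "
                               f"species, found {n}")
    abbrs = [r.abbreviation for r in records]
    if len(set(abbrs)) != len(abbrs):
        raise FixtureError(f"{_FILES['species']}: duplicate abbreviations")
    return records


def load_tissue_nutrients() -> pd.DataFrame:
    """Tissue N (mg g^-1) and P (mg kg^-1) means +- SE, long format.

    Complete 16 species x 6 tissues x 2 elements grid (192 rows).
    """
    df = _as_float(read_raw("nutrients"), ["mean", "se"], "nutrients")
    expected = 16 * len(TISSUES) * len(ELEMENTS)
    if len(df) != expected:
        raise FixtureError(f"{_FILES['nutrients']}: expected {expected} rows, "
                           f"found {len(df)}")
    cells = df.groupby(["species_name", "element", "tissue"]).size()
    if (cells != 1).any() or len(cells) != expected:
        raise FixtureError(f"{_FILES['nutrients']}: species x tissue x element "
                           f"grid is not complete and unique")
    if (df["mean"] <= 0).any():
        bad = df.index[df["mean"] <= 0][0]
        raise FixtureError(f"{_FILES['nutrients']}: non-positive mean at line "
                           f"{bad + 2}")
    return df


def load_trait_table() -> pd.DataFrame:
    """Structural, hydraulic and growth traits by species x organ, long format."""
    df = read_raw("traits")
    df = df.assign(mean=pd.to_numeric(df["mean"]),
                   se=pd.to_numeric(df["se"].replace("", None)))
    if df["species_name"].nunique() != 16:
        raise FixtureError(f"{_FILES['traits']}: expected 16 species")
    dup = df.groupby(["species_name", "organ", "trait"]).size()
    if (dup != 1).any():
        raise FixtureError(f"{_FILES['traits']}: duplicate species/organ/trait rows")
    return df


def load_packaged_tables():
    """Load all packaged fixtures: (soil, species, tissue nutrients, traits)."""
    return (load_soil_table(), load_species(), load_tissue_nutrients(),
            load_trait_table())


def tissue_nutrient_lookup(table: pd.DataFrame, species_name: str, tissue: str,
                           element: str) -> float:
    """Mean concentration for one species/tissue/element cell of the table."""
    sel = table[(table.species_name == species_name) & (table.tissue == tissue)
                & (table.element == element)]
    if len(sel) != 1:
        raise KeyError(f"no unique entry for {species_name}/{tissue}/{element}")
    return float(sel["mean"].iloc[0])
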