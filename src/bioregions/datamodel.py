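"""Core domain containers: sites, species traits, and the incidence matrix.

The central object is :class:`OccurrenceMatrix`, a boolean sites x species
incidence table. Sites are ordered shelf sections (``SiteTable.order_index``)
with a ``core_region`` flag marking the bounding area used for endemism
classification. Species traits carry habitat guild, salinity class, depth
limits, residency and the endemism class filled by :func:`classify_endemics`.

All tables round-trip losslessly through headered CSV (UTF-8).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

HABITATS = ("reef", "soft_bottom", "pelagic", "unassigned")
SALINITIES = ("marine", "non_marine")
ENDEMISM = ("regional_endemic", "non_endemic", "unknown")


# ---------------------------------------------------------------------------
# SiteTable
# ---------------------------------------------------------------------------

@dataclass
class SiteTable:
    """Ordered shelf sections with a core-region flag.

    Parameters
    ----------
    df : DataFrame with columns ``site_id`` (unique strings), ``order_index``
        (unique integers, contiguous from 0), ``core_region`` (bool) and an
        optional free-text ``label``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        required = {"site_id", "order_index", "core_region"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigurationError(f"site table missing columns: {sorted(missing)}")
        if "label" not in df.columns:
            df["label"] = df["site_id"]
        df["site_id"] = df["site_id"].astype(str)
        df["order_index"] = df["order_index"].astype(int)
        df["core_region"] = df["core_region"].astype(bool)
        if df["site_id"].duplicated().any():
            raise DataError("duplicate site_id in site table")
        order = np.sort(df["order_index"].to_numpy())
        if not np.array_equal(order, np.arange(len(df))):
            raise DataError("order_index values must be unique and contiguous from 0")
        self.df = df.sort_values("order_index").reset_index(drop=True)

    @property
    def site_ids(self) -> list[str]:
        return self.df["site_id"].tolist()

    @property
    def core_flags(self) -> dict[str, bool]:
        return dict(zip(self.df["site_id"], self.df["core_region"]))

    def core_site_ids(self) -> list[str]:
        return self.df.loc[self.df["core_region"], "site_id"].tolist()

    @classmethod
    def from_ids(cls, site_ids: Sequence[str], core: Sequence[bool] | None = None) -> "SiteTable":
        core = [True] * len(site_ids) if core is None else list(core)
        return cls(pd.DataFrame({
            "site_id": list(site_ids),
            "order_index": range(len(site_ids)),
            "core_region": core,
        }))

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SiteTable":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# SpeciesTraits
# ---------------------------------------------------------------------------

_TRAIT_DEFAULTS = {
    "habitat": "unassigned",
    "salinity": "marine",
    "depth_min_m": np.nan,
    "depth_max_m": np.nan,
    "resident": True,
    "endemic": "unknown",
}


@dataclass
class SpeciesTraits:
    """Per-species trait table: habitat guild, salinity class, depth limits,
    residency and endemism class.

    Missing species (relative to a matrix) default to resident marine fishes of
    unassigned habitat, with a warning — this mirrors treating species that
    lack habitat data as usable in whole-fauna analyses while letting
    habitat-based subsetting drop them.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "species_id" not in df.columns:
            raise ConfigurationError("trait table missing species_id column")
        df["species_id"] = df["species_id"].astype(str)
        if df["species_id"].duplicated().any():
            raise DataError("duplicate species_id in trait table")
        for col, default in _TRAIT_DEFAULTS.items():
            if col not in df.columns:
                df[col] = default
        bad_hab = set(df["habitat"].dropna()) - set(HABITATS)
        if bad_hab:
            raise DataError(f"unknown habitat classes: {sorted(bad_hab)}")
        bad_sal = set(df["salinity"].dropna()) - set(SALINITIES)
        if bad_sal:
            raise DataError(f"unknown salinity classes: {sorted(bad_sal)}")
        bad_end = set(df["endemic"].dropna()) - set(ENDEMISM)
        if bad_end:
            raise DataError(f"unknown endemism classes: {sorted(bad_end)}")
        both = df["depth_min_m"].notna() & df["depth_max_m"].notna()
        if (df.loc[both, "depth_min_m"] > df.loc[both, "depth_max_m"]).any():
            raise DataError("depth_min_m exceeds depth_max_m for some species")
        df["resident"] = df["resident"].astype(bool)
        self.df = df.reset_index(drop=True)

    @property
    def species_ids(self) -> list[str]:
        return self.df["species_id"].tolist()

    def aligned_to(self, species: Sequence[str]) -> pd.DataFrame:
        """Trait rows aligned to ``species`` order, filling defaults for
        species absent from the table (with a warning)."""
        indexed = self.df.set_index("species_id")
        missing = [s for s in species if s not in indexed.index]
        if missing:
            warnings.warn(
                f"{len(missing)} species missing from trait table; "
                "defaulting to resident, habitat=unassigned, salinity=marine",
                stacklevel=2,
            )
            filler = pd.DataFrame(_TRAIT_DEFAULTS, index=pd.Index(missing, name="species_id"))
            indexed = pd.concat([indexed, filler])
        out = indexed.loc[list(species)].reset_index()
        return out

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "SpeciesTraits":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# OccurrenceMatrix
# ---------------------------------------------------------------------------

@dataclass
class OccurrenceMatrix:
    """Boolean sites x species incidence table.

    ``sites`` and ``species`` are ordered, unique identifier lists matching the
    rows and columns of ``incidence``.
    """

    sites: list[str]
    species: list[str]
    incidence: np.ndarray

    def __post_init__(self) -> None:
        self.sites = [str(s) for s in self.sites]
        self.species = [str(s) for s in self.species]
        inc = np.asarray(self.incidence, dtype=bool)
        if inc.ndim != 2 or inc.shape != (len(self.sites), len(self.species)):
            raise DataError(
                f"incidence shape {inc.shape} does not match "
                f"{len(self.sites)} sites x {len(self.species)} species"
            )
        if len(set(self.sites)) != len(self.sites):
            raise DataError("duplicate site ids in matrix")
        if len(set(self.species)) != len(self.species):
            raise DataError("duplicate species ids in matrix")
        if inc.size == 0:
            raise DataError("empty occurrence matrix")
        self.incidence = inc

    # -- basic accessors ----------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def richness(self) -> pd.Series:
        """Species count per site."""
        return pd.Series(self.incidence.sum(axis=1), index=self.sites, name="richness")

    def empty_sites(self) -> list[str]:
        mask = ~self.incidence.any(axis=1)
        return [s for s, m in zip(self.sites, mask) if m]

    def empty_species(self) -> list[str]:
        mask = ~self.incidence.any(axis=0)
        return [s for s, m in zip(self.species, mask) if m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.incidence.astype(int), index=pd.Index(self.sites, name="site_id"),
                            columns=self.species)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OccurrenceMatrix":
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy().astype(bool))

    # -- subsetting ---------------------------------------------------------

    def select_sites(self, site_ids: Sequence[str]) -> "OccurrenceMatrix":
        idx = {s: i for i, s in enumerate(self.sites)}
        unknown = [s for s in site_ids if s not in idx]
        if unknown:
            raise DataError(f"unknown sites: {unknown}")
        rows = [idx[s] for s in site_ids]
        return OccurrenceMatrix(list(site_ids), list(self.species), self.incidence[rows, :])

    def select_species(self, species_ids: Sequence[str]) -> "OccurrenceMatrix":
        idx = {s: i for i, s in enumerate(self.species)}
        unknown = [s for s in species_ids if s not in idx]
        if unknown:
            raise DataError(f"unknown species: {unknown}")
        cols = [idx[s] for s in species_ids]
        return OccurrenceMatrix(list(self.sites), list(species_ids), self.incidence[:, cols])

    def drop_empty(self, *, warn: bool = True) -> "OccurrenceMatrix":
        """Drop species with no occurrences, then sites with no species."""
        m = self
        dead_sp = m.empty_species()
        if dead_sp:
            keep = [s for s in m.species if s not in set(dead_sp)]
            m = m.select_species(keep)
        dead_sites = m.empty_sites()
        if dead_sites:
            if warn:
                warnings.warn(f"dropping {len(dead_sites)} empty sites: {dead_sites}",
                              stacklevel=2)
            keep = [s for s in m.sites if s not in set(dead_sites)]
            m = m.select_sites(keep)
        return m

    # -- I/O ----------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def read_csv(cls, path: str | Path) -> "OccurrenceMatrix":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split(",")
        species_cols = header[1:]
        if len(set(species_cols)) != len(species_cols):
            raise DataError(f"{path}: duplicated species columns in header")
        df = pd.read_csv(path, index_col=0)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise DataError(f"{path}: empty matrix")
        if df.index.duplicated().any():
            raise DataError(f"{path}: duplicated site identifiers")
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise DataError(f"{path}: incidence cells must be 0/1")
        return cls.from_frame(df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OccurrenceMatrix):
            return NotImplemented
        return (self.sites == other.sites and self.species == other.species
                and np.array_equal(self.incidence, other.incidence))


# ---------------------------------------------------------------------------
# CleaningReport
# ---------------------------------------------------------------------------

@dataclass
class CleaningReport:
    """Bookkeeping for a record-cleaning pass."""

    n_input: int
    n_duplicates_removed: int = 0
    n_outliers_removed: int = 0
    removed_detail: list = field(default_factory=list)

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_duplicates_removed - self.n_outliers_removed

    @property
    def fraction_removed(self) -> float:
        if self.n_input == 0:
            return 0.0
        return (self.n_duplicates_removed + self.n_outliers_removed) / self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_duplicates_removed": self.n_duplicates_removed,
            "n_outliers_removed": self.n_outliers_removed,
            "n_output": self.n_output,
            "fraction_removed": self.fraction_removed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ---------------------------------------------------------------------------
# Matrix construction and trait-driven filters
# ---------------------------------------------------------------------------

def build_matrix(records: Iterable, site_table: SiteTable,
                 site_lookup: Mapping[tuple[float, float], str] | None = None,
                 ) -> OccurrenceMatrix:
    """Rasterize occurrence records into a sites x species incidence matrix.

    Records resolve to a site either through their ``site_id`` or, failing
    that, through an explicit ``site_lookup`` keyed by (lat, lon) rounded to
    2 decimals. Row order follows ``site_table.order_index``. Records naming
    unknown sites are collected and reported in a single error.
    """
    records = list(records)
    if not records:
        raise DataError("no records to build a matrix from")
    site_ids = site_table.site_ids
    site_idx = {s: i for i, s in enumerate(site_ids)}
    pairs: set[tuple[int, str]] = set()
    unknown: list[str] = []
    for rec in records:
        sid = rec.site_id
        if sid is None and site_lookup is not None and rec.lat is not None:
            sid = site_lookup.get((round(rec.lat, 2), round(rec.lon, 2)))
        if sid is None or sid not in site_idx:
            unknown.append(f"{rec.species_id}@{sid}")
            continue
        pairs.add((site_idx[sid], rec.species_id))
    if unknown:
        raise DataError(f"{len(unknown)} records with unresolvable sites "
                        f"(first few: {unknown[:5]})")
    species = sorted({sp for _, sp in pairs})
    sp_idx = {s: j for j, s in enumerate(species)}
    inc = np.zeros((len(site_ids), len(species)), dtype=bool)
    for i, sp in pairs:
        inc[i, sp_idx[sp]] = True
    m = OccurrenceMatrix(site_ids, species, inc)
    empty = m.empty_sites()
    if empty:
        warnings.warn(f"{len(empty)} sites received no records: {empty}", stacklevel=2)
    return m


def filter_residents(matrix: OccurrenceMatrix, traits: SpeciesTraits) -> OccurrenceMatrix:
    """Drop species flagged non-resident. Species absent from the trait table
    are treated as resident (with a warning from trait alignment)."""
    aligned = traits.aligned_to(matrix.species)
    keep = [sp for sp, res in zip(matrix.species, aligned["resident"]) if res]
    out = matrix.select_species(keep)
    empty = out.empty_sites()
    if empty:
        warnings.warn(f"resident filter left {len(empty)} sites empty: {empty}",
                      stacklevel=2)
    return out


def classify_endemics(matrix: OccurrenceMatrix, site_table: SiteTable,
                      threshold: float = 0.75) -> SpeciesTraits:
    """Classify each species as regional endemic or not.

    A species is a regional endemic when the fraction of its occupied sites
    flagged ``core_region`` is at least ``threshold`` (inclusive boundary).
    Site counts stand proxy for geographic range area; the proxy is recorded
    in the returned table's ``attrs``.
    """
    if not 0 < threshold <= 1:
        raise ConfigurationError("threshold must be in (0, 1]")
    core = np.array([site_table.core_flags.get(s, False) for s in matrix.sites])
    occ = matrix.incidence.sum(axis=0)
    if (occ == 0).any():
        dead = matrix.empty_species()
        raise DataError(f"species occupying zero sites: {dead[:5]}")
    core_occ = (matrix.incidence & core[:, None]).sum(axis=0)
    frac = core_occ / occ
    endemic = np.where(frac >= threshold, "regional_endemic", "non_endemic")
    df = pd.DataFrame({
        "species_id": matrix.species,
        "endemic": endemic,
        "core_site_fraction": frac,
    })
    traits = SpeciesTraits(df)
    traits.df.attrs["endemism_rule"] = (
        f"occupied core sites / occupied sites >= {threshold} (site-count proxy "
        "for range area)")
    return traits
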