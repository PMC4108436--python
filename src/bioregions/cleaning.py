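"""Occurrence-record ingestion and rule-based cleaning.

Aggregator and museum occurrence data carry two pervasive error classes:
duplicate records (the same specimen re-served by several databases) and
geo-referencing errors that strand single records of well-sampled species far
outside their ranges. Both are handled here with simple, configurable rules:

* :func:`dedupe_records` keeps one record per (species, site, rounded
  coordinate) key;
* :func:`flag_outlier_records` deletes records of common species with no
  conspecific neighbour within a great-circle radius.

Rare species are exempt from outlier deletion — a single record of a rarely
collected species is data, not noise.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .datamodel import CleaningReport
from .errors import ConfigurationError, DataError

_EARTH_RADIUS_KM = 6371.0088


@dataclass(frozen=True)
class OccurrenceRecord:
    """One species occurrence at a site and/or coordinate."""

    species_id: str
    site_id: str | None = None
    lat: float | None = None
    lon: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.species_id:
            raise DataError("record with empty species_id")
        if self.site_id is None and (self.lat is None or self.lon is None):
            raise DataError(f"{self.species_id}: record needs site_id or lat/lon")
        if self.lat is not None and not -90 <= self.lat <= 90:
            raise DataError(f"{self.species_id}: latitude {self.lat} out of bounds")
        if self.lon is not None and not -180 <= self.lon <= 180:
            raise DataError(f"{self.species_id}: longitude {self.lon} out of bounds")


class RecordBatch(list):
    """A list of records plus per-row errors collected during parsing."""

    def __init__(self, records: Iterable[OccurrenceRecord] = (),
                 errors: list[str] | None = None) -> None:
        super().__init__(records)
        self.errors: list[str] = errors or []


_COLUMN_ALIASES = {
    "species": "species_id", "species_id": "species_id", "scientificname": "species_id",
    "site": "site_id", "site_id": "site_id", "section": "site_id",
    "lat": "lat", "latitude": "lat", "decimallatitude": "lat",
    "lon": "lon", "longitude": "lon", "decimallongitude": "lon", "lng": "lon",
    "source": "source",
}


def read_records(path: str | Path, format_config: dict | None = None) -> RecordBatch:
    """Read occurrence records from a delimited text file.

    The header must name at least a species column and either a site column or
    lat/lon columns (common aliases are recognized; ``format_config`` may map
    canonical names to actual column headers and set ``delimiter``). Malformed
    rows are collected in ``result.errors`` with their line numbers, never
    silently dropped.
    """
    cfg = format_config or {}
    delimiter = cfg.get("delimiter", ",")
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"records file not found: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ConfigurationError(f"{path}: empty file, no header")
        colmap: dict[str, str] = {}
        for col in reader.fieldnames:
            canon = cfg.get(col) or _COLUMN_ALIASES.get(col.strip().lower())
            if canon:
                colmap[canon] = col
        if "species_id" not in colmap:
            raise ConfigurationError(f"{path}: no species column in header {reader.fieldnames}")
        if "site_id" not in colmap and not {"lat", "lon"} <= colmap.keys():
            raise ConfigurationError(
                f"{path}: need a site column or lat+lon columns, got {reader.fieldnames}")
        batch = RecordBatch()
        for lineno, row in enumerate(reader, start=2):
            try:
                lat = row.get(colmap.get("lat", ""), "")
                lon = row.get(colmap.get("lon", ""), "")
                batch.append(OccurrenceRecord(
                    species_id=(row.get(colmap["species_id"]) or "").strip(),
                    site_id=(row.get(colmap["site_id"], "") or "").strip() or None
                    if "site_id" in colmap else None,
                    lat=float(lat) if lat not in ("", None) else None,
                    lon=float(lon) if lon not in ("", None) else None,
                    source=(row.get(colmap.get("source", ""), "") or "").strip(),
                ))
            except (DataError, ValueError) as exc:
                batch.errors.append(f"line {lineno}: {exc}")
    return batch


def _dedupe_key(rec: OccurrenceRecord, precision: int) -> tuple:
    lat = None if rec.lat is None else round(rec.lat, precision)
    lon = None if rec.lon is None else round(rec.lon, precision)
    return (rec.species_id, rec.site_id, lat, lon)


def dedupe_records(records: Sequence[OccurrenceRecord], coord_precision: int = 2,
                   ) -> tuple[list[OccurrenceRecord], CleaningReport]:
    """Keep one record per (species, site, rounded lat/lon) key.

    The default 2-decimal rounding (~1 km) treats re-served aggregator copies
    of the same collection event as duplicates. ``source`` is deliberately not
    part of the key. First occurrence wins; idempotent.
    """
    seen: set[tuple] = set()
    kept: list[OccurrenceRecord] = []
    removed = 0
    for rec in records:
        key = _dedupe_key(rec, coord_precision)
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            kept.append(rec)
    return kept, CleaningReport(n_input=len(records), n_duplicates_removed=removed)


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between coordinate arrays (degrees)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (np.asarray(lat1, float), np.asarray(lon1, float),
                                              np.asarray(lat2, float), np.asarray(lon2, float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def flag_outlier_records(records: Sequence[OccurrenceRecord],
                         min_conspecific_neighbors: int = 1,
                         max_km: float = 500.0,
                         min_total_records: int = 20,
                         ) -> tuple[list[OccurrenceRecord], CleaningReport]:
    """Delete isolated records of common species.

    A record is removed when the species has at least ``min_total_records``
    records overall (the "common species" proxy) yet fewer than
    ``min_conspecific_neighbors`` conspecific records lie within ``max_km``
    great-circle distance. Records without coordinates pass through untouched.
    Idempotent: surviving records keep their neighbours.
    """
    if max_km <= 0:
        raise ConfigurationError("max_km must be positive")
    by_species: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_species.setdefault(rec.species_id, []).append(i)
    drop: set[int] = set()
    detail: list[str] = []
    for sp, idxs in by_species.items():
        if len(idxs) < min_total_records:
            continue  # rarity exemption
        coords = [(i, records[i].lat, records[i].lon) for i in idxs
                  if records[i].lat is not None and records[i].lon is not None]
        if len(coords) < 2:
            continue
        ids, lats, lons = zip(*coords)
        lats = np.array(lats)
        lons = np.array(lons)
        for j, i in enumerate(ids):
            d = haversine_km(lats[j], lons[j], lats, lons)
            d[j] = np.inf
            if (d <= max_km).sum() < min_conspecific_neighbors:
                drop.add(i)
                detail.append(f"{sp} at ({lats[j]:.3f},{lons[j]:.3f})")
    kept = [rec for i, rec in enumerate(records) if i not in drop]
    report = CleaningReport(n_input=len(records), n_outliers_removed=len(drop),
                            removed_detail=detail)
    return kept, report
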