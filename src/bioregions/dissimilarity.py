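"""Presence/absence dissimilarity indices between site assemblages.

For two sites with ``a`` shared species and ``b``, ``c`` species unique to
each, the package offers:

* **beta-sim** (Simpson-based turnover): ``min(b, c) / (min(b, c) + a)``.
  Insensitive to richness differences and nestedness — a site whose fauna is a
  subset of another's scores 0 — and never counts joint absences as
  similarity. This makes it the index of choice for comparing faunas of very
  different size.
* **Sørensen**: ``(b + c) / (2a + b + c)``, which is exactly what the
  Bray-Curtis index reduces to on 0/1 data; exposed under the metric name
  ``bray_curtis_pa`` as well. Sensitive to richness differences.

Pairs of empty assemblages are errors, not zeros: a silent 0 would fabricate
similarity from the absence of data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import OccurrenceMatrix
from .errors import ConfigurationError, DataError, DegeneracyError

METRICS = ("beta_sim", "sorensen", "bray_curtis_pa")


@dataclass(frozen=True)
class TurnoverComponents:
    """Incidence overlap counts for a pair of sites: ``a`` shared, ``b``/``c``
    unique to the first/second site."""

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise DataError("negative turnover component")


def components(x, y) -> TurnoverComponents:
    """Exact set-overlap counts between two equal-length boolean vectors."""
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError(f"incidence vectors of unequal shape: {x.shape} vs {y.shape}")
    a = int(np.count_nonzero(x & y))
    b = int(np.count_nonzero(x & ~y))
    c = int(np.count_nonzero(~x & y))
    return TurnoverComponents(a, b, c)


def _as_components(x, y) -> TurnoverComponents:
    if y is None and isinstance(x, TurnoverComponents):
        return x
    return components(x, y)


def beta_sim(x, y=None) -> float:
    """Simpson-based turnover dissimilarity min(b,c)/(min(b,c)+a).

    Accepts two incidence vectors or a single :class:`TurnoverComponents`.
    0 when one assemblage nests inside the other, 1 when disjoint.
    """
    comp = _as_components(x, y)
    if comp.a + comp.b == 0 and comp.a + comp.c == 0:
        raise DegeneracyError("beta-sim undefined: both assemblages empty")
    m = min(comp.b, comp.c)
    if m + comp.a == 0:
        return 0.0  # nested (min(b,c)=0), incl. the one-empty edge
    return m / (m + comp.a)


def sorensen_dissimilarity(x, y=None) -> float:
    """Sørensen dissimilarity (b+c)/(2a+b+c); Bray-Curtis on 0/1 data."""
    comp = _as_components(x, y)
    denom = 2 * comp.a + comp.b + comp.c
    if denom == 0:
        raise DegeneracyError("Sørensen undefined: both assemblages empty")
    return (comp.b + comp.c) / denom


_METRIC_FUNCS = {
    "beta_sim": beta_sim,
    "sorensen": sorensen_dissimilarity,
    "bray_curtis_pa": sorensen_dissimilarity,
}


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise site dissimilarities in [0, 1]."""

    sites: list[str]
    values: np.ndarray
    metric_name: str = "beta_sim"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sites)
        if v.shape != (n, n):
            raise DataError(f"dissimilarity matrix shape {v.shape} != ({n},{n})")
        if not np.allclose(np.diag(v), 0, atol=1e-12):
            raise DataError("dissimilarity diagonal must be 0")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DataError("dissimilarity matrix must be symmetric")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise DataError("dissimilarities must lie in [0, 1]")
        np.fill_diagonal(v, 0.0)
        self.values = np.clip((v + v.T) / 2, 0.0, 1.0)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def condensed(self) -> np.ndarray:
        """Upper-triangle vector in scipy's condensed order."""
        iu = np.triu_indices(self.n_sites, k=1)
        return self.values[iu]

    def loc(self, s1: str, s2: str) -> float:
        i, j = self.sites.index(s1), self.sites.index(s2)
        return float(self.values[i, j])

    def select_sites(self, site_ids) -> "DissimilarityMatrix":
        idx = [self.sites.index(s) for s in site_ids]
        return DissimilarityMatrix(list(site_ids), self.values[np.ix_(idx, idx)],
                                   self.metric_name)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.sites, columns=self.sites).to_csv(path)
        Path(path).with_suffix(".meta.json").write_text(
            json.dumps({"metric_name": self.metric_name}))

    @classmethod
    def read_csv(cls, path: str | Path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        meta = Path(path).with_suffix(".meta.json")
        metric = "beta_sim"
        if meta.exists():
            metric = json.loads(meta.read_text()).get("metric_name", metric)
        return cls(list(df.index.astype(str)), df.to_numpy(), metric)


def pairwise(matrix: OccurrenceMatrix, metric: str = "beta_sim") -> DissimilarityMatrix:
    """Pairwise dissimilarities among all sites of an occurrence matrix.

    Vectorized over the boolean incidence table; every site must host at least
    one species.
    """
    if metric not in METRICS:
        raise ConfigurationError(f"unknown metric {metric!r}; choose from {METRICS}")
    empty = matrix.empty_sites()
    if empty:
        raise DataError(f"cannot compute dissimilarities with empty sites: {empty}")
    X = matrix.incidence.astype(np.int64)
    A = X @ X.T                              # shared species counts
    rich = X.sum(axis=1)
    B = rich[:, None] - A                    # unique to row site
    C = rich[None, :] - A                    # unique to column site
    if metric == "beta_sim":
        m = np.minimum(B, C)
        vals = np.divide(m, m + A, out=np.zeros_like(A, dtype=float), where=(m + A) > 0)
    else:
        vals = (B + C) / (2 * A + B + C)
    np.fill_diagonal(vals, 0.0)
    return DissimilarityMatrix(list(matrix.sites), vals, metric)
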