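"""Sorensen similarity between riparian community censuses.

The Sorensen index of two presence/absence communities is ``2a / (2a + b + c)``
where ``a`` counts species shared by both sites and ``b``/``c`` count species
unique to the first and second site.  It equals the number of shared species
divided by the average species richness of the pair: 1 means identical
composition, 0 means disjoint communities.

Pairs are only formed *within* a river basin; similarity between sites of
different basins is never computed, because the downstream regression models
each basin as an independent level of a varying intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PairOverlap",
    "CommunityMatrix",
    "UndefinedSimilarityError",
    "sorensen_index",
    "pairwise_sorensen",
]


class UndefinedSimilarityError(ValueError):
    """Raised when both communities of a pair are empty (a = b = c = 0)."""


@dataclass(frozen=True)
class PairOverlap:
    """Species-count decomposition of one pair of sites.

    Attributes
    ----------
    a : int
        Number of species present at both sites.
    b : int
        Number of species present only at the first site.
    c : int
        Number of species present only at the second site.
    """

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("overlap counts must be non-negative")


def sorensen_index(overlap: PairOverlap) -> float:
    """Sorensen similarity ``2a / (2a + b + c)`` of one pair.

    Symmetric in the roles of the two sites (``b`` vs ``c``).  Raises
    :class:`UndefinedSimilarityError` if both communities are empty.
    """
    a, b, c = overlap.a, overlap.b, overlap.c
    denom = 2 * a + b + c
    if denom == 0:
        raise UndefinedSimilarityError(
            "Sorensen index undefined: both communities are empty (a=b=c=0)"
        )
    return 2 * a / denom


class CommunityMatrix:
    """Site x species presence/absence table.

    Wraps a pandas DataFrame indexed by site id with species ids as columns
    and entries in {0, 1}.  Abundances, if supplied, are binarized (> 0 -> 1).
    Every site must host at least one species.
    """

    def __init__(self, data: pd.DataFrame):
        values = (data.to_numpy() > 0).astype(np.int8)
        self.data = pd.DataFrame(values, index=data.index, columns=data.columns)
        if self.data.index.has_duplicates:
            raise ValueError("duplicate site ids in community matrix")
        richness = self.data.to_numpy().sum(axis=1)
        if (richness == 0).any():
            empty = list(self.data.index[richness == 0])
            raise ValueError(f"sites with no species present: {empty}")

    @property
    def site_ids(self) -> list:
        return list(self.data.index)

    @property
    def species_ids(self) -> list:
        return list(self.data.columns)

    def species_set(self, site_id) -> set:
        row = self.data.loc[site_id]
        return set(row.index[row > 0])

    # ---- I/O ------------------------------------------------------------

    @classmethod
    def from_wide_csv(cls, path: str | Path) -> "CommunityMatrix":
        """Read a wide binary CSV: first column site id, one column per species."""
        return cls(pd.read_csv(path, index_col=0))

    @classmethod
    def from_long_csv(cls, path: str | Path) -> "CommunityMatrix":
        """Read a long-format CSV with columns ``site_id, species_id``."""
        long = pd.read_csv(path)
        long["presence"] = 1
        wide = long.pivot_table(
            index="site_id", columns="species_id", values="presence", fill_value=0
        )
        return cls(wide)

    def to_wide_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="site_id")

    def to_long_csv(self, path: str | Path) -> None:
        long = (
            self.data.stack()
            .rename("presence")
            .reset_index()
            .rename(columns={"level_0": "site_id", "level_1": "species_id"})
        )
        long = long[long["presence"] > 0][["site_id", "species_id"]]
        long.to_csv(path, index=False)


def pairwise_sorensen(
    matrix: CommunityMatrix, basin_of: Mapping
) -> pd.DataFrame:
    """Sorensen index for every unordered within-basin pair of sites.

    Parameters
    ----------
    matrix : CommunityMatrix
        Presence/absence data for all sites.
    basin_of : mapping site id -> basin id
        Basin assignment; every site in ``matrix`` must be present.

    Returns
    -------
    DataFrame with columns ``site_a, site_b, basin, sorensen``; each
    within-basin pair appears exactly once with ``site_a < site_b`` in the
    natural ordering of the site ids, and no cross-basin pairs are emitted.
    A basin with n sites contributes n(n-1)/2 rows.
    """
    missing = [s for s in matrix.site_ids if s not in basin_of]
    if missing:
        raise KeyError(f"sites missing from basin map: {missing}")

    rows = []
    basins = sorted({basin_of[s] for s in matrix.site_ids}, key=str)
    values = matrix.data
    for basin in basins:
        sites = sorted(s for s in matrix.site_ids if basin_of[s] == basin)
        if len(sites) < 2:
            continue
        sub = values.loc[sites].to_numpy()
        shared = sub @ sub.T                      # a for every ordered pair
        richness = sub.sum(axis=1)
        for i, j in combinations(range(len(sites)), 2):
            a = int(shared[i, j])
            s = 2 * a / (richness[i] + richness[j])
            rows.append((sites[i], sites[j], basin, s))
    return pd.DataFrame(rows, columns=["site_a", "site_b", "basin", "sorensen"])
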