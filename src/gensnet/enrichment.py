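"""Hypergeometric over-representation analysis against GMT gene-set files."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe they are tested against."""

    sets: dict[str, set[str]]
    universe: set[str]

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set and the universe with a new background."""
        universe = set(universe) & self.universe if self.universe else set(universe)
        sets = {}
        for name, members in self.sets.items():
            kept = members & universe
            if kept:
                sets[name] = kept
            else:
                logger.warning("gene set %r empty after restriction; dropped", name)
        return GeneSetCollection(sets=sets, universe=universe)


def read_gmt(path: str | Path, uppercase: bool = True) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members per line).

    Duplicate members within a line are stored once; empty sets are dropped
    with a warning; duplicate set names are suffixed.  The universe defaults
    to the union of all members.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name = fields[0].strip()
            members = {
                (m.strip().upper() if uppercase else m.strip())
                for m in fields[2:]
                if m.strip()
            }
            if not members:
                logger.warning("%s:%d: gene set %r is empty; dropped", path, lineno, name)
                continue
            if name in sets:
                base, i = name, 2
                while name in sets:
                    name = f"{base}_{i}"
                    i += 1
                logger.warning("%s:%d: duplicate set name %r stored as %r", path, lineno, base, name)
            sets[name] = members
    universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, universe=universe)


def hypergeom_enrichment(
    query: set[str],
    collection: GeneSetCollection,
    correction: str = "BH",
) -> pd.DataFrame:
    """One-sided (upper-tail) hypergeometric over-representation test.

    For each set, with universe size N, set size K and query size n (after
    restricting the query to the universe), the p-value is
    P(X >= overlap) for X ~ Hypergeometric(N, K, n).  ``correction`` is one
    of ``BH`` (Benjamini-Hochberg), ``bonferroni`` or ``none``.
    """
    if correction not in ("BH", "bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    universe = collection.universe
    if not universe:
        raise ValueError("empty universe")
    query_u = set(query) & universe
    if not query_u:
        logger.warning("query empty after restriction to universe")
        return pd.DataFrame(
            columns=["set", "set_size", "overlap", "genes", "p", "p_adj"]
        )
    N, n = len(universe), len(query_u)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        overlap = query_u & members
        K = len(members)
        # survival function at overlap-1 gives P(X >= overlap)
        p = float(stats.hypergeom.sf(len(overlap) - 1, N, K, n))
        rows.append(
            {
                "set": name,
                "set_size": K,
                "overlap": len(overlap),
                "genes": ";".join(sorted(overlap)),
                "p": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    if correction == "none" or table.empty:
        table["p_adj"] = table["p"]
    else:
        method = "fdr_bh" if correction == "BH" else "bonferroni"
        table["p_adj"] = multipletests(table["p"].to_numpy(), method=method)[1]
    return table.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
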