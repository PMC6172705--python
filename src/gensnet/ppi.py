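"""High-confidence PPI graph construction from interaction tables.

Interaction records (one binary interaction per row, each carrying the set of
publications that report it) are filtered so that only interactions supported
by a configurable minimum number of *distinct* publications survive.  Two rows
citing the same PMID count once: independence of literature support is judged
on distinct publication identifiers, not on record count.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import networkx as nx

logger = logging.getLogger(__name__)

_PUBMED_RE = re.compile(r"pubmed:([^|\s]+)", re.IGNORECASE)


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass(frozen=True)
class Interaction:
    """One binary interaction record.

    ``support_ids`` holds the distinct publication identifiers (PMIDs) that
    report this interaction.  Self-pairs are legal at the record stage and are
    dropped only at graph build.
    """

    gene_a: str
    gene_b: str
    support_ids: frozenset[str] = field(default_factory=frozenset)


def _norm_symbol(symbol: str, uppercase: bool) -> str:
    symbol = symbol.strip()
    return symbol.upper() if uppercase else symbol


def read_interactions(
    path: str | Path,
    format: Literal["simple-tsv", "mitab"] = "simple-tsv",
    uppercase: bool = True,
) -> list[Interaction]:
    """Read an interaction table into a list of :class:`Interaction`.

    ``simple-tsv`` expects a header with columns ``gene_a``, ``gene_b`` and
    ``pubmed_ids`` (semicolon-separated).  ``mitab`` expects a MITAB-style
    export: interactors in columns 1–2 and publication identifiers
    (``pubmed:<id>`` tokens, ``|``-separated) in the 9th column; all other
    columns are ignored.  Rows with a missing identifier are skipped and the
    skip count logged.
    """
    path = Path(path)
    if format == "simple-tsv":
        records = _read_simple_tsv(path, uppercase)
    elif format == "mitab":
        records = _read_mitab(path, uppercase)
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown interaction format: {format!r}")
    return records


def _read_simple_tsv(path: Path, uppercase: bool) -> list[Interaction]:
    records: list[Interaction] = []
    skipped = 0
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        cols = {name.strip().lower(): i for i, name in enumerate(header)}
        for required in ("gene_a", "gene_b", "pubmed_ids"):
            if required not in cols:
                raise FormatError(f"{path}: missing required column {required!r}")
        ia, ib, ip = cols["gene_a"], cols["gene_b"], cols["pubmed_ids"]
        for row in reader:
            if not row or all(not c.strip() for c in row):
                continue
            try:
                a, b, pubs = row[ia], row[ib], row[ip]
            except IndexError:
                skipped += 1
                continue
            a = _norm_symbol(a, uppercase)
            b = _norm_symbol(b, uppercase)
            if not a or not b:
                skipped += 1
                continue
            ids = frozenset(p.strip() for p in pubs.split(";") if p.strip())
            records.append(Interaction(a, b, ids))
    if skipped:
        logger.warning("%s: skipped %d rows with missing identifiers", path, skipped)
    return records


def _read_mitab(path: Path, uppercase: bool) -> list[Interaction]:
    records: list[Interaction] = []
    skipped = 0
    with path.open(newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        first = True
        for row in reader:
            if not row:
                continue
            if first:
                first = False
                if row[0].lstrip().startswith("#"):
                    continue  # commented MITAB header
            if len(row) < 9:
                raise FormatError(
                    f"{path}: MITAB row has {len(row)} columns, expected >= 9 "
                    "(publication identifiers live in column 9)"
                )
            a = _mitab_symbol(row[0], uppercase)
            b = _mitab_symbol(row[1], uppercase)
            if not a or not b:
                skipped += 1
                continue
            ids = frozenset(m.group(1) for m in _PUBMED_RE.finditer(row[8]))
            records.append(Interaction(a, b, ids))
    if skipped:
        logger.warning("%s: skipped %d MITAB rows with missing interactors", path, skipped)
    return records


def _mitab_symbol(cell: str, uppercase: bool) -> str:
    cell = cell.strip()
    if cell in ("", "-"):
        return ""
    # take the value part of the first "db:value" token
    token = cell.split("|", 1)[0]
    if ":" in token:
        token = token.split(":", 1)[1]
    return _norm_symbol(token, uppercase)


def build_graph(
    interactions: Iterable[Interaction],
    min_support: int = 2,
) -> nx.Graph:
    """Build the high-confidence undirected PPI graph.

    Parallel records for the same unordered gene pair are merged by unioning
    their publication-id sets; edges supported by fewer than ``min_support``
    distinct publications are removed, as are self-loops.  Isolated nodes are
    not retained: the node set is exactly the union of surviving edge
    endpoints.  The returned :class:`networkx.Graph` carries per-edge
    attributes ``support`` (distinct-publication count) and ``support_ids``.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    merged: dict[tuple[str, str], set[str]] = {}
    for rec in interactions:
        if rec.gene_a == rec.gene_b:
            continue
        key = (rec.gene_a, rec.gene_b) if rec.gene_a < rec.gene_b else (rec.gene_b, rec.gene_a)
        merged.setdefault(key, set()).update(rec.support_ids)
    graph = nx.Graph()
    for (a, b), ids in merged.items():
        if len(ids) >= min_support:
            graph.add_edge(a, b, support=len(ids), support_ids=sorted(ids))
    return graph


def graph_to_interactions(graph: nx.Graph) -> list[Interaction]:
    """Dump a graph back to interaction records (inverse of :func:`build_graph`)."""
    return [
        Interaction(a, b, frozenset(data.get("support_ids", ())))
        for a, b, data in graph.edges(data=True)
    ]


def write_edgelist(graph: nx.Graph, path: str | Path) -> None:
    """Write the filtered graph as a TSV edge list (gene_a, gene_b, support, pubmed_ids)."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["gene_a", "gene_b", "support", "pubmed_ids"])
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            data = graph.edges[a, b]
            writer.writerow(
                [a, b, data.get("support", ""), ";".join(data.get("support_ids", ()))]
            )


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """GraphML export; list-valued attributes are flattened to strings."""
    export = nx.Graph()
    export.add_nodes_from(graph.nodes(data=True))
    for a, b, data in graph.edges(data=True):
        flat = {
            k: (";".join(v) if isinstance(v, (list, tuple, set)) else v)
            for k, v in data.items()
            if v is not None
        }
        export.add_edge(a, b, **flat)
    nx.write_graphml(export, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    graph = nx.read_graphml(str(path))
    for _, _, data in graph.edges(data=True):
        if isinstance(data.get("support_ids"), str):
            data["support_ids"] = data["support_ids"].split(";")
    return graph
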