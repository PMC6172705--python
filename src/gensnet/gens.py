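"""Edge-based greedy module search (Gens) with empirical null calibration.

Each edge (i, j) of the PPI graph is weighted by the product of the two
gene-level association p-values and the magnitude of the genes' expression
correlation,

    W_ij = |C_ij| * P_i * P_j,

and converted to a Z score through the inverse standard-normal CDF,

    Z_ij = Phi^-1(1 - W_ij),

so that strongly associated, strongly co-expressed pairs get large positive
Z.  A module is a connected induced subgraph scored by the mean of its edge
Z scores, Z_m = sum(Z_ij) / k over its k induced edges.  Greedy growth starts
from a seed edge and admits the neighbouring gene with the best induced score
as long as the improvement exceeds a relative threshold r (default 0.05).

Significance is calibrated against randomly grown connected modules of the
same gene count: the empirical p is the pseudo-counted fraction of random
module scores >= Z_m, and the size-normalized score is
Z_n = (Z_m - mean) / sd of the null scores.

Negative correlations enter the weight through |C| (a negative W would put
1 - W outside the quantile domain); the sign is kept as edge metadata.  A
missing correlation defaults to C = 1 so the weight degenerates to P_i * P_j.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from gensnet.coexpression import correlation_map

logger = logging.getLogger(__name__)

#: Clamp bounds keeping Phi^-1 finite.
EPS = 1e-16


def edge_weight(C: float | None, p_i: float, p_j: float, absent_c: float = 1.0) -> float:
    """Edge weight W = clamp(|C| * p_i * p_j, EPS, 1 - EPS).

    ``C=None`` (missing correlation) uses ``absent_c``; an exactly-zero
    correlation is floored at EPS so the weight stays positive.
    """
    for name, p in (("p_i", p_i), ("p_j", p_j)):
        if not 0 < p <= 1:
            raise ValueError(f"{name}={p} outside (0, 1]")
    c_eff = abs(absent_c) if C is None else abs(C)
    if c_eff == 0:
        c_eff = EPS
    w = c_eff * p_i * p_j
    return min(max(w, EPS), 1 - EPS)


def edge_z(W: float) -> float:
    """Z = Phi^-1(1 - W), the standard normal upper-tail quantile of W."""
    if not 0 < W < 1:
        raise ValueError(f"W={W} outside (0, 1)")
    return float(stats.norm.isf(W))


def module_score(edge_zs, norm: str = "k") -> float:
    """Module score: mean edge Z (``norm='k'``) or sum/sqrt(k) (``norm='sqrt'``)."""
    zs = np.asarray(list(edge_zs), dtype=float)
    if zs.size == 0:
        raise ValueError("a module is edge-seeded and has at least one edge")
    if norm == "k":
        return float(zs.sum() / zs.size)
    if norm == "sqrt":
        return float(zs.sum() / np.sqrt(zs.size))
    raise ValueError(f"unknown norm {norm!r}")


def score_edges(
    graph: nx.Graph,
    table: pd.DataFrame,
    expr: pd.DataFrame | None = None,
    corr: dict[tuple[str, str], float | None] | None = None,
    absent_c: float = 1.0,
) -> nx.Graph:
    """Annotate a copy of ``graph`` with per-node p and per-edge C/W/Z.

    ``corr`` (unordered-pair keyed) takes precedence over computing
    correlations from ``expr``; with neither, every C is treated as missing.
    Nodes absent from the score table get p = 1 (logged).
    """
    scored = graph.copy()
    pmap = table["p"].to_dict()
    missing = [n for n in scored.nodes if n not in pmap]
    if missing:
        logger.warning("%d node(s) lack a p-value; assigned p=1", len(missing))
    nx.set_node_attributes(scored, {n: pmap.get(n, 1.0) for n in scored.nodes}, "p")
    if corr is None:
        corr = correlation_map(expr, scored.edges()) if expr is not None else {}
    for a, b, data in scored.edges(data=True):
        key = (a, b) if a < b else (b, a)
        c = corr.get(key)
        w = edge_weight(c, scored.nodes[a]["p"], scored.nodes[b]["p"], absent_c=absent_c)
        data["C"] = c
        data["W"] = w
        data["Z"] = edge_z(w)
    return scored


@dataclass
class Module:
    """A connected gene set with its induced edges and scores."""

    genes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    z_m: float
    seed_edge: tuple[str, str]
    z_n: float | None = None
    p_empirical: float | None = None

    @property
    def k(self) -> int:
        return len(self.edges)

    def to_dict(self, graph: nx.Graph | None = None) -> dict:
        rec = {
            "genes": sorted(self.genes),
            "edges": [list(e) for e in sorted(self.edges)],
            "k": self.k,
            "z_m": self.z_m,
            "z_n": self.z_n,
            "p_empirical": self.p_empirical,
            "seed_edge": list(self.seed_edge),
        }
        if graph is not None:
            rec["edge_scores"] = [
                {
                    "edge": [a, b],
                    "C": graph.edges[a, b].get("C"),
                    "W": graph.edges[a, b].get("W"),
                    "Z": graph.edges[a, b].get("Z"),
                }
                for a, b in sorted(self.edges)
            ]
        return rec


@dataclass
class ModuleNull:
    """Background Z_m distribution from random connected modules of one size."""

    k_genes: int
    scores: np.ndarray
    mean: float
    sd: float
    n_sim: int
    seed: int

    @property
    def degenerate(self) -> bool:
        return not self.sd > 0


def _induced_edges(graph: nx.Graph, members: set[str]) -> list[tuple[str, str]]:
    edges = []
    for node in members:
        for nbr in graph.adj[node]:
            if nbr in members and node < nbr:
                edges.append((node, nbr))
    return edges


def _induced_z_sum(graph: nx.Graph, members: set[str]) -> tuple[float, int]:
    total, k = 0.0, 0
    for node in members:
        adj = graph.adj[node]
        for nbr, data in adj.items():
            if nbr in members and node < nbr:
                total += data["Z"]
                k += 1
    return total, k


def _score(total: float, k: int, norm: str) -> float:
    return total / k if norm == "k" else total / np.sqrt(k)


def grow_module(
    graph: nx.Graph,
    seed_edge: tuple[str, str],
    r: float = 0.05,
    max_genes: int | None = None,
    norm: str = "k",
) -> Module:
    """Greedy best-first growth from a seed edge.

    At each step every node adjacent to the module is evaluated with ALL of
    its edges into the module counted (induced-subgraph scoring); the best
    candidate is admitted iff its score exceeds the current score by more
    than ``z_m * r`` AND improves strictly.  Ties break toward the higher new
    score, then the lexicographically smaller gene symbol.
    """
    a, b = seed_edge
    if not graph.has_edge(a, b):
        raise ValueError(f"seed edge {seed_edge!r} not in graph")
    members = {a, b}
    total = graph.edges[a, b]["Z"]
    k = 1
    z_cur = _score(total, k, norm)
    while max_genes is None or len(members) < max_genes:
        best: tuple[float, str, float, int] | None = None  # (z_new, gene, dz, dk)
        frontier = set()
        for node in members:
            frontier.update(n for n in graph.adj[node] if n not in members)
        for cand in sorted(frontier):
            dz, dk = 0.0, 0
            for nbr, data in graph.adj[cand].items():
                if nbr in members:
                    dz += data["Z"]
                    dk += 1
            z_new = _score(total + dz, k + dk, norm)
            if best is None or z_new > best[0]:
                best = (z_new, cand, dz, dk)
        if best is None:
            break
        z_new, cand, dz, dk = best
        if not (z_new - z_cur > z_cur * r and z_new > z_cur):
            break
        members.add(cand)
        total += dz
        k += dk
        z_cur = z_new
    edges = frozenset(_induced_edges(graph, members))
    return Module(
        genes=frozenset(members),
        edges=edges,
        z_m=_score(total, k, norm),
        seed_edge=tuple(sorted((a, b))),
    )


def search_all(
    graph: nx.Graph,
    r: float = 0.05,
    seed_policy: str = "all-edges",
    top_q: float = 0.1,
    max_genes: int | None = None,
    norm: str = "k",
) -> list[Module]:
    """Grow one module per seed edge and deduplicate identical gene sets.

    ``seed_policy='all-edges'`` seeds from every edge; ``'top-q-edges'`` from
    the fraction ``top_q`` of edges with the highest Z.  Duplicates keep the
    module with the highest Z_m (then the lexicographically smallest seed).
    """
    edges = [tuple(sorted(e)) for e in graph.edges()]
    edges.sort()
    if seed_policy == "top-q-edges":
        n_keep = max(1, int(round(top_q * len(edges))))
        edges = sorted(edges, key=lambda e: (-graph.edges[e]["Z"], e))[:n_keep]
    elif seed_policy != "all-edges":
        raise ValueError(f"unknown seed_policy {seed_policy!r}")
    by_genes: dict[frozenset[str], Module] = {}
    for seed in edges:
        mod = grow_module(graph, seed, r=r, max_genes=max_genes, norm=norm)
        prev = by_genes.get(mod.genes)
        if prev is None or mod.z_m > prev.z_m or (
            mod.z_m == prev.z_m and mod.seed_edge < prev.seed_edge
        ):
            by_genes[mod.genes] = mod
    return sorted(by_genes.values(), key=lambda m: (-m.z_m, tuple(sorted(m.genes))))


def module_from_genes(
    graph: nx.Graph, genes, norm: str = "k", seed_edge: tuple[str, str] | None = None
) -> Module:
    """Build a scored :class:`Module` from an explicit connected gene set."""
    members = set(genes)
    sub = graph.subgraph(members)
    if sub.number_of_nodes() != len(members) or not nx.is_connected(sub):
        raise ValueError("gene set does not induce a connected subgraph")
    edges = _induced_edges(graph, members)
    if not edges:
        raise ValueError("a module needs at least one induced edge")
    total, k = _induced_z_sum(graph, members)
    return Module(
        genes=frozenset(members),
        edges=frozenset(edges),
        z_m=_score(total, k, norm),
        seed_edge=seed_edge or min(edges),
    )


def sample_random_module(
    graph: nx.Graph, k_genes: int, rng: np.random.Generator
) -> set[str]:
    """Uniform random frontier expansion to a connected node set of size k.

    Starts from a uniformly chosen node and repeatedly absorbs a uniformly
    chosen frontier node; restarts when the component is exhausted early.
    """
    if k_genes < 1:
        raise ValueError("k_genes must be >= 1")
    nodes = sorted(graph.nodes)
    if not any(len(c) >= k_genes for c in nx.connected_components(graph)):
        raise ValueError(f"no connected component with >= {k_genes} nodes")
    while True:
        start = nodes[rng.integers(len(nodes))]
        members = {start}
        frontier = sorted(graph.adj[start])
        while len(members) < k_genes and frontier:
            pick = frontier.pop(rng.integers(len(frontier)))
            if pick in members:
                continue
            members.add(pick)
            frontier.extend(n for n in graph.adj[pick] if n not in members)
        if len(members) == k_genes:
            return members
        # stuck in a too-small component: restart


def module_null(
    graph: nx.Graph,
    k_genes: int,
    n_sim: int = 100_000,
    seed: int = 0,
    norm: str = "k",
) -> ModuleNull:
    """Score ``n_sim`` random connected modules of ``k_genes`` genes."""
    if n_sim <= 0:
        raise ValueError("n_sim must be positive")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_sim, dtype=float)
    for i in range(n_sim):
        members = sample_random_module(graph, k_genes, rng)
        total, k = _induced_z_sum(graph, members)
        scores[i] = _score(total, k, norm)
    sd = float(np.std(scores, ddof=1)) if n_sim > 1 else 0.0
    null = ModuleNull(
        k_genes=k_genes,
        scores=scores,
        mean=float(np.mean(scores)),
        sd=sd,
        n_sim=n_sim,
        seed=seed,
    )
    if null.degenerate:
        logger.warning("null for k=%d is degenerate (sd=0); Z_n undefined", k_genes)
    return null


def module_significance(module: Module, null: ModuleNull) -> tuple[float, float | None]:
    """Empirical p (pseudo-counted upper tail) and normalized score Z_n."""
    if null.k_genes != len(module.genes):
        raise ValueError(
            f"null is for k={null.k_genes} genes but module has {len(module.genes)}"
        )
    p = (int(np.sum(null.scores >= module.z_m)) + 1) / (null.n_sim + 1)
    z_n = (module.z_m - null.mean) / null.sd if not null.degenerate else None
    return p, z_n


def calibrate_modules(
    modules: list[Module],
    graph: nx.Graph,
    n_sim: int = 100_000,
    seed: int = 0,
    norm: str = "k",
    null_cache: dict[int, ModuleNull] | None = None,
) -> dict[int, ModuleNull]:
    """Attach p_empirical and z_n to every module, caching nulls per size."""
    cache = null_cache if null_cache is not None else {}
    for mod in modules:
        k = len(mod.genes)
        if k not in cache:
            # per-size substream so cached nulls are order-independent
            cache[k] = module_null(graph, k, n_sim=n_sim, seed=seed + k, norm=norm)
        mod.p_empirical, mod.z_n = module_significance(mod, cache[k])
    return cache


def top_gene_network(
    modules: list[Module],
    graph: nx.Graph,
    p_threshold: float = 0.05,
) -> tuple[nx.Graph, pd.Series]:
    """Consensus 'top genes' across significant modules.

    Restricts to modules with p_empirical < ``p_threshold``, counts gene
    occurrences across them and keeps the genes whose count is strictly above
    the 75th percentile (linear interpolation) of the counts.  When the
    quartile is degenerate (no count strictly above it), genes at or above
    the quartile are kept instead.  Returns the induced subgraph on the top
    genes and the full occurrence table.
    """
    sig = [m for m in modules if m.p_empirical is not None and m.p_empirical < p_threshold]
    if not sig:
        logger.warning("no module below p < %g; empty top-gene network", p_threshold)
        return nx.Graph(), pd.Series(dtype=int, name="count")
    counts = Counter()
    for mod in sig:
        counts.update(mod.genes)
    freq = pd.Series(counts, name="count")
    freq = freq.sort_index(kind="stable").sort_values(ascending=False, kind="stable")
    q3 = float(np.percentile(list(counts.values()), 75))
    top = {g for g, c in counts.items() if c > q3}
    if not top:
        top = {g for g, c in counts.items() if c >= q3}
    return graph.subgraph(top).copy(), freq
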