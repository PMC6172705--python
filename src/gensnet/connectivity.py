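"""Connectivity statistics: significant-gene subnetworks, LCC extraction and
permutation nulls.

Two nulls are provided.  The p-value permutation null keeps the network
topology fixed and shuffles the gene→p assignment uniformly over nodes, which
is equivalent to selecting a uniformly random node subset of the same size as
the observed significant set.  The augmentation null compares the LCC grown by
adding a candidate gene set (e.g. genes carrying de novo mutations) to the
LCCs grown by adding equally sized random gene sets.

Empirical p-values use the (r + 1) / (n + 1) pseudo-count convention, so they
are never zero and always lie in [1/(n_perm+1), 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from gensnet.scores import significant_genes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LCCObservation:
    """Size and membership of a largest connected component."""

    n_nodes: int
    n_edges: int
    members: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class PermutationResult:
    observed: LCCObservation
    null_nodes: np.ndarray
    null_edges: np.ndarray
    p_node: float
    p_edge: float
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "observed_nodes": self.observed.n_nodes,
            "observed_edges": self.observed.n_edges,
            "p_node": self.p_node,
            "p_edge": self.p_edge,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "null_nodes_mean": float(np.mean(self.null_nodes)) if self.n_perm else None,
            "null_edges_mean": float(np.mean(self.null_edges)) if self.n_perm else None,
        }


def significant_subnetwork(graph: nx.Graph, genes: set[str]) -> nx.Graph:
    """Induced subgraph on ``genes`` ∩ graph nodes (singletons retained)."""
    present = set(genes) & set(graph.nodes)
    return graph.subgraph(present).copy()


def largest_connected_component(graph: nx.Graph) -> LCCObservation:
    """Component with the most nodes; ties broken by edge count, then by the
    lexicographically smallest member set (deterministic)."""
    if graph.number_of_nodes() == 0:
        return LCCObservation(0, 0, frozenset())
    best: tuple[int, int, tuple[str, ...]] | None = None
    best_members: set[str] | None = None
    for comp in nx.connected_components(graph):
        n_edges = graph.subgraph(comp).number_of_edges()
        key = (len(comp), n_edges, tuple(sorted(comp)))
        # larger node count, then larger edge count, then smaller member tuple
        if best is None or key[0] > best[0] or (
            key[0] == best[0]
            and (key[1] > best[1] or (key[1] == best[1] and key[2] < best[2]))
        ):
            best = key
            best_members = set(comp)
    assert best is not None and best_members is not None
    return LCCObservation(best[0], best[1], frozenset(best_members))


def _lcc_counts(graph: nx.Graph, nodes: set[str]) -> tuple[int, int]:
    """(n_nodes, n_edges) of the LCC of the induced subgraph, no membership."""
    sub = graph.subgraph(nodes)
    if sub.number_of_nodes() == 0:
        return 0, 0
    best = (0, 0)
    for comp in nx.connected_components(sub):
        cand = (len(comp), sub.subgraph(comp).number_of_edges())
        if cand > best:
            best = cand
    return best


def _empirical_p(null: np.ndarray, observed: int) -> float:
    return (int(np.sum(null >= observed)) + 1) / (len(null) + 1)


def lcc_permutation_test(
    graph: nx.Graph,
    table: pd.DataFrame,
    alpha: float,
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """P-value-permutation null for the significant-subnetwork LCC.

    The observed statistic is the LCC of the induced subgraph on significant
    genes (p < alpha).  Each replicate permutes the node→p assignment over the
    fixed topology; nodes absent from the score table are assigned p = 1
    before permutation (logged), so the number of significant nodes is
    invariant and each replicate reduces to a uniform random subset of that
    size.
    """
    nodes = sorted(graph.nodes)
    scored = set(table.index)
    unscored = [g for g in nodes if g not in scored]
    if unscored:
        logger.warning(
            "%d graph node(s) lack a p-value; assigned p=1 before permutation",
            len(unscored),
        )
    sig_nodes = significant_genes(table, alpha) & set(nodes)
    observed = largest_connected_component(significant_subnetwork(graph, sig_nodes))

    n_sig = len(sig_nodes)
    rng = np.random.default_rng(seed)
    null_nodes = np.zeros(n_perm, dtype=np.int64)
    null_edges = np.zeros(n_perm, dtype=np.int64)
    node_arr = np.array(nodes, dtype=object)
    for i in range(n_perm):
        pick = rng.choice(len(node_arr), size=n_sig, replace=False)
        null_nodes[i], null_edges[i] = _lcc_counts(graph, set(node_arr[pick]))
    return PermutationResult(
        observed=observed,
        null_nodes=null_nodes,
        null_edges=null_edges,
        p_node=_empirical_p(null_nodes, observed.n_nodes),
        p_edge=_empirical_p(null_edges, observed.n_edges),
        n_perm=n_perm,
        seed=seed,
    )


def augmentation_test(
    graph: nx.Graph,
    base_genes: set[str],
    added_genes: set[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationResult:
    """Gene-set augmentation null.

    The observed statistic is the LCC of the induced subgraph on
    ``base_genes ∪ added_genes``.  Each replicate adds the same number of
    genes (|added ∖ base|) drawn uniformly from graph nodes outside the base
    set and recomputes the LCC.
    """
    base = set(base_genes)
    added = set(added_genes) - base
    observed = largest_connected_component(
        significant_subnetwork(graph, base | added)
    )
    pool = np.array(sorted(set(graph.nodes) - base), dtype=object)
    k = len(added)
    if k > len(pool):
        raise ValueError(
            f"cannot draw {k} random genes from a pool of {len(pool)} graph nodes"
        )
    base_in_graph = base & set(graph.nodes)
    rng = np.random.default_rng(seed)
    null_nodes = np.zeros(n_perm, dtype=np.int64)
    null_edges = np.zeros(n_perm, dtype=np.int64)
    for i in range(n_perm):
        pick = rng.choice(len(pool), size=k, replace=False) if k else []
        null_nodes[i], null_edges[i] = _lcc_counts(
            graph, base_in_graph | set(pool[pick])
        )
    return PermutationResult(
        observed=observed,
        null_nodes=null_nodes,
        null_edges=null_edges,
        p_node=_empirical_p(null_nodes, observed.n_nodes),
        p_edge=_empirical_p(null_edges, observed.n_edges),
        n_perm=n_perm,
        seed=seed,
    )


def plot_null_histogram(result: PermutationResult, path, statistic: str = "nodes"):
    """Histogram of the null distribution with the observed value marked."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    null = result.null_nodes if statistic == "nodes" else result.null_edges
    obs = result.observed.n_nodes if statistic == "nodes" else result.observed.n_edges
    p = result.p_node if statistic == "nodes" else result.p_edge
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(null, bins=30, color="0.7", edgecolor="0.4")
    ax.axvline(obs, color="crimson", linestyle="--", label=f"observed ({obs})")
    ax.set_xlabel(f"LCC {statistic}")
    ax.set_ylabel("replicates")
    ax.set_title(f"P = {p:.4g} ({result.n_perm} permutations)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
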