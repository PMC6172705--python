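"""Synthetic inputs with controlled structure for every pipeline stage.

The generator emulates the five input kinds the pipeline consumes — an
interaction table, a gene-level p-value table with genomic coordinates, a
genes x samples expression matrix, plain-text rare-variant gene lists (DNM
and CNV carriers) and a GMT gene-set file — plus a truth table recording
planted-module membership for recovery tests.

Planted modules are realized as cliques wired into the background topology:
their genes draw association p-values from uniform(p_low, p_high) and their
expression rows share a latent factor that induces pairwise correlation of
about ``corr_within``.  Background genes draw p from the configured
background distribution (default uniform(0, 1)) with independent expression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from gensnet.enrichment import GeneSetCollection
from gensnet.ppi import Interaction, build_graph

_CHROMS = [str(c) for c in range(1, 23)]
_GENE_LEN = 10_000
_GENE_STEP = 1_000_000


@dataclass(frozen=True)
class PlantedModule:
    size: int
    p_low: float = 1e-6
    p_high: float = 1e-4
    corr_within: float = 0.8


@dataclass
class SyntheticSpec:
    """Study-condition parameters for one synthetic instance."""

    n_genes: int = 200
    topology: str = "scale-free"  # scale-free | erdos-renyi | small-world
    planted_modules: list[PlantedModule] = field(default_factory=list)
    background_p: tuple = ("uniform", 0.0, 1.0)
    n_samples: int = 50
    dnm_overlap_fraction: float = 0.5
    n_dnm: int = 50
    n_cnv: int = 30
    n_gene_sets: int = 10
    gene_set_size: int = 15
    seed: int = 0

    def __post_init__(self):
        self.planted_modules = [
            m if isinstance(m, PlantedModule) else PlantedModule(*m)
            for m in self.planted_modules
        ]
        if sum(m.size for m in self.planted_modules) > self.n_genes:
            raise ValueError("planted module sizes exceed n_genes")
        for m in self.planted_modules:
            if not 0 < m.p_low <= m.p_high <= 1:
                raise ValueError("require 0 < p_low <= p_high <= 1")
        if not 0 <= self.dnm_overlap_fraction <= 1:
            raise ValueError("dnm_overlap_fraction must be in [0, 1]")


@dataclass
class SyntheticData:
    graph: nx.Graph
    scores: pd.DataFrame
    expression: pd.DataFrame
    dnm_genes: set[str]
    cnv_genes: set[str]
    gene_sets: GeneSetCollection
    truth: dict[str, set[str]]
    spec: SyntheticSpec


def _background_graph(spec: SyntheticSpec, seed: int) -> nx.Graph:
    n = spec.n_genes
    if spec.topology == "scale-free":
        g = nx.barabasi_albert_graph(n, 2, seed=seed)
    elif spec.topology == "erdos-renyi":
        g = nx.gnp_random_graph(n, min(1.0, 4.0 / max(n - 1, 1)), seed=seed)
    elif spec.topology == "small-world":
        g = nx.watts_strogatz_graph(n, 4, 0.1, seed=seed)
    else:
        raise ValueError(f"unknown topology {spec.topology!r}")
    return g


def _draw_background_p(dist: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    kind = dist[0]
    if kind == "uniform":
        lo, hi = (dist[1], dist[2]) if len(dist) == 3 else (0.0, 1.0)
        return rng.uniform(lo, hi, size=size)
    if kind == "beta":
        return rng.beta(dist[1], dist[2], size=size)
    raise ValueError(f"unknown background_p distribution {dist!r}")


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Generate one synthetic instance from the spec's study conditions."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    base = _background_graph(spec, seed=int(rng.integers(2**31 - 1)))
    graph = nx.relabel_nodes(base, {i: genes[i] for i in range(spec.n_genes)})

    # planted cliques on disjoint gene sets
    free = list(genes)
    truth: dict[str, set[str]] = {}
    for idx, mod in enumerate(spec.planted_modules, start=1):
        pick_idx = rng.choice(len(free), size=mod.size, replace=False)
        members = sorted(free[i] for i in pick_idx)
        free = [g for g in free if g not in set(members)]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                graph.add_edge(a, b)
        truth[f"planted_module_{idx}"] = set(members)
    planted_all = set().union(*truth.values()) if truth else set()

    # per-edge synthetic literature support: two distinct PMIDs per edge so the
    # default min_support=2 filter keeps every edge on round-trip
    for j, (a, b) in enumerate(sorted(tuple(sorted(e)) for e in graph.edges())):
        graph.edges[a, b]["support"] = 2
        graph.edges[a, b]["support_ids"] = [f"{2*j+1}", f"{2*j+2}"]

    # gene-level p-values and sequential coordinates on synthetic chromosomes
    p = _draw_background_p(spec.background_p, spec.n_genes, rng)
    p = np.clip(p, 1e-300, 1.0)
    pmap = dict(zip(genes, p))
    for name, members in truth.items():
        mod = spec.planted_modules[int(name.rsplit("_", 1)[1]) - 1]
        draws = rng.uniform(mod.p_low, mod.p_high, size=len(members))
        for g, val in zip(sorted(members), draws):
            pmap[g] = float(val)
    per_chrom = -(-spec.n_genes // len(_CHROMS))  # ceil division
    rows = []
    for i, g in enumerate(genes):
        chrom = _CHROMS[i // per_chrom]
        start = (i % per_chrom) * _GENE_STEP + 1
        rows.append((g, chrom, start, start + _GENE_LEN - 1, pmap[g]))
    scores = (
        pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "p"])
        .set_index("gene")
        .astype({"start": float, "end": float})
    )

    # expression: shared latent factor inside each planted module
    expr = rng.standard_normal((spec.n_genes, spec.n_samples))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for name, members in truth.items():
        mod = spec.planted_modules[int(name.rsplit("_", 1)[1]) - 1]
        rho = mod.corr_within
        factor = rng.standard_normal(spec.n_samples)
        for g in sorted(members):
            noise = rng.standard_normal(spec.n_samples)
            expr[gene_pos[g]] = np.sqrt(rho) * factor + np.sqrt(1 - rho) * noise
    expression = pd.DataFrame(
        expr, index=pd.Index(genes, name="gene"),
        columns=[f"S{j:03d}" for j in range(spec.n_samples)],
    )

    # DNM list: a fraction is network-adjacent to planted genes
    neighbours = sorted(
        {n for g in planted_all for n in graph.adj[g]} - planted_all
    )
    n_adjacent = int(round(spec.dnm_overlap_fraction * spec.n_dnm)) if planted_all else 0
    n_adjacent = min(n_adjacent, len(neighbours))
    dnm = set()
    if n_adjacent:
        dnm.update(
            neighbours[i] for i in rng.choice(len(neighbours), n_adjacent, replace=False)
        )
    rest_pool = sorted(set(genes) - dnm - planted_all - set(neighbours))
    n_rest = min(spec.n_dnm - len(dnm), len(rest_pool))
    if n_rest:
        dnm.update(rest_pool[i] for i in rng.choice(len(rest_pool), n_rest, replace=False))
    cnv_pool = sorted(genes)
    cnv = {cnv_pool[i] for i in rng.choice(len(cnv_pool), min(spec.n_cnv, len(cnv_pool)), replace=False)}

    # gene sets: one per planted module plus random sets
    sets: dict[str, set[str]] = {name: set(m) for name, m in truth.items()}
    for j in range(spec.n_gene_sets):
        size = min(spec.gene_set_size, spec.n_genes)
        pick = rng.choice(spec.n_genes, size=size, replace=False)
        sets[f"random_set_{j + 1}"] = {genes[i] for i in pick}
    collection = GeneSetCollection(sets=sets, universe=set(genes))

    return SyntheticData(
        graph=graph,
        scores=scores,
        expression=expression,
        dnm_genes=dnm,
        cnv_genes=cnv,
        gene_sets=collection,
        truth=truth,
        spec=spec,
    )


def write_inputs(data: SyntheticData, outdir: str | Path) -> dict[str, Path]:
    """Write every input kind in the formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": outdir / "interactions.tsv",
        "scores": outdir / "scores.tsv",
        "expression": outdir / "expression.tsv",
        "dnm": outdir / "dnm_genes.txt",
        "cnv": outdir / "cnv_genes.txt",
        "gmt": outdir / "gene_sets.gmt",
        "truth": outdir / "truth.json",
    }
    with paths["interactions"].open("w") as fh:
        fh.write("gene_a\tgene_b\tpubmed_ids\n")
        for a, b in sorted(tuple(sorted(e)) for e in data.graph.edges()):
            ids = ";".join(data.graph.edges[a, b]["support_ids"])
            fh.write(f"{a}\t{b}\t{ids}\n")
    scores = data.scores.reset_index()
    scores["start"] = scores["start"].astype(int)
    scores["end"] = scores["end"].astype(int)
    scores.to_csv(paths["scores"], sep="\t", index=False, float_format="%.17g")
    data.expression.to_csv(paths["expression"], sep="\t", float_format="%.17g")
    for key, members in (("dnm", data.dnm_genes), ("cnv", data.cnv_genes)):
        paths[key].write_text("".join(f"{g}\n" for g in sorted(members)))
    with paths["gmt"].open("w") as fh:
        for name in sorted(data.gene_sets.sets):
            members = "\t".join(sorted(data.gene_sets.sets[name]))
            fh.write(f"{name}\tsynthetic\t{members}\n")
    payload = {name: sorted(members) for name, members in sorted(data.truth.items())}
    paths["truth"].write_text(json.dumps(payload, indent=2) + "\n")
    return paths


def read_gene_list(path: str | Path, uppercase: bool = True) -> set[str]:
    """Plain-text gene list, one symbol per line; blank lines and # comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.add(line.upper() if uppercase else line)
    return out


def spec_from_yaml(path: str | Path) -> SyntheticSpec:
    import yaml

    payload = yaml.safe_load(Path(path).read_text()) or {}
    if "planted_modules" in payload:
        payload["planted_modules"] = [
            PlantedModule(**m) if isinstance(m, dict) else PlantedModule(*m)
            for m in payload["planted_modules"]
        ]
    if "background_p" in payload and isinstance(payload["background_p"], list):
        payload["background_p"] = tuple(payload["background_p"])
    return SyntheticSpec(**payload)


def spec_to_dict(spec: SyntheticSpec) -> dict:
    payload = asdict(spec)
    payload["background_p"] = list(spec.background_p)
    return payload
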