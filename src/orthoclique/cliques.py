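"""Multi-species ortholog graph and 1-to-1 ortholog clique enumeration.

Genes are nodes labelled with their species; each accepted ortholog pair is
an unweighted edge (all edges score 1).  Because every edge crosses species,
the graph is multipartite and a clique can contain at most one gene per
species.  A clique of k genes is a set of genes, one in each of k species,
that are pairwise 1-to-1 orthologs; its size is the Ortholog Clique Level
(OCL) of its member genes — the number of species, host included, in which
each gene has 1-to-1 orthologs.

Enumeration reports maximal cliques by default (Bron–Kerbosch with
pivoting, via networkx); the all-cliques mode additionally reports every
non-maximal clique of at least ``min_size`` genes.  Per-gene OCL is the
maximum clique size over memberships, which coincides between the modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import networkx as nx

from .orthology import OrthologPair

__all__ = [
    "OrthologGraph",
    "OrthologClique",
    "build_graph",
    "enumerate_cliques",
    "assign_ocl",
    "write_dimacs",
]

Gene = tuple[str, str]  # (species, gene id)


@dataclass(frozen=True)
class OrthologClique:
    """A set of pairwise-orthologous genes, one per species."""

    genes: tuple[Gene, ...]  # sorted (species, gene) tuples
    clique_id: str = ""

    @property
    def ocl(self) -> int:
        return len(self.genes)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.genes)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(sorted(self.genes)))
        species = [s for s, _ in self.genes]
        if len(set(species)) != len(species):
            raise ValueError("clique contains two genes of one species")


class OrthologGraph:
    """Thin species-aware wrapper around an undirected networkx graph."""

    def __init__(self) -> None:
        self.g = nx.Graph()

    def add_gene(self, species: str, gene: str) -> None:
        self.g.add_node((species, gene))

    def add_pair(self, pair: OrthologPair) -> None:
        if pair.species_a == pair.species_b:
            raise ValueError(f"same-species pair for {pair.gene_a}")
        self.g.add_edge((pair.species_a, pair.gene_a), (pair.species_b, pair.gene_b))

    @property
    def n_genes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def has_edge(self, a: Gene, b: Gene) -> bool:
        return self.g.has_edge(a, b)


def build_graph(pairs: Iterable[OrthologPair]) -> OrthologGraph:
    """Graph with one node per distinct gene and one edge per ortholog pair.

    Idempotent under duplicate pairs; raises on a same-species pair.
    """
    graph = OrthologGraph()
    for p in pairs:
        graph.add_pair(p)
    return graph


def enumerate_cliques(
    graph: OrthologGraph, min_size: int = 3, maximal_only: bool = True
) -> list[OrthologClique]:
    """All (maximal) cliques with at least ``min_size`` genes.

    Output order is deterministic: size descending, then lexicographic on
    the sorted (species, gene) tuples.  Clique ids ``C000001`` ... follow
    that order.
    """
    if min_size < 3:
        raise ValueError("min_size must be >= 3")
    if maximal_only:
        raw = [c for c in nx.find_cliques(graph.g) if len(c) >= min_size]
    else:
        raw = [c for c in nx.enumerate_all_cliques(graph.g) if len(c) >= min_size]
    keys = sorted({tuple(sorted(c)) for c in raw}, key=lambda c: (-len(c), c))
    return [
        OrthologClique(genes=c, clique_id=f"C{i + 1:06d}") for i, c in enumerate(keys)
    ]


def assign_ocl(cliques: Iterable[OrthologClique]) -> dict[Gene, int]:
    """Per-gene OCL: the maximum clique size over cliques containing the gene."""
    ocl: dict[Gene, int] = {}
    for c in cliques:
        for gene in c.genes:
            ocl[gene] = max(ocl.get(gene, 0), c.ocl)
    return ocl


def write_dimacs(graph: OrthologGraph, stream: IO[str]) -> dict[Gene, int]:
    """Write the graph in DIMACS edge format; return the gene -> 1-based
    vertex index table (deterministic: sorted by (species, gene))."""
    if graph.n_genes == 0:
        raise ValueError("refusing to write DIMACS for an empty graph")
    index: Mapping[Gene, int] = {
        node: i + 1 for i, node in enumerate(sorted(graph.g.nodes))
    }
    stream.write(f"p edge {graph.n_genes} {graph.n_edges}\n")
    edges = sorted(
        tuple(sorted((index[u], index[v]))) for u, v in graph.g.edges
    )
    for i, j in edges:
        stream.write(f"e {i} {j}\n")
    return dict(index)
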