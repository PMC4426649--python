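"""Ortholog clique enumeration and the Ortholog Clique Level (OCL).

Assembles a graph planted with three cliques of sizes 3, 7 and 8 over ten
species, enumerates maximal cliques of size >= 3, and reports each gene's
OCL — the number of species (its own included) in which it has pairwise
1-to-1 orthologs.
"""

from io import StringIO
from itertools import combinations

from orthoclique.cliques import assign_ocl, build_graph, enumerate_cliques, write_dimacs
from orthoclique.orthology import OrthologPair


def planted(tag, k):
    genes = [(f"S{i}", f"S{i}_{tag}") for i in range(k)]
    return [OrthologPair(sa, ga, sb, gb) for (sa, ga), (sb, gb) in combinations(genes, 2)]


graph = build_graph(planted("a", 3) + planted("b", 7) + planted("c", 8))
cliques = enumerate_cliques(graph, min_size=3)
print(f"graph: {graph.n_genes} genes, {graph.n_edges} ortholog edges")
print(f"maximal cliques found: {[c.ocl for c in cliques]} (OCLs)")

ocl = assign_ocl(cliques)
print(f"gene S0_c has OCL {ocl[('S0', 'S0_c')]}: it has 1-to-1 orthologs in "
      "7 other species plus its own")

buf = StringIO()
write_dimacs(graph, buf)
print("DIMACS header for external clique solvers:", buf.getvalue().splitlines()[0])
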