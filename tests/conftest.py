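"""Shared fixtures: a small hand-built ontology, clique builders, and an
independent exhaustive clique enumerator used as oracle."""

from __future__ import annotations

from io import StringIO
from itertools import combinations

import pytest

from orthoclique.cliques import OrthologClique, OrthologGraph
from orthoclique.ontology import parse_obo

# Hand-built toy ontology.  biological_process namespace:
#
#   GO:0008150 (root)
#     +-- GO:0000002 (b)
#     |     +-- GO:0000003 (c)
#     |     +-- GO:0000004 (d; also part_of c  -> diamond)
#     |     +-- GO:0000007 (e; also is_a y -> short path 2, long path 3)
#     +-- GO:0000005 (x)
#           +-- GO:0000006 (y)
#
# molecular_function: root GO:0003674 with child GO:0016887 (ATPase
# activity); GO:0006200 is obsolete, replaced_by GO:0016887.
# cellular_component: bare root GO:0005575.
TOY_OBO = """\
format-version: 1.2

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process

[Term]
id: GO:0000002
name: b
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0000003
name: c
namespace: biological_process
is_a: GO:0000002 ! b

[Term]
id: GO:0000004
name: d
namespace: biological_process
is_a: GO:0000002
relationship: part_of GO:0000003

[Term]
id: GO:0000005
name: x
namespace: biological_process
is_a: GO:0008150

[Term]
id: GO:0000006
name: y
namespace: biological_process
is_a: GO:0000005

[Term]
id: GO:0000007
name: e
namespace: biological_process
is_a: GO:0000002
is_a: GO:0000006

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0016887
name: ATPase activity
namespace: molecular_function
is_a: GO:0003674

[Term]
id: GO:0006200
name: ATP catabolic process
namespace: biological_process
is_obsolete: true
replaced_by: GO:0016887

[Term]
id: GO:0005575
name: cellular_component
namespace: cellular_component
"""

BP_ROOT = "GO:0008150"
MF_ROOT = "GO:0003674"
CC_ROOT = "GO:0005575"


@pytest.fixture(scope="session")
def toy_dag():
    return parse_obo(StringIO(TOY_OBO))


def make_clique(members: dict[str, str], clique_id: str = "C1") -> OrthologClique:
    """Clique from a {species: gene} mapping."""
    return OrthologClique(genes=tuple(sorted(members.items())), clique_id=clique_id)


def brute_force_cliques(
    graph: OrthologGraph, min_size: int = 3, maximal_only: bool = True
) -> set[tuple]:
    """Exhaustive subset enumeration, independent of the production path.

    Checks every node subset for pairwise adjacency; maximality is checked
    against all strict supersets among the cliques found.
    """
    nodes = sorted(graph.g.nodes)
    cliques: set[tuple] = set()
    for k in range(min_size, len(nodes) + 1):
        for subset in combinations(nodes, k):
            if all(graph.g.has_edge(u, v) for u, v in combinations(subset, 2)):
                cliques.add(subset)
    if not maximal_only:
        return cliques
    return {
        c
        for c in cliques
        if not any(c != d and set(c) < set(d) for d in cliques)
        and not any(
            all(graph.g.has_edge(n, m) for m in c) for n in nodes if n not in c
        )
    }
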