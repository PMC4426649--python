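"""Gene Ontology DAG: OBO 1.2 parsing and ancestry queries.

The enrichment refinement step needs three things from the ontology: the set
of proper ancestors of a term (to decide whether a candidate annotation is
less specific than an existing one), the namespace roots (place-holder terms
that are only transferred to otherwise unannotated genes), and obsolescence
flags (obsolete terms are flagged, never silently transferred).

Only the go-basic dialect is supported: ``[Term]`` stanzas with ``is_a`` and
``relationship: part_of`` links, which are guaranteed acyclic in go-basic
releases.  ``part_of`` is treated identically to ``is_a`` for ancestry;
regulates-type relations are ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import IO, Iterable

import networkx as nx

__all__ = ["GOTerm", "OntologyDAG", "parse_obo", "NAMESPACES"]

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")

_GO_ID_RE = re.compile(r"^GO:\d{7}$")


def is_go_id(s: str) -> bool:
    """True if *s* is syntactically a GO identifier (``GO:`` + 7 digits)."""
    return bool(_GO_ID_RE.match(s))


@dataclass
class GOTerm:
    """One ontology term.

    ``parent_ids`` holds the direct is_a/part_of parents.  Obsolete terms
    carry no parents; ``replaced_by`` points at the suggested replacement
    when the OBO file provides one.
    """

    id: str
    name: str = ""
    namespace: str = ""
    parent_ids: set[str] = field(default_factory=set)
    obsolete: bool = False
    replaced_by: str | None = None

    def __post_init__(self) -> None:
        if not is_go_id(self.id):
            raise ValueError(f"malformed GO id: {self.id!r}")
        if self.id in self.parent_ids:
            raise ValueError(f"{self.id}: term lists itself as a parent")
        if self.obsolete and self.parent_ids:
            raise ValueError(f"{self.id}: obsolete term must not have parents")


class OntologyDAG:
    """Parsed ontology: terms plus a child-to-parent DAG over live terms.

    Parameters
    ----------
    terms
        Mapping GO id -> :class:`GOTerm`.  Validated on construction:
        every parent id must exist, every namespace must be one of the
        three GO sub-ontologies, the live (non-obsolete) graph must be
        acyclic, namespaces must be closed under parent links, and each
        namespace present must have exactly one root.
    """

    def __init__(self, terms: dict[str, GOTerm]):
        self.terms = dict(terms)
        # child -> parent edges over non-obsolete terms
        g = nx.DiGraph()
        for t in self.terms.values():
            if t.obsolete:
                continue
            if t.namespace not in NAMESPACES:
                raise ValueError(f"{t.id}: missing or unknown namespace {t.namespace!r}")
            g.add_node(t.id)
            for p in t.parent_ids:
                parent = self.terms.get(p)
                if parent is None:
                    raise ValueError(f"{t.id}: dangling parent id {p}")
                if parent.namespace != t.namespace:
                    raise ValueError(
                        f"{t.id} ({t.namespace}) has parent {p} in namespace "
                        f"{parent.namespace}; namespaces must be closed under parents"
                    )
                g.add_edge(t.id, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"cyclic is_a/part_of structure involving {cycle[0][0]}")
        self._graph = g

        self.roots: dict[str, str] = {}
        for t in self.terms.values():
            if t.obsolete or t.parent_ids:
                continue
            if t.namespace in self.roots:
                raise ValueError(
                    f"namespace {t.namespace} has two roots: "
                    f"{self.roots[t.namespace]} and {t.id}"
                )
            self.roots[t.namespace] = t.id
        for t in self.terms.values():
            if not t.obsolete and t.namespace not in self.roots:
                raise ValueError(f"namespace {t.namespace} has no root term")

    # -- queries ----------------------------------------------------------

    def __contains__(self, go_id: str) -> bool:
        return go_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def _live(self, go_id: str) -> GOTerm:
        term = self.terms.get(go_id)
        if term is None:
            raise KeyError(f"unknown GO id: {go_id}")
        if term.obsolete:
            raise ValueError(f"{go_id} is obsolete")
        return term

    def ancestors(self, go_id: str) -> frozenset[str]:
        """Proper ancestors of *go_id* via is_a/part_of (the term excluded)."""
        self._live(go_id)
        return self._ancestors_cached(go_id)

    @lru_cache(maxsize=None)
    def _ancestors_cached(self, go_id: str) -> frozenset[str]:
        # edges point child -> parent, so descendants in graph terms
        return frozenset(nx.descendants(self._graph, go_id))

    def path_length_to_root(self, go_id: str) -> int:
        """Edge count on the shortest parent path from *go_id* to its root."""
        term = self._live(go_id)
        root = self.roots[term.namespace]
        return nx.shortest_path_length(self._graph, go_id, root)

    def namespace_of(self, go_id: str) -> str:
        term = self.terms.get(go_id)
        if term is None:
            raise KeyError(f"unknown GO id: {go_id}")
        return term.namespace

    def is_root(self, go_id: str) -> bool:
        return go_id in self.roots.values()

    def live_terms(self) -> Iterable[GOTerm]:
        return (t for t in self.terms.values() if not t.obsolete)

    def leaves(self, namespace: str | None = None) -> list[str]:
        """Live terms with no live children, optionally within one namespace."""
        have_children = {p for _, p in self._graph.edges}
        out = [
            t.id
            for t in self.live_terms()
            if t.id not in have_children
            and (namespace is None or t.namespace == namespace)
        ]
        return sorted(out)


def parse_obo(stream: IO[str] | Iterable[str]) -> OntologyDAG:
    """Parse OBO 1.2 text into an :class:`OntologyDAG`.

    Reads ``[Term]`` stanzas only.  ``is_a`` and ``relationship: part_of``
    both populate ``parent_ids``; other relationship types are ignored.
    Raises ``ValueError`` on cycles, dangling parents or missing namespaces.
    """
    terms: dict[str, GOTerm] = {}
    in_term = False
    cur: dict | None = None

    def flush() -> None:
        nonlocal cur
        if cur is None:
            return
        if "id" not in cur:
            raise ValueError("[Term] stanza without an id")
        term = GOTerm(
            id=cur["id"],
            name=cur.get("name", ""),
            namespace=cur.get("namespace", ""),
            parent_ids=set() if cur.get("obsolete") else cur.get("parents", set()),
            obsolete=cur.get("obsolete", False),
            replaced_by=cur.get("replaced_by"),
        )
        terms[term.id] = term
        cur = None

    for raw in stream:
        line = raw.split("!")[0].strip()
        if not line:
            continue
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            cur = {"parents": set()} if in_term else None
            continue
        if not in_term or cur is None:
            continue
        key, _, value = line.partition(":")
        value = value.strip()
        key = key.strip()
        if key == "id":
            cur["id"] = value
        elif key == "name":
            cur["name"] = value
        elif key == "namespace":
            cur["namespace"] = value
        elif key == "is_a":
            cur["parents"].add(value.split()[0])
        elif key == "relationship":
            parts = value.split()
            if len(parts) >= 2 and parts[0] == "part_of":
                cur["parents"].add(parts[1])
        elif key == "is_obsolete":
            cur["obsolete"] = value.lower() == "true"
        elif key == "replaced_by":
            cur["replaced_by"] = value.split()[0]
    flush()
    return OntologyDAG(terms)
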