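"""Seeded generators for every input the pipeline consumes.

The generators emulate the shape of the real inputs — BLAST tabular hit
files per species pair and sequence type, per-species gene-to-GO tables, an
OBO ontology and a species group-score configuration — with known planted
structure, so the whole tool is testable end to end without any download:

* planted ortholog cliques whose member genes are unique mutual best hits
  in both the DNA and the protein tables (e-values far below the 1e-5
  cutoff), recoverable exactly by RBBH + intersection + clique enumeration;
* decoy hits that always fail the inclusive e-value cutoff (e-values drawn
  log-uniformly from [1e-4, 1]), so they can never displace a planted hit;
* planted transferable GO terms: leaf terms shared by every non-target
  member of a clique and absent from the target gene, which the enrichment
  model must accept with score equal to the clique bound minus the target's
  own contribution.

Everything is a pure function of (spec, seed): identical inputs give
byte-identical files.  No sequences are simulated, only hit tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

from .cliques import OrthologClique
from .enrichment import DEFAULT_GROUP_SCORES, SpeciesGroupConfig
from .ontology import NAMESPACES, OntologyDAG, parse_obo
from .orthology import BLAST6_COLUMNS, OrthologPair

__all__ = [
    "PlantedClique",
    "ScenarioSpec",
    "generate_ontology",
    "plant_orthologs",
    "plant_annotations",
    "simulate_scenario",
    "ScenarioBundle",
]

#: fixed species order used to pick the members of a size-k planted clique
SPECIES_ORDER = ("TAE", "TUR", "ATA", "HVU", "BDI", "OSA", "SBI", "ZMA", "ATH", "BRA")


@dataclass(frozen=True)
class PlantedClique:
    """One clique to plant: k pairwise mutual-best genes, with
    ``shared_terms`` leaf GO terms on every non-target member."""

    size: int
    species: tuple[str, ...] = ()  # default: first `size` of SPECIES_ORDER
    shared_terms: int = 2
    target_mode: str = "annotated"  # or "unannotated"

    def resolve_species(self, all_species: tuple[str, ...]) -> tuple[str, ...]:
        if self.species:
            return self.species
        return all_species[: self.size]


@dataclass(frozen=True)
class ScenarioSpec:
    """The stated world a simulation run realizes.

    Defaults mirror the ten-plant setting: ten species with the default
    group scores, one planted clique at every size 3–10.
    """

    seed: int
    species: tuple[str, ...] = SPECIES_ORDER
    group_scores: tuple[tuple[str, int], ...] = tuple(DEFAULT_GROUP_SCORES.items())
    target_species: str = "TAE"
    # one clique per size 3-10; the size-6 clique's target gene is left
    # unannotated, so the "no previous annotation" path is always exercised
    planted: tuple[PlantedClique, ...] = tuple(
        PlantedClique(size=k, target_mode="unannotated" if k == 6 else "annotated")
        for k in range(3, 11)
    )
    background_genes: int = 20
    ontology_depth: int = 3
    ontology_branching: int = 3
    annotation_density: float = 0.3
    decoy_rate: float = 0.1

    def __post_init__(self) -> None:
        for pc in self.planted:
            if pc.size > len(self.species):
                raise ValueError(
                    f"planted clique size {pc.size} exceeds {len(self.species)} species"
                )

    def groups(self) -> SpeciesGroupConfig:
        return SpeciesGroupConfig(
            scores=dict(self.group_scores), target_species=self.target_species
        )


def generate_ontology(
    depth: int, branching: int, seed: int, diamond_fraction: float = 0.1
) -> tuple[OntologyDAG, str]:
    """Random three-namespace ontology as (parsed DAG, OBO 1.2 text).

    Each namespace is a rooted ``branching``-ary tree of the given depth,
    plus a fraction of extra diamond edges (a second parent one level up).
    The DAG is obtained by round-tripping the serialized text through
    :func:`parse_obo`, so the two returned views always agree.
    """
    if depth < 1 or branching < 1:
        raise ValueError("depth and branching must be >= 1")
    rng = np.random.default_rng(seed)
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"GO:{counter:07d}"

    buf = StringIO()
    buf.write("format-version: 1.2\nontology: synthetic-go\n")
    for ns in NAMESPACES:
        root = next_id()
        _stanza(buf, root, f"{ns} root", ns, parents=[])
        levels: list[list[str]] = [[root]]
        for d in range(depth):
            level: list[str] = []
            for parent in levels[-1]:
                for b in range(branching):
                    tid = next_id()
                    parents = [parent]
                    # diamond edge: occasional second parent from the same level
                    if d >= 1 and rng.random() < diamond_fraction:
                        other = levels[-1][int(rng.integers(len(levels[-1])))]
                        if other != parent:
                            parents.append(other)
                    _stanza(buf, tid, f"synthetic {ns} term {tid[3:]}", ns, parents)
                    level.append(tid)
            levels.append(level)
    obo_text = buf.getvalue()
    return parse_obo(StringIO(obo_text)), obo_text


def _stanza(buf: StringIO, tid: str, name: str, ns: str, parents: list[str]) -> None:
    buf.write(f"\n[Term]\nid: {tid}\nname: {name}\nnamespace: {ns}\n")
    for i, p in enumerate(parents):
        if i == 0:
            buf.write(f"is_a: {p}\n")
        else:
            buf.write(f"relationship: part_of {p}\n")


@dataclass
class ScenarioBundle:
    """Everything one simulation run produced."""

    spec: ScenarioSpec
    truth_pairs: set
    truth_cliques: list
    hit_tables: dict  # (species_a, species_b, seqtype) -> forward DataFrame
    transcript_to_gene: dict
    transcript_lengths: dict  # gene -> [(transcript id, length), ...]
    dag: OntologyDAG
    obo_text: str
    annotations: dict  # species -> gene -> set of GO ids
    transferable: list  # (clique_id, target gene, GO id, expected score)
    groups: SpeciesGroupConfig


def plant_orthologs(spec: ScenarioSpec) -> ScenarioBundle:
    """Genes, transcripts, planted cliques and similarity tables.

    The returned bundle has no ontology/annotations yet; use
    :func:`simulate_scenario` for the complete world.
    """
    rng = np.random.default_rng(spec.seed)
    gene_counter = {sp: 0 for sp in spec.species}

    def new_gene(sp: str) -> str:
        gene_counter[sp] += 1
        return f"{sp}_G{gene_counter[sp]:04d}"

    # planted cliques, one gene per member species
    truth_cliques: list[OrthologClique] = []
    truth_pairs: set[OrthologPair] = set()
    for i, pc in enumerate(spec.planted):
        members = tuple((sp, new_gene(sp)) for sp in pc.resolve_species(spec.species))
        clique = OrthologClique(genes=members, clique_id=f"T{i + 1:06d}")
        truth_cliques.append(clique)
        gs = list(clique.genes)
        for j in range(len(gs)):
            for k in range(j + 1, len(gs)):
                (sa, ga), (sb, gb) = gs[j], gs[k]
                truth_pairs.add(
                    OrthologPair(sa, ga, sb, gb, evidence=frozenset({"dna", "protein"}))
                )

    background = {
        sp: [new_gene(sp) for _ in range(spec.background_genes)] for sp in spec.species
    }

    # two transcripts per gene; the longer one represents the gene in DNA hits
    transcript_lengths: dict[str, list[tuple[str, int]]] = {}
    transcript_to_gene: dict[str, str] = {}
    rep_transcript: dict[str, str] = {}
    all_genes = [g for c in truth_cliques for _, g in c.genes]
    all_genes += [g for sp in spec.species for g in background[sp]]
    for g in all_genes:
        l1, l2 = int(rng.integers(200, 2000)), int(rng.integers(200, 2000))
        transcript_lengths[g] = [(f"{g}.T1", l1), (f"{g}.T2", l2)]
        for t, _ in transcript_lengths[g]:
            transcript_to_gene[t] = g
        rep_transcript[g] = min(transcript_lengths[g], key=lambda t: (-t[1], t[0]))[0]

    # similarity tables per ordered species pair and sequence type
    rows: dict[tuple[str, str, str], list[list]] = {}

    def add_hit(sa: str, sb: str, seqtype: str, q: str, s: str, evalue: float, bit: float) -> None:
        key = (sa, sb, seqtype)
        rows.setdefault(key, []).append(
            [q, s, round(float(rng.uniform(80, 100)), 2), int(rng.integers(100, 1000)),
             int(rng.integers(0, 50)), int(rng.integers(0, 5)), 1, 100, 1, 100,
             evalue, bit]
        )

    def planted_evalue() -> float:
        return 10.0 ** float(rng.uniform(-50, -10))

    def decoy_evalue() -> float:
        return 10.0 ** float(rng.uniform(-4, 0))

    for clique in truth_cliques:
        gs = list(clique.genes)
        for j in range(len(gs)):
            for k in range(len(gs)):
                if j == k:
                    continue
                (sa, ga), (sb, gb) = gs[j], gs[k]
                bit = float(rng.uniform(500, 1000))
                add_hit(sa, sb, "protein", ga, gb, planted_evalue(), bit)
                add_hit(
                    sa, sb, "dna",
                    rep_transcript[ga], rep_transcript[gb], planted_evalue(), bit,
                )

    # decoys: sub-threshold noise between random background genes
    species = list(spec.species)
    n_decoys = int(
        spec.decoy_rate * spec.background_genes * len(species) * (len(species) - 1) / 2
    )
    for _ in range(n_decoys):
        ia, ib = rng.choice(len(species), size=2, replace=False)
        sa, sb = species[int(ia)], species[int(ib)]
        ga = background[sa][int(rng.integers(len(background[sa])))]
        gb = background[sb][int(rng.integers(len(background[sb])))]
        bit = float(rng.uniform(20, 60))
        add_hit(sa, sb, "protein", ga, gb, decoy_evalue(), bit)
        add_hit(sa, sb, "dna", rep_transcript[ga], rep_transcript[gb], decoy_evalue(), bit)

    hit_tables = {
        key: pd.DataFrame(r, columns=BLAST6_COLUMNS) for key, r in sorted(rows.items())
    }
    return ScenarioBundle(
        spec=spec,
        truth_pairs=truth_pairs,
        truth_cliques=truth_cliques,
        hit_tables=hit_tables,
        transcript_to_gene=transcript_to_gene,
        transcript_lengths=transcript_lengths,
        dag=None,  # filled by simulate_scenario
        obo_text="",
        annotations={},
        transferable=[],
        groups=spec.groups(),
    )


def plant_annotations(
    spec: ScenarioSpec,
    dag: OntologyDAG,
    truth_cliques: list[OrthologClique],
    seed: int,
) -> tuple[dict, list]:
    """Annotation maps with planted transferable terms.

    Each planted clique receives ``shared_terms`` distinct leaf terms on all
    non-target members; the target gene is annotated with a parent of the
    first planted term (mode ``annotated``) or left empty.  Background
    annotation is drawn at ``annotation_density``.
    Returns (annotations, transferable) where transferable lists
    (clique_id, target gene, GO id, expected GO score).
    """
    rng = np.random.default_rng(seed)
    leaves = dag.leaves()
    groups = spec.groups()
    ann: dict[str, dict[str, set]] = {sp: {} for sp in spec.species}

    # distinct leaves per clique: shared_terms transferable leaves, plus one
    # extra "common" leaf for annotated-target cliques (shared by every
    # member, target included, so Eq. 1 overlap is high for real cliques)
    total_needed = sum(
        pc.shared_terms + (1 if pc.target_mode == "annotated" else 0)
        for pc in spec.planted
    )
    if total_needed > len(leaves):
        raise ValueError(
            f"need {total_needed} distinct leaf terms but the ontology has {len(leaves)}"
        )
    leaf_iter = iter(leaves)
    used_leaves: set[str] = set()

    transferable: list[tuple[str, str, str, float]] = []
    for pc, clique in zip(spec.planted, truth_cliques):
        planted_terms = [next(leaf_iter) for _ in range(pc.shared_terms)]
        used_leaves.update(planted_terms)
        target_gene = next(
            (g for sp, g in clique.genes if sp == spec.target_species), None
        )
        if pc.target_mode == "annotated" and planted_terms:
            # target carries a LESS specific version (the parent) of the
            # first planted term plus a common leaf; non-target members
            # carry both too, so the target's set is contained in theirs
            # and the clique overlaps at 100%
            common = next(leaf_iter)
            used_leaves.add(common)
            parent = sorted(dag.terms[planted_terms[0]].parent_ids)[0]
            shared_with_target = {parent, common}
        else:
            shared_with_target = set()
        for sp, g in clique.genes:
            if sp == spec.target_species:
                continue
            ann[sp].setdefault(g, set()).update(planted_terms, shared_with_target)
        if target_gene is None:
            continue
        ann[spec.target_species].setdefault(target_gene, set()).update(shared_with_target)
        expected = groups.max_score(clique.species) - groups.weight(spec.target_species)
        for t in planted_terms:
            transferable.append((clique.clique_id, target_gene, t, expected))

    # background annotation at the requested density, avoiding planted leaves
    vocab = [t.id for t in dag.live_terms() if t.id not in used_leaves]
    for sp in spec.species:
        for g in _background_gene_ids(spec, sp, truth_cliques):
            if rng.random() < spec.annotation_density:
                k = int(rng.integers(1, 4))
                terms = {vocab[int(rng.integers(len(vocab)))] for _ in range(k)}
                ann[sp][g] = terms
    return ann, transferable


def _background_gene_ids(
    spec: ScenarioSpec, sp: str, truth_cliques: list[OrthologClique]
) -> list[str]:
    n_planted = sum(1 for c in truth_cliques for s, _ in c.genes if s == sp)
    return [
        f"{sp}_G{i:04d}" for i in range(n_planted + 1, n_planted + spec.background_genes + 1)
    ]


def simulate_scenario(spec: ScenarioSpec) -> ScenarioBundle:
    """The complete stated world: orthology inputs plus ontology and
    annotations, all derived from ``spec.seed``."""
    bundle = plant_orthologs(spec)
    dag, obo_text = generate_ontology(
        spec.ontology_depth, spec.ontology_branching, seed=spec.seed + 1
    )
    ann, transferable = plant_annotations(spec, dag, bundle.truth_cliques, seed=spec.seed + 2)
    bundle.dag = dag
    bundle.obo_text = obo_text
    bundle.annotations = ann
    bundle.transferable = transferable
    return bundle
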