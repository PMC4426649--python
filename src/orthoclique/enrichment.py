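"""Phylogenetically weighted GO annotation transfer to a target species.

Three steps, run per ortholog clique that contains exactly one gene of the
target species:

1. seed every gene with its direct GO annotations;
2. score every GO term carried by any clique member as the sum over members
   carrying it of the reciprocal of their species' phylogenetic group score
   (1 = closest to the target .. 6 = most distant), and keep candidates at
   or above the threshold G_T = 0.5 — exactly the contribution of a single
   annotation in a group-2 species, the closest non-conspecific evidence;
3. refine by ontology specificity: a candidate is accepted only if it is
   not already annotated and not a proper ancestor (less specific version)
   of an existing annotation.  Namespace roots are place-holders and are
   accepted only for genes with no annotation in that namespace; obsolete
   candidates are flagged, never silently transferred.

With the default plant group scores a term present in all ten members of a
size-10 clique scores 1 + 1 + 1/2 + 1/2 + 1/3 + 1/4 + 1/5 + 1/5 + 1/6 + 1/6
= 4.3166667, the attainable maximum.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cliques import OrthologClique
from .ontology import OntologyDAG
from .validation import AnnotationMap, terms_of

__all__ = [
    "DEFAULT_GROUP_SCORES",
    "SpeciesGroupConfig",
    "EnrichmentConfig",
    "ScoredAssignment",
    "go_score",
    "candidate_terms",
    "threshold_filter",
    "refine_by_dag",
    "enrich_target",
    "EnrichmentSummary",
    "score_histogram",
]

#: Default evolutionary-proximity group scores for the ten plant species,
#: centred on bread wheat (TAE).  Keys are the conventional 3-letter codes:
#: TAE=T. aestivum, TUR=T. urartu, ATA=A. tauschii, HVU=H. vulgare,
#: BDI=B. distachyon, OSA=O. sativa, SBI=S. bicolor, ZMA=Z. mays,
#: ATH=A. thaliana, BRA=B. rapa.
DEFAULT_GROUP_SCORES: dict[str, int] = {
    "TAE": 1,
    "TUR": 1,
    "ATA": 2,
    "HVU": 2,
    "BDI": 3,
    "OSA": 4,
    "SBI": 5,
    "ZMA": 5,
    "ATH": 6,
    "BRA": 6,
}


@dataclass(frozen=True)
class SpeciesGroupConfig:
    """Species -> phylogenetic group score, plus the annotation target."""

    scores: Mapping[str, int]
    target_species: str = "TAE"

    def __post_init__(self) -> None:
        if self.target_species not in self.scores:
            raise ValueError(f"target species {self.target_species} has no group score")
        if self.scores[self.target_species] != 1:
            raise ValueError("target species must be in group 1")
        for sp, g in self.scores.items():
            if not (isinstance(g, int) and g >= 1):
                raise ValueError(f"group score for {sp} must be an integer >= 1")

    @classmethod
    def default_plants(cls) -> "SpeciesGroupConfig":
        return cls(scores=dict(DEFAULT_GROUP_SCORES), target_species="TAE")

    def weight(self, species: str) -> float:
        try:
            return 1.0 / self.scores[species]
        except KeyError:
            raise KeyError(f"species {species} missing from group config") from None

    def max_score(self, species: Iterable[str]) -> float:
        """Attainable score bound for a clique over the given species."""
        return sum(self.weight(sp) for sp in species)


@dataclass(frozen=True)
class EnrichmentConfig:
    score_threshold: float = 0.5
    threshold_inclusive: bool = True  # score == G_T passes by default
    resolve_obsolete: bool = False  # re-enter replaced_by terms as candidates

    def __post_init__(self) -> None:
        if not self.score_threshold > 0:
            raise ValueError("score_threshold must be > 0")

    def passes(self, score: float) -> bool:
        if self.threshold_inclusive:
            return score >= self.score_threshold
        return score > self.score_threshold


# status values a ScoredAssignment can carry
STATUSES = (
    "original",
    "candidate",
    "accepted",
    "rejected-below-threshold",
    "rejected-ancestor-of-original",
    "rejected-duplicate",
    "flagged-obsolete",
)


@dataclass(frozen=True)
class ScoredAssignment:
    gene: str
    go_id: str
    clique_id: str
    go_score: float
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def go_score(
    go: str,
    clique: OrthologClique,
    ann: AnnotationMap,
    groups: SpeciesGroupConfig,
) -> float:
    """Weighted evidence for *go* in *clique*: sum of 1/group over members
    whose gene carries *go* directly."""
    total = 0.0
    for sp, gene in clique.genes:
        w = groups.weight(sp)  # raises if species unknown
        if go in terms_of(ann, sp, gene):
            total += w
    return total


def candidate_terms(
    clique: OrthologClique,
    ann: AnnotationMap,
    groups: SpeciesGroupConfig,
) -> list[ScoredAssignment]:
    """Scored term records for the clique's target gene.

    Every GO term carried by any member is scored; terms already on the
    target gene are labelled ``original``, the rest ``candidate``.  A clique
    without exactly one target-species gene yields nothing.
    """
    target_genes = [g for sp, g in clique.genes if sp == groups.target_species]
    if len(target_genes) != 1:
        return []
    target = target_genes[0]
    own = terms_of(ann, groups.target_species, target)
    universe = set()
    for sp, gene in clique.genes:
        universe |= terms_of(ann, sp, gene)
    out = []
    for go in sorted(universe):
        status = "original" if go in own else "candidate"
        out.append(
            ScoredAssignment(
                gene=target,
                go_id=go,
                clique_id=clique.clique_id,
                go_score=go_score(go, clique, ann, groups),
                status=status,
            )
        )
    return out


def threshold_filter(
    scored: Iterable[ScoredAssignment], cfg: EnrichmentConfig | None = None
) -> list[ScoredAssignment]:
    """Mark candidates below G_T as rejected; originals always pass."""
    cfg = cfg or EnrichmentConfig()
    out = []
    for a in scored:
        if a.status == "candidate" and not cfg.passes(a.go_score):
            a = replace(a, status="rejected-below-threshold")
        out.append(a)
    return out


def refine_by_dag(
    gene: str,
    passing: Iterable[ScoredAssignment],
    original: set,
    dag: OntologyDAG,
    cfg: EnrichmentConfig | None = None,
) -> list[ScoredAssignment]:
    """Specificity refinement of one gene's passing candidates.

    A candidate is accepted iff it is new to the gene and not a proper
    ancestor of any original term — i.e. it sits deeper than, or on a
    different path from, what the gene already has.  Namespace roots are
    accepted only when the gene has no original term in that namespace.
    Obsolete candidates are flagged; with ``resolve_obsolete`` their
    ``replaced_by`` term re-enters the candidate set at the same score.
    """
    cfg = cfg or EnrichmentConfig()
    # proper ancestors of the original annotation set (obsolete originals
    # contribute none) and the namespaces they occupy
    original_live = {t for t in original if t in dag and not dag.terms[t].obsolete}
    blocked = set()
    for t in original_live:
        blocked |= dag.ancestors(t)
    occupied_namespaces = {dag.namespace_of(t) for t in original_live}

    queue = list(passing)
    out: list[ScoredAssignment] = []
    seen: set[str] = set()
    while queue:
        a = queue.pop(0)
        if a.go_id not in dag:
            raise KeyError(f"unknown GO id in candidates: {a.go_id}")
        if a.go_id in seen:
            continue
        seen.add(a.go_id)
        term = dag.terms[a.go_id]
        if term.obsolete:
            out.append(replace(a, status="flagged-obsolete"))
            if cfg.resolve_obsolete and term.replaced_by:
                queue.append(replace(a, go_id=term.replaced_by, status="candidate"))
            continue
        if a.go_id in original:
            out.append(replace(a, status="rejected-duplicate"))
        elif dag.is_root(a.go_id):
            ns = dag.namespace_of(a.go_id)
            status = "accepted" if ns not in occupied_namespaces else "rejected-ancestor-of-original"
            out.append(replace(a, status=status))
        elif a.go_id in blocked:
            out.append(replace(a, status="rejected-ancestor-of-original"))
        else:
            out.append(replace(a, status="accepted"))
    return sorted(out, key=lambda a: (a.gene, a.go_id, a.clique_id))


@dataclass
class EnrichmentSummary:
    """Aggregate description of one enrichment run."""

    n_target_genes_in_cliques: int
    n_genes_enriched: int
    n_genes_newly_annotated: int  # previously unannotated genes gaining terms
    n_accepted: int
    n_original_assignments: int
    pct_increase: float  # accepted / original assignments * 100
    mean_accepted_score: float
    accepted_path_lengths: Counter = field(default_factory=Counter)
    n_accepted_roots: int = 0
    n_genes_with_accepted_root: int = 0


def enrich_target(
    cliques: Sequence[OrthologClique],
    ann: AnnotationMap,
    dag: OntologyDAG,
    groups: SpeciesGroupConfig | None = None,
    cfg: EnrichmentConfig | None = None,
) -> tuple[list[ScoredAssignment], EnrichmentSummary]:
    """Run candidate generation, scoring, thresholding and refinement over
    all cliques; union per-gene assignments keeping the best-scored record
    per (gene, GO id)."""
    groups = groups or SpeciesGroupConfig.default_plants()
    cfg = cfg or EnrichmentConfig()

    per_gene_pass: dict[str, dict[str, ScoredAssignment]] = {}
    records: list[ScoredAssignment] = []
    target_genes: set[str] = set()
    for clique in cliques:
        scored = candidate_terms(clique, ann, groups)
        if not scored:
            continue
        target_genes.add(scored[0].gene)
        for a in threshold_filter(scored, cfg):
            if a.status == "candidate":
                best = per_gene_pass.setdefault(a.gene, {})
                prev = best.get(a.go_id)
                # keep the strongest evidence across cliques
                if prev is None or a.go_score > prev.go_score:
                    best[a.go_id] = a
            else:
                records.append(a)

    for gene in sorted(per_gene_pass):
        original = terms_of(ann, groups.target_species, gene)
        records.extend(
            refine_by_dag(gene, per_gene_pass[gene].values(), original, dag, cfg)
        )
    records.sort(key=lambda a: (a.gene, a.go_id, a.clique_id, a.status))

    accepted = [a for a in records if a.status == "accepted"]
    genes_enriched = {a.gene for a in accepted}
    newly = {
        g for g in genes_enriched if not terms_of(ann, groups.target_species, g)
    }
    n_original = sum(
        len(terms_of(ann, groups.target_species, g)) for g in sorted(target_genes)
    )
    path_lengths = Counter(dag.path_length_to_root(a.go_id) for a in accepted)
    roots = [a for a in accepted if dag.is_root(a.go_id)]
    summary = EnrichmentSummary(
        n_target_genes_in_cliques=len(target_genes),
        n_genes_enriched=len(genes_enriched),
        n_genes_newly_annotated=len(newly),
        n_accepted=len(accepted),
        n_original_assignments=n_original,
        pct_increase=(100.0 * len(accepted) / n_original) if n_original else float("inf"),
        mean_accepted_score=(
            sum(a.go_score for a in accepted) / len(accepted) if accepted else 0.0
        ),
        accepted_path_lengths=path_lengths,
        n_accepted_roots=len(roots),
        n_genes_with_accepted_root=len({a.gene for a in roots}),
    )
    return records, summary


def score_histogram(
    assignments: Iterable[ScoredAssignment],
    bins: Sequence[tuple[float, float]],
) -> pd.DataFrame:
    """Counts of original vs accepted (new) term scores per score interval.

    ``bins`` are right-closed intervals, the first closed on the left;
    together they must tile [0, max attainable score].
    """
    bins = sorted(bins)
    for (_, hi1), (lo2, _) in zip(bins, bins[1:]):
        if hi1 != lo2:
            raise ValueError("bins must tile the score range without gaps/overlap")
    labels = [f"({lo:g},{hi:g}]" for lo, hi in bins]
    labels[0] = f"[{bins[0][0]:g},{bins[0][1]:g}]"
    table = pd.DataFrame(0, index=pd.Index(["original", "new"], name="status"), columns=labels)
    for a in assignments:
        if a.status == "original":
            row = "original"
        elif a.status == "accepted":
            row = "new"
        else:
            continue
        for (lo, hi), lab in zip(bins, labels):
            closed_left = lab.startswith("[")
            if (lo < a.go_score or (closed_left and a.go_score == lo)) and a.go_score <= hi:
                table.loc[row, lab] += 1
                break
    return table
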