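"""End-to-end chain over a simulated or file-based scenario.

``run_all`` wires the stages together: similarity tables -> RBBH with
DNA/protein intersection -> ortholog graph -> clique enumeration -> overlap
validation (with a seeded random-clique null of matching size counts) ->
phylogenetically weighted enrichment of the target species.  When given an
output directory it writes the standard TSVs with provenance headers;
otherwise it returns everything in memory.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from . import cliques as cq
from . import io as oio
from . import validation as val
from .enrichment import (
    EnrichmentConfig,
    EnrichmentSummary,
    ScoredAssignment,
    enrich_target,
)
from .orthology import OrthologyConfig, call_pairs
from .simulate import ScenarioBundle, ScenarioSpec, simulate_scenario

__all__ = ["PipelineResult", "run_all"]


@dataclass
class PipelineResult:
    pairs: set
    cliques: list
    ocl: dict
    overlaps: list
    random_overlaps: list
    assignments: list[ScoredAssignment]
    summary: EnrichmentSummary


def run_all(
    bundle: ScenarioBundle | ScenarioSpec,
    out_dir: str | Path | None = None,
    orthology_cfg: OrthologyConfig | None = None,
    enrichment_cfg: EnrichmentConfig | None = None,
    min_clique_size: int = 3,
    null_seed: int | None = None,
) -> PipelineResult:
    """Run the whole pipeline on a scenario.

    ``null_seed`` seeds the random-clique null (defaults to the scenario
    seed + 3); the null uses the same per-size clique counts as the real
    enumeration, drawn from each species' complete simulated gene pool.
    """
    if isinstance(bundle, ScenarioSpec):
        bundle = simulate_scenario(bundle)
    orthology_cfg = orthology_cfg or OrthologyConfig()
    enrichment_cfg = enrichment_cfg or EnrichmentConfig()
    if null_seed is None:
        null_seed = bundle.spec.seed + 3

    # orthology: every ordered pair has a forward table keyed (sa, sb, type)
    pairs = set()
    seen = set()
    for sa, sb, _ in bundle.hit_tables:
        key = tuple(sorted((sa, sb)))
        if key in seen:
            continue
        seen.add(key)
        sa, sb = key
        pairs |= call_pairs(
            sa, sb,
            dna_fwd=_get(bundle, sa, sb, "dna"),
            dna_rev=_get(bundle, sb, sa, "dna"),
            prot_fwd=_get(bundle, sa, sb, "protein"),
            prot_rev=_get(bundle, sb, sa, "protein"),
            cfg=orthology_cfg,
            transcript_to_gene=bundle.transcript_to_gene,
        )

    graph = cq.build_graph(pairs)
    found = cq.enumerate_cliques(graph, min_size=min_clique_size)
    ocl = cq.assign_ocl(found)

    overlaps = [val.go_set_overlap(c, bundle.annotations) for c in found]
    size_counts = Counter(c.ocl for c in found)
    # complete pool per species: every simulated gene, annotated or not
    pools = {
        sp: sorted(
            set(bundle.annotations.get(sp, {}))
            | {g for (s, g) in graph.g.nodes if s == sp}
        )
        for sp in bundle.spec.species
    }
    rand = val.random_cliques(pools, dict(size_counts), seed=null_seed)
    random_overlaps = [val.go_set_overlap(c, bundle.annotations) for c in rand]

    assignments, summary = enrich_target(
        found, bundle.annotations, bundle.dag, bundle.groups, enrichment_cfg
    )

    result = PipelineResult(
        pairs=pairs,
        cliques=found,
        ocl=ocl,
        overlaps=overlaps,
        random_overlaps=random_overlaps,
        assignments=assignments,
        summary=summary,
    )
    if out_dir is not None:
        _write(result, bundle, Path(out_dir), null_seed)
    return result


def _get(bundle: ScenarioBundle, sa: str, sb: str, seqtype: str):
    import pandas as pd

    from .orthology import BLAST6_COLUMNS

    return bundle.hit_tables.get(
        (sa, sb, seqtype), pd.DataFrame(columns=BLAST6_COLUMNS)
    )


def _write(result: PipelineResult, bundle: ScenarioBundle, out: Path, null_seed: int) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = dict(seed=bundle.spec.seed)
    with open(out / "pairs.tsv", "w") as fh:
        oio.write_pairs(result.pairs, fh, **cfg)
    with open(out / "cliques.tsv", "w") as fh:
        oio.write_cliques(result.cliques, fh, **cfg)
    with open(out / "ocl.tsv", "w") as fh:
        oio.write_ocl(result.ocl, fh, **cfg)
    with open(out / "overlaps.tsv", "w") as fh:
        oio.write_overlaps(result.overlaps, fh, **cfg)
    with open(out / "random_overlaps.tsv", "w") as fh:
        oio.write_overlaps(result.random_overlaps, fh, seed=null_seed)
    with open(out / "assignments.tsv", "w") as fh:
        oio.write_assignments(result.assignments, fh, **cfg)
    with open(out / "ontology.obo", "w") as fh:
        fh.write(bundle.obo_text)
    with open(out / "groups.tsv", "w") as fh:
        oio.write_groups(bundle.groups, fh)
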