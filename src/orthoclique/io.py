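"""Readers and writers for the plain-text formats the pipeline touches.

BLAST tabular (outfmt 6), gene->GO annotation tables (2-column TSV or GAF
2.x), OBO 1.2 ontologies, species group-score configs, and the TSV outputs
(ortholog pairs, cliques, OCLs, overlaps, assignments).  Every writer puts
a provenance header (tool version, config, seed where applicable) in
comment lines, and rows are emitted in a deterministic order so reruns are
diff-clean.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd

from . import __version__
from .cliques import OrthologClique
from .enrichment import ScoredAssignment, SpeciesGroupConfig
from .ontology import OntologyDAG, is_go_id, parse_obo
from .orthology import BLAST6_COLUMNS, OrthologPair
from .validation import OverlapResult

__all__ = [
    "read_blast_tab",
    "read_annotations",
    "read_obo_file",
    "read_groups",
    "write_groups",
    "write_pairs",
    "read_pairs",
    "write_cliques",
    "read_cliques",
    "write_ocl",
    "write_overlaps",
    "write_assignments",
    "provenance_header",
]


def provenance_header(**config) -> str:
    parts = [f"# orthoclique {__version__}"]
    for k in sorted(config):
        parts.append(f"# {k} = {config[k]}")
    return "\n".join(parts) + "\n"


def read_blast_tab(path: str | Path) -> pd.DataFrame:
    """Read a 12-column BLAST -outfmt 6 file (tab-separated, headerless)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=BLAST6_COLUMNS, comment="#",
        dtype={"qseqid": str, "sseqid": str},
    )
    for col in ("evalue", "bitscore", "pident"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ValueError(f"{path}: non-numeric {col} at line {line}")
        df[col] = pd.to_numeric(df[col])
    return df


def read_annotations(path: str | Path, dialect: str = "tsv") -> dict[str, set]:
    """Read direct gene->GO annotations for one species.

    ``tsv``: two columns (gene, GO id), optional further columns ignored,
    '#' comments skipped.  ``gaf``: GAF 2.x, '!' comments skipped, column 2
    is the object id and column 5 the GO id.  Duplicate rows collapse to
    set semantics.  A malformed GO id raises with its line number.
    """
    out: dict[str, set] = {}
    comment = {"tsv": "#", "gaf": "!"}[dialect]
    gene_col, go_col = {"tsv": (0, 1), "gaf": (1, 4)}[dialect]
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith(comment):
                continue
            if len(row) <= max(gene_col, go_col):
                raise ValueError(f"{path}: too few columns at line {lineno}")
            gene, go = row[gene_col].strip(), row[go_col].strip()
            if not is_go_id(go):
                raise ValueError(f"{path}: malformed GO id {go!r} at line {lineno}")
            out.setdefault(gene, set()).add(go)
    return out


def read_obo_file(path: str | Path) -> OntologyDAG:
    with open(path) as fh:
        return parse_obo(fh)


def read_groups(path: str | Path) -> SpeciesGroupConfig:
    """Species group config TSV: species, group_score, target flag (0/1)."""
    scores: dict[str, int] = {}
    target = None
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            sp, score = row[0], int(row[1])
            scores[sp] = score
            if len(row) > 2 and row[2].strip() == "1":
                target = sp
    if target is None:
        raise ValueError(f"{path}: no species flagged as target")
    return SpeciesGroupConfig(scores=scores, target_species=target)


def write_groups(groups: SpeciesGroupConfig, stream: IO[str]) -> None:
    stream.write(provenance_header(format="species\tgroup_score\ttarget"))
    for sp in sorted(groups.scores):
        flag = 1 if sp == groups.target_species else 0
        stream.write(f"{sp}\t{groups.scores[sp]}\t{flag}\n")


def write_pairs(pairs: Iterable[OrthologPair], stream: IO[str], **config) -> None:
    stream.write(provenance_header(**config))
    stream.write("species_a\tgene_a\tspecies_b\tgene_b\tevidence\n")
    for p in sorted(pairs):
        ev = ",".join(sorted(p.evidence))
        stream.write(f"{p.species_a}\t{p.gene_a}\t{p.species_b}\t{p.gene_b}\t{ev}\n")


def read_pairs(path: str | Path) -> set[OrthologPair]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    return {
        OrthologPair(
            r.species_a, r.gene_a, r.species_b, r.gene_b,
            evidence=frozenset(r.evidence.split(",")),
        )
        for r in df.itertuples()
    }


def write_cliques(cliques: Iterable[OrthologClique], stream: IO[str], **config) -> None:
    """One row per clique member: clique_id, ocl, species, gene."""
    stream.write(provenance_header(**config))
    stream.write("clique_id\tocl\tspecies\tgene\n")
    for c in cliques:
        for sp, g in c.genes:
            stream.write(f"{c.clique_id}\t{c.ocl}\t{sp}\t{g}\n")


def read_cliques(path: str | Path) -> list[OrthologClique]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"clique_id": str})
    out = []
    for cid, grp in df.groupby("clique_id", sort=True):
        genes = tuple(sorted(zip(grp["species"], grp["gene"])))
        out.append(OrthologClique(genes=genes, clique_id=str(cid)))
    return sorted(out, key=lambda c: (-c.ocl, c.genes))


def write_ocl(ocl: Mapping[tuple[str, str], int], stream: IO[str], **config) -> None:
    stream.write(provenance_header(**config))
    stream.write("species\tgene\tocl\n")
    for (sp, g), k in sorted(ocl.items()):
        stream.write(f"{sp}\t{g}\t{k}\n")


def write_overlaps(results: Iterable[OverlapResult], stream: IO[str], **config) -> None:
    stream.write(provenance_header(**config))
    stream.write("clique_id\tocl\toverlap_pct\n")
    for r in sorted(results, key=lambda r: r.clique_id):
        stream.write(f"{r.clique_id}\t{r.ocl}\t{r.overlap_pct:.4f}\n")


def write_assignments(
    assignments: Iterable[ScoredAssignment], stream: IO[str], **config
) -> None:
    """Scores are printed to 2 decimals; comparisons elsewhere stay at full
    precision."""
    stream.write(provenance_header(**config))
    stream.write("gene\tgo_id\tclique_id\tgo_score\tstatus\n")
    for a in sorted(assignments, key=lambda a: (a.gene, a.go_id, a.clique_id)):
        stream.write(f"{a.gene}\t{a.go_id}\t{a.clique_id}\t{a.go_score:.2f}\t{a.status}\n")
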