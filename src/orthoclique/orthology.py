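"""1-to-1 ortholog calling by reciprocal best hits with dual evidence.

For every ordered species pair the caller supplies BLAST tabular hits in
both directions, separately for DNA (coding sequence) and protein evidence.
Per direction the best surviving hit per query is selected (e-value cutoff
inclusive, default 1e-5), reciprocity of the two directions yields candidate
1-to-1 pairs, and the DNA-based and protein-based pair sets are intersected:
a pair is accepted only when both kinds of sequence agree, and dismissed on
any disagreement.

Hit tables are plain pandas DataFrames with outfmt-6 column names (see
:data:`BLAST6_COLUMNS`); :func:`orthoclique.io.read_blast_tab` produces
them from files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "BLAST6_COLUMNS",
    "OrthologyConfig",
    "OrthologPair",
    "select_longest_transcript",
    "best_hits",
    "reciprocal_best_hits",
    "intersect_evidence",
    "lift_to_genes",
    "call_pairs",
]

#: Column names of BLAST tabular output (-outfmt 6).
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class OrthologyConfig:
    """RBBH parameters.  The e-value cutoff is inclusive (evalue <= cutoff kept)."""

    evalue_cutoff: float = 1e-5

    def __post_init__(self) -> None:
        if not self.evalue_cutoff > 0:
            raise ValueError("evalue_cutoff must be > 0")


@dataclass(frozen=True, order=True)
class OrthologPair:
    """A cross-species 1-to-1 ortholog edge in canonical orientation.

    Canonical means species are in lexicographic order, so equality and
    set membership are orientation-free.  ``evidence`` records which
    sequence types supported the pair ({'dna'}, {'protein'} or both).
    """

    species_a: str
    gene_a: str
    species_b: str
    gene_b: str
    evidence: frozenset = field(default_factory=frozenset, compare=False)

    def __post_init__(self) -> None:
        if self.species_a == self.species_b:
            raise ValueError(f"same-species pair: {self.species_a}")
        if self.species_a > self.species_b:
            sa, ga = self.species_a, self.gene_a
            object.__setattr__(self, "species_a", self.species_b)
            object.__setattr__(self, "gene_a", self.gene_b)
            object.__setattr__(self, "species_b", sa)
            object.__setattr__(self, "gene_b", ga)


def select_longest_transcript(
    transcripts: Mapping[str, list[tuple[str, int]]],
) -> dict[str, str]:
    """Pick one representative transcript per gene: longest, ties to the
    lexicographically smallest transcript id."""
    out: dict[str, str] = {}
    for gene, tlist in transcripts.items():
        if not tlist:
            raise ValueError(f"gene {gene} has no transcripts")
        out[gene] = min(tlist, key=lambda t: (-t[1], t[0]))[0]
    return out


def best_hits(hits: pd.DataFrame, cfg: OrthologyConfig | None = None) -> dict[str, str]:
    """Best surviving subject per query from one directed hit table.

    Hits with evalue above the (inclusive) cutoff are discarded; multiple
    HSP rows for one (query, subject) pair are collapsed to the best
    bitscore first.  Ties break by highest bitscore, then lowest evalue,
    then lexicographically smallest subject id.
    """
    cfg = cfg or OrthologyConfig()
    if hits.empty:
        return {}
    df = hits[["qseqid", "sseqid", "evalue", "bitscore"]].copy()
    if df["evalue"].isna().any() or df["bitscore"].isna().any():
        bad = df.index[df["evalue"].isna() | df["bitscore"].isna()][0]
        raise ValueError(f"malformed hit row at index {bad}: non-numeric evalue/bitscore")
    df = df[df["evalue"] <= cfg.evalue_cutoff]
    if df.empty:
        return {}
    # collapse HSPs: best bitscore (then evalue) per (query, subject)
    df = (
        df.sort_values(["bitscore", "evalue"], ascending=[False, True])
        .drop_duplicates(["qseqid", "sseqid"], keep="first")
    )
    df = df.sort_values(
        ["qseqid", "bitscore", "evalue", "sseqid"],
        ascending=[True, False, True, True],
    ).drop_duplicates("qseqid", keep="first")
    return dict(zip(df["qseqid"], df["sseqid"]))


def reciprocal_best_hits(
    forward: Mapping[str, str], reverse: Mapping[str, str]
) -> set[tuple[str, str]]:
    """Pairs (a, b) with forward[a] == b and reverse[b] == a."""
    return {(a, b) for a, b in forward.items() if reverse.get(b) == a}


def lift_to_genes(
    pairs: Iterable[tuple[str, str]],
    transcript_to_gene_a: Mapping[str, str] | None = None,
    transcript_to_gene_b: Mapping[str, str] | None = None,
) -> set[tuple[str, str]]:
    """Map transcript-level RBBH pairs to gene level.

    Identifiers absent from a mapping pass through unchanged, so
    protein tables already keyed by gene need no mapping.
    """
    ta = transcript_to_gene_a or {}
    tb = transcript_to_gene_b or {}
    return {(ta.get(a, a), tb.get(b, b)) for a, b in pairs}


def intersect_evidence(
    dna_pairs: set[tuple[str, str]],
    protein_pairs: set[tuple[str, str]],
    species_a: str = "",
    species_b: str = "",
) -> set[OrthologPair]:
    """Keep only gene pairs supported by BOTH DNA and protein RBBH.

    Disagreeing predictions are dismissed entirely, at the cost of losing
    potentially valid orthologs — the conservative choice that makes the
    surviving pairs trustworthy enough for annotation transfer.
    """
    both = dna_pairs & protein_pairs
    return {
        OrthologPair(species_a, a, species_b, b, evidence=frozenset({"dna", "protein"}))
        for a, b in both
    }


def call_pairs(
    species_a: str,
    species_b: str,
    dna_fwd: pd.DataFrame,
    dna_rev: pd.DataFrame,
    prot_fwd: pd.DataFrame,
    prot_rev: pd.DataFrame,
    cfg: OrthologyConfig | None = None,
    transcript_to_gene: Mapping[str, str] | None = None,
) -> set[OrthologPair]:
    """Full pipeline for one species pair: RBBH per evidence type, DNA
    transcript->gene lifting, then intersection.

    ``transcript_to_gene`` maps transcript ids of either species to gene
    ids; it is applied to the DNA pair set only.
    """
    cfg = cfg or OrthologyConfig()
    dna_fwd = _drop_within_species(dna_fwd, species_a, species_b)
    dna = reciprocal_best_hits(best_hits(dna_fwd, cfg), best_hits(dna_rev, cfg))
    dna = lift_to_genes(dna, transcript_to_gene, transcript_to_gene)
    prot = reciprocal_best_hits(best_hits(prot_fwd, cfg), best_hits(prot_rev, cfg))
    return intersect_evidence(dna, prot, species_a, species_b)


def _drop_within_species(hits: pd.DataFrame, species_a: str, species_b: str) -> pd.DataFrame:
    """Warn about and drop q==s self-hit rows if a file contains them."""
    if hits.empty:
        return hits
    selfhits = hits["qseqid"] == hits["sseqid"]
    if selfhits.any():
        warnings.warn(
            f"{species_a}->{species_b}: ignoring {int(selfhits.sum())} self-hit rows",
            stacklevel=2,
        )
        hits = hits[~selfhits]
    return hits
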