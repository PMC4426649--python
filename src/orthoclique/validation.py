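"""Clique validation by GO-term set overlap against a random-clique null.

A clique of putative functional equivalents should share annotation: the
overlap statistic is the number of GO terms common to every member divided
by the size of the smallest member's term set, times 100.  Well-predicted
cliques concentrate near 100%; cliques assembled from genes drawn uniformly
at random from each species' gene pool concentrate at 0%, which is the
contrast the null generator provides.

Direct annotations only — term sets are used exactly as assigned, with no
ancestor propagation up the DAG (propagation would inflate every overlap).
A member with an empty term set makes the ratio 0/0; by convention the
overlap is then 0, since an unannotated member contributes no supporting
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cliques import OrthologClique

__all__ = [
    "AnnotationMap",
    "OverlapResult",
    "go_set_overlap",
    "random_cliques",
    "overlap_histogram",
    "DEFAULT_BINS",
]

#: gene annotations per species: species -> gene -> set of GO ids
AnnotationMap = Mapping[str, Mapping[str, set]]

#: ten right-closed intervals of width 10 covering [0, 100]
DEFAULT_BINS: tuple[tuple[float, float], ...] = tuple(
    (float(lo), float(lo + 10)) for lo in range(0, 100, 10)
)


@dataclass(frozen=True)
class OverlapResult:
    clique_id: str
    ocl: int
    overlap_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_pct <= 100.0:
            raise ValueError(f"overlap_pct out of [0, 100]: {self.overlap_pct}")


def terms_of(ann: AnnotationMap, species: str, gene: str) -> set:
    """Direct GO term set of a gene; genes absent from the map have none."""
    return set(ann.get(species, {}).get(gene, set()))


def go_set_overlap(clique: OrthologClique, ann: AnnotationMap) -> OverlapResult:
    """Percentage of the smallest member term set shared by all members."""
    if clique.ocl == 0:
        raise ValueError("empty clique")
    sets = [terms_of(ann, sp, g) for sp, g in clique.genes]
    smallest = min(len(s) for s in sets)
    if smallest == 0:
        pct = 0.0
    else:
        common = set.intersection(*sets)
        pct = 100.0 * len(common) / smallest
    return OverlapResult(clique.clique_id, clique.ocl, pct)


def random_cliques(
    species_pools: Mapping[str, Sequence[str]],
    size_counts: Mapping[int, int],
    seed: int,
) -> list[OrthologClique]:
    """Pseudo-cliques for the null: for each requested size k, sample a
    uniform k-subset of species and one gene uniformly from each species'
    complete pool.  Reproducible under ``seed``."""
    rng = np.random.default_rng(seed)
    nonempty = sorted(sp for sp, pool in species_pools.items() if len(pool) > 0)
    out: list[OrthologClique] = []
    counter = 0
    for k in sorted(size_counts):
        n = size_counts[k]
        if k > len(nonempty):
            raise ValueError(
                f"requested clique size {k} exceeds the {len(nonempty)} species "
                "with nonempty pools"
            )
        for _ in range(n):
            chosen = rng.choice(len(nonempty), size=k, replace=False)
            genes = []
            for idx in sorted(chosen):
                sp = nonempty[idx]
                pool = species_pools[sp]
                genes.append((sp, pool[int(rng.integers(len(pool)))]))
            counter += 1
            out.append(OrthologClique(genes=tuple(genes), clique_id=f"R{counter:06d}"))
    return out


def overlap_histogram(
    results: Iterable[OverlapResult],
    bins: Sequence[tuple[float, float]] = DEFAULT_BINS,
) -> pd.DataFrame:
    """Counts of cliques per OCL (rows) and overlap interval (columns).

    ``bins`` must partition [0, 100] into non-overlapping intervals;
    intervals are right-closed and the first is closed on the left, so 0
    falls in the lowest bin.
    """
    bins = sorted(bins)
    for (lo1, hi1), (lo2, _) in zip(bins, bins[1:]):
        if hi1 > lo2:
            raise ValueError(f"overlapping bins: ({lo1}, {hi1}) and ({lo2}, ...)")
        if hi1 < lo2:
            raise ValueError(f"gap between bins at {hi1}..{lo2}")
    if not bins or bins[0][0] != 0.0 or bins[-1][1] != 100.0:
        raise ValueError("bins must cover [0, 100]")

    edges = [b[0] for b in bins] + [100.0]
    labels = [f"({lo:g},{hi:g}]" for lo, hi in bins]
    labels[0] = f"[{bins[0][0]:g},{bins[0][1]:g}]"
    results = list(results)
    ocls = sorted({r.ocl for r in results})
    table = pd.DataFrame(0, index=pd.Index(ocls, name="ocl"), columns=labels)
    if results:
        vals = np.array([r.overlap_pct for r in results])
        # right-closed: index of the first edge >= value, shifted for the
        # closed-left first bin
        which = np.searchsorted(edges, vals, side="left")
        which = np.clip(which - 1, 0, len(bins) - 1)
        for r, b in zip(results, which):
            table.loc[r.ocl, labels[int(b)]] += 1
    return table
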