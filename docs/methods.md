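# Methods

## Scope and assumptions

`orthoclique` implements clique-based GO annotation transfer for a target
species given (a) pairwise cross-species similarity tables in BLAST
tabular format, separately for DNA coding sequences and proteins, (b)
per-species direct gene→GO annotation tables, (c) a go-basic-style OBO 1.2
ontology, and (d) a phylogenetic group-score configuration. Sequence
search itself is out of scope: the package consumes hit tables, it never
runs BLAST. Paralogy is deliberately excluded — only 1-to-1 reciprocal
best hits supported by both sequence types enter the graph, trading recall
for precision, which is the right trade when transferred annotations seed
downstream curation.

## Orthology calling

Per directed species pair, rows with e-value above the cutoff are dropped
(the cutoff is **inclusive**, default 1e-5: a hit at exactly 1e-5
survives). Multiple HSP rows for one (query, subject) pair collapse to the
best bitscore before best-hit selection. The best hit per query is chosen
by highest bitscore, then lowest e-value, then lexicographically smallest
subject id — the tie-break cascade is a package convention chosen for
determinism, since biological inputs rarely tie exactly. Reciprocity of
the two directions gives candidate pairs; DNA pairs called on transcripts
are lifted to genes through an explicit transcript→gene table (each gene
being represented by its longest transcript, ties to the smallest id);
the DNA and protein pair sets are then intersected. Within-species hit
rows, if a file contains them, are ignored with a warning rather than an
error. Raising the e-value cutoff can only add pairs (filter
monotonicity), which the tests assert.

## Clique enumeration and OCL

The ortholog graph is unweighted (every accepted pair counts 1) and
multipartite, so a clique holds at most one gene per species. The default
mode enumerates **maximal** cliques of size ≥ 3 via networkx's
Bron–Kerbosch-with-pivoting; an all-cliques mode
(`enumerate_cliques(..., maximal_only=False)`) reports every clique of
size ≥ 3. The historical clique solver this replaces was run with flags
whose all-vs-maximal semantics are ambiguous; maximal is the default here
because non-maximal cliques add no annotation information (every term
reachable through a sub-clique is reachable through its maximal superset
at an equal or higher score) while inflating output combinatorially.
Per-gene OCL — the maximum clique size over memberships — coincides
between the modes. Exactness is enforced by an independent exhaustive
subset-enumeration oracle over 100 random seeded multipartite graphs of
up to 15 nodes. A DIMACS edge-format writer is kept for interoperability
with external clique solvers.

## Overlap validation

GO set overlap of a clique is |intersection of member term sets| /
min member set size × 100, computed on **direct** annotations only — no
DAG up-propagation, which would inflate every overlap. If any member is
unannotated the minimum is zero and the overlap is defined as 0: an
unannotated member provides no supporting evidence, and this convention
keeps the random-clique null (dominated by unannotated and disjoint
members) at 0%. The null generator draws, per requested clique size k, a
uniform k-subset of species and one gene uniformly from each species'
complete pool; how species subsets "should" be drawn for k < N is not
specified by the transfer model, and uniform sampling is the documented
stand-in. Histograms use ten width-10 right-closed bins over [0, 100] by
default (the first bin closed on both ends), configurable.

## Weighted transfer and refinement

GO_score(go, c) = Σ δ(go, i)/G(i) over clique members, with δ computed on
direct annotations (consistent with validation). Default group scores:
wheat and *T. urartu* 1; *Ae. tauschii* and barley 2; *B. distachyon* 3;
rice 4; sorghum and maize 5; *A. thaliana* and *B. rapa* 6. The threshold
G_T = 0.5 is **inclusive** by default: the 0.5 value is motivated as the
contribution of a single group-2 annotation being "sufficiently
significant", which only works if 0.5 itself passes;
`EnrichmentConfig(threshold_inclusive=False)` restores strict >.

"More specific" is operationalized by the ancestor relation, not numeric
depth: a candidate is accepted iff it is not among the gene's original
terms and not a proper ancestor of any of them. This is unambiguous where
numeric depth is not (a DAG term has minimum and maximum root paths).
Numeric path length — the **shortest** parent path to the namespace root —
is computed for reporting only. Namespace roots are place-holders:
accepted only when the gene has no original term in that namespace.
Obsolete candidates are flagged (`flagged-obsolete`), and with
`resolve_obsolete=True` their `replaced_by` term re-enters the candidate
pool at the same score — where it is then rejected as a duplicate if the
gene already carries it, reproducing the "no real enrichment" outcome of
an obsolete transfer whose replacement already exists.

When a gene belongs to several cliques, per-(gene, term) records keep the
maximum score across cliques: the strongest available evidence, and a
deterministic rule. Scores are written to 2 decimals in output TSVs;
every comparison happens at full precision. The summary reports the
percentage increase as accepted **assignments** over original assignment
counts (not genes), and counts root-term acceptances both per assignment
and per gene, since either tally convention is defensible.

## Synthetic world

The generator's defaults state one desk-scale world: ten species with the
default group scores; one planted clique at every size 3–10, sized k
cliques using the first k species in proximity order; 20 background genes
per species; a three-namespace ontology of depth 3 and branching 3 with
~10% extra diamond edges; background annotation density 0.3 (a background
gene has a 30% chance of carrying 1–3 random terms); decoy hit rate 0.1.
Background count, density and decoy rate are package choices (nothing in
the transfer model fixes them) picked once to give non-trivial noise at
sub-second runtimes.

Planted clique members are unique mutual best hits in both tables with
e-values log-uniform in [1e-50, 1e-10]; decoys draw e-values log-uniform
in [1e-4, 1], strictly above the cutoff, so recovery of exactly the
planted pairs is guaranteed by construction — a green end-to-end test
establishes that the pipeline implements its own contract, not that RBBH
is biologically accurate. Each clique carries planted **transferable
terms**: distinct leaf terms on every non-target member, absent from the
target, whose expected accepted score is the clique's bound minus the
target's own 1/1 contribution. Annotated-mode targets carry the parent of
the first planted term plus one common leaf shared by all members (so
real cliques overlap at 100% and refinement's deeper-than-parent path is
exercised); the default world leaves the size-6 clique's target gene
unannotated, exercising the no-previous-annotation path. Every generator
is a pure function of (spec, seed); two transcripts per gene exercise
longest-transcript selection and gene lifting.

What the synthetic world does **not** emulate: realistic sequence
evolution (no sequences exist at all), gene loss/duplication patterns,
correlated annotation between related background genes, evidence codes,
and annotation bias toward model species. Green tests on this world
establish algorithmic correctness and determinism, not transfer accuracy
on real genomes.

## Numerical and degenerate-input choices

Ties everywhere break lexicographically after the scientific criteria.
Output row order is fixed, so reruns are byte-identical. An empty graph
enumerates no cliques; an empty DIMACS export is refused. OBO parsing
validates acyclicity (naming a cycle member on failure), dangling parent
ids, one root per namespace present, and namespace closure under parent
links; obsolete terms are retained but excluded from the live DAG and
from ancestor/path queries. `part_of` is treated identically to `is_a`;
regulates-type relations are ignored. Floating-point scores are exact
sums of small rationals; tests compare at 1e-6 or tighter.

## Known limitations

- Only 1-to-1 orthology: co-orthology from lineage-specific duplication
  is invisible, and a single wrong best hit removes a gene from a clique.
- Direct-annotation δ makes the score sensitive to annotation granularity
  differences between species (a term annotated one level apart in two
  species contributes nothing to overlap or score).
- The group-score configuration encodes a fixed species tree; uncertainty
  in the phylogeny is not propagated.
- Maximal-clique enumeration is exponential in the worst case; on real
  RBBH-intersection graphs (sparse, near-disjoint cliques) it is fast,
  but adversarial dense graphs are not handled specially.
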