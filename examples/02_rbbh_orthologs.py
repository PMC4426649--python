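"""Reciprocal-best-hit ortholog calling with DNA/protein intersection.

Builds tiny BLAST-style hit tables for one species pair in which gene pair
(TAE_G1, TUR_G1) is a mutual best hit for both sequence types, while
(TAE_G2, TUR_G2) agrees only at the protein level — so only the first pair
survives the evidence intersection.
"""

import pandas as pd

from orthoclique.orthology import BLAST6_COLUMNS, call_pairs


def table(*rows):
    return pd.DataFrame(
        [[q, s, 95.0, 400, 5, 1, 1, 400, 1, 400, e, b] for q, s, e, b in rows],
        columns=BLAST6_COLUMNS,
    )


# DNA hits are on transcripts; .T1 suffixes are lifted to genes afterwards
dna_fwd = table(("TAE_G1.T1", "TUR_G1.T1", 1e-40, 800),
                ("TAE_G2.T1", "TUR_G9.T1", 1e-30, 500))   # disagrees with protein
dna_rev = table(("TUR_G1.T1", "TAE_G1.T1", 1e-40, 800),
                ("TUR_G9.T1", "TAE_G2.T1", 1e-30, 500))
prot_fwd = table(("TAE_G1", "TUR_G1", 1e-45, 900),
                 ("TAE_G2", "TUR_G2", 1e-35, 600))
prot_rev = table(("TUR_G1", "TAE_G1", 1e-45, 900),
                 ("TUR_G2", "TAE_G2", 1e-35, 600))

t2g = {f"{g}.T1": g for g in ["TAE_G1", "TAE_G2", "TUR_G1", "TUR_G2", "TUR_G9"]}
pairs = call_pairs("TAE", "TUR", dna_fwd, dna_rev, prot_fwd, prot_rev,
                   transcript_to_gene=t2g)

print(f"accepted 1-to-1 ortholog pairs: {len(pairs)}")
for p in sorted(pairs):
    print(f"  {p.gene_a} <-> {p.gene_b}  evidence={sorted(p.evidence)}")
print("TAE_G2 was dismissed: its DNA and protein best hits disagreed, and")
print("only pairs supported by both sequence types are trusted for transfer.")
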