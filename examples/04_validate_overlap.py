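"""Clique validation: GO-set overlap of real vs randomly assembled cliques.

Simulates the default ten-plant world, computes the overlap statistic
(|shared terms| / smallest member set * 100) for every planted clique, then
builds an equal number of random pseudo-cliques from the full gene pools
and contrasts the two distributions.
"""

import collections

from orthoclique.simulate import ScenarioSpec, simulate_scenario
from orthoclique.validation import go_set_overlap, overlap_histogram, random_cliques

bundle = simulate_scenario(ScenarioSpec(seed=17))

planted = [go_set_overlap(c, bundle.annotations) for c in bundle.truth_cliques]
print("planted cliques (OCL: overlap%):",
      {r.ocl: round(r.overlap_pct) for r in planted})

pools = {sp: sorted(bundle.annotations.get(sp, {})) for sp in bundle.spec.species}
sizes = collections.Counter(c.ocl for c in bundle.truth_cliques)
rand = random_cliques(pools, dict(sizes), seed=18)
rand_overlaps = [go_set_overlap(c, bundle.annotations) for c in rand]
zero = sum(r.overlap_pct == 0 for r in rand_overlaps)
print(f"random cliques at 0% overlap: {zero}/{len(rand_overlaps)}")

table = overlap_histogram(planted + rand_overlaps)
print("\ncounts per OCL and overlap interval:")
print(table.to_string())
print("\nreal cliques sit in the top interval (except the one whose wheat")
print("member is unannotated), random ones at zero — the separation that")
print("justifies treating high-overlap cliques as validated.")
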