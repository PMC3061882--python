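"""Parsimony optimization of body size on competing topologies.

Classifies the twelve allosauroid terminals as larger- or smaller-bodied
(body > 10 m, skull > 1 m, femur > 1 m; every available measurement must
exceed its threshold) and counts the state changes each placement of
Acrocanthosaurus implies on the taxa shared between the two analyses.
"""

from maxpars import classify_body_size, optimize_trait, prune
from maxpars.datasets import (
    SHARED_TAXA_8,
    allosauroid_tree,
    alternative_placement_tree,
    body_size_measurements,
)

sizes = classify_body_size(body_size_measurements())
for taxon, grade in sizes.items():
    print(f"{taxon:22s} {grade}")

reference = prune(allosauroid_tree(), SHARED_TAXA_8)
alternative = alternative_placement_tree()

ref = optimize_trait(reference, sizes)
alt = optimize_trait(alternative, sizes)
print(f"\nreference placement:  {ref.changes} change(s), "
      f"gains/losses {ref.gains_losses}")
print(f"alternative placement: {alt.changes} change(s), "
      f"gains/losses {alt.gains_losses}")
# Nesting Acrocanthosaurus among the carcharodontosaurids needs a single
# acquisition of large body size; grouping it with Allosaurus/Neovenator
# needs two changes (two gains, or one gain plus a reversal).
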