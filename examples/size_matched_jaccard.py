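"""Size-matching removes map-size confounding from Jaccard comparisons.

Builds two maps of very different sizes where the big map contains the
small one; raw Jaccard is dominated by the size difference, normalized
Jaccard saturates, and truncating both maps to the same bp budget of
top-scoring regions gives a comparison on equal footing.
"""

import numpy as np

from intromaps import jaccard, normalized_jaccard, size_match_top_scoring
from intromaps.synthetic import EnsembleSpec, generate_ensemble

# one small, one large map over the same core
spec = EnsembleSpec(n_maps=2, core_fraction=0.2, private_fraction=(0.02, 0.3), seed=5)
(small, large), _ = generate_ensemble(spec)

print(f"{small.name}: {small.total_bp:,} bp; {large.name}: {large.total_bp:,} bp")
print(f"raw Jaccard        = {jaccard(small, large):.3f}  (depressed by size gap)")
print(f"normalized Jaccard = {normalized_jaccard(small, large):.3f}  (smaller-set denominator)")

budget = min(small.total_bp, large.total_bp)
matched = [size_match_top_scoring(m, budget) for m in (small, large)]
print(f"\nafter truncating both maps to their top-scoring {budget:,} bp:")
print(f"raw Jaccard        = {jaccard(*matched):.3f}")
print("Core regions carry higher confidence scores, so the trimmed large map")
print("preferentially retains shared core bp and agreement rises; merged")
print("core+private regions inherit the core's score, so some private bp")
print("still ride along - exactly the behaviour the budget-based truncation has")
print("on real maps, where merged regions mix confident and marginal calls.")
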