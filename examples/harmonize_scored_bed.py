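"""Harmonizing a heterogeneous scored callset into a canonical map.

Writes a small scored BED with overlapping fragments (as published
callsets often have, one row per population grouping), reads it back with
a score threshold, and shows the merge-with-max-score behaviour and the
variant-position convention.
"""

import tempfile
from pathlib import Path

from intromaps import GenomeDefinition, ScoredMap, variants_to_map

genome = GenomeDefinition([("1", 10_000)])

raw = "\n".join(
    [
        "1\t100\t400\t3.2",   # EUR grouping
        "1\t300\t700\t5.8",   # EAS grouping, overlaps -> merged, score 5.8 kept
        "1\t900\t1200\t0.4",  # below threshold -> dropped
        "1\t2000\t2500\t2.1",
    ]
) + "\n"

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "callset.bed"
    path.write_text(raw)
    m = ScoredMap.read_bed(path, genome, name="demo", score_col=3, min_score=1.0)

print(f"map {m.name!r}: {len(m.regions)} regions, {m.total_bp} bp after harmonization")
for chrom, start, end, score in m.records():
    print(f"  {chrom}:{start}-{end}  score={score}")
print("Overlapping fragments merged; the highest constituent score is retained.")

variants = variants_to_map([("1", 100), ("1", 100), ("1", 250)], "snps", genome)
print(f"\nvariant map: {variants.total_bp} bp from 3 positions (duplicates collapse);")
print(f"1-based position 100 becomes the half-open interval {variants.regions.to_tuples()[0]}")
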