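"""Aggregate a jury panel into one performance score.

Seven judges rate a performance on a 1-100 scale; the highest and lowest
scores are removed (one of each, even under ties) and the remaining five
are averaged.
"""

from izof import aggregate_judges

panel = (85, 88, 90, 92, 95, 80, 99)
print(f"panel:  {panel}")
print(f"score:  {aggregate_judges(panel):.1f}")
# drops 99 and 80, averages (85, 88, 90, 92, 95) -> 90.0

tied = (90, 90, 90, 90, 90, 100, 100)
print(f"tied panel {tied} -> {aggregate_judges(tied):.1f}")
# exactly one 100 and one 90 are trimmed, so the mean is 92.0
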