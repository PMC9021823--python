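"""Estimate one pianist's optimal anxiety zone from recalled performances.

The zone for a subscale is M ± ½SD: M is the mean intensity over the
occasions tied for the personal-best score, SD the population standard
deviation over all recalled occasions. The inputs below reproduce a
published high-anxiety case whose cognitive-anxiety zone is 24.0-28.0.
"""

from izof import (
    Phase,
    PerformanceOccasion,
    SubscaleTriplet,
    classify,
    estimate_zone,
    zone_distance,
)

scores = (95.0, 90.0, 95.0, 90.0)
ca_values = (22, 30, 30, 22)
occasions = [
    PerformanceOccasion(
        participant_id="14",
        occasion_id=f"R{i + 1}",
        phase=Phase.RECALLED,
        triplet=SubscaleTriplet(ca=ca, sa=20, sc=20),
        score=s,
    )
    for i, (s, ca) in enumerate(zip(scores, ca_values))
]

zone = estimate_zone(occasions).ca
print(f"CA zone: [{zone.lower:.1f}, {zone.upper:.1f}]  "
      f"(center {zone.center:.1f}, half-width {zone.half_width:.1f})")
# the two best occasions (score 95) carry CA 22 and 30 -> M = 26.0;
# population SD of (22, 30, 30, 22) is 4.0 -> zone [24.0, 28.0]

for intensity in (19, 26, 30):
    print(f"CA {intensity}: {classify(intensity, zone).value:>5}, "
          f"distance {zone_distance(intensity, zone):.1f}")
# 19 is below the band (distance 5.0), 26 inside (0), 30 above (2.0)
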