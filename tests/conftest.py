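"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately re-derive each statistic from first
principles (explicit loops, explicit formulas) and never call into the
package's own implementations, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import math
import statistics
from typing import Sequence

import pytest
from hypothesis import HealthCheck, settings

from izof import Cohort, PerformanceOccasion, Phase, SubscaleTriplet

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_occ(
    pid: str,
    occ: str,
    score: float,
    ca: int = 20,
    sa: int = 20,
    sc: int = 20,
    phase: Phase = Phase.RECALLED,
    judges=None,
) -> PerformanceOccasion:
    return PerformanceOccasion(
        participant_id=pid,
        occasion_id=occ,
        phase=phase,
        triplet=SubscaleTriplet(ca=ca, sa=sa, sc=sc),
        score=score,
        judge_scores=tuple(judges) if judges is not None else None,
    )


@pytest.fixture
def item_key() -> dict[int, str]:
    """A synthetic 27-item key: items 1-9 -> ca, 10-18 -> sa, 19-27 -> sc."""
    key: dict[int, str] = {}
    for i in range(1, 28):
        key[i] = "ca" if i <= 9 else "sa" if i <= 18 else "sc"
    return key


@pytest.fixture
def participant_14() -> list[PerformanceOccasion]:
    """Recalled occasions consistent with the printed CA zone 24.0-28.0:
    best occasions (scores 95) carry CA 22 and 30 -> M 26, pop SD 4."""
    scores = (95.0, 90.0, 95.0, 90.0)
    cas = (22, 30, 30, 22)
    return [
        make_occ("14", f"R{i+1}", s, ca=c)
        for i, (s, c) in enumerate(zip(scores, cas))
    ]


@pytest.fixture
def participant_29() -> list[PerformanceOccasion]:
    """Recalled occasions consistent with the printed CA zone 18.0-20.0."""
    scores = (93.0, 93.0, 90.0, 90.0)
    cas = (17, 21, 17, 21)
    return [
        make_occ("29", f"R{i+1}", s, ca=c)
        for i, (s, c) in enumerate(zip(scores, cas))
    ]


# ----------------------------------------------------------------------
# independent oracles


def oracle_trimmed_mean(panel: Sequence[float]) -> float:
    """Sort, drop one from each end, plain average."""
    s = sorted(panel)
    kept = s[1:-1]
    return sum(kept) / len(kept)


def oracle_zone(values: Sequence[float], scores: Sequence[float]) -> tuple[float, float]:
    """(M, half_width): explicit mean over argmax-score occasions and
    explicit population SD over all occasions."""
    best = max(scores)
    chosen = [v for v, s in zip(values, scores) if s == best]
    m = sum(chosen) / len(chosen)
    xbar = sum(values) / len(values)
    sd = math.sqrt(sum((v - xbar) ** 2 for v in values) / len(values))
    return m, sd / 2.0


def oracle_correct_classification(
    values: Sequence[float],
    scores: Sequence[float],
    lower: float,
    upper: float,
    threshold: float,
) -> float:
    hits = 0
    for v, s in zip(values, scores):
        in_zone = lower <= v <= upper
        outstanding = s >= threshold
        if in_zone == outstanding:
            hits += 1
    return 100.0 * hits / len(values)


def oracle_midranks(x: Sequence[float]) -> list[float]:
    """Average rank of ties, 1-based, by explicit position averaging."""
    n = len(x)
    ranks = [0.0] * n
    for i, xi in enumerate(x):
        less = sum(1 for xj in x if xj < xi)
        equal = sum(1 for xj in x if xj == xi)
        # positions less+1 .. less+equal share the average rank
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def oracle_spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation of the midranks, from the textbook formula."""
    rx = oracle_midranks(x)
    ry = oracle_midranks(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den
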