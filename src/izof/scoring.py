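"""Instrument scoring: CSAI-2 item totals and judge-panel aggregation.

Two conversions sit in front of every analysis stage:

* ``score_items`` turns 27 item ratings (1-4 Likert) into the three
  subscale totals, given a user-supplied item-to-subscale key (the
  published CSAI-2 key is not bundled; 9 items map to each subscale).
* ``aggregate_judges`` collapses a panel of judge scores (1-100) into one
  performance score by removing exactly one occurrence of the highest and
  one of the lowest score and averaging the remainder — the standard
  trimmed jury rule (7 judges -> mean of 5).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_model import SUBSCALES, SubscaleTriplet
from .errors import ConfigurationError, InsufficientPanelError, ValidationError

N_ITEMS = 27
ITEMS_PER_SUBSCALE = 9
ITEM_MIN = 1
ITEM_MAX = 4


def validate_item_key(key: Mapping[int, str]) -> dict[int, str]:
    """Check an item->subscale key: 27 items, 9 per subscale, 1-based."""
    normalized: dict[int, str] = {}
    for raw_item, subscale in key.items():
        item = int(raw_item)
        if not 1 <= item <= N_ITEMS:
            raise ConfigurationError(
                f"item key: item index {item} outside 1..{N_ITEMS}"
            )
        if subscale not in SUBSCALES:
            raise ConfigurationError(
                f"item key: item {item} maps to unknown subscale {subscale!r}"
            )
        normalized[item] = subscale
    if len(normalized) != N_ITEMS:
        raise ConfigurationError(
            f"item key must cover all {N_ITEMS} items, got {len(normalized)}"
        )
    for subscale in SUBSCALES:
        n = sum(1 for s in normalized.values() if s == subscale)
        if n != ITEMS_PER_SUBSCALE:
            raise ConfigurationError(
                f"item key assigns {n} items to {subscale!r}; "
                f"expected {ITEMS_PER_SUBSCALE}"
            )
    return normalized


def score_items(items: Sequence[int], key: Mapping[int, str]) -> SubscaleTriplet:
    """Sum 27 item ratings into the (ca, sa, sc) subscale totals.

    Each subscale total is the plain sum of its nine 1-4 ratings, so
    totals land in [9, 36] by construction.
    """
    key = validate_item_key(key)
    if len(items) != N_ITEMS:
        raise ValidationError(
            f"expected {N_ITEMS} item responses, got {len(items)}"
        )
    totals = {s: 0 for s in SUBSCALES}
    for idx, rating in enumerate(items, start=1):
        r = int(rating)
        if r != rating or not ITEM_MIN <= r <= ITEM_MAX:
            raise ValidationError(
                f"item {idx}: rating {rating!r} outside "
                f"[{ITEM_MIN}, {ITEM_MAX}]"
            )
        totals[key[idx]] += r
    return SubscaleTriplet(**totals)


def aggregate_judges(panel: Iterable[float]) -> float:
    """Trimmed jury aggregate: drop one max and one min, average the rest.

    Ties are trimmed one-per-end (sort, drop the first and last element),
    so a panel of N yields the mean of N-2 retained scores. Requires
    N >= 3 so at least one score survives.
    """
    scores = np.asarray(list(panel), dtype=float)
    if scores.size < 3:
        raise InsufficientPanelError(
            f"judge panel needs at least 3 scores, got {scores.size}"
        )
    if np.any(np.isnan(scores)):
        raise ValidationError("judge panel contains missing scores")
    if np.any((scores < 1) | (scores > 100)):
        bad = scores[(scores < 1) | (scores > 100)][0]
        raise ValidationError(f"judge score {bad:g} outside [1, 100]")
    trimmed = np.sort(scores)[1:-1]
    return float(trimmed.mean())
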