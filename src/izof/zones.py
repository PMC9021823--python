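"""Individual zone of optimal functioning: estimation and geometry.

A participant's zone for one subscale is the band M ± ½SD, where M is the
mean subscale intensity over the occasion(s) attaining the participant's
personal-best performance score and SD is the standard deviation of that
subscale across *all* recalled occasions. New intensities are classified
as below / in / above the band (bounds inclusive), and the zone distance
is the distance to the closest band border, zero inside.

The "personal best" rule is configurable because a participant can have
several occasions tied at the maximum score:

* ``"all-tied-best"`` (default) — every occasion tied for the maximum
  score contributes to M;
* ``"top1"`` — only the first max-score occasion in input order;
* ``"topk:K"`` — the K highest-scoring occasions (ties broken by order);
* ``"quantile:Q"`` — all occasions with score at or above the Q-quantile
  of the participant's scores (Q in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import SUBSCALES, PerformanceOccasion, Phase
from .errors import ConfigurationError, EstimabilityError

__all__ = [
    "Zone",
    "ZoneSet",
    "Membership",
    "estimate_zone",
    "estimate_zones",
    "classify",
    "zone_distance",
    "zones_frame",
]


@dataclass(frozen=True)
class Zone:
    """Optimal band for one subscale: [center - half_width, center + half_width]."""

    center: float
    half_width: float

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ConfigurationError(
                f"zone half_width must be >= 0, got {self.half_width}"
            )

    @property
    def lower(self) -> float:
        return self.center - self.half_width

    @property
    def upper(self) -> float:
        return self.center + self.half_width

    def rounded(self, ndigits: int = 1) -> "Zone":
        """Zone with bounds at reporting precision (captions print 1 dp)."""
        return Zone(round(self.center, ndigits), round(self.half_width, ndigits))


@dataclass(frozen=True)
class ZoneSet:
    """The three per-subscale zones of one participant."""

    participant_id: str
    ca: Zone
    sa: Zone
    sc: Zone
    n_occasions_used: int

    def __post_init__(self) -> None:
        if self.n_occasions_used < 2:
            raise EstimabilityError(
                f"participant {self.participant_id!r}: a zone set needs "
                f">= 2 occasions, got {self.n_occasions_used}"
            )

    def zone(self, subscale: str) -> Zone:
        if subscale not in SUBSCALES:
            raise KeyError(subscale)
        return getattr(self, subscale)


class Membership(str, Enum):
    BELOW = "below"
    IN = "in"
    ABOVE = "above"


def _best_indices(scores: np.ndarray, best_rule: str) -> np.ndarray:
    """Row indices of the occasions whose intensities define the zone center."""
    if best_rule == "all-tied-best":
        return np.flatnonzero(scores == scores.max())
    if best_rule == "top1":
        return np.array([int(np.argmax(scores))])
    if best_rule.startswith("topk:"):
        try:
            k = int(best_rule.split(":", 1)[1])
        except ValueError:
            raise ConfigurationError(f"malformed best_rule {best_rule!r}")
        if not 1 <= k <= scores.size:
            raise ConfigurationError(
                f"best_rule {best_rule!r}: k must be in 1..{scores.size}"
            )
        # stable sort keeps input order among ties
        order = np.argsort(-scores, kind="stable")
        return np.sort(order[:k])
    if best_rule.startswith("quantile:"):
        try:
            q = float(best_rule.split(":", 1)[1])
        except ValueError:
            raise ConfigurationError(f"malformed best_rule {best_rule!r}")
        if not 0.0 <= q <= 1.0:
            raise ConfigurationError(
                f"best_rule {best_rule!r}: quantile must be in [0, 1]"
            )
        cutoff = np.quantile(scores, q)
        return np.flatnonzero(scores >= cutoff)
    raise ConfigurationError(f"unknown best_rule {best_rule!r}")


def estimate_zone(
    recalled: Sequence[PerformanceOccasion],
    best_rule: str = "all-tied-best",
    sd_convention: str = "population",
) -> ZoneSet:
    """Estimate one participant's zone set from recalled occasions.

    Per subscale: M = mean intensity over the personal-best occasion(s)
    (see ``best_rule``); SD = standard deviation of the intensity over all
    recalled occasions (population ÷n by default, ``sd_convention="sample"``
    for ÷(n−1)); zone = [M − SD/2, M + SD/2].
    """
    occs = list(recalled)
    if len(occs) < 2:
        raise EstimabilityError(
            f"zone estimation needs >= 2 recalled occasions, got {len(occs)}"
        )
    pids = {o.participant_id for o in occs}
    if len(pids) != 1:
        raise ConfigurationError(
            f"estimate_zone expects occasions of one participant, got {sorted(pids)}"
        )
    if sd_convention not in ("population", "sample"):
        raise ConfigurationError(
            f"sd_convention must be 'population' or 'sample', got {sd_convention!r}"
        )
    ddof = 0 if sd_convention == "population" else 1
    scores = np.array([o.score for o in occs], dtype=float)
    best = _best_indices(scores, best_rule)
    zones: dict[str, Zone] = {}
    for subscale in SUBSCALES:
        x = np.array([o.intensity(subscale) for o in occs], dtype=float)
        center = float(x[best].mean())
        half_width = float(x.std(ddof=ddof)) / 2.0
        zones[subscale] = Zone(center=center, half_width=half_width)
    return ZoneSet(
        participant_id=occs[0].participant_id,
        n_occasions_used=len(occs),
        **zones,
    )


def estimate_zones(
    cohort: Iterable[PerformanceOccasion],
    best_rule: str = "all-tied-best",
    sd_convention: str = "population",
) -> dict[str, ZoneSet]:
    """Zone sets for every participant with recalled occasions, keyed by id."""
    by_pid: dict[str, list[PerformanceOccasion]] = {}
    for occ in cohort:
        if occ.phase is Phase.RECALLED:
            by_pid.setdefault(occ.participant_id, []).append(occ)
    return {
        pid: estimate_zone(occs, best_rule=best_rule, sd_convention=sd_convention)
        for pid, occs in by_pid.items()
    }


def classify(intensity: float, zone: Zone) -> Membership:
    """Below / in / above the band; both bounds count as in."""
    if intensity < zone.lower:
        return Membership.BELOW
    if intensity > zone.upper:
        return Membership.ABOVE
    return Membership.IN


def zone_distance(intensity: float, zone: Zone) -> float:
    """Distance to the closest zone border; zero anywhere inside the band."""
    if zone.lower <= intensity <= zone.upper:
        return 0.0
    return float(min(abs(intensity - zone.lower), abs(intensity - zone.upper)))


def zones_frame(zonesets: Mapping[str, ZoneSet] | Iterable[ZoneSet]) -> pd.DataFrame:
    """Long-format zone table: one row per participant per subscale.

    Columns: participant_id, subscale, M, half_SD, lower, upper,
    n_occasions_used (full precision; round on display if needed).
    """
    if isinstance(zonesets, Mapping):
        zonesets = zonesets.values()
    rows = []
    for zs in zonesets:
        for subscale in SUBSCALES:
            z = zs.zone(subscale)
            rows.append(
                {
                    "participant_id": zs.participant_id,
                    "subscale": subscale,
                    "M": z.center,
                    "half_SD": z.half_width,
                    "lower": z.lower,
                    "upper": z.upper,
                    "n_occasions_used": zs.n_occasions_used,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "subscale",
            "M",
            "half_SD",
            "lower",
            "upper",
            "n_occasions_used",
        ],
    )
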