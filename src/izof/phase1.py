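"""Retrospective zone-validity metrics (the study's first phase).

Given per-participant zones estimated from recalled occasions, this module
answers: did the zones actually discriminate good performances?

* ``outstanding_threshold`` — the cohort-level bar for an "outstanding"
  performance: pooled mean + 1 SD of all recalled scores (88.98 + 3.47
  -> 92.45, reported as 92 after rounding to the nearest integer).
* ``d_statistic`` — per participant and subscale, the mean performance
  score on in-zone occasions minus the mean on out-of-zone occasions;
  undefined when either side is empty.
* ``correct_classification`` — the percentage of a participant's occasions
  that are concordant: outstanding and in-zone, or less-than-outstanding
  and out-of-zone.
* ``build_cohort_tables`` — the cohort descriptive table (best score S and
  zone parameters M, ½SD per subscale) and the classification report
  (mean/SD/min/max of the per-participant percentages per subscale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data_model import SUBSCALES, Cohort, PerformanceOccasion
from .errors import ConfigurationError, EstimabilityError
from .zones import Membership, Zone, ZoneSet, classify

__all__ = [
    "ThresholdResult",
    "DStatistic",
    "outstanding_threshold",
    "d_statistic",
    "correct_classification",
    "CohortTables",
    "build_cohort_tables",
]


@dataclass(frozen=True)
class ThresholdResult:
    """Outstanding-performance threshold: full precision and as reported."""

    value: float      # mean + 1 SD, unrounded
    reported: float   # after the reporting rounding rule
    mean: float
    sd: float
    n: int

    def __float__(self) -> float:
        return self.reported


def outstanding_threshold(
    scores: Sequence[float],
    sd_convention: str = "population",
    round_mode: str = "nearest",
) -> ThresholdResult:
    """Pooled mean + 1 SD of the recalled performance scores.

    ``round_mode`` controls the reported value: ``"nearest"`` (default,
    integer scores make x.45 report as x), ``"floor"``, or ``"none"``.
    Full precision is always retained in ``.value``.
    """
    x = np.asarray(list(scores), dtype=float)
    if x.size < 2:
        raise EstimabilityError(
            f"outstanding threshold needs >= 2 scores, got {x.size}"
        )
    if sd_convention not in ("population", "sample"):
        raise ConfigurationError(
            f"sd_convention must be 'population' or 'sample', got {sd_convention!r}"
        )
    mean = float(x.mean())
    sd = float(x.std(ddof=0 if sd_convention == "population" else 1))
    value = mean + sd
    if round_mode == "nearest":
        reported = float(round(value))
    elif round_mode == "floor":
        reported = float(math.floor(value))
    elif round_mode == "none":
        reported = value
    else:
        raise ConfigurationError(
            f"round_mode must be 'nearest', 'floor' or 'none', got {round_mode!r}"
        )
    return ThresholdResult(value=value, reported=reported, mean=mean, sd=sd, n=x.size)


@dataclass(frozen=True)
class DStatistic:
    """In-zone minus out-of-zone mean performance score for one
    participant and subscale; NaN (undefined) when one side is empty."""

    participant_id: str
    subscale: str
    d_value: float
    n_in: int
    n_out: int

    @property
    def defined(self) -> bool:
        return self.n_in >= 1 and self.n_out >= 1


def d_statistic(
    occasions: Sequence[PerformanceOccasion],
    zone: Zone,
    subscale: str,
) -> DStatistic:
    occs = list(occasions)
    in_scores = [
        o.score for o in occs if classify(o.intensity(subscale), zone) is Membership.IN
    ]
    out_scores = [
        o.score for o in occs if classify(o.intensity(subscale), zone) is not Membership.IN
    ]
    if in_scores and out_scores:
        d = float(np.mean(in_scores) - np.mean(out_scores))
    else:
        d = float("nan")
    return DStatistic(
        participant_id=occs[0].participant_id if occs else "",
        subscale=subscale,
        d_value=d,
        n_in=len(in_scores),
        n_out=len(out_scores),
    )


def correct_classification(
    occasions: Sequence[PerformanceOccasion],
    zone: Zone,
    subscale: str,
    threshold: float,
) -> float:
    """Percentage of occasions concordant with the zone.

    Concordant: score >= threshold and in-zone, or score < threshold and
    out-of-zone. The >= comparison means a score exactly at the bar counts
    as outstanding.
    """
    occs = list(occasions)
    if not occs:
        raise EstimabilityError("correct_classification needs >= 1 occasion")
    concordant = 0
    for o in occs:
        outstanding = o.score >= threshold
        in_zone = classify(o.intensity(subscale), zone) is Membership.IN
        if outstanding == in_zone:
            concordant += 1
    return 100.0 * concordant / len(occs)


@dataclass
class CohortTables:
    """Phase-1 report bundle."""

    descriptives: pd.DataFrame          # best score S + M, ½SD per subscale
    classification: pd.DataFrame        # per-subscale %-correct summary
    d_statistics: pd.DataFrame          # per participant × subscale D
    threshold: ThresholdResult


_STAT_ROWS = ("mean", "std", "median", "min", "max")


def _column_stats(values: np.ndarray, sd_undefined: float = 0.0) -> dict[str, float]:
    std = float(np.std(values, ddof=1)) if values.size > 1 else sd_undefined
    return {
        "mean": float(np.mean(values)),
        "std": std,
        "median": float(np.median(values)),
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


def build_cohort_tables(
    cohort: Cohort,
    zonesets: Mapping[str, ZoneSet],
    threshold: Optional[ThresholdResult] = None,
) -> CohortTables:
    """Assemble the phase-1 report from recalled occasions and zones.

    Descriptive statistics (mean, sample SD, median, min, max) are taken
    across participants: of the personal-best score S, and of each zone's
    center M and half-width ½SD. The classification report summarises the
    per-participant correct-classification percentages per subscale; the
    D table lists every participant × subscale difference, with undefined
    values left as NaN and excluded from cohort averages.
    """
    pids = [p for p in cohort.participants if p in zonesets]
    if not pids:
        raise EstimabilityError("no participants with estimated zones")
    pooled = [o.score for o in cohort.recalled()]
    if threshold is None:
        threshold = outstanding_threshold(pooled)

    best_scores = np.array(
        [max(o.score for o in cohort.recalled(pid)) for pid in pids]
    )
    desc: dict[str, dict[str, float]] = {"S": _column_stats(best_scores)}
    for subscale in SUBSCALES:
        centers = np.array([zonesets[pid].zone(subscale).center for pid in pids])
        halves = np.array([zonesets[pid].zone(subscale).half_width for pid in pids])
        desc[f"{subscale}_M"] = _column_stats(centers)
        desc[f"{subscale}_half_SD"] = _column_stats(halves)
    descriptives = pd.DataFrame(
        {col: [stats[row] for row in _STAT_ROWS] for col, stats in desc.items()},
        index=list(_STAT_ROWS),
    )
    descriptives.insert(0, "statistic", list(_STAT_ROWS))
    descriptives = descriptives.reset_index(drop=True)

    cls_rows = []
    for subscale in SUBSCALES:
        pct = np.array(
            [
                correct_classification(
                    cohort.recalled(pid),
                    zonesets[pid].zone(subscale),
                    subscale,
                    threshold.reported,
                )
                for pid in pids
            ]
        )
        stats = _column_stats(pct)
        cls_rows.append(
            {
                "subscale": subscale,
                "mean_pct": stats["mean"],
                "sd_pct": stats["std"],
                "min_pct": stats["min"],
                "max_pct": stats["max"],
            }
        )
    classification = pd.DataFrame(cls_rows)

    d_rows = []
    for pid in pids:
        occs = cohort.recalled(pid)
        for subscale in SUBSCALES:
            d = d_statistic(occs, zonesets[pid].zone(subscale), subscale)
            d_rows.append(
                {
                    "participant_id": pid,
                    "subscale": subscale,
                    "D": d.d_value,
                    "n_in": d.n_in,
                    "n_out": d.n_out,
                }
            )
    d_statistics = pd.DataFrame(d_rows)

    return CohortTables(
        descriptives=descriptives,
        classification=classification,
        d_statistics=d_statistics,
        threshold=threshold,
    )
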