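"""Predictive use of the zones (the study's second phase).

Before an upcoming jury each participant reports a fresh CSAI-2 triplet;
each subscale is either In its zone or Out (below and above collapse to
Out). The 2³ = 8 membership patterns over (SA, CA, SC) partition the
cohort; the combination table summarises the actual jury scores per
pattern. Zone distance (0 inside, distance to the closest border outside)
feeds a tie-aware Spearman rank correlation against the jury score — the
direction of effect the zones predict is negative.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import SUBSCALES, PerformanceOccasion
from .errors import ConfigurationError, EstimabilityError, ValidationError
from .zones import Membership, ZoneSet, classify, zone_distance

__all__ = [
    "COMBINATION_ORDER",
    "TABLE_SUBSCALE_ORDER",
    "CombinationTable",
    "combination_table",
    "at_least_k_in",
    "membership_tally",
    "CorrelationResult",
    "spearman",
    "distance_score_dataset",
    "correlate_distances",
]

#: Subscale order used by the combination table columns.
TABLE_SUBSCALE_ORDER = ("sa", "ca", "sc")

#: Fixed row order of the 8 In/Out patterns over (SA, CA, SC).
COMBINATION_ORDER: tuple[tuple[str, str, str], ...] = (
    ("In", "In", "In"),
    ("In", "In", "Out"),
    ("In", "Out", "In"),
    ("Out", "In", "In"),
    ("In", "Out", "Out"),
    ("Out", "In", "Out"),
    ("Out", "Out", "In"),
    ("Out", "Out", "Out"),
)


@dataclass
class CombinationTable:
    """The 8-pattern summary plus the underlying per-participant assignments.

    ``summary`` has one row per pattern (fixed order) with n, pct and the
    score statistics; ``assignments`` keeps one row per predicted occasion
    with its In/Out flags and actual score, so follow-up queries (e.g.
    "at least k subscales In and score >= floor") stay exact.
    """

    summary: pd.DataFrame
    assignments: pd.DataFrame

    @classmethod
    def from_counts(
        cls,
        counts: Sequence[int],
        scores: Optional[Sequence[Optional[Sequence[float]]]] = None,
    ) -> "CombinationTable":
        """Build a table from published pattern counts (pattern order as
        in ``COMBINATION_ORDER``), optionally with per-pattern score lists."""
        if len(counts) != 8:
            raise ConfigurationError(f"need 8 pattern counts, got {len(counts)}")
        if scores is not None and len(scores) != 8:
            raise ConfigurationError("scores must align with the 8 patterns")
        rows = []
        i = 0
        for p_idx, (pattern, n) in enumerate(zip(COMBINATION_ORDER, counts)):
            pattern_scores: list[float]
            if scores is not None and scores[p_idx] is not None:
                pattern_scores = list(scores[p_idx])  # type: ignore[arg-type]
                if len(pattern_scores) != n:
                    raise ConfigurationError(
                        f"pattern {pattern}: {len(pattern_scores)} scores for n={n}"
                    )
            else:
                pattern_scores = [float("nan")] * n
            for s in pattern_scores:
                i += 1
                rows.append(
                    {
                        "participant_id": f"counts_{i:03d}",
                        "occasion_id": "J1",
                        "sa": pattern[0],
                        "ca": pattern[1],
                        "sc": pattern[2],
                        "n_in": sum(1 for m in pattern if m == "In"),
                        "score": s,
                    }
                )
        assignments = pd.DataFrame(
            rows,
            columns=[
                "participant_id",
                "occasion_id",
                "sa",
                "ca",
                "sc",
                "n_in",
                "score",
            ],
        )
        return cls(summary=_summarize(assignments), assignments=assignments)


def _summarize(assignments: pd.DataFrame) -> pd.DataFrame:
    total = len(assignments)
    rows = []
    for idx, pattern in enumerate(COMBINATION_ORDER, start=1):
        mask = (
            (assignments["sa"] == pattern[0])
            & (assignments["ca"] == pattern[1])
            & (assignments["sc"] == pattern[2])
        )
        scores = assignments.loc[mask, "score"].to_numpy(dtype=float)
        scores = scores[~np.isnan(scores)]
        n = int(mask.sum())
        row: dict[str, object] = {
            "combination": idx,
            "sa": pattern[0],
            "ca": pattern[1],
            "sc": pattern[2],
            "n": n,
            "pct": 100.0 * n / total if total else float("nan"),
        }
        if scores.size:
            row.update(
                mean=float(scores.mean()),
                sd=float(scores.std(ddof=1)) if scores.size > 1 else float("nan"),
                median=float(np.median(scores)),
                min=float(scores.min()),
                max=float(scores.max()),
            )
        else:
            row.update(mean=np.nan, sd=np.nan, median=np.nan, min=np.nan, max=np.nan)
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["combination", "sa", "ca", "sc", "n", "pct",
                 "mean", "sd", "median", "min", "max"],
    )


def combination_table(
    predicted: Sequence[PerformanceOccasion],
    zonesets: Mapping[str, ZoneSet],
) -> CombinationTable:
    """Assign each predicted occasion to one of the 8 In/Out patterns.

    Below and above both collapse to Out; the jury scores attached to the
    occasions populate the per-pattern statistics.
    """
    rows = []
    for occ in predicted:
        zs = zonesets.get(occ.participant_id)
        if zs is None:
            raise EstimabilityError(
                f"participant {occ.participant_id!r} has a predicted occasion "
                "but no estimated zone set"
            )
        flags = {
            s: "In"
            if classify(occ.intensity(s), zs.zone(s)) is Membership.IN
            else "Out"
            for s in SUBSCALES
        }
        rows.append(
            {
                "participant_id": occ.participant_id,
                "occasion_id": occ.occasion_id,
                "sa": flags["sa"],
                "ca": flags["ca"],
                "sc": flags["sc"],
                "n_in": sum(1 for v in flags.values() if v == "In"),
                "score": occ.score,
            }
        )
    assignments = pd.DataFrame(
        rows,
        columns=["participant_id", "occasion_id", "sa", "ca", "sc", "n_in", "score"],
    )
    return CombinationTable(summary=_summarize(assignments), assignments=assignments)


def at_least_k_in(
    table: CombinationTable,
    k: int,
    score_floor: Optional[float] = None,
) -> float:
    """Percent of the predicted cohort with >= k subscales In (and, if a
    floor is given, an actual score at or above it)."""
    if not 0 <= k <= 3:
        raise ConfigurationError(f"k must be in 0..3, got {k}")
    a = table.assignments
    if len(a) == 0:
        return float("nan")
    hit = a["n_in"] >= k
    if score_floor is not None and score_floor > 0:
        if a["score"].isna().any():
            raise ValidationError(
                "score_floor requires individual scores in the assignments"
            )
        hit = hit & (a["score"] >= score_floor)
    return 100.0 * float(hit.mean())


def membership_tally(
    predicted: Sequence[PerformanceOccasion],
    zonesets: Mapping[str, ZoneSet],
) -> pd.DataFrame:
    """Full trichotomy per subscale: counts and % below / in / above."""
    counts = {s: {m: 0 for m in Membership} for s in SUBSCALES}
    total = 0
    for occ in predicted:
        zs = zonesets.get(occ.participant_id)
        if zs is None:
            raise EstimabilityError(
                f"participant {occ.participant_id!r} has no estimated zone set"
            )
        total += 1
        for s in SUBSCALES:
            counts[s][classify(occ.intensity(s), zs.zone(s))] += 1
    rows = []
    for s in SUBSCALES:
        row: dict[str, object] = {"subscale": s}
        for m in Membership:
            n = counts[s][m]
            row[f"n_{m.value}"] = n
            row[f"pct_{m.value}"] = 100.0 * n / total if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation with its p-value; rho is NaN when an
    input vector is constant (ranks undefined)."""

    rho: float
    p_value: float
    n: int
    subscale: Optional[str] = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)


_EXACT_MAX_N = 10


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "t-approx",
    subscale: Optional[str] = None,
) -> CorrelationResult:
    """Tie-aware Spearman correlation between two equal-length vectors.

    rho is the Pearson correlation of midranks. ``method="t-approx"``
    (default) takes the p-value from the t distribution with n-2 degrees
    of freedom; ``method="exact"`` enumerates all permutations of one
    vector (n <= 10) for a two-sided exact p.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("spearman needs two equal-length 1-D vectors")
    n = xa.size
    if n < 3:
        raise EstimabilityError(f"spearman needs n >= 3, got {n}")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return CorrelationResult(float("nan"), float("nan"), n, subscale)
    if method == "t-approx":
        res = sps.spearmanr(xa, ya)
        return CorrelationResult(float(res.statistic), float(res.pvalue), n, subscale)
    if method == "exact":
        if n > _EXACT_MAX_N:
            raise ConfigurationError(
                f"exact permutation p-value limited to n <= {_EXACT_MAX_N}, got {n}"
            )
        rx = sps.rankdata(xa)
        ry = sps.rankdata(ya)
        obs = float(np.corrcoef(rx, ry)[0, 1])
        # Pearson of rx against every permutation of ry; only the cross
        # term varies, so work with dot products
        mx, my = rx.mean(), ry.mean()
        sx = math.sqrt(float(np.sum((rx - mx) ** 2)))
        sy = math.sqrt(float(np.sum((ry - my) ** 2)))
        count = 0
        total = 0
        target = abs(obs) - 1e-12
        for perm in itertools.permutations(ry):
            r = (float(np.dot(rx, perm)) - n * mx * my) / (sx * sy)
            if abs(r) >= target:
                count += 1
            total += 1
        return CorrelationResult(obs, count / total, n, subscale)
    raise ConfigurationError(f"method must be 't-approx' or 'exact', got {method!r}")


def distance_score_dataset(
    predicted: Sequence[PerformanceOccasion],
    zonesets: Mapping[str, ZoneSet],
) -> pd.DataFrame:
    """One (distance, score) pair per predicted occasion per subscale —
    the scatterplot data behind the rank correlations."""
    rows = []
    for occ in predicted:
        zs = zonesets.get(occ.participant_id)
        if zs is None:
            raise EstimabilityError(
                f"participant {occ.participant_id!r} has no estimated zone set"
            )
        for s in SUBSCALES:
            rows.append(
                {
                    "participant_id": occ.participant_id,
                    "occasion_id": occ.occasion_id,
                    "subscale": s,
                    "distance": zone_distance(occ.intensity(s), zs.zone(s)),
                    "score": occ.score,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "occasion_id", "subscale", "distance", "score"],
    )


def correlate_distances(
    dataset: pd.DataFrame,
    method: str = "t-approx",
) -> dict[str, CorrelationResult]:
    """Per-subscale Spearman correlation of zone distance against score."""
    out: dict[str, CorrelationResult] = {}
    for s in SUBSCALES:
        sub = dataset[dataset["subscale"] == s]
        out[s] = spearman(
            sub["distance"].to_numpy(),
            sub["score"].to_numpy(),
            method=method,
            subscale=s,
        )
    return out
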