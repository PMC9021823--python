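"""Domain types shared by every stage of the IZOF pipeline.

The unit of observation is one *performance occasion*: a participant sat
the CSAI-2 state-anxiety inventory around one judged performance, giving a
triplet of subscale intensities (cognitive anxiety ``ca``, somatic anxiety
``sa``, self-confidence ``sc``, each on the instrument's 9-36 scale) plus a
performance score on a 1-100 scale, optionally backed by a raw judge panel.
Occasions are either ``recalled`` (retrospective, used to locate the zone)
or ``predicted`` (the upcoming jury the zone is used to predict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ValidationError

#: Canonical subscale identifiers, in instrument order.
SUBSCALES = ("ca", "sa", "sc")

SUBSCALE_MIN = 9
SUBSCALE_MAX = 36
SCORE_MIN = 1.0
SCORE_MAX = 100.0

#: Tolerated discrepancy between a supplied aggregate score and the trimmed
#: aggregate of a supplied judge panel before a warning is emitted.
JUDGE_SCORE_MISMATCH_TOL = 0.5


class Phase(str, Enum):
    """Study phase an occasion belongs to."""

    RECALLED = "recalled"
    PREDICTED = "predicted"


@dataclass(frozen=True)
class SubscaleTriplet:
    """One occasion's CSAI-2 subscale intensities.

    Each subscale totals nine items rated 1-4, so intensities are integers
    in [9, 36].
    """

    ca: int
    sa: int
    sc: int

    def __post_init__(self) -> None:
        for name in SUBSCALES:
            value = getattr(self, name)
            if not isinstance(value, (int,)) or isinstance(value, bool):
                raise ValidationError(
                    f"subscale {name!r} must be an integer, got {value!r}"
                )
            if not SUBSCALE_MIN <= value <= SUBSCALE_MAX:
                raise ValidationError(
                    f"subscale {name!r} = {value} outside the instrument "
                    f"range [{SUBSCALE_MIN}, {SUBSCALE_MAX}]"
                )

    def __getitem__(self, subscale: str) -> int:
        if subscale not in SUBSCALES:
            raise KeyError(subscale)
        return getattr(self, subscale)

    def as_dict(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in SUBSCALES}


@dataclass(frozen=True)
class PerformanceOccasion:
    """One (participant, occasion) record linking anxiety to a score.

    ``score`` is the aggregated performance score. If the raw
    ``judge_scores`` panel is present, ``score`` should equal its trimmed
    aggregate; a discrepancy greater than ``JUDGE_SCORE_MISMATCH_TOL``
    triggers a warning (not an error).
    """

    participant_id: str
    occasion_id: str
    phase: Phase
    triplet: SubscaleTriplet
    score: float
    judge_scores: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if not SCORE_MIN <= self.score <= SCORE_MAX:
            raise ValidationError(
                f"occasion ({self.participant_id}, {self.occasion_id}): "
                f"score {self.score} outside [{SCORE_MIN:g}, {SCORE_MAX:g}]"
            )
        if self.judge_scores is not None:
            from .scoring import aggregate_judges  # avoid import cycle

            agg = aggregate_judges(self.judge_scores)
            if abs(agg - self.score) > JUDGE_SCORE_MISMATCH_TOL:
                warnings.warn(
                    f"occasion ({self.participant_id}, {self.occasion_id}): "
                    f"score {self.score} differs from the trimmed judge "
                    f"aggregate {agg:.2f} by more than "
                    f"{JUDGE_SCORE_MISMATCH_TOL}",
                    stacklevel=2,
                )

    def intensity(self, subscale: str) -> int:
        return self.triplet[subscale]


@dataclass
class Cohort:
    """An ordered collection of performance occasions.

    Invariants: (participant_id, occasion_id) pairs are unique, and every
    participant carrying a predicted occasion has at least two recalled
    occasions (otherwise no zone can be estimated for them).
    """

    occasions: list[PerformanceOccasion] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for occ in self.occasions:
            key = (occ.participant_id, occ.occasion_id)
            if key in seen:
                raise ValidationError(
                    f"duplicate (participant, occasion) pair {key}"
                )
            seen.add(key)
        recalled_counts: dict[str, int] = {}
        for occ in self.occasions:
            if occ.phase is Phase.RECALLED:
                recalled_counts[occ.participant_id] = (
                    recalled_counts.get(occ.participant_id, 0) + 1
                )
        for occ in self.occasions:
            if occ.phase is Phase.PREDICTED:
                if recalled_counts.get(occ.participant_id, 0) < 2:
                    raise ValidationError(
                        f"participant {occ.participant_id!r} has a predicted "
                        "occasion but fewer than 2 recalled occasions; the "
                        "zone is not estimable"
                    )

    def __len__(self) -> int:
        return len(self.occasions)

    def __iter__(self):
        return iter(self.occasions)

    @property
    def participants(self) -> list[str]:
        """Participant ids in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for occ in self.occasions:
            if occ.participant_id not in seen:
                seen.add(occ.participant_id)
                out.append(occ.participant_id)
        return out

    def recalled(self, participant_id: Optional[str] = None) -> list[PerformanceOccasion]:
        return [
            o
            for o in self.occasions
            if o.phase is Phase.RECALLED
            and (participant_id is None or o.participant_id == participant_id)
        ]

    def predicted(self, participant_id: Optional[str] = None) -> list[PerformanceOccasion]:
        return [
            o
            for o in self.occasions
            if o.phase is Phase.PREDICTED
            and (participant_id is None or o.participant_id == participant_id)
        ]

    def to_frame(self):
        """Long-format view of the cohort (one row per occasion)."""
        import pandas as pd

        rows = []
        n_judges = max(
            (len(o.judge_scores) for o in self.occasions if o.judge_scores),
            default=0,
        )
        for occ in self.occasions:
            row: dict[str, object] = {
                "participant_id": occ.participant_id,
                "occasion_id": occ.occasion_id,
                "phase": occ.phase.value,
                **occ.triplet.as_dict(),
                "score": occ.score,
            }
            if occ.judge_scores is not None:
                for j, s in enumerate(occ.judge_scores, start=1):
                    row[f"judge_{j}"] = s
            rows.append(row)
        columns = ["participant_id", "occasion_id", "phase", *SUBSCALES, "score"]
        columns += [f"judge_{j}" for j in range(1, n_judges + 1)]
        return pd.DataFrame(rows, columns=columns)
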