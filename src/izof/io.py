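"""Long-format cohort CSV reading/writing and report export.

Cohort schema (one row per participant-occasion):

* ``participant_id``, ``occasion_id``, ``phase`` (``recalled``/``predicted``)
* anxiety: either ``ca, sa, sc`` integer subscale totals, or
  ``item_01 .. item_27`` raw ratings (1-4) plus an item-key file
* performance: either an aggregated ``score`` (1-100) or a judge panel
  ``judge_1 .. judge_N`` (N >= 3, integers) to be trim-aggregated.

If both ``score`` and judge columns are present the judge columns win; a
mismatch above 0.5 points emits a warning. Missing values are rejected —
the design assumes complete repeated-measures data.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    SUBSCALES,
    Cohort,
    PerformanceOccasion,
    Phase,
    SubscaleTriplet,
)
from .errors import ConfigurationError, SchemaError, ValidationError
from .scoring import aggregate_judges, score_items, validate_item_key

_REQUIRED = ("participant_id", "occasion_id", "phase")
_JUDGE_RE = re.compile(r"^judge_(\d+)$")
_ITEM_COLS = tuple(f"item_{i:02d}" for i in range(1, 28))


def load_item_key(path: Union[str, Path]) -> dict[int, str]:
    """Read a JSON or YAML item->subscale key and validate it."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ConfigurationError(
            f"item key file {path} must contain a mapping of item -> subscale"
        )
    return validate_item_key({int(k): v for k, v in raw.items()})


def _judge_columns(columns) -> list[str]:
    found = [(int(m.group(1)), c) for c in columns if (m := _JUDGE_RE.match(c))]
    return [c for _, c in sorted(found)]


def _require_int(value, row: int, column: str) -> int:
    if pd.isna(value):
        raise ValidationError(f"row {row}: missing value in column {column!r}")
    f = float(value)
    if f != int(f):
        raise ValidationError(
            f"row {row}: column {column!r} must be an integer, got {value!r}"
        )
    return int(f)


def read_cohort(
    path: Union[str, Path],
    item_key: Optional[Union[Mapping[int, str], str, Path]] = None,
) -> Cohort:
    """Read and validate a long-format cohort CSV.

    ``item_key`` (mapping or path to a JSON/YAML file) is required when the
    file carries raw ``item_*`` columns instead of subscale totals. Row
    order is preserved.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")

    has_subscales = all(s in df.columns for s in SUBSCALES)
    has_items = all(c in df.columns for c in _ITEM_COLS)
    if not has_subscales and not has_items:
        raise SchemaError(
            "anxiety columns missing: need either 'ca','sa','sc' or "
            "'item_01'..'item_27'"
        )
    if has_items and not has_subscales:
        if item_key is None:
            raise ConfigurationError(
                "file carries item_* columns; an item key is required"
            )
        if not isinstance(item_key, Mapping):
            item_key = load_item_key(item_key)
        else:
            item_key = validate_item_key(item_key)

    judge_cols = _judge_columns(df.columns)
    if judge_cols and len(judge_cols) < 3:
        raise SchemaError(
            f"judge panel needs >= 3 judge_* columns, found {len(judge_cols)}"
        )
    if not judge_cols and "score" not in df.columns:
        raise SchemaError(
            "performance columns missing: need either 'score' or 'judge_1'..'judge_N'"
        )

    occasions: list[PerformanceOccasion] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 1  # 1-based, header excluded
        for col in _REQUIRED:
            if pd.isna(row[col]):
                raise ValidationError(
                    f"row {rownum}: missing value in column {col!r}"
                )
        phase_raw = str(row["phase"]).strip().lower()
        try:
            phase = Phase(phase_raw)
        except ValueError:
            raise ValidationError(
                f"row {rownum}: phase {row['phase']!r} must be "
                "'recalled' or 'predicted'"
            )
        if has_subscales:
            triplet = SubscaleTriplet(
                **{s: _require_int(row[s], rownum, s) for s in SUBSCALES}
            )
        else:
            items = [_require_int(row[c], rownum, c) for c in _ITEM_COLS]
            triplet = score_items(items, item_key)

        judge_scores: Optional[tuple[int, ...]] = None
        row_judges = [row[c] for c in judge_cols]
        if judge_cols and all(pd.isna(v) for v in row_judges):
            # no panel for this occasion: fall back to the aggregate column
            if "score" not in df.columns:
                raise ValidationError(
                    f"row {rownum}: judge columns are empty and no 'score' "
                    "column is available"
                )
            judge_cols_row = []
        else:
            judge_cols_row = judge_cols
        if judge_cols_row:
            judge_scores = tuple(
                _require_int(row[c], rownum, c) for c in judge_cols_row
            )
            # judge columns win over a supplied aggregate
            score = aggregate_judges(judge_scores)
            if "score" in df.columns and not pd.isna(row["score"]):
                supplied = float(row["score"])
                if abs(supplied - score) > 0.5:
                    warnings.warn(
                        f"row {rownum}: supplied score {supplied} differs "
                        f"from the trimmed judge aggregate {score:.2f}; "
                        "using the aggregate",
                        stacklevel=2,
                    )
        else:
            if pd.isna(row["score"]):
                raise ValidationError(
                    f"row {rownum}: missing value in column 'score'"
                )
            score = float(row["score"])
        occasions.append(
            PerformanceOccasion(
                participant_id=str(row["participant_id"]),
                occasion_id=str(row["occasion_id"]),
                phase=phase,
                triplet=triplet,
                score=score,
                judge_scores=judge_scores,
            )
        )
    return Cohort(occasions)


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> Path:
    """Write a cohort back to the long-format CSV schema."""
    path = Path(path)
    cohort.to_frame().to_csv(path, index=False)
    return path


def write_report(
    tables: Mapping[str, pd.DataFrame],
    outdir: Union[str, Path],
    float_format: str = "%.10g",
) -> list[Path]:
    """Write each named table to ``<outdir>/<name>.csv``.

    Column order is whatever the builder produced (stable); an empty
    mapping writes nothing and succeeds. Returns the written paths.
    """
    outdir = Path(outdir)
    written: list[Path] = []
    if not tables:
        return written
    outdir.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        target = outdir / f"{name}.csv"
        table.to_csv(target, index=False, float_format=float_format)
        written.append(target)
    return written
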