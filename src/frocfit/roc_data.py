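"""Confidence-rating count tables and the false-memory ROCs derived from them.

A recognition test with similar lures yields, for each item class (similar
lure, genuinely new, and optionally studied/old), a table of response counts
on a K-point confidence scale (conventionally 1 = "sure new" ... K = "sure
old").  Cumulating those counts from the most confident "old" response
downward gives, at each confidence criterion, the proportion of items
endorsed as old; pairing the lure proportions (y) against the new-item
proportions (x) across criteria traces out the false-memory ROC (fROC).

This module holds the data containers (:class:`RatingScale`,
:class:`ConfidenceCounts`, :class:`FrocPoints`, :class:`SubjectRecord`),
the cumulation/pooling operations, and CSV I/O in two dialects (wide: one
column per rating level; long: one row per rating level).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemClass",
    "RatingScale",
    "ConfidenceCounts",
    "FrocPoints",
    "SubjectRecord",
    "cumulate_counts",
    "build_froc",
    "pool_records",
    "read_counts",
    "write_counts",
]


class ItemClass(str, enum.Enum):
    """Test-item category: similar lure, genuinely new, or studied (old)."""

    LURE = "lure"
    NEW = "new"
    OLD = "old"


@dataclass(frozen=True)
class RatingScale:
    """A K-point confidence scale.

    Parameters
    ----------
    k_levels:
        Number of rating categories (at least 3; 6 is conventional).
    high_end_is_old:
        If True (the canonical orientation), rating ``k_levels`` means
        "sure old" and rating 1 means "sure new".  Reversed scales are
        flipped to canonical orientation at parse time.
    """

    k_levels: int = 6
    high_end_is_old: bool = True

    def __post_init__(self) -> None:
        if int(self.k_levels) != self.k_levels or self.k_levels < 3:
            raise ValueError(
                f"k_levels must be an integer >= 3, got {self.k_levels!r}"
            )
        object.__setattr__(self, "k_levels", int(self.k_levels))


@dataclass(frozen=True, eq=False)
class ConfidenceCounts:
    """Rating frequencies for one item class on one confidence scale.

    Counts are stored in canonical orientation (index 0 = rating 1 =
    "sure new", last index = "sure old"); if ``scale.high_end_is_old`` is
    False the count vector is reversed on construction and the scale flag
    is normalised.
    """

    item_class: ItemClass
    counts: np.ndarray
    scale: RatingScale = field(default_factory=RatingScale)

    def __post_init__(self) -> None:
        item_class = ItemClass(self.item_class)
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.shape[0] != self.scale.k_levels:
            raise ValueError(
                f"counts must be a length-{self.scale.k_levels} vector, "
                f"got shape {counts.shape}"
            )
        if not np.issubdtype(counts.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(counts != np.floor(counts)):
            raise ValueError("counts must be integers")
        counts = counts.astype(np.int64)
        scale = self.scale
        if not scale.high_end_is_old:
            counts = counts[::-1].copy()
            scale = RatingScale(scale.k_levels, high_end_is_old=True)
        counts.setflags(write=False)
        object.__setattr__(self, "item_class", item_class)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "scale", scale)

    @property
    def total(self) -> int:
        """Total number of trials."""
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        """Per-bin response proportions (requires ``total > 0``)."""
        if self.total == 0:
            raise ValueError(
                f"no trials recorded for item class {self.item_class.value!r}"
            )
        return self.counts / self.total

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConfidenceCounts):
            return NotImplemented
        return (
            self.item_class == other.item_class
            and self.scale == other.scale
            and np.array_equal(self.counts, other.counts)
        )


@dataclass(frozen=True, eq=False)
class FrocPoints:
    """Paired cumulative acceptance proportions across confidence criteria.

    ``x[i]`` is P("old" | new) and ``y[i]`` is P("old" | lure) at the i-th
    criterion, ordered from the strictest ("sure old" only) to the most
    lenient informative criterion.  The trivial (1, 1) endpoint is never
    stored.  ``n_new``/``n_lure`` record the trial totals behind the
    proportions (0 for analytic, infinite-n curves).
    """

    x: np.ndarray
    y: np.ndarray
    n_new: int = 0
    n_lure: int = 0

    _MONOTONE_TOL = 1e-9

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D vectors of equal length")
        if x.size == 0:
            raise ValueError("an fROC needs at least one point")
        for name, v in (("x", x), ("y", y)):
            if np.any(v < -self._MONOTONE_TOL) or np.any(v > 1 + self._MONOTONE_TOL):
                raise ValueError(f"{name} proportions must lie in [0, 1]")
            if np.any(np.diff(v) < -self._MONOTONE_TOL):
                raise ValueError(
                    f"{name} must be non-decreasing across criteria "
                    "(cumulate from highest confidence downward)"
                )
        x = np.clip(x, 0.0, 1.0)
        y = np.clip(y, 0.0, 1.0)
        x.setflags(write=False)
        y.setflags(write=False)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "n_new", int(self.n_new))
        object.__setattr__(self, "n_lure", int(self.n_lure))

    def __len__(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion_index": np.arange(1, len(self) + 1),
                "x": self.x,
                "y": self.y,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> str:
        return json.dumps(
            {
                "x": self.x.tolist(),
                "y": self.y.tolist(),
                "n_new": self.n_new,
                "n_lure": self.n_lure,
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrocPoints):
            return NotImplemented
        return (
            np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and self.n_new == other.n_new
            and self.n_lure == other.n_lure
        )


@dataclass(frozen=True)
class SubjectRecord:
    """All count tables for one subject (or one pooled group)."""

    subject_id: str
    counts: Mapping[ItemClass, ConfidenceCounts]

    def __post_init__(self) -> None:
        counts = {ItemClass(k): v for k, v in self.counts.items()}
        if not counts:
            raise ValueError("a SubjectRecord needs at least one count table")
        scales = {c.scale for c in counts.values()}
        if len(scales) != 1:
            raise ValueError("all count tables of a subject must share one scale")
        for klass, c in counts.items():
            if c.item_class != klass:
                raise ValueError(
                    f"table stored under {klass.value!r} is labelled "
                    f"{c.item_class.value!r}"
                )
        object.__setattr__(self, "counts", counts)

    @property
    def scale(self) -> RatingScale:
        return next(iter(self.counts.values())).scale

    def __getitem__(self, item_class: ItemClass | str) -> ConfidenceCounts:
        return self.counts[ItemClass(item_class)]


def cumulate_counts(counts: ConfidenceCounts) -> np.ndarray:
    """Cumulative acceptance proportions P(rating >= j), j = K down to 2.

    The first entry is the proportion of highest-confidence "old" responses;
    each subsequent entry folds in the next confidence level.  The trivial
    P(rating >= 1) = 1 endpoint is excluded.
    """
    total = counts.total
    if total == 0:
        raise ValueError(
            f"cannot cumulate an empty count table "
            f"(item class {counts.item_class.value!r} has zero trials)"
        )
    return np.cumsum(counts.counts[::-1])[:-1] / total


def build_froc(lure: ConfidenceCounts, new: ConfidenceCounts) -> FrocPoints:
    """Build the observed fROC from lure and new-item count tables."""
    if lure.item_class != ItemClass.LURE:
        raise ValueError(f"first argument must be lure counts, got {lure.item_class.value!r}")
    if new.item_class != ItemClass.NEW:
        raise ValueError(f"second argument must be new-item counts, got {new.item_class.value!r}")
    if lure.scale != new.scale:
        raise ValueError("lure and new counts must share one rating scale")
    return FrocPoints(
        x=cumulate_counts(new),
        y=cumulate_counts(lure),
        n_new=new.total,
        n_lure=lure.total,
    )


def pool_records(records: Iterable[SubjectRecord]) -> SubjectRecord:
    """Element-wise sum of counts across subjects (group-aggregate record).

    All records must share one rating scale; the result is independent of
    input order.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to pool")
    scale = records[0].scale
    pooled: dict[ItemClass, np.ndarray] = {}
    for rec in records:
        if rec.scale != scale:
            raise ValueError(
                f"record {rec.subject_id!r} uses a different rating scale"
            )
        for klass, c in rec.counts.items():
            pooled[klass] = pooled.get(klass, np.zeros(scale.k_levels, dtype=np.int64)) + c.counts
    return SubjectRecord(
        subject_id="pooled",
        counts={
            klass: ConfidenceCounts(klass, v, scale)
            for klass, v in sorted(pooled.items(), key=lambda kv: kv[0].value)
        },
    )


def _validated_count(value, row_label) -> int:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"row {row_label}: count {value!r} is not a number") from None
    if not np.isfinite(v) or v != int(v):
        raise ValueError(f"row {row_label}: count {value!r} is not an integer")
    if v < 0:
        raise ValueError(f"row {row_label}: negative count {value!r}")
    return int(v)


def read_counts(
    path: str | Path,
    fmt: str = "wide",
    *,
    high_end_is_old: bool = True,
) -> list[SubjectRecord]:
    """Read confidence-count tables from CSV.

    Wide dialect: columns ``subject_id, item_class, r1, ..., rK`` (one count
    column per rating level, ascending).  Long dialect: columns
    ``subject_id, item_class, rating, count``.  Row numbers in error
    messages refer to data rows (header = row 0).

    Set ``high_end_is_old=False`` for files whose rating 1 means "sure old";
    counts are flipped to the canonical orientation on load.
    """
    if fmt not in ("wide", "long"):
        raise ValueError(f"fmt must be 'wide' or 'long', got {fmt!r}")
    df = pd.read_csv(path)
    required = ["subject_id", "item_class"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")

    records: list[SubjectRecord] = []
    if fmt == "wide":
        rating_cols = [c for c in df.columns if c not in required]
        k = len(rating_cols)
        scale = RatingScale(k_levels=k, high_end_is_old=True)
        tables: dict[str, dict[ItemClass, ConfidenceCounts]] = {}
        for i, row in df.iterrows():
            row_label = i + 1
            try:
                klass = ItemClass(str(row["item_class"]))
            except ValueError:
                raise ValueError(
                    f"row {row_label}: unknown item_class {row['item_class']!r}"
                ) from None
            vec = np.array(
                [_validated_count(row[c], row_label) for c in rating_cols]
            )
            if not high_end_is_old:
                vec = vec[::-1]
            subj = tables.setdefault(str(row["subject_id"]), {})
            if klass in subj:
                raise ValueError(
                    f"row {row_label}: duplicate {klass.value!r} table for "
                    f"subject {row['subject_id']!r}"
                )
            subj[klass] = ConfidenceCounts(klass, vec, scale)
    else:
        for col in ("rating", "count"):
            if col not in df.columns:
                raise ValueError(f"long format requires a {col!r} column")
        k = int(df["rating"].max())
        scale = RatingScale(k_levels=k, high_end_is_old=True)
        raw: dict[tuple[str, ItemClass], np.ndarray] = {}
        for i, row in df.iterrows():
            row_label = i + 1
            try:
                klass = ItemClass(str(row["item_class"]))
            except ValueError:
                raise ValueError(
                    f"row {row_label}: unknown item_class {row['item_class']!r}"
                ) from None
            rating = _validated_count(row["rating"], row_label)
            if not 1 <= rating <= k:
                raise ValueError(f"row {row_label}: rating {rating} outside 1..{k}")
            count = _validated_count(row["count"], row_label)
            key = (str(row["subject_id"]), klass)
            vec = raw.setdefault(key, np.zeros(k, dtype=np.int64))
            idx = rating - 1 if high_end_is_old else k - rating
            vec[idx] += count
        tables = {}
        for (subject_id, klass), vec in raw.items():
            tables.setdefault(subject_id, {})[klass] = ConfidenceCounts(
                klass, vec, scale
            )

    for subject_id, counts in tables.items():
        records.append(SubjectRecord(subject_id=subject_id, counts=counts))
    return records


def write_counts(
    records: Sequence[SubjectRecord], path: str | Path, fmt: str = "wide"
) -> None:
    """Write subject records to CSV in the wide or long dialect."""
    if fmt not in ("wide", "long"):
        raise ValueError(f"fmt must be 'wide' or 'long', got {fmt!r}")
    rows = []
    for rec in records:
        k = rec.scale.k_levels
        for klass in sorted(rec.counts, key=lambda c: c.value):
            c = rec.counts[klass]
            if fmt == "wide":
                row = {"subject_id": rec.subject_id, "item_class": klass.value}
                row.update({f"r{j + 1}": int(c.counts[j]) for j in range(k)})
                rows.append(row)
            else:
                for j in range(k):
                    rows.append(
                        {
                            "subject_id": rec.subject_id,
                            "item_class": klass.value,
                            "rating": j + 1,
                            "count": int(c.counts[j]),
                        }
                    )
    pd.DataFrame(rows).to_csv(path, index=False)
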