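"""The nine-type typology of binocular fixation asynchronies.

A binocular fixation carries two signed offsets, each defined as the right
eye's event time minus the left eye's event time:

* **start offset** — at fixation onset;
* **end offset** — at fixation offset.

On a 500 Hz tracker events land on a 2 ms lattice, so a difference of
±2 ms is treated as simultaneous (the tolerance is configurable through
:class:`ToleranceRule` for other sampling rates).  Crossing the start axis
{sync, right-early, left-early} with the end axis {sync, left-late,
right-late} yields nine types::

                      end sync   left ends later   right ends later
    starts sync         Syn            T1                T2
    right starts early  T3             T4                T5
    left starts early   T6             T7                T8

Priority groupings used in the analysis: left-eye priority {T1, T6, T7},
right-eye priority {T2, T3, T5}; T4 and T8 mix an early advantage for one
eye with a late advantage for the other and are therefore ambiguous.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable

import numpy as np
import pandas as pd

LABELS = ("Syn", "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8")

#: start-axis class by signed start offset (right − left)
START_CLASSES = ("sync", "right_early", "left_early")
#: end-axis class by signed end offset (right − left)
END_CLASSES = ("sync", "left_late", "right_late")

#: bijection (start_class, end_class) -> label
CLASS_TO_LABEL = {
    ("sync", "sync"): "Syn",
    ("sync", "left_late"): "T1",
    ("sync", "right_late"): "T2",
    ("right_early", "sync"): "T3",
    ("right_early", "left_late"): "T4",
    ("right_early", "right_late"): "T5",
    ("left_early", "sync"): "T6",
    ("left_early", "left_late"): "T7",
    ("left_early", "right_late"): "T8",
}
LABEL_TO_CLASS = {v: k for k, v in CLASS_TO_LABEL.items()}

LEFT_PRIORITY = frozenset({"T1", "T6", "T7"})
RIGHT_PRIORITY = frozenset({"T2", "T3", "T5"})
AMBIGUOUS = frozenset({"T4", "T8"})

#: label map induced by swapping the two eyes (offsets negate)
EYE_SWAP = {
    "Syn": "Syn",
    "T1": "T2", "T2": "T1",
    "T3": "T6", "T6": "T3",
    "T4": "T8", "T8": "T4",
    "T5": "T7", "T7": "T5",
}


@dataclasses.dataclass(frozen=True)
class ToleranceRule:
    """Simultaneity tolerance: |offset| <= tol_ms counts as synchronous.

    The comparison is inclusive, so with the default 2 ms tolerance the
    synchronous band on the 2 ms lattice is {−2, 0, +2}.
    """

    tol_ms: float = 2.0

    def __post_init__(self) -> None:
        if self.tol_ms < 0:
            raise ValueError("tol_ms must be >= 0")


DEFAULT_RULE = ToleranceRule()


def start_offset(left_start_ms, right_start_ms):
    """Signed start-time offset: right eye start minus left eye start."""
    return np.asarray(right_start_ms) - np.asarray(left_start_ms)


def end_offset(left_end_ms, right_end_ms):
    """Signed end-time offset: right eye end minus left eye end."""
    return np.asarray(right_end_ms) - np.asarray(left_end_ms)


def _classify_arrays(start, end, rule: ToleranceRule) -> np.ndarray:
    tol = rule.tol_ms
    # start axis index: 0 sync, 1 right_early (start < -tol), 2 left_early
    s = np.where(np.abs(start) <= tol, 0, np.where(start < -tol, 1, 2))
    # end axis index: 0 sync, 1 left_late (end < -tol), 2 right_late
    e = np.where(np.abs(end) <= tol, 0, np.where(end < -tol, 1, 2))
    table = np.array(
        [[CLASS_TO_LABEL[(sc, ec)] for ec in END_CLASSES] for sc in START_CLASSES]
    )
    return table[s, e]


def classify(start_offset_ms, end_offset_ms, rule: ToleranceRule = DEFAULT_RULE):
    """Classify start/end offsets into the nine-type typology.

    Accepts scalars or arrays; returns a label (or array of labels) from
    :data:`LABELS`.  Offsets off the 2 ms sampling lattice are allowed but
    warned about, since they usually indicate mis-parsed timestamps.
    """
    start = np.asarray(start_offset_ms, dtype=float)
    end = np.asarray(end_offset_ms, dtype=float)
    if np.any(start % 2 != 0) or np.any(end % 2 != 0):
        warnings.warn("offsets off the 2 ms sampling lattice", stacklevel=2)
    labels = _classify_arrays(start, end, rule)
    if np.ndim(labels) == 0:
        return str(labels)
    return labels


def classify_pairs(pairs: pd.DataFrame, rule: ToleranceRule = DEFAULT_RULE) -> pd.DataFrame:
    """Annotate a pairs table with its asynchrony ``type`` column."""
    out = pairs.copy()
    out["type"] = _classify_arrays(
        out["start_offset_ms"].to_numpy(float),
        out["end_offset_ms"].to_numpy(float),
        rule,
    )
    return out


@dataclasses.dataclass
class TypeDistribution:
    """Proportions of the nine types plus the derived aggregates."""

    proportions: pd.Series  # indexed by LABELS, sums to 1
    n: int

    @property
    def aggregates(self) -> dict[str, float]:
        p = self.proportions
        return {
            "start_synchronous": float(p["Syn"] + p["T1"] + p["T2"]),
            "end_synchronous": float(p["Syn"] + p["T3"] + p["T6"]),
            "left_priority": float(sum(p[t] for t in sorted(LEFT_PRIORITY))),
            "right_priority": float(sum(p[t] for t in sorted(RIGHT_PRIORITY))),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"type": self.proportions.index, "proportion": self.proportions.values}
        )


def type_distribution(labels: Iterable[str] | pd.DataFrame) -> TypeDistribution:
    """Proportion of each asynchrony type among classified pairs.

    *labels* may be a classified pairs table (with a ``type`` column) or any
    iterable of labels.  Raises on empty input.
    """
    if isinstance(labels, pd.DataFrame):
        labels = labels["type"]
    s = pd.Series(list(labels), dtype=object)
    if len(s) == 0:
        raise ValueError("cannot compute a type distribution from zero pairs")
    bad = set(s.unique()) - set(LABELS)
    if bad:
        raise ValueError(f"unknown type labels: {sorted(bad)}")
    counts = s.value_counts().reindex(LABELS, fill_value=0)
    return TypeDistribution(proportions=counts / counts.sum(), n=int(counts.sum()))
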