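"""Matching the two eyes' fixation streams into binocular fixations.

A binocular fixation is a pair of temporally overlapping fixations, one per
eye.  The two monocular streams are each strictly ordered in time, so a
physiologically meaningful matching cannot cross: if left fixation *i* pairs
with right fixation *j*, no earlier left fixation may pair with a later
right one.  Under that non-crossing constraint the one-to-one matching that
maximizes total temporal overlap is found exactly by dynamic programming
over the two sorted streams, in O(|L|·|R|).

Overlap must be strictly positive for a pair to form: on the 2 ms sampling
lattice a shared endpoint is a saccade boundary, not co-fixation.  Ties in
total overlap are broken toward pairing with the earlier right fixation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

try:  # optional jit of the DP kernel; pure-python fallback is exact
    from numba import njit as _njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

#: columns of the binocular-pairs table
PAIR_COLUMNS = [
    "participant_id",
    "group",
    "article_id",
    "page_id",
    "left_start_ms",
    "left_end_ms",
    "right_start_ms",
    "right_end_ms",
    "overlap_ms",
    "start_offset_ms",
    "end_offset_ms",
    "x_px",
    "y_px",
]


def temporal_overlap(a_start, a_end, b_start, b_end):
    """Temporal overlap of two intervals: max(0, min(ends) − max(starts))."""
    return np.maximum(
        0, np.minimum(a_end, b_end) - np.maximum(a_start, b_start)
    )


def _dp_table_py(ls, le, rs, re_):
    n, m = len(ls), len(rs)
    M = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(1, n + 1):
        s1, e1 = ls[i - 1], le[i - 1]
        for j in range(1, m + 1):
            w = min(e1, re_[j - 1]) - max(s1, rs[j - 1])
            best = M[i - 1, j]
            if M[i, j - 1] > best:
                best = M[i, j - 1]
            if w > 0 and M[i - 1, j - 1] + w > best:
                best = M[i - 1, j - 1] + w
            M[i, j] = best
    return M


if _HAVE_NUMBA:
    _dp_table = _njit(cache=True)(_dp_table_py)
else:  # pragma: no cover
    _dp_table = _dp_table_py


def _check_stream(start: np.ndarray, end: np.ndarray, eye: str) -> None:
    if np.any(end <= start):
        raise ValueError(f"{eye} stream has non-positive durations")
    if len(start) > 1:
        if np.any(np.diff(start) <= 0):
            raise ValueError(f"{eye} stream is not strictly sorted by start time")
        if np.any(start[1:] < end[:-1]):
            raise ValueError(f"{eye} stream has overlapping fixations")


@dataclasses.dataclass
class PairingResult:
    """Matched index pairs plus per-eye unpaired tallies."""

    left_idx: np.ndarray
    right_idx: np.ndarray
    overlap_ms: np.ndarray
    n_unpaired_left: int
    n_unpaired_right: int


def pair_fixations(
    left_start, left_end, right_start, right_end
) -> PairingResult:
    """Optimal non-crossing one-to-one matching of two fixation streams.

    Inputs are the start/end times (ms) of each eye's fixations, sorted by
    start and non-overlapping within the eye (violations are a hard error).
    Returns the matched index pairs, each with strictly positive overlap.
    Among matchings of equal total overlap, left fixations pair with the
    earliest compatible right fixation.
    """
    ls = np.asarray(left_start, dtype=np.int64)
    le = np.asarray(left_end, dtype=np.int64)
    rs = np.asarray(right_start, dtype=np.int64)
    re_ = np.asarray(right_end, dtype=np.int64)
    _check_stream(ls, le, "left")
    _check_stream(rs, re_, "right")
    n, m = len(ls), len(rs)
    if n == 0 or m == 0:
        return PairingResult(
            np.empty(0, int), np.empty(0, int), np.empty(0, np.int64), n, m
        )
    M = _dp_table(ls, le, rs, re_)
    # Backtrack.  Preferring to drop the *later* right fixation whenever the
    # value allows pairs left fixations with the earliest right alternative.
    li, ri, ov = [], [], []
    i, j = n, m
    while i > 0 and j > 0:
        if M[i, j] == M[i, j - 1]:
            j -= 1
            continue
        w = min(le[i - 1], re_[j - 1]) - max(ls[i - 1], rs[j - 1])
        if w > 0 and M[i, j] == M[i - 1, j - 1] + w:
            li.append(i - 1)
            ri.append(j - 1)
            ov.append(w)
            i -= 1
            j -= 1
        else:
            i -= 1
    li.reverse()
    ri.reverse()
    ov.reverse()
    k = len(li)
    return PairingResult(
        np.array(li, int),
        np.array(ri, int),
        np.array(ov, np.int64),
        n - k,
        m - k,
    )


def pair_streams(fixations: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Pair a full fixation-event table page by page.

    Fixations are grouped by (participant, article, page); the two eyes'
    streams within each page are matched with :func:`pair_fixations`.  No
    pair is formed across a page boundary.  Returns the binocular-pairs
    table (columns :data:`PAIR_COLUMNS`; position is the right eye's) and
    the per-eye unpaired tallies.
    """
    required = {
        "participant_id", "article_id", "page_id", "eye",
        "start_ms", "end_ms", "x_px", "y_px",
    }
    missing = required - set(fixations.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    unpaired = {"L": 0, "R": 0}
    rows: list[pd.DataFrame] = []
    keys = ["participant_id", "article_id", "page_id"]
    for key, grp in fixations.groupby(keys, sort=True):
        left = grp[grp["eye"] == "L"].sort_values("start_ms")
        right = grp[grp["eye"] == "R"].sort_values("start_ms")
        res = pair_fixations(
            left["start_ms"].to_numpy(),
            left["end_ms"].to_numpy(),
            right["start_ms"].to_numpy(),
            right["end_ms"].to_numpy(),
        )
        unpaired["L"] += res.n_unpaired_left
        unpaired["R"] += res.n_unpaired_right
        if len(res.left_idx) == 0:
            continue
        lsel = left.iloc[res.left_idx]
        rsel = right.iloc[res.right_idx]
        group_label = grp["group"].iloc[0] if "group" in grp.columns else ""
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": key[0],
                    "group": group_label,
                    "article_id": key[1],
                    "page_id": key[2],
                    "left_start_ms": lsel["start_ms"].to_numpy(),
                    "left_end_ms": lsel["end_ms"].to_numpy(),
                    "right_start_ms": rsel["start_ms"].to_numpy(),
                    "right_end_ms": rsel["end_ms"].to_numpy(),
                    "overlap_ms": res.overlap_ms,
                    "start_offset_ms": rsel["start_ms"].to_numpy()
                    - lsel["start_ms"].to_numpy(),
                    "end_offset_ms": rsel["end_ms"].to_numpy()
                    - lsel["end_ms"].to_numpy(),
                    # spatial position of the pair = right eye's mean coordinates
                    "x_px": rsel["x_px"].to_numpy(),
                    "y_px": rsel["y_px"].to_numpy(),
                }
            )
        )
    if rows:
        pairs = pd.concat(rows, ignore_index=True)
    else:
        pairs = pd.DataFrame(columns=PAIR_COLUMNS)
    return pairs, unpaired
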