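"""Reading and writing per-eye fixation event data.

The canonical in-memory container for fixation events is a pandas
``DataFrame`` with one row per monocular fixation and the columns in
:data:`FIXATION_COLUMNS`.  Two on-disk dialects are supported: a canonical
CSV, and the EyeLink ASCII export's ``EFIX``/``MSG`` subset.

Times are integers in milliseconds on the tracker grid (500 Hz trackers
report on a 2 ms lattice).  Fractional input times are *rejected*, not
rounded: silent rounding would corrupt the ±2 ms simultaneity rule
downstream.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical column order for fixation-event tables.
FIXATION_COLUMNS = [
    "participant_id",
    "group",
    "article_id",
    "page_id",
    "eye",
    "start_ms",
    "end_ms",
    "x_px",
    "y_px",
]

_REQUIRED_NUMERIC = ["start_ms", "end_ms", "x_px", "y_px"]


@dataclasses.dataclass(frozen=True)
class ScreenGeometry:
    """Display geometry and the left/middle/right split of the screen.

    Parameters
    ----------
    width_px, height_px
        Screen resolution in pixels (default 1024 × 768).
    region_bounds
        Two x-coordinates splitting the width into left / middle / right.
        Defaults to equal thirds of the width.
    """

    width_px: float = 1024.0
    height_px: float = 768.0
    region_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("screen dimensions must be positive")
        if self.region_bounds is None:
            object.__setattr__(
                self, "region_bounds", (self.width_px / 3.0, 2.0 * self.width_px / 3.0)
            )
        b1, b2 = self.region_bounds
        if not (0 < b1 < b2 < self.width_px):
            raise ValueError(
                f"region bounds must satisfy 0 < {b1} < {b2} < {self.width_px}"
            )


@dataclasses.dataclass
class RejectionLog:
    """Per-reason tallies of input records dropped during parsing."""

    reasons: dict[str, int] = dataclasses.field(default_factory=dict)

    def add(self, reason: str, n: int = 1) -> None:
        if n:
            self.reasons[reason] = self.reasons.get(reason, 0) + int(n)

    @property
    def total(self) -> int:
        return sum(self.reasons.values())


def _validate_events(
    df: pd.DataFrame,
    screen: ScreenGeometry | None,
    log: RejectionLog,
) -> pd.DataFrame:
    """Drop rows violating the fixation invariants, tallying reasons."""
    keep = pd.Series(True, index=df.index)

    bad = ~df["eye"].isin(["L", "R"])
    log.add("invalid_eye", int((bad & keep).sum()))
    keep &= ~bad

    for col in _REQUIRED_NUMERIC:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        log.add(f"non_numeric_{col}", int((bad & keep).sum()))
        keep &= ~bad
        df[col] = vals

    # integral-time requirement on the tracker grid
    for col in ("start_ms", "end_ms"):
        with np.errstate(invalid="ignore"):
            frac = df[col] % 1 != 0
        bad = frac.fillna(False)
        log.add(f"fractional_{col}", int((bad & keep).sum()))
        keep &= ~bad

    bad = ~(df["end_ms"] > df["start_ms"])
    log.add("end_not_after_start", int((bad & keep).sum()))
    keep &= ~bad

    if screen is not None:
        bad = ~(
            (df["x_px"] >= 0)
            & (df["x_px"] <= screen.width_px)
            & (df["y_px"] >= 0)
            & (df["y_px"] <= screen.height_px)
        )
        bad = bad.fillna(True)
        log.add("off_screen", int((bad & keep).sum()))
        keep &= ~bad

    out = df.loc[keep].copy()
    out["start_ms"] = out["start_ms"].astype(np.int64)
    out["end_ms"] = out["end_ms"].astype(np.int64)
    return out


def read_fixation_csv(
    path: str | Path,
    *,
    screen: ScreenGeometry | None = None,
    drop_blinks: bool = True,
) -> tuple[pd.DataFrame, RejectionLog]:
    """Read the canonical fixation CSV.

    Rows violating the event invariants (non-numeric fields, fractional
    times, ``end_ms <= start_ms``, off-screen coordinates when *screen* is
    given) are rejected and counted in the returned :class:`RejectionLog`.
    A missing required column is a hard error.  Rows flagged in an optional
    ``blink`` column are dropped when *drop_blinks* (the default).

    Returns the events sorted by (participant_id, eye, start_ms).
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "article_id": str, "page_id": str})
    missing = [c for c in FIXATION_COLUMNS if c != "group" and c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if "group" not in df.columns:
        df["group"] = ""
    log = RejectionLog()
    if "blink" in df.columns:
        if drop_blinks:
            flagged = df["blink"].fillna(0).astype(bool)
            log.add("blink", int(flagged.sum()))
            df = df.loc[~flagged]
        df = df.drop(columns=["blink"])
    df = _validate_events(df, screen, log)
    df = df.sort_values(["participant_id", "eye", "start_ms"], kind="mergesort")
    return df[FIXATION_COLUMNS].reset_index(drop=True), log


_EFIX_RE = re.compile(
    r"^EFIX\s+([LR])\s+(\S+)\s+(\S+)\s+(\S+)\s+(\S+)\s+(\S+)\s+(\S+)\s*$"
)
_MSG_RE = re.compile(r"^MSG\s+(\S+)\s+(.*)$")


def read_eyelink_asc(
    path: str | Path,
    page_message_pattern: str = "PAGE",
    *,
    participant_id: str = "P1",
    group: str = "",
    article_id: str = "A1",
    screen: ScreenGeometry | None = None,
) -> tuple[pd.DataFrame, RejectionLog]:
    """Parse fixation events from an EyeLink ASCII export.

    Only the ``EFIX`` (fixation end) and ``MSG`` records are consumed.  An
    ``EFIX <eye> <start> <end> <dur> <x> <y> <pupil>`` line yields one
    monocular fixation.  ``MSG`` lines whose text starts with
    *page_message_pattern* delimit pages: the remainder of the message (or a
    running index when empty) becomes ``page_id``.  Events before the first
    page message are dropped and counted; malformed ``EFIX`` lines are
    skipped and counted; a file with no ``EFIX`` line at all is an error.
    """
    log = RejectionLog()
    rows: list[dict] = []
    page_id: str | None = None
    page_counter = 0
    n_efix_lines = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            m = _MSG_RE.match(line)
            if m:
                text = m.group(2).strip()
                if text.startswith(page_message_pattern):
                    page_counter += 1
                    rest = text[len(page_message_pattern):].strip()
                    page_id = rest if rest else str(page_counter)
                continue
            if not line.startswith("EFIX"):
                continue
            n_efix_lines += 1
            m = _EFIX_RE.match(line)
            if m is None:
                log.add("malformed_efix")
                continue
            eye, start, end, _dur, x, y, _pupil = m.groups()
            try:
                row = {
                    "eye": eye,
                    "start_ms": float(start),
                    "end_ms": float(end),
                    "x_px": float(x),
                    "y_px": float(y),
                }
            except ValueError:
                log.add("malformed_efix")
                continue
            if page_id is None:
                log.add("outside_page")
                continue
            row.update(
                participant_id=participant_id,
                group=group,
                article_id=article_id,
                page_id=page_id,
            )
            rows.append(row)
    if n_efix_lines == 0:
        raise ValueError(f"no EFIX records found in {path}")
    df = pd.DataFrame(rows, columns=FIXATION_COLUMNS)
    df = _validate_events(df, screen, log)
    df = df.sort_values(["participant_id", "eye", "start_ms"], kind="mergesort")
    return df[FIXATION_COLUMNS].reset_index(drop=True), log


# ---------------------------------------------------------------------------
# writers

_FLOAT_FMT = "%.3f"


def _write_csv(df: pd.DataFrame, path: str | Path, columns: list[str]) -> None:
    if len(df) == 0:
        warnings.warn(f"writing header-only file: {path}", stacklevel=3)
        df = pd.DataFrame(columns=columns)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, columns=columns, float_format=_FLOAT_FMT)


def write_fixations_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write fixation events in the canonical CSV dialect."""
    _write_csv(df, path, FIXATION_COLUMNS)


def write_pairs_csv(pairs: pd.DataFrame, path: str | Path) -> None:
    """Write binocular fixation pairs; column order is deterministic."""
    from .pairing import PAIR_COLUMNS

    cols = [c for c in PAIR_COLUMNS if c in pairs.columns]
    cols += [c for c in ("type", "region") if c in pairs.columns]
    _write_csv(pairs, path, cols)


def write_counts_csv(counts: pd.DataFrame, path: str | Path) -> None:
    """Write the per-cell count table used by the models."""
    cols = ["participant_id", "group", "article_id", "page_id", "region", "type", "count"]
    _write_csv(counts, path, [c for c in cols if c in counts.columns])


def write_fit_json(obj, path: str | Path) -> None:
    """Serialize a fit result (or any mapping) to JSON at fixed precision."""
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
        fh.write("\n")
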