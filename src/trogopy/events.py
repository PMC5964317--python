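"""Typed event tables shared by the simulator (ground truth) and detectors.

An :class:`EventLog` is a thin wrapper over a pandas DataFrame with the
mandatory columns ``event_id, event_type, object_ids, onset_frame,
offset_frame`` plus free-form per-event measurements. Measurement column
names carry a unit suffix (``length_um``, ``latency_s``, ...) so values are
unambiguous on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd

MANDATORY_COLUMNS = ("event_id", "event_type", "object_ids", "onset_frame", "offset_frame")

#: recognised event types; extension/retraction cover process motility
EVENT_TYPES = frozenset(
    {
        "contact",
        "engulfment",
        "shf",
        "disappearance",
        "appearance",
        "inclusion",
        "extension",
        "retraction",
    }
)


@dataclass
class EventLog:
    """Table of interaction events with measurements.

    ``object_ids`` is stored as a ``;``-joined string of scene object ids
    so the table round-trips through CSV without ambiguity.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.table.empty and not len(self.table.columns):
            self.table = pd.DataFrame(
                {c: pd.Series(dtype=t) for c, t in zip(
                    MANDATORY_COLUMNS, ["int64", "object", "object", "int64", "int64"]
                )}
            )
        missing = [c for c in MANDATORY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"EventLog missing mandatory columns: {missing}")
        self._validate()

    def _validate(self) -> None:
        t = self.table
        if t.empty:
            return
        if t["event_id"].duplicated().any():
            dupes = t.loc[t["event_id"].duplicated(), "event_id"].tolist()
            raise ValueError(f"duplicate event_id values: {dupes}")
        bad = t.index[t["onset_frame"] > t["offset_frame"]]
        if len(bad):
            raise ValueError(
                f"onset_frame > offset_frame at row(s) {list(bad)}"
            )
        unknown = set(t["event_type"]) - EVENT_TYPES
        if unknown:
            raise ValueError(f"unknown event_type values: {sorted(unknown)}")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[Mapping[str, Any]]) -> "EventLog":
        rows = []
        for rec in records:
            row = dict(rec)
            oids = row.get("object_ids", "")
            if isinstance(oids, (list, tuple)):
                row["object_ids"] = ";".join(str(o) for o in oids)
            rows.append(row)
        if not rows:
            return cls()
        df = pd.DataFrame(rows)
        # stable column order: mandatory first, measurements sorted
        extra = sorted(c for c in df.columns if c not in MANDATORY_COLUMNS)
        df = df[[*MANDATORY_COLUMNS, *extra]]
        return cls(df)

    # -- queries -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.table)

    def of_type(self, event_type: str) -> pd.DataFrame:
        return self.table[self.table["event_type"] == event_type]

    @property
    def measurement_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in MANDATORY_COLUMNS]

    def equals(self, other: "EventLog") -> bool:
        a = self.table.reset_index(drop=True)
        b = other.table.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        if a.empty:
            return True
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False, check_exact=False)
        except AssertionError:
            return False
        return True


def write_events(log: EventLog, path: str | Path) -> None:
    """Write an event log to CSV (UTF-8, comma separated, sorted measurement
    columns, 0-based frames)."""
    df = log.table
    extra = sorted(c for c in df.columns if c not in MANDATORY_COLUMNS)
    df = df[[*MANDATORY_COLUMNS, *extra]] if len(df.columns) else df
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> EventLog:
    """Read an event-table CSV; unknown extra columns become measurements."""
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    if df.empty:
        return EventLog()
    df["object_ids"] = df["object_ids"].fillna("").astype(str)
    bad = df.index[df["onset_frame"] > df["offset_frame"]]
    if len(bad):
        raise ValueError(f"{path}: onset_frame > offset_frame at row {bad[0] + 2}")
    return EventLog(df)
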