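"""Ingest server: validate, deduplicate and store minute records.

Records are keyed by ``(device_id, minute timestamp)``.  Ingest is
idempotent: a re-sent duplicate is acknowledged as success without mutating
the store, which is what turns the client's at-least-once retransmission
into an effectively exactly-once stored dataset.  Invalid records are
rejected with reasons but still *acknowledged*, so a client never retries
poison data forever.

Time-range queries use half-open intervals ``[t0, t1)`` throughout, and gap
reports are computed against the instrument's fixed one-record-per-minute
cadence.
"""

from __future__ import annotations

import json
import sqlite3
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone
from typing import Protocol

from .protocol import (
    ParticleRecord,
    RecordSeries,
    RecordValidationError,
    floor_to_minute,
)
from .telemetry import Ack, TransmissionBatch

MINUTE = timedelta(minutes=1)


@dataclass(frozen=True)
class GapRun:
    """A maximal run of consecutive expected-but-absent minutes."""

    start: datetime
    length_min: int


class StoreBackend(Protocol):
    def insert(self, device: str, ts: datetime, small: int, large: int) -> bool: ...
    def contains(self, device: str, ts: datetime) -> bool: ...
    def query(self, device: str, t0: datetime, t1: datetime) -> list[tuple[datetime, int, int]]: ...
    def count(self, device: str) -> int: ...


class MemoryStore:
    """Default embedded store: a dict keyed by (device, minute)."""

    def __init__(self) -> None:
        self._rows: dict[tuple[str, datetime], tuple[int, int]] = {}

    def insert(self, device: str, ts: datetime, small: int, large: int) -> bool:
        key = (device, ts)
        if key in self._rows:
            return False
        self._rows[key] = (small, large)
        return True

    def contains(self, device: str, ts: datetime) -> bool:
        return (device, ts) in self._rows

    def query(self, device: str, t0: datetime, t1: datetime) -> list[tuple[datetime, int, int]]:
        out = [
            (ts, sm, lg)
            for (dev, ts), (sm, lg) in self._rows.items()
            if dev == device and t0 <= ts < t1
        ]
        out.sort()
        return out

    def count(self, device: str) -> int:
        return sum(1 for (dev, _) in self._rows if dev == device)


class SqliteStore:
    """Single-file embedded store with the same narrow interface."""

    def __init__(self, path: str = ":memory:") -> None:
        self._conn = sqlite3.connect(path)
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS records ("
            " device TEXT NOT NULL, ts TEXT NOT NULL,"
            " small INTEGER NOT NULL, large INTEGER NOT NULL,"
            " PRIMARY KEY (device, ts))"
        )
        self._conn.commit()

    @staticmethod
    def _key(ts: datetime) -> str:
        return ts.strftime("%Y-%m-%dT%H:%M:%SZ")

    def insert(self, device: str, ts: datetime, small: int, large: int) -> bool:
        cur = self._conn.execute(
            "INSERT OR IGNORE INTO records (device, ts, small, large) VALUES (?,?,?,?)",
            (device, self._key(ts), small, large),
        )
        self._conn.commit()
        return cur.rowcount == 1

    def contains(self, device: str, ts: datetime) -> bool:
        row = self._conn.execute(
            "SELECT 1 FROM records WHERE device=? AND ts=?", (device, self._key(ts))
        ).fetchone()
        return row is not None

    def query(self, device: str, t0: datetime, t1: datetime) -> list[tuple[datetime, int, int]]:
        rows = self._conn.execute(
            "SELECT ts, small, large FROM records WHERE device=? AND ts>=? AND ts<? ORDER BY ts",
            (device, self._key(t0), self._key(t1)),
        ).fetchall()
        return [
            (floor_to_minute(datetime.fromisoformat(ts)), sm, lg) for ts, sm, lg in rows
        ]

    def count(self, device: str) -> int:
        (n,) = self._conn.execute(
            "SELECT COUNT(*) FROM records WHERE device=?", (device,)
        ).fetchone()
        return n


class IngestServer:
    """Receives transmission batches and serves queries and gap reports."""

    def __init__(self, store: StoreBackend | None = None) -> None:
        self.store: StoreBackend = store if store is not None else MemoryStore()
        self.n_accepted = 0
        self.n_duplicate = 0
        self.n_rejected = 0

    # -- ingest ---------------------------------------------------------

    def ingest_batch(self, batch: TransmissionBatch) -> Ack:
        """Insert new keys, acknowledge duplicates, reject invalid records."""
        accepted: list[datetime] = []
        duplicate: list[datetime] = []
        rejected: list[datetime] = []
        for r in batch.records:
            if self.store.insert(r.device_id, r.timestamp, r.small_count, r.large_count):
                accepted.append(r.timestamp)
            else:
                duplicate.append(r.timestamp)
        self.n_accepted += len(accepted)
        self.n_duplicate += len(duplicate)
        self.n_rejected += len(rejected)
        return Ack(tuple(accepted), tuple(duplicate), tuple(rejected))

    def ingest_payload(self, payload: str | bytes) -> Ack:
        """Ingest the JSON wire form; the path every transport goes through.

        A malformed envelope rejects the whole batch with an error ack (the
        client treats it as acknowledged and does not retry).  Individually
        invalid records are rejected with their keys; valid siblings are
        still accepted.
        """
        try:
            doc = json.loads(payload)
            device = doc["device_id"]
            raw = doc["records"]
            if not isinstance(device, str) or not isinstance(raw, list) or not raw:
                raise ValueError("bad envelope")
        except (ValueError, KeyError, TypeError) as exc:
            return Ack(error=f"malformed batch: {exc}")
        accepted: list[datetime] = []
        duplicate: list[datetime] = []
        rejected: list[datetime] = []
        for item in raw:
            try:
                ts = floor_to_minute(datetime.fromisoformat(item["ts"]))
                rec = ParticleRecord(device, ts, item["small"], item["large"])
            except (RecordValidationError, ValueError, KeyError, TypeError):
                try:
                    ts = floor_to_minute(datetime.fromisoformat(item["ts"]))
                    rejected.append(ts)
                except Exception:
                    pass  # no usable key to acknowledge
                continue
            if self.store.insert(rec.device_id, rec.timestamp, rec.small_count, rec.large_count):
                accepted.append(rec.timestamp)
            else:
                duplicate.append(rec.timestamp)
        self.n_accepted += len(accepted)
        self.n_duplicate += len(duplicate)
        self.n_rejected += len(rejected)
        return Ack(tuple(accepted), tuple(duplicate), tuple(rejected))

    # -- queries --------------------------------------------------------

    def query_series(self, device_id: str, t0: datetime, t1: datetime) -> RecordSeries:
        """Sorted minute records in ``[t0, t1)``; unknown device → empty."""
        t0, t1 = floor_to_minute(t0), floor_to_minute(t1)
        if t0 > t1:
            raise ValueError("t0 must not exceed t1")
        rows = self.store.query(device_id, t0, t1)
        return RecordSeries(
            device_id,
            [ParticleRecord(device_id, ts, sm, lg) for ts, sm, lg in rows],
        )

    def gap_report(self, device_id: str, t0: datetime, t1: datetime) -> list[GapRun]:
        """Maximal runs of missing minutes on the 1/min grid over ``[t0, t1)``."""
        t0, t1 = floor_to_minute(t0), floor_to_minute(t1)
        if t0 > t1:
            raise ValueError("t0 must not exceed t1")
        held = {ts for ts, _, _ in self.store.query(device_id, t0, t1)}
        runs: list[GapRun] = []
        run_start: datetime | None = None
        run_len = 0
        t = t0
        while t < t1:
            if t not in held:
                if run_start is None:
                    run_start, run_len = t, 0
                run_len += 1
            elif run_start is not None:
                runs.append(GapRun(run_start, run_len))
                run_start = None
            t += MINUTE
        if run_start is not None:
            runs.append(GapRun(run_start, run_len))
        return runs


class LocalTransport:
    """In-process transport that still exercises the JSON wire path."""

    def __init__(self, server: IngestServer):
        self.server = server

    def send(self, batch: TransmissionBatch, timeout_s: float) -> Ack:
        return self.server.ingest_payload(batch.to_payload())
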