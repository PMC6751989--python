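"""Store-and-forward telemetry client.

Each minute record is handed to the client, which attempts delivery to the
server within a bounded timeout.  Records the server does not acknowledge
are persisted in a local buffer and retransmitted on later flushes, giving
an at-least-once contract; the server's minute-key deduplication turns that
into effectively exactly-once storage.  A ``legacy_mode`` flag disables the
buffer entirely — each record gets exactly one delivery attempt and is
dropped on failure — reproducing the behaviour of a first-generation field
deployment in which transient mobile-network failures translated directly
into lost minutes.

The buffer is an sqlite file so pending records survive a process restart
(mains-powered monitors in homes get unplugged).  Default capacity is 9000
records, a little over six days of minutes, so the client never holds less
history than the instrument's own onboard memory.
"""

from __future__ import annotations

import json
import logging
import sqlite3
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Protocol, Sequence

from .protocol import ParticleRecord, floor_to_minute

logger = logging.getLogger(__name__)

DEFAULT_TIMEOUT_S = 10.0
DEFAULT_BATCH_SIZE = 60
DEFAULT_CAPACITY = 9000


class TransportError(Exception):
    """Delivery attempt failed (connection refused, outage, dropped request)."""


class TransportTimeout(TransportError):
    """The request exceeded its timeout budget; delivery state unknown."""


@dataclass(frozen=True)
class TransmissionBatch:
    """Records in flight to the server in one request."""

    device_id: str
    records: tuple[ParticleRecord, ...]
    attempt_count: int = 0
    created_at: datetime | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a transmission batch must be non-empty")
        for r in self.records:
            if r.device_id != self.device_id:
                raise ValueError(
                    f"batch device {self.device_id!r} contains record for {r.device_id!r}"
                )

    def to_payload(self) -> str:
        """JSON wire form: ``{device_id, records: [{ts, small, large}]}``."""
        return json.dumps(
            {
                "device_id": self.device_id,
                "records": [
                    {
                        "ts": r.timestamp.strftime("%Y-%m-%dT%H:%M:%SZ"),
                        "small": r.small_count,
                        "large": r.large_count,
                    }
                    for r in self.records
                ],
            }
        )


@dataclass(frozen=True)
class Ack:
    """Server acknowledgement: disposition of every key in the batch.

    Rejected keys are acknowledged (the client must not retry poison data).
    """

    accepted: tuple[datetime, ...] = ()
    duplicate: tuple[datetime, ...] = ()
    rejected: tuple[datetime, ...] = ()
    error: str | None = None

    @property
    def acknowledged(self) -> tuple[datetime, ...]:
        return self.accepted + self.duplicate + self.rejected


class Transport(Protocol):
    """Anything that can carry a batch to the server and return its ack."""

    def send(self, batch: TransmissionBatch, timeout_s: float) -> Ack: ...


class PersistentBuffer:
    """Sqlite-backed pending-record store keyed by minute timestamp.

    Oldest records are evicted when capacity is exceeded (an eviction
    counter is kept).  Use path ``":memory:"`` for an ephemeral buffer.
    """

    def __init__(self, path: str = ":memory:", capacity: int = DEFAULT_CAPACITY):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._conn = sqlite3.connect(path)
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS pending ("
            " device TEXT NOT NULL, ts TEXT NOT NULL,"
            " small INTEGER NOT NULL, large INTEGER NOT NULL,"
            " PRIMARY KEY (device, ts))"
        )
        self._conn.execute(
            "CREATE TABLE IF NOT EXISTS meta (key TEXT PRIMARY KEY, value INTEGER)"
        )
        self._conn.execute(
            "INSERT OR IGNORE INTO meta (key, value) VALUES ('evictions', 0)"
        )
        self._conn.commit()

    def __len__(self) -> int:
        (n,) = self._conn.execute("SELECT COUNT(*) FROM pending").fetchone()
        return n

    @property
    def eviction_count(self) -> int:
        (n,) = self._conn.execute(
            "SELECT value FROM meta WHERE key='evictions'"
        ).fetchone()
        return n

    def enqueue(self, record: ParticleRecord) -> None:
        """Append a record; re-enqueueing an existing minute is a no-op."""
        self._conn.execute(
            "INSERT OR IGNORE INTO pending (device, ts, small, large) VALUES (?,?,?,?)",
            (
                record.device_id,
                record.timestamp.strftime("%Y-%m-%dT%H:%M:%SZ"),
                record.small_count,
                record.large_count,
            ),
        )
        overflow = len(self) - self.capacity
        if overflow > 0:
            self._conn.execute(
                "DELETE FROM pending WHERE (device, ts) IN "
                "(SELECT device, ts FROM pending ORDER BY ts LIMIT ?)",
                (overflow,),
            )
            self._conn.execute(
                "UPDATE meta SET value = value + ? WHERE key='evictions'", (overflow,)
            )
            logger.warning("buffer full: evicted %d oldest record(s)", overflow)
        self._conn.commit()

    def pending(self, device_id: str) -> list[ParticleRecord]:
        rows = self._conn.execute(
            "SELECT ts, small, large FROM pending WHERE device=? ORDER BY ts",
            (device_id,),
        ).fetchall()
        return [
            ParticleRecord(
                device_id,
                floor_to_minute(datetime.fromisoformat(ts)),
                small,
                large,
            )
            for ts, small, large in rows
        ]

    def remove(self, device_id: str, timestamps: Iterable[datetime]) -> None:
        self._conn.executemany(
            "DELETE FROM pending WHERE device=? AND ts=?",
            [(device_id, t.strftime("%Y-%m-%dT%H:%M:%SZ")) for t in timestamps],
        )
        self._conn.commit()

    def close(self) -> None:
        self._conn.close()


@dataclass
class FlushReport:
    delivered: list[datetime] = field(default_factory=list)
    failed: list[datetime] = field(default_factory=list)
    rejected: list[datetime] = field(default_factory=list)


@dataclass
class MinuteOutcome:
    timestamp: datetime
    delivered_now: bool
    pending_after: int


@dataclass
class SessionLog:
    device_id: str
    minutes: list[MinuteOutcome] = field(default_factory=list)

    @property
    def n_delivered(self) -> int:
        return sum(m.delivered_now for m in self.minutes)


class TelemetryClient:
    """Per-device delivery loop: submit each minute record, flush pending.

    With ``legacy_mode=True`` the buffer is bypassed: one delivery attempt
    per record, failures dropped.
    """

    def __init__(
        self,
        device_id: str,
        transport: Transport,
        buffer: PersistentBuffer | None = None,
        *,
        timeout_s: float = DEFAULT_TIMEOUT_S,
        batch_size: int = DEFAULT_BATCH_SIZE,
        legacy_mode: bool = False,
    ):
        self.device_id = device_id
        self.transport = transport
        self.buffer = buffer if buffer is not None else PersistentBuffer()
        self.timeout_s = timeout_s
        self.batch_size = max(1, batch_size)
        self.legacy_mode = legacy_mode
        self.n_dropped = 0  # legacy-mode drops

    def _attempt(self, records: Sequence[ParticleRecord]) -> Ack | None:
        batch = TransmissionBatch(self.device_id, tuple(records))
        try:
            return self.transport.send(batch, self.timeout_s)
        except TransportError as exc:
            logger.debug("delivery attempt failed: %s", exc)
            return None

    def submit(self, record: ParticleRecord) -> bool:
        """Hand one record to the client; returns True if delivered now."""
        if self.legacy_mode:
            ack = self._attempt([record])
            ok = ack is not None and record.timestamp in ack.acknowledged
            if not ok:
                self.n_dropped += 1
            return ok
        self.buffer.enqueue(record)
        return False

    def flush(self) -> FlushReport:
        """Attempt every pending batch once; remove acknowledged records."""
        report = FlushReport()
        pending = self.buffer.pending(self.device_id)
        for i in range(0, len(pending), self.batch_size):
            chunk = pending[i : i + self.batch_size]
            ack = self._attempt(chunk)
            if ack is None:
                report.failed.extend(r.timestamp for r in chunk)
                continue
            if ack.error is not None:
                # Whole-batch parse rejection: acknowledged as poison, never retried.
                logger.warning("server rejected batch as malformed: %s", ack.error)
                self.buffer.remove(self.device_id, [r.timestamp for r in chunk])
                report.rejected.extend(r.timestamp for r in chunk)
                continue
            acked = set(ack.acknowledged)
            self.buffer.remove(self.device_id, acked)
            report.delivered.extend(t for t in (ack.accepted + ack.duplicate))
            report.rejected.extend(ack.rejected)
            report.failed.extend(r.timestamp for r in chunk if r.timestamp not in acked)
        return report

    def run_session(
        self,
        source: Iterable[ParticleRecord],
        clock: "SimulatedClock | None" = None,
    ) -> SessionLog:
        """Consume a minute-record source until exhaustion.

        Each yielded record is submitted and (in buffered mode) a flush is
        attempted, so pending records from earlier failed minutes are
        retried every minute.  ``clock``, when given, is advanced to each
        record's timestamp before the delivery attempt — the seam that lets
        simulated transports schedule outages on the session timeline.
        """
        log = SessionLog(self.device_id)
        for record in source:
            if clock is not None:
                clock.now = record.timestamp
            if self.legacy_mode:
                ok = self.submit(record)
                log.minutes.append(MinuteOutcome(record.timestamp, ok, 0))
            else:
                self.submit(record)
                report = self.flush()
                log.minutes.append(
                    MinuteOutcome(
                        record.timestamp,
                        record.timestamp in report.delivered,
                        len(self.buffer),
                    )
                )
        if not self.legacy_mode:
            self.flush()
        return log


@dataclass
class SimulatedClock:
    """Session-timeline clock shared between the run loop and transports."""

    now: datetime = datetime(1970, 1, 1, tzinfo=timezone.utc)
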