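"""Minute-record wire format of the Dylos DC1700 optical particle counter.

The DC1700 reports two particle-count channels once per minute over its
RS232 serial port: particles larger than 0.5 µm ("small"/total channel) and
particles larger than 2.5 µm ("large" channel), both per 0.01 cubic feet of
sampled air.  Each serial line carries the two counts divided by a fixed
scale (100 on the stock firmware) as ``<total>,<large>`` followed by an end
of line.  This module parses and serializes that line format, and reads and
writes the timestamped CSV interchange files used everywhere else in the
package (memory dumps downloaded from the instrument, simulator output,
server exports).

Timestamps are client-side, UTC and floored to the minute: the instrument
emits exactly one record per minute and the whole pipeline dedupes on
minute keys.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

#: Divisor applied by the instrument firmware before printing counts on the
#: serial line.  Exposed as a parameter because firmware revisions differ.
DEFAULT_COUNT_SCALE = 100

_SERIAL_RE = re.compile(r"^\s*(\d+)\s*,\s*(\d+)\s*$")

#: Timestamp layouts accepted in CSV files: the package's own ISO-8601
#: interchange form, plus the ``MM/DD/YY HH:MM`` layout of conventional
#: instrument memory exports.
DUMP_DATE_FORMATS: tuple[str, ...] = ("%m/%d/%y %H:%M", "%m/%d/%Y %H:%M")

CSV_HEADER = "timestamp,small_count,large_count"


class ProtocolError(ValueError):
    """Base class for wire-format and interchange-file errors."""


class SerialParseError(ProtocolError):
    """A serial line was not two comma-separated non-negative integers."""


class RecordValidationError(ProtocolError):
    """A record violates a physical invariant (e.g. large > small)."""


class DumpFormatError(ProtocolError):
    """A memory-dump file yielded no parseable records."""


def floor_to_minute(ts: datetime) -> datetime:
    """Normalise a timestamp to a UTC instant with zero seconds.

    Naive datetimes are taken to already be UTC; aware ones are converted.
    """
    if ts.tzinfo is None:
        ts = ts.replace(tzinfo=timezone.utc)
    else:
        ts = ts.astimezone(timezone.utc)
    return ts.replace(second=0, microsecond=0)


@dataclass(frozen=True)
class ParticleRecord:
    """One minute of particle counts from one device.

    Counts are in instrument units: particles per 0.01 ft³ of air, on the
    small (>0.5 µm, total) and large (>2.5 µm) channels.
    """

    device_id: str
    timestamp: datetime
    small_count: int
    large_count: int

    def __post_init__(self) -> None:
        if not self.device_id:
            raise RecordValidationError("device_id must be a non-empty token")
        ts = self.timestamp
        if ts.tzinfo is None or ts.utcoffset() != timezone.utc.utcoffset(None):
            raise RecordValidationError(f"timestamp must be UTC-aware: {ts!r}")
        if ts.second != 0 or ts.microsecond != 0:
            raise RecordValidationError(
                f"timestamp must be minute-aligned (zero seconds): {ts.isoformat()}"
            )
        for name in ("small_count", "large_count"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise RecordValidationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.large_count > self.small_count:
            raise RecordValidationError(
                f"large_count {self.large_count} exceeds small_count {self.small_count} "
                "(the >2.5 µm channel is a subset of the >0.5 µm channel)"
            )

    @property
    def minute_key(self) -> tuple[str, datetime]:
        return (self.device_id, self.timestamp)


@dataclass
class RecordSeries:
    """A sorted, duplicate-free minute series for a single device."""

    device_id: str
    records: list[ParticleRecord] = field(default_factory=list)
    n_skipped: int = field(default=0, compare=False)
    n_duplicates: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        for i, r in enumerate(self.records):
            if r.device_id != self.device_id:
                raise RecordValidationError(
                    f"record {i} belongs to device {r.device_id!r}, series is {self.device_id!r}"
                )
            if i and self.records[i - 1].timestamp >= r.timestamp:
                raise RecordValidationError(
                    "series timestamps must be strictly increasing "
                    f"(violated at index {i}: {r.timestamp.isoformat()})"
                )

    @classmethod
    def from_records(
        cls, device_id: str, records: Iterable[ParticleRecord], n_skipped: int = 0
    ) -> "RecordSeries":
        """Sort and de-duplicate; the first occurrence of a minute wins."""
        seen: dict[datetime, ParticleRecord] = {}
        dups = 0
        for r in records:
            if r.timestamp in seen:
                dups += 1
                logger.warning(
                    "duplicate minute %s for device %s: keeping first occurrence",
                    r.timestamp.isoformat(),
                    device_id,
                )
                continue
            seen[r.timestamp] = r
        ordered = [seen[t] for t in sorted(seen)]
        return cls(device_id, ordered, n_skipped=n_skipped, n_duplicates=dups)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ParticleRecord]:
        return iter(self.records)

    def timestamps(self) -> list[datetime]:
        return [r.timestamp for r in self.records]


def parse_serial_line(
    line: str | bytes,
    device_id: str,
    timestamp: datetime,
    *,
    count_scale: int = DEFAULT_COUNT_SCALE,
) -> ParticleRecord:
    """Parse one serial line into a :class:`ParticleRecord`.

    The two integers on the line are each multiplied by ``count_scale`` to
    recover instrument-unit counts; ``timestamp`` (arrival time at the
    client) is floored to the minute.

    Raises
    ------
    SerialParseError
        if the line is not two comma-separated non-negative integers.
    RecordValidationError
        if the scaled counts violate ``large <= small``.
    """
    if isinstance(line, bytes):
        try:
            line = line.decode("ascii")
        except UnicodeDecodeError as exc:
            raise SerialParseError(f"undecodable serial bytes: {line!r}") from exc
    m = _SERIAL_RE.match(line.rstrip("\r\n"))
    if m is None:
        raise SerialParseError(f"malformed serial line: {line!r}")
    small = int(m.group(1)) * count_scale
    large = int(m.group(2)) * count_scale
    return ParticleRecord(device_id, floor_to_minute(timestamp), small, large)


def format_serial_line(
    record: ParticleRecord, *, count_scale: int = DEFAULT_COUNT_SCALE
) -> str:
    """Serialize a record back to the instrument's line format.

    Counts that are not multiples of the scale are rounded half-up to the
    nearest scale unit (a lossy step, logged); scale-divisible records
    round-trip exactly through :func:`parse_serial_line`.
    """
    out = []
    for v in (record.small_count, record.large_count):
        q, r = divmod(v, count_scale)
        if r:
            q = (v + count_scale // 2) // count_scale
            logger.warning(
                "count %d not divisible by scale %d: rounded half-up to %d00-unit value %d",
                v,
                count_scale,
                count_scale,
                q,
            )
        out.append(q)
    return f"{out[0]},{out[1]}"


def _parse_dump_timestamp(text: str) -> datetime:
    text = text.strip()
    try:
        return floor_to_minute(datetime.fromisoformat(text))
    except ValueError:
        pass
    for fmt in DUMP_DATE_FORMATS:
        try:
            return floor_to_minute(datetime.strptime(text, fmt))
        except ValueError:
            continue
    raise SerialParseError(f"unparseable timestamp: {text!r}")


def _looks_like_header(line: str) -> bool:
    first = line.split(",", 1)[0].strip().lower()
    return first in {"timestamp", "date", "date/time", "time"}


def read_memory_dump(path: str | Path, device_id: str) -> RecordSeries:
    """Read a timestamped CSV log (``timestamp,small,large`` per line).

    Accepts the package's ISO-8601 interchange files and conventional
    ``MM/DD/YY HH:MM`` instrument memory exports; an optional header line is
    skipped.  Unreadable lines are skipped with a warning (counted on the
    returned series); duplicated minutes keep the first occurrence.

    Raises
    ------
    DumpFormatError
        if the file contains no parseable record at all.
    """
    path = Path(path)
    records: list[ParticleRecord] = []
    skipped = 0
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if lineno == 1 and _looks_like_header(line):
                continue
            parts = [p.strip() for p in line.split(",")]
            try:
                if len(parts) != 3:
                    raise SerialParseError(f"expected 3 fields, got {len(parts)}")
                ts = _parse_dump_timestamp(parts[0])
                records.append(
                    ParticleRecord(device_id, ts, int(parts[1]), int(parts[2]))
                )
            except (ProtocolError, ValueError) as exc:
                skipped += 1
                logger.warning("%s:%d: skipping unreadable line (%s)", path, lineno, exc)
    if not records:
        raise DumpFormatError(f"{path}: no parseable records")
    return RecordSeries.from_records(device_id, records, n_skipped=skipped)


def write_series_csv(series: RecordSeries, path: str | Path) -> None:
    """Write a series as interchange CSV; round-trips with :func:`read_memory_dump`."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(CSV_HEADER + "\n")
        for r in series:
            fh.write(
                f"{r.timestamp.strftime('%Y-%m-%dT%H:%M:%SZ')},{r.small_count},{r.large_count}\n"
            )


def records_from_rows(
    device_id: str, rows: Sequence[tuple[datetime, int, int]]
) -> RecordSeries:
    """Build a series from (timestamp, small, large) tuples (test/sim helper)."""
    return RecordSeries.from_records(
        device_id,
        (ParticleRecord(device_id, floor_to_minute(t), s, l) for t, s, l in rows),
    )
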