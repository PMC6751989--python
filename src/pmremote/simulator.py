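"""Synthetic indoor particle streams and fault-injected transports.

The whole pipeline — serial protocol, calibration, telemetry, ingest — is
testable without an instrument or a mobile network by simulating both
sides:

* **Indoor PM2.5.**  A minute-resolution concentration series built as a
  non-smoking background plus episodic smoking events.  Each event raises
  the concentration instantaneously by its peak and decays exponentially
  with a configurable half-life — the standard single-compartment picture
  of indoor aerosol removal by ventilation and deposition.  Multiplicative
  lognormal noise keeps the series non-negative and right-skewed, as real
  indoor PM is.  Counts are manufactured by inverting the calibration
  model, so simulator and calibration agree by construction.

* **Unreliable transport.**  Scheduled outage windows (every request inside
  fails), independent per-request drops with probability ``p``, and a fixed
  per-request latency compared against the client's timeout.  A timed-out
  request is delivered *before* the timeout is raised, which is exactly the
  ambiguity that forces the server-side deduplication contract.

Everything is deterministic given the profile/plan seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone

import numpy as np

from .calibration import CalibrationModel, DEFAULT_MODEL, PmRecord
from .protocol import ParticleRecord, RecordSeries
from .server import IngestServer, LocalTransport
from .telemetry import (
    Ack,
    PersistentBuffer,
    SessionLog,
    SimulatedClock,
    TelemetryClient,
    Transport,
    TransmissionBatch,
    TransportError,
    TransportTimeout,
)

MINUTE = timedelta(minutes=1)
DEFAULT_START = datetime(2017, 7, 1, 0, 0, tzinfo=timezone.utc)


@dataclass(frozen=True)
class SmokingEvent:
    """One indoor smoking episode: instant rise, exponential decay."""

    start_minute: int
    peak_pm: float          # µg/m³ added at the event start
    decay_halflife_min: float = 30.0

    def __post_init__(self) -> None:
        if self.start_minute < 0 or self.peak_pm < 0 or self.decay_halflife_min <= 0:
            raise ValueError(f"invalid event parameters: {self}")


@dataclass(frozen=True)
class SimProfile:
    """Generative settings for one monitored home.

    Defaults describe a multi-day deployment in a non-smoking home:
    background around 7 µg/m³ (the level seen as the median of smoke-free
    homes) with moderate lognormal scatter.  Add events to turn it into a
    smoking home.
    """

    duration_minutes: int = 1440
    baseline_pm: float = 7.0           # µg/m³
    noise_sigma_log: float = 0.3       # sd of log-multiplicative noise
    events: tuple[SmokingEvent, ...] = ()
    seed: int = 0
    device_id: str = "SIM-01"
    start_time: datetime = DEFAULT_START
    large_fraction: float = 0.03       # large-channel share of the total count

    def __post_init__(self) -> None:
        if self.duration_minutes < 1:
            raise ValueError("duration must be >= 1 minute")
        if self.baseline_pm < 0 or self.noise_sigma_log < 0:
            raise ValueError("baseline and noise must be non-negative")
        if not 0 <= self.large_fraction <= 1:
            raise ValueError("large_fraction must be in [0, 1]")
        for e in self.events:
            if e.start_minute >= self.duration_minutes:
                raise ValueError(f"event at minute {e.start_minute} outside duration")


@dataclass(frozen=True)
class OutagePlan:
    """Fault schedule for a session: outage windows, drops, latency.

    ``intervals`` are half-open minute ranges on the session timeline
    during which every request fails.  Outside them each request fails
    independently with probability ``drop_p``; successes take ``latency_s``
    seconds, and a latency above the client's timeout still delivers but
    raises a timeout (delivery state unknown to the client).
    """

    intervals: tuple[tuple[int, int], ...] = ()
    drop_p: float = 0.0
    latency_s: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.drop_p <= 1:
            raise ValueError("drop_p must be in [0, 1]")
        for a, b in self.intervals:
            if a < 0 or b <= a:
                raise ValueError(f"invalid outage interval [{a}, {b})")

    @property
    def total_outage_minutes(self) -> int:
        return sum(b - a for a, b in self.intervals)

    @property
    def longest_outage_minutes(self) -> int:
        return max((b - a for a, b in self.intervals), default=0)


def generate_true_series(
    profile: SimProfile, model: CalibrationModel = DEFAULT_MODEL
) -> tuple[list[PmRecord], RecordSeries]:
    """Generate the minute PM2.5 series and its matching count records.

    PM(t) = [baseline + Σ over events peak·2^(−(t−start)/halflife)] · exp(ε_t)
    with ε_t ~ N(0, noise_sigma_log²).  Counts come from inverting the
    calibration model and rounding to whole count units; the large channel
    is a fixed fraction of the total.  Deterministic given ``profile.seed``.
    """
    n = profile.duration_minutes
    t = np.arange(n, dtype=float)
    pm = np.full(n, profile.baseline_pm)
    for ev in profile.events:
        dt = t - ev.start_minute
        mask = dt >= 0
        pm[mask] += ev.peak_pm * np.power(2.0, -dt[mask] / ev.decay_halflife_min)
    if profile.noise_sigma_log > 0:
        rng = np.random.default_rng(profile.seed)
        pm *= np.exp(rng.normal(0.0, profile.noise_sigma_log, size=n))
    times = [profile.start_time + i * MINUTE for i in range(n)]
    pm_records = [PmRecord(ts, float(v)) for ts, v in zip(times, pm)]
    records = []
    for ts, v in zip(times, pm):
        small = int(round(model.invert(float(v))))
        large = min(small, int(round(small * profile.large_fraction)))
        records.append(ParticleRecord(profile.device_id, ts, small, large))
    return pm_records, RecordSeries(profile.device_id, records)


def smoking_home_profile(seed: int = 0, duration_minutes: int = 1440) -> SimProfile:
    """A home where smoking is permitted: several episodes per day.

    Peaks of a few hundred µg/m³ with ~30 min decay reproduce the
    field-observed contrast of mean far above median (heavy right skew).
    """
    per_day = [
        SmokingEvent(9 * 60, 400.0, 30.0),
        SmokingEvent(13 * 60 + 30, 250.0, 30.0),
        SmokingEvent(18 * 60, 500.0, 30.0),
        SmokingEvent(21 * 60 + 15, 300.0, 30.0),
    ]
    events = tuple(
        SmokingEvent(ev.start_minute + day * 1440, ev.peak_pm, ev.decay_halflife_min)
        for day in range((duration_minutes + 1439) // 1440)
        for ev in per_day
        if ev.start_minute + day * 1440 < duration_minutes
    )
    return SimProfile(
        duration_minutes=duration_minutes,
        baseline_pm=7.0,
        noise_sigma_log=0.3,
        events=events,
        seed=seed,
        device_id=f"SIM-SMOKE-{seed:02d}",
    )


def nonsmoking_home_profile(seed: int = 0, duration_minutes: int = 1440) -> SimProfile:
    """A smoke-free home: background only."""
    return SimProfile(
        duration_minutes=duration_minutes,
        baseline_pm=7.0,
        noise_sigma_log=0.3,
        events=(),
        seed=seed,
        device_id=f"SIM-CLEAN-{seed:02d}",
    )


class FaultyTransport:
    """Wrap a transport with an :class:`OutagePlan` on a simulated clock."""

    def __init__(
        self,
        inner: Transport,
        plan: OutagePlan,
        clock: SimulatedClock,
        session_start: datetime = DEFAULT_START,
    ):
        self.inner = inner
        self.plan = plan
        self.clock = clock
        self.session_start = session_start
        self._rng = np.random.default_rng(plan.seed)
        self.n_requests = 0
        self.n_failed = 0

    def _minute_of(self, now: datetime) -> float:
        return (now - self.session_start) / MINUTE

    def send(self, batch: TransmissionBatch, timeout_s: float) -> Ack:
        self.n_requests += 1
        m = self._minute_of(self.clock.now)
        for a, b in self.plan.intervals:
            if a <= m < b:
                self.n_failed += 1
                raise TransportError(f"scheduled outage [{a}, {b}) at minute {m:g}")
        if self.plan.drop_p > 0 and self._rng.random() < self.plan.drop_p:
            self.n_failed += 1
            raise TransportError("request dropped")
        if self.plan.latency_s > timeout_s:
            # Slow link: the server receives the batch, but the client's
            # timeout fires first — delivery state unknown to the client.
            self.inner.send(batch, timeout_s)
            self.n_failed += 1
            raise TransportTimeout(
                f"latency {self.plan.latency_s}s exceeded timeout {timeout_s}s"
            )
        return self.inner.send(batch, timeout_s)


def faulty_transport(
    plan: OutagePlan,
    server: IngestServer,
    clock: SimulatedClock,
    session_start: datetime = DEFAULT_START,
) -> FaultyTransport:
    """Convenience: fault-inject an in-process transport to ``server``."""
    return FaultyTransport(LocalTransport(server), plan, clock, session_start)


@dataclass
class ScenarioResult:
    """Both sides of an end-to-end simulated session."""

    local: RecordSeries           # what the instrument's memory holds
    server_series: RecordSeries   # what reached the server
    pm: list[PmRecord]
    session: SessionLog
    server: IngestServer = field(repr=False, default=None)  # type: ignore[assignment]


def run_scenario(
    profile: SimProfile,
    plan: OutagePlan,
    *,
    buffering: bool = True,
    model: CalibrationModel = DEFAULT_MODEL,
    timeout_s: float = 10.0,
) -> ScenarioResult:
    """Run simulator → telemetry client → ingest server end to end.

    Returns the locally held series (the instrument-memory reference) and
    the server-held series over the same window, the paired dataset the
    reliability analysis consumes.  ``buffering=False`` is legacy mode: one
    attempt per record, failures lost.
    """
    pm, local = generate_true_series(profile, model)
    server = IngestServer()
    clock = SimulatedClock()
    transport = faulty_transport(plan, server, clock, profile.start_time)
    client = TelemetryClient(
        profile.device_id,
        transport,
        PersistentBuffer(),
        timeout_s=timeout_s,
        legacy_mode=not buffering,
    )
    session = client.run_session(iter(local), clock=clock)
    t0 = profile.start_time
    t1 = t0 + profile.duration_minutes * MINUTE
    server_series = server.query_series(profile.device_id, t0, t1)
    return ScenarioResult(local, server_series, pm, session, server)
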