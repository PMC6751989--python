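"""Piecewise-linear conversion of particle counts to PM2.5 mass concentration.

Optical particle counters report number counts, not mass; converting the
count channel to an estimated PM2.5 concentration (µg/m³) requires an
empirically derived equation specific to the instrument and aerosol.  Such
equations are typically piecewise linear in the count value, with different
slopes at low and high loadings.  This module represents them as an ordered
list of segments ``(lower_break, slope, intercept)`` over a configurable
input channel — the total >0.5 µm count, or total minus the >2.5 µm count
for groups that define the fine fraction that way.

The shipped :data:`DEFAULT_MODEL` is a clearly-labelled placeholder (a
single linear segment, 0.01 µg/m³ per count unit).  It is *not* a published
calibration; users with an instrument-specific equation should supply its
coefficients through the ``calibration:`` config block.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Mapping, Sequence

from .protocol import ParticleRecord, RecordSeries

VALID_CHANNELS = ("small", "small_minus_large")


class CalibrationConfigError(ValueError):
    """The supplied segments do not define a valid monotone map."""


@dataclass(frozen=True)
class Segment:
    lower_break: float  # count units; segment applies for x >= lower_break
    slope: float        # µg/m³ per count unit
    intercept: float    # µg/m³


@dataclass(frozen=True)
class PmRecord:
    """One minute of estimated PM2.5 mass concentration."""

    timestamp: datetime
    pm25: float  # µg/m³

    def __post_init__(self) -> None:
        if self.pm25 < 0:
            raise ValueError(f"pm25 must be non-negative, got {self.pm25}")


@dataclass(frozen=True)
class CalibrationModel:
    """Ordered piecewise-linear count → PM2.5 map.

    Invariants (checked on construction): breaks strictly increasing and
    starting at 0; every slope non-negative; no downward jump at a break —
    together these make the map monotone non-decreasing and non-negative
    over counts >= 0.
    """

    segments: tuple[Segment, ...]
    channel: str = "small"

    def __post_init__(self) -> None:
        if self.channel not in VALID_CHANNELS:
            raise CalibrationConfigError(
                f"channel must be one of {VALID_CHANNELS}, got {self.channel!r}"
            )
        segs = self.segments
        if not segs:
            raise CalibrationConfigError("at least one segment is required")
        if segs[0].lower_break != 0:
            raise CalibrationConfigError("first segment must start at count 0")
        for a, b in zip(segs, segs[1:]):
            if not b.lower_break > a.lower_break:
                raise CalibrationConfigError(
                    f"breaks must be strictly increasing: {a.lower_break} -> {b.lower_break}"
                )
        for s in segs:
            if s.slope < 0:
                raise CalibrationConfigError(f"negative slope {s.slope} breaks monotonicity")
        # No downward jump at internal breaks, and non-negative at every
        # segment start (with slopes >= 0 this bounds the whole map).
        for a, b in zip(segs, segs[1:]):
            left = a.slope * b.lower_break + a.intercept
            right = b.slope * b.lower_break + b.intercept
            if right < left - 1e-9:
                raise CalibrationConfigError(
                    f"map decreases at break {b.lower_break}: {left:.6g} -> {right:.6g}"
                )
        for s in segs:
            if s.slope * s.lower_break + s.intercept < 0:
                raise CalibrationConfigError(
                    f"map is negative at break {s.lower_break}"
                )

    def channel_value(self, record: ParticleRecord) -> int:
        if self.channel == "small":
            return record.small_count
        return record.small_count - record.large_count

    def _segment_for(self, x: float) -> Segment:
        chosen = self.segments[0]
        for s in self.segments:
            if x >= s.lower_break:
                chosen = s
            else:
                break
        return chosen

    def pm25(self, x: float) -> float:
        """Evaluate the map at channel value ``x`` (clamped at 0)."""
        if x < 0:
            raise ValueError(f"channel value must be non-negative, got {x}")
        s = self._segment_for(x)
        return max(0.0, s.slope * x + s.intercept)

    def invert(self, pm: float) -> float:
        """Smallest channel value mapping to ``pm`` (µg/m³).

        Used by the simulator to manufacture counts consistent with a target
        concentration.  Values below the map's minimum clamp to count 0;
        values above the last break extrapolate along the final segment
        (which must then have positive slope).
        """
        if pm < 0:
            raise ValueError(f"pm must be non-negative, got {pm}")
        if pm <= self.pm25(0):
            return 0.0
        segs = self.segments
        for i, s in enumerate(segs):
            hi = segs[i + 1].lower_break if i + 1 < len(segs) else None
            lo_val = self.pm25(s.lower_break)
            hi_val = self.pm25(hi) if hi is not None else None
            if hi_val is not None and pm > hi_val:
                continue
            if s.slope > 0:
                x = (pm - s.intercept) / s.slope
                return max(x, s.lower_break)
            if pm <= lo_val:
                return s.lower_break
        last = segs[-1]
        if last.slope <= 0:
            raise CalibrationConfigError(
                f"cannot invert {pm} µg/m³: final segment has zero slope"
            )
        return (pm - last.intercept) / last.slope


#: Placeholder single-segment model: PM2.5 = 0.01 µg/m³ per count unit on
#: the total (>0.5 µm) channel.  A stand-in, not a published calibration.
DEFAULT_MODEL = CalibrationModel(segments=(Segment(0.0, 0.01, 0.0),), channel="small")


def build_model(config: Mapping | Sequence) -> CalibrationModel:
    """Validate a config block into a :class:`CalibrationModel`.

    Accepts ``{"channel": ..., "segments": [{"lower_break":, "slope":,
    "intercept":}, ...]}`` (segments may also be 3-sequences).
    """
    if isinstance(config, Mapping):
        channel = config.get("channel", "small")
        raw = config.get("segments")
    else:
        channel, raw = "small", config
    if not raw:
        raise CalibrationConfigError("config must supply at least one segment")
    segs = []
    for item in raw:
        if isinstance(item, Mapping):
            segs.append(
                Segment(
                    float(item["lower_break"]),
                    float(item["slope"]),
                    float(item["intercept"]),
                )
            )
        else:
            lb, sl, ic = item
            segs.append(Segment(float(lb), float(sl), float(ic)))
    return CalibrationModel(segments=tuple(segs), channel=channel)


def counts_to_pm25(record: ParticleRecord, model: CalibrationModel = DEFAULT_MODEL) -> PmRecord:
    """Convert one minute record to an estimated PM2.5 concentration."""
    return PmRecord(record.timestamp, model.pm25(model.channel_value(record)))


def calibrate_series(
    series: RecordSeries | Iterable[ParticleRecord],
    model: CalibrationModel = DEFAULT_MODEL,
) -> list[PmRecord]:
    """Convert a whole minute series to PM2.5 records."""
    return [counts_to_pm25(r, model) for r in series]
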