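"""Built-in reference dataset: the eight-home field deployment.

Four prototype remote monitors were rotated through eight homes in four
Israeli cities over a combined 44 days of minute-resolution monitoring in
summer 2017 — four homes where smoking was permitted indoors and four where
it was not.  The published per-home arithmetic mean and median PM2.5
summaries (µg/m³, from the server-retrieved data) are reproduced here as
the canonical small worked example for the exposure analysis: geometric
means across homes and the exact Mann–Whitney comparison between the two
smoking-status groups.

The raw minute series behind these summaries were never deposited; only
the per-home summaries are available.
"""

from __future__ import annotations

from .analysis import HomeSummary

#: Per-home summaries from the eight-home deployment (µg/m³).
FIELD_HOME_SUMMARIES: tuple[HomeSummary, ...] = (
    HomeSummary("BE_03", "permitted", 82.01, 13.92),
    HomeSummary("HA_04", "permitted", 30.85, 15.32),
    HomeSummary("JE_03", "permitted", 7.10, 6.05),
    HomeSummary("TA_04", "permitted", 7.10, 6.33),
    HomeSummary("HA_01", "not permitted", 9.27, 7.75),
    HomeSummary("JE_05", "not permitted", 8.08, 6.89),
    HomeSummary("TA_01", "not permitted", 6.77, 6.21),
    HomeSummary("TA_02", "not permitted", 7.14, 5.90),
)


def load_field_summaries() -> list[HomeSummary]:
    """The eight published per-home summaries, as a fresh list."""
    return list(FIELD_HOME_SUMMARIES)
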