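# pmremote

Remote, minute-resolution PM2.5 monitoring for smoke-free-home research.

Secondhand tobacco smoke indoors is usually measured indirectly, as fine
particulate matter (PM2.5, µg/m³), with a low-cost optical particle counter
such as the Dylos DC1700 placed in a home's main living area. Feedback
interventions built on these monitors suffer from a delay: data sit in the
instrument's onboard memory (just over six days of capacity) until someone
retrieves it. Bolting a small single-board computer and a mobile-network
modem onto the instrument removes that delay — every minute record can be
relayed to a server while the monitor is still on site — but introduces a
new failure mode: an unreliable mobile link silently losing minutes.

`pmremote` implements that whole pipeline as testable software:

* **protocol** — parse/serialize the DC1700's serial minute record
  (`<total/100>,<large/100>`; two channels: particles >0.5 µm and >2.5 µm
  per 0.01 ft³) and the timestamped CSV interchange/memory-dump formats.
* **calibration** — configurable piecewise-linear conversion of counts to
  estimated PM2.5. The shipped default is a labelled placeholder; enter
  your instrument-specific coefficients via the `calibration:` config block.
* **telemetry** — a store-and-forward client: bounded-timeout delivery,
  sqlite-persisted buffer, retransmission until the server acknowledges
  (at-least-once), plus a `legacy_mode` that drops failed records, emulating
  a first-generation deployment without the buffer.
* **server** — validating, deduplicating ingest keyed by (device, minute),
  with half-open time-range queries and missing-minute gap reports; an
  optional stdlib HTTP layer (`POST /ingest`, `GET /series`, `GET /gaps`).
* **simulator** — synthetic indoor PM streams (background + episodic
  smoking spikes with exponential decay, lognormal noise) and
  fault-injected transports (scheduled outages, random drops, latency), so
  the full loop runs with no hardware and no network.
* **analysis** — loss auditing (lost fraction, outage runs), Bland–Altman
  agreement with limits mean ± 1.96·SD, per-home mean/median summaries,
  geometric means, and *exact* small-sample rank tests (Wilcoxon
  signed-rank by sign-assignment enumeration; Mann–Whitney U by the
  classical tie-free permutation null).

## Worked example

The package ships the per-home summaries of an eight-home field deployment
(four homes where smoking was permitted indoors, four smoke-free; 44
combined days of minute data) as its canonical small dataset:

```sh
$ pmremote field-summary
Home     Status             Mean   Median
BE_03    permitted         82.01    13.92
HA_04    permitted         30.85    15.32
JE_03    permitted          7.10     6.05
TA_04    permitted          7.10     6.33
HA_01    not permitted      9.27     7.75
JE_05    not permitted      8.08     6.89
TA_01    not permitted      6.77     6.21
TA_02    not permitted      7.14     5.90
Geometric means (smoking-permitted): mean 18.90, median 9.51
Geometric means (smoke-free):        mean 7.76, median 6.65
Mann-Whitney exact two-sided: means p=0.686, medians p=0.486
```

Smoking-permitted homes show markedly higher PM2.5 (geometric mean of home
means 18.90 vs 7.76 µg/m³), with means well above medians in the heaviest
homes — the signature of short, intense smoking episodes on a clean
background. With only four homes per group, the exact Mann–Whitney test
cannot call the difference significant (p=0.686 for means, p=0.486 for
medians).

An end-to-end simulated session, with the mobile link down for minutes
20–39 of 200:

```sh
$ pmremote simulate --profile profile.yaml --plan plan.yaml --legacy-mode --out run/
session of 200 min: 20 lost (10.00%), longest outage 20 min
```

Re-run without `--legacy-mode` and the store-and-forward buffer retransmits
the backlog once the link returns: 0 lost (0.00%). `pmremote compare
local.csv server.csv [...]` prints the same loss audit (plus Bland–Altman
agreement across homes) for real paired exports.

The library mirrors the CLI: see `pmremote.run_scenario`,
`pmremote.align_series`, `pmremote.bland_altman`,
`pmremote.mann_whitney_exact`, `pmremote.wilcoxon_signed_rank_exact`.

## Notes on deployment

Monitors are placed in the main living area, ≥30 cm from walls and floor
and away from windows. The physical serial link (RS232 over an FTDI
USB adapter) is behind a seam — any iterable of serial lines drives
`pmremote listen`; the simulator provides one in tests.
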