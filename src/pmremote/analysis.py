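"""Reliability audit and exposure summaries.

Two families of computation live here.

**Reliability** — given the instrument-memory series (the reference) and
the server-held series over the same window, quantify what the telemetry
link lost: the lost-minute fraction, and the maximal runs of consecutive
missing minutes (outages) with the longest run highlighted.  Method
agreement between the two retrieval routes is summarised Bland–Altman
style: per-home differences of paired summaries, their mean and SD, and
limits of agreement mean ± 1.96·SD, conventionally plotted against the
pairwise means on a logarithmic axis because home concentrations span
orders of magnitude.

**Exposure** — per-home arithmetic mean and median minute PM2.5, geometric
means across homes, and small-sample *exact* nonparametric tests:

* Wilcoxon signed-rank (paired, e.g. server vs memory summaries per home):
  zero differences are dropped, absolute differences are mid-ranked, and
  the two-sided p-value is the probability, over all 2^n equiprobable sign
  assignments, of a positive-rank sum W at least as far from its null mean
  n(n+1)/4 as the observed one.

* Mann–Whitney U (two independent groups, e.g. smoking-permitted vs
  smoke-free homes): U is computed from mid-ranks, and the two-sided p is
  the doubled lower-tail probability of the classical tie-free null
  distribution of U at the observed (smaller) U, capped at 1 — the
  convention of standard exact tables and mainstream statistical software.
  A tie-aware permutation variant is available behind a flag.

Both null distributions are computed by dynamic programming over rank sums,
which enumerates exactly the same assignments as brute force; the test
suite checks equality against literal enumeration oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .calibration import PmRecord
from .protocol import RecordSeries
from .server import GapRun

MINUTE = timedelta(minutes=1)


# ---------------------------------------------------------------------------
# reliability: series alignment and loss accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LossReport:
    """Completeness audit of the server-held vs locally-held record sets.

    The denominator of ``lost_fraction`` is the locally recorded minute
    count: the instrument memory is the reference against which telemetry
    loss is measured.
    """

    n_local: int
    n_server: int
    n_matched: int
    lost_minutes: int
    lost_fraction: float
    outage_runs: tuple[GapRun, ...]
    longest_outage_min: int


def align_series(
    local: RecordSeries, server: RecordSeries
) -> tuple[list[datetime], LossReport]:
    """Match the two series on exact minute keys and audit the loss.

    Outage runs are maximal blocks of consecutive minutes (on the 1/min
    grid) that exist locally but never reached the server.
    """
    if local.device_id != server.device_id:
        raise ValueError(
            f"device mismatch: {local.device_id!r} vs {server.device_id!r}"
        )
    if len(local) == 0:
        raise ValueError("local series is empty: lost fraction undefined")
    server_keys = set(server.timestamps())
    matched = [t for t in local.timestamps() if t in server_keys]
    lost = len(local) - len(matched)
    runs: list[GapRun] = []
    run_start: datetime | None = None
    run_len = 0
    prev_missing_ts: datetime | None = None
    for t in local.timestamps():
        if t in server_keys:
            continue
        if run_start is not None and prev_missing_ts is not None and t - prev_missing_ts == MINUTE:
            run_len += 1
        else:
            if run_start is not None:
                runs.append(GapRun(run_start, run_len))
            run_start, run_len = t, 1
        prev_missing_ts = t
    if run_start is not None:
        runs.append(GapRun(run_start, run_len))
    report = LossReport(
        n_local=len(local),
        n_server=len(server),
        n_matched=len(matched),
        lost_minutes=lost,
        lost_fraction=lost / len(local),
        outage_runs=tuple(runs),
        longest_outage_min=max((r.length_min for r in runs), default=0),
    )
    return matched, report


# ---------------------------------------------------------------------------
# method agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgreementReport:
    """Bland–Altman agreement between two measurement routes, plus the
    paired rank test and rank correlation on the same pairs."""

    n_pairs: int
    mean_difference: float        # µg/m³, method A − method B
    sd_difference: float          # µg/m³, n−1 denominator
    loa_lower: float              # mean − 1.96·sd
    loa_upper: float              # mean + 1.96·sd
    wilcoxon_p_two_sided: float
    spearman_rho: float


def bland_altman(
    method_a: Sequence[float],
    method_b: Sequence[float],
    *,
    plot_path: str | None = None,
) -> AgreementReport:
    """Paired-method agreement on per-home summaries.

    Differences are A − B; limits of agreement are mean ± 1.96·SD with the
    SD on n−1 degrees of freedom.  When ``plot_path`` is given, writes the
    conventional plot (differences against pairwise arithmetic means, log
    x-axis) to that file.
    """
    a = np.asarray(method_a, dtype=float)
    b = np.asarray(method_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("method_a and method_b must be equal-length 1-d sequences")
    if a.size < 2:
        raise ValueError("at least 2 pairs are required")
    diff = a - b
    mean_diff = float(np.mean(diff))
    sd_diff = float(np.std(diff, ddof=1))
    report = AgreementReport(
        n_pairs=int(a.size),
        mean_difference=mean_diff,
        sd_difference=sd_diff,
        loa_lower=mean_diff - 1.96 * sd_diff,
        loa_upper=mean_diff + 1.96 * sd_diff,
        wilcoxon_p_two_sided=wilcoxon_signed_rank_exact(a, b).p_two_sided,
        spearman_rho=spearman_rho(a, b),
    )
    if plot_path is not None:
        _bland_altman_plot(a, b, report, plot_path)
    return report


def _bland_altman_plot(a: np.ndarray, b: np.ndarray, rep: AgreementReport, path: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = (a + b) / 2.0
    diffs = a - b
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, color="k", zorder=3)
    ax.axhline(rep.mean_difference, color="tab:blue", label="mean difference")
    for y in (rep.loa_lower, rep.loa_upper):
        ax.axhline(y, color="tab:red", linestyle="--", label="limit of agreement")
    ax.set_xscale("log")
    ax.set_xlabel("Mean of the two methods (µg/m³, log scale)")
    ax.set_ylabel("Difference between methods (µg/m³)")
    handles, labels = ax.get_legend_handles_labels()
    seen: dict[str, object] = {}
    for h, l in zip(handles, labels):
        seen.setdefault(l, h)
    ax.legend(seen.values(), seen.keys(), fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# exact rank tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    n_used: int            # pairs remaining after zero-difference removal
    w_statistic: float     # positive-rank sum (mid-ranks)
    p_two_sided: float


def _signed_rank_null_counts(double_ranks: Sequence[int]) -> np.ndarray:
    """Counts of sign assignments by doubled positive-rank sum.

    Polynomial product Π (1 + z^r) over doubled ranks: coefficient k is the
    number of the 2^n sign vectors whose positive ranks sum to k/2.
    """
    total = sum(double_ranks)
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in double_ranks:
        counts[r:] += counts[: counts.size - r].copy()
    return counts


def wilcoxon_signed_rank_exact(
    x: Sequence[float], y: Sequence[float] | None = None
) -> WilcoxonResult:
    """Exact two-sided Wilcoxon signed-rank test on paired data.

    ``x`` may be the differences directly, or paired with ``y`` (then the
    differences are x − y).  Zero differences are dropped before ranking
    (the original signed-rank convention); absolute differences receive
    mid-ranks.  The p-value is P(|W − n(n+1)/4| ≥ |w_obs − n(n+1)/4|) under
    the uniform null over all 2^n sign assignments.  If every difference is
    zero the methods are indistinguishable and p = 1.0 by convention.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise ValueError("need a non-empty 1-d vector of paired differences")
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(0, 0.0, 1.0)
    ranks = stats.rankdata(np.abs(d))          # mid-ranks, multiples of 0.5
    w_obs = float(np.sum(ranks[d > 0]))
    double_ranks = [int(round(2 * r)) for r in ranks]
    counts = _signed_rank_null_counts(double_ranks)
    total2 = sum(double_ranks)                 # = n(n+1) in doubled units
    dev = abs(2 * w_obs - total2 / 2)          # doubled |W − E[W]|
    sums = np.arange(counts.size, dtype=float)
    tail = counts[np.abs(sums - total2 / 2) >= dev - 1e-9].sum()
    p = float(tail / counts.sum())
    return WilcoxonResult(int(d.size), w_obs, min(1.0, p))


@dataclass(frozen=True)
class GroupComparison:
    n1: int
    n2: int
    u_statistic: float     # min(U1, U2) from mid-ranks
    p_two_sided: float


def _rank_sum_null_counts(n_total: int, n1: int) -> np.ndarray:
    """Counts of n1-subsets of ranks {1..N} by rank sum (tie-free null)."""
    max_sum = n_total * (n_total + 1) // 2
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    counts[0, 0] = 1.0
    for r in range(1, n_total + 1):
        for k in range(min(n1, r), 0, -1):
            counts[k, r:] += counts[k - 1, : max_sum + 1 - r]
    return counts[n1]


def mann_whitney_exact(
    group1: Sequence[float],
    group2: Sequence[float],
    *,
    tie_aware: bool = False,
) -> GroupComparison:
    """Exact two-sided Mann–Whitney U test for two small groups.

    U is computed from mid-ranks of the pooled sample.  By default the
    p-value is twice the lower-tail probability of min(U1, U2) under the
    classical tie-free null (all C(N, n1) rank splits equiprobable), capped
    at 1.  With ``tie_aware=True`` the null instead permutes the observed
    mid-ranks themselves and the p-value is the two-sided deviation tail
    around n1·n2/2 (only feasible for pooled sizes up to ~22).
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = int(g1.size), int(g2.size)
    pooled = np.concatenate([g1, g2])
    ranks = stats.rankdata(pooled)
    r1 = float(np.sum(ranks[:n1]))
    u1 = r1 - n1 * (n1 + 1) / 2
    u2 = n1 * n2 - u1
    u_obs = min(u1, u2)
    n_total = n1 + n2
    if tie_aware:
        if n_total > 22:
            raise ValueError("tie-aware permutation null limited to n1+n2 <= 22")
        mu = n1 * n2 / 2
        dev = abs(u1 - mu)
        hits = 0
        total = 0
        offset = n1 * (n1 + 1) / 2
        for idx in combinations(range(n_total), n1):
            u = float(ranks[list(idx)].sum()) - offset
            total += 1
            if abs(u - mu) >= dev - 1e-9:
                hits += 1
        p = hits / total
    else:
        counts = _rank_sum_null_counts(n_total, n1)
        offset = n1 * (n1 + 1) // 2
        sums = np.arange(counts.size, dtype=float) - offset   # null U1 values
        cdf = counts[sums <= u_obs + 1e-9].sum() / counts.sum()
        p = min(1.0, 2.0 * float(cdf))
    return GroupComparison(n1, n2, float(u_obs), float(p))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks).

    Returns NaN when either vector is constant (the correlation is
    undefined there).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# exposure summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HomeSummary:
    """Per-home exposure outcome: arithmetic mean and median minute PM2.5."""

    home_id: str
    smoking_status: str    # "permitted" | "not permitted"
    mean_pm25: float
    median_pm25: float

    def __post_init__(self) -> None:
        if self.mean_pm25 < 0 or self.median_pm25 < 0:
            raise ValueError("summary concentrations must be non-negative")


def summarize_home(
    pm: Iterable[PmRecord] | Sequence[float], home_id: str, smoking_status: str
) -> HomeSummary:
    """Arithmetic mean and median of a home's minute PM2.5 series.

    The median uses the mid-point convention for even n.  Accepts either
    :class:`PmRecord` sequences or bare concentration values.
    """
    values = [p.pm25 if isinstance(p, PmRecord) else float(p) for p in pm]
    if not values:
        raise ValueError("cannot summarise an empty series")
    arr = np.asarray(values, dtype=float)
    return HomeSummary(
        home_id, smoking_status, float(np.mean(arr)), float(np.median(arr))
    )


def geometric_mean(values: Sequence[float]) -> float:
    """exp(mean(ln x)); requires strictly positive inputs."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("geometric mean of an empty vector is undefined")
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(math.exp(float(np.mean(np.log(arr)))))


@dataclass(frozen=True)
class GroupTable:
    """Across-home roll-up: per-group geometric means of the per-home
    means and medians, plus the two exact group tests."""

    gmean_mean_smoking: float
    gmean_mean_nonsmoking: float
    gmean_median_smoking: float
    gmean_median_nonsmoking: float
    test_means: GroupComparison
    test_medians: GroupComparison


def compare_groups(summaries: Sequence[HomeSummary]) -> GroupTable:
    """Roll up per-home summaries by smoking status."""
    smoking = [s for s in summaries if s.smoking_status == "permitted"]
    clean = [s for s in summaries if s.smoking_status == "not permitted"]
    if not smoking or not clean:
        raise ValueError("need at least one home in each smoking-status group")
    return GroupTable(
        gmean_mean_smoking=geometric_mean([s.mean_pm25 for s in smoking]),
        gmean_mean_nonsmoking=geometric_mean([s.mean_pm25 for s in clean]),
        gmean_median_smoking=geometric_mean([s.median_pm25 for s in smoking]),
        gmean_median_nonsmoking=geometric_mean([s.median_pm25 for s in clean]),
        test_means=mann_whitney_exact(
            [s.mean_pm25 for s in smoking], [s.mean_pm25 for s in clean]
        ),
        test_medians=mann_whitney_exact(
            [s.median_pm25 for s in smoking], [s.median_pm25 for s in clean]
        ),
    )
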