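"""Reliability audit and exposure statistics, checked against independent
oracles (literal enumeration, two-pass arithmetic, scipy)."""

from __future__ import annotations

import math
from datetime import timedelta
from itertools import combinations, product

import numpy as np
import pytest
from scipy import stats

from pmremote.analysis import (
    align_series,
    bland_altman,
    compare_groups,
    geometric_mean,
    mann_whitney_exact,
    spearman_rho,
    summarize_home,
    wilcoxon_signed_rank_exact,
)
from pmremote.datasets import load_field_summaries
from pmremote.protocol import ParticleRecord, RecordSeries

MINUTE = timedelta(minutes=1)


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

def wilcoxon_oracle(diffs) -> float:
    """Literal enumeration over all 2^n sign vectors of mid-ranked |d|."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    e_w = ranks.sum() / 2
    hits = 0
    for signs in product((0, 1), repeat=d.size):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if abs(w - e_w) >= abs(w_obs - e_w) - 1e-9:
            hits += 1
    return hits / 2 ** d.size


def mann_whitney_oracle(g1, g2) -> float:
    """Doubled lower tail of the tie-free null of U, by literal enumeration
    of all C(N, n1) splits of the integer ranks 1..N."""
    n1, n2 = len(g1), len(g2)
    ranks = stats.rankdata(np.concatenate([g1, g2]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    u_obs = min(u1, n1 * n2 - u1)
    hits = total = 0
    for subset in combinations(range(1, n1 + n2 + 1), n1):
        u = sum(subset) - n1 * (n1 + 1) / 2
        total += 1
        if u <= u_obs + 1e-9:
            hits += 1
    return min(1.0, 2 * hits / total)


def subset_series(series: RecordSeries, keep) -> RecordSeries:
    return RecordSeries(series.device_id, [r for i, r in enumerate(series) if i in keep])


# --------------------------------------------------------------------------
# alignment / loss accounting
# --------------------------------------------------------------------------

class TestAlignSeries:
    def test_identical_series_have_zero_loss(self, flat_series):
        matched, loss = align_series(flat_series, flat_series)
        assert len(matched) == 100
        assert loss.lost_fraction == 0.0
        assert loss.outage_runs == ()
        assert loss.longest_outage_min == 0

    def test_missing_block_is_one_run(self, flat_series):
        server = subset_series(flat_series, set(range(100)) - set(range(5, 15)))
        _, loss = align_series(flat_series, server)
        assert loss.lost_fraction == pytest.approx(0.10)
        assert len(loss.outage_runs) == 1
        assert loss.outage_runs[0].length_min == 10
        assert loss.longest_outage_min == 10

    def test_two_isolated_missing_minutes(self, flat_series):
        server = subset_series(flat_series, set(range(100)) - {5, 50})
        _, loss = align_series(flat_series, server)
        assert [r.length_min for r in loss.outage_runs] == [1, 1]
        assert loss.longest_outage_min == 1

    def test_empty_server_means_total_loss(self, flat_series):
        _, loss = align_series(flat_series, RecordSeries(flat_series.device_id, []))
        assert loss.lost_fraction == 1.0

    def test_empty_local_is_an_error(self, flat_series):
        with pytest.raises(ValueError):
            align_series(RecordSeries(flat_series.device_id, []), flat_series)

    def test_device_mismatch_is_an_error(self, flat_series):
        with pytest.raises(ValueError):
            align_series(flat_series, RecordSeries("OTHER", []))

    def test_runs_agree_with_membership_scan_on_random_patterns(self, rng, flat_series):
        for _ in range(50):
            keep = {i for i in range(100) if rng.random() > 0.3}
            server = subset_series(flat_series, keep)
            _, loss = align_series(flat_series, server)
            # brute-force scan
            runs, start = [], None
            for m in range(100):
                if m not in keep:
                    start = m if start is None else start
                elif start is not None:
                    runs.append((start, m - start))
                    start = None
            if start is not None:
                runs.append((start, 100 - start))
            got = [
                ((r.start - flat_series.records[0].timestamp) // MINUTE, r.length_min)
                for r in loss.outage_runs
            ]
            assert got == runs


# --------------------------------------------------------------------------
# Bland–Altman agreement
# --------------------------------------------------------------------------

class TestBlandAltman:
    def test_identical_pairs(self):
        rep = bland_altman([5.0, 8.0, 12.0], [5.0, 8.0, 12.0])
        assert rep.mean_difference == 0.0
        assert rep.sd_difference == 0.0
        assert rep.loa_lower == rep.loa_upper == 0.0
        assert rep.wilcoxon_p_two_sided == 1.0

    def test_constant_offset(self):
        rep = bland_altman([6.0, 9.0, 13.0], [5.0, 8.0, 12.0])
        assert rep.mean_difference == pytest.approx(1.0)
        assert rep.sd_difference == 0.0

    def test_matches_two_pass_oracle(self, rng):
        a = rng.lognormal(2, 0.5, size=8)
        b = a * rng.normal(1.0, 0.02, size=8)
        rep = bland_altman(a, b)
        d = a - b
        mean = sum(d) / len(d)
        sd = math.sqrt(sum((x - mean) ** 2 for x in d) / (len(d) - 1))
        assert rep.mean_difference == pytest.approx(mean)
        assert rep.sd_difference == pytest.approx(sd)
        assert rep.loa_lower == pytest.approx(mean - 1.96 * sd)
        assert rep.loa_upper == pytest.approx(mean + 1.96 * sd)

    def test_fewer_than_two_pairs_is_an_error(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])

    def test_plot_written(self, rng, tmp_path):
        a = rng.lognormal(2, 0.8, size=8)
        b = a + rng.normal(0, 0.1, size=8)
        out = tmp_path / "ba.png"
        bland_altman(a, b, plot_path=str(out))
        assert out.stat().st_size > 0


# --------------------------------------------------------------------------
# exact Wilcoxon signed-rank
# --------------------------------------------------------------------------

class TestWilcoxonExact:
    def test_identical_vectors_give_p_one(self):
        res = wilcoxon_signed_rank_exact([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.p_two_sided == 1.0
        assert res.n_used == 0

    def test_all_positive_five_differences(self):
        # All 5 signs positive: only the two extreme assignments of 32 are
        # at least as far from E[W] = 7.5, so p = 2/32.
        res = wilcoxon_signed_rank_exact([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.p_two_sided == pytest.approx(0.0625)

    def test_zeros_dropped_before_ranking(self):
        res = wilcoxon_signed_rank_exact([0.0, 0.0, 1.0, 2.0, 3.0])
        assert res.n_used == 3
        assert res.p_two_sided == pytest.approx(wilcoxon_oracle([1.0, 2.0, 3.0]))

    def test_matches_enumeration_oracle_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 11))
            d = np.round(rng.normal(0, 2, size=n), 1)
            assert wilcoxon_signed_rank_exact(d).p_two_sided == pytest.approx(
                wilcoxon_oracle(d)
            )

    def test_matches_scipy_exact_when_tie_free(self, rng):
        # Independent cross-check against scipy's exact method (valid only
        # without ties or zeros, where conventions coincide).
        for _ in range(20):
            n = int(rng.integers(3, 12))
            d = rng.normal(0, 2, size=n)  # continuous: ties have measure zero
            ours = wilcoxon_signed_rank_exact(d).p_two_sided
            ref = stats.wilcoxon(d, method="exact").pvalue
            assert ours == pytest.approx(ref)


# --------------------------------------------------------------------------
# exact Mann–Whitney U
# --------------------------------------------------------------------------

class TestMannWhitneyExact:
    def test_field_means_and_medians(self):
        """The eight-home deployment: smoking-permitted vs smoke-free."""
        means = mann_whitney_exact(
            [82.01, 30.85, 7.10, 7.10], [9.27, 8.08, 6.77, 7.14]
        )
        assert round(means.p_two_sided, 3) == 0.686
        medians = mann_whitney_exact(
            [13.92, 15.32, 6.05, 6.33], [7.75, 6.89, 6.21, 5.90]
        )
        assert round(medians.p_two_sided, 3) == 0.486

    def test_fully_separated_tiny_groups(self):
        res = mann_whitney_exact([1.0, 2.0], [3.0, 4.0])
        assert res.u_statistic == 0.0
        assert res.p_two_sided == pytest.approx(2 / 6)

    def test_u_bounds_and_p_range(self, rng):
        for _ in range(30):
            n1, n2 = rng.integers(1, 8, size=2)
            res = mann_whitney_exact(rng.normal(size=n1), rng.normal(size=n2))
            assert 0 <= res.u_statistic <= res.n1 * res.n2
            assert 0 < res.p_two_sided <= 1

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])

    def test_matches_enumeration_oracle_on_random_instances(self, rng):
        for _ in range(60):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 6))
            g1 = np.round(rng.normal(0, 2, size=n1), 1)
            g2 = np.round(rng.normal(0, 2, size=n2), 1)
            assert mann_whitney_exact(g1, g2).p_two_sided == pytest.approx(
                mann_whitney_oracle(g1, g2)
            )

    def test_matches_scipy_exact_when_tie_free(self, rng):
        for _ in range(20):
            n1 = int(rng.integers(2, 9))
            n2 = int(rng.integers(2, 9))
            g1, g2 = rng.normal(size=n1), rng.normal(size=n2)
            ours = mann_whitney_exact(g1, g2).p_two_sided
            ref = stats.mannwhitneyu(g1, g2, method="exact").pvalue
            assert ours == pytest.approx(ref)

    def test_tie_aware_variant_is_a_valid_permutation_p(self, rng):
        g1 = [1.0, 2.0, 2.0]
        g2 = [2.0, 3.0, 4.0]
        res = mann_whitney_exact(g1, g2, tie_aware=True)
        assert 0 < res.p_two_sided <= 1
        # symmetric inputs give p = 1 under the permutation null
        sym = mann_whitney_exact([1.0, 4.0], [2.0, 3.0], tie_aware=True)
        assert sym.p_two_sided == 1.0


# --------------------------------------------------------------------------
# Spearman, summaries, geometric mean
# --------------------------------------------------------------------------

class TestSpearman:
    def test_concordant_and_reversed(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [30, 20, 10]) == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        expected = stats.pearsonr(stats.rankdata(x), stats.rankdata(y)).statistic
        assert spearman_rho(x, y) == pytest.approx(expected)

    def test_constant_vector_flagged_nan(self):
        assert math.isnan(spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestSummaries:
    def test_constant_series(self):
        s = summarize_home([7.0] * 10, "H1", "not permitted")
        assert s.mean_pm25 == s.median_pm25 == 7.0

    def test_even_n_median_midpoint(self):
        s = summarize_home([1.0, 2.0, 3.0, 4.0], "H1", "permitted")
        assert s.mean_pm25 == pytest.approx(2.5)
        assert s.median_pm25 == pytest.approx(2.5)

    def test_right_skewed_series_mean_exceeds_median(self, rng):
        values = np.concatenate([rng.uniform(5, 9, 500), rng.uniform(100, 600, 25)])
        s = summarize_home(values, "H1", "permitted")
        assert s.mean_pm25 > s.median_pm25

    def test_empty_series_is_an_error(self):
        with pytest.raises(ValueError):
            summarize_home([], "H1", "permitted")


class TestGeometricMean:
    def test_field_group_values(self):
        assert round(geometric_mean([82.01, 30.85, 7.10, 7.10]), 2) == 18.90
        assert round(geometric_mean([9.27, 8.08, 6.77, 7.14]), 2) == 7.76

    def test_identity_on_constant_vector(self):
        assert geometric_mean([4.2, 4.2, 4.2]) == pytest.approx(4.2)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            geometric_mean([1.0, 0.0])
        with pytest.raises(ValueError):
            geometric_mean([1.0, -2.0])

    def test_am_gm_inequality(self, rng):
        for _ in range(20):
            v = rng.lognormal(1, 1, size=int(rng.integers(2, 12)))
            assert geometric_mean(v) <= np.mean(v) + 1e-12


class TestGroupRollUp:
    def test_field_table_bottom_rows_reproduced(self):
        table = compare_groups(load_field_summaries())
        assert round(table.gmean_mean_smoking, 2) == 18.90
        assert round(table.gmean_median_smoking, 2) == 9.51
        assert round(table.gmean_mean_nonsmoking, 2) == 7.76
        assert round(table.gmean_median_nonsmoking, 2) == 6.65
        assert round(table.test_means.p_two_sided, 3) == 0.686
        assert round(table.test_medians.p_two_sided, 3) == 0.486

    def test_single_status_group_is_an_error(self):
        smoking_only = [s for s in load_field_summaries() if s.smoking_status == "permitted"]
        with pytest.raises(ValueError):
            compare_groups(smoking_only)
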