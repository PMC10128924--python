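import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invrec import (
    RecombinationEvent,
    WindowedFrequency,
    bin_and_normalize,
    clopper_pearson,
    detection_probability,
    expected_ncogc_recovery,
    fisher_exact_two_sided,
    format_p,
    ks_two_sample,
    map_length_cM,
    simulated_detection_probability,
    spearman_distance_corr,
)

from oracle import fisher_enumeration


class TestMapLength:
    @pytest.mark.parametrize(
        "k,n,cM,decimals",
        [(87, 914, 9.5, 1), (95, 914, 10.4, 1), (62, 3524, 1.76, 2)],
    )
    def test_printed_map_lengths(self, k, n, cM, decimals):
        assert round(map_length_cM(k, n).cM, decimals) == cM

    def test_zero_recombinants(self):
        est = map_length_cM(0, 1000)
        assert est.cM == 0.0 and est.ci_lo_cM == 0.0

    def test_ci_contains_point_estimate(self):
        est = map_length_cM(87, 914)
        assert est.ci_lo_cM <= est.cM <= est.ci_hi_cM

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            map_length_cM(5, 4)
        with pytest.raises(ValueError):
            map_length_cM(0, 0)


class TestClopperPearson:
    def test_k0_closed_form(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-12)
        assert round(hi, 4) == 0.3085

    def test_kn_upper_is_one(self):
        assert clopper_pearson(10, 10)[1] == 1.0

    def test_symmetric_midpoint(self):
        lo, hi = clopper_pearson(5, 10)
        assert lo == pytest.approx(0.187, abs=0.001)
        assert hi == pytest.approx(0.813, abs=0.001)

    def test_interval_inverts_binomial_tails(self):
        # independent check: at the bounds, the tail probability is alpha/2
        from scipy.stats import binom

        k, n = 7, 50
        lo, hi = clopper_pearson(k, n)
        assert binom.sf(k - 1, n, lo) == pytest.approx(0.025, abs=1e-9)
        assert binom.cdf(k, n, hi) == pytest.approx(0.025, abs=1e-9)

    def test_coverage_at_least_nominal(self):
        """Empirical coverage over simulated binomial draws >= 95% - 2 MC SE."""
        rng = np.random.default_rng(0)
        n, reps = 50, 2000
        mc_se = math.sqrt(0.95 * 0.05 / reps)
        for p in (0.05, 0.3, 0.7):
            ks = rng.binomial(n, p, size=reps)
            covered = 0
            for k in np.unique(ks):
                lo, hi = clopper_pearson(int(k), n)
                if lo <= p <= hi:
                    covered += int((ks == k).sum())
            assert covered / reps >= 0.95 - 2 * mc_se


class TestFisherExact:
    def test_printed_ncogc_table(self):
        p = fisher_exact_two_sided(((2, 28), (2, 9)))
        assert round(p, 2) == 0.29
        assert p == pytest.approx(fisher_enumeration(2, 28, 2, 9), rel=1e-9)

    def test_balanced_table_is_one(self):
        assert fisher_exact_two_sided(((1, 1), (1, 1))) == 1.0

    def test_extreme_table(self):
        assert fisher_exact_two_sided(((5, 0), (0, 5))) == pytest.approx(2 / 252, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(((0, 0), (1, 2)))

    def test_matches_enumeration_oracle_on_small_tables(self):
        for a in range(7):
            for b in range(7):
                for c in range(7):
                    for d in range(7):
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        got = fisher_exact_two_sided(((a, b), (c, d)))
                        want = fisher_enumeration(a, b, c, d)
                        assert got == pytest.approx(want, rel=1e-9), (a, b, c, d)

    @given(st.tuples(*[st.integers(0, 30)] * 4))
    @settings(deadline=None, max_examples=80)
    def test_invariant_under_row_column_swap_and_transpose(self, t):
        a, b, c, d = t
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        p = fisher_exact_two_sided(((a, b), (c, d)))
        assert p == pytest.approx(fisher_exact_two_sided(((c, d), (a, b))), rel=1e-9)
        assert p == pytest.approx(fisher_exact_two_sided(((b, a), (d, c))), rel=1e-9)
        assert p == pytest.approx(fisher_exact_two_sided(((a, c), (b, d))), rel=1e-9)


def windows_from(dist, freq):
    return [
        WindowedFrequency(i * 10, i * 10 + 10, 0, f, 0.0, 1.0, d)
        for i, (d, f) in enumerate(zip(dist, freq))
    ]


class TestSpearman:
    def test_monotone_increase_gives_one(self):
        sp = spearman_distance_corr(windows_from([1, 2, 3, 4, 5], [0.1, 0.2, 0.3, 0.4, 0.5]))
        assert sp.r == pytest.approx(1.0)

    def test_hand_computed_rank_correlation(self):
        # ranks (1,2,3,4) vs (2,1,3,4): sum d^2 = 2 -> r = 1 - 12/60 = 0.8
        sp = spearman_distance_corr(windows_from([1, 2, 3, 4], [0.2, 0.1, 0.3, 0.4]))
        assert sp.r == pytest.approx(0.8)

    def test_constant_frequency_undefined(self):
        sp = spearman_distance_corr(windows_from([1, 2, 3, 4], [0.25] * 4))
        assert sp.undefined

    def test_recomputes_distance_from_breakpoint(self):
        w = windows_from([0, 0, 0, 0], [0.1, 0.2, 0.3, 0.4])
        sp = spearman_distance_corr(w, breakpoint=0)  # midpoints 5,15,25,35
        assert sp.r == pytest.approx(1.0)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            spearman_distance_corr(windows_from([1, 2, 3], [0.1, 0.2, 0.3]))

    @given(st.permutations(range(6)))
    @settings(deadline=None, max_examples=40)
    def test_invariant_under_monotone_transform(self, perm):
        freq = [0.05 * (p + 1) for p in perm]
        dist = [1, 2, 3, 4, 5, 6]
        a = spearman_distance_corr(windows_from(dist, freq))
        b = spearman_distance_corr(windows_from([d**3 for d in dist], [math.exp(f) for f in freq]))
        assert a.r == pytest.approx(b.r)
        assert -1.0 <= a.r <= 1.0


class TestKS:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_hand_computed_statistic(self):
        d, _ = ks_two_sample([1, 2, 3], [1, 2, 4])
        assert d == pytest.approx(1 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])


def co_at(mid, oid="o"):
    # an event whose uncertainty interval midpoint is exactly `mid`
    return RecombinationEvent(
        offspring_id=oid, event_class="CO", left_flank=int(mid) - 100,
        right_flank=int(mid) + 100, inner_start=int(mid) + 100,
        inner_end=int(mid) + 100, n_support=2,
    )


class TestBinAndNormalize:
    def test_single_loaded_window(self):
        events = [co_at(1_000_000 + 75_000) for _ in range(10)]
        w = bin_and_normalize(events, (1_000_000, 1_600_000), 150_000)
        assert [x.count for x in w] == [10, 0, 0, 0]
        assert w[0].frequency == 1.0

    def test_frequencies_sum_to_one(self):
        events = [co_at(13_427_212 + 150_000 * i + 7) for i in range(20)]
        w = bin_and_normalize(events, (13_427_212, 17_432_000), 150_000)
        assert sum(x.frequency for x in w) == pytest.approx(1.0, abs=1e-12)

    def test_half_open_window_assignment(self):
        # midpoint exactly on a window edge goes to the right-hand window
        start = 13_400_000
        events = [co_at(start + 150_000)]
        w = bin_and_normalize(events, (start, start + 450_000), 150_000)
        assert [x.count for x in w] == [0, 1, 0]

    def test_excluded_events_ignored(self):
        keep = co_at(1_050_000)
        drop = co_at(1_050_000)
        drop.excluded = True
        w = bin_and_normalize([keep, drop], (1_000_000, 1_600_000), 150_000)
        assert sum(x.count for x in w) == 1

    def test_empty_set_flagged_undefined(self):
        w = bin_and_normalize([], (0, 600_000), 150_000)
        assert all(math.isnan(x.frequency) for x in w)
        assert all(x.count == 0 for x in w)

    def test_distance_to_breakpoint(self):
        w = bin_and_normalize([], (1_000_000, 1_300_000), 150_000, breakpoint=1_000_000)
        assert w[0].distance_to_breakpoint == 75_000.0
        assert w[1].distance_to_breakpoint == 225_000.0


class TestDetectionPower:
    def test_fixed_tract_closed_form(self):
        p = detection_probability(400, 367)
        assert p == pytest.approx(1 - math.exp(-400 / 367), rel=1e-12)
        assert round(p, 3) == 0.664

    def test_vanishes_for_sparse_markers(self):
        assert detection_probability(400, 1e12) < 1e-9

    def test_monte_carlo_agrees_with_both_closed_forms(self):
        for model in ("fixed", "geometric"):
            closed = detection_probability(400, 367, model)
            mc, se = simulated_detection_probability(400, 367, n_sim=200_000, seed=5, tract_model=model)
            assert abs(mc - closed) < 3 * se

    def test_geometric_tracts_detect_less(self):
        # short tracts dominate a geometric law: detection drops
        assert detection_probability(400, 367, "geometric") < detection_probability(400, 367)

    def test_expected_recovery_scales(self):
        lam = 50 / (100 * detection_probability(400, 367))
        r = expected_ncogc_recovery(lam, 400, 367, 100)
        assert r.expected_recovered == pytest.approx(50.0)

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            detection_probability(0, 367)
        with pytest.raises(ValueError):
            expected_ncogc_recovery(0.5, 400, 367, 0)


class TestFormatP:
    def test_two_significant_figures(self):
        assert format_p(0.28838) == "0.29"

    def test_floor_below_1e4(self):
        assert format_p(3e-5) == "< 0.0001"
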