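import math
from dataclasses import replace

import numpy as np
import pytest

from invrec import (
    DEFAULT_MARKERS,
    InversionCrossModel,
    MeioticProduct,
    SelectionScheme,
    assign_parental_origin,
    calibrated_p_co_intra,
    call_events,
    detect_nondisjunction,
    expected_map_length,
    find_jackpots,
    intra_inversion_single_co_probability,
    origin_at,
    scaled_to_map_length,
    score_recovery,
    simulate_cross,
    simulate_meiosis,
    suppression_factor,
    suppression_profile,
    synthetic_panel,
)


@pytest.fixture(scope="module")
def model():
    return InversionCrossModel()


@pytest.fixture(scope="module")
def coarse_panel():
    """Full-length chromosome, sparser markers: fast to render and call."""
    return synthetic_panel(mean_spacing=2_000, low_density_region=None, seed=99)


def call_all(offspring, panel, **kw):
    out = {}
    for o in offspring:
        if o.product is None:
            continue
        vec = assign_parental_origin(o.observation, panel)
        out[o.offspring_id] = call_events(vec, panel, **kw)
    return out


class TestSuppressionProfile:
    def test_zero_at_breakpoint(self, model):
        assert suppression_factor(model, 0) == 0.0

    def test_zero_within_radius(self, model):
        assert suppression_factor(model, model.suppression_radius) == 0.0

    def test_one_beyond_full_distance(self, model):
        assert suppression_factor(model, model.suppression_full_distance) == 1.0

    def test_linear_midpoint(self, model):
        r, full = model.suppression_radius, model.suppression_full_distance
        assert suppression_factor(model, r + (full - r) / 2) == pytest.approx(0.5)

    def test_monotone_in_distance(self, model):
        d = np.linspace(0, 5_000_000, 200)
        f = suppression_factor(model, d)
        assert (np.diff(f) >= 0).all()

    def test_profile_sides_and_interior(self, model):
        bp_d, bp_p = model.breakpoint_distal, model.breakpoint_proximal
        prof = suppression_profile(model, [bp_d - 100, bp_d + 100, bp_p + 100, bp_p + 4_000_000])
        assert prof[0] == 0.0  # just distal of the distal breakpoint
        assert math.isnan(prof[1])  # inside the inversion: governed by p_co_intra
        assert prof[2] == 0.0
        assert prof[3] == 1.0


class TestSimulateMeiosis:
    def test_seed_determinism(self, model):
        a = simulate_meiosis(model, 123)
        b = simulate_meiosis(model, 123)
        assert a == b

    def test_no_transmitted_single_intra_inversion_co(self, model):
        # heavy DSB load to force frequent intra-inversion COs
        hot = replace(model, dsb_mean=6.0)
        for seed in range(300):
            prod = simulate_meiosis(hot, seed)
            n_intra = int(hot.is_intra_inversion(np.array(prod.co_positions)).sum())
            assert n_intra % 2 == 0

    def test_rejection_disabled_without_inversion(self, model):
        off = replace(model, inversion_active=False, dsb_mean=6.0)
        seen_odd = any(
            int(off.is_intra_inversion(np.array(simulate_meiosis(off, s).co_positions)).sum()) % 2
            for s in range(200)
        )
        assert seen_odd  # single "intra" COs transmit freely when no inversion

    def test_wildtype_co_count_matches_map_length(self):
        """In an unsuppressed interval, E[CO] = map length / 100."""
        wt = InversionCrossModel(inversion_active=False)
        interval = (DEFAULT_MARKERS["y"], DEFAULT_MARKERS["cv"])
        wt = scaled_to_map_length(wt, interval, 9.5)
        assert expected_map_length(wt, interval) == pytest.approx(9.5)
        rng = np.random.default_rng(42)
        n = 20_000
        lo, hi = interval
        hits = 0
        for _ in range(n):
            prod = simulate_meiosis(wt, rng)
            hits += sum(1 for x in prod.co_positions if lo <= x < hi)
        p = 9.5 / 100
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_intra_inversion_single_co_rate_calibration(self, model):
        # defaults reproduce the ~12% single-CO rate inside the inversion
        assert intra_inversion_single_co_probability(model) == pytest.approx(0.12, abs=0.002)
        p = calibrated_p_co_intra(model, target=0.12)
        assert p == pytest.approx(model.p_co_intra, abs=0.01)

    def test_transmission_distortion_enriches_conversions(self, model):
        """Polar-body elimination raises the transmitted NCOGC fraction
        while leaving conversion *generation* untouched."""
        on = model
        off = replace(model, inversion_active=False)
        n = 12_000
        rng_on = np.random.default_rng(7)
        rng_off = np.random.default_rng(7)
        frac_on = sum(bool(simulate_meiosis(on, rng_on).tracts) for _ in range(n)) / n
        frac_off = sum(bool(simulate_meiosis(off, rng_off).tracts) for _ in range(n)) / n
        se = math.sqrt(2 * 0.25 / n)
        assert frac_on - frac_off > 3 * se


class TestOriginAt:
    def test_co_switches_origin(self):
        prod = MeioticProduct(base_origin=0, co_positions=(1000,), tracts=())
        assert origin_at(prod, [500, 1000, 1001, 2000]).tolist() == [0, 0, 1, 1]

    def test_tract_flips_locally(self):
        prod = MeioticProduct(base_origin=0, co_positions=(), tracts=((300, 500),))
        assert origin_at(prod, [200, 300, 400, 500, 600]).tolist() == [0, 1, 1, 1, 0]

    def test_tract_on_switched_background(self):
        prod = MeioticProduct(base_origin=0, co_positions=(1000,), tracts=((2000, 2100),))
        assert origin_at(prod, [1500, 2050, 2500]).tolist() == [1, 0, 1]


class TestSimulateCross:
    def test_seed_determinism(self, model, coarse_panel):
        a = simulate_cross(model, coarse_panel, None, 20, seed=5)
        b = simulate_cross(model, coarse_panel, None, 20, seed=5)
        assert all(
            np.array_equal(x.observation.alleles, y.observation.alleles)
            and x.product == y.product
            for x, y in zip(a, b)
        )

    def test_noise_free_round_trip(self, model, coarse_panel):
        """With no genotyping error every resolvable CO and every tract
        covering a marker is recovered, with no spurious calls."""
        offspring = simulate_cross(model, coarse_panel, None, 150, seed=11)
        results = call_all(offspring, coarse_panel)
        s = score_recovery(offspring, results, coarse_panel)
        assert s.n_co_resolvable > 30  # sanity: the test exercises something
        assert s.n_tract_detectable > 10
        assert s.co_recovery == 1.0
        assert s.tract_recovery == 1.0
        assert s.n_spurious == 0

    def test_uncertainty_intervals_contain_truth(self, model, coarse_panel):
        offspring = simulate_cross(model, coarse_panel, None, 60, seed=13)
        results = call_all(offspring, coarse_panel)
        for o in offspring:
            for e in results[o.offspring_id].events:
                if e.event_class != "CO":
                    continue
                assert any(
                    e.left_flank <= x < e.right_flank for x in o.product.co_positions
                )

    def test_ndj_offspring_lack_y_coverage(self, coarse_panel):
        m = InversionCrossModel(ndj_rate=0.5)
        offspring = simulate_cross(m, coarse_panel, None, 40, seed=3)
        ndj = [o for o in offspring if o.is_ndj]
        assert ndj and all(o.observation.y_coverage < 0.1 for o in ndj)
        normal = [o for o in offspring if not o.is_ndj]
        assert all(o.observation.y_coverage > 0.1 for o in normal)

    def test_ndj_mimics_recombinant_selection(self, coarse_panel):
        """Cross-2 style: NDJ contaminates the recombinant-selected pool
        at the expected fraction, and the Y-coverage detector finds it."""
        scheme = SelectionScheme(mode="recombinant")
        base = InversionCrossModel()
        # estimate the phenotypic recombinant rate, then set the NDJ rate
        # so that ~42% of selected offspring are nondisjunction
        probe = simulate_cross(
            base, coarse_panel, SelectionScheme(mode=None), 1500, seed=21
        )
        p_rec = np.mean([
            o.observation.selection_class == "recombinant" for o in probe
        ])
        k = 0.42 / 0.58 * p_rec
        m = replace(base, ndj_rate=k / (1 + k))
        n = 300
        offspring = simulate_cross(m, coarse_panel, scheme, n, seed=22)
        flagged = sum(
            detect_nondisjunction(o.observation).is_nondisjunction for o in offspring
        )
        truth = sum(o.is_ndj for o in offspring)
        assert flagged == truth  # detector recovers exactly the injected NDJ
        se = math.sqrt(0.42 * 0.58 / n)
        assert abs(flagged / n - 0.42) < 3 * se

    def test_jackpot_clone_recovered_as_group(self, model, coarse_panel):
        offspring = simulate_cross(
            model, coarse_panel, None, 30, seed=17, jackpot_clone_sizes=(3,)
        )
        results = call_all(offspring, coarse_panel)
        events = [e for r in results.values() for e in r.events]
        groups = find_jackpots(events)
        assert [g.size for g in groups] == [3]
        members = set(groups[0].offspring_ids)
        assert members == {o.offspring_id for o in offspring if o.jackpot_id == 0}

    def test_unsatisfiable_selection_raises(self, coarse_panel):
        no_co = InversionCrossModel(dsb_mean=0.0, ndj_rate=0.0)
        scheme = SelectionScheme(mode="recombinant")
        with pytest.raises(RuntimeError, match="selection"):
            simulate_cross(no_co, coarse_panel, scheme, 5, seed=1)
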