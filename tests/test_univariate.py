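from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from urimet import (
    BucketTable,
    CohortConfig,
    MetaboliteRegion,
    MetaboliteSignature,
    bucket_spectra,
    build_table,
    integrate_region,
    mann_whitney,
    percent_variation,
    simulate_cohort,
)


def make_table(values, lows, width=0.01, groups=None):
    values = np.asarray(values, dtype=float)
    lows = np.asarray(lows, dtype=float)
    edges = np.column_stack([lows, lows + width])
    ids = [f"s{i}" for i in range(values.shape[0])]
    return BucketTable(ids, edges, values, groups)


def mann_whitney_oracle(a, b):
    """Brute force: U and its exact two-sided p by enumerating every
    assignment of the pooled values to the two groups."""
    pooled = list(a) + list(b)
    n, na = len(pooled), len(a)
    u_obs = sum(1 for x in a for y in b if x > y)
    us = []
    for comb in combinations(range(n), na):
        in_a = set(comb)
        sa = [pooled[i] for i in comb]
        sb = [pooled[i] for i in range(n) if i not in in_a]
        us.append(sum(1 for x in sa for y in sb if x > y))
    us = np.array(us)
    p_le = (us <= u_obs).mean()
    p_ge = (us >= u_obs).mean()
    return u_obs, min(1.0, 2 * min(p_le, p_ge))


class TestIntegration:
    def test_window_covering_three_buckets_sums_them(self):
        table = make_table([[1.0, 2.0, 3.0]], [1.00, 1.01, 1.02])
        region = MetaboliteRegion("x", (1.00, 1.03))
        assert integrate_region(table, region)[0] == pytest.approx(6.0)

    def test_half_covered_bucket_weighted_by_overlap(self):
        table = make_table([[4.0]], [1.00])
        region = MetaboliteRegion("x", (1.005, 1.02))
        assert integrate_region(table, region)[0] == pytest.approx(2.0)

    def test_singlet_area_recovered_within_one_percent(self):
        # isolated synthetic singlet of known area; window spans the
        # truncated support, so the integral recovers area/step. The probe
        # linewidth is several grid steps wide so the discrete sum carries
        # no sampling (aliasing) error, leaving only the ~0.6% tail
        # truncation of the generator's lineshape
        lib = [MetaboliteSignature("probe", ((6.520, 1.0, 0.004),), 5.0)]
        cfg = CohortConfig(
            n_group_a=3, n_group_b=3, effect_map={}, dilution_range=(1, 1),
            noise_sd=0.0, baseline_amplitude=0.0, log_concentration_sd=0.1,
            jitter_scale=0.0, seed=9,
        )
        spectra, truth = simulate_cohort(cfg, lib)
        table = bucket_spectra(spectra, 0.001)
        region = MetaboliteRegion("probe", (6.31, 6.73))
        areas = integrate_region(table, region) * 0.001
        np.testing.assert_allclose(areas, truth.concentrations["probe"], rtol=0.01)

    def test_fine_and_coarse_integrals_agree_for_blockwise_data(self):
        # overlap weighting treats a bucket's mass as uniform within the
        # bucket, so fine and rebinned representations agree exactly for
        # signal that is constant within each coarse bucket
        from urimet import rebin

        rng = np.random.default_rng(0)
        block = rng.gamma(2.0, 1.0, size=(4, 12))
        fine_vals = np.repeat(block, 10, axis=1) / 10.0
        fine = make_table(fine_vals, 1.0 + 0.001 * np.arange(120), width=0.001)
        coarse = rebin(fine, 10)
        region = MetaboliteRegion("x", (1.0145, 1.0910))
        np.testing.assert_allclose(
            integrate_region(fine, region),
            integrate_region(coarse, region),
            rtol=1e-9,
        )

    def test_window_inside_excluded_region_rejected(self):
        table = BucketTable(
            ["s0"], np.array([[1.0, 1.01]]), np.array([[1.0]]),
            excluded_regions=[(4.55, 5.09)],
        )
        with pytest.raises(ValueError, match="excluded"):
            integrate_region(table, MetaboliteRegion("water-ish", (4.6, 4.7)))

    def test_window_overlapping_no_bucket_rejected(self):
        table = make_table([[1.0]], [1.00])
        with pytest.raises(ValueError):
            integrate_region(table, MetaboliteRegion("x", (2.0, 2.1)))


class TestMannWhitney:
    def test_identical_groups_give_p_one(self):
        u, p = mann_whitney([1.0, 2.0], [1.0, 2.0])
        assert p == pytest.approx(1.0)

    def test_fully_separated_triplets_match_enumeration(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        u_o, p_o = mann_whitney_oracle([1, 2, 3], [4, 5, 6])
        assert u == u_o == 0
        assert p == pytest.approx(p_o) == pytest.approx(0.1)

    @pytest.mark.parametrize(
        "na,nb",
        [(na, nb) for na in range(2, 9) for nb in range(na, 9) if na + nb <= 10],
    )
    def test_exact_p_matches_brute_force_for_small_samples(self, na, nb):
        rng = np.random.default_rng(100 * na + nb)
        for _ in range(5):
            pooled = rng.permutation(np.arange(1.0, na + nb + 1))
            a, b = pooled[:na], pooled[na:]
            u, p = mann_whitney(a, b)
            u_o, p_o = mann_whitney_oracle(a, b)
            assert u == u_o
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_shifted_gaussians_usually_detected(self):
        rng = np.random.default_rng(30)
        hits = 0
        for _ in range(30):
            a = rng.normal(0.0, 1.0, 50)
            b = rng.normal(1.0, 1.0, 50)
            hits += mann_whitney(a, b)[1] < 0.05
        assert hits >= 27

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0], [2.0, 3.0])


class TestPercentVariation:
    def test_equal_means_give_zero(self):
        assert percent_variation(3.7, 3.7) == 0.0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_variation(0.0, 1.0)

    @given(
        ref=st.floats(0.1, 100.0),
        case=st.floats(0.1, 100.0),
    )
    def test_exchange_of_roles_follows_algebraic_identity(self, ref, case):
        r = percent_variation(ref, case) / 100.0
        back = percent_variation(case, ref) / 100.0
        assert back == pytest.approx(-r / (1.0 + r), rel=1e-9)


class TestBuildTable:
    def test_row_count_and_sorting(self, strong_cohort):
        from urimet import discriminant_regions

        rows = build_table(strong_cohort.coarse, discriminant_regions(), "BPH", "PCa")
        assert len(rows) == 8
        assert [r.window[0] for r in rows] == sorted(r.window[0] for r in rows)
        assert all(r.sem_reference >= 0 and 0 <= r.p_value <= 1 for r in rows)

    def test_signs_match_planted_directions(self, strong_cohort):
        from urimet import discriminant_regions

        rows = build_table(strong_cohort.coarse, discriminant_regions(), "BPH", "PCa")
        effects = strong_cohort.config.effect_map
        for r in rows:
            planted = effects[r.name]
            assert (r.percent_variation > 0) == (planted > 1.0), r.name

    def test_benjamini_hochberg_flag_is_monotone(self, strong_cohort):
        from urimet import discriminant_regions

        raw = build_table(strong_cohort.coarse, discriminant_regions(), "BPH", "PCa")
        adj = build_table(
            strong_cohort.coarse, discriminant_regions(), "BPH", "PCa", adjust=True
        )
        for r_raw, r_adj in zip(raw, adj):
            assert r_adj.p_adjusted >= r_raw.p_value - 1e-15
        assert sum(r.significant for r in adj) <= sum(r.significant for r in raw)
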