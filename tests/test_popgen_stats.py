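import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from afdld.io_formats import PopulationMap
from afdld.popgen_stats import (
    afd,
    allele_freq,
    call_afd_ld_candidates,
    daf,
    daf_spectrum,
    maf_filter,
    panel_alt_freq,
    snp_mean_r2,
    window_scan,
)

from conftest import toy_matrix


def popmap_for(matrix, split):
    mapping = {
        s: ("a" if i < split else "b") for i, s in enumerate(matrix.samples)
    }
    if "b" not in mapping.values():  # keep the focal pair well-formed
        mapping["placeholder_b"] = "b"
    return PopulationMap(mapping, "a", "b")


class TestAlleleFreq:
    def test_haploid_half(self):
        m = toy_matrix([10], [[1, 1, 0, 0]])
        pm = popmap_for(m, 4)
        assert allele_freq(m, pm, "a")[0] == 0.5

    def test_missing_excluded_from_denominator(self):
        m = toy_matrix([10], [[1, None, 1]])
        pm = popmap_for(m, 3)
        assert allele_freq(m, pm, "a")[0] == 1.0

    def test_all_missing_is_missing(self):
        m = toy_matrix([10], [[None, None, None]])
        pm = popmap_for(m, 3)
        assert np.isnan(allele_freq(m, pm, "a")[0])

    def test_unknown_population_aborts(self):
        m = toy_matrix([10], [[0, 1, 0]])
        pm = popmap_for(m, 3)
        with pytest.raises(KeyError):
            allele_freq(m, pm, "c")


class TestAfd:
    @pytest.mark.parametrize(
        "fa,fb,expected", [(1.0, 0.0, 1.0), (0.3, 0.3, 0.0), (0.9, 0.15, 0.75)]
    )
    def test_elementwise(self, fa, fb, expected):
        assert afd(np.array([fa]), np.array([fb]))[0] == pytest.approx(expected)

    def test_missing_propagates(self):
        out = afd(np.array([np.nan, 0.5]), np.array([0.2, np.nan]))
        assert np.isnan(out).all()

    def test_length_mismatch_aborts(self):
        with pytest.raises(ValueError):
            afd(np.array([0.1, 0.2]), np.array([0.1]))

    @given(st.lists(st.integers(0, 1), min_size=6, max_size=6))
    @settings(deadline=None, max_examples=50)
    def test_invariant_under_ref_alt_relabeling(self, row):
        """Flipping which allele is counted leaves AFD unchanged."""
        m = toy_matrix([10], [row])
        flipped = toy_matrix([10], [[1 - v for v in row]])
        pm = popmap_for(m, 3)
        a1 = afd(allele_freq(m, pm, "a"), allele_freq(m, pm, "b"))
        a2 = afd(allele_freq(flipped, pm, "a"), allele_freq(flipped, pm, "b"))
        np.testing.assert_allclose(a1, a2, atol=1e-12)


class TestMafFilter:
    def test_strict_threshold_boundary(self):
        # panel freq exactly 0.05 must be removed under a strict rule
        m = toy_matrix([10, 20], [[1] + [0] * 19, [1] * 10 + [0] * 10])
        out = maf_filter(m, 0.05)
        assert out.pos.tolist() == [20]

    def test_common_site_retained(self):
        m = toy_matrix([10], [[1] * 10 + [0] * 10])
        assert maf_filter(m, 0.05).n_variants == 1

    def test_threshold_zero_drops_only_monomorphic(self):
        m = toy_matrix([10, 20], [[0, 0, 0, 0], [1, 0, 0, 0]])
        assert maf_filter(m, 0.0).pos.tolist() == [20]


class TestSnpMeanR2:
    def test_perfect_ld_neighbor(self):
        m = toy_matrix([100, 200], [[0, 0, 1, 1], [0, 0, 1, 1]])
        np.testing.assert_allclose(snp_mean_r2(m, window_bp=20_000), [1.0, 1.0])

    def test_orthogonal_neighbor(self):
        m = toy_matrix([100, 200], [[0, 0, 1, 1], [0, 1, 0, 1]])
        np.testing.assert_allclose(
            snp_mean_r2(m, window_bp=20_000), [0.0, 0.0], atol=1e-12
        )

    def test_mean_over_two_neighbors(self):
        m = toy_matrix(
            [100, 200, 300], [[0, 1, 0, 1], [0, 0, 1, 1], [0, 0, 1, 1]]
        )
        got = snp_mean_r2(m, window_bp=20_000)
        assert got[1] == pytest.approx(0.5, abs=1e-12)

    def test_no_neighbor_in_window_missing(self):
        m = toy_matrix([100, 50_000], [[0, 0, 1, 1], [0, 0, 1, 1]])
        assert np.isnan(snp_mean_r2(m, window_bp=20_000)).all()

    def test_zero_variance_neighbor_contributes_nothing(self):
        m = toy_matrix([100, 200], [[0, 0, 1, 1], [1, 1, 1, 1]])
        assert np.isnan(snp_mean_r2(m, window_bp=20_000)[0])

    def test_centered_mode_halves_reach(self):
        m = toy_matrix([100, 12_000], [[0, 0, 1, 1], [0, 0, 1, 1]])
        assert np.isnan(snp_mean_r2(m, window_bp=20_000, neighbor_mode="centered")).all()
        np.testing.assert_allclose(
            snp_mean_r2(m, window_bp=20_000, neighbor_mode="distance"), [1.0, 1.0]
        )

    def test_nonpositive_window_aborts(self):
        m = toy_matrix([100], [[0, 1, 0, 1]])
        with pytest.raises(ValueError):
            snp_mean_r2(m, window_bp=0)

    def test_pairwise_complete_samples(self):
        # missing entries drop the sample from that pair only
        m = toy_matrix([100, 200], [[0, 0, 1, 1, None], [0, 0, 1, 1, 0]])
        np.testing.assert_allclose(snp_mean_r2(m, window_bp=20_000), [1.0, 1.0])


class TestDaf:
    def test_ancestral_ref_keeps_alt_freq(self):
        m = toy_matrix([10], [[1, 1, 1, 0, 0, 0, 0, 0, 0, 0]])
        out = daf(m, np.array(["A"]), np.array([0.9]))
        assert out[0] == pytest.approx(0.3)

    def test_ancestral_alt_flips_polarity(self):
        m = toy_matrix([10], [[1, 1, 1, 0, 0, 0, 0, 0, 0, 0]])
        out = daf(m, np.array(["T"]), np.array([0.8]))
        assert out[0] == pytest.approx(0.7)

    def test_probability_at_or_below_threshold_missing(self):
        m = toy_matrix([10, 20], [[1, 0, 0, 0], [1, 0, 0, 0]])
        out = daf(m, np.array(["A", "A"]), np.array([0.55, 0.6]), prob_threshold=0.6)
        assert np.isnan(out).all()

    def test_ancestral_matching_neither_allele_missing(self):
        m = toy_matrix([10], [[1, 0, 0, 0]])
        out = daf(m, np.array(["G"]), np.array([0.99]))
        assert np.isnan(out[0])


class TestDafSpectrum:
    def test_two_bin_proportions(self):
        out = daf_spectrum(np.array([0.05, 0.05, 0.95]), [0, 0.5, 1])
        np.testing.assert_allclose(out, [2 / 3, 1 / 3])

    def test_boundary_value_in_right_bin(self):
        out = daf_spectrum(np.array([0.5]), [0, 0.5, 1])
        np.testing.assert_allclose(out, [0, 1])

    def test_last_bin_closed(self):
        out = daf_spectrum(np.array([1.0]), [0, 0.5, 1])
        np.testing.assert_allclose(out, [0, 1])

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            daf_spectrum(np.array([np.nan]), [0, 0.5, 1])

    def test_unsorted_edges_abort(self):
        with pytest.raises(ValueError):
            daf_spectrum(np.array([0.5]), [0, 1, 0.5])

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(5)
        out = daf_spectrum(rng.random(500), np.linspace(0, 1, 11))
        assert out.sum() == pytest.approx(1.0)


class TestCandidateCalling:
    def test_fixed_thresholds_candidate(self):
        call = call_afd_ld_candidates(
            np.array([0.75]), np.array([0.25]), fixed_thresholds=(0.70, 0.19)
        )
        assert call.indicator[0]

    def test_exact_threshold_not_candidate(self):
        call = call_afd_ld_candidates(
            np.array([0.70]), np.array([0.25]), fixed_thresholds=(0.70, 0.19)
        )
        assert not call.indicator[0]

    def test_percentile_thresholds_linear_interpolation(self):
        # 19 values at 0.1 plus one at 1.0: the 95th percentile interpolates
        # between the 19th and 20th order statistics at 0.145
        afd_col = np.array([0.1] * 19 + [1.0])
        ld_col = np.linspace(0, 1, 20)
        call = call_afd_ld_candidates(afd_col, ld_col, 95, 95)
        assert call.afd_threshold == pytest.approx(0.145)
        assert (~call.indicator[:-1]).all()

    def test_too_few_values_abort(self):
        with pytest.raises(ValueError):
            call_afd_ld_candidates(np.full(10, 0.5), np.full(10, 0.5))

    def test_missing_never_candidate(self):
        call = call_afd_ld_candidates(
            np.array([np.nan]), np.array([0.9]), fixed_thresholds=(0.1, 0.1)
        )
        assert not call.indicator[0]


class TestWindowScan:
    def test_ratio(self):
        pos = np.arange(1, 11) * 100
        qual = np.array([True] * 4 + [False] * 6)
        out = window_scan(["c"] * 10, pos, qual, window_bp=20_000, step_bp=20_000)
        assert out["ratio"].iloc[0] == pytest.approx(0.4)

    def test_all_qualifying_every_window_one(self):
        pos = np.arange(1, 51) * 500
        out = window_scan(["c"] * 50, pos, np.ones(50, bool), 5_000, 1_000)
        nonempty = out[out["n_total"] > 0]
        assert (nonempty["ratio"] == 1.0).all()

    def test_empty_window_missing_ratio(self):
        pos = np.array([100, 90_000])
        out = window_scan(["c"] * 2, pos, np.ones(2, bool), 10_000, 10_000)
        middle = out[(out["start"] > 20_000) & (out["end"] < 80_000)]
        assert middle["ratio"].isna().all()

    def test_invalid_window_step_aborts(self):
        with pytest.raises(ValueError):
            window_scan(["c"], np.array([1]), np.array([True]), 100, 200)

    def test_disjoint_tabulation_oracle_when_step_equals_window(self):
        rng = np.random.default_rng(21)
        pos = np.sort(rng.choice(50_000, 300, replace=False) + 1)
        qual = rng.random(300) < 0.3
        w = 5_000
        out = window_scan(["c"] * 300, pos, qual, w, w)
        first = pos[0]
        for _, row in out.iterrows():
            sel = (pos >= row["start"]) & (pos <= row["end"])
            assert row["n_total"] == sel.sum()
            assert row["n_qualifying"] == qual[sel].sum()
            assert (row["start"] - first) % w == 0
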