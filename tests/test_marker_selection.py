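import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mirperm.expression_io import ExpressionMatrix
from mirperm.marker_selection import (
    NullDistribution,
    PermutationScheme,
    benjamini_hochberg,
    call_differential,
    per_mirna_p_values,
    permutation_null,
    select_markers,
    signed_fold_change,
    smoothed_p,
    smoothed_p_values,
    snr_statistic,
    standardize_and_cluster,
)
from mirperm.preprocessing import collapse_to_mirna, filter_background
from mirperm.synthetic_data import generate_expression, mirna_names

from conftest import spiked_config


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Independent BH formulation: q_i = min over thresholds t >= p_i of t*m/#{p<=t}."""
    m = len(p)
    out = np.empty(m)
    for i, pi in enumerate(p):
        candidates = [t * m / np.sum(p <= t) for t in p if t >= pi]
        out[i] = min(1.0, min(candidates))
    return out


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "t, c, expected",
        [(10.0, 10.0, 1.0), (2.0, 10.0, -5.0), (15.0, 10.0, 1.5)],
    )
    def test_hand_values(self, t, c, expected):
        assert signed_fold_change(t, c) == pytest.approx(expected)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            signed_fold_change(0.0, 1.0)

    @given(st.floats(0.1, 1e6), st.floats(0.1, 1e6))
    @settings(derandomize=True, max_examples=50)
    def test_magnitude_at_least_one_and_reciprocal_antisymmetry(self, a, b):
        fc = signed_fold_change(a, b)
        assert abs(fc) >= 1.0
        back = signed_fold_change(b, a)
        assert math.isclose(abs(fc), abs(back), rel_tol=1e-9)


class TestSnrStatistic:
    def test_hand_value(self):
        snr, summary = snr_statistic([4.0, 6.0], [1.0, 3.0])
        assert snr == pytest.approx(3.0 / (2.0 * math.sqrt(2.0)), rel=1e-12)
        assert summary.mu_treated == 5.0 and summary.mu_control == 2.0

    def test_equal_means_zero(self):
        snr, _ = snr_statistic([1.0, 3.0], [3.0, 1.0])
        assert snr == 0.0

    def test_group_swap_negates(self):
        a, b = [4.0, 6.0, 5.0], [1.0, 3.0, 2.0]
        assert snr_statistic(a, b)[0] == pytest.approx(-snr_statistic(b, a)[0])

    @pytest.mark.parametrize("seed", range(5))
    def test_shift_and_scale_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(5, 1, 4), rng.normal(3, 1, 4)
        base = snr_statistic(a, b)[0]
        assert snr_statistic(a + 7.5, b + 7.5)[0] == pytest.approx(base)
        assert snr_statistic(a * 3.25, b * 3.25)[0] == pytest.approx(base)

    def test_sigma_floor_guards_constant_groups(self):
        snr, _ = snr_statistic([2.0, 2.0], [1.0, 1.0], sigma_floor=1e-8)
        assert np.isfinite(snr) and snr > 0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            snr_statistic([1.0], [1.0, 2.0])


class TestPermutationNull:
    def make_values(self, m=7, seed=0):
        rng = np.random.default_rng(seed)
        return rng.normal(8, 1, size=(m, 6)), np.array([True] * 3 + [False] * 3)

    def test_exhaustive_three_vs_three_has_twenty_relabelings(self):
        values, mask = self.make_values()
        null = permutation_null(values, mask)
        assert null.n_relabelings == math.comb(6, 3) == 20
        assert null.stats.shape == (20, 7)
        assert null.mode == "exhaustive"
        assert null.identity_index >= 0 and null.complement_index >= 0

    def test_exhaustive_is_seed_independent(self):
        values, mask = self.make_values()
        a = permutation_null(values, mask, PermutationScheme(seed=1))
        b = permutation_null(values, mask, PermutationScheme(seed=99))
        assert np.array_equal(a.stats, b.stats)

    def test_constant_matrix_all_null_statistics_zero(self):
        values = np.full((4, 6), 3.0)
        mask = np.array([True] * 3 + [False] * 3)
        null = permutation_null(values, mask)
        assert np.all(null.stats == 0.0)

    def test_complement_relabeling_negates_identity(self):
        values, mask = self.make_values()
        null = permutation_null(values, mask)
        assert np.allclose(null.stats[null.complement_index],
                           -null.stats[null.identity_index])

    def test_sampled_mode_draws_distinct_relabelings(self):
        rng = np.random.default_rng(0)
        values = rng.normal(8, 1, size=(3, 10))
        mask = np.array([True] * 5 + [False] * 5)
        null = permutation_null(values, mask,
                                PermutationScheme(n_permutations=50, seed=4))
        assert null.mode == "sampled"
        assert null.n_relabelings == 50
        assert len(set(null.assignments)) == 50

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValueError):
            PermutationScheme(mode="sampled", n_permutations=0)


class TestSmoothedP:
    def test_hand_pool(self):
        assert smoothed_p(0.75, [-1.0, -0.5, 0.5, 1.0]) == pytest.approx(0.6)

    def test_observed_zero_gives_one(self):
        assert smoothed_p(0.0, [-1.0, -0.5, 0.5, 1.0]) == 1.0

    def test_observed_beyond_pool_gives_floor(self):
        pool = np.linspace(-1, 1, 40)
        assert smoothed_p(2.0, pool) == pytest.approx(1.0 / 41.0)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            smoothed_p(1.0, [])

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(3)
        values = rng.normal(8, 1, size=(9, 6))
        mask = np.array([True] * 3 + [False] * 3)
        null = permutation_null(values, mask)
        observed = null.stats[null.identity_index]
        pooled = null.pool(exclude_signal_splits=True)
        expected = [smoothed_p(o, pooled) for o in observed]
        assert np.allclose(smoothed_p_values(observed, null), expected)

    def test_per_mirna_p_granularity_bound(self):
        """Per-miRNA (unpooled) permutation p can never beat the 1/20 resolution."""
        rng = np.random.default_rng(5)
        values = rng.normal(8, 1, size=(30, 6))
        mask = np.array([True] * 3 + [False] * 3)
        null = permutation_null(values, mask)
        p = per_mirna_p_values(null.stats[null.identity_index], null)
        assert np.all(p >= 1.0 / 20.0)

    def test_pooling_beats_single_mirna_resolution(self):
        """A strongly separated miRNA among many nulls reaches p < 0.005."""
        rng = np.random.default_rng(6)
        values = rng.normal(8, 0.2, size=(200, 6))
        values[0, :3] += 5.0
        mask = np.array([True] * 3 + [False] * 3)
        null = permutation_null(values, mask)
        p = smoothed_p_values(null.stats[null.identity_index], null)
        assert p[0] < 0.005


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.2]).tolist() == [0.2]

    def test_hand_example(self):
        adjusted = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adjusted, 0.04)

    def test_all_ones(self):
        assert np.all(benjamini_hochberg([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.0001], [np.nan, 0.5]):
            with pytest.raises(ValueError):
                benjamini_hochberg(bad)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
    @settings(derandomize=True, max_examples=200)
    def test_matches_bruteforce_definition(self, p_list):
        p = np.array(p_list)
        assert np.allclose(benjamini_hochberg(p), bh_oracle(p), atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(1e-4, 1, size=30)
        assert np.all(benjamini_hochberg(p) >= p - 1e-15)


class TestCallDifferential:
    def frame(self, rows):
        df = pd.DataFrame(rows, columns=["fc", "p_value", "fdr"])
        df.index = [f"mir{i}" for i in range(len(df))]
        return df

    @pytest.mark.parametrize(
        "fc, p, fdr, expected",
        [
            (1.0, 1e-6, 1e-6, False),   # FC criterion fails whatever p
            (-1.5, 0.004, 0.004, True),  # FC boundary inclusive
            (1.5, 0.004, 0.004, True),
            (-5.0, 0.005, 0.001, False),  # p boundary strict
            (-5.0, 0.001, 0.005, False),  # FDR boundary strict
        ],
    )
    def test_three_criterion_boundaries(self, fc, p, fdr, expected):
        out = call_differential(self.frame([(fc, p, fdr)]))
        assert bool(out["significant"].iloc[0]) is expected

    def test_ranking_order(self):
        out = call_differential(self.frame([
            (1.2, 0.5, 0.5), (-3.0, 0.01, 0.02), (3.0, 0.001, 0.002),
            (-3.0, 0.001, 0.002),
        ]))
        # |fc| desc, then p asc, then id asc
        assert list(out.index) == ["mir2", "mir3", "mir1", "mir0"]
        assert out["rank"].tolist() == [1, 2, 3, 4]

    def test_vacuous_thresholds_flag_everything_with_fc(self):
        out = call_differential(self.frame([(1.0, 0.9, 0.9), (2.0, 0.9, 0.9)]),
                                fc_cut=1.0, p_cut=1.1, fdr_cut=1.1)
        assert out["significant"].all()


class TestSelectMarkers:
    def test_down_only_spikes_give_down_only_calls(self):
        spikes = {m: -4.5 for m in mirna_names(300)[:20]}
        config = spiked_config(300, spikes, seed=21)
        matrix, annotation, truth = generate_expression(config)
        filtered, _ = filter_background(matrix, 30.0, annotation)
        collapsed = collapse_to_mirna(filtered, annotation)
        res = select_markers(collapsed, seed=2)
        sig = res[res["significant"]]
        assert len(sig) > 0
        assert (sig["fc"] < 0).all()

    def test_strong_spikes_rank_above_all_nulls(self):
        spikes = {m: -4.0 for m in mirna_names(200)[:15]}
        config = spiked_config(200, spikes, seed=22)
        matrix, annotation, truth = generate_expression(config)
        filtered, _ = filter_background(matrix, 30.0, annotation)
        collapsed = collapse_to_mirna(filtered, annotation)
        res = select_markers(collapsed, seed=3)
        top = set(res.index[:15])
        assert top == set(truth.differential_ids)
        assert res["significant"].iloc[:15].all()


class TestStandardizeAndCluster:
    def matrix(self):
        rng = np.random.default_rng(11)
        values = pd.DataFrame(
            rng.uniform(10, 100, size=(5, 6)),
            index=[f"mir{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(6)],
        )
        values.loc["mir2"] = 42.0                 # constant row
        values.loc["mir4"] = values.loc["mir0"]   # duplicate row
        groups = {s: ("treated" if i < 3 else "control")
                  for i, s in enumerate(values.columns)}
        return ExpressionMatrix(values, groups)

    def test_rows_standardized(self):
        order, z = standardize_and_cluster(self.matrix(), ["mir0", "mir1", "mir3"])
        arr = z.to_numpy()
        assert np.allclose(arr.mean(axis=1), 0.0, atol=1e-12)
        assert np.allclose(arr.std(axis=1), 1.0, atol=1e-12)

    def test_constant_row_becomes_zeros(self):
        _, z = standardize_and_cluster(self.matrix(), ["mir0", "mir2"])
        assert np.all(z.loc["mir2"] == 0.0)

    def test_identical_rows_are_adjacent_leaves(self):
        order, _ = standardize_and_cluster(
            self.matrix(), ["mir0", "mir1", "mir3", "mir4"])
        assert abs(order.index("mir0") - order.index("mir4")) == 1

    def test_unknown_mirna_rejected(self):
        with pytest.raises(KeyError):
            standardize_and_cluster(self.matrix(), ["mir0", "nope"])

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            standardize_and_cluster(self.matrix(), [])
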