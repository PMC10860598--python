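"""Slope statistic, bootstrap/permutation inference, FDR, power, adjudication."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.power import TTestPower

from dsriem.basis import ChannelBasis
from dsriem.stats import (
    MODEL_PREDICTIONS,
    SlopeTest,
    adjudicate_models,
    bootstrap_difference_test,
    bootstrap_slope_test,
    collapse_curve,
    fdr_bh,
    paired_permutation_test,
    pearson_correlation,
    reconstruction_slope,
    required_sample_size,
    slope_operator,
)
from dsriem.synth import remap_channel_vector


def brute_force_bh(p, q):
    """Exhaustive step-up oracle: largest i with p_(i) <= i q / m."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    return mask


class TestReconstructionSlope:
    def test_stated_location_example(self, loc_basis):
        # offsets (0, +-40, +-80, +-120, +-160) with values
        # (1,.6,.6,.3,.3,.1,.1,0,0) collapse to [0,.1,.3,.6,1] -> slope 0.25
        by_abs = {0: 1.0, 40: 0.6, 80: 0.3, 120: 0.1, 160: 0.0}
        curve = np.array([by_abs[abs(o)] for o in loc_basis.offsets])
        assert reconstruction_slope(curve, loc_basis) == pytest.approx(0.25)
        ranks, vals = collapse_curve(curve, loc_basis)
        assert list(ranks) == [0, 1, 2, 3, 4]
        assert np.allclose(vals, [0, 0.1, 0.3, 0.6, 1.0])

    def test_flat_curve_zero_slope(self, ori_basis):
        assert reconstruction_slope(np.full(6, 0.3), ori_basis) == pytest.approx(0.0)

    def test_reflection_negates_slope(self, loc_basis, rng):
        curve = rng.uniform(0, 1, 9)
        s = reconstruction_slope(curve, loc_basis)
        assert reconstruction_slope(remap_channel_vector(curve), loc_basis) == (
            pytest.approx(-s)
        )

    def test_orientation_collapses_to_four_points(self, ori_basis):
        ranks, vals = collapse_curve(np.arange(6, dtype=float), ori_basis)
        # offsets -60,-30,0,30,60,90: 90 alone, +-60 pair, +-30 pair, 0 alone
        assert len(ranks) == 4
        assert vals[0] == 5.0          # the +90 channel enters singly
        assert vals[-1] == 2.0         # the 0-offset channel

    def test_unrecentered_rejected(self, loc_basis):
        with pytest.raises(ValueError):
            reconstruction_slope(np.ones(9), loc_basis, recentered=False)

    @given(st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, a, b):
        basis = ChannelBasis.location()
        curve = np.linspace(0, 1, 9)
        lhs = reconstruction_slope(a * curve + b, basis)
        assert lhs == pytest.approx(a * reconstruction_slope(curve, basis), abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    def test_operator_agrees_with_explicit_regression(self, seed):
        rng = np.random.default_rng(seed)
        for basis in (ChannelBasis.location(), ChannelBasis.orientation()):
            curve = rng.normal(size=basis.n_channels)
            assert slope_operator(basis) @ curve == pytest.approx(
                reconstruction_slope(curve, basis), abs=1e-12
            )


class TestBootstrapSlopeTest:
    def test_degenerate_one_sided_distribution_hits_floor(self, loc_basis):
        curve = np.array([0, 0, 0.1, 0.4, 1.0, 0.4, 0.1, 0, 0], dtype=float)
        curves = np.tile(curve, (24, 1))
        t = bootstrap_slope_test(curves, loc_basis, n_boot=1000, seed=0)
        assert t.p_is_bound
        assert t.p_two_tailed == pytest.approx(2 / 1000)

    def test_subject_order_invariance(self, loc_basis, rng):
        curves = rng.normal(size=(24, 9))
        t1 = bootstrap_slope_test(curves, loc_basis, n_boot=500, seed=3)
        t2 = bootstrap_slope_test(curves[::-1], loc_basis, n_boot=500, seed=3)
        assert t1.point_estimate == pytest.approx(t2.point_estimate)
        assert np.allclose(
            np.sort(t1.per_subject_slopes), np.sort(t2.per_subject_slopes)
        )

    def test_p_monotone_in_positive_offset(self, loc_basis, rng):
        base = rng.normal(scale=0.5, size=(24, 9))
        peak = slope_operator(loc_basis)
        ps = []
        for shift in [0.0, 0.5, 1.0, 2.0, 4.0]:
            curves = base + shift * peak / (peak @ peak)  # adds +shift slope
            ps.append(
                bootstrap_slope_test(curves, loc_basis, n_boot=2000, seed=11).p_two_tailed
            )
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_needs_two_subjects(self, loc_basis):
        with pytest.raises(ValueError):
            bootstrap_slope_test(np.ones((1, 9)), loc_basis)


class TestBootstrapDifferenceTest:
    def test_identical_conditions_give_p_one(self, loc_basis, rng):
        curves = rng.normal(size=(10, 9))
        t = bootstrap_difference_test(curves, curves, loc_basis, n_boot=500, seed=0)
        assert t.p_two_tailed == 1.0
        assert np.allclose(t.boot_distribution, 0.0)

    def test_large_separation_hits_floor(self, loc_basis, rng):
        a = rng.normal(size=(10, 9))
        w = slope_operator(loc_basis)
        b = a - 5.0 * w / (w @ w)
        t = bootstrap_difference_test(a, b, loc_basis, n_boot=1000, seed=0)
        assert t.p_is_bound
        assert t.p_two_tailed <= 2 / 1000

    def test_unpaired_lengths_raise(self, loc_basis, rng):
        with pytest.raises(ValueError):
            bootstrap_difference_test(
                rng.normal(size=(10, 9)), rng.normal(size=(9, 9)), loc_basis
            )


class TestFdrBh:
    def test_all_small_ps_rejected(self):
        assert fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05).all()

    def test_all_ones_none_rejected(self):
        assert not fdr_bh([1.0, 1.0, 1.0], q=0.05).any()

    def test_single_p_reduces_to_raw_threshold(self):
        assert fdr_bh([0.04], q=0.05)[0]
        assert not fdr_bh([0.06], q=0.05)[0]

    def test_invalid_q_raises(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5], q=1.5)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20),
           st.sampled_from([0.01, 0.05, 0.1, 0.25]))
    def test_matches_exhaustive_step_up(self, ps, q):
        assert np.array_equal(fdr_bh(ps, q=q), brute_force_bh(ps, q))


class TestRequiredSampleSize:
    def test_smallest_predicted_effect_needs_24_subjects(self):
        assert required_sample_size(0.62, 0.90, 0.05, "one") == 24

    @pytest.mark.parametrize("d,power,alpha,tail", [
        (0.62, 0.90, 0.05, "one"),
        (2.0, 0.90, 0.05, "one"),
        (0.5, 0.80, 0.05, "two"),
        (1.2, 0.95, 0.01, "two"),
    ])
    def test_boundary_property_and_oracle(self, d, power, alpha, tail):
        n = required_sample_size(d, power, alpha, tail)
        alternative = "larger" if tail == "one" else "two-sided"
        oracle = TTestPower().solve_power(
            effect_size=d, power=power, alpha=alpha, alternative=alternative
        )
        assert n == int(np.ceil(oracle))
        from dsriem.stats import _one_sample_t_power

        assert _one_sample_t_power(n, d, alpha, tail) >= power
        if n > 2:
            assert _one_sample_t_power(n - 1, d, alpha, tail) < power

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            required_sample_size(-1.0)
        with pytest.raises(ValueError):
            required_sample_size(0.5, alpha=1.2)
        with pytest.raises(ValueError):
            required_sample_size(0.5, tail="three")


class TestPairedPermutationTest:
    def test_all_zero_differences_give_p_one(self):
        x = np.arange(10.0)
        assert paired_permutation_test(x, x, n_perm=200, seed=0) == 1.0

    def test_constant_large_differences_near_floor(self):
        a = np.full(24, 5.0)
        b = np.zeros(24)
        p = paired_permutation_test(a, b, n_perm=1000, seed=0)
        # only all-same-sign flips reach |obs|; observed flip included
        assert p < 0.01

    def test_unpaired_raises(self):
        with pytest.raises(ValueError):
            paired_permutation_test(np.ones(5), np.ones(4))


class TestPearsonCorrelation:
    def test_perfect_linear_relation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, r2, p = pearson_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([1.0, 3, 2, 5])
        r, r2, _ = pearson_correlation(x, y)
        num = np.sum((x - x.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r == pytest.approx(num / den)
        assert r2 == pytest.approx((num / den) ** 2)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            pearson_correlation(np.ones(5), np.arange(5.0))


def fake_test(slope, p):
    return SlopeTest(
        per_subject_slopes=np.full(24, slope),
        point_estimate=slope,
        boot_distribution=np.full(100, slope),
        p_two_tailed=p,
        p_is_bound=False,
        n_boot=100,
        seed=0,
    )


def make_pattern_tests(pattern):
    return {
        cell: fake_test(
            {"+": 0.2, "-": -0.2, "0": 0.001}[sign],
            0.001 if sign in "+-" else 0.9,
        )
        for cell, sign in pattern.items()
    }


class TestAdjudicateModels:
    @pytest.mark.parametrize("model", list(MODEL_PREDICTIONS))
    def test_each_model_matches_itself(self, model):
        adj = adjudicate_models(make_pattern_tests(MODEL_PREDICTIONS[model]))
        assert adj.match_counts[model] == 8
        assert model in adj.best_models

    def test_observed_study_pattern_in_early_visual_cortex(self):
        """Positive content reconstructions for both items with silent
        context: 3 of 4 early-visual cells match the functional account
        (which expects the unprioritized content to invert, not persist)."""
        observed = dict(MODEL_PREDICTIONS["functional"])
        observed[("EVC", "content", "umi")] = "+"   # persisted, not inverted
        adj = adjudicate_models(make_pattern_tests(observed))
        evc_matches = [
            adj.matches["functional"][("EVC", role, item)]
            for role in ("content", "context") for item in ("pmi", "umi")
        ]
        assert sum(evc_matches) == 3
        assert not adj.matches["functional"][("EVC", "content", "umi")]

    def test_all_null_pattern_matches_only_predicted_zeros(self):
        pattern = {cell: "0" for cell in MODEL_PREDICTIONS["hybrid"]}
        adj = adjudicate_models(make_pattern_tests(pattern))
        for model, table in MODEL_PREDICTIONS.items():
            expected = sum(1 for s in table.values() if s == "0")
            assert adj.match_counts[model] == expected

    def test_missing_cell_raises(self):
        tests = make_pattern_tests(MODEL_PREDICTIONS["hybrid"])
        tests.pop(("IPS", "context", "umi"))
        with pytest.raises(ValueError, match="missing"):
            adjudicate_models(tests)
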