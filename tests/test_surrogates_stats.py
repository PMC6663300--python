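"""Surrogate generation and the hierarchical test battery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mtenet import (
    Candidate,
    Embedding,
    SurrogateScheme,
    TimeSeriesData,
    fdr_combine_targets,
    gaussian_cmi,
    gaussian_null_cdf,
    generate_candidate_surrogate,
    max_statistic_test,
    min_statistic_test,
    omnibus_test,
    permute_column,
    tfpr_from_alpha,
    vfpr_from_alpha,
)


class TestSurrogates:
    def test_permutation_preserves_marginal(self, rng):
        col = rng.standard_normal(200)
        perm = permute_column(col, [slice(0, 200)], "shuffle_embedded_samples", rng)
        assert np.array_equal(np.sort(perm), np.sort(col))

    def test_seeded_determinism(self):
        col = np.arange(100.0)
        a = permute_column(
            col, [slice(0, 100)], "shuffle_embedded_samples",
            np.random.default_rng(5),
        )
        b = permute_column(
            col, [slice(0, 100)], "shuffle_embedded_samples",
            np.random.default_rng(5),
        )
        assert np.array_equal(a, b)
        assert not np.array_equal(a, col)

    def test_replication_shuffle_keeps_blocks_intact(self, rng):
        col = np.arange(12.0)
        slices = [slice(0, 4), slice(4, 8), slice(8, 12)]
        perm = permute_column(col, slices, "shuffle_replications", rng)
        blocks = {tuple(perm[s]) for s in slices}
        assert blocks == {tuple(col[s]) for s in slices}

    def test_single_replication_shuffle_replications_rejected(self, rng):
        with pytest.raises(ValueError, match="shuffle_embedded_samples"):
            permute_column(np.arange(10.0), [slice(0, 10)], "shuffle_replications", rng)

    def test_scheme_validates_permutation_count(self):
        scheme = SurrogateScheme(mode="shuffle_replications")
        with pytest.raises(ValueError, match="distinct"):
            scheme.validate(n_replications=4, n_surrogates=100)
        scheme.validate(n_replications=6, n_surrogates=100)

    def test_embedded_surrogate_destroys_coupling(self, rng):
        # y_t = 0.8 x_{t-1} + noise; surrogates break the lagged coupling
        t = 1_000
        x = rng.standard_normal(t)
        y = np.empty(t)
        y[0] = rng.standard_normal()
        y[1:] = 0.8 * x[:-1] + 0.2 * rng.standard_normal(t - 1)
        data = TimeSeriesData(np.stack([x, y], axis=1))
        emb = Embedding(data, max_lag=1)
        cand = Candidate(0, 1)
        target = emb.present(1)
        observed = gaussian_cmi(emb.column(cand), target).value
        scheme = SurrogateScheme(mode="shuffle_embedded_samples")
        null = np.array(
            [
                gaussian_cmi(
                    generate_candidate_surrogate(emb, cand, scheme, rng), target
                ).value
                for _ in range(200)
            ]
        )
        assert observed > np.percentile(null, 97.5)


class TestMaxStatistic:
    def test_observed_above_all_surrogates_gives_p_zero(self):
        surr = np.random.default_rng(0).uniform(0, 0.1, size=(3, 100))
        result, null = max_statistic_test([0.5, 0.2, 0.1], 0.05, surrogate_stats=surr)
        assert result.p_value == 0.0
        assert result.significant
        assert null.n_candidates == 3
        assert null.n_surrogates == 100

    def test_observed_below_all_surrogates_gives_p_one(self):
        surr = np.random.default_rng(0).uniform(0, 0.1, size=(2, 50))
        result, _ = max_statistic_test([-1.0, -2.0], 0.05, surrogate_stats=surr)
        assert result.p_value == 1.0
        assert not result.significant

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            max_statistic_test([], 0.05, null_cdf=lambda v: 0.5)

    def test_analytic_family_wise_calibration(self):
        # 9 independent white-noise candidates against an unrelated target:
        # the selection (false-positive) rate must match alpha = 0.05
        g = np.random.default_rng(42)
        m, n_cand, repeats = 500, 9, 1000
        hits = 0
        for _ in range(repeats):
            y = g.standard_normal(m)
            stats = [
                gaussian_cmi(g.standard_normal(m), y).value for _ in range(n_cand)
            ]
            result, _ = max_statistic_test(
                stats, 0.05, null_cdf=lambda v: gaussian_null_cdf(v, m)
            )
            hits += result.significant
        assert hits / repeats == pytest.approx(0.05, abs=0.015)

    def test_surrogate_and_analytic_p_agree_for_gaussian(self, rng):
        # weak coupling so the p-value falls mid-range, S large for resolution
        m, n_cand, s_count = 300, 3, 10_000
        y = rng.standard_normal(m)
        cands = [
            0.05 * y + rng.standard_normal(m) for _ in range(n_cand)
        ]
        stats = [gaussian_cmi(c, y).value for c in cands]
        surr = np.array(
            [
                [gaussian_cmi(rng.permutation(c), y).value for _ in range(s_count)]
                for c in cands
            ]
        )
        emp, _ = max_statistic_test(stats, 0.05, surrogate_stats=surr)
        ana, _ = max_statistic_test(
            stats, 0.05, null_cdf=lambda v: gaussian_null_cdf(v, m)
        )
        assert 0.01 < emp.p_value < 0.99  # the comparison is informative
        assert emp.p_value == pytest.approx(ana.p_value, abs=0.01)

    def test_p_nonincreasing_in_observed_statistic(self, rng):
        surr = rng.uniform(0, 1, size=(4, 500))
        ps = [
            max_statistic_test([v, 0, 0, 0], 0.05, surrogate_stats=surr)[0].p_value
            for v in np.linspace(0, 1.2, 20)
        ]
        assert np.all(np.diff(ps) <= 0)


class TestMinStatisticAndOmnibus:
    def test_strong_single_variable_retained(self, rng):
        surr = rng.uniform(0, 0.05, size=(1, 200))
        result, _ = min_statistic_test([0.5], 0.01, surrogate_stats=surr)
        assert result.p_value == 0.0
        assert result.significant

    def test_redundant_minimum_removed(self, rng):
        # observed minimum below every surrogate minimum -> p = 1 -> removal
        surr = rng.uniform(0.01, 0.05, size=(3, 200))
        result, _ = min_statistic_test([-0.01, 0.5, 0.4], 0.05, surrogate_stats=surr)
        assert result.p_value == 1.0
        assert not result.significant

    def test_analytic_min_null_is_extreme_value_of_f(self):
        null_cdf = lambda v: gaussian_null_cdf(v, 500)
        result, _ = min_statistic_test([0.01, 0.02], 0.05, null_cdf=null_cdf)
        assert result.p_value == pytest.approx((1 - null_cdf(0.01)) ** 2)

    def test_omnibus_strong_coupling_p_zero(self, rng):
        y = rng.standard_normal(10_000)
        x = 0.9 * y + 0.1 * rng.standard_normal(10_000)
        t_star = gaussian_cmi(x, y).value
        null = np.array(
            [gaussian_cmi(rng.permutation(x), y).value for _ in range(200)]
        )
        result, _ = omnibus_test(t_star, 0.05, surrogate_stats=null)
        assert result.p_value == 0.0

    def test_omnibus_analytic_calibration(self, rng):
        # independent source forced in: rejection rate tracks alpha
        m, repeats = 500, 1000
        hits = 0
        for _ in range(repeats):
            x = rng.standard_normal(m)
            y = rng.standard_normal(m)
            t_star = gaussian_cmi(x, y).value
            result, _ = omnibus_test(
                t_star, 0.05, null_cdf=lambda v: gaussian_null_cdf(v, m)
            )
            hits += result.significant
        assert hits / repeats == pytest.approx(0.05, abs=0.02)


class TestFwerFormulas:
    def test_vfpr_reduces_to_alpha_for_single_comparison(self):
        assert vfpr_from_alpha(0.05, 1) == pytest.approx(0.05)

    def test_vfpr_matches_dunn_sidak(self):
        assert vfpr_from_alpha(0.05, 10) == pytest.approx(0.005116196891823743)
        # never below the Bonferroni rate
        assert vfpr_from_alpha(0.05, 10) >= 0.05 / 10

    def test_vfpr_first_order_is_bonferroni(self):
        for n in (2, 5, 50):
            assert vfpr_from_alpha(1e-7, n) / (1e-7 / n) == pytest.approx(1, rel=1e-4)

    @settings(derandomize=True, max_examples=50)
    @given(
        alpha=st.floats(1e-6, 0.5),
        n=st.integers(1, 200),
    )
    def test_vfpr_monotonicity_and_bonferroni_bound(self, alpha, n):
        v = vfpr_from_alpha(alpha, n)
        assert v >= alpha / n - 1e-15
        assert vfpr_from_alpha(alpha, n + 1) <= v
        if alpha < 0.49:
            assert vfpr_from_alpha(alpha + 0.01, n) >= v

    def test_tfpr_closed_form(self):
        assert tfpr_from_alpha(0.5, 1) == pytest.approx(0.5)
        assert tfpr_from_alpha(0.5, 2) == pytest.approx(0.75)
        # small alpha: the FWER is essentially alpha even for many steps
        assert tfpr_from_alpha(0.001, 100) == pytest.approx(0.001, rel=0.0011)

    @settings(derandomize=True, max_examples=50)
    @given(alpha=st.floats(1e-6, 0.9), n=st.integers(1, 50))
    def test_tfpr_equals_direct_summation(self, alpha, n):
        direct = sum(alpha**j for j in range(1, n + 1))
        assert tfpr_from_alpha(alpha, n) == pytest.approx(direct, rel=1e-9)


def brute_force_bh(p_values, q):
    """Step-up definition: reject 1..k for the largest k with p(k) <= k q / m."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_max = rank
    keep = np.zeros(m, dtype=bool)
    keep[order[:k_max]] = True
    return keep


class TestFdr:
    def test_all_p_one_rejects_everything(self):
        assert not fdr_combine_targets([1.0, 1.0, 1.0], 0.05).any()

    def test_single_small_p_survives(self):
        assert fdr_combine_targets([0.01], 0.05).all()

    def test_step_up_examples(self):
        # p(2) = 0.03 <= 2q/3: the first two are rejected together
        assert fdr_combine_targets([0.001, 0.03, 0.9], 0.05).tolist() == [
            True, True, False,
        ]
        # p(2) = 0.04 > 2q/3: only the smallest survives the step-up
        assert fdr_combine_targets([0.001, 0.04, 0.9], 0.05).tolist() == [
            True, False, False,
        ]

    @settings(derandomize=True, max_examples=100)
    @given(
        p=st.lists(st.floats(0, 1), min_size=1, max_size=20),
        q=st.sampled_from([0.01, 0.05, 0.1, 0.25]),
    )
    def test_matches_brute_force_definition(self, p, q):
        assert np.array_equal(fdr_combine_targets(p, q), brute_force_bh(p, q))

    @settings(derandomize=True, max_examples=50)
    @given(
        p=st.lists(st.floats(0, 1), min_size=2, max_size=10),
        seed=st.integers(0, 100),
    )
    def test_decisions_invariant_to_ordering(self, p, seed):
        perm = np.random.default_rng(seed).permutation(len(p))
        direct = fdr_combine_targets(p, 0.05)
        shuffled = fdr_combine_targets(np.asarray(p)[perm], 0.05)
        assert np.array_equal(direct[perm], shuffled)
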