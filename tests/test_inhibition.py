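import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from overflux.inhibition import (
    NullModel,
    TestKind as TTestKind,
    fold_variance,
    metabolite_ttest,
    null_expectation,
    secretion_delta,
    suppression_coefficient,
    suppression_table,
)
from overflux.synthetic import GeneratorConfig, generate_profiles

ACETATE_NULL = NullModel("acetate", x_init=6.6, additive_supplement=True)


class TestSecretionDelta:
    def test_reported_acetate_increase(self):
        # 10.81 mM observed after 10 mM supplement, 6.6 mM control
        assert secretion_delta(10.81, 6.6) == pytest.approx(4.21, abs=1e-12)

    def test_control_identity(self):
        for x in (0.0, 0.12, 6.6):
            assert secretion_delta(x, x) == 0.0

    def test_suppressed_metabolite_goes_negative(self):
        assert secretion_delta(0.0, 0.12) == pytest.approx(-0.12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            secretion_delta(float("nan"), 1.0)


class TestNullExpectation:
    def test_supplemented_species_is_additive(self):
        assert null_expectation(ACETATE_NULL, 10.0) == pytest.approx(16.60)

    def test_zero_supplement_returns_control(self):
        assert null_expectation(ACETATE_NULL, 0.0) == 6.6

    def test_non_supplemented_species_keeps_control_level(self):
        formate = NullModel("formate", x_init=0.5, additive_supplement=False)
        assert null_expectation(formate, 10.0) == 0.5


class TestFoldVariance:
    def test_null_identity(self):
        assert fold_variance(16.60, ACETATE_NULL, 10.0) == pytest.approx(0.0)

    def test_reported_acetate_deviation(self):
        # 10.81 observed vs 16.60 expected: about 35% of the expected
        # acetate is "missing"
        assert fold_variance(10.81, ACETATE_NULL, 10.0) == pytest.approx(
            -0.3488, abs=5e-5
        )

    def test_complete_suppression_is_minus_one(self):
        assert fold_variance(0.0, ACETATE_NULL, 10.0) == -1.0

    def test_zero_null_flagged_undefined(self):
        model = NullModel("lactate", x_init=0.0)
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert np.isnan(fold_variance(0.5, model, 10.0))

    @settings(derandomize=True, max_examples=30)
    @given(
        lo=st.floats(0.0, 5.0),
        gap=st.floats(0.001, 5.0),
        a_sup=st.floats(0.0, 10.0),
    )
    def test_monotone_in_observation(self, lo, gap, a_sup):
        assert fold_variance(lo + gap, ACETATE_NULL, a_sup) > fold_variance(
            lo, ACETATE_NULL, a_sup
        )


class TestSuppressionCoefficient:
    def test_exact_line(self):
        res = suppression_coefficient([(0, 0), (5, -0.5), (10, -1.0)])
        assert res.slope == pytest.approx(-0.1, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_response_has_zero_slope(self):
        res = suppression_coefficient([(0, 0.0), (5, 0.0), (10, 0.0)])
        assert res.slope == 0.0 and res.r_squared == 1.0

    def test_requires_three_levels_and_control(self):
        with pytest.raises(ValueError):
            suppression_coefficient([(0, 0), (10, -1)])
        with pytest.raises(ValueError):
            suppression_coefficient([(1, 0), (5, -0.5), (10, -1)])
        with pytest.raises(ValueError):
            suppression_coefficient([(5, 0), (5, -0.5), (5, -1)])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(-2, 2)),
                    min_size=4, max_size=12))
    def test_matches_brute_force_normal_equations(self, noise_points):
        # anchor required levels, then add arbitrary points
        points = [(0.0, 0.0), (5.0, -0.3), (10.0, -0.9)] + [
            (abs(a) + 0.1, y) for a, y in noise_points
        ]
        res = suppression_coefficient(points)
        x = np.array([p[0] for p in points])
        y = np.array([p[1] for p in points])
        # brute-force normal equations for [slope, intercept]
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = np.corrcoef(x, y)[0, 1]
        assert res.slope == pytest.approx(beta[0], abs=1e-10)
        assert res.r_squared == pytest.approx(r**2, abs=1e-10)

    def test_parameter_recovery_at_study_design(self):
        # per-treatment-mean regression recovers a generating slope of
        # -0.068 (echoing the histidine-scale suppression) within 3 SE
        true_slope = -0.068
        slopes = []
        for seed in range(30):
            config = GeneratorConfig(
                baseline_means={"histidine": 0.101},
                suppression_slopes={"histidine": true_slope},
                noise_cv=0.1,
                seed=seed,
            )
            profiles, _ = generate_profiles(config)
            table = suppression_table(profiles)
            slopes.append(table[0].slope)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - true_slope) < 3 * se + 1e-4


class TestMetaboliteTTest:
    def test_identical_samples(self):
        res = metabolite_ttest([1, 2, 3], [1, 2, 3])
        assert res.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_pooled_t_against_hand_formula(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        res = metabolite_ttest(a, b, TTestKind.student_pooled)
        # independent closed form for the pooled two-sample statistic
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
            na + nb - 2
        )
        t_hand = (np.mean(a) - np.mean(b)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        from scipy.stats import t as t_dist

        p_hand = 2 * t_dist.sf(abs(t_hand), na + nb - 2)
        assert res.t_statistic == pytest.approx(t_hand, abs=1e-10)
        assert res.t_statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.p_value == pytest.approx(p_hand, abs=1e-10)
        assert res.p_value == pytest.approx(0.2879, abs=1e-4)

    def test_separated_samples_are_significant(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 20)
        b = rng.normal(10, 1, 20)
        assert metabolite_ttest(a, b).p_value < 1e-6

    def test_zero_variance_equal_means_p_is_one(self):
        res = metabolite_ttest([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            metabolite_ttest([1.0], [1.0, 2.0])


class TestBenjaminiHochberg:
    def test_matches_step_up_hand_computation(self):
        from overflux.inhibition import benjamini_hochberg

        p = [0.01, 0.04, 0.03, 0.5]
        adj = benjamini_hochberg(p)
        # hand step-up: sorted p * m / rank, cumulative min from the top
        assert adj == pytest.approx([0.04, 0.0533333333, 0.0533333333, 0.5])

    def test_out_of_range_rejected(self):
        from overflux.inhibition import benjamini_hochberg

        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


class TestSuppressionTable:
    def test_rank_ordering_recovered_from_generator(self):
        profiles, truth = generate_profiles(GeneratorConfig(noise_cv=0.05, seed=11))
        results = suppression_table(profiles)
        estimated_order = [r.metabolite for r in results]
        true_order = sorted(
            truth.suppression_slopes,
            key=lambda m: abs(truth.suppression_slopes[m]),
            reverse=True,
        )
        assert estimated_order == true_order

    def test_control_only_input_rejected(self):
        profiles, _ = generate_profiles(
            GeneratorConfig(acetate_levels=(0.0,), noise_cv=0.0)
        )
        with pytest.raises(ValueError, match="titration"):
            suppression_table(profiles)

    def test_table_schema(self):
        from overflux.inhibition import suppression_frame

        profiles, _ = generate_profiles(GeneratorConfig(noise_cv=0.0))
        df = suppression_frame(suppression_table(profiles))
        assert list(df.columns) == ["metabolite", "slope", "r_squared"]
        assert (df["r_squared"].between(0, 1)).all()
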