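import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from coupletrans.core_io import ExpressionMatrix, PipelineConfig, SampleMap
from coupletrans.coupling import (
    bootstrap_pcc_null,
    classify_coupling,
    coefficient_of_variation,
    cv_matrix,
    fisher_z,
    pearson_correlation,
    row_pearson,
    run_coupling,
    two_sided_z_critical,
)


class TestCoefficientOfVariation:
    def test_constant_vector_is_zero(self):
        assert coefficient_of_variation([2, 2, 2, 2]) == 0.0

    def test_hand_computed_example(self):
        # sd(1,3) = sqrt(2), mean 2 -> 0.7071
        assert coefficient_of_variation([1, 3]) == pytest.approx(0.70710678)

    def test_zero_mean_is_degenerate(self):
        assert np.isnan(coefficient_of_variation([0, 0]))
        assert np.isnan(coefficient_of_variation([-1, 1]))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0])

    def test_matrix_form_matches_scalar(self, rng):
        X = rng.uniform(1, 10, size=(5, 4))
        expect = [coefficient_of_variation(row) for row in X]
        np.testing.assert_allclose(cv_matrix(X), expect)


class TestPearsonCorrelation:
    def test_identity(self):
        assert pearson_correlation([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_negation(self):
        assert pearson_correlation([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        assert pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            pearson_correlation([1, 2, 3], [1, 2])

    def test_zero_variance_undefined(self):
        assert np.isnan(pearson_correlation([1, 1, 1], [1, 2, 3]))

    def test_length_two_warns(self):
        with pytest.warns(UserWarning, match="length-2"):
            pearson_correlation([1, 2], [3, 1])

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=10),
           st.floats(0.1, 10), st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_affine_invariance(self, xs, a, b):
        rng = np.random.default_rng(0)
        x = np.asarray(xs)
        y = rng.normal(size=x.size)
        if np.ptp(x) == 0:
            return
        r1 = pearson_correlation(x, y)
        if np.isnan(r1):  # centered values can underflow to zero variance
            assert np.isnan(pearson_correlation(y, x))
            return
        assert pearson_correlation(y, x) == pytest.approx(r1, abs=1e-12)
        assert pearson_correlation(a * x + b, y) == pytest.approx(r1, rel=1e-6)

    def test_row_form_matches_scalar(self, rng):
        A = rng.normal(size=(6, 5))
        B = rng.normal(size=(6, 5))
        expect = [pearson_correlation(a, b) for a, b in zip(A, B)]
        np.testing.assert_allclose(row_pearson(A, B), expect, atol=1e-12)


class TestFisherZ:
    def test_zero_fixed_point(self):
        assert fisher_z(0.0) == 0.0

    def test_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(np.arctanh(0.5))
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_boundary_clipped_finite(self):
        z = fisher_z(1.0)
        assert np.isfinite(z) and z > 10

    def test_magnitude_above_one_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.0001)

    @given(st.floats(-1, 1))
    @settings(max_examples=100, deadline=None)
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)


def test_two_sided_z_critical_at_5_percent():
    assert two_sided_z_critical(0.05) == pytest.approx(1.959964, abs=1e-6)


class TestClassify:
    def test_at_null_mean_is_neutral(self):
        z, cls = classify_coupling(np.array([0.2]), np.array([0.2]),
                                   np.array([0.1]), 1.96)
        assert z[0] == pytest.approx(0.0) and cls[0] == "neutral"

    def test_three_sigma_coupled_and_uncoupled(self):
        z, cls = classify_coupling(np.array([0.3, -0.3]), np.zeros(2),
                                   np.full(2, 0.1), 1.96)
        np.testing.assert_allclose(z, [3.0, -3.0])
        assert list(cls) == ["coupled", "uncoupled"]

    def test_degenerate_on_zero_sd_or_nan(self):
        z, cls = classify_coupling(np.array([0.5, np.nan]), np.zeros(2),
                                   np.array([0.0, 0.1]), 1.96)
        assert list(cls) == ["degenerate", "degenerate"]
        assert np.isnan(z).all()


def _two_promoter_map():
    """Each level has exactly two promoters with two replicates each."""
    rows = []
    for lv, pref in (("transcriptome", "tx"), ("translatome", "tl")):
        for prom in ("pA", "pB"):
            for r in (1, 2):
                rows.append({"sample_id": f"{pref}_{prom}_r{r}", "level": lv,
                             "promoter": prom, "cell_type": f"ct_{prom}",
                             "replicate": r})
    return SampleMap(pd.DataFrame(rows))


class TestBootstrapNull:
    def test_seed_reproducibility(self, small_dataset, fast_config):
        _, em_tr, em_tl, smap, _ = small_dataset
        a = bootstrap_pcc_null(em_tr, em_tl, smap, 4, fast_config)
        b = bootstrap_pcc_null(em_tr, em_tl, smap, 4, fast_config)
        pd.testing.assert_frame_equal(a, b)

    def test_pool_smaller_than_k_is_error(self, small_dataset, fast_config):
        _, em_tr, em_tl, smap, _ = small_dataset
        with pytest.raises(ValueError, match="fewer than"):
            bootstrap_pcc_null(em_tr, em_tl, smap, 99, fast_config)

    def test_pool_equals_k_draws_are_pairing_orbit(self, rng):
        # with pool == k == 2 every draw is the full pool in one of two
        # orders, so each null PCC is +/- r0 and mean^2 + population
        # variance recovers r0^2 exactly
        smap = _two_promoter_map()
        values = rng.normal(8, 1, size=(6, 4))
        em_tr = ExpressionMatrix([f"g{i}" for i in range(6)],
                                 smap.samples_for("transcriptome"), values)
        em_tl = ExpressionMatrix([f"g{i}" for i in range(6)],
                                 smap.samples_for("translatome"),
                                 rng.normal(8, 1, size=(6, 4)))
        cfg = PipelineConfig(n_boot=40, seed=0, z_scale="raw")
        null = bootstrap_pcc_null(em_tr, em_tl, smap, 2, cfg)
        n = null["n_null_used"].to_numpy()
        mean = null["null_mean"].to_numpy()
        sd = null["null_sd"].to_numpy()
        var_pop = sd**2 * (n - 1) / n
        np.testing.assert_allclose(mean**2 + var_pop, 1.0, atol=1e-10)

    def test_undefined_iterations_are_dropped_and_counted(self, fast_config):
        smap = _two_promoter_map()
        # one constant gene: its PCC is undefined in every iteration
        em_tr = ExpressionMatrix(["g0", "g1"], smap.samples_for("transcriptome"),
                                 [[5, 5, 5, 5], [1, 2, 3, 4]])
        em_tl = ExpressionMatrix(["g0", "g1"], smap.samples_for("translatome"),
                                 [[1, 2, 3, 4], [4, 3, 2, 1]])
        null = bootstrap_pcc_null(em_tr, em_tl, smap, 2, fast_config)
        assert null.loc["g0", "n_null_used"] == 0
        assert np.isnan(null.loc["g0", "null_mean"])
        assert null.loc["g1", "n_null_used"] == fast_config.n_boot


class TestRunCoupling:
    def test_output_schema_and_classes(self, small_dataset, fast_config):
        _, em_tr, em_tl, smap, _ = small_dataset
        table = run_coupling(em_tr, em_tl, smap, "identical", fast_config)
        assert set(table.columns) == {
            "cv_tr", "cv_tl", "pcc", "fisher_z", "null_mean", "null_sd",
            "zscore", "coupling_class", "n_null_used"}
        assert set(table["coupling_class"]) <= {
            "coupled", "uncoupled", "neutral", "degenerate"}
        assert len(table) == 200
        # class boundaries respected
        z = table["zscore"].to_numpy(float)
        cls = table["coupling_class"].to_numpy()
        assert (z[cls == "coupled"] >= fast_config.z_crit).all()
        assert (z[cls == "uncoupled"] <= -fast_config.z_crit).all()

    def test_deterministic_under_fixed_seed(self, small_dataset, fast_config):
        _, em_tr, em_tl, smap, _ = small_dataset
        a = run_coupling(em_tr, em_tl, smap, "common", fast_config)
        b = run_coupling(em_tr, em_tl, smap, "common", fast_config)
        pd.testing.assert_frame_equal(a, b)
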