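"""Imputation engine: simple fills, knn, low-rank completion, and chained
equations with norm/pmm/rf/col rules."""

import numpy as np
import pandas as pd
import pytest

import ehrmiss as em
from ehrmiss.impute import ALL_METHODS, DETERMINISTIC_METHODS, pmm_fill, rf_fill

from conftest import make_correlated_gaussian


@pytest.mark.parametrize("method", ALL_METHODS)
def test_observed_cells_pass_through_and_no_missing_remain(
    method, gauss_masked_small
):
    ds = gauss_masked_small
    completed = em.impute(ds, method, m=2, seed=1)
    observed = ~ds.mask.to_numpy()
    for copy in completed.copies:
        assert not copy.isna().any().any()
        assert np.array_equal(
            copy.to_numpy()[observed], ds.truth.to_numpy()[observed]
        )


@pytest.mark.parametrize("method", ALL_METHODS)
def test_no_missing_input_returned_unchanged(method, gauss_truth_small):
    completed = em.impute(gauss_truth_small, method, m=2, seed=1)
    for copy in completed.copies:
        pd.testing.assert_frame_equal(copy, gauss_truth_small)


@pytest.mark.parametrize("method", ALL_METHODS)
def test_seeded_runs_reproducible(method, gauss_masked_small):
    a = em.impute(gauss_masked_small, method, m=2, seed=42)
    b = em.impute(gauss_masked_small, method, m=2, seed=42)
    for ca, cb in zip(a.copies, b.copies):
        pd.testing.assert_frame_equal(ca, cb)


def test_fully_missing_variable_rejected_by_name():
    values = pd.DataFrame({"ok": [1.0, 2.0], "gone": [np.nan, np.nan]})
    with pytest.raises(ValueError, match="gone"):
        em.impute(values, "mean")


class TestSimple:
    def test_mean_and_median_fill_exact_statistics(self):
        values = pd.DataFrame({"a": [1.0, 2.0, 6.0, np.nan]})
        mean_done = em.impute_simple(values, "mean", m=1).copies[0]
        median_done = em.impute_simple(values, "median", m=1).copies[0]
        assert mean_done.loc[3, "a"] == 3.0
        assert median_done.loc[3, "a"] == 2.0

    def test_random_sample_draws_from_observed_support(self):
        values = pd.DataFrame({"a": [1.0, 2.0, 6.0] + [np.nan] * 30})
        done = em.impute_simple(values, "random_sample", seed=0, m=3)
        for copy in done.copies:
            assert set(copy["a"]) <= {1.0, 2.0, 6.0}
        assert not done.copies[0].equals(done.copies[1])


class TestKnn:
    def test_exact_duplicate_copied_at_k1(self):
        values = pd.DataFrame(
            [[1.0, 2.0, np.nan], [1.0, 2.0, 9.0], [50.0, 60.0, 7.0]]
        )
        done = em.impute_knn(values, k=1, m=1)
        assert done.copies[0].iloc[0, 2] == 9.0

    def test_four_row_toy_mean_of_two_nearest(self):
        """Distances from row 0 (over shared cols a, b):
        r1: sqrt((0.1^2+0)/2)~0.07, r2: sqrt((1+1)/2)=1, r3: sqrt(50)=~7;
        k=2 -> mean of r1.c and r2.c."""
        values = pd.DataFrame(
            {
                "a": [0.0, 0.1, 1.0, 10.0],
                "b": [0.0, 0.0, 1.0, 0.0],
                "c": [np.nan, 4.0, 8.0, 100.0],
            }
        )
        done = em.impute_knn(values, k=2, m=1)
        assert done.copies[0].loc[0, "c"] == pytest.approx(6.0)

    def test_neighbor_lacking_variable_skipped(self):
        """The nearest row also misses the needed cell; the pool extends."""
        values = pd.DataFrame(
            {
                "a": [0.0, 0.01, 5.0],
                "c": [np.nan, np.nan, 3.0],
            }
        )
        done = em.impute_knn(values, k=1, m=1)
        assert done.copies[0].loc[0, "c"] == 3.0


class TestLowRank:
    def test_rank_one_matrix_recovered(self):
        """Masked cells of an exact outer product are recovered to high
        relative accuracy (oracle: the generating outer product)."""
        rng = np.random.default_rng(11)
        truth = pd.DataFrame(
            np.outer(rng.normal(1, 0.5, 100), rng.normal(2, 1, 8))
        )
        ds = em.ampute_mcar(truth, p=0.3, seed=1)
        # identifiability: a rank-2 completion needs >= 2 observed per row
        assert int((~ds.mask).sum(axis=1).min()) >= 2
        done = em.impute_low_rank(ds, "soft_impute", lam=1e-3, tol=1e-9,
                                  max_iter=6000, m=1)
        err = (done.copies[0] - truth)[ds.mask].to_numpy()
        ref = truth[ds.mask].to_numpy()
        rel = np.sqrt(np.nansum(err**2) / np.nansum(ref**2))
        assert rel < 1e-3

    def test_large_lambda_reduces_to_mean_imputation(self, gauss_masked_small):
        ds = gauss_masked_small
        masked = ds.masked
        mu = masked.mean()
        centered = (masked - mu).fillna(0.0)
        s_max = np.linalg.svd(centered.to_numpy(), compute_uv=False)[0]
        done = em.impute_low_rank(ds, "soft_impute", lam=1.1 * s_max, m=1)
        expected = masked.fillna(mu)
        assert np.allclose(done.copies[0].to_numpy(), expected.to_numpy())

    def test_svd_iterative_recovers_low_rank(self):
        rng = np.random.default_rng(12)
        truth = pd.DataFrame(
            np.outer(rng.normal(1, 0.5, 100), rng.normal(2, 1, 8))
        )
        ds = em.ampute_mcar(truth, p=0.3, seed=4)
        assert int((~ds.mask).sum(axis=1).min()) >= 2
        done = em.impute_low_rank(ds, "svd_iterative", rank=2, tol=1e-9,
                                  max_iter=6000, m=1)
        err = (done.copies[0] - truth)[ds.mask].to_numpy()
        ref = truth[ds.mask].to_numpy()
        assert np.sqrt(np.nansum(err**2) / np.nansum(ref**2)) < 1e-3


class TestPredictorMatrix:
    def test_orthogonal_variables_all_allowed(self):
        rng = np.random.default_rng(13)
        values = pd.DataFrame(rng.normal(size=(2000, 4)),
                              columns=list("abcd"))
        allowed = em.build_predictor_matrix(values)
        off_diag = allowed.to_numpy()[~np.eye(4, dtype=bool)]
        assert off_diag.all()
        assert not np.diag(allowed.to_numpy()).any()

    def test_duplicated_columns_mutually_excluded(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=100)
        values = pd.DataFrame({"a": x, "a2": x, "b": rng.normal(size=100)})
        allowed = em.build_predictor_matrix(values)
        assert not allowed.loc["a", "a2"] and not allowed.loc["a2", "a"]
        assert allowed.loc["a", "b"] and allowed.loc["b", "a2"]

    def test_single_high_correlation_pair_excluded(self):
        rng = np.random.default_rng(15)
        x = rng.normal(size=3000)
        values = pd.DataFrame(
            {
                "a": x,
                "b": 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=3000),
                "c": rng.normal(size=3000),
                "d": rng.normal(size=3000),
            }
        )
        allowed = em.build_predictor_matrix(values, r_threshold=0.85)
        excluded = [
            (i, j)
            for i in values.columns
            for j in values.columns
            if i != j and not allowed.loc[i, j]
        ]
        assert set(excluded) == {("a", "b"), ("b", "a")}


class TestChainedEquations:
    def test_norm_predict_copies_identical(self, gauss_masked_small):
        done = em.impute(gauss_masked_small, "ce_norm_predict", m=3, seed=1)
        for copy in done.copies[1:]:
            pd.testing.assert_frame_equal(copy, done.copies[0])

    def test_norm_copies_differ(self, gauss_masked_small):
        done = em.impute(gauss_masked_small, "ce_norm", m=2, seed=1)
        assert not done.copies[0].equals(done.copies[1])

    def test_pmm_and_rf_respect_observed_support(self, gauss_masked_small):
        ds = gauss_masked_small
        for method in ("ce_pmm", "ce_rf"):
            done = em.impute(ds, method, m=1, seed=2)
            copy = done.copies[0]
            for col in ds.truth.columns:
                observed = set(ds.masked[col].dropna())
                imputed = copy.loc[ds.mask[col], col]
                assert set(imputed) <= observed


class TestPmmFill:
    def test_constant_target_constant_output(self):
        rng = np.random.default_rng(16)
        y = np.full(10, 4.2)
        x = np.column_stack([np.ones(10), rng.normal(size=10)])
        out = pmm_fill(y, x, x[:3], d=3, rng=rng)
        assert (out == 4.2).all()

    def test_single_donor_matches_brute_force_on_linear_toy(self):
        """Noise-free linear relation: the donor is the observed case with
        the closest predictor value (predicted means are monotone in x)."""
        x_vals = np.arange(10.0)
        y = 2.0 * x_vals
        x_obs = np.column_stack([np.ones(10), x_vals])
        x_mis = np.array([[1.0, 3.7], [1.0, 8.9]])
        rng = np.random.default_rng(17)
        out = pmm_fill(y, x_obs, x_mis, d=1, rng=rng)
        assert out[0] == 2.0 * 4.0  # nearest x is 4
        assert out[1] == 2.0 * 9.0

    def test_donor_pool_larger_than_observed_shrunk(self):
        rng = np.random.default_rng(18)
        y = np.array([1.0, 2.0, 5.0])
        x = np.column_stack([np.ones(3), rng.normal(size=3)])
        out = pmm_fill(y, x, x[:2], d=10, rng=rng)
        assert set(out) <= set(y)


class TestRfFill:
    def test_constant_target_constant_output(self):
        rng = np.random.default_rng(19)
        y = np.full(20, 1.5)
        x = np.column_stack([np.ones(20), rng.normal(size=20)])
        assert (rf_fill(y, x, x[:4], rng=rng) == 1.5).all()

    def test_step_function_signal_followed(self):
        """Target is a noiseless step in one predictor; nearly all
        imputations land on the correct side of the step."""
        rng = np.random.default_rng(20)
        x_vals = rng.uniform(-1, 1, 300)
        y = (x_vals > 0).astype(float) * 10.0
        x_obs = np.column_stack([np.ones(300), x_vals])
        mis_vals = np.concatenate([rng.uniform(0.3, 1, 30),
                                   rng.uniform(-1, -0.3, 30)])
        x_mis = np.column_stack([np.ones(60), mis_vals])
        out = rf_fill(y, x_obs, x_mis, rng=rng, n_trees=20)
        expected = (mis_vals > 0).astype(float) * 10.0
        assert (out == expected).mean() >= 0.95


def test_determinism_classes_partition_all_methods():
    assert DETERMINISTIC_METHODS | em.STOCHASTIC_METHODS == set(ALL_METHODS)
    assert not DETERMINISTIC_METHODS & em.STOCHASTIC_METHODS


def test_unknown_method_rejected():
    with pytest.raises(ValueError, match="unknown"):
        em.ImputationConfig(method="magic")
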