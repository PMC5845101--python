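"""Amputation mechanisms: MCAR/MAR/MNAR grids and realistic patterns."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

import ehrmiss as em

from conftest import make_correlated_gaussian


@pytest.fixture()
def toy8():
    """8 rows, two columns with distinct, ordered-by-hand values."""
    return pd.DataFrame(
        {
            "a": [10.0, 20, 30, 40, 50, 60, 70, 80],
            "b": [5.0, 15, 25, 35, 45, 55, 65, 75],
        },
        index=range(1, 9),
    )


class TestQuartiles:
    def test_distinct_values_split_two_per_quartile(self, toy8):
        q = em.quartile_of(toy8["a"].to_numpy())
        assert list(q) == [1, 1, 2, 2, 3, 3, 4, 4]

    def test_boundary_ties_go_to_lower_quartile(self):
        values = np.array([1.0, 2.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        cuts = np.quantile(values, [0.25, 0.5, 0.75])
        q = em.quartile_of(values)
        at_cut = values == cuts[0]
        assert (q[at_cut] == 1).all()


class TestMcar:
    def test_invalid_p_rejected(self):
        truth = pd.DataFrame(np.ones((3, 2)))
        for p in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                em.ampute_mcar(truth, p=p)

    def test_incomplete_truth_rejected(self):
        truth = pd.DataFrame([[1.0, np.nan]])
        with pytest.raises(ValueError, match="complete"):
            em.ampute_mcar(truth, p=0.3)

    def test_removed_fraction_within_binomial_interval(self):
        truth = pd.DataFrame(np.ones((1000, 10)))
        ds = em.ampute_mcar(truth, p=0.3, seed=1)
        n_cells = 10000
        half_width = 2.576 * np.sqrt(0.3 * 0.7 / n_cells)
        assert abs(ds.missing_fraction - 0.3) < half_width

    def test_same_seed_identical_masks(self):
        truth = pd.DataFrame(np.ones((50, 4)))
        a = em.ampute_mcar(truth, p=0.2, seed=9)
        b = em.ampute_mcar(truth, p=0.2, seed=9)
        pd.testing.assert_frame_equal(a.mask, b.mask)

    def test_mask_independent_of_values(self):
        """Point-biserial correlation between removal and value ~ 0."""
        truth = make_correlated_gaussian(1000, 10, rho=0.3, seed=2)
        ds = em.ampute_mcar(truth, p=0.3, seed=3)
        r, _ = pearsonr(ds.mask.to_numpy().ravel(),
                        truth.to_numpy().ravel())
        assert abs(r) < 0.03

    def test_unmasking_reproduces_truth(self):
        truth = make_correlated_gaussian(100, 5, rho=0.2, seed=4)
        ds = em.ampute_mcar(truth, p=0.4, seed=5)
        recovered = ds.masked.where(~ds.mask, ds.truth)
        pd.testing.assert_frame_equal(recovered, truth)


class TestGrids:
    def test_default_mcar_grid_size(self):
        truth = pd.DataFrame(np.ones((20, 3)))
        assert len(em.mcar_grid(truth)) == 50

    @pytest.mark.parametrize(
        "levels,reps,expected",
        [((0.5,), 1, 1), ((0.1, 0.2), 2, 4), ((0.1, 0.3, 0.5), 3, 9)],
    )
    def test_mcar_grid_enumeration(self, levels, reps, expected):
        truth = pd.DataFrame(np.ones((10, 2)))
        grid = em.mcar_grid(truth, levels=levels, reps=reps)
        assert len(grid) == expected
        assert len({(d.spec.p, d.spec.replicate) for d in grid}) == expected

    @pytest.mark.parametrize("v,expected", [(2, 8), (3, 24), (5, 80)])
    def test_mar_grid_closed_form(self, v, expected):
        truth = make_correlated_gaussian(16, v, rho=0.0, seed=6)
        assert len(em.mar_grid(truth)) == expected  # V*(V-1)*4

    def test_mar_grid_single_variable_is_empty(self):
        truth = pd.DataFrame({"a": np.arange(8.0)})
        assert em.mar_grid(truth) == []

    @pytest.mark.parametrize("v,expected", [(1, 4), (3, 12), (7, 28)])
    def test_mnar_grid_closed_form(self, v, expected):
        truth = make_correlated_gaussian(16, v, rho=0.0, seed=7)
        assert len(em.mnar_grid(truth)) == expected  # V*4


class TestMar:
    def test_identical_columns_rejected(self, toy8):
        with pytest.raises(ValueError, match="differ"):
            em.ampute_mar(toy8, "a", "a", quartile=1)

    def test_frac_zero_empty_mask(self, toy8):
        ds = em.ampute_mar(toy8, "a", "b", quartile=1, frac=0.0)
        assert not ds.mask.to_numpy().any()

    def test_bottom_quartile_full_removal(self, toy8):
        """Quartile 1 of col a = the 2 lowest rows; frac 1 removes their b."""
        ds = em.ampute_mar(toy8, "a", "b", quartile=1, frac=1.0)
        assert ds.mask["b"].tolist() == [True, True] + [False] * 6
        assert not ds.mask["a"].any()

    def test_mask_confined_to_eligible_rows_of_col_b(self, toy8):
        for q in (1, 2, 3, 4):
            ds = em.ampute_mar(toy8, "a", "b", quartile=q, frac=0.7, seed=q)
            eligible = em.quartile_of(toy8["a"].to_numpy()) == q
            assert not ds.mask["a"].any()
            assert not ds.mask.loc[~eligible, "b"].any()


class TestMnar:
    def test_second_quartile_full_removal(self, toy8):
        """Quartile 2 of col b = rows ranked 3-4 by value."""
        ds = em.ampute_mnar(toy8, "b", quartile=2, frac=1.0)
        assert ds.mask["b"].tolist() == [False, False, True, True,
                                         False, False, False, False]

    def test_top_quartile_full_removal(self, toy8):
        ds = em.ampute_mnar(toy8, "b", quartile=4, frac=1.0)
        assert ds.mask["b"].tolist() == [False] * 6 + [True, True]

    def test_removed_values_inside_quartile_bounds(self):
        truth = make_correlated_gaussian(500, 3, rho=0.2, seed=8)
        q = 3
        ds = em.ampute_mnar(truth, "v1", quartile=q, frac=0.5, seed=9)
        removed = truth.loc[ds.mask["v1"], "v1"]
        cuts = np.quantile(truth["v1"], [0.25, 0.5, 0.75])
        assert (removed > cuts[1]).all() and (removed <= cuts[2]).all()


class TestRealistic:
    def test_three_patient_toy_copies_neighbor_pattern(self):
        cc_values = pd.DataFrame(
            {"a": [1.0, 2.0], "b": [1.0, 2.0]}, index=[1, 2]
        )
        cc = em.LabMatrix(cc_values)
        cc_demo = pd.DataFrame(
            {"patient_id": [1, 2], "sex": ["F", "F"],
             "age": [30.0, 60.0], "bmi": [22.0, 30.0]}
        )
        pop_values = pd.DataFrame(
            {"a": [np.nan, 5.0, 6.0], "b": [7.0, np.nan, 8.0]},
            index=[10, 11, 12],
        )
        pop = em.LabMatrix(pop_values)
        pop_demo = pd.DataFrame(
            {"patient_id": [10, 11, 12], "sex": ["F", "F", "F"],
             "age": [31.0, 59.0, 80.0], "bmi": [22.0, 30.0, 39.0]}
        )
        ds = em.ampute_realistic(cc, cc_demo, pop, pop_demo)
        # patient 1 -> neighbor 10 (missing a); patient 2 -> 11 (missing b)
        assert ds.mask.loc[1].tolist() == [True, False]
        assert ds.mask.loc[2].tolist() == [False, True]

    def test_fully_observed_population_gives_empty_mask(self):
        values = pd.DataFrame(np.ones((4, 2)), index=[1, 2, 3, 4],
                              columns=["a", "b"])
        demo = pd.DataFrame(
            {"patient_id": [1, 2, 3, 4], "sex": ["F", "F", "M", "M"],
             "age": [30.0, 40, 50, 60], "bmi": [20.0, 25, 30, 35]}
        )
        ds = em.ampute_realistic(em.LabMatrix(values), demo,
                                 em.LabMatrix(values), demo)
        assert not ds.mask.to_numpy().any()

    def test_missingness_rates_track_population(self, synth_population_2000):
        """Per-variable missingness of the amputed complete cases rank-
        correlates strongly with the population's rates."""
        s = synth_population_2000
        ds = em.ampute_realistic(
            s["complete"], s["complete_demographics"], s["matrix"],
            s["demographics"],
        )
        pop_rates = s["matrix"].values.isna().mean()
        cc_rates = ds.mask.mean()
        rho = spearmanr(pop_rates[ds.mask.columns], cc_rates).statistic
        assert rho > 0.9


def test_masked_dataset_rejects_mask_outside_observed():
    truth = pd.DataFrame([[1.0, np.nan]])
    mask = pd.DataFrame([[False, True]])
    with pytest.raises(ValueError, match="never observed"):
        em.MaskedDataset(truth, mask, em.AmputationSpec("MCAR", p=0.5))
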