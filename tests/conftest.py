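"""Shared fixtures: synthetic populations and correlated Gaussian matrices.

Expensive fixtures are session-scoped; everything is generated from fixed
seeds so the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ehrmiss as em
from ehrmiss.synth import PanelSpec, _default_panels


def make_correlated_gaussian(
    n: int, v: int, rho: float, seed: int, standardize: bool = False
) -> pd.DataFrame:
    """Complete n x v draw from an equicorrelated multivariate normal."""
    rng = np.random.default_rng(seed)
    cov = np.full((v, v), rho)
    np.fill_diagonal(cov, 1.0)
    x = rng.multivariate_normal(np.zeros(v), cov, size=n)
    if standardize:
        x = (x - x.mean(axis=0)) / x.std(axis=0)
    return pd.DataFrame(
        x, index=pd.RangeIndex(1, n + 1, name="patient_id"),
        columns=[f"v{j}" for j in range(v)],
    )


def always_observed_config(n_patients: int, seed: int) -> em.SynthConfig:
    """The default 28-variable population with panel ordering forced on,
    Gaussian marginals, and one record per cell — a complete lab matrix."""
    panels = tuple(
        PanelSpec(p.panel_id, p.variables, rho_within=p.rho_within,
                  presence_intercept=50.0)
        for p in _default_panels()
    )
    return em.default_config(
        n_patients=n_patients, seed=seed, panels=panels, marginal_skew=0.0,
        records_per_patient=1.0, death_fraction=0.0,
    )


@pytest.fixture(scope="session")
def complete_matrix_5000() -> em.LabMatrix:
    """Complete 5,000-patient x 28-variable matrix for diagnostics tests."""
    cfg = always_observed_config(5000, seed=301)
    demo, events = em.generate_population(cfg)
    events = em.filter_records(events, demo)
    matrix = em.window_and_aggregate(events, panel_map=cfg.panel_map)
    assert not matrix.values.isna().any().any()
    return matrix


@pytest.fixture(scope="session")
def synth_population_2000():
    """Default population (with its natural missingness) plus matrices and
    demographics carrying age, shared by matching/realistic-amputation
    tests."""
    cfg = em.default_config(n_patients=2000, seed=302)
    demo, events = em.generate_population(cfg)
    filtered = em.filter_records(events, demo)
    matrix = em.window_and_aggregate(filtered, panel_map=cfg.panel_map)
    matrix, _ = em.boxcox_z(matrix)
    demo_age = em.add_age(demo, ref_date=int(filtered["date"].median()))
    complete = em.extract_complete_cases(matrix)
    cc_demo = demo_age.loc[
        demo_age["patient_id"].isin(complete.values.index)
    ]
    return {
        "config": cfg,
        "demographics": demo_age,
        "events": filtered,
        "matrix": matrix,
        "complete": complete,
        "complete_demographics": cc_demo,
    }


@pytest.fixture(scope="session")
def gauss_truth_small() -> pd.DataFrame:
    """400 x 6 equicorrelated (rho = 0.5) Gaussian truth."""
    return make_correlated_gaussian(400, 6, rho=0.5, seed=303)


@pytest.fixture(scope="session")
def gauss_masked_small(gauss_truth_small) -> em.MaskedDataset:
    return em.ampute_mcar(gauss_truth_small, p=0.3, seed=304)


@pytest.fixture(scope="session")
def bivariate_2000() -> pd.DataFrame:
    """2,000 x 2 bivariate Gaussian with r = 0.8, exactly standardized."""
    return make_correlated_gaussian(2000, 2, rho=0.8, seed=305,
                                    standardize=True)
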