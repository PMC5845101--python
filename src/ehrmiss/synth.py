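"""Synthetic EHR-like population generator.

Real laboratory data from health-system EHRs cannot generally be shared, so
every downstream stage of this package (preprocessing, missingness
diagnostics, amputation, imputation benchmarking) is exercised on synthetic
populations with a *known* generating process:

* a Gaussian-copula latent model — one multivariate-normal draw per patient
  with block (within-panel / cross-panel) correlation, pushed through a
  monotone marginal transform to obtain skewed, positive lab-like values;
* age / sex / BMI covariates that may shift each variable's latent mean;
* panel-level observation indicators from a logistic model on the covariates
  (a missing-at-random channel) and optionally on the panel's own latent
  value (a missing-not-at-random channel), because real lab panels are
  ordered jointly;
* longitudinal records: each observed (patient, variable) pair yields several
  dated measurements jittered around a patient-specific anchor date.

Dates are integer day offsets from 1970-01-01 throughout; the I/O layer
renders them as ISO-8601 calendar dates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EPOCH = np.datetime64("1970-01-01")

#: The 28 most frequently ordered laboratory assays (LOINC codes), grouped
#: into the panels they are typically ordered with: complete blood count
#: (CBC), basic/comprehensive metabolic chemistry, and the lipid panel.
DEFAULT_PANEL_VARIABLES: dict[str, tuple[str, ...]] = {
    "cbc": (
        "718-7",    # hemoglobin
        "4544-3",   # hematocrit
        "787-2",    # MCV
        "786-4",    # MCHC
        "785-6",    # MCH
        "6690-2",   # leukocytes
        "789-8",    # erythrocytes
        "788-0",    # RDW
        "32623-1",  # mean platelet volume
        "777-3",    # platelets
        "751-8",    # neutrophils
    ),
    "chemistry": (
        "2345-7",   # glucose
        "2160-0",   # creatinine
        "2823-3",   # potassium
        "3094-0",   # urea nitrogen
        "2951-2",   # sodium
        "2075-0",   # chloride
        "2028-9",   # CO2
        "17861-6",  # calcium
        "1743-4",   # ALT
        "30239-8",  # AST
        "1975-2",   # total bilirubin
        "2885-2",   # total protein
        "10466-1",  # anion gap
    ),
    "lipids": (
        "2093-3",   # total cholesterol
        "2571-8",   # triglycerides
        "2085-9",   # HDL cholesterol
        "13457-7",  # LDL cholesterol
    ),
}


def default_panel_map() -> dict[str, str]:
    """Variable -> panel_id mapping for the default 28-variable fixture."""
    return {
        v: panel for panel, variables in DEFAULT_PANEL_VARIABLES.items()
        for v in variables
    }


@dataclass(frozen=True)
class PanelSpec:
    """One lab panel: its member variables and its observation model.

    The probability that a patient has the panel ordered follows a logistic
    model::

        logit P(observed) = intercept + b_age * z_age + b_sex * [sex == M]
                            + b_bmi * z_bmi + b_value * panel_mean_latent

    where ``z_age`` / ``z_bmi`` are population-standardized covariates.
    ``b_age``/``b_sex``/``b_bmi`` form the MAR channel (observation depends
    on observed covariates) and ``b_value`` the MNAR channel (observation
    depends on the underlying values themselves).
    """

    panel_id: str
    variables: tuple[str, ...]
    rho_within: float = 0.3
    presence_intercept: float = 2.0
    b_age: float = 0.0
    b_sex: float = 0.0
    b_bmi: float = 0.0
    b_value: float = 0.0


@dataclass(frozen=True)
class SynthConfig:
    """Full description of a synthetic population.

    Parameters
    ----------
    n_patients:
        Number of patients.
    panels:
        Panel specifications; member variable names must be globally unique.
    cross_panel_correlation:
        Latent correlation between variables of different panels, in [0, 1).
    marginal_skew:
        Per-variable skew exponent ``s`` (a mapping, or one value for all
        variables).  ``s == 0`` keeps the latent normal scale (identity
        transform); ``s > 0`` applies ``x = exp(s * z)``, a monotone map to a
        positive, right-skewed (lognormal) scale, emulating lab-result
        marginals.
    value_effects:
        Mapping variable -> (b_age, b_sex, b_bmi): linear effects of the
        standardized covariates on the variable's latent mean.
    records_per_patient:
        Mean number of dated measurements per observed (patient, variable)
        pair (Poisson with a floor of one record).
    record_jitter_days:
        Measurement dates are uniform within +/- this many days of the
        patient's anchor date.
    measurement_noise:
        Within-patient latent-scale standard deviation across repeat
        measurements of the same variable.
    cell_dropout:
        Probability that an individual cell of an ordered panel is still
        unobserved (cell-level completely-at-random noise on top of
        panel-level ordering).
    death_fraction:
        Fraction of patients given a death date after their anchor date.
    seed:
        Master seed; identical config + seed reproduces output bitwise.
    """

    n_patients: int = 1000
    panels: tuple[PanelSpec, ...] = field(
        default_factory=lambda: _default_panels()
    )
    cross_panel_correlation: float = 0.1
    marginal_skew: Mapping[str, float] | float = 0.0
    value_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=dict
    )
    records_per_patient: float = 3.0
    record_jitter_days: int = 365
    measurement_noise: float = 0.1
    cell_dropout: float = 0.0
    death_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if not 0 <= self.cross_panel_correlation < 1:
            raise ValueError("cross_panel_correlation must be in [0, 1)")
        if not 0 <= self.death_fraction <= 1:
            raise ValueError("death_fraction must be in [0, 1]")
        if not 0 <= self.cell_dropout <= 1:
            raise ValueError("cell_dropout must be in [0, 1]")
        names = self.variables
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique across panels")
        # fail fast on an invalid correlation spec
        corr = self.correlation_matrix()
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "implied latent correlation matrix is not positive definite"
            ) from exc

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(v for p in self.panels for v in p.variables)

    @property
    def panel_map(self) -> dict[str, str]:
        return {v: p.panel_id for p in self.panels for v in p.variables}

    def skew_of(self, variable: str) -> float:
        if isinstance(self.marginal_skew, Mapping):
            return float(self.marginal_skew.get(variable, 0.0))
        return float(self.marginal_skew)

    def correlation_matrix(self) -> np.ndarray:
        """Block latent correlation: rho_within inside panels, the
        cross-panel coefficient elsewhere, ones on the diagonal."""
        names = self.variables
        v = len(names)
        corr = np.full((v, v), self.cross_panel_correlation)
        offset = 0
        for panel in self.panels:
            k = len(panel.variables)
            block = slice(offset, offset + k)
            corr[block, block] = panel.rho_within
            offset += k
        np.fill_diagonal(corr, 1.0)
        return corr


def _default_panels() -> tuple[PanelSpec, ...]:
    """Default 28-variable fixture.

    Within-panel correlations and presence models are chosen to mimic the
    qualitative structure of outpatient lab data: CBC and chemistry panels
    are ordered for most patients, lipids are screened selectively with a
    strong dependence on age, sex and BMI (an MAR pattern).
    """
    return (
        PanelSpec("cbc", DEFAULT_PANEL_VARIABLES["cbc"], rho_within=0.4,
                  presence_intercept=1.8, b_age=0.3),
        PanelSpec("chemistry", DEFAULT_PANEL_VARIABLES["chemistry"],
                  rho_within=0.3, presence_intercept=1.5, b_age=0.3,
                  b_bmi=0.2),
        PanelSpec("lipids", DEFAULT_PANEL_VARIABLES["lipids"], rho_within=0.5,
                  presence_intercept=0.0, b_age=0.8, b_sex=0.3, b_bmi=0.5),
    )


def default_config(n_patients: int = 1000, seed: int = 0,
                   **overrides) -> SynthConfig:
    """The standard 28-variable study population at a chosen size."""
    params = dict(
        n_patients=n_patients,
        marginal_skew=0.4,
        records_per_patient=3.0,
        death_fraction=0.05,
        seed=seed,
    )
    params.update(overrides)
    return SynthConfig(**params)


def _marginal_transform(z: np.ndarray, skew: float) -> np.ndarray:
    if skew == 0.0:
        return z
    return np.exp(skew * z)


def generate_population(
    config: SynthConfig, return_latent: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame] | tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw one synthetic population.

    Returns
    -------
    demographics:
        One row per patient: ``patient_id, sex, birth_date, death_date, bmi``
        (dates as integer epoch-day offsets, ``death_date`` NaN when absent).
    events:
        Long-format lab records: ``patient_id, loinc, date, value``.
    latent (only if ``return_latent``):
        Dict with the pre-transform latent matrix, the per-panel observation
        probabilities and indicators, and the patient anchor days — the
        internal state that recovery tests check against.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    names = list(config.variables)
    v = len(names)

    patient_id = np.arange(1, n + 1)
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    age = rng.uniform(20.0, 85.0, n)
    bmi = np.clip(rng.normal(28.0, 5.0, n), 15.0, None)
    anchor = rng.integers(12000, 18000, n)  # ~2002-2019
    birth_date = anchor - np.round(age * 365.25).astype(np.int64)
    death_date = np.full(n, np.nan)
    dies = rng.random(n) < config.death_fraction
    death_date[dies] = anchor[dies] + rng.integers(400, 4000, int(dies.sum()))

    z_age = (age - age.mean()) / age.std() if n > 1 else np.zeros(n)
    z_bmi = (bmi - bmi.mean()) / bmi.std() if n > 1 else np.zeros(n)
    is_male = (sex == "M").astype(float)

    # latent values: covariate mean shift + correlated Gaussian noise
    mean = np.zeros((n, v))
    for j, name in enumerate(names):
        b = config.value_effects.get(name)
        if b is not None:
            mean[:, j] = b[0] * z_age + b[1] * is_male + b[2] * z_bmi
    chol = np.linalg.cholesky(config.correlation_matrix())
    latent = mean + rng.standard_normal((n, v)) @ chol.T

    # panel-level observation indicators
    observed = np.zeros((n, v), dtype=bool)
    presence_prob = np.zeros((n, v))
    offset = 0
    for panel in config.panels:
        k = len(panel.variables)
        block = slice(offset, offset + k)
        panel_value = latent[:, block].mean(axis=1)
        logit = (
            panel.presence_intercept
            + panel.b_age * z_age
            + panel.b_sex * is_male
            + panel.b_bmi * z_bmi
            + panel.b_value * panel_value
        )
        prob = 1.0 / (1.0 + np.exp(-logit))
        ordered = rng.random(n) < prob
        observed[:, block] = ordered[:, None]
        presence_prob[:, block] = prob[:, None]
        offset += k
    if config.cell_dropout > 0:
        observed &= rng.random((n, v)) >= config.cell_dropout

    demographics = pd.DataFrame(
        {
            "patient_id": patient_id,
            "sex": sex,
            "birth_date": birth_date,
            "death_date": death_date,
            "bmi": bmi,
        }
    )

    # longitudinal records for every observed (patient, variable) cell
    rows_i, cols_j = np.nonzero(observed)
    if rows_i.size:
        counts = 1 + rng.poisson(
            max(config.records_per_patient - 1.0, 0.0), rows_i.size
        )
        rep_i = np.repeat(rows_i, counts)
        rep_j = np.repeat(cols_j, counts)
        total = int(counts.sum())
        jitter = rng.integers(
            -config.record_jitter_days, config.record_jitter_days + 1, total
        )
        noise = rng.normal(0.0, config.measurement_noise, total)
        latent_event = latent[rep_i, rep_j] + noise
        skews = np.array([config.skew_of(name) for name in names])
        values = np.where(
            skews[rep_j] == 0.0,
            latent_event,
            np.exp(skews[rep_j] * latent_event),
        )
        events = pd.DataFrame(
            {
                "patient_id": patient_id[rep_i],
                "loinc": np.array(names, dtype=object)[rep_j],
                "date": anchor[rep_i] + jitter,
                "value": values,
            }
        )
    else:
        events = pd.DataFrame(
            {
                "patient_id": pd.Series([], dtype=np.int64),
                "loinc": pd.Series([], dtype=object),
                "date": pd.Series([], dtype=np.int64),
                "value": pd.Series([], dtype=float),
            }
        )

    if return_latent:
        internals = {
            "latent": pd.DataFrame(latent, index=patient_id, columns=names),
            "observed": pd.DataFrame(observed, index=patient_id, columns=names),
            "presence_prob": pd.DataFrame(
                presence_prob, index=patient_id, columns=names
            ),
            "anchor": pd.Series(anchor, index=patient_id),
        }
        return demographics, events, internals
    return demographics, events


def ground_truth_mask(
    events: pd.DataFrame,
    demographics: pd.DataFrame,
    variables: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Which (patient, variable) pairs were generated as observed.

    Boolean patients x variables frame aligned with the wide matrix the
    preprocessing stage builds; used as labels when validating missingness
    diagnostics against the generator's own observation model.
    """
    patients = demographics["patient_id"].to_numpy()
    if variables is None:
        variables = sorted(events["loinc"].unique())
    mask = pd.DataFrame(False, index=patients, columns=list(variables))
    if len(events):
        seen = events.drop_duplicates(["patient_id", "loinc"])
        flags = pd.crosstab(seen["patient_id"], seen["loinc"]).astype(bool)
        mask.update(flags)
    mask.index.name = "patient_id"
    return mask.astype(bool)
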