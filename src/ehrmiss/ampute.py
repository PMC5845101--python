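"""Amputation: simulating missingness in complete data with known truth.

Four mechanisms, mirroring how missingness arises in clinical data:

* **MCAR** — every cell removed independently with probability ``p``; run as
  a grid of 10 replicates at 10%-50% missingness (50 datasets).
* **MAR** — pick columns A and B and a quartile of A; rows whose A value
  falls in that quartile lose their B value with probability ``frac``
  (default 0.5).  Over all ordered pairs and quartiles this yields
  V*(V-1)*4 datasets — 3,024 for the 28-variable set.
* **MNAR** — pick a column and a quartile of *its own* values; cells in the
  quartile are removed with probability ``frac``; V*4 datasets (112 for 28
  variables).
* **REALISTIC** — each complete case borrows the observed/missing pattern of
  its nearest demographic neighbor (same sex, closest standardized age/BMI,
  self excluded) in the full population.

Quartiles use empirical quantiles at 0.25/0.5/0.75; boundary ties are
assigned to the lower quartile.  Every masked dataset keeps the complete
truth and the spec that produced it, so evaluation is exact.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .complete_cases import nearest_same_sex
from .preprocess import LabMatrix

logger = logging.getLogger(__name__)

MECHANISMS = ("MCAR", "MAR", "MNAR", "REALISTIC")
DEFAULT_MCAR_LEVELS = (0.1, 0.2, 0.3, 0.4, 0.5)


def derive_rng(master_seed: int, *parts) -> np.random.Generator:
    """Stable per-task generator: master seed + a hash of the task labels.

    Hashing the labels (rather than a running counter) makes grids
    reproducible and independent of generation order.
    """
    key = zlib.crc32("|".join(map(str, parts)).encode())
    return np.random.default_rng(np.random.SeedSequence([master_seed, key]))


@dataclass(frozen=True)
class AmputationSpec:
    """Parameters of one amputation; which fields apply depends on
    ``mechanism`` (see module docstring)."""

    mechanism: str
    p: float | None = None
    replicate: int = 0
    col_a: str | None = None
    col_b: str | None = None
    col: str | None = None
    quartile: int | None = None
    frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "MCAR":
            if self.p is None or not 0 < self.p < 1:
                raise ValueError("MCAR requires p in (0, 1)")
        if self.mechanism in ("MAR", "MNAR"):
            if self.quartile not in (1, 2, 3, 4):
                raise ValueError("quartile must be in {1, 2, 3, 4}")
            if not 0 <= self.frac <= 1:
                raise ValueError("frac must be in [0, 1]")
        if self.mechanism == "MAR" and self.col_a == self.col_b:
            raise ValueError("col_a and col_b must differ")

    def label(self) -> str:
        parts = [self.mechanism]
        for name in ("p", "replicate", "col_a", "col_b", "col", "quartile",
                     "frac"):
            value = getattr(self, name)
            if value is not None:
                parts.append(f"{name}={value}")
        return ";".join(parts)


@dataclass
class MaskedDataset:
    """A complete truth matrix plus a simulated removal mask.

    ``mask`` is True where a value was amputed; ``masked`` is the matrix an
    imputation method sees.  The truth is never modified, so unmasking is
    exact by construction.
    """

    truth: pd.DataFrame
    mask: pd.DataFrame
    spec: AmputationSpec

    def __post_init__(self) -> None:
        if self.truth.shape != self.mask.shape:
            raise ValueError("truth and mask shapes differ")
        if bool((self.mask & self.truth.isna()).any().any()):
            raise ValueError("mask marks cells that were never observed")

    @property
    def masked(self) -> pd.DataFrame:
        return self.truth.where(~self.mask)

    @property
    def missing_fraction(self) -> float:
        return float(self.mask.to_numpy().mean())


def _require_complete(truth: pd.DataFrame) -> np.ndarray:
    values = truth.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("truth matrix must be complete")
    return values


def quartile_of(values: np.ndarray) -> np.ndarray:
    """Quartile index (1-4) of each value by empirical quantiles; boundary
    ties go to the lower quartile."""
    cuts = np.quantile(values, [0.25, 0.5, 0.75])
    return np.searchsorted(cuts, values, side="left") + 1


def ampute_mcar(
    truth: pd.DataFrame, p: float, seed: int = 0, replicate: int = 0
) -> MaskedDataset:
    """Remove every cell independently with probability ``p``."""
    spec = AmputationSpec("MCAR", p=p, replicate=replicate, seed=seed)
    _require_complete(truth)
    rng = derive_rng(seed, "MCAR", p, replicate)
    mask = pd.DataFrame(
        rng.random(truth.shape) < p, index=truth.index, columns=truth.columns
    )
    return MaskedDataset(truth, mask, spec)


def mcar_grid(
    truth: pd.DataFrame,
    levels: Sequence[float] = DEFAULT_MCAR_LEVELS,
    reps: int = 10,
    seed: int = 0,
) -> list[MaskedDataset]:
    """One MCAR dataset per (missingness level, replicate); the default
    grid of 5 levels x 10 replicates yields 50 datasets."""
    return [
        ampute_mcar(truth, p=level, seed=seed, replicate=rep)
        for level in levels
        for rep in range(reps)
    ]


def ampute_mar(
    truth: pd.DataFrame,
    col_a: str,
    col_b: str,
    quartile: int,
    frac: float = 0.5,
    seed: int = 0,
) -> MaskedDataset:
    """Rows whose ``col_a`` value is in the given quartile lose ``col_b``
    with probability ``frac``; no other cell is touched."""
    spec = AmputationSpec(
        "MAR", col_a=col_a, col_b=col_b, quartile=quartile, frac=frac,
        seed=seed,
    )
    _require_complete(truth)
    rng = derive_rng(seed, "MAR", col_a, col_b, quartile, frac)
    eligible = quartile_of(truth[col_a].to_numpy(dtype=float)) == quartile
    hit = eligible & (rng.random(len(truth)) < frac)
    mask = pd.DataFrame(False, index=truth.index, columns=truth.columns)
    mask.loc[hit, col_b] = True
    return MaskedDataset(truth, mask, spec)


def mar_grid(
    truth: pd.DataFrame, frac: float = 0.5, seed: int = 0
) -> list[MaskedDataset]:
    """One dataset per ordered column pair per quartile: V*(V-1)*4 datasets
    (3,024 for 28 variables)."""
    cols = list(truth.columns)
    if len(cols) < 2:
        logger.warning("mar_grid needs >= 2 variables; returning empty grid")
        return []
    return [
        ampute_mar(truth, a, b, q, frac=frac, seed=seed)
        for a in cols
        for b in cols
        if a != b
        for q in (1, 2, 3, 4)
    ]


def ampute_mnar(
    truth: pd.DataFrame,
    col: str,
    quartile: int,
    frac: float = 0.5,
    seed: int = 0,
) -> MaskedDataset:
    """Cells of ``col`` whose own value is in the given quartile are removed
    with probability ``frac``."""
    spec = AmputationSpec("MNAR", col=col, quartile=quartile, frac=frac,
                          seed=seed)
    _require_complete(truth)
    rng = derive_rng(seed, "MNAR", col, quartile, frac)
    eligible = quartile_of(truth[col].to_numpy(dtype=float)) == quartile
    hit = eligible & (rng.random(len(truth)) < frac)
    mask = pd.DataFrame(False, index=truth.index, columns=truth.columns)
    mask.loc[hit, col] = True
    return MaskedDataset(truth, mask, spec)


def mnar_grid(
    truth: pd.DataFrame, frac: float = 0.5, seed: int = 0
) -> list[MaskedDataset]:
    """One dataset per column per quartile: V*4 datasets (112 for 28)."""
    return [
        ampute_mnar(truth, col, q, frac=frac, seed=seed)
        for col in truth.columns
        for q in (1, 2, 3, 4)
    ]


def ampute_realistic(
    complete: LabMatrix,
    complete_demographics: pd.DataFrame,
    population: LabMatrix,
    population_demographics: pd.DataFrame,
) -> MaskedDataset:
    """Copy real missingness patterns onto the complete cases.

    Each complete-case patient is matched to the nearest non-self population
    patient (sex exact, Euclidean on standardized age/BMI, ties to lowest
    patient id) and inherits that neighbor's observed/missing pattern over
    the shared variables.  Deterministic: no randomness is involved.
    """
    shared = [c for c in complete.values.columns
              if c in population.values.columns]
    if not shared:
        raise ValueError("complete cases and population share no variables")
    truth = complete.values[shared]
    _require_complete(truth)
    cc_demo = complete_demographics.loc[
        complete_demographics["patient_id"].isin(truth.index)
    ]
    # candidates must have a row in the population matrix to donate a pattern
    pop_demo = population_demographics.loc[
        population_demographics["patient_id"].isin(population.values.index)
    ]
    matches = nearest_same_sex(cc_demo, pop_demo, exclude_self=True)
    matched = matches.set_index("patient_id")["matched_id"]
    neighbor_missing = population.values[shared].isna()
    mask = neighbor_missing.loc[matched.loc[truth.index]].to_numpy()
    mask = pd.DataFrame(mask, index=truth.index, columns=shared)
    spec = AmputationSpec("REALISTIC")
    return MaskedDataset(truth, mask, spec)
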