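"""Native implementations of 11 representative imputation methods.

Three families, matching how the methods behave under multiple imputation:

* simple fills — ``mean``, ``median`` (deterministic) and ``random_sample``
  (each missing cell drawn uniformly from the column's observed values);
* matrix-level methods — ``knn`` (row-similarity averaging),
  ``svd_iterative`` (iterative fixed-rank SVD completion) and
  ``soft_impute`` (iterative soft-thresholded SVD, i.e. nuclear-norm
  regularized completion); all deterministic;
* chained equations (fully conditional specification) — missing cells are
  initialized, then each variable in turn is regressed on the others'
  current completed values and its missing cells refilled, for a number of
  iterations and ``m`` independent chains.  Per-variable fill rules:
  ``norm_predict`` (OLS predicted mean, deterministic), ``norm`` (Bayesian
  linear regression: posterior parameter draw plus residual noise), ``pmm``
  (predictive mean matching: borrow an observed donor value with a nearby
  predicted mean), ``rf`` (random forest: sample an observed value from a
  random tree's terminal node), and ``col`` (a single deterministic
  column-wise regression pass).

Deterministic methods return ``m`` identical copies — they cannot express
imputation uncertainty — while the stochastic ones return genuinely
different copies; the evaluation module's calibration statistics quantify
exactly this distinction.

Observed cells always pass through bitwise untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics.pairwise import nan_euclidean_distances

from .ampute import MaskedDataset, derive_rng

logger = logging.getLogger(__name__)

SIMPLE_METHODS = ("mean", "median", "random_sample")
LOW_RANK_METHODS = ("svd_iterative", "soft_impute")
CE_METHODS = ("ce_norm_predict", "ce_norm", "ce_pmm", "ce_rf", "ce_col")
ALL_METHODS = SIMPLE_METHODS + ("knn",) + LOW_RANK_METHODS + CE_METHODS

#: methods whose m copies are identical (unsuitable for multiple imputation)
DETERMINISTIC_METHODS = frozenset(
    {"mean", "median", "knn", "svd_iterative", "soft_impute",
     "ce_norm_predict", "ce_col"}
)
STOCHASTIC_METHODS = frozenset(ALL_METHODS) - DETERMINISTIC_METHODS

RIDGE_EPS = 1e-6


@dataclass(frozen=True)
class ImputationConfig:
    """Method choice plus every tunable the engine exposes.

    k: neighbors for knn.  donors: PMM donor-pool size.  lam: soft-threshold
    level.  rank: target rank for iterative SVD.  m: number of completed
    copies.  iterations: chained-equation cycles.  r_threshold: predictors
    correlated with the target above this (absolute) bound are pruned from
    its regression.  n_trees: forest size for the rf rule.  tol / max_iter:
    low-rank convergence controls.
    """

    method: str
    k: int = 5
    donors: int = 5
    lam: float = 0.1
    rank: int = 3
    m: int = 5
    iterations: int = 10
    r_threshold: float = 0.85
    n_trees: int = 10
    tol: float = 1e-4
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ALL_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        for name in ("k", "donors", "m", "iterations", "rank", "n_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not 0 < self.r_threshold <= 1:
            raise ValueError("r_threshold must be in (0, 1]")


@dataclass
class CompletedSet:
    """``m`` completed copies of one masked matrix.

    Observed cells are identical (and bitwise equal to the input) across all
    copies; ``diagnostics`` records convergence behaviour and fallbacks.
    """

    copies: list[pd.DataFrame]
    mask: pd.DataFrame
    config: ImputationConfig
    diagnostics: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return len(self.copies)

    def __post_init__(self) -> None:
        for copy in self.copies:
            if copy.isna().any().any():
                raise ValueError("completed copy still has missing cells")


def _as_frame(masked: pd.DataFrame | MaskedDataset) -> pd.DataFrame:
    if isinstance(masked, MaskedDataset):
        return masked.masked
    return masked


def _check_observed(values: pd.DataFrame) -> None:
    empty = values.columns[values.notna().sum(axis=0) == 0]
    if len(empty):
        raise ValueError(
            f"variable {empty[0]!r} has no observed cells; cannot impute"
        )


def impute(
    masked: pd.DataFrame | MaskedDataset,
    config: ImputationConfig | str,
    **overrides,
) -> CompletedSet:
    """Dispatch to the configured method; accepts a config or a method name
    plus keyword overrides."""
    if isinstance(config, str):
        config = ImputationConfig(method=config, **overrides)
    elif overrides:
        raise TypeError("pass overrides only with a method name")
    values = _as_frame(masked)
    _check_observed(values)
    if config.method in SIMPLE_METHODS:
        return impute_simple(values, config.method, seed=config.seed,
                             m=config.m)
    if config.method == "knn":
        return impute_knn(values, k=config.k, m=config.m)
    if config.method in LOW_RANK_METHODS:
        return impute_low_rank(
            values, variant=config.method, lam=config.lam, rank=config.rank,
            tol=config.tol, max_iter=config.max_iter, m=config.m,
        )
    ce_method = config.method.removeprefix("ce_")
    predictor_matrix = build_predictor_matrix(values, config.r_threshold)
    return chained_equations(
        values, method=ce_method, m=config.m, iterations=config.iterations,
        predictor_matrix=predictor_matrix, seed=config.seed,
        donors=config.donors, n_trees=config.n_trees,
    )


# ---------------------------------------------------------------------------
# simple fills


def impute_simple(
    masked: pd.DataFrame | MaskedDataset,
    method: str = "mean",
    seed: int = 0,
    m: int = 5,
) -> CompletedSet:
    """Column-statistic fill (mean / median) or uniform resampling from each
    column's observed values (random_sample)."""
    if method not in SIMPLE_METHODS:
        raise ValueError(f"unknown simple method {method!r}")
    values = _as_frame(masked)
    _check_observed(values)
    mask = values.isna()
    config = ImputationConfig(method=method, seed=seed, m=m)
    if method in ("mean", "median"):
        stat = values.mean() if method == "mean" else values.median()
        filled = values.fillna(stat)
        return CompletedSet([filled.copy() for _ in range(m)], mask, config)
    copies = []
    for j in range(m):
        rng = derive_rng(seed, "random_sample", j)
        filled = values.copy()
        for col in values.columns:
            miss = mask[col].to_numpy()
            if miss.any():
                observed = values[col].dropna().to_numpy()
                filled.loc[miss, col] = rng.choice(observed, size=miss.sum())
        copies.append(filled)
    return CompletedSet(copies, mask, config)


# ---------------------------------------------------------------------------
# k-nearest-neighbor fill


def impute_knn(
    masked: pd.DataFrame | MaskedDataset, k: int = 5, m: int = 5
) -> CompletedSet:
    """Fill each missing cell with the mean of the k nearest rows that
    observe the variable.

    Row distance is the Euclidean distance over jointly observed variables
    scaled by the square root of their number (an RMS per shared variable),
    so rows sharing few variables are comparable to rows sharing many.
    Neighbors lacking the needed variable are skipped and the pool extended;
    if no row observes it among comparable rows, the column mean is used.
    """
    values = _as_frame(masked)
    _check_observed(values)
    mask = values.isna()
    x = values.to_numpy(dtype=float)
    n, _ = x.shape
    with np.errstate(invalid="ignore"):
        d = nan_euclidean_distances(x)  # sqrt(V/shared * ss)
    d /= np.sqrt(x.shape[1])  # -> sqrt(ss / shared)
    np.fill_diagonal(d, np.inf)
    d[np.isnan(d)] = np.inf  # rows sharing no observed variable
    col_means = np.nanmean(x, axis=0)
    filled = x.copy()
    fallbacks = 0
    for i in np.nonzero(mask.any(axis=1).to_numpy())[0]:
        order = np.argsort(d[i], kind="stable")
        order = order[np.isfinite(d[i][order])]
        for j in np.nonzero(mask.iloc[i].to_numpy())[0]:
            donor_rows = order[~np.isnan(x[order, j])]
            if donor_rows.size == 0:
                filled[i, j] = col_means[j]
                fallbacks += 1
            else:
                filled[i, j] = x[donor_rows[:k], j].mean()
    if fallbacks:
        logger.warning("knn fell back to column means for %d cells",
                       fallbacks)
    out = pd.DataFrame(filled, index=values.index, columns=values.columns)
    config = ImputationConfig(method="knn", k=k, m=m)
    return CompletedSet(
        [out.copy() for _ in range(m)], mask, config,
        diagnostics={"mean_fallbacks": fallbacks},
    )


# ---------------------------------------------------------------------------
# low-rank matrix completion


def impute_low_rank(
    masked: pd.DataFrame | MaskedDataset,
    variant: str = "soft_impute",
    lam: float = 0.1,
    rank: int = 3,
    tol: float = 1e-4,
    max_iter: int = 100,
    m: int = 5,
) -> CompletedSet:
    """Iterative SVD completion of the column-centered matrix.

    Repeat: reconstruct from the current fill's SVD — truncated to ``rank``
    (svd_iterative) or with singular values soft-thresholded (soft_impute) —
    and refill the missing cells, until the relative change of the filled
    cells drops below ``tol`` or ``max_iter`` is hit (the latter sets a
    non-convergence flag).  The soft variant anneals the threshold along a
    warm-started geometric path from just below the leading singular value
    down to ``lam`` (small thresholds move the iterate only O(lam) per step,
    so a cold start at a small ``lam`` stalls), then debiases by re-running
    the iteration with hard truncation at the rank the soft solution
    retained.  Observed cells are restored exactly in the output.
    """
    if variant not in LOW_RANK_METHODS:
        raise ValueError(f"unknown low-rank variant {variant!r}")
    values = _as_frame(masked)
    _check_observed(values)
    mask_df = values.isna()
    x = values.to_numpy(dtype=float)
    miss = np.isnan(x)
    mu = np.nanmean(x, axis=0)
    z = x - mu
    z[miss] = 0.0
    converged = True
    iterations_run = 0
    change_norms: list[float] = []

    def sweep(threshold: float | None, keep_rank: int | None) -> bool:
        """Iterate one (threshold or rank) stage; returns convergence."""
        nonlocal iterations_run
        for _ in range(max_iter):
            iterations_run += 1
            u, s, vt = np.linalg.svd(z, full_matrices=False)
            if threshold is not None:
                s = np.maximum(s - threshold, 0.0)
            else:
                s = np.where(np.arange(s.size) < keep_rank, s, 0.0)
            recon = (u * s) @ vt
            old = z[miss]
            z[miss] = recon[miss]
            denom = max(float(np.linalg.norm(old)), 1e-12)
            change = float(np.linalg.norm(z[miss] - old)) / denom
            change_norms.append(change)
            if change < tol:
                return True
        return False

    if miss.any():
        if variant == "svd_iterative":
            # grow the rank one component at a time: cold-starting at the
            # full target rank leaves spurious components that EM never
            # removes (a known bad-stationary-point failure mode)
            for r in range(1, min(rank, min(z.shape)) + 1):
                converged = sweep(None, r)
        else:
            s1 = float(np.linalg.svd(z, compute_uv=False)[0])
            path = []
            step = 0.3 * s1
            while step > max(lam, 1e-3 * s1):
                path.append(step)
                step *= 0.3
            for stage_lam in path:
                sweep(stage_lam, None)
            converged = sweep(lam, None)
            # debias: re-run with hard truncation at the rank the soft
            # solution retained.  Components below 2% of the leading
            # (thresholded) singular value are treated as annealing residue
            # rather than structure; for a tiny lam the iterate approaches
            # the minimum-nuclear-norm completion only at O(lam) per step,
            # and this hard polish removes the residual shrinkage bias.
            s_soft = np.linalg.svd(z, compute_uv=False) - lam
            soft_rank = int((s_soft > 0.02 * s_soft[0]).sum()) \
                if s_soft[0] > 0 else 0
            converged = sweep(None, soft_rank) and converged
        if not converged:
            logger.warning("%s did not converge in %d iterations (last "
                           "relative change %.3g)", variant, iterations_run,
                           change_norms[-1])
    filled = z + mu
    filled[~miss] = x[~miss]  # bitwise pass-through of observed cells
    out = pd.DataFrame(filled, index=values.index, columns=values.columns)
    config = ImputationConfig(
        method=variant, lam=lam, rank=rank, tol=tol, max_iter=max_iter, m=m
    )
    return CompletedSet(
        [out.copy() for _ in range(m)], mask_df, config,
        diagnostics={
            "converged": converged,
            "iterations": iterations_run,
            "change_norms": change_norms,
        },
    )


# ---------------------------------------------------------------------------
# chained equations (fully conditional specification)


def build_predictor_matrix(
    masked: pd.DataFrame | MaskedDataset, r_threshold: float = 0.85
) -> pd.DataFrame:
    """Which variables may predict which targets.

    Pairs with absolute pairwise-complete correlation above ``r_threshold``
    are mutually excluded — near-duplicate assays make the regressions
    ill-conditioned — and the diagonal is always excluded.  Rows index
    targets, columns predictors; True = allowed.
    """
    values = _as_frame(masked)
    corr = values.corr()
    allowed = corr.isna() | (corr.abs() <= r_threshold)
    np.fill_diagonal(allowed.to_numpy(), False)
    return allowed.astype(bool)


def _solve_ols(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Least squares with a tiny-ridge fallback for singular designs."""
    xtx = x.T @ x
    xty = x.T @ y
    try:
        beta = np.linalg.solve(xtx, xty)
        if not np.all(np.isfinite(beta)):
            raise np.linalg.LinAlgError
        return beta, False
    except np.linalg.LinAlgError:
        beta = np.linalg.solve(
            xtx + RIDGE_EPS * np.eye(xtx.shape[0]), xty
        )
        return beta, True


def _posterior_draw(
    x: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, float, bool]:
    """Draw (beta, sigma) from the normal-inverse-chi-squared posterior of
    the least-squares fit."""
    n, p = x.shape
    beta_hat, ridged = _solve_ols(x, y)
    resid = y - x @ beta_hat
    df = max(n - p, 1)
    rss = float(resid @ resid)
    sigma2 = (rss + RIDGE_EPS) / rng.chisquare(df)
    xtx = x.T @ x + RIDGE_EPS * np.eye(p)
    # chol of sigma2 * (X'X)^-1 via the inverse cholesky factor
    l = np.linalg.cholesky(np.linalg.inv(xtx))
    beta = beta_hat + np.sqrt(sigma2) * (l @ rng.standard_normal(p))
    return beta, float(np.sqrt(sigma2)), ridged


def pmm_fill(
    y_obs: np.ndarray,
    x_obs: np.ndarray,
    x_mis: np.ndarray,
    d: int = 5,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Predictive mean matching.

    A Bayesian parameter draw gives predicted means for the observed and the
    missing cases; each missing case receives the observed value of a donor
    chosen uniformly among the ``d`` observed cases with the nearest
    predicted means.  Imputed values therefore always lie in the observed
    support.
    """
    rng = rng or np.random.default_rng()
    n_obs = len(y_obs)
    if d > n_obs:
        logger.warning("pmm donor pool reduced from %d to %d", d, n_obs)
        d = n_obs
    if np.all(y_obs == y_obs[0]):
        return np.full(len(x_mis), y_obs[0])
    beta, _, _ = _posterior_draw(x_obs, y_obs, rng)
    yhat_obs = x_obs @ beta
    yhat_mis = x_mis @ beta
    gaps = np.abs(yhat_obs[None, :] - yhat_mis[:, None])
    if d < n_obs:
        pool = np.argpartition(gaps, d - 1, axis=1)[:, :d]
    else:
        pool = np.broadcast_to(np.arange(n_obs), (len(x_mis), n_obs))
    choice = rng.integers(0, d, size=len(x_mis))
    return y_obs[pool[np.arange(len(x_mis)), choice]]


def rf_fill(
    y_obs: np.ndarray,
    x_obs: np.ndarray,
    x_mis: np.ndarray,
    rng: np.random.Generator | None = None,
    n_trees: int = 10,
) -> np.ndarray:
    """Random-forest donor sampling.

    Fit a forest on the observed cases; for each missing case draw one tree
    uniformly and sample uniformly among the observed values landing in that
    tree's terminal node for the case.  Falls back to predictive mean
    matching if the forest degenerates.
    """
    rng = rng or np.random.default_rng()
    if np.all(y_obs == y_obs[0]):
        return np.full(len(x_mis), y_obs[0])
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        min_samples_leaf=5,
        random_state=int(rng.integers(2**31)),
        n_jobs=1,
    )
    try:
        forest.fit(x_obs, y_obs)
        leaves_obs = forest.apply(x_obs)  # (n_obs, n_trees)
        leaves_mis = forest.apply(x_mis)
    except Exception:  # degenerate forest
        logger.warning("rf fill degenerated; falling back to pmm")
        return pmm_fill(y_obs, x_obs, x_mis, rng=rng)
    trees = rng.integers(0, n_trees, size=len(x_mis))
    out = np.empty(len(x_mis))
    for i, t in enumerate(trees):
        donors = y_obs[leaves_obs[:, t] == leaves_mis[i, t]]
        if donors.size == 0:  # cannot occur for trees fit on x_obs; guard
            donors = y_obs
        out[i] = rng.choice(donors)
    return out


def chained_equations(
    masked: pd.DataFrame | MaskedDataset,
    method: str = "pmm",
    m: int = 5,
    iterations: int = 10,
    predictor_matrix: pd.DataFrame | None = None,
    seed: int = 0,
    donors: int = 5,
    n_trees: int = 10,
) -> CompletedSet:
    """Fully conditional specification with a per-variable fill rule.

    Variables are visited in ascending order of missingness; each target is
    regressed (with intercept) on its allowed predictors' current completed
    values, and its missing cells are refilled by the method rule.  The
    cycle repeats ``iterations`` times and ``m`` independent chains are run.

    Stochastic rules (norm, pmm, rf) initialize missing cells with random
    draws from the observed values, one independent stream per chain.  The
    deterministic rules (norm_predict, col) instead initialize with column
    means and run a single chain replicated m times, so that repeated
    imputation is exactly reproducible — these rules carry no imputation
    uncertainty.  ``col`` is a single deterministic column-wise pass;
    ``norm_predict`` iterates to a fixed point of the regression fills.
    """
    if method not in ("norm_predict", "norm", "pmm", "rf", "col"):
        raise ValueError(f"unknown chained-equations method {method!r}")
    values = _as_frame(masked)
    _check_observed(values)
    mask = values.isna()
    deterministic = method in ("norm_predict", "col")
    if predictor_matrix is None:
        predictor_matrix = pd.DataFrame(
            ~np.eye(values.shape[1], dtype=bool),
            index=values.columns, columns=values.columns,
        )
    missing_counts = mask.sum(axis=0)
    visit_order = [
        c for c in sorted(values.columns,
                          key=lambda c: (missing_counts[c], str(c)))
        if missing_counts[c] > 0
    ]
    n_iter = 1 if method == "col" else iterations
    n_chains = 1 if deterministic else m

    copies = []
    change_norms: list[list[float]] = []
    ridge_events = 0
    for chain in range(n_chains):
        rng = derive_rng(seed, "ce", method, chain)
        data = values.copy()
        for col in visit_order:
            miss = mask[col].to_numpy()
            observed = values[col].dropna().to_numpy()
            if deterministic:
                data.loc[miss, col] = observed.mean()
            else:
                data.loc[miss, col] = rng.choice(observed, size=miss.sum())
        chain_changes = []
        for _ in range(n_iter):
            total_change = 0.0
            for col in visit_order:
                miss = mask[col].to_numpy()
                predictors = [
                    c for c in values.columns
                    if c != col and predictor_matrix.loc[col, c]
                ]
                xall = np.column_stack(
                    [np.ones(len(data))]
                    + [data[c].to_numpy(dtype=float) for c in predictors]
                )
                y_obs = data.loc[~miss, col].to_numpy(dtype=float)
                x_obs = xall[~miss]
                x_mis = xall[miss]
                if method in ("norm_predict", "col"):
                    beta, ridged = _solve_ols(x_obs, y_obs)
                    fill = x_mis @ beta
                    ridge_events += ridged
                elif method == "norm":
                    beta, sigma, ridged = _posterior_draw(x_obs, y_obs, rng)
                    fill = x_mis @ beta + sigma * rng.standard_normal(
                        len(x_mis)
                    )
                    ridge_events += ridged
                elif method == "pmm":
                    fill = pmm_fill(y_obs, x_obs, x_mis, d=donors, rng=rng)
                else:  # rf
                    fill = rf_fill(y_obs, x_obs, x_mis, rng=rng,
                                   n_trees=n_trees)
                old = data.loc[miss, col].to_numpy(dtype=float)
                data.loc[miss, col] = fill
                total_change += float(np.abs(fill - old).sum())
            n_missing = int(mask.to_numpy().sum())
            chain_changes.append(total_change / max(n_missing, 1))
        change_norms.append(chain_changes)
        copies.append(data)
    if deterministic:
        copies = [copies[0].copy() for _ in range(m)]
    if ridge_events:
        logger.warning("ridge fallback used %d times for singular designs",
                       ridge_events)
    config = ImputationConfig(
        method=f"ce_{method}", m=m, iterations=iterations, donors=donors,
        n_trees=n_trees, seed=seed,
    )
    return CompletedSet(
        copies, mask, config,
        diagnostics={"change_norms": change_norms,
                     "ridge_events": ridge_events},
    )
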