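"""Synthetic landscapes, Metropolis-Hastings sampling, corruption processes,
and the benchmark harness.

The generator emulates the study conditions of the simulation benchmarks:
20-question landscapes with couplings and fields drawn i.i.d. from a
zero-mean Gaussian whose scale sigma sets the regime (dispersed, ordered,
near-critical, critical), 128-observation samples drawn by single-flip
Metropolis-Hastings, and three corruption processes — random masking of
answers, 2:1 group-sampling bias against a marked minority, and (via the
data module) inconsistent duplicate coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    IsingParameters,
    LandscapeDistribution,
    all_states,
    kl_between_params,
    log_partition,
    model_moments,
    n_pairs,
)
from .data import ObservationSet, impute_observation_set, reweight_groups
from .model_selection import (
    _build_system,
    _fit_system,
    default_lambda_grid,
    fit_with_cv,
    loo_cv,
)
from .mpf import MPFSettings, fit_mpf

#: Gaussian-scale ranges that delimit the qualitative landscape regimes.
REGIMES = {
    "dispersed": (0.01, 0.125),
    "ordered": (0.125, 0.25),
    "near-critical": (0.25, 0.5),
    "critical": (0.5, 1.0),
}


@dataclass
class SimulationConfig:
    n: int = 20
    sigma: float | tuple[float, float] = (0.125, 0.25)
    n_samples: int = 128
    burn_in_sweeps: int = 2000
    thin_sweeps: int = 10
    seed: int = 0
    replicates: int = 10
    n_missing: int = 5  # masked answers per incomplete row


@dataclass
class BiasScenario:
    """2:1 oversampling of Type-A (marker +1) over Type-B (marker -1)."""

    marker_question: int = 0
    n_typeA: int = 128
    n_typeB: int = 64


def draw_parameters(n: int, sigma: float, rng: np.random.Generator) -> IsingParameters:
    """J and h i.i.d. Normal(0, sigma^2)."""
    return IsingParameters(
        couplings=rng.normal(0.0, sigma, n_pairs(n)),
        fields=rng.normal(0.0, sigma, n),
    )


def metropolis_sample(
    params: IsingParameters,
    n_samples: int,
    rng: np.random.Generator,
    burn_in_sweeps: int = 2000,
    thin_sweeps: int = 10,
    fixed_site: int | None = None,
    fixed_value: int = 1,
) -> np.ndarray:
    """Single-flip Metropolis-Hastings draws from p proportional to exp(E).

    A sweep proposes n flips; acceptance is min(1, exp(E_new - E_old)).
    ``fixed_site`` clamps one question (used for stratified conditional
    sampling); proposals then touch only the free sites.
    """
    n = params.n
    J = params.coupling_matrix()
    h = params.fields
    free = np.arange(n)
    s = (2 * rng.integers(0, 2, n) - 1).astype(np.float64)
    if fixed_site is not None:
        s[fixed_site] = fixed_value
        free = np.delete(free, fixed_site)
    F = J @ s + h  # local field at each site
    steps_per_sweep = n
    total = (burn_in_sweeps + n_samples * thin_sweeps) * steps_per_sweep
    sites = free[rng.integers(0, len(free), total)]
    logu = np.log(rng.random(total))
    out = np.empty((n_samples, n), dtype=np.int8)
    record_every = thin_sweeps * steps_per_sweep
    burn = burn_in_sweeps * steps_per_sweep
    k = 0
    for t in range(total):
        a = sites[t]
        dE = -2.0 * s[a] * F[a]
        if dE >= 0 or logu[t] < dE:
            s[a] = -s[a]
            F += (2.0 * s[a]) * J[:, a]
        if t >= burn and (t - burn + 1) % record_every == 0:
            out[k] = s
            k += 1
    return out


def mask_random(
    samples: np.ndarray, n_missing_per_row: int, rng: np.random.Generator,
    max_missing: int = 10,
) -> np.ndarray:
    """Blank out a uniformly random set of positions in every row."""
    if n_missing_per_row > max_missing:
        raise ValueError(
            f"n_missing_per_row={n_missing_per_row} exceeds the cap ({max_missing})"
        )
    S = np.asarray(samples, dtype=float).copy()
    n = S.shape[1]
    for row in S:
        row[rng.choice(n, size=n_missing_per_row, replace=False)] = np.nan
    return S


def biased_sample(
    params: IsingParameters,
    scenario: BiasScenario,
    config: SimulationConfig,
    rng: np.random.Generator,
    n_full: int = 256,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balanced full sample plus a group-biased sample.

    The full sample is stratified: exactly half the rows drawn from the model
    conditional on marker = +1 (Type A), half on marker = -1 (Type B).  The
    biased sample draws ``n_typeA`` / ``n_typeB`` conditional observations.
    Returns ``(full, biased, biased_labels)`` with labels "A"/"B".
    """
    q = scenario.marker_question
    need_a = max(n_full // 2, scenario.n_typeA)
    need_b = max(n_full - n_full // 2, scenario.n_typeB)
    chain_a = metropolis_sample(
        params, need_a, rng, config.burn_in_sweeps, config.thin_sweeps,
        fixed_site=q, fixed_value=1,
    )
    chain_b = metropolis_sample(
        params, need_b, rng, config.burn_in_sweeps, config.thin_sweeps,
        fixed_site=q, fixed_value=-1,
    )
    full = np.vstack([chain_a[: n_full // 2], chain_b[: n_full - n_full // 2]])
    biased = np.vstack([chain_a[: scenario.n_typeA], chain_b[: scenario.n_typeB]])
    labels = np.array(["A"] * scenario.n_typeA + ["B"] * scenario.n_typeB)
    return full, biased, labels


def marker_log_odds(dist_or_params, marker: int) -> float:
    """log(pB / pA): log-odds of the marker question answering NO."""
    if isinstance(dist_or_params, LandscapeDistribution):
        n = dist_or_params.n
        probs = dist_or_params.probs
        S = all_states(n)
        p_b = float(probs[S[:, marker] < 0].sum())
    else:
        means, _ = model_moments(dist_or_params)
        p_b = 0.5 * (1.0 - means[marker])
    return float(np.log(p_b) - np.log1p(-p_b))


def bias_metric(dist_or_params, marker: int) -> float:
    """Single-replicate log-odds bias, exp(log(pB/pA)) - 1.

    Zero when the estimated landscape gives the marked minority its true
    50% share; negative values are bias against it.
    """
    return float(np.expm1(marker_log_odds(dist_or_params, marker)))


def aggregate_bias(log_odds: np.ndarray) -> float:
    """Replicate-averaged bias: exp(mean log(pB/pA)) - 1."""
    return float(np.expm1(np.mean(np.asarray(log_odds, dtype=float))))


# ---------------------------------------------------------------------------
# Benchmark harness
# ---------------------------------------------------------------------------

ESTIMATORS = (
    "optimal-lambda",
    "cv-lambda",
    "standard-mpf",
    "partial-mpf",
    "naive-impute",
    "reweighted",
    "naive-biased",
    "ideal",
)

_TABLE_OF_ESTIMATOR = {
    "optimal-lambda": 1,
    "cv-lambda": 1,
    "standard-mpf": 1,
    "partial-mpf": 3,
    "naive-impute": 3,
    "reweighted": 2,
    "naive-biased": 2,
    "ideal": 2,
}


def _replicate_rng(config: SimulationConfig, rep: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, rep])


def _cv_fit_kl(obs, settings, grid, n_folds, truth):
    """CV-chosen-lambda fit and its exact KL to truth."""
    true_params, m_true, log_z_true = truth
    fit, cv = fit_with_cv(obs, lambda_grid=grid, settings=settings, n_folds=n_folds)
    kl = kl_between_params(
        true_params, fit.params, true_moments=m_true, true_log_z=log_z_true
    )
    return fit, cv, kl


def _truth_cache(params: IsingParameters):
    means, pmeans = model_moments(params)
    return params, np.concatenate([pmeans, means]), log_partition(params)


def benchmark_regularization(
    regime: str, config: SimulationConfig, lambda_grid=None, n_folds=None
) -> pd.DataFrame:
    """One row per replicate: KL of optimal-lambda, CV-lambda, and standard
    (unregularized) MPF fits on a shared dataset."""
    lo_hi = REGIMES[regime]
    rows = []
    grid = np.asarray(
        lambda_grid if lambda_grid is not None else default_lambda_grid()
    )
    for rep in range(config.replicates):
        rng = _replicate_rng(config, rep)
        sigma = float(rng.uniform(*lo_hi))
        params = draw_parameters(config.n, sigma, rng)
        samples = metropolis_sample(
            params, config.n_samples, rng, config.burn_in_sweeps, config.thin_sweeps
        )
        obs = ObservationSet.from_array(samples.astype(float))
        truth = _truth_cache(params)
        settings = MPFSettings(seed=config.seed)

        # fits on the full data at every grid value (optimal-lambda oracle)
        kls = []
        for lam in grid:
            system = _build_system(obs, MPFSettings(lam=float(lam), seed=config.seed))
            fit = _fit_system(system, settings, obs.n)
            kls.append(
                kl_between_params(
                    truth[0], fit.params, true_moments=truth[1], true_log_z=truth[2]
                )
            )
        kls = np.array(kls)

        cv = loo_cv(obs, lambda_grid=grid, settings=settings, n_folds=n_folds)
        li = int(np.where(grid == cv.best_lambda)[0][0])

        fit0 = fit_mpf(obs, MPFSettings(lam=0.0, seed=config.seed))
        kl_std = kl_between_params(
            truth[0], fit0.params, true_moments=truth[1], true_log_z=truth[2]
        )
        rows.append(
            {
                "replicate": rep,
                "sigma": sigma,
                "kl_optimal": float(kls.min()),
                "kl_cv": float(kls[li]),
                "kl_standard": kl_std,
                "best_lambda_cv": cv.best_lambda,
                "optimal_lambda": float(grid[int(np.argmin(kls))]),
            }
        )
    return pd.DataFrame(rows)


def benchmark_bias(
    regime: str, config: SimulationConfig, lambda_grid=None, n_folds=None,
    scenario: BiasScenario | None = None,
) -> pd.DataFrame:
    """Ideal / naive-biased / reweighted comparison on a marked landscape."""
    lo_hi = REGIMES[regime]
    scenario = scenario or BiasScenario()
    rows = []
    for rep in range(config.replicates):
        rng = _replicate_rng(config, rep)
        sigma = float(rng.uniform(*lo_hi))
        params = draw_parameters(config.n, sigma, rng)
        full, biased, labels = biased_sample(params, scenario, config, rng)
        truth = _truth_cache(params)
        settings = MPFSettings(seed=config.seed)
        q = scenario.marker_question

        obs_full = ObservationSet.from_array(full.astype(float))
        obs_biased = ObservationSet.from_array(biased.astype(float))
        obs_rw = reweight_groups(obs_biased, labels, {"A": 0.5, "B": 0.5})

        row = {"replicate": rep, "sigma": sigma}
        fit_i, _, row["kl_ideal"] = _cv_fit_kl(obs_full, settings, lambda_grid, n_folds, truth)
        fit_n, _, row["kl_naive"] = _cv_fit_kl(obs_biased, settings, lambda_grid, n_folds, truth)
        fit_r, _, row["kl_reweighted"] = _cv_fit_kl(obs_rw, settings, lambda_grid, n_folds, truth)
        row["logodds_naive"] = marker_log_odds(fit_n.params, q)
        row["logodds_reweighted"] = marker_log_odds(fit_r.params, q)
        row["logodds_ideal"] = marker_log_odds(fit_i.params, q)
        rows.append(row)
    return pd.DataFrame(rows)


def benchmark_partial(
    regime: str, config: SimulationConfig, lambda_grid=None, n_folds=None,
    n_total: int = 256,
) -> pd.DataFrame:
    """Full-only / Partial-MPF / naive-imputation / ideal comparison.

    Per replicate, ``n_total`` samples are drawn; the first half stays fully
    observed, the second half has ``config.n_missing`` answers masked.
    """
    lo_hi = REGIMES[regime]
    rows = []
    n_half = n_total // 2
    for rep in range(config.replicates):
        rng = _replicate_rng(config, rep)
        sigma = float(rng.uniform(*lo_hi))
        params = draw_parameters(config.n, sigma, rng)
        samples = metropolis_sample(
            params, n_total, rng, config.burn_in_sweeps, config.thin_sweeps
        )
        truth = _truth_cache(params)
        settings = MPFSettings(seed=config.seed)

        masked_part = mask_random(samples[n_half:], config.n_missing, rng)
        mixed = np.vstack([samples[:n_half].astype(float), masked_part])

        obs_full_only = ObservationSet.from_array(samples[:n_half].astype(float))
        obs_mixed = ObservationSet.from_array(mixed)
        obs_naive = impute_observation_set(obs_mixed)
        obs_ideal = ObservationSet.from_array(samples.astype(float))

        row = {"replicate": rep, "sigma": sigma}
        _, _, row["kl_full_only"] = _cv_fit_kl(obs_full_only, settings, lambda_grid, n_folds, truth)
        _, _, row["kl_partial_mpf"] = _cv_fit_kl(obs_mixed, settings, lambda_grid, n_folds, truth)
        _, _, row["kl_naive_impute"] = _cv_fit_kl(obs_naive, settings, lambda_grid, n_folds, truth)
        _, _, row["kl_ideal"] = _cv_fit_kl(obs_ideal, settings, lambda_grid, n_folds, truth)
        rows.append(row)
    return pd.DataFrame(rows)


def run_table(
    table: int, regime: str, config: SimulationConfig, lambda_grid=None,
    n_folds=None, **kwargs,
) -> pd.DataFrame:
    if table == 1:
        return benchmark_regularization(regime, config, lambda_grid, n_folds,
                                        **kwargs)
    if table == 2:
        return benchmark_bias(regime, config, lambda_grid, n_folds, **kwargs)
    if table == 3:
        return benchmark_partial(regime, config, lambda_grid, n_folds, **kwargs)
    raise ValueError(f"unknown benchmark table {table}")


_COLUMN_OF_ESTIMATOR = {
    "optimal-lambda": "kl_optimal",
    "cv-lambda": "kl_cv",
    "standard-mpf": "kl_standard",
    "partial-mpf": "kl_partial_mpf",
    "naive-impute": "kl_naive_impute",
    "reweighted": "kl_reweighted",
    "naive-biased": "kl_naive",
    "ideal": "kl_ideal",
}


def run_benchmark(
    regime: str, estimator: str, config: SimulationConfig, lambda_grid=None,
    n_folds=None,
) -> dict:
    """Summary row (mean KL and Monte-Carlo SE, plus bias where defined)."""
    if estimator not in ESTIMATORS:
        raise ValueError(
            f"unknown estimator {estimator!r}; choose one of {ESTIMATORS}"
        )
    table = _TABLE_OF_ESTIMATOR[estimator]
    df = run_table(table, regime, config, lambda_grid, n_folds)
    col = _COLUMN_OF_ESTIMATOR[estimator]
    vals = df[col].to_numpy()
    out = {
        "regime": regime,
        "estimator": estimator,
        "replicates": len(df),
        "mean_kl": float(vals.mean()),
        "se_kl": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
    }
    if estimator in ("reweighted", "naive-biased", "ideal"):
        key = {
            "reweighted": "logodds_reweighted",
            "naive-biased": "logodds_naive",
            "ideal": "logodds_ideal",
        }[estimator]
        out["bias"] = aggregate_bias(df[key].to_numpy())
    return out
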