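"""Partial-MPF: exact, dynamically weighted handling of missing answers.

A partially observed record with m unknown answers is expanded into its 2^m
completions.  Each completion c enters the flow objective with weight

    w_c(theta) = W * exp(E_c) / sum_{c'} exp(E_{c'})

— the *exact* conditional probability of the missing assignment given the
known answers under the current parameters, times the record's weight W.
Because the weights move with theta, the gradient carries a second term,

    dK/dtheta  =  sum_c w_c dGamma/dtheta  +  sum_c (sum_i Gamma_ic) dw_c/dtheta ,

with the softmax derivative dw_c/dtheta = w_c (phi_c - sum_{c'} u_{c'} phi_{c'}).
The neighbourhood of a completion is restricted to flips of *known* questions,
so probability is never asked to flow along directions we have no evidence
about.  The whole thing is a single smooth objective, minimized jointly
(an EM-style alternation is available behind a switch).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core import IsingParameters, energies, n_pairs, pair_index_arrays
from .data import ObservationSet
from .mpf import (
    FitResult,
    FlowSystem,
    MPFSettings,
    NeighborhoodSpec,
    _build_delta,
    _run_lbfgs,
    fit_mpf,
    flip_sets,
)

#: Hard cap on unknowns per observation (2^m completions are enumerated).
MAX_MISSING = 10


def _missing_positions(values: np.ndarray) -> np.ndarray:
    return np.where(np.isnan(values))[0]


def expand(values: np.ndarray, max_missing: int = MAX_MISSING) -> np.ndarray:
    """All 2^m completions of a partial observation, in deterministic order.

    Missing positions are filled by a counter running through NO(-1)/YES(+1)
    combinations with the *last* missing position varying fastest, e.g.
    {1,0,X,X} -> {1,0,0,0}, {1,0,0,1}, {1,0,1,0}, {1,0,1,1}.
    """
    values = np.asarray(values, dtype=float)
    miss = _missing_positions(values)
    m = len(miss)
    if m > max_missing:
        raise ValueError(
            f"observation has {m} unknown answers, above the cap "
            f"({max_missing}); Partial-MPF enumerates 2^m completions"
        )
    out = np.tile(values, (2**m, 1))
    for t, combo in enumerate(itertools.product((-1.0, 1.0), repeat=m)):
        out[t, miss] = combo
    return out.astype(np.int8)


@dataclass
class CompletionSet:
    """Completions of one partial observation with their dynamic weights."""

    completions: np.ndarray
    weights: np.ndarray


def completion_weights(
    params: IsingParameters, values: np.ndarray, weight: float = 1.0,
    max_missing: int = MAX_MISSING,
) -> CompletionSet:
    """Exact conditional weights w_c over the completions (log-sum-exp safe)."""
    comps = expand(values, max_missing=max_missing)
    E = energies(comps, params)
    E = E - E.max()
    u = np.exp(E)
    u /= u.sum()
    return CompletionSet(completions=comps, weights=weight * u)


def restricted_neighbors(
    completion: np.ndarray, partial_values: np.ndarray, spec: NeighborhoodSpec
) -> np.ndarray:
    """Neighbours of a completion reachable by flipping *known* questions."""
    completion = np.asarray(completion)
    known = np.where(~np.isnan(np.asarray(partial_values, dtype=float)))[0]
    out = []
    for T in flip_sets(len(known), spec.order):
        nb = completion.copy()
        nb[known[list(T)]] *= -1
        out.append(nb)
    return np.array(out)


class PartialFlowSystem:
    """Precompiled joint objective for mixed full/partial observations.

    Completions, their sufficient statistics, and the sparse flow-difference
    matrix are built once; every objective/gradient call re-evaluates the
    theta-dependent completion weights.
    """

    def __init__(self, obs: ObservationSet, settings: MPFSettings,
                 max_missing: int = MAX_MISSING):
        values = obs.values
        n = obs.n
        self.n = n
        self.n_params = n_pairs(n) + n
        spec = settings.neighborhood
        self.lam = settings.lam
        self.total_weight = obs.total_weight
        self.nbhd_size = spec.size(n)

        is_partial = np.isnan(values).any(axis=1)
        # ---- fully observed part (plain weighted MPF) --------------------
        self.full_system = None
        if (~is_partial).any():
            full_obs = ObservationSet(
                values=values[~is_partial],
                weights=obs.weights[~is_partial],
                sources=obs.sources[~is_partial],
            )
            full_settings = MPFSettings(
                neighborhood=spec, lam=0.0, tol=settings.tol,
                max_iter=settings.max_iter, seed=settings.seed,
            )
            self.full_system = FlowSystem(full_obs, full_settings)

        # ---- partial part -------------------------------------------------
        self.has_partial = bool(is_partial.any())
        if self.has_partial:
            comp_blocks, group_ptr, W = [], [0], []
            src_list, s1_list, s2_list, comp_of_flow = [], [], [], []
            offset = 0
            for row, w in zip(values[is_partial], obs.weights[is_partial]):
                comps = expand(row, max_missing=max_missing)
                k = len(comps)
                comp_blocks.append(comps)
                W.append(w)
                known = np.where(~np.isnan(row))[0]
                sets = flip_sets(len(known), spec.order)
                sites1 = np.array([known[t[0]] for t in sets])
                sites2 = np.array(
                    [known[t[1]] if len(t) > 1 else -1 for t in sets]
                )
                for c in range(k):
                    src_list.append(np.full(len(sets), offset + c))
                    s1_list.append(sites1)
                    s2_list.append(sites2)
                    comp_of_flow.append(np.full(len(sets), offset + c))
                offset += k
                group_ptr.append(offset)
            self.comps = np.vstack(comp_blocks)
            self.group_ptr = np.array(group_ptr)
            self.group_w = np.array(W)
            self.n_groups = len(W)
            src = np.concatenate(src_list)
            self.comp_of_flow = np.concatenate(comp_of_flow)
            self.delta_p = _build_delta(
                self.comps, src, np.concatenate(s1_list), np.concatenate(s2_list)
            )
            # dense sufficient statistics of every completion (softmax term)
            rows, cols = pair_index_arrays(n)
            Sf = self.comps.astype(np.float64)
            self.phi = np.hstack([Sf[:, rows] * Sf[:, cols], Sf])
            self.group_of_comp = np.repeat(
                np.arange(self.n_groups), np.diff(self.group_ptr)
            )

    # -- theta-dependent completion weights (softmax within each group) ----
    def _completion_softmax(self, theta: np.ndarray) -> np.ndarray:
        E = self.phi @ theta
        starts = self.group_ptr[:-1]
        gmax = np.maximum.reduceat(E, starts)
        ex = np.exp(E - gmax[self.group_of_comp])
        denom = np.add.reduceat(ex, starts)
        return ex / denom[self.group_of_comp]

    @property
    def reg_scale(self) -> float:
        return self.lam / (self.total_weight * self.nbhd_size)

    def objective_and_grad(
        self, theta: np.ndarray, frozen_u: np.ndarray | None = None,
        with_weight_grad: bool = True,
    ) -> tuple[float, np.ndarray]:
        obj = 0.0
        grad = np.zeros_like(theta)
        if self.full_system is not None:
            o, g = self.full_system.objective_and_grad(theta)
            obj += o
            grad += g
        if self.has_partial:
            u = frozen_u if frozen_u is not None else self._completion_softmax(theta)
            wc = self.group_w[self.group_of_comp] * u          # w_c(theta)
            gamma = np.exp(0.5 * (self.delta_p @ theta))
            flow_sum = np.bincount(
                self.comp_of_flow, weights=gamma, minlength=len(self.comps)
            )
            obj += float(wc @ flow_sum)
            # term 1: sum w_c dGamma/dtheta
            grad += 0.5 * (self.delta_p.T @ (gamma * wc[self.comp_of_flow]))
            if frozen_u is None and with_weight_grad:
                # term 2: sum (sum_i Gamma_ic) dw_c/dtheta
                a = wc * flow_sum                               # (Mc,)
                starts = self.group_ptr[:-1]
                grad += self.phi.T @ a
                phibar = np.add.reduceat(self.phi * u[:, None], starts, axis=0)
                s_g = np.add.reduceat(a, starts)
                grad -= s_g @ phibar
        if self.lam > 0:
            obj += self.reg_scale * 0.5 * float(theta @ theta)
            grad = grad + self.reg_scale * theta
        return obj, grad


def _as_obs(obs) -> ObservationSet:
    if isinstance(obs, ObservationSet):
        return obs
    return ObservationSet.from_array(obs)


def partial_mpf_objective(
    obs, params: IsingParameters, settings: MPFSettings,
    max_missing: int = MAX_MISSING,
) -> float:
    """K' over mixed full/partial data with dynamic completion weights."""
    system = PartialFlowSystem(_as_obs(obs), settings, max_missing=max_missing)
    return system.objective_and_grad(params.vector)[0]


def partial_mpf_gradient(
    obs, params: IsingParameters, settings: MPFSettings,
    max_missing: int = MAX_MISSING, with_weight_grad: bool = True,
) -> np.ndarray:
    """Analytic gradient, including the softmax (dw/dtheta) term.

    ``with_weight_grad=False`` drops that term — wrong on purpose, as a
    negative control for gradient checks.
    """
    system = PartialFlowSystem(_as_obs(obs), settings, max_missing=max_missing)
    return system.objective_and_grad(
        params.vector, with_weight_grad=with_weight_grad
    )[1]


def fit_partial_mpf(
    obs, settings: MPFSettings | None = None, mode: str = "joint",
    max_missing: int = MAX_MISSING,
) -> FitResult:
    """Fit theta on mixed full/partial data.

    ``mode="joint"`` (default) minimizes the single differentiable objective,
    re-evaluating completion weights at every call.  ``mode="alternating"``
    freezes the weights, fits, re-infers the weights, and repeats until the
    parameters stop moving (EM-flavoured; kept for comparison).
    Data with no unknowns takes exactly the fully observed code path.
    """
    obs = _as_obs(obs)
    if settings is None:
        settings = MPFSettings()
    if not obs.has_missing:
        return fit_mpf(obs, settings)
    if mode not in ("joint", "alternating"):
        raise ValueError(f"unknown mode {mode!r}")
    system = PartialFlowSystem(obs, settings, max_missing=max_missing)
    theta0 = np.zeros(system.n_params)
    if mode == "joint":
        res = _run_lbfgs(system.objective_and_grad, theta0, settings)
        theta, fun = res.x, float(res.fun)
        converged, nit = bool(res.success), int(res.nit)
    else:
        theta = theta0
        converged, nit, fun = False, 0, np.inf
        for _ in range(50):
            u = system._completion_softmax(theta)
            res = _run_lbfgs(
                lambda t: system.objective_and_grad(t, frozen_u=u),
                theta,
                settings,
            )
            nit += int(res.nit)
            moved = float(np.max(np.abs(res.x - theta)))
            theta, fun = res.x, float(res.fun)
            if moved < 1e-6:
                converged = True
                break
    return FitResult(
        params=IsingParameters.from_vector(theta, obs.n),
        objective_value=fun,
        converged=converged,
        n_iterations=nit,
        lambda_used=settings.lam,
    )
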