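"""Minimum probability flow (MPF) for fully observed, weighted data.

MPF sidesteps the partition function: instead of maximizing likelihood it
minimizes the initial flow of probability from the observed states to their
neighbours under a continuous-time dynamics whose stationary distribution is
the model.  With flow rates

    Gamma_ij = exp( (E_i - E_j) / 2 )        (positive-exponent convention)

the weighted objective over data D with neighbourhoods N(j) is

    K(theta) = sum_{j in D} sum_{i in N(j)} w_j Gamma_ij(theta)
               + lambda / (|D| |N|) * sum_k theta_k^2 / 2

where |D| is the *total weight* (so duplicating an observation and doubling
its weight are exactly equivalent) and |N| the nominal neighbourhood size.
K is a sum of exponentials of linear functions of theta, hence convex; its
gradient is analytic and the fit is a deterministic quasi-Newton descent
from theta = 0.

Flow differences are encoded once per dataset as a sparse matrix ``Delta``
with one row per (data state, neighbour) pair holding the sufficient-statistic
difference ``phi(i) - phi(j)``; then ``Gamma = exp(Delta @ theta / 2)`` and
``grad K = Delta.T @ (w * Gamma) / 2``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import minimize

from .core import IsingParameters, energy, n_pairs, pair_id_matrix
from .data import ObservationSet


@dataclass
class NeighborhoodSpec:
    """States within Hamming distance ``order`` of a data state (N1 / N2)."""

    order: int = 1
    include_data_states: bool = True

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError("neighborhood order must be 1 or 2")

    def size(self, n: int) -> int:
        return n if self.order == 1 else n + n_pairs(n)


@dataclass
class MPFSettings:
    neighborhood: NeighborhoodSpec = field(default_factory=NeighborhoodSpec)
    lam: float = 0.0
    tol: float = 1e-8
    max_iter: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class FitResult:
    params: IsingParameters
    objective_value: float
    converged: bool
    n_iterations: int
    lambda_used: float


def flip_sets(n: int, order: int) -> list[tuple[int, ...]]:
    """All site sets of size <= order: the flips generating a neighbourhood."""
    sets: list[tuple[int, ...]] = [(a,) for a in range(n)]
    if order >= 2:
        sets += list(itertools.combinations(range(n), 2))
    return sets


def neighbors(
    config: np.ndarray, spec: NeighborhoodSpec, data: np.ndarray | None = None
) -> np.ndarray:
    """Configurations at Hamming distance <= order from ``config``.

    With ``include_data_states=False`` and ``data`` given, states present in
    the data are filtered out (the original exclusion rule).
    """
    config = np.asarray(config)
    n = len(config)
    out = []
    for T in flip_sets(n, spec.order):
        nb = config.copy()
        nb[list(T)] *= -1
        out.append(nb)
    out = np.array(out)
    if not spec.include_data_states and data is not None:
        data = np.atleast_2d(np.asarray(data))
        keep = [
            i for i, nb in enumerate(out)
            if not np.any(np.all(data == nb, axis=1))
        ]
        out = out[keep]
    return out


def flow_rate(params: IsingParameters, j: np.ndarray, i: np.ndarray) -> float:
    """Gamma_ij = exp((E_i - E_j)/2); satisfies Gamma_ij/Gamma_ji = p_i/p_j."""
    return float(np.exp(0.5 * (energy(i, params) - energy(j, params))))


# ---------------------------------------------------------------------------
# Sparse flow-difference construction
# ---------------------------------------------------------------------------

def _build_delta(
    S: np.ndarray,
    src: np.ndarray,
    site1: np.ndarray,
    site2: np.ndarray,
) -> sp.csr_matrix:
    """Sparse (n_flows, n_params) matrix of phi(neighbour) - phi(source).

    Flow f goes from source row ``src[f]`` of S to the state obtained by
    flipping ``site1[f]`` (and ``site2[f]`` if >= 0).  Flipping site a
    changes the coupling statistic of every pair (a, c), c != a, by
    -2 s_a s_c and the field statistic of a by -2 s_a; for a double flip
    (a, b) the (a, b) coupling statistic is unchanged.
    """
    n = S.shape[1]
    P = n_pairs(n) + n
    pid = pair_id_matrix(n)
    # column map for a single flip at site a: pair cols for c != a, h col at c == a
    colmap = pid.copy()
    colmap[np.arange(n), np.arange(n)] = n_pairs(n) + np.arange(n)

    rows_parts, cols_parts, data_parts = [], [], []
    F = len(src)
    flow_ids = np.arange(F)

    def add_single(sites: np.ndarray, zero_out: np.ndarray | None, sel: np.ndarray):
        """Contribution of flipping ``sites[sel]`` for flows ``sel``."""
        s_rows = S[src[sel]].astype(np.float64)          # (f, n)
        s_a = s_rows[np.arange(len(sel)), sites[sel]]    # (f,)
        D = -2.0 * s_a[:, None] * s_rows                 # pair entries
        D[np.arange(len(sel)), sites[sel]] = -2.0 * s_a  # field entry
        if zero_out is not None:
            # double flip: the (a, b) coupling statistic does not change
            D[np.arange(len(sel)), zero_out[sel]] = 0.0
        C = colmap[sites[sel]]                           # (f, n)
        rows_parts.append(np.repeat(flow_ids[sel], n))
        cols_parts.append(C.ravel())
        data_parts.append(D.ravel())

    singles = site2 < 0
    if singles.any():
        add_single(site1, None, np.where(singles)[0])
    doubles = np.where(~singles)[0]
    if len(doubles):
        add_single(site1, site2, doubles)
        add_single(site2, site1, doubles)

    delta = sp.coo_matrix(
        (
            np.concatenate(data_parts),
            (np.concatenate(rows_parts), np.concatenate(cols_parts)),
        ),
        shape=(F, P),
    )
    return delta.tocsr()


def _pack_states(S: np.ndarray) -> np.ndarray:
    """Bit-pack +/-1 rows into integers for fast membership tests."""
    bits = (S > 0).astype(np.int64)
    return bits @ (1 << np.arange(S.shape[1], dtype=np.int64))


class FlowSystem:
    """Precompiled MPF objective/gradient for one fully observed dataset."""

    def __init__(self, obs: ObservationSet, settings: MPFSettings):
        if obs.has_missing:
            raise ValueError(
                "observation set contains unknown answers; use the partial "
                "MPF objective (isingmpf.partial) instead"
            )
        S = obs.values.astype(np.int8)
        m, n = S.shape
        self.n = n
        spec = settings.neighborhood
        sets = flip_sets(n, spec.order)
        src = np.repeat(np.arange(m), len(sets))
        s1 = np.tile(np.array([t[0] for t in sets]), m)
        s2 = np.tile(np.array([t[1] if len(t) > 1 else -1 for t in sets]), m)

        if not spec.include_data_states:
            packed = _pack_states(S)
            data_set = set(packed.tolist())
            flip_masks = np.array(
                [sum(1 << a for a in t) for t in sets], dtype=np.int64
            )
            nb_packed = packed[src] ^ np.tile(flip_masks, m)
            keep = np.array([v not in data_set for v in nb_packed.tolist()])
            src, s1, s2 = src[keep], s1[keep], s2[keep]

        self.delta = _build_delta(S, src, s1, s2)
        self.flow_w = obs.weights[src]
        self.total_weight = obs.total_weight
        self.nbhd_size = spec.size(n)
        self.lam = settings.lam
        self.n_params = n_pairs(n) + n

    @property
    def reg_scale(self) -> float:
        return self.lam / (self.total_weight * self.nbhd_size)

    def objective_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        gamma = np.exp(0.5 * (self.delta @ theta))
        obj = float(self.flow_w @ gamma)
        grad = 0.5 * (self.delta.T @ (self.flow_w * gamma))
        if self.lam > 0:
            obj += self.reg_scale * 0.5 * float(theta @ theta)
            grad = grad + self.reg_scale * theta
        return obj, grad


def _as_obs(obs) -> ObservationSet:
    if isinstance(obs, ObservationSet):
        return obs
    return ObservationSet.from_array(obs)


def mpf_objective(obs, params: IsingParameters, settings: MPFSettings) -> float:
    """Regularized flow objective K' for fully observed (weighted) data."""
    system = FlowSystem(_as_obs(obs), settings)
    return system.objective_and_grad(params.vector)[0]


def mpf_gradient(obs, params: IsingParameters, settings: MPFSettings) -> np.ndarray:
    """Analytic dK'/dtheta, same layout as ``IsingParameters.vector``."""
    system = FlowSystem(_as_obs(obs), settings)
    return system.objective_and_grad(params.vector)[1]


def _run_lbfgs(fun, x0, settings: MPFSettings):
    return minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": settings.max_iter,
            "gtol": settings.tol,
            "ftol": 1e-14,
            "maxcor": 20,
        },
    )


def fit_mpf(obs, settings: MPFSettings | None = None) -> FitResult:
    """Minimize K' by L-BFGS from theta = 0 (deterministic)."""
    obs = _as_obs(obs)
    if settings is None:
        settings = MPFSettings()
    if obs.n < 2:
        raise ValueError("MPF fitting requires n >= 2 questions")
    system = FlowSystem(obs, settings)
    res = _run_lbfgs(
        system.objective_and_grad, np.zeros(system.n_params), settings
    )
    return FitResult(
        params=IsingParameters.from_vector(res.x, obs.n),
        objective_value=float(res.fun),
        converged=bool(res.success),
        n_iterations=int(res.nit),
        lambda_used=settings.lam,
    )
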