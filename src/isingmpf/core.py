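"""Pairwise maximum-entropy (inverse Ising) model: energies, exact landscape
enumeration, moments, and divergence metrics.

Conventions used throughout the package
---------------------------------------
* A configuration is a length-``n`` vector of answers with YES = +1 and
  NO = -1.
* The probability of configuration ``i`` is ``p_i = exp(E_i) / Z`` — note the
  **positive** exponent: higher energy means *more* probable.  The energy is

      E_i(theta) = sum_{a<b} J_ab s_a s_b + sum_a h_a s_a

  with ``n(n-1)/2`` pairwise couplings ``J`` and ``n`` local fields ``h``.
* Pairs ``(a, b)`` with ``a < b`` are indexed in row-major upper-triangle
  order, i.e. ``numpy.triu_indices(n, k=1)``.
* A state index is an integer in ``[0, 2^n)``; bit ``a`` (0-based, the a-th
  least significant bit) encodes question ``a``, with bit value 1 <-> +1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

#: Largest n for which exact enumeration over 2^n states is permitted.
ENUMERATION_CAP = 25

#: Chunk size (rows) for exact enumeration passes, keeps memory modest.
_CHUNK = 1 << 16


def n_pairs(n: int) -> int:
    """Number of unordered pairs (couplings) for an n-question model."""
    return n * (n - 1) // 2


def pair_index_arrays(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the upper triangle, defining the pair order."""
    return np.triu_indices(n, k=1)


def pair_id_matrix(n: int) -> np.ndarray:
    """(n, n) matrix mapping an unordered pair to its coupling index.

    Diagonal entries are -1 (no self-coupling).
    """
    pid = np.full((n, n), -1, dtype=np.int64)
    rows, cols = pair_index_arrays(n)
    ids = np.arange(len(rows))
    pid[rows, cols] = ids
    pid[cols, rows] = ids
    return pid


@dataclass
class IsingParameters:
    """The theta vector: pairwise couplings J (pair-indexed) and fields h."""

    couplings: np.ndarray
    fields: np.ndarray

    def __post_init__(self) -> None:
        self.couplings = np.asarray(self.couplings, dtype=float)
        self.fields = np.asarray(self.fields, dtype=float)
        n = len(self.fields)
        if len(self.couplings) != n_pairs(n):
            raise ValueError(
                f"got {len(self.couplings)} couplings for {n} fields; "
                f"expected n(n-1)/2 = {n_pairs(n)}"
            )
        if not (np.all(np.isfinite(self.couplings)) and np.all(np.isfinite(self.fields))):
            raise ValueError("parameters must be finite")

    @property
    def n(self) -> int:
        return len(self.fields)

    @property
    def vector(self) -> np.ndarray:
        """Flat theta = [couplings, fields]."""
        return np.concatenate([self.couplings, self.fields])

    @classmethod
    def from_vector(cls, theta: np.ndarray, n: int) -> "IsingParameters":
        theta = np.asarray(theta, dtype=float)
        p = n_pairs(n)
        if len(theta) != p + n:
            raise ValueError(f"theta has length {len(theta)}, expected {p + n} for n={n}")
        return cls(couplings=theta[:p], fields=theta[p:])

    @classmethod
    def zeros(cls, n: int) -> "IsingParameters":
        return cls(np.zeros(n_pairs(n)), np.zeros(n))

    def coupling_matrix(self) -> np.ndarray:
        """Symmetric (n, n) coupling matrix with zero diagonal."""
        n = self.n
        J = np.zeros((n, n))
        rows, cols = pair_index_arrays(n)
        J[rows, cols] = self.couplings
        J[cols, rows] = self.couplings
        return J

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        rows, cols = pair_index_arrays(self.n)
        return {
            "n": self.n,
            "couplings": [
                {"a": int(a), "b": int(b), "value": float(v)}
                for a, b, v in zip(rows, cols, self.couplings)
            ],
            "fields": [float(v) for v in self.fields],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IsingParameters":
        n = int(d["n"])
        pid = pair_id_matrix(n)
        couplings = np.zeros(n_pairs(n))
        for item in d["couplings"]:
            couplings[pid[int(item["a"]), int(item["b"])]] = float(item["value"])
        return cls(couplings=couplings, fields=np.asarray(d["fields"], dtype=float))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "IsingParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def all_states(n: int) -> np.ndarray:
    """All 2^n configurations as an (2^n, n) int8 array of +/-1.

    Row ``i`` is the configuration whose state index is ``i`` under the bit
    convention (bit a = a-th least significant bit, bit 1 <-> +1).
    """
    if n > ENUMERATION_CAP:
        raise ValueError(
            f"n={n} exceeds the enumeration cap ({ENUMERATION_CAP}); "
            "use Metropolis-Hastings sampling instead"
        )
    idx = np.arange(1 << n, dtype=np.int64)
    bits = (idx[:, None] >> np.arange(n)) & 1
    return (2 * bits - 1).astype(np.int8)


def config_to_index(config: np.ndarray) -> int:
    """State index of a +/-1 configuration (inverse of ``index_to_config``)."""
    config = np.asarray(config)
    bits = (config > 0).astype(np.int64)
    return int(np.sum(bits << np.arange(len(config))))


def index_to_config(index: int, n: int) -> np.ndarray:
    bits = (index >> np.arange(n)) & 1
    return (2 * bits - 1).astype(np.int8)


def _check_dims(m: int, n: int) -> None:
    if m != n:
        raise ValueError(f"configuration has {m} entries but model has n={n} questions")


def energies(configs: np.ndarray, params: IsingParameters) -> np.ndarray:
    """Energies of a batch of +/-1 configurations, shape (m,)."""
    S = np.atleast_2d(np.asarray(configs))
    _check_dims(S.shape[1], params.n)
    J = params.coupling_matrix()
    out = np.empty(len(S))
    for lo in range(0, len(S), _CHUNK):
        chunk = S[lo : lo + _CHUNK].astype(np.float64)
        out[lo : lo + _CHUNK] = 0.5 * np.einsum(
            "ij,ij->i", chunk @ J, chunk
        ) + chunk @ params.fields
    return out


def energy(config: np.ndarray, params: IsingParameters) -> float:
    """E(sigma) = sum_{a<b} J_ab s_a s_b + sum_a h_a s_a."""
    config = np.asarray(config)
    _check_dims(config.shape[-1], params.n)
    return float(energies(config[None, :], params)[0])


@dataclass
class LandscapeDistribution:
    """Exact Boltzmann distribution over all 2^n configurations."""

    n: int
    log_probs: np.ndarray
    log_z: float

    @property
    def probs(self) -> np.ndarray:
        return np.exp(self.log_probs)

    def __len__(self) -> int:
        return 1 << self.n


def enumerate_distribution(params: IsingParameters) -> LandscapeDistribution:
    """Exact p_i = exp(E_i)/Z over all 2^n states (log-sum-exp stabilized)."""
    n = params.n
    E = energies(all_states(n), params)
    log_z = float(logsumexp(E))
    return LandscapeDistribution(n=n, log_probs=E - log_z, log_z=log_z)


def model_moments(params: IsingParameters) -> tuple[np.ndarray, np.ndarray]:
    """Exact <s_a> and <s_a s_b> (pair order as everywhere) under the model."""
    n = params.n
    dist = enumerate_distribution(params)
    S = all_states(n)
    p = dist.probs
    means = np.zeros(n)
    second = np.zeros((n, n))
    for lo in range(0, len(S), _CHUNK):
        chunk = S[lo : lo + _CHUNK].astype(np.float64)
        w = p[lo : lo + _CHUNK]
        means += w @ chunk
        second += (chunk * w[:, None]).T @ chunk
    rows, cols = pair_index_arrays(n)
    return means, second[rows, cols]


def data_moments(values, weights=None) -> tuple[np.ndarray, np.ndarray]:
    """Weighted sample means and pair products of fully observed data.

    ``values`` may be an (m, n) +/-1 array or an object with ``values`` /
    ``weights`` attributes (an ObservationSet).  Weights are normalized to
    sum to one.
    """
    if hasattr(values, "values") and hasattr(values, "weights"):
        weights = values.weights
        values = values.values
    S = np.atleast_2d(np.asarray(values, dtype=float))
    if S.size == 0:
        raise ValueError("empty observation set")
    if np.isnan(S).any():
        raise ValueError("data_moments requires fully observed configurations")
    m = len(S)
    w = np.ones(m) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    means = w @ S
    second = (S * w[:, None]).T @ S
    rows, cols = pair_index_arrays(S.shape[1])
    return means, second[rows, cols]


def kl_divergence(
    p_true: LandscapeDistribution, p_est: LandscapeDistribution, base: float | None = None
) -> float:
    """KL(p_true || p_est) = sum_i p_i (log p_i - log q_i).

    Natural log by default; pass ``base=2`` for bits.
    """
    if p_true.n != p_est.n:
        raise ValueError(f"dimension mismatch: n={p_true.n} vs n={p_est.n}")
    kl = float(np.sum(p_true.probs * (p_true.log_probs - p_est.log_probs)))
    kl = max(kl, 0.0)  # clip tiny negative rounding
    if base is not None:
        kl /= np.log(base)
    return kl


def log_partition(params: IsingParameters) -> float:
    """log Z(theta) by exact enumeration (n within the cap)."""
    return float(logsumexp(energies(all_states(params.n), params)))


def kl_between_params(
    true_params: IsingParameters,
    est_params: IsingParameters,
    base: float | None = None,
    true_moments: np.ndarray | None = None,
    true_log_z: float | None = None,
) -> float:
    """KL from the landscape of ``true_params`` to that of ``est_params``.

    Uses the moment identity KL = (theta_p - theta_q) . m_p - log Z_p + log Z_q,
    avoiding a second full-distribution pass; exact, same result as
    ``kl_divergence`` on the enumerated distributions.  ``true_moments`` (the
    concatenated pair/field moment vector) and ``true_log_z`` may be passed to
    amortize the true-landscape pass across many estimates.
    """
    if true_params.n != est_params.n:
        raise ValueError(
            f"dimension mismatch: n={true_params.n} vs n={est_params.n}"
        )
    if true_moments is None:
        means, pmeans = model_moments(true_params)
        true_moments = np.concatenate([pmeans, means])
    if true_log_z is None:
        true_log_z = log_partition(true_params)
    log_z_q = log_partition(est_params)
    kl = float(
        (true_params.vector - est_params.vector) @ true_moments
        - true_log_z
        + log_z_q
    )
    kl = max(kl, 0.0)
    if base is not None:
        kl /= np.log(base)
    return kl
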