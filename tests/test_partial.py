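"""Partial-MPF: completion expansion, dynamic weights, restricted flows,
the softmax gradient term, and the value of partial data."""

import numpy as np
import pytest

from isingmpf.core import (
    IsingParameters,
    config_to_index,
    enumerate_distribution,
    kl_between_params,
    n_pairs,
)
from isingmpf.data import ObservationSet, impute_observation_set
from isingmpf.mpf import MPFSettings, NeighborhoodSpec, fit_mpf, mpf_gradient, mpf_objective, neighbors
from isingmpf.partial import (
    completion_weights,
    expand,
    fit_partial_mpf,
    partial_mpf_gradient,
    partial_mpf_objective,
    restricted_neighbors,
)
from isingmpf.simulate import draw_parameters, mask_random, metropolis_sample

from conftest import fd_gradient, random_configs, random_params

X = np.nan


def _settings(lam=0.0, order=1, **kw):
    return MPFSettings(neighborhood=NeighborhoodSpec(order=order), lam=lam, **kw)


class TestExpand:
    def test_canonical_example(self):
        got = expand(np.array([1, -1, X, X]))
        expected = [
            [1, -1, -1, -1], [1, -1, -1, 1], [1, -1, 1, -1], [1, -1, 1, 1]
        ]
        np.testing.assert_array_equal(got, expected)

    def test_no_missing_is_identity(self):
        row = np.array([1.0, -1.0, 1.0])
        got = expand(row)
        assert got.shape == (1, 3)
        np.testing.assert_array_equal(got[0], row)

    def test_three_missing_gives_eight_distinct(self):
        got = expand(np.array([X, 1, X, X]))
        assert got.shape == (8, 4)
        assert len({tuple(r) for r in got}) == 8

    def test_cap_enforced(self):
        row = np.full(12, X)
        with pytest.raises(ValueError, match="cap"):
            expand(row, max_missing=10)


class TestCompletionWeights:
    def test_uniform_at_zero_theta(self):
        cs = completion_weights(
            IsingParameters.zeros(4), np.array([1, -1, X, X]), weight=3.0
        )
        np.testing.assert_allclose(cs.weights, 3.0 / 4, atol=1e-14)

    def test_two_state_closed_form(self):
        # known sigma1=+1, J=0.5, h=0: p(sigma2=+1 | sigma1) = 1/(1+e^{-1})
        cs = completion_weights(
            IsingParameters([0.5], [0.0, 0.0]), np.array([1.0, X])
        )
        w_plus = cs.weights[np.where(cs.completions[:, 1] == 1)[0][0]]
        assert w_plus == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-10)

    @pytest.mark.parametrize("n,m", [(6, 2), (8, 4), (12, 6)])
    def test_matches_full_enumeration_conditional(self, rng, n, m):
        params = random_params(rng, n)
        row = random_configs(rng, 1, n)[0]
        row[rng.choice(n, m, replace=False)] = X
        cs = completion_weights(params, row)
        dist = enumerate_distribution(params)
        probs = np.array(
            [dist.probs[config_to_index(c)] for c in cs.completions]
        )
        np.testing.assert_allclose(cs.weights, probs / probs.sum(), atol=1e-10)

    def test_weights_sum_to_source_weight(self, rng):
        params = random_params(rng, 6)
        row = np.array([1, X, -1, X, X, 1], dtype=float)
        cs = completion_weights(params, row, weight=0.7)
        assert cs.weights.sum() == pytest.approx(0.7, abs=1e-12)


class TestRestrictedNeighbors:
    def test_counts(self):
        row = np.array([1, -1, X, X], dtype=float)
        comp = expand(row)[0]
        nb1 = restricted_neighbors(comp, row, NeighborhoodSpec(order=1))
        assert len(nb1) == 2  # n - m
        nb2 = restricted_neighbors(comp, row, NeighborhoodSpec(order=2))
        assert len(nb2) == 2 + 1  # (n-m) + C(n-m, 2)

    def test_reduces_to_plain_neighbors_when_complete(self, rng):
        row = random_configs(rng, 1, 5)[0]
        spec = NeighborhoodSpec(order=2)
        np.testing.assert_array_equal(
            restricted_neighbors(row, row, spec), neighbors(row, spec)
        )

    def test_unknown_positions_untouched(self):
        row = np.array([1, X, -1, X], dtype=float)
        for comp in expand(row):
            for nb in restricted_neighbors(comp, row, NeighborhoodSpec(order=2)):
                np.testing.assert_array_equal(nb[[1, 3]], comp[[1, 3]])


class TestObjective:
    def test_reduces_to_standard_on_full_data(self, rng):
        S = random_configs(rng, 6, 5)
        obs = ObservationSet.from_array(S)
        params = random_params(rng, 5)
        st = _settings(lam=1.5, order=2)
        assert partial_mpf_objective(obs, params, st) == pytest.approx(
            mpf_objective(obs, params, st), abs=1e-12
        )
        np.testing.assert_allclose(
            partial_mpf_gradient(obs, params, st),
            mpf_gradient(obs, params, st),
            atol=1e-12,
        )

    def test_hand_count_single_partial(self):
        # {+1, X} at theta=0: 2 completions x weight 1/2 x 1 restricted
        # neighbour x Gamma=1 -> K = 1
        obs = ObservationSet.from_array(np.array([[1.0, X]]))
        k = partial_mpf_objective(obs, IsingParameters.zeros(2), _settings())
        assert k == pytest.approx(1.0, abs=1e-14)

    def test_flow_mass_conserved_at_zero_theta(self, rng):
        # all Gamma = 1: objective = sum_g W_g * |restricted N(g)|
        n = 6
        rows = []
        for m in (0, 1, 3):
            row = random_configs(rng, 1, n)[0]
            if m:
                row[rng.choice(n, m, replace=False)] = X
            rows.append(row)
        w = np.array([0.5, 1.5, 2.0])
        obs = ObservationSet.from_array(np.array(rows), weights=w)
        k = partial_mpf_objective(obs, IsingParameters.zeros(n), _settings())
        expected = w[0] * 6 + w[1] * 5 + w[2] * 3
        assert k == pytest.approx(expected, abs=1e-12)


class TestGradient:
    @pytest.mark.parametrize("order", [1, 2])
    def test_matches_finite_differences(self, rng, order):
        for trial in range(4):
            n = int(rng.integers(4, 7))
            S = random_configs(rng, 5, n)
            for r in range(2, 5):
                m = int(rng.integers(1, 4))
                S[r, rng.choice(n, m, replace=False)] = X
            w = rng.uniform(0.3, 1.7, 5)
            obs = ObservationSet.from_array(S, weights=w)
            # include a point near theta = 0 (continuity there matters)
            scale = 0.0 if trial == 0 else 0.5
            theta = rng.normal(0, 1, n_pairs(n) + n) * scale + (
                1e-4 if trial == 0 else 0.0
            )
            st = _settings(lam=2.0, order=order)
            g = partial_mpf_gradient(
                obs, IsingParameters.from_vector(theta, n), st
            )
            fd = fd_gradient(
                lambda t: partial_mpf_objective(
                    obs, IsingParameters.from_vector(t, n), st
                ),
                theta,
            )
            np.testing.assert_allclose(g, fd, rtol=1e-6, atol=1e-7)

    def test_dropping_weight_term_breaks_gradient(self, rng):
        n = 5
        S = random_configs(rng, 4, n)
        S[1, [0, 2]] = X
        S[3, 4] = X
        obs = ObservationSet.from_array(S)
        theta = rng.normal(0, 0.5, n_pairs(n) + n)
        st = _settings()
        fd = fd_gradient(
            lambda t: partial_mpf_objective(
                obs, IsingParameters.from_vector(t, n), st
            ),
            theta,
        )
        broken = partial_mpf_gradient(
            obs, IsingParameters.from_vector(theta, n), st, with_weight_grad=False
        )
        assert np.max(np.abs(broken - fd)) > 1e-3


class TestFit:
    def test_no_unknowns_identical_to_standard(self, rng):
        S = random_configs(rng, 10, 5)
        obs = ObservationSet.from_array(S)
        st = _settings(lam=1.0)
        a = fit_mpf(obs, st)
        b = fit_partial_mpf(obs, st)
        np.testing.assert_array_equal(a.params.vector, b.params.vector)
        assert a.n_iterations == b.n_iterations

    def test_alternating_mode_agrees_roughly(self, rng):
        n = 5
        S = random_configs(rng, 12, n)
        S[6:, 1] = X
        obs = ObservationSet.from_array(S)
        st = _settings(lam=20.0)
        joint = fit_partial_mpf(obs, st, mode="joint")
        alt = fit_partial_mpf(obs, st, mode="alternating")
        assert alt.converged
        # the two fixed points differ slightly (the objective is only an
        # approximation to likelihood, so freezing vs differentiating the
        # completion weights need not agree exactly) but stay close
        assert kl_between_params(joint.params, alt.params) < 0.1

    def test_partial_data_beats_full_only_and_naive(self, rng):
        # the qualitative pattern: adding 25%-missing data through the
        # dynamic-weight objective improves the fit; modal imputation does not
        n = 10
        deltas_partial, deltas_naive = [], []
        for rep in range(5):
            rep_rng = np.random.default_rng([123, rep])
            truth = draw_parameters(n, 0.2, rep_rng)
            S = metropolis_sample(truth, 256, rep_rng,
                                  burn_in_sweeps=300, thin_sweeps=3)
            masked = mask_random(S[128:], 3, rep_rng)
            mixed = np.vstack([S[:128].astype(float), masked])
            st = _settings(lam=3000.0)
            obs_full = ObservationSet.from_array(S[:128].astype(float))
            obs_mixed = ObservationSet.from_array(mixed)
            obs_naive = impute_observation_set(obs_mixed)
            kl_full = kl_between_params(truth, fit_mpf(obs_full, st).params)
            kl_partial = kl_between_params(
                truth, fit_partial_mpf(obs_mixed, st).params
            )
            kl_naive = kl_between_params(truth, fit_mpf(obs_naive, st).params)
            deltas_partial.append(kl_full - kl_partial)
            deltas_naive.append(kl_naive - kl_partial)
        assert np.mean(deltas_partial) > 0  # partial data helps
        assert np.mean(deltas_naive) > 0    # and beats modal imputation

    def test_masking_independent_question_preserves_field(self, rng):
        # a question with no couplings in truth: masking it should barely
        # move its recovered field relative to the full-data fit
        n = 6
        truth = random_params(rng, n, sigma=0.3)
        q = 2
        J = truth.coupling_matrix()
        J[q, :] = 0.0
        J[:, q] = 0.0
        from isingmpf.core import pair_index_arrays

        rows, cols = pair_index_arrays(n)
        truth = IsingParameters(J[rows, cols], truth.fields)
        S = metropolis_sample(truth, 600, rng, burn_in_sweeps=300, thin_sweeps=3)
        masked = S.astype(float).copy()
        masked[::2, q] = X  # half the rows lose question q
        st = _settings(lam=100.0)
        h_full = fit_mpf(ObservationSet.from_array(S.astype(float)), st).params.fields[q]
        h_masked = fit_partial_mpf(ObservationSet.from_array(masked), st).params.fields[q]
        assert abs(h_full - h_masked) < 0.15


from hypothesis import given, settings as hsettings, strategies as st


@hsettings(derandomize=True, deadline=None, max_examples=30)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_completion_invariants_property(seed):
    """Completions agree with the known entries; weights are a conditional
    distribution carrying exactly the source weight."""
    r = np.random.default_rng(seed)
    n = int(r.integers(2, 9))
    m = int(r.integers(0, min(n, 5) + 1))
    row = (2.0 * r.integers(0, 2, n) - 1).astype(float)
    if m:
        row[r.choice(n, m, replace=False)] = np.nan
    params = IsingParameters(
        r.normal(0, 0.8, n_pairs(n)), r.normal(0, 0.8, n)
    )
    w = float(r.uniform(0.1, 3.0))
    cs = completion_weights(params, row, weight=w)
    assert cs.completions.shape == (2**m, n)
    known = ~np.isnan(row)
    assert np.all(cs.completions[:, known] == row[known])
    assert cs.weights.sum() == pytest.approx(w, abs=1e-12)
    assert np.all(cs.weights > 0)
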