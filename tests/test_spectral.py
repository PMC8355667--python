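import math

import numpy as np
import pytest

from hypersis import (
    Hypergraph,
    ModelParams,
    comembership,
    effective_matrix,
    eta,
    extinction_bounds,
    make_rate_function,
    nonextinction_certificate,
    partition_comembership,
    random_hypergraph,
    spectral_threshold,
    subset_pressure,
    symmetric_part,
)
from hypersis.hypergraph import laplacian
from hypersis.spectral import largest_eigenvalue

IDENTITY = make_rate_function("identity")
H3_LAMBDA = (5 + math.sqrt(17)) / 2  # largest eigenvalue of W(H3)


def connected_instances(n_instances=8):
    """Seeded connected hypergraphs with n <= 12 for brute-force checks."""
    out, seed = [], 500
    while len(out) < n_instances:
        seed += 1
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        H = random_hypergraph(n, {2: n, 3: 3}, seed)
        if laplacian(H).n_zero == 1:
            out.append(H)
    return out


class TestSymmetricPart:
    def test_symmetric_unchanged(self):
        M = np.array([[1.0, 2.0], [2.0, 3.0]])
        np.testing.assert_array_equal(symmetric_part(M), M)

    def test_forced_by_formula(self):
        np.testing.assert_array_equal(
            symmetric_part(np.array([[0.0, 2.0], [0.0, 0.0]])),
            np.array([[0.0, 1.0], [1.0, 0.0]]),
        )

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            symmetric_part(np.zeros((2, 3)))

    def test_jacobian_symmetric_part_negative_subcritical(self, h3):
        # along a subcritical trajectory the symmetrized Jacobian stays
        # negative definite (the global-stability certificate)
        from hypersis import integrate_adaptive, jacobian

        rep = spectral_threshold(h3, IDENTITY, ModelParams(beta=1.0, delta=1.0, i0=0.5))
        params = ModelParams(beta=0.8 * rep.beta_c, delta=1.0, i0=0.5)
        traj = integrate_adaptive(np.full(3, 0.7), h3, params, IDENTITY, T=10.0,
                                  t_eval=np.linspace(0, 10, 21))
        for p in traj.states:
            J = jacobian(p, h3, params, IDENTITY)
            assert largest_eigenvalue(symmetric_part(J)) < 0


class TestEffectiveMatrix:
    def test_identity_gives_w(self, h3):
        np.testing.assert_array_equal(effective_matrix(h3, IDENTITY), comembership(h3))
        np.testing.assert_array_equal(effective_matrix(h3, IDENTITY, "majorant"),
                                      comembership(h3))

    def test_partitioned_weighted_sum(self, h3_partitioned):
        fams = [IDENTITY, make_rate_function("log1p", a=2)]
        W1, W2 = partition_comembership(h3_partitioned)
        np.testing.assert_allclose(effective_matrix(h3_partitioned, fams), W1 + 2 * W2)

    def test_step_majorant_half_w(self, h3):
        f = make_rate_function("step", c1=2, c2=1)
        np.testing.assert_allclose(effective_matrix(h3, f, "majorant"),
                                   0.5 * comembership(h3))

    def test_unknown_mode(self, h3):
        with pytest.raises(ValueError, match="mode"):
            effective_matrix(h3, IDENTITY, "fastest")


class TestSpectralThreshold:
    def test_h3_identity(self, h3):
        rep = spectral_threshold(h3, IDENTITY, ModelParams(beta=0.1, delta=1.0, i0=0.5))
        assert rep.lambda_max == pytest.approx(H3_LAMBDA, rel=1e-12)
        assert rep.beta_c == pytest.approx(1 / H3_LAMBDA, rel=1e-12)
        assert rep.condition_met
        assert rep.concavity_certified

    def test_single_edge(self, single_edge):
        rep = spectral_threshold(single_edge, IDENTITY, ModelParams(beta=1.0, delta=1.0, i0=0.5))
        assert rep.lambda_max == pytest.approx(2.0)
        assert rep.beta_c == pytest.approx(0.5)
        assert not rep.condition_met

    def test_no_hyperedges_always_met(self):
        H = Hypergraph(4, [])
        rep = spectral_threshold(H, IDENTITY, ModelParams(beta=100.0, delta=1.0, i0=0.5))
        assert rep.beta_c == math.inf
        assert rep.condition_met

    def test_invariant_beta_c_identity(self, h3):
        for rf in [IDENTITY, make_rate_function("log1p", a=2)]:
            rep = spectral_threshold(h3, rf, ModelParams(beta=0.2, delta=1.7, i0=0.5))
            assert rep.beta_c * rep.c_f * rep.lambda_max == pytest.approx(1.7)

    def test_delta_scale_equivariance(self, h3):
        r1 = spectral_threshold(h3, IDENTITY, ModelParams(beta=0.1, delta=1.0, i0=0.5))
        r3 = spectral_threshold(h3, IDENTITY, ModelParams(beta=0.1, delta=3.0, i0=0.5))
        assert r3.beta_c == pytest.approx(3 * r1.beta_c, rel=1e-12)

    def test_step_local_basis_only(self, h3):
        f = make_rate_function("step", c1=2, c2=1)
        rep = spectral_threshold(h3, f, ModelParams(beta=5.0, delta=1.0, i0=0.5))
        # f'(0) = 0 -> vacuous beta_c, flagged as a local claim only
        assert rep.beta_c == math.inf
        assert not rep.concavity_certified
        assert "local" in rep.theorem_basis

    def test_step_majorant_mode(self, h3):
        f = make_rate_function("step", c1=2, c2=1)
        rep = spectral_threshold(h3, f, ModelParams(beta=0.1, delta=1.0, i0=0.5),
                                 mode="majorant")
        assert rep.c_f == pytest.approx(0.5)
        assert rep.beta_c == pytest.approx(2 / H3_LAMBDA, rel=1e-12)

    def test_graph_reduction_conservative(self):
        # for size-2 hypergraphs lambda(W) >= lambda(A): the diagonal adds
        # degree mass, so beta_c is conservative versus the adjacency rule
        for seed in range(5):
            H = random_hypergraph(15, {2: 20}, seed=seed)
            lam_w = largest_eigenvalue(comembership(H))
            lam_a = largest_eigenvalue(comembership(H, zero_diagonal=True))
            assert lam_w >= lam_a - 1e-12

    def test_partitioned_threshold(self, h3_partitioned):
        fams = [IDENTITY, make_rate_function("log1p", a=2)]
        rep = spectral_threshold(h3_partitioned, fams, ModelParams(beta=0.1, delta=1.0, i0=0.5))
        W1, W2 = partition_comembership(h3_partitioned)
        assert rep.c_f == 1.0
        assert rep.lambda_max == pytest.approx(largest_eigenvalue(W1 + 2 * W2))


class TestExtinctionBounds:
    def test_prob_bound_at_zero(self, h3):
        rep = spectral_threshold(h3, IDENTITY, ModelParams(beta=0.1, delta=1.0, i0=0.5))
        eb = extinction_bounds(rep, n=3, i0=0.2, params=ModelParams(beta=0.1, delta=1.0, i0=0.2))
        assert eb.prob_bound(0.0) == pytest.approx(min(1.0, 3 * 0.2))

    def test_h3_expected_tau(self, h3):
        params = ModelParams(beta=0.1, delta=1.0, i0=0.5)
        rep = spectral_threshold(h3, IDENTITY, params)
        eb = extinction_bounds(rep, n=3, i0=0.5, params=params)
        expected = (math.log(3) + 1) / (1 - 0.1 * H3_LAMBDA)
        assert eb.expected_tau_bound == pytest.approx(expected, rel=1e-10)
        assert eb.expected_tau_bound == pytest.approx(3.859, abs=5e-3)

    def test_boundary_infinite_tau(self, h3):
        # at beta = beta_c the exponent vanishes (to rounding): the tau
        # bound blows up and the probability bound stays flat at n*i0
        rep = spectral_threshold(h3, IDENTITY, ModelParams(beta=0.1, delta=1.0, i0=0.2))
        params = ModelParams(beta=rep.beta_c, delta=1.0, i0=0.2)
        rep2 = spectral_threshold(h3, IDENTITY, params)
        eb = extinction_bounds(rep2, n=3, i0=0.2, params=params)
        assert eb.expected_tau_bound > 1e10
        np.testing.assert_allclose(eb.prob_bound(np.array([0.0, 5.0])), 0.6, rtol=1e-9)

    def test_uncertified_concavity_refused(self, h3):
        f = make_rate_function("step", c1=2, c2=1)
        params = ModelParams(beta=0.1, delta=1.0, i0=0.5)
        rep = spectral_threshold(h3, f, params)
        with pytest.raises(ValueError, match="majorant"):
            extinction_bounds(rep, n=3, i0=0.5, params=params)
        # majorant mode is the sanctioned route
        rep_m = spectral_threshold(h3, f, params, mode="majorant")
        eb = extinction_bounds(rep_m, n=3, i0=0.5, params=params)
        assert eb.expected_tau_bound < math.inf

    def test_prob_bound_monotone_decay(self, h3):
        params = ModelParams(beta=0.05, delta=1.0, i0=0.1)
        rep = spectral_threshold(h3, IDENTITY, params)
        eb = extinction_bounds(rep, n=3, i0=0.1, params=params)
        ts = np.linspace(0, 10, 50)
        vals = eb.prob_bound(ts)
        assert np.all(np.diff(vals) <= 0)


class TestSubsetPressure:
    def test_h3_singletons(self, h3):
        assert subset_pressure(h3, {2}, IDENTITY).value == pytest.approx(2.0)
        assert subset_pressure(h3, {0}, IDENTITY).value == pytest.approx(3.0)

    def test_full_set_zero(self, h3):
        assert subset_pressure(h3, {0, 1, 2}, IDENTITY).value == 0.0

    def test_empty_rejected(self, h3):
        with pytest.raises(ValueError, match="non-empty"):
            subset_pressure(h3, set(), IDENTITY)

    def test_against_definition(self, brute_instances):
        # direct double-sum oracle over nodes and hyperedges
        rng = np.random.default_rng(9)
        for H in brute_instances[:4]:
            S = set(rng.choice(H.n, size=max(1, H.n // 3), replace=False).tolist())
            expected = 0.0
            for i in S:
                for h in H.hyperedges:
                    if i in h:
                        expected += float(len(h - S))
            assert subset_pressure(H, S, IDENTITY).value == pytest.approx(expected)


class TestEta:
    def test_h3_singleton(self, h3):
        val, S, method = eta(h3, 1, IDENTITY, method="brute")
        assert val == pytest.approx(2.0)
        assert S == frozenset({2})
        assert method == "brute"

    def test_isolated_component_zero(self):
        H = Hypergraph(5, [frozenset({0, 1}), frozenset({2, 3}), frozenset({2, 4})])
        val, S, _ = eta(H, 2, IDENTITY, method="brute")
        assert val == 0.0
        assert S == frozenset({0, 1})

    def test_greedy_upper_bounds_brute(self, brute_instances):
        for H in brute_instances:
            m = max(1, H.n // 2)
            b, _, _ = eta(H, m, IDENTITY, method="brute")
            g, _, _ = eta(H, m, IDENTITY, method="greedy")
            assert g >= b - 1e-12

    def test_greedy_matches_brute_on_singleton_minimizer(self, h3):
        b, _, _ = eta(h3, 1, IDENTITY, method="brute")
        g, _, _ = eta(h3, 1, IDENTITY, method="greedy")
        assert g == pytest.approx(b)

    def test_budget_refusal(self):
        H = random_hypergraph(40, {2: 30}, seed=1)
        with pytest.raises(ValueError, match="greedy"):
            eta(H, 20, IDENTITY, method="brute", budget=1000)

    def test_bad_m_limit(self, h3):
        with pytest.raises(ValueError, match="m_limit"):
            eta(h3, 2, IDENTITY)  # floor(3/2) = 1


class TestLemma87AndCheeger:
    def test_chord_eta_inequality(self):
        # (f(e_max-1)/(e_max-1)) * eta(H, m) <= eta(H, m, f) for concave
        # non-decreasing f, brute-forced on both sides
        fs = [make_rate_function("log1p", a=1), make_rate_function("arctan"),
              make_rate_function("capped_linear", c=2)]
        for H in connected_instances(5):
            from hypersis import max_hyperedge_size

            e_max = max_hyperedge_size(H)
            m = max(1, H.n // 2)
            eta_id, _, _ = eta(H, m, IDENTITY, method="brute")
            for f in fs:
                chord = float(f(e_max - 1)) / (e_max - 1)
                eta_f, _, _ = eta(H, m, f, method="brute")
                assert chord * eta_id <= eta_f + 1e-10

    def test_cheeger_consistency(self):
        # 2 * eta(H, floor(n/2)) >= lambda_c(Delta) on connected instances
        for H in connected_instances(8):
            m = max(1, H.n // 2)
            val, _, _ = eta(H, m, IDENTITY, method="brute")
            assert 2 * val >= laplacian(H).lambda_c - 1e-10


class TestEigenvalueMonotonicity:
    def test_diagonal_subtraction_monotone(self):
        # the quadratic-form argument gives lambda((B-Lam)^S) <= lambda(B^S)
        # for ANY real B; the unsymmetrized claim needs symmetric B (for a
        # general non-normal B, subtracting a non-negative diagonal can
        # increase the largest real eigenvalue part)
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = int(rng.integers(2, 9))
            B = rng.normal(size=(n, n))
            lam = np.diag(rng.random(n) * 3)
            assert (largest_eigenvalue(symmetric_part(B - lam))
                    <= largest_eigenvalue(symmetric_part(B)) + 1e-10)
            B_sym = symmetric_part(rng.normal(size=(n, n)))
            assert largest_eigenvalue(B_sym - lam) <= largest_eigenvalue(B_sym) + 1e-10


class TestNonextinctionCertificate:
    def test_identity_prefactor_cancels(self):
        H = random_hypergraph(10, {2: 14}, seed=2)
        params = ModelParams(beta=2.0, delta=1.0, i0=0.5)
        rep = nonextinction_certificate(H, IDENTITY, params)
        eta_val, _, _ = eta(H, H.n // 2, IDENTITY, method="brute")
        if eta_val > 0:
            assert rep.r == pytest.approx(1.0 / (2.0 * eta_val))

    def test_r_above_one_withholds_certificate(self):
        H = random_hypergraph(10, {2: 14}, seed=2)
        params = ModelParams(beta=1e-6, delta=1.0, i0=0.5)
        rep = nonextinction_certificate(H, IDENTITY, params)
        assert rep.r >= 1.0
        assert not rep.condition_met
        assert rep.prob_lower_bound is None

    def test_supercritical_certificate_granted(self):
        for H in connected_instances(3):
            params = ModelParams(beta=50.0, delta=1.0, i0=0.5)
            rep = nonextinction_certificate(H, IDENTITY, params)
            assert rep.r < 1.0
            assert rep.condition_met
            assert rep.time_horizon > 0
            assert "O(r^m)" in rep.caveat

    def test_nonconcave_refused(self, h3):
        params = ModelParams(beta=1.0, delta=1.0, i0=0.5)
        with pytest.raises(ValueError, match="concave"):
            nonextinction_certificate(h3, make_rate_function("step", c1=2, c2=1), params)

    def test_greedy_direction_labelled(self):
        H = random_hypergraph(12, {2: 16}, seed=4)
        params = ModelParams(beta=10.0, delta=1.0, i0=0.5)
        rep = nonextinction_certificate(H, IDENTITY, params, eta_method="greedy")
        assert rep.eta_method == "greedy"
        assert "upper bound" in rep.eta_direction_note
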