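import numpy as np
import pytest
from scipy import integrate
from scipy.special import gammaln

from oracle_utils import enumerate_posterior
from smartdeconv import core
from smartdeconv.data import MarkerSpec, ModelConfig, SpotCounts
from smartdeconv.simulate import generate_from_model


def _decrement(state, t):
    d, v, m = state.doc[t], state.word[t], state.weight[t]
    k, s = state.z[t], state.s[t]
    state.n_dk[d, k] -= m
    if s:
        state.nt_kv[k, v] -= m
        state.nt_k[k] -= m
    else:
        state.n_kv[k, v] -= m
        state.n_k[k] -= m


def _set_assignments(state, z, s):
    state.z[:] = z
    state.s[:] = s
    (state.n_dk, state.n_kv, state.nt_kv,
     state.n_k, state.nt_k) = state.rebuild_tables()


class TestGeneWeights:
    def test_equal_frequencies_give_unit_weights(self):
        sc = SpotCounts(np.array([[2, 3], [3, 2]]), ["a", "b"], ["s0", "s1"])
        np.testing.assert_allclose(core.gene_weights(sc, True), [1.0, 1.0])

    def test_disabled_weighting_is_identity(self):
        sc = SpotCounts(np.array([[5, 0], [1, 7]]), ["a", "b"], ["s0", "s1"])
        np.testing.assert_allclose(core.gene_weights(sc, False), [1.0, 1.0])

    def test_skewed_frequencies_match_direct_arithmetic(self):
        # f = (0.75, 0.25): raw = (-log2 0.75, -log2 0.25) = (0.41504, 2),
        # token-average 0.75*0.41504 + 0.25*2 = 0.81128
        sc = SpotCounts(np.array([[3], [1]]), ["a", "b"], ["s0"])
        np.testing.assert_allclose(core.gene_weights(sc, True),
                                   [0.511585, 2.465246], atol=1e-5)

    def test_absent_gene_gets_zero_weight(self):
        sc = SpotCounts(np.array([[3], [1], [0]]), ["a", "b", "c"], ["s0"])
        m = core.gene_weights(sc, True)
        assert m[2] == 0.0 and m[0] > 0

    def test_token_average_weight_is_one(self):
        rng = np.random.default_rng(3)
        mat = rng.poisson(2.0, size=(20, 10))
        mat[:, mat.sum(axis=0) == 0] += 1
        sc = SpotCounts(mat, [f"g{i}" for i in range(20)],
                        [f"s{i}" for i in range(10)])
        m = core.gene_weights(sc, True)
        f = mat.sum(axis=1) / mat.sum()
        assert np.isclose(np.sum(f * m), 1.0)


class TestInitializeState:
    def test_deterministic_under_fixed_seed(self, tiny_counts, tiny_markers,
                                            tiny_config):
        a = core.initialize_state(tiny_counts, tiny_markers, tiny_config, 5)
        b = core.initialize_state(tiny_counts, tiny_markers, tiny_config, 5)
        np.testing.assert_array_equal(a.z, b.z)
        np.testing.assert_array_equal(a.s, b.s)
        np.testing.assert_array_equal(a.alpha, b.alpha)

    def test_non_marker_molecules_start_on_standard_branch(
            self, tiny_counts, tiny_markers, tiny_config):
        st = core.initialize_state(tiny_counts, tiny_markers, tiny_config, 11)
        non_marker = st.word != 0  # only g0 is a marker
        assert np.all(st.s[non_marker] == 0)

    def test_tables_match_rebuild(self, tiny_counts, tiny_markers,
                                  tiny_config):
        st = core.initialize_state(tiny_counts, tiny_markers, tiny_config, 2)
        n_dk, n_kv, nt_kv, n_k, nt_k = st.rebuild_tables()
        np.testing.assert_allclose(st.n_dk, n_dk, atol=1e-9)
        np.testing.assert_allclose(st.n_kv, n_kv, atol=1e-9)
        np.testing.assert_allclose(st.nt_kv, nt_kv, atol=1e-9)


class TestConditional:
    def test_marker_branch_zero_off_support(self, tiny_counts, tiny_markers,
                                            tiny_config):
        st = core.initialize_state(tiny_counts, tiny_markers, tiny_config, 1)
        t = int(np.flatnonzero(st.word == 1)[0])  # g1 is nobody's marker
        _decrement(st, t)
        p = core.conditional_probs(st, st.doc[t], st.word[t], tiny_config)
        assert np.all(p[:, 1] == 0)
        assert np.isclose(p.sum(), 1.0)

    def test_symmetric_types_get_equal_probability(self):
        # two marked types sharing the marker gene, fully symmetric tables
        counts = SpotCounts(np.array([[2], [3]]), ["g0", "g1"], ["s0"])
        markers = MarkerSpec(["A", "B"], {"A": ["g0"], "B": ["g0"]})
        cfg = ModelConfig(beta=0.05, beta_tilde=0.3, use_weighting=False,
                          iterations=2, burn_in=1)
        st = core.initialize_state(counts, markers, cfg, 0)
        # after removing molecule 4, both types hold one g0 marker-branch
        # molecule and one g1 standard molecule each
        _set_assignments(st, np.array([0, 1, 0, 1, 0]),
                         np.array([1, 1, 0, 0, 0]))
        st.alpha[:] = 0.5
        st.sync_alpha_dk()
        _decrement(st, 4)
        p = core.conditional_probs(st, 0, st.word[4], cfg)
        np.testing.assert_allclose(p[0], p[1])

    def test_matches_enumeration_oracle(self, tiny_counts, tiny_markers,
                                        tiny_config):
        """Full conditional of one molecule given the others equals the
        restricted, renormalized exact posterior."""
        st = core.initialize_state(tiny_counts, tiny_markers, tiny_config, 3)
        st.alpha[:] = np.array([0.4, 0.7])
        st.sync_alpha_dk()
        fixed_z = np.array([0, 1, 0, 1, 0])
        fixed_s = np.array([1, 0, 0, 0, 0])
        _set_assignments(st, fixed_z, fixed_s)
        configs, p, _ = enumerate_posterior(
            st.doc, st.word, st.support, st.alpha,
            tiny_config.beta, tiny_config.beta_tilde,
            tiny_config.gamma1, tiny_config.gamma2,
            D=2, K=2, V=3, n_marked=1)
        t0 = 0
        cond = np.zeros((2, 2))
        for cfg_states, prob in zip(configs, p):
            if all(cfg_states[t] == (fixed_z[t], fixed_s[t])
                   for t in range(5) if t != t0):
                k, s = cfg_states[t0]
                cond[k, s] += prob
        cond /= cond.sum()
        _decrement(st, t0)
        got = core.conditional_probs(st, st.doc[t0], st.word[t0], tiny_config)
        np.testing.assert_allclose(got, cond, atol=1e-12)


class TestGibbsSweep:
    def test_single_molecule_single_type_is_fixed(self):
        counts = SpotCounts(np.array([[1]]), ["g0"], ["s0"])
        markers = MarkerSpec(["A"], {"A": []})
        cfg = ModelConfig(use_weighting=False, iterations=2, burn_in=1)
        st = core.initialize_state(counts, markers, cfg, 0)
        before = (st.z.copy(), st.n_dk.copy())
        core._sampler.seed_rng(0)
        core.gibbs_sweep(st, cfg)
        np.testing.assert_array_equal(st.z, before[0])
        np.testing.assert_allclose(st.n_dk, before[1])

    def test_weighted_token_conservation_and_consistency(self, small_sim):
        cfg = ModelConfig(seed=0)
        st = core.initialize_state(small_sim["counts"], small_sim["markers"],
                                   cfg, 4)
        totals_before = st.n_dk.sum(axis=1).copy()
        core._sampler.seed_rng(1)
        for _ in range(3):
            core.gibbs_sweep(st, cfg)
        np.testing.assert_allclose(st.n_dk.sum(axis=1), totals_before,
                                   atol=1e-9)
        n_dk, n_kv, nt_kv, n_k, nt_k = st.rebuild_tables()
        np.testing.assert_allclose(st.n_dk, n_dk, atol=1e-9)
        np.testing.assert_allclose(st.n_kv, n_kv, atol=1e-9)
        np.testing.assert_allclose(st.nt_kv, nt_kv, atol=1e-9)
        # marker-branch counts never leave the marker support
        assert np.all(nt_kv[~st.support] == 0)


class TestSampleAlpha:
    def _stub_state(self, n_dk, n_marked=0):
        D, K = n_dk.shape
        V = 2
        return core.ModelState(
            doc=np.zeros(0, dtype=np.int32), word=np.zeros(0, dtype=np.int32),
            weight=np.zeros(0), z=np.zeros(0, dtype=np.int32),
            s=np.zeros(0, dtype=np.int8), n_dk=np.asarray(n_dk, dtype=float),
            n_kv=np.zeros((K, V)), nt_kv=np.zeros((K, V)),
            n_k=np.zeros(K), nt_k=np.zeros(K),
            alpha=np.ones(K), alpha_dk=np.ones((D, K)),
            weights=np.ones(V), support=np.zeros((K, V), dtype=bool),
            n_markers=np.zeros(K), n_marked=n_marked,
            N_dw=np.asarray(n_dk, dtype=float).sum(axis=1),
        )

    def test_no_spots_recovers_gamma_prior_moments(self):
        """With D=0 the conditional is the prior; chain moments must match
        Gamma(2, 1) within 3 batch-means standard errors."""
        st = self._stub_state(np.zeros((0, 1)))
        cfg = ModelConfig()
        rng = np.random.default_rng(0)
        draws = []
        for _ in range(6000):
            core.sample_alpha(st, cfg, rng)
            draws.append(st.alpha[0])
        draws = np.array(draws[500:])
        batches = draws.reshape(50, -1).mean(axis=1)
        se = batches.std(ddof=1) / np.sqrt(len(batches))
        prior_mean = cfg.eta1 / cfg.eta2
        assert abs(draws.mean() - prior_mean) < 3 * se + 1e-3

    def test_dominant_type_gets_larger_alpha(self):
        n_dk = np.tile([50.0, 2.0, 2.0], (30, 1))
        st = self._stub_state(n_dk)
        cfg = ModelConfig()
        rng = np.random.default_rng(1)
        tot = np.zeros(3)
        for _ in range(300):
            core.sample_alpha(st, cfg, rng)
            tot += st.alpha
        assert tot[0] > tot[1] and tot[0] > tot[2]

    def test_reproducible_chain(self):
        res = []
        for _ in range(2):
            st = self._stub_state(np.tile([5.0, 1.0], (4, 1)))
            rng = np.random.default_rng(9)
            for _ in range(20):
                core.sample_alpha(st, cfg := ModelConfig(), rng)
            res.append(st.alpha.copy())
        np.testing.assert_array_equal(res[0], res[1])


class TestEstimatePi:
    def test_prior_mean_when_no_counts(self, tiny_counts, tiny_markers,
                                       tiny_config):
        st = core.initialize_state(tiny_counts, tiny_markers, tiny_config, 0)
        st.n_k[:] = 0
        st.nt_k[:] = 0
        pi = core.estimate_pi(st, tiny_config)
        assert np.allclose(pi, tiny_config.gamma1
                           / (tiny_config.gamma1 + tiny_config.gamma2))

    def test_formula_arithmetic(self, tiny_counts, tiny_markers, tiny_config):
        st = core.initialize_state(tiny_counts, tiny_markers, tiny_config, 0)
        st.nt_k[0], st.n_k[0] = 30.0, 10.0
        assert np.isclose(core.estimate_pi(st, tiny_config)[0], 31 / 42)

    def test_matches_numeric_integration(self):
        """Posterior mean of a Beta-Bernoulli success rate by quadrature."""
        g1, g2, nt, n = 1.5, 2.5, 7.0, 3.0
        dens = lambda p: p ** (nt + g1 - 1) * (1 - p) ** (n + g2 - 1)
        num = integrate.quad(lambda p: p * dens(p), 0, 1)[0]
        den = integrate.quad(dens, 0, 1)[0]
        assert np.isclose((nt + g1) / (n + nt + g1 + g2), num / den,
                          atol=1e-10)


class TestEstimateResult:
    def test_combination_formula_limits(self):
        phi = np.array([[0.2, 0.8], [0.5, 0.5]])
        phit = np.array([[0.4, 0.6], [1.0, 0.0]])
        # pi = 0 -> phi; pi = 1 -> phi~; pi = 0.5 -> midpoint
        np.testing.assert_allclose(
            core.combine_phi(phi, phit, np.array([0.0, 1.0])),
            [[0.2, 0.8], [1.0, 0.0]])
        got = core.combine_phi(phi, phit, np.array([0.5, 0.5]))
        np.testing.assert_allclose(got[0], [0.3, 0.7])

    def test_unmarked_rows_passed_through(self):
        phi = np.array([[0.2, 0.8], [0.9, 0.1]])
        phit = np.array([[1.0, 0.0]])
        out = core.combine_phi(phi, phit, np.array([0.7]))
        np.testing.assert_allclose(out[1], phi[1])

    def test_prior_mean_ordering_on_empty_data(self, tiny_counts,
                                               tiny_markers, tiny_config):
        """With no observed counts the smoothed estimates reduce to prior
        means: a marker gene's phi* must exceed a non-marker gene's within
        its own type (the model's key assumption)."""
        st = core.initialize_state(tiny_counts, tiny_markers, tiny_config, 0)
        snap = core.Snapshot(
            n_dk=np.zeros_like(st.n_dk), n_kv=np.zeros_like(st.n_kv),
            nt_kv=np.zeros_like(st.nt_kv), n_k=np.zeros_like(st.n_k),
            nt_k=np.zeros_like(st.nt_k), alpha_dk=st.alpha_dk.copy())
        est = core.estimate_result([snap], st, tiny_config)
        phi_star = est["phi_star"]
        assert phi_star[0, 0] > phi_star[0, 1]  # g0 is M's marker

    def test_rows_sum_to_one_on_fitted_instance(self, small_sim):
        cfg = ModelConfig(iterations=60, burn_in=30, thin=3, seed=1)
        res = core.fit(small_sim["counts"], small_sim["markers"], cfg)
        np.testing.assert_allclose(res.theta.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(res.phi_star.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(res.phi.sum(axis=1), 1.0, atol=1e-8)
        # phi* is a convex combination of phi and phi~ for marked types
        for k in range(res.n_marked):
            lo = np.minimum(res.phi.iloc[k], res.phi_tilde.iloc[k]) - 1e-12
            hi = np.maximum(res.phi.iloc[k], res.phi_tilde.iloc[k]) + 1e-12
            assert np.all(res.phi_star.iloc[k] >= lo)
            assert np.all(res.phi_star.iloc[k] <= hi)
        # marker-restricted rows live on the marker support only
        sup = small_sim["markers"].support_matrix(list(res.phi.columns))
        assert np.all(res.phi_tilde.to_numpy()[~sup[:res.n_marked]] == 0)

    def test_empty_snapshot_list_rejected(self, tiny_counts, tiny_markers,
                                          tiny_config):
        st = core.initialize_state(tiny_counts, tiny_markers, tiny_config, 0)
        with pytest.raises(ValueError):
            core.estimate_result([], st, tiny_config)


class TestFit:
    def test_deterministic(self, small_sim):
        cfg = ModelConfig(iterations=40, burn_in=20, thin=2, seed=3)
        a = core.fit(small_sim["counts"], small_sim["markers"], cfg)
        b = core.fit(small_sim["counts"], small_sim["markers"], cfg)
        np.testing.assert_array_equal(a.theta.to_numpy(), b.theta.to_numpy())
        np.testing.assert_array_equal(a.phi_star.to_numpy(),
                                      b.phi_star.to_numpy())

    def test_repeats_average_is_row_stochastic(self, small_sim):
        cfg = ModelConfig(iterations=40, burn_in=20, thin=2, seed=3,
                          n_repeats=2)
        res = core.fit(small_sim["counts"], small_sim["markers"], cfg)
        np.testing.assert_allclose(res.theta.sum(axis=1), 1.0, atol=1e-8)
        np.testing.assert_allclose(res.phi_star.sum(axis=1), 1.0, atol=1e-8)

    def test_extra_no_marker_type_keeps_recovery(self):
        """Adding a no-marker type must not break normalization and should
        only mildly degrade marked-type recovery at the reference setting."""
        from smartdeconv.evaluate import proportion_metrics
        sim = generate_from_model(V=100, D=200, K=5, K_tilde=5,
                                  markers_per_type=5, N_d=500, seed=1)
        cfg = ModelConfig(iterations=600, burn_in=300, thin=5, seed=2)
        base = core.fit(sim["counts"], sim["markers"], cfg)
        small_sim = sim
        m = small_sim["markers"]
        aug = MarkerSpec(m.cell_types + ["extra"],
                         {**m.markers, "extra": []})
        ext = core.fit(small_sim["counts"], aug, cfg)
        np.testing.assert_allclose(ext.theta.sum(axis=1), 1.0, atol=1e-8)
        truth = small_sim["theta"]
        pcc_base = proportion_metrics(base.theta[truth.columns],
                                      truth).pcc_all
        pcc_ext = proportion_metrics(
            ext.theta[truth.columns]
            .div(ext.theta[truth.columns].sum(axis=1), axis=0), truth).pcc_all
        assert pcc_base - pcc_ext < 0.1
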