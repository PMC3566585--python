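"""Post-hoc reduction, parameter averaging, graph building, embedding."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

import dcmodes as dm
from dcmodes.inversion import InversionSettings
from dcmodes.model_core import ParameterIndex
from dcmodes.reduction import (GroupPosterior, _MaskScorer,
                               bayesian_parameter_average, build_graph,
                               gaussian_model_reduction, prune_edges,
                               reduced_evidence, search_reduced_models,
                               spectral_embed)
from dcmodes.workbench import SimulationProtocol, generate_dataset


def closed_form_evidence(X, eta, Sigma, y, lam):
    marg = X @ Sigma @ X.T + np.exp(-lam) * np.eye(X.shape[0])
    return float(multivariate_normal(mean=X @ eta, cov=marg).logpdf(y))


class TestGaussianModelReduction:
    def test_identity_reduction_is_zero(self, rng):
        C = np.array([[0.5, 0.1], [0.1, 0.4]])
        mu = np.array([0.3, -0.2])
        C0 = np.eye(2)
        eta = np.zeros(2)
        dF, mu_r, C_r = gaussian_model_reduction(mu, C, eta, C0, eta, C0)
        assert dF == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(mu_r, mu, atol=1e-12)
        np.testing.assert_allclose(C_r, C, atol=1e-12)

    def test_matches_two_direct_conjugate_inversions(self, rng):
        """dF equals F_reduced - F_full computed by two independent
        closed-form linear-Gaussian evidences."""
        T, P, lam = 40, 4, 0.8
        X = rng.standard_normal((T, P))
        eta = np.zeros(P)
        C0 = np.diag(rng.uniform(0.5, 1.5, P))
        theta = np.array([0.8, -0.6, 0.0, 0.0])
        y = X @ theta + rng.standard_normal(T) * np.exp(-lam / 2)
        # full posterior (conjugate)
        Pi = np.exp(lam)
        Cpost = np.linalg.inv(Pi * X.T @ X + np.linalg.inv(C0))
        mupost = Cpost @ (Pi * X.T @ y)
        # reduced prior: shrink parameters 2 and 3
        C0r = C0.copy()
        C0r[2, 2] = C0r[3, 3] = 1e-8
        dF, _, _ = gaussian_model_reduction(mupost, Cpost, eta, C0,
                                            eta, C0r)
        F_full = closed_form_evidence(X, eta, C0, y, lam)
        F_red = closed_form_evidence(X, eta, C0r, y, lam)
        assert dF == pytest.approx(F_red - F_full, abs=1e-6)

    def test_pruning_a_supported_effect_is_penalised(self, rng):
        """Removing a well-identified large coupling gives strongly
        negative dF."""
        T, lam = 200, 2.0
        X = rng.standard_normal((T, 2))
        theta = np.array([1.0, 0.0])
        y = X @ theta + rng.standard_normal(T) * np.exp(-lam / 2)
        Pi = np.exp(lam)
        C0 = np.eye(2)
        Cpost = np.linalg.inv(Pi * X.T @ X + np.eye(2))
        mupost = Cpost @ (Pi * X.T @ y)
        C0r = C0.copy()
        C0r[0, 0] = 1e-8
        dF, _, _ = gaussian_model_reduction(mupost, Cpost, np.zeros(2), C0,
                                            np.zeros(2), C0r)
        assert dF < -20


@pytest.fixture(scope="module")
def inverted_3node():
    proto = SimulationProtocol(n_nodes=3, n_volumes=90, n_driven=1,
                               seed=31, steps_per_tr=8,
                               connection_prob=0.4)
    ds = generate_dataset(proto, seed=31)
    prior = dm.default_priors(proto.spec)
    settings = InversionSettings(max_iterations=24, dt_micro=proto.TR / 8)
    post = dm.invert(proto.spec, ds.Y, ds.u, prior, settings)
    return proto, ds, prior, post


class TestReducedEvidence:
    def test_unchanged_prior_scores_zero(self, inverted_3node):
        _, _, prior, post = inverted_3node
        mask = np.ones((3, 3), bool)
        assert reduced_evidence(post, prior, prune_edges(prior, mask)) \
            == pytest.approx(0.0, abs=1e-8)

    def test_scorer_agrees_with_generic_route(self, inverted_3node):
        """The fast A-block scorer and the generic projection compute the
        same dF for the same mask."""
        _, _, prior, post = inverted_3node
        mask = np.ones((3, 3), bool)
        mask[0, 1] = mask[2, 0] = False
        generic = reduced_evidence(post, prior, prune_edges(prior, mask))
        scorer = _MaskScorer(post, prior)
        fast, _, _ = scorer.score({(0, 1), (2, 0)})
        assert fast == pytest.approx(generic, abs=1e-6)


class TestSearchReducedModels:
    def test_exhaustive_matches_greedy_on_3_nodes(self, inverted_3node):
        _, _, prior, post = inverted_3node
        greedy = search_reduced_models(post, prior, strategy="greedy")
        exhaustive = search_reduced_models(post, prior,
                                           strategy="exhaustive")
        assert exhaustive.dF >= greedy.dF - 1e-9
        assert abs(exhaustive.dF - greedy.dF) < 1.0
        assert np.all(np.diag(greedy.edge_mask))

    def test_returns_full_model_when_nothing_improves(self, rng):
        """If every edge is strongly supported, the search keeps them."""
        idx = ParameterIndex(2, 1)
        spec = dm.ModelSpec(n_nodes=2, n_inputs=1, driven_nodes=(0,))
        prior = dm.default_priors(spec)
        V, d = np.eye(idx.size), np.diag(prior.Sigma).copy()
        # synthetic posterior: both couplings large and precise
        from dcmodes.inversion import Posterior, prior_support
        Vs, ds_ = prior_support(prior.Sigma)
        mu_b = np.zeros(ds_.size)
        # locate the two off-diagonal A entries within the support basis
        C_b = np.diag(np.full(ds_.size, 1e-4))
        for (i, j) in [(0, 1), (1, 0)]:
            p = idx.a_index(i, j)
            col = np.argmax(np.abs(Vs[p, :]))
            mu_b[col] = 0.6 * np.sign(Vs[p, col])
        post = Posterior(
            mu=prior.eta + Vs @ mu_b, Sigma_post=Vs @ C_b @ Vs.T,
            lam=np.full(2, 4.0), lam_cov=np.zeros(2), F=0.0, accuracy=0.0,
            complexity=0.0, n_effective_params=ds_.size, converged=True,
            n_iterations=1, support_V=Vs, support_d=ds_, mu_beta=mu_b,
            C_beta=C_b, prior_eta=prior.eta)
        res = search_reduced_models(post, prior)
        assert res.anti_edge_count == 0
        assert res.dF == pytest.approx(0.0, abs=1e-6)

    def test_anti_edge_count_consistency(self, inverted_3node):
        _, _, prior, post = inverted_3node
        res = search_reduced_models(post, prior)
        assert res.anti_edge_count \
            == int((~res.edge_mask).sum())

    def test_edge_recovery_on_sparse_truth(self):
        """Known sparse 6-node feedforward coupling at SNR 1: the reduced
        model recovers edges well above chance and retained edges carry
        systematically larger true couplings than pruned ones.

        Directed BOLD data admit near-equivalent path decompositions
        (credit for a chain i->j->k can redistribute onto i->k), so
        individual-edge sensitivity/specificity fluctuates with the noise
        realisation; the assertions aggregate over seeds at the level the
        information in the data supports (see docs/methods.md)."""
        n = 6
        true_edges = {(1, 0): 0.55, (2, 1): 0.50, (3, 2): 0.50,
                      (4, 3): 0.50, (5, 4): 0.55, (3, 0): 0.35,
                      (5, 2): -0.35, (4, 1): -0.30}
        A = np.zeros((n, n))
        np.fill_diagonal(A, -0.5)
        for (i, j), v in true_edges.items():
            A[i, j] = v
        Cmat = np.zeros((n, 1))
        Cmat[0, 0] = 0.25
        cp = dm.CouplingParameters(A=A, C=Cmat)
        null = [(i, j) for i in range(n) for j in range(n)
                if i != j and (i, j) not in true_edges]
        sens, spec_, sep = [], [], []
        for seed in (41, 42, 43):
            proto = SimulationProtocol(n_nodes=n, n_volumes=198,
                                       n_driven=1, seed=seed,
                                       steps_per_tr=8, noise_fwhm_tr=0.0)
            ds = generate_dataset(proto, theta_true=cp, seed=seed)
            prior = dm.default_priors(proto.spec)
            settings = InversionSettings(max_iterations=48,
                                         dt_micro=proto.TR / 8)
            post = dm.invert(proto.spec, ds.Y, ds.u, prior, settings)
            red = search_reduced_models(post, prior)
            kept = red.edge_mask
            tp = sum(kept[i, j] for (i, j) in true_edges)
            tn = sum(not kept[i, j] for (i, j) in null)
            sens.append(tp / len(true_edges))
            spec_.append(tn / len(null))
            kept_mags = [abs(A[i, j]) for i in range(n) for j in range(n)
                         if i != j and kept[i, j]]
            pruned_mags = [abs(A[i, j]) for i in range(n)
                           for j in range(n) if i != j and not kept[i, j]]
            sep.append(np.mean(kept_mags) - np.mean(pruned_mags))
        assert np.mean(sens) >= 0.5
        assert np.mean(spec_) >= 0.65
        assert np.mean(sens) + np.mean(spec_) >= 1.2   # above chance
        assert np.mean(sep) > 0.05   # retained edges are the stronger ones


class TestBayesianParameterAverage:
    def test_single_posterior_unchanged(self, rng):
        mu = rng.standard_normal(3)
        C = np.diag(rng.uniform(0.5, 1.0, 3))
        g = bayesian_parameter_average([(mu, C)])
        np.testing.assert_allclose(g.mu, mu, atol=1e-12)
        np.testing.assert_allclose(g.Sigma, C, atol=1e-12)

    def test_iid_averaging_halves_variance(self):
        mu = np.array([1.5])
        C = np.array([[0.4]])
        g = bayesian_parameter_average([(mu, C), (mu, C)], prior=None,
                                       subtract_redundant_priors=False)
        assert g.mu[0] == pytest.approx(1.5)
        assert g.Sigma[0, 0] == pytest.approx(0.2)

    def test_matches_product_of_gaussians_oracle(self, rng):
        """Two arbitrary 2-D Gaussians: result equals the normalised
        product density computed by brute force."""
        A1 = rng.standard_normal((2, 2))
        A2 = rng.standard_normal((2, 2))
        C1 = A1 @ A1.T + 0.5 * np.eye(2)
        C2 = A2 @ A2.T + 0.5 * np.eye(2)
        mu1, mu2 = rng.standard_normal(2), rng.standard_normal(2)
        g = bayesian_parameter_average([(mu1, C1), (mu2, C2)], prior=None,
                                       subtract_redundant_priors=False)
        P1, P2 = np.linalg.inv(C1), np.linalg.inv(C2)
        C_ref = np.linalg.inv(P1 + P2)
        mu_ref = C_ref @ (P1 @ mu1 + P2 @ mu2)
        np.testing.assert_allclose(g.mu, mu_ref, atol=1e-10)
        np.testing.assert_allclose(g.Sigma, C_ref, atol=1e-10)

    def test_variance_shrinks_like_one_over_k(self):
        mu = np.array([0.7])
        C = np.array([[0.9]])
        for K in (2, 4, 5):
            g = bayesian_parameter_average(
                [(mu, C)] * K, prior=None,
                subtract_redundant_priors=False)
            assert g.Sigma[0, 0] == pytest.approx(0.9 / K)

    def test_prior_counted_once_across_datasets(self):
        """With the shared-prior convention, averaging K copies of the
        prior itself returns the prior (no spurious sharpening)."""
        eta = np.array([0.0, 0.0])
        C0 = np.diag([2.0, 0.5])
        g = bayesian_parameter_average([(eta, C0)] * 3, prior=(eta, C0),
                                       subtract_redundant_priors=True)
        np.testing.assert_allclose(g.Sigma, C0, atol=1e-10)

    def test_mismatched_spaces_rejected(self, inverted_3node, rng):
        _, _, prior, post = inverted_3node
        other = dm.Posterior.from_dict(post.to_dict())
        other.support_V = other.support_V[:, :-1]
        other.support_d = other.support_d[:-1]
        with pytest.raises(ValueError):
            bayesian_parameter_average([post, other])


class TestBuildGraph:
    def _posterior(self, A_mean, a_sd):
        n = A_mean.shape[0]
        idx = ParameterIndex(n, 1)
        mu = np.zeros(idx.size)
        mu[idx.a_slice] = A_mean.ravel(order="F")
        Sigma = np.zeros((idx.size, idx.size))
        np.fill_diagonal(Sigma[idx.a_slice, idx.a_slice],
                         (a_sd ** 2).ravel(order="F"))
        return GroupPosterior(mu=mu, Sigma=Sigma), idx

    def test_zero_mean_edge_has_half_probability(self):
        A = np.diag([-0.5, -0.5])
        g, idx = self._posterior(A, np.full((2, 2), 0.1))
        gs = build_graph(g, idx)
        assert gs.prob[0, 1] == pytest.approx(0.5)
        assert not gs.binary[0, 1]

    def test_gaussian_tail_probability(self):
        A = np.array([[-0.5, 0.4], [0.0, -0.5]])
        sd = np.full((2, 2), 0.1)
        g, idx = self._posterior(A, sd)
        gs = build_graph(g, idx)
        assert gs.prob[0, 1] == pytest.approx(norm.cdf(4.0), abs=1e-12)
        assert gs.binary[0, 1]

    def test_strength_symmetric_zero_diagonal(self, rng):
        A = rng.standard_normal((4, 4))
        g, idx = self._posterior(A, np.full((4, 4), 0.2))
        gs = build_graph(g, idx)
        np.testing.assert_array_equal(gs.strength, gs.strength.T)
        np.testing.assert_array_equal(np.diag(gs.strength), np.zeros(4))
        i, j = 1, 3
        assert gs.strength[i, j] == max(abs(A[i, j]), abs(A[j, i]))

    def test_probabilities_in_unit_interval_and_monotone_threshold(
            self, rng):
        A = rng.standard_normal((4, 4)) * 0.3
        g, idx = self._posterior(A, np.full((4, 4), 0.15))
        low = build_graph(g, idx, prob_threshold=0.8)
        high = build_graph(g, idx, prob_threshold=0.99)
        assert np.all((low.prob >= 0) & (low.prob <= 1))
        assert np.all(high.binary <= low.binary)

    def test_masked_edges_are_zero_weight(self, rng):
        A = rng.standard_normal((3, 3))
        g, idx = self._posterior(A, np.full((3, 3), 0.1))
        mask = np.ones((3, 3), bool)
        mask[0, 2] = False
        gs = build_graph(g, idx, edge_mask=mask)
        assert gs.W[0, 2] == 0.0


class TestSpectralEmbed:
    def test_two_cliques_separate(self):
        S = np.zeros((6, 6))
        for grp in ([0, 1, 2], [3, 4, 5]):
            for i in grp:
                for j in grp:
                    if i != j:
                        S[i, j] = 0.8
        S[2, 3] = S[3, 2] = 0.05
        coords = spectral_embed(S)
        d_within = np.linalg.norm(coords[0] - coords[1])
        d_between = np.linalg.norm(coords[0] - coords[4])
        assert d_within < d_between

    def test_permutation_equivariance(self, rng):
        S = rng.uniform(0, 1, (5, 5))
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, 0.0)
        perm = np.array([3, 1, 4, 0, 2])
        c1 = spectral_embed(S)
        c2 = spectral_embed(S[np.ix_(perm, perm)])
        np.testing.assert_allclose(c2, c1[perm], atol=1e-8)

    def test_zero_matrix_collapses_to_origin(self):
        coords = spectral_embed(np.zeros((4, 4)))
        np.testing.assert_allclose(coords, 0.0, atol=1e-12)

    def test_small_graph_warns_and_reduces(self):
        S = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.warns(UserWarning):
            coords = spectral_embed(S)
        assert coords.shape == (2, 2)
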