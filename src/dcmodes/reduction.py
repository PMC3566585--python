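"""Post-hoc model reduction, parameter averaging and graph construction.

Given one inverted fully-connected model, the evidence for any model whose
prior shrinks selected coupling parameters to (effectively) zero can be
scored analytically from the full model's prior and posterior moments,
without re-inversion.  For Gaussian prior p0 = N(eta0, C0), posterior
q = N(mu, C) and reduced prior pr = N(eta_r, C0r), the change in log
evidence is

    dF = 1/2 [ ln|P| + ln|P0r| - ln|P0| - ln|Pr| ]
       + 1/2 [ b' Pr^-1 b - mu' P mu - eta_r' P0r eta_r + eta0' P0 eta0 ]

with precisions P = C^-1 etc., Pr = P + P0r - P0 and
b = P mu + P0r eta_r - P0 eta0; the reduced posterior is N(Pr^-1 b, Pr^-1).
This is exact for linear-Gaussian models and is the standard proxy score
for searching over the combinatorially many sparsity structures ("absent
edges") of a large coupling matrix.

An absent edge is implemented as prior variance 1e-8 (not exactly zero)
with prior mean 0 on that vec(A) entry, which keeps the covariance algebra
well-posed while matching the pruning semantics.  The search over edge
masks is greedy backward elimination by default, with an exhaustive mode
for small candidate sets.  Group-level summaries use Bayesian parameter
averaging (precision-weighted combination of per-dataset posteriors), and
the resulting coupling matrix is turned into weighted/thresholded
adjacency matrices and a spectral embedding for graph analyses.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import constants as K
from .inversion import Posterior
from .model_core import ParameterIndex
from .priors_modes import ConstrainedPrior, PriorSpec


# ---------------------------------------------------------------------------
# Gaussian model reduction (coordinate-free core)
# ---------------------------------------------------------------------------

def _safe_inv(Cov: np.ndarray, what: str) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a PD matrix, with jitter fallback."""
    Cov = 0.5 * (Cov + Cov.T)
    for jitter in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            scaled = Cov + (jitter * max(np.abs(np.diag(Cov)).max(), 1.0)
                            * np.eye(Cov.shape[0]) if jitter else 0.0)
            L = np.linalg.cholesky(scaled)
            Linv = np.linalg.inv(L)
            if jitter:
                warnings.warn(
                    f"ill-conditioned {what}; regularised with jitter "
                    f"{jitter:g}", stacklevel=3)
            return Linv.T @ Linv, 2.0 * float(np.sum(np.log(np.diag(L))))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(f"{what} is not positive definite")


def gaussian_model_reduction(mu: np.ndarray, C: np.ndarray,
                             eta0: np.ndarray, C0: np.ndarray,
                             eta_r: np.ndarray, C0r: np.ndarray
                             ) -> tuple[float, np.ndarray, np.ndarray]:
    """Change in log evidence when the prior (eta0, C0) becomes (eta_r, C0r).

    All moments must live in the same full-rank coordinate system.
    Returns (dF, reduced posterior mean, reduced posterior covariance).
    """
    P, ld_P = _safe_inv(C, "posterior covariance")
    P0, ld_P0 = _safe_inv(C0, "prior covariance")
    P0r, ld_P0r = _safe_inv(C0r, "reduced prior covariance")
    Pr = P + P0r - P0
    Cr, neg_ld_Pr = _safe_inv(Pr, "reduced posterior precision")
    b = P @ mu + P0r @ eta_r - P0 @ eta0
    mu_r = Cr @ b
    dF = 0.5 * (-ld_P - ld_P0r + ld_P0 - neg_ld_Pr) \
        + 0.5 * (b @ mu_r - mu @ P @ mu - eta_r @ P0r @ eta_r
                 + eta0 @ P0 @ eta0)
    # log-determinants above are of covariances; ln|P| = -ln|C|
    return float(dF), mu_r, Cr


# ---------------------------------------------------------------------------
# Reduced priors over coupling edges
# ---------------------------------------------------------------------------

def prune_edges(prior: PriorSpec | ConstrainedPrior,
                edge_mask: np.ndarray) -> PriorSpec:
    """Reduced prior with absent off-diagonal coupling edges.

    ``edge_mask`` is an (n, n) boolean matrix; False off-diagonal entries
    are pruned: their prior mean is set to 0 and their prior variance to
    1e-8, with all prior covariances to other parameters removed.
    Self-connections are always retained.
    """
    idx = prior.index_map
    n = idx.n_nodes
    edge_mask = np.asarray(edge_mask, bool)
    if edge_mask.shape != (n, n):
        raise ValueError(f"edge mask must be {(n, n)}")
    eta = prior.eta.copy()
    Sigma = prior.Sigma.copy()
    for row, col in zip(*np.nonzero(~edge_mask)):
        if row == col:
            continue
        p = idx.a_index(row, col)
        eta[p] = 0.0
        Sigma[p, :] = 0.0
        Sigma[:, p] = 0.0
        Sigma[p, p] = K.PRUNED_EDGE_PRIOR_VARIANCE
    return PriorSpec(eta=eta, Sigma=Sigma, index_map=idx,
                     hyper_mean=prior.hyper_mean,
                     hyper_variance=prior.hyper_variance)


def _support_moments(posterior: Posterior,
                     prior: PriorSpec | ConstrainedPrior):
    """Posterior/prior moments in the prior-support basis stored on the
    posterior (the optimisation coordinates of the inversion)."""
    V = posterior.support_V
    d = posterior.support_d
    if V is None:
        raise ValueError("posterior carries no support basis")
    return V, d, posterior.mu_beta, posterior.C_beta


def reduced_evidence(posterior: Posterior,
                     prior: PriorSpec | ConstrainedPrior,
                     reduced_prior: PriorSpec | ConstrainedPrior) -> float:
    """Log-evidence change for replacing ``prior`` by ``reduced_prior``.

    Computed analytically from the full model's posterior, in the support
    basis of the full prior; no re-inversion is performed.
    """
    dF, _, _ = _reduced_moments(posterior, prior, reduced_prior)
    return dF


def _reduced_moments(posterior: Posterior, prior, reduced_prior):
    V, d, mu_b, C_b = _support_moments(posterior, prior)
    eta0_b = np.zeros(d.size)
    C0_b = np.diag(d)
    Sr = reduced_prior.Sigma
    C0r_b = V.T @ Sr @ V
    eta_r_b = V.T @ (reduced_prior.eta - prior.eta)
    return gaussian_model_reduction(mu_b, C_b, eta0_b, C0_b, eta_r_b, C0r_b)


# ---------------------------------------------------------------------------
# Search over edge masks
# ---------------------------------------------------------------------------

@dataclass
class ReducedModel:
    """Best-scoring sparsity structure found by post-hoc reduction."""

    edge_mask: np.ndarray              # (n, n) bool, diagonal always True
    dF: float                          # log-evidence gain vs the full model
    mu: np.ndarray                     # reduced posterior mean (full theta)
    Sigma: np.ndarray = field(repr=False)  # reduced posterior covariance
    anti_edge_count: int = 0
    search: str = "greedy"
    history: list = field(default_factory=list, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.edge_mask.shape[0]

    def a_matrix(self, idx: ParameterIndex) -> np.ndarray:
        return self.mu[idx.a_slice].reshape(
            (self.n_nodes, self.n_nodes), order="F")


class _MaskScorer:
    """Fast dF evaluation for edge masks: only the A-block of the reduced
    prior differs from the full prior, so V' Sigma_r V is assembled from a
    cached non-A part plus a masked A-block product."""

    def __init__(self, posterior: Posterior, prior):
        self.idx = prior.index_map
        V, d, mu_b, C_b = _support_moments(posterior, prior)
        self.V = V
        self.d = d
        self.mu_b = mu_b
        self.P, self.ld_C = _safe_inv(C_b, "posterior covariance")
        self.Pmu = self.P @ mu_b
        self.quad_post = float(mu_b @ self.Pmu)
        self.C0_b = np.diag(d)
        self.P0 = np.diag(1.0 / d)
        self.ld_C0 = float(np.sum(np.log(d)))
        self.Va = V[self.idx.a_slice, :]
        self.S_A = np.asarray(prior.Sigma)[self.idx.a_slice,
                                           self.idx.a_slice]
        self.base = V.T @ np.asarray(prior.Sigma) @ V \
            - self.Va.T @ self.S_A @ self.Va
        self.eta = prior.eta
        # prior-mean shift of pruned entries, projected into the basis
        self.eta_a = prior.eta[self.idx.a_slice]

    def flat_indices(self, pruned: set[tuple[int, int]]) -> list[int]:
        return [self.idx.a_index(i, j) - self.idx.a_slice.start
                for (i, j) in pruned]

    def score(self, pruned: set[tuple[int, int]]
              ) -> tuple[float, np.ndarray, np.ndarray]:
        p = self.flat_indices(pruned)
        S_Ar = self.S_A.copy()
        if p:
            S_Ar[p, :] = 0.0
            S_Ar[:, p] = 0.0
            S_Ar[p, p] = K.PRUNED_EDGE_PRIOR_VARIANCE
        C0r = self.base + self.Va.T @ S_Ar @ self.Va
        deta = np.zeros(self.eta_a.size)
        deta[p] = -self.eta_a[p]
        eta_r_b = self.Va.T @ deta
        P0r, ld_C0r = _safe_inv(C0r, "reduced prior covariance")
        Pr = self.P + P0r - self.P0
        Cr, ld_Cr = _safe_inv(Pr, "reduced posterior precision")
        b = self.Pmu + P0r @ eta_r_b
        mu_r = Cr @ b
        dF = 0.5 * (-self.ld_C - ld_C0r + self.ld_C0 - ld_Cr) \
            + 0.5 * (b @ mu_r - self.quad_post - eta_r_b @ P0r @ eta_r_b)
        return float(dF), mu_r, Cr


def _candidate_edges(prior, tol: float = 1e-12) -> list[tuple[int, int]]:
    idx = prior.index_map
    n = idx.n_nodes
    diag = np.diag(np.asarray(prior.Sigma))
    out = []
    for col in range(n):
        for row in range(n):
            if row == col:
                continue
            if diag[idx.a_index(row, col)] > tol:
                out.append((row, col))
    return out


def search_reduced_models(posterior: Posterior,
                          prior: PriorSpec | ConstrainedPrior,
                          strategy: str = "greedy",
                          candidates: list[tuple[int, int]] | None = None,
                          tol: float = 1e-10) -> ReducedModel:
    """Find the sparsity structure (edge mask) with the highest evidence.

    ``strategy`` is "greedy" (backward elimination: repeatedly prune the
    single edge whose removal most increases the reduction score, stopping
    when no pruning improves it) or "exhaustive" (all masks; at most 12
    candidate edges).  Always returns at least the full model.
    """
    idx = prior.index_map
    n = idx.n_nodes
    scorer = _MaskScorer(posterior, prior)
    if candidates is None:
        candidates = _candidate_edges(prior)

    best_set: set[tuple[int, int]] = set()
    best_dF, best_mu, best_C = scorer.score(best_set)
    history = [(0, best_dF)]

    if strategy == "exhaustive":
        if len(candidates) > 12:
            raise ValueError("exhaustive search limited to 12 candidate edges")
        for k in range(1, len(candidates) + 1):
            for combo in itertools.combinations(candidates, k):
                dF, mu_r, Cr = scorer.score(set(combo))
                if dF > best_dF + tol:
                    best_set, best_dF = set(combo), dF
                    best_mu, best_C = mu_r, Cr
        history.append((len(best_set), best_dF))
    elif strategy == "greedy":
        remaining = list(candidates)
        while remaining:
            trial_best = None
            for e in remaining:
                dF, mu_r, Cr = scorer.score(best_set | {e})
                if trial_best is None or dF > trial_best[0]:
                    trial_best = (dF, e, mu_r, Cr)
            if trial_best is None or trial_best[0] <= best_dF + tol:
                break
            best_dF, e, best_mu, best_C = trial_best
            best_set.add(e)
            remaining.remove(e)
            history.append((len(best_set), best_dF))
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    mask = np.ones((n, n), bool)
    for (i, j) in best_set:
        mask[i, j] = False
    V = scorer.V
    mu_full = prior.eta + V @ best_mu
    Sigma_full = V @ best_C @ V.T
    return ReducedModel(edge_mask=mask, dF=best_dF, mu=mu_full,
                        Sigma=Sigma_full, anti_edge_count=len(best_set),
                        search=strategy, history=history)


# ---------------------------------------------------------------------------
# Bayesian parameter averaging
# ---------------------------------------------------------------------------

@dataclass
class GroupPosterior:
    """Precision-weighted combination of per-dataset Gaussian posteriors."""

    mu: np.ndarray
    Sigma: np.ndarray = field(repr=False)
    n_datasets: int = 1


def bayesian_parameter_average(posteriors: list,
                               prior: tuple[np.ndarray, np.ndarray] | None = None,
                               subtract_redundant_priors: bool = True
                               ) -> GroupPosterior:
    """Combine posteriors from several datasets into one group posterior.

    ``posteriors`` is either a list of :class:`Posterior` (sharing one
    parameterisation and prior) or a list of ``(mu, Sigma)`` pairs in a
    common full-rank coordinate system.  Group precision is the sum of
    posterior precisions; under the default convention the shared prior is
    counted once, i.e. K-1 redundant prior precisions are subtracted.  With
    ``prior=None`` (flat-prior convention) precisions are simply summed.
    """
    if not posteriors:
        raise ValueError("need at least one posterior")

    if isinstance(posteriors[0], Posterior):
        ref = posteriors[0]
        for p in posteriors[1:]:
            if (p.support_V.shape != ref.support_V.shape
                    or not np.allclose(p.support_V, ref.support_V)
                    or not np.allclose(p.prior_eta, ref.prior_eta)):
                raise ValueError(
                    "posteriors do not share a common parameterisation")
        pairs = [(p.mu_beta, p.C_beta) for p in posteriors]
        if prior is None and subtract_redundant_priors:
            prior = (np.zeros(ref.support_d.size), np.diag(ref.support_d))
        mu_g, C_g = _bpa_moments(pairs, prior, subtract_redundant_priors)
        V = ref.support_V
        return GroupPosterior(mu=ref.prior_eta + V @ mu_g,
                              Sigma=V @ C_g @ V.T,
                              n_datasets=len(posteriors))

    mu_g, C_g = _bpa_moments(posteriors, prior, subtract_redundant_priors)
    return GroupPosterior(mu=mu_g, Sigma=C_g, n_datasets=len(posteriors))


def _bpa_moments(pairs, prior, subtract_redundant_priors):
    Ks = len(pairs)
    precisions = []
    weighted = []
    for mu_i, C_i in pairs:
        Pi, _ = _safe_inv(np.asarray(C_i, float), "posterior covariance")
        precisions.append(Pi)
        weighted.append(Pi @ np.asarray(mu_i, float))
    P_g = sum(precisions)
    b_g = sum(weighted)
    if prior is not None and subtract_redundant_priors and Ks > 1:
        eta0, C0 = prior
        P0, _ = _safe_inv(np.asarray(C0, float), "prior covariance")
        P_g = P_g - (Ks - 1) * P0
        b_g = b_g - (Ks - 1) * (P0 @ np.asarray(eta0, float))
    P_g = 0.5 * (P_g + P_g.T)
    if np.linalg.eigvalsh(P_g).min() <= 0:
        raise ValueError(
            "group precision not positive definite; check the prior "
            "convention or use subtract_redundant_priors=False")
    C_g = np.linalg.inv(P_g)
    C_g = 0.5 * (C_g + C_g.T)
    return C_g @ b_g, C_g


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

@dataclass
class GraphSummary:
    """Adjacency representations of the (reduced) coupling matrix."""

    W: np.ndarray                  # weighted adjacency, Hz
    prob: np.ndarray               # per-edge posterior probability
    binary: np.ndarray             # unweighted adjacency at the threshold
    strength: np.ndarray           # symmetrised max |coupling|, zero diagonal
    embedding: np.ndarray          # nodes x 3 spectral coordinates
    prob_threshold: float = 0.95
    node_labels: tuple[str, ...] | None = None

    def edge_list(self) -> pd.DataFrame:
        n = self.W.shape[0]
        rows = []
        labels = self.node_labels or [f"node{i + 1}" for i in range(n)]
        for i in range(n):
            for j in range(n):
                if i == j or self.W[i, j] == 0:
                    continue
                rows.append({"source": labels[j], "target": labels[i],
                             "weight": self.W[i, j],
                             "probability": self.prob[i, j]})
        return pd.DataFrame(rows)

    def export(self, directory) -> None:
        import pathlib
        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        labels = list(self.node_labels or
                      [f"node{i + 1}" for i in range(self.W.shape[0])])
        for name, M in (("adjacency_weighted", self.W),
                        ("adjacency_probability", self.prob),
                        ("adjacency_binary", self.binary.astype(int)),
                        ("strength", self.strength)):
            pd.DataFrame(M, index=labels, columns=labels).to_csv(
                d / f"{name}.tsv", sep="\t")
        self.edge_list().to_csv(d / "edges.tsv", sep="\t", index=False)
        pd.DataFrame(self.embedding, index=labels,
                     columns=[f"dim{i + 1}" for i in
                              range(self.embedding.shape[1])]).to_csv(
            d / "embedding.tsv", sep="\t")


def build_graph(posterior: Posterior | GroupPosterior | ReducedModel,
                idx: ParameterIndex,
                edge_mask: np.ndarray | None = None,
                prob_threshold: float = 0.95,
                node_labels: tuple[str, ...] | None = None) -> GraphSummary:
    """Adjacency matrices and embedding from a posterior over coupling.

    The per-edge posterior probability is the probability that the coupling
    differs from zero in the direction of its posterior mean (Gaussian tail
    from the marginal posterior); a zero mean gives probability 0.5.
    """
    if isinstance(posterior, ReducedModel):
        mu, Sigma = posterior.mu, posterior.Sigma
        if edge_mask is None:
            edge_mask = posterior.edge_mask
    elif isinstance(posterior, Posterior):
        mu, Sigma = posterior.mu, posterior.Sigma_post
    else:
        mu, Sigma = posterior.mu, posterior.Sigma
    n = idx.n_nodes
    A_mean = mu[idx.a_slice].reshape(n, n, order="F")
    a_var = np.clip(np.diag(Sigma)[idx.a_slice], 0.0, None).reshape(
        n, n, order="F")
    if edge_mask is None:
        edge_mask = np.ones((n, n), bool)

    sd = np.sqrt(a_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        zscore = np.where(sd > 0, np.abs(A_mean) / np.where(sd > 0, sd, 1.0),
                          np.inf)
    prob = np.where(np.abs(A_mean) > 0, norm.cdf(zscore), 0.5)
    prob = np.where((sd == 0) & (np.abs(A_mean) == 0), 0.5, prob)

    W = np.where(edge_mask, A_mean, 0.0)
    binary = (prob > prob_threshold) & edge_mask
    absW = np.abs(W)
    strength = np.maximum(absW, absW.T)
    np.fill_diagonal(strength, 0.0)
    embedding = spectral_embed(strength)
    return GraphSummary(W=W, prob=prob, binary=binary, strength=strength,
                        embedding=embedding, prob_threshold=prob_threshold,
                        node_labels=node_labels)


def spectral_embed(strength: np.ndarray, ndim: int = 3) -> np.ndarray:
    """Place nodes in a low-dimensional space via principal components.

    Coordinates are the first ``ndim`` principal components of the
    column-centred symmetrised strength matrix (scores scaled by singular
    values), with a deterministic sign convention.  Fewer than ``ndim``
    nodes yields a reduced dimensionality with a warning.
    """
    S = np.asarray(strength, float)
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("strength matrix must be symmetric")
    n = S.shape[0]
    if n < ndim:
        warnings.warn(f"only {n} nodes; embedding in {n} dimensions",
                      stacklevel=2)
        ndim = n
    Xc = S - S.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    coords = U[:, :ndim] * s[:ndim]
    for j in range(coords.shape[1]):
        if s[j] > 0:
            i = np.argmax(np.abs(coords[:, j]))
            if coords[i, j] < 0:
                coords[:, j] = -coords[:, j]
    return coords
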