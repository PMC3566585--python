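"""Variational-Laplace inversion of a deterministic generative model.

The observation model is y = g(theta) + e with independent Gaussian noise
per node, precision exp(lambda_i) per node i (iid over volumes), a Gaussian
prior over the flat parameter vector (possibly rank-deficient, as produced
by the mode-constrained priors) and a Gaussian hyperprior over each
log precision (mean 4 by default).

The posterior is approximated as Gaussian (Laplace assumption).  The scheme
alternates Gauss-Newton updates of the parameter mode with Newton updates
of the per-node log precisions, maximising the variational free energy

    F = accuracy - complexity
    accuracy   = E_q[ log p(y | theta, lambda) ]
    complexity = KL(q(theta) || p(theta)) + KL(q(lambda) || p(lambda))

Because the mode-constrained prior covariance is singular by construction,
the optimisation runs in an orthonormal basis of the prior support
(eigenvectors of Sigma with eigenvalue above a relative tolerance); fixed
directions are never moved, so parameters with zero prior variance keep
their prior mean exactly.  Jacobians of the integrator are obtained by
central finite differences over a batch of perturbed parameter vectors.
A Levenberg-Marquardt step-size policy accepts only steps that increase F,
so F is non-decreasing over accepted Gauss-Newton steps.

On linear-Gaussian problems with fixed noise precision this free energy is
exact: it equals the log evidence of the equivalent Bayesian linear
regression, which is used as an oracle in the test-suite.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import constants as K
from .model_core import (InputFunctions, IntegrationError, ModelSpec,
                         TimeSeries, bold_predictions)
from .priors_modes import ConstrainedPrior, PriorSpec

LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class InversionSettings:
    """Numerical controls for the variational scheme."""

    max_iterations: int = K.MAX_ITERATIONS
    tol_df: float = K.CONVERGENCE_DF          # nats
    convergence_streak: int = K.CONVERGENCE_STREAK
    fd_step: float = K.FD_RELATIVE_STEP       # in prior-sd units
    rank_tol: float = K.PRIOR_RANK_TOL
    lm_init: float = 0.25                     # initial LM regularisation
    max_step_retries: int = 8
    dt_micro: float | None = None             # override input microtime step
    n_starts: int = 1                         # restarts of the GN scheme
    start_jitter: float = 0.5                 # restart spread, prior-sd units
    seed: int | None = None                   # seeds the restart draws only

    def __post_init__(self):
        if self.tol_df <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Posterior:
    """Laplace posterior with free-energy bookkeeping.

    ``mu``/``Sigma_post`` are in the original parameter coordinates; the
    posterior is supported on the prior's support subspace, described by the
    orthonormal columns of ``support_V`` with prior variances ``support_d``.
    """

    mu: np.ndarray
    Sigma_post: np.ndarray = field(repr=False)
    lam: np.ndarray
    lam_cov: np.ndarray
    F: float
    accuracy: float
    complexity: float
    n_effective_params: int
    converged: bool
    n_iterations: int
    f_history: list = field(default_factory=list, repr=False)
    support_V: np.ndarray = field(default=None, repr=False)
    support_d: np.ndarray = field(default=None, repr=False)
    mu_beta: np.ndarray = field(default=None, repr=False)
    C_beta: np.ndarray = field(default=None, repr=False)
    prior_eta: np.ndarray = field(default=None, repr=False)
    settings_hash: str = ""
    prior_hash: str = ""

    def to_dict(self) -> dict:
        return {
            "mu": self.mu.tolist(),
            "Sigma_post": self.Sigma_post.tolist(),
            "lam": self.lam.tolist(),
            "lam_cov": self.lam_cov.tolist(),
            "F": self.F,
            "accuracy": self.accuracy,
            "complexity": self.complexity,
            "n_effective_params": self.n_effective_params,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "support_V": self.support_V.tolist(),
            "support_d": self.support_d.tolist(),
            "mu_beta": self.mu_beta.tolist(),
            "C_beta": self.C_beta.tolist(),
            "prior_eta": self.prior_eta.tolist(),
            "settings_hash": self.settings_hash,
            "prior_hash": self.prior_hash,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "Posterior":
        arrays = {k: np.array(d[k]) for k in
                  ("mu", "Sigma_post", "lam", "lam_cov", "support_V",
                   "support_d", "mu_beta", "C_beta", "prior_eta")}
        return cls(F=d["F"], accuracy=d["accuracy"],
                   complexity=d["complexity"],
                   n_effective_params=d["n_effective_params"],
                   converged=d["converged"], n_iterations=d["n_iterations"],
                   settings_hash=d.get("settings_hash", ""),
                   prior_hash=d.get("prior_hash", ""), **arrays)

    @classmethod
    def from_json(cls, path) -> "Posterior":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def prior_support(Sigma: np.ndarray, rank_tol: float = K.PRIOR_RANK_TOL
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis V and variances d of the prior support subspace."""
    Sigma = 0.5 * (Sigma + Sigma.T)
    w, V = np.linalg.eigh(Sigma)
    keep = w > rank_tol * max(w.max(), np.finfo(float).tiny)
    return V[:, keep][:, ::-1], w[keep][::-1]


def _prior_hash(eta: np.ndarray, Sigma: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(eta).tobytes())
    h.update(np.ascontiguousarray(Sigma).tobytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Core scheme (model-agnostic)
# ---------------------------------------------------------------------------

def variational_laplace(forward, y: np.ndarray, eta: np.ndarray,
                        Sigma: np.ndarray, hyper_mean: float,
                        hyper_variance: float,
                        settings: InversionSettings | None = None) -> Posterior:
    """Invert ``y = forward(theta) + noise`` under a Gaussian prior.

    ``forward`` maps a (batch, P) array of parameter vectors to a
    (batch, T, n) array of predictions and must be deterministic.

    With ``settings.n_starts > 1`` the Gauss-Newton scheme is restarted
    from modes jittered within the prior (draws seeded by
    ``settings.seed``) and the run with the highest free energy is kept —
    a standard guard against local optima of the nonconvex landscape.
    The default (one start from the prior mean) is fully deterministic.
    """
    settings = settings or InversionSettings()
    eta = np.asarray(eta, float)
    V, d = prior_support(np.asarray(Sigma, float), settings.rank_tol)
    prior_hash = _prior_hash(eta, np.asarray(Sigma, float))

    best = None
    rng = np.random.default_rng(0 if settings.seed is None else settings.seed)
    for start in range(max(1, settings.n_starts)):
        beta0 = np.zeros(d.size) if start == 0 else \
            settings.start_jitter * np.sqrt(d) * rng.standard_normal(d.size)
        try:
            post = _vl_single(forward, y, eta, V, d, hyper_mean,
                              hyper_variance, settings, beta0, prior_hash)
        except IntegrationError:
            if start == 0:
                raise
            continue
        if best is None or post.F > best.F:
            best = post
    return best


def _vl_single(forward, y, eta, V, d, hyper_mean, hyper_variance,
               settings, beta0, prior_hash) -> Posterior:
    y = np.atleast_2d(np.asarray(y, float))
    T, n = y.shape
    r = d.size
    inv_d = 1.0 / d if r else np.empty(0)
    logdet_prior = float(np.sum(np.log(d))) if r else 0.0

    update_hyper = hyper_variance > 1e-12
    lam = np.full(n, float(hyper_mean))
    beta = np.asarray(beta0, float).copy()
    h_steps = settings.fd_step * np.sqrt(d)

    def predict_one(b):
        return forward((eta + V @ b)[None, :])[0]

    def jacobian(b):
        """Central-difference Jacobian; returns (g0, J) with J (T, n, r)."""
        thetas = np.empty((2 * r + 1, eta.size))
        base = eta + V @ b
        thetas[0] = base
        for j in range(r):
            thetas[1 + j] = base + h_steps[j] * V[:, j]
            thetas[1 + r + j] = base - h_steps[j] * V[:, j]
        G = forward(thetas)
        g0 = G[0]
        J = np.empty((T, n, r))
        for j in range(r):
            J[:, :, j] = (G[1 + j] - G[1 + r + j]) / (2.0 * h_steps[j])
        return g0, J

    def free_energy(e, beta_, lam_, Cb, logdet_Cb, Gi):
        w = np.exp(lam_)
        resid = np.einsum("tn,tn->n", e, e)
        tr = np.array([np.sum(Gi[i] * Cb) for i in range(n)]) if r else np.zeros(n)
        r_i = resid + tr
        acc = float(np.sum(-0.5 * w * r_i + 0.5 * T * lam_) - 0.5 * T * n * LOG2PI)
        if r:
            comp_t = 0.5 * (np.sum(np.diag(Cb) * inv_d)
                            + np.sum(beta_ ** 2 * inv_d)
                            - r + logdet_prior - logdet_Cb)
        else:
            comp_t = 0.0
        comp_h = 0.0
        lam_var = np.zeros(n)
        if update_hyper:
            lam_var = 1.0 / (0.5 * w * r_i + 1.0 / hyper_variance)
            comp_h = float(0.5 * np.sum(
                lam_var / hyper_variance
                + (lam_ - hyper_mean) ** 2 / hyper_variance
                - 1.0 + np.log(hyper_variance) - np.log(lam_var)))
        F = acc - comp_t - comp_h
        return F, acc, comp_t + comp_h, r_i, lam_var

    lm = settings.lm_init
    F_prev = -np.inf
    f_history: list[float] = []
    streak = 0
    converged = False
    g0, J = jacobian(beta)
    e = y - g0
    it = 0

    Cb = np.zeros((0, 0))
    logdet_Cb = 0.0
    Gi = [np.zeros((r, r)) for _ in range(n)]
    lam_var = np.zeros(n)

    for it in range(1, settings.max_iterations + 1):
        # per-node Gauss-Newton curvature blocks
        Gi = [J[:, i, :].T @ J[:, i, :] for i in range(n)] if r \
            else [np.zeros((0, 0))] * n
        resid = np.einsum("tn,tn->n", e, e)

        # coupled hyperparameter / posterior-covariance updates
        for _ in range(8 if update_hyper else 1):
            w = np.exp(lam)
            if r:
                Pb = sum(w[i] * Gi[i] for i in range(n)) + np.diag(inv_d)
                Pb = 0.5 * (Pb + Pb.T)
                L = np.linalg.cholesky(Pb)
                Linv = np.linalg.inv(L)
                Cb = Linv.T @ Linv
                logdet_Cb = -2.0 * float(np.sum(np.log(np.diag(L))))
            if not update_hyper:
                break
            moved = 0.0
            for i in range(n):
                tr_i = float(np.sum(Gi[i] * Cb)) if r else 0.0
                r_i = resid[i] + tr_i
                grad = 0.5 * T - 0.5 * np.exp(lam[i]) * r_i \
                    - (lam[i] - hyper_mean) / hyper_variance
                hess = -0.5 * np.exp(lam[i]) * r_i - 1.0 / hyper_variance
                step = np.clip(-grad / hess, -2.0, 2.0)
                lam[i] += step
                moved = max(moved, abs(step))
            if moved < 1e-6:
                w = np.exp(lam)
                if r:
                    Pb = sum(w[i] * Gi[i] for i in range(n)) + np.diag(inv_d)
                    Pb = 0.5 * (Pb + Pb.T)
                    L = np.linalg.cholesky(Pb)
                    Linv = np.linalg.inv(L)
                    Cb = Linv.T @ Linv
                    logdet_Cb = -2.0 * float(np.sum(np.log(np.diag(L))))
                break

        F_cur, acc, comp, r_i, lam_var = free_energy(
            e, beta, lam, Cb, logdet_Cb, Gi)
        f_history.append(F_cur)

        dF = F_cur - F_prev
        F_prev = F_cur
        if abs(dF) < settings.tol_df:
            streak += 1
            if streak >= settings.convergence_streak:
                converged = True
                break
        else:
            streak = 0

        if r == 0:
            converged = True
            break

        # Gauss-Newton step with Levenberg-Marquardt regularisation; a few
        # candidate regularisations are evaluated in one batched forward
        # call and the best F-improving one is kept
        w = np.exp(lam)
        grad = sum(w[i] * (J[:, i, :].T @ e[:, i]) for i in range(n)) \
            - beta * inv_d
        H = sum(w[i] * Gi[i] for i in range(n)) + np.diag(inv_d)
        diagH = np.diag(np.diag(H))
        beta_prev, e_prev = beta.copy(), e
        accepted = False
        for _round in range(settings.max_step_retries):
            factors = [lm / 8.0, lm, lm * 8.0] if _round == 0 \
                else [lm, lm * 8.0, lm * 64.0]
            trials, used = [], []
            for fac in factors:
                try:
                    db = np.linalg.solve(H + fac * diagH, grad)
                except np.linalg.LinAlgError:
                    continue
                trials.append(beta + db)
                used.append(fac)
            if not trials:
                lm *= 64.0
                continue
            thetas = eta[None, :] + np.asarray(trials) @ V.T
            try:
                G_tr = forward(thetas)
            except (IntegrationError, FloatingPointError):
                # fall back to one-at-a-time so a single divergent
                # candidate does not mask the others
                G_tr = []
                for t_ in thetas:
                    try:
                        G_tr.append(forward(t_[None, :])[0])
                    except (IntegrationError, FloatingPointError):
                        G_tr.append(np.full((T, n), np.nan))
                G_tr = np.asarray(G_tr)
            best = None
            for t_idx, trial in enumerate(trials):
                g_trial = G_tr[t_idx]
                if not np.all(np.isfinite(g_trial)):
                    continue
                e_trial = y - g_trial
                F_trial, *_ = free_energy(e_trial, trial, lam, Cb,
                                          logdet_Cb, Gi)
                if F_trial > F_cur and (best is None or F_trial > best[0]):
                    best = (F_trial, trial, e_trial, used[t_idx])
            if best is not None:
                _, beta, e_new, lm_used = best
                lm = max(lm_used / 2.0, 1e-6)
                accepted = True
                break
            lm *= 64.0
        if not accepted:
            # stationary within the step policy: no step improves F
            converged = True
            break
        try:
            g0, J = jacobian(beta)
        except (IntegrationError, FloatingPointError):
            # the accepted mode integrates but a finite-difference
            # perturbation crosses the stability boundary: retreat to the
            # previous mode and regularise harder
            beta, e = beta_prev, e_prev
            lm = min(lm * 64.0, 1e8)
            continue
        e = y - g0

    mu = eta + (V @ beta if r else 0.0)
    Sigma_post = V @ Cb @ V.T if r else np.zeros((eta.size, eta.size))
    F_cur, acc, comp, _, lam_var = free_energy(
        e, beta, lam, Cb, logdet_Cb, Gi)
    return Posterior(
        mu=mu, Sigma_post=Sigma_post, lam=lam.copy(), lam_cov=lam_var,
        F=float(F_cur), accuracy=float(acc), complexity=float(comp),
        n_effective_params=r, converged=converged, n_iterations=it,
        f_history=f_history, support_V=V, support_d=d, mu_beta=beta,
        C_beta=Cb if r else np.zeros((0, 0)), prior_eta=eta.copy(),
        settings_hash=settings.hash(), prior_hash=prior_hash)


# ---------------------------------------------------------------------------
# DCM-facing wrappers
# ---------------------------------------------------------------------------

def _resample_inputs(u: InputFunctions, dt_micro: float) -> InputFunctions:
    """Rebuild inputs on a coarser/finer microtime grid (nearest sample)."""
    if abs(dt_micro - u.dt_micro) < 1e-12:
        return u
    spv = u.TR / dt_micro
    if abs(spv - round(spv)) > 1e-9:
        raise ValueError("TR must be an integer multiple of dt_micro")
    n_steps = int(round(u.n_volumes * u.TR / dt_micro))
    t = (np.arange(n_steps) + 0.5) * dt_micro
    src = np.clip((t / u.dt_micro).astype(int), 0, u.u.shape[0] - 1)
    return InputFunctions(u=u.u[src], dt_micro=dt_micro, TR=u.TR,
                          n_volumes=u.n_volumes)


def invert(spec: ModelSpec, Y: TimeSeries, u: InputFunctions,
           prior: PriorSpec | ConstrainedPrior,
           settings: InversionSettings | None = None,
           TE: float = K.DEFAULT_TE) -> Posterior:
    """Variational-Laplace inversion of the full generative model."""
    settings = settings or InversionSettings()
    if Y.n_nodes != spec.n_nodes:
        raise ValueError("data and model disagree on the number of nodes")
    if Y.n_volumes != u.n_volumes:
        raise ValueError("data and inputs disagree on the number of volumes")
    if abs(Y.TR - u.TR) > 1e-9:
        raise ValueError("data and inputs disagree on TR")
    if settings.dt_micro is not None:
        u = _resample_inputs(u, settings.dt_micro)

    def forward(thetas):
        return bold_predictions(thetas, spec, u, TE=TE)

    return variational_laplace(forward, Y.Y, prior.eta, prior.Sigma,
                               prior.hyper_mean, prior.hyper_variance,
                               settings)


def free_energy_components(posterior: Posterior) -> tuple[float, float]:
    """(accuracy, complexity); F = accuracy - complexity."""
    return posterior.accuracy, posterior.complexity


def predict_from_posterior(posterior: Posterior, spec: ModelSpec,
                           u: InputFunctions, Y: TimeSeries | None = None,
                           TE: float = K.DEFAULT_TE
                           ) -> tuple[TimeSeries, dict]:
    """Prediction at the posterior mean plus variance-explained summary."""
    g = bold_predictions(posterior.mu, spec, u, TE=TE)
    pred = TimeSeries(Y=g, TR=u.TR, node_labels=spec.labels)
    summary: dict = {}
    if Y is not None:
        resid = Y.Y - g
        ss_res = np.sum(resid ** 2, axis=0)
        ss_tot = np.sum((Y.Y - Y.Y.mean(axis=0)) ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, np.nan)
        summary["r2_per_node"] = r2
        summary["r2_total"] = float(1.0 - ss_res.sum() / ss_tot.sum())
    return pred, summary
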