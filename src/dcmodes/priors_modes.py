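"""Shrinkage priors and functional-connectivity mode constraints.

The default prior over the endogenous coupling matrix A is a diagonal
Gaussian whose precision grows with the number of nodes (self-connections
N(-1/2, 1/(8n)); between-node connections N(1/(64n), 8/n)), which prevents
runaway excitation in densely connected models.

For large models the rank of the A-block prior covariance can be reduced by
projecting onto the leading eigenvectors ("modes") of the functional
connectivity matrix — the sample correlation matrix of the node
timeseries.  With orthonormal modes U_m and P = U_m U_m', the projector

    K_m = P (x) P          (column-stacking convention)

acts on vec(A) as A -> P A P, and the constrained covariance is
Sigma_m = K_m Sigma_A K_m'.  This induces prior correlations among coupling
parameters and leaves only m^2 effective degrees of freedom in A; priors on
C, B, hemodynamic parameters and noise precisions are untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import constants as K
from .model_core import ModelSpec, ParameterIndex, TimeSeries


class DegenerateNodeError(ValueError):
    """A node timeseries has zero variance and cannot be standardised."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class PriorSpec:
    """Gaussian prior over the full flat parameter vector.

    ``eta``/``Sigma`` are the prior mean and covariance in the
    ``ParameterIndex`` layout; parameters with zero prior variance are fixed.
    ``hyper_mean``/``hyper_variance`` are the Gaussian hyperprior moments of
    each node's log noise precision.
    """

    eta: np.ndarray
    Sigma: np.ndarray
    index_map: ParameterIndex
    hyper_mean: float = K.LOG_PRECISION_PRIOR_MEAN
    hyper_variance: float = K.LOG_PRECISION_PRIOR_VARIANCE

    def __post_init__(self):
        self.eta = np.asarray(self.eta, float)
        self.Sigma = np.asarray(self.Sigma, float)
        P = self.index_map.size
        if self.eta.shape != (P,) or self.Sigma.shape != (P, P):
            raise ValueError("prior moments inconsistent with index map")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-12):
            raise ValueError("prior covariance must be symmetric")

    @property
    def a_block(self) -> np.ndarray:
        s = self.index_map.a_slice
        return self.Sigma[s, s]

    def copy(self) -> "PriorSpec":
        return PriorSpec(self.eta.copy(), self.Sigma.copy(), self.index_map,
                         self.hyper_mean, self.hyper_variance)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_nodes": self.index_map.n_nodes,
            "n_inputs": self.index_map.n_inputs,
            "eta": self.eta.tolist(),
            "Sigma": self.Sigma.tolist(),
            "hyper_mean": self.hyper_mean,
            "hyper_variance": self.hyper_variance,
            "vectorisation": "column-stacking",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        idx = ParameterIndex(d["n_nodes"], d["n_inputs"])
        return cls(np.array(d["eta"]), np.array(d["Sigma"]), idx,
                   d["hyper_mean"], d["hyper_variance"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "PriorSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ModeBasis:
    """Leading functional-connectivity modes.

    Columns of ``U_m`` are orthonormal eigenvectors of the node-by-node
    correlation matrix, ordered by decreasing singular value.
    """

    U_m: np.ndarray            # (n, m)
    singular_values: np.ndarray
    m: int = 0

    def __post_init__(self):
        self.U_m = np.asarray(self.U_m, float)
        self.singular_values = np.asarray(self.singular_values, float)
        if self.m == 0:
            self.m = self.U_m.shape[1]
        n, m = self.U_m.shape
        if not 1 <= m <= n:
            raise ValueError("need 1 <= m <= n modes")
        if self.singular_values.shape != (m,):
            raise ValueError("one singular value per mode required")
        if np.any(np.diff(self.singular_values) > 1e-9):
            raise ValueError("singular values must be non-increasing")
        G = self.U_m.T @ self.U_m
        if not np.allclose(G, np.eye(m), atol=1e-8):
            raise ValueError("mode matrix must have orthonormal columns")

    @property
    def n_nodes(self) -> int:
        return self.U_m.shape[0]

    def to_dict(self) -> dict:
        return {"U_m": self.U_m.tolist(),
                "singular_values": self.singular_values.tolist(),
                "m": self.m}

    @classmethod
    def from_dict(cls, d: dict) -> "ModeBasis":
        return cls(np.array(d["U_m"]), np.array(d["singular_values"]), d["m"])


@dataclass
class ConstrainedPrior:
    """Prior with the A-block covariance projected onto m modes.

    Exposes ``eta``/``Sigma``/``index_map`` like :class:`PriorSpec`, so it
    can be passed anywhere a prior is expected.  ``K_m`` is the n^2 x n^2
    Kronecker projector; only the vec(A) block differs from ``base``.
    """

    base: PriorSpec
    basis: ModeBasis
    K_m: np.ndarray = field(repr=False, default=None)
    Sigma_m: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        full = self.basis.m == self.basis.n_nodes
        if self.K_m is None:
            # with the full basis the projector is the identity analytically;
            # use it exactly so m = n recovers the unconstrained prior
            self.K_m = np.eye(self.base.index_map.n_a) if full \
                else mode_projector(self.basis)
        a = self.base.a_block
        if self.Sigma_m is None:
            if full:
                self.Sigma_m = a.copy()
            else:
                self.Sigma_m = self.K_m @ a @ self.K_m.T
                self.Sigma_m = 0.5 * (self.Sigma_m + self.Sigma_m.T)

    @property
    def index_map(self) -> ParameterIndex:
        return self.base.index_map

    @property
    def eta(self) -> np.ndarray:
        return self.base.eta

    @property
    def hyper_mean(self) -> float:
        return self.base.hyper_mean

    @property
    def hyper_variance(self) -> float:
        return self.base.hyper_variance

    @property
    def Sigma(self) -> np.ndarray:
        S = self.base.Sigma.copy()
        s = self.index_map.a_slice
        S[s, s] = self.Sigma_m
        return S

    @property
    def m(self) -> int:
        return self.basis.m


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def default_priors(spec: ModelSpec) -> PriorSpec:
    """Default shrinkage priors for a model with n nodes and k inputs."""
    n, k = spec.n_nodes, spec.n_inputs
    idx = ParameterIndex(n, k)
    eta = np.zeros(idx.size)
    var = np.zeros(idx.size)

    a_mean = np.full((n, n), K.a_between_prior_mean(n))
    np.fill_diagonal(a_mean, K.A_SELF_PRIOR_MEAN)
    a_var = np.full((n, n), K.a_between_prior_variance(n))
    np.fill_diagonal(a_var, K.a_self_prior_variance(n))
    eta[idx.a_slice] = a_mean.ravel(order="F")
    var[idx.a_slice] = a_var.ravel(order="F")

    # B fixed at zero by default (no modulatory effects a priori).
    eta[idx.b_all_slice] = K.B_PRIOR_MEAN
    var[idx.b_all_slice] = K.B_PRIOR_VARIANCE

    c_var = np.zeros((n, k))
    if k:
        c_var[list(spec.driven_nodes), :] = K.C_PRIOR_VARIANCE
    eta[idx.c_slice] = K.C_PRIOR_MEAN
    var[idx.c_slice] = c_var.ravel(order="F")

    eta[idx.decay_slice] = K.HEMO_SCALE_PRIOR_MEAN
    var[idx.decay_slice] = K.HEMO_DECAY_SCALE_PRIOR_VARIANCE
    eta[idx.transit_slice] = K.HEMO_SCALE_PRIOR_MEAN
    var[idx.transit_slice] = K.HEMO_TRANSIT_SCALE_PRIOR_VARIANCE
    eta[idx.epsilon_index] = K.HEMO_SCALE_PRIOR_MEAN
    var[idx.epsilon_index] = K.HEMO_EPSILON_SCALE_PRIOR_VARIANCE

    return PriorSpec(eta=eta, Sigma=np.diag(var), index_map=idx)


def _orient_modes(U: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-magnitude element positive."""
    U = U.copy()
    for j in range(U.shape[1]):
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    return U


def compute_modes(Y: TimeSeries | np.ndarray, m: int) -> ModeBasis:
    """Leading eigenvectors of the functional connectivity matrix.

    Each node timeseries is z-scored, so the modes are exactly the
    eigenvectors of the sample correlation matrix (equivalently, left
    singular vectors of the standardised node x time data matrix).
    """
    data = Y.Y if isinstance(Y, TimeSeries) else np.asarray(Y, float)
    T, n = data.shape
    if not 1 <= m <= n:
        raise ValueError(f"need 1 <= m <= {n}, got m={m}")
    sd = data.std(axis=0, ddof=0)
    dead = np.flatnonzero(sd <= 0)
    if dead.size:
        raise DegenerateNodeError(
            f"node(s) {dead.tolist()} have zero variance")
    Z = (data - data.mean(axis=0)) / sd
    U, s, _ = np.linalg.svd(Z.T, full_matrices=False)
    U = _orient_modes(U[:, :m])
    return ModeBasis(U_m=U, singular_values=s[:m], m=m)


def mode_projector(basis: ModeBasis) -> np.ndarray:
    """K_m = (U_m U_m') (x) (U_m U_m'), acting on column-stacked vec(A)."""
    U = basis.U_m
    G = U.T @ U
    if not np.allclose(G, np.eye(basis.m), atol=1e-8):
        raise ValueError("mode basis is not orthonormal")
    P = U @ U.T
    return np.kron(P, P)


def constrain_prior(prior: PriorSpec, basis: ModeBasis) -> ConstrainedPrior:
    """Replace the A-block covariance with K_m Sigma_A K_m'."""
    n = prior.index_map.n_nodes
    if basis.n_nodes != n:
        raise ValueError("mode basis and prior have different node counts")
    return ConstrainedPrior(base=prior, basis=basis)


def prior_correlation_summary(cp: ConstrainedPrior,
                              tol: float = 1e-12) -> dict:
    """Mean and spread of off-diagonal prior correlations among A parameters.

    Correlations are computed over the subspace of coupling parameters that
    retain nonzero prior variance; as the number of modes shrinks, the
    projector mixes parameters and correlation magnitudes grow.
    """
    S = cp.Sigma_m
    d = np.diag(S)
    free = d > tol * max(d.max(), 1.0)
    Sf = S[np.ix_(free, free)]
    sd = np.sqrt(np.diag(Sf))
    R = Sf / np.outer(sd, sd)
    off = R[~np.eye(R.shape[0], dtype=bool)]
    return {
        "m": cp.m,
        "n_free": int(free.sum()),
        "mean_abs_correlation": float(np.mean(np.abs(off))) if off.size else 0.0,
        "sd_correlation": float(np.std(off)) if off.size else 0.0,
    }
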