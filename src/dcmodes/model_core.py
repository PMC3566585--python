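"""Deterministic generative model for fMRI effective connectivity.

Two coupled components:

* a bilinear neuronal state equation
      dz/dt = (A + sum_i u_i B_i) z + C u
  where ``z`` is one lumped activity variable per node, ``A`` (Hz) is the
  endogenous coupling, ``B_i`` (Hz) bilinear input modulation and ``C`` (Hz)
  the driving efficacy of exogenous inputs ``u(t)``;

* a per-node balloon-Windkessel hemodynamic model (vasodilatory signal,
  blood inflow, venous volume, deoxyhemoglobin content) with the standard
  nonlinear BOLD observation equation.

Flow, volume and dHb are integrated in log space to enforce positivity.
Integration is fixed-step classical RK4 on a microtime grid (default
TR/16), with inputs held piecewise constant over each micro step; BOLD is
sampled at volume-acquisition times.  All predictions are deterministic.

The module also defines the flat parameter-vector layout (column-stacked
vec(A), vec(B_i), vec(C), then per-node decay/transit log-scalings and the
global epsilon log-scaling) used by the prior and inversion machinery, and
supports batched prediction over many parameter vectors at once, which is
what makes finite-difference Jacobians of the integrator affordable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C


class IntegrationError(RuntimeError):
    """Raised when the state trajectory becomes non-finite."""

    def __init__(self, message: str, time_s: float | None = None):
        super().__init__(message)
        self.time_s = time_s


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Structural description of the network model.

    Parameters
    ----------
    n_nodes : number of regions n.
    n_inputs : number of exogenous inputs k.
    driven_nodes : node indices (0-based) whose driving efficacies C are
        free parameters; all other C entries are fixed at zero a priori.
    node_labels : optional region names.
    """

    n_nodes: int
    n_inputs: int = 1
    driven_nodes: tuple[int, ...] = ()
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.n_inputs < 0:
            raise ValueError("n_inputs must be >= 0")
        object.__setattr__(self, "driven_nodes", tuple(sorted(set(self.driven_nodes))))
        for i in self.driven_nodes:
            if not 0 <= i < self.n_nodes:
                raise ValueError(f"driven node {i} outside 0..{self.n_nodes - 1}")
        if self.node_labels is not None:
            object.__setattr__(self, "node_labels", tuple(self.node_labels))
            if len(self.node_labels) != self.n_nodes:
                raise ValueError("node_labels length must equal n_nodes")

    @property
    def labels(self) -> tuple[str, ...]:
        if self.node_labels is not None:
            return self.node_labels
        return tuple(f"node{i + 1}" for i in range(self.n_nodes))


@dataclass
class CouplingParameters:
    """Neuronal coupling parameters (all in Hz)."""

    A: np.ndarray                      # (n, n)
    B: list[np.ndarray] = field(default_factory=list)  # k matrices (n, n)
    C: np.ndarray | None = None        # (n, k)

    def validate(self, spec: ModelSpec) -> None:
        n, k = spec.n_nodes, spec.n_inputs
        if self.A.shape != (n, n):
            raise ValueError(f"A must be {(n, n)}, got {self.A.shape}")
        if self.C is None:
            self.C = np.zeros((n, k))
        if self.C.shape != (n, k):
            raise ValueError(f"C must be {(n, k)}, got {self.C.shape}")
        if self.B and len(self.B) != k:
            raise ValueError(f"need {k} B matrices, got {len(self.B)}")
        for Bi in self.B:
            if Bi.shape != (n, n):
                raise ValueError("B matrices must be (n, n)")


@dataclass
class HemodynamicParameters:
    """Balloon-Windkessel parameters.

    ``decay_scale``/``transit_scale`` are per-node log-scaling factors on
    the canonical signal-decay rate and transit time; ``epsilon_scale`` is
    a global log-scaling on the intra/extravascular ratio.  A value of 0
    means the canonical constant.
    """

    n_nodes: int
    decay_scale: np.ndarray | None = None    # (n,)
    transit_scale: np.ndarray | None = None  # (n,)
    epsilon_scale: float = 0.0
    TE: float = C.DEFAULT_TE

    def __post_init__(self):
        n = self.n_nodes
        if self.decay_scale is None:
            self.decay_scale = np.zeros(n)
        if self.transit_scale is None:
            self.transit_scale = np.zeros(n)
        self.decay_scale = np.asarray(self.decay_scale, float)
        self.transit_scale = np.asarray(self.transit_scale, float)
        if self.decay_scale.shape != (n,) or self.transit_scale.shape != (n,):
            raise ValueError("hemodynamic scalings must have one entry per node")
        if self.TE <= 0:
            raise ValueError("TE must be positive")

    @property
    def decay(self) -> np.ndarray:
        """Signal decay rate kappa per node (1/s)."""
        return C.HEMO_SIGNAL_DECAY * np.exp(self.decay_scale)

    @property
    def transit(self) -> np.ndarray:
        """Mean transit time tau per node (s)."""
        return C.HEMO_TRANSIT_TIME * np.exp(self.transit_scale)

    @property
    def epsilon(self) -> float:
        return C.HEMO_EPSILON * np.exp(self.epsilon_scale)


@dataclass
class InputFunctions:
    """Exogenous inputs sampled on a microtime grid."""

    u: np.ndarray        # (T_micro, k)
    dt_micro: float      # s
    TR: float            # s
    n_volumes: int

    def __post_init__(self):
        self.u = np.atleast_2d(np.asarray(self.u, float))
        if not np.all(np.isfinite(self.u)):
            raise ValueError("inputs must be finite")
        if self.dt_micro <= 0 or self.TR <= 0:
            raise ValueError("dt_micro and TR must be positive")
        if self.u.shape[0] * self.dt_micro < (self.n_volumes - 1) * self.TR:
            raise ValueError("input grid shorter than the scan")

    @property
    def n_inputs(self) -> int:
        return self.u.shape[1]

    @property
    def steps_per_volume(self) -> int:
        spv = self.TR / self.dt_micro
        if abs(spv - round(spv)) > 1e-9:
            raise ValueError("TR must be an integer multiple of dt_micro")
        return int(round(spv))


@dataclass
class TimeSeries:
    """Confound-adjusted BOLD observations, one column per node."""

    Y: np.ndarray        # (T, n)
    TR: float
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self):
        self.Y = np.atleast_2d(np.asarray(self.Y, float))
        if self.Y.shape[0] < 2:
            raise ValueError("need at least two volumes")
        if not np.all(np.isfinite(self.Y)):
            raise ValueError("timeseries must not contain missing values")

    @property
    def n_volumes(self) -> int:
        return self.Y.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.Y.shape[1]


# ---------------------------------------------------------------------------
# Flat parameter-vector layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterIndex:
    """Layout of the flat parameter vector theta.

    Order: vec(A) column-stacked (n^2), vec(B_1)..vec(B_k) (k * n^2),
    vec(C) column-stacked (n*k), decay scalings (n), transit scalings (n),
    epsilon scaling (1).  Column-stacking is used throughout so that the
    Kronecker identity vec(P A P) = (P (x) P) vec(A) holds.
    """

    n_nodes: int
    n_inputs: int

    @property
    def n_a(self) -> int:
        return self.n_nodes ** 2

    @property
    def a_slice(self) -> slice:
        return slice(0, self.n_a)

    def b_slice(self, i: int) -> slice:
        return slice(self.n_a * (1 + i), self.n_a * (2 + i))

    @property
    def b_all_slice(self) -> slice:
        return slice(self.n_a, self.n_a * (1 + self.n_inputs))

    @property
    def c_slice(self) -> slice:
        start = self.n_a * (1 + self.n_inputs)
        return slice(start, start + self.n_nodes * self.n_inputs)

    @property
    def decay_slice(self) -> slice:
        start = self.c_slice.stop
        return slice(start, start + self.n_nodes)

    @property
    def transit_slice(self) -> slice:
        start = self.decay_slice.stop
        return slice(start, start + self.n_nodes)

    @property
    def epsilon_index(self) -> int:
        return self.transit_slice.stop

    @property
    def size(self) -> int:
        return self.epsilon_index + 1

    def a_index(self, row: int, col: int) -> int:
        """Flat index of A[row, col] under column stacking."""
        return col * self.n_nodes + row

    def encode(self, coupling: CouplingParameters,
               hemo: HemodynamicParameters) -> np.ndarray:
        n, k = self.n_nodes, self.n_inputs
        theta = np.zeros(self.size)
        theta[self.a_slice] = coupling.A.ravel(order="F")
        for i, Bi in enumerate(coupling.B):
            theta[self.b_slice(i)] = Bi.ravel(order="F")
        Cm = coupling.C if coupling.C is not None else np.zeros((n, k))
        theta[self.c_slice] = Cm.ravel(order="F")
        theta[self.decay_slice] = hemo.decay_scale
        theta[self.transit_slice] = hemo.transit_scale
        theta[self.epsilon_index] = hemo.epsilon_scale
        return theta

    def decode(self, theta: np.ndarray, TE: float = C.DEFAULT_TE
               ) -> tuple[CouplingParameters, HemodynamicParameters]:
        n, k = self.n_nodes, self.n_inputs
        theta = np.asarray(theta, float)
        if theta.shape != (self.size,):
            raise ValueError(f"theta must have length {self.size}")
        A = theta[self.a_slice].reshape(n, n, order="F")
        B = [theta[self.b_slice(i)].reshape(n, n, order="F") for i in range(k)]
        Cm = theta[self.c_slice].reshape(n, k, order="F")
        coupling = CouplingParameters(A=A, B=B, C=Cm)
        hemo = HemodynamicParameters(
            n_nodes=n,
            decay_scale=theta[self.decay_slice].copy(),
            transit_scale=theta[self.transit_slice].copy(),
            epsilon_scale=float(theta[self.epsilon_index]),
            TE=TE,
        )
        return coupling, hemo


# ---------------------------------------------------------------------------
# Derivatives
# ---------------------------------------------------------------------------

def neuronal_derivative(z: np.ndarray, u: np.ndarray,
                        params: CouplingParameters) -> np.ndarray:
    """dz/dt = (A + sum_i u_i B_i) z + C u."""
    z = np.asarray(z, float)
    u = np.atleast_1d(np.asarray(u, float))
    n = params.A.shape[0]
    if params.A.shape != (n, n) or z.shape != (n,):
        raise ValueError("A and z have inconsistent shapes")
    A_eff = params.A
    if params.B:
        if len(params.B) != u.shape[0]:
            raise ValueError("number of B matrices must match inputs")
        A_eff = A_eff + sum(ui * Bi for ui, Bi in zip(u, params.B))
    dz = A_eff @ z
    if params.C is not None and u.size:
        if params.C.shape != (n, u.shape[0]):
            raise ValueError("C shape inconsistent with z and u")
        dz = dz + params.C @ u
    return dz


def hemodynamic_derivative(h_state: np.ndarray, z: float,
                           H: HemodynamicParameters, node: int = 0) -> np.ndarray:
    """Balloon-model derivatives for one node.

    ``h_state`` is (signal s, flow f, volume v, dHb q) in natural units;
    flow, volume and dHb must be strictly positive.  Returns d/dt of the
    same quantities.
    """
    s, f, v, q = np.asarray(h_state, float)
    if not np.all(np.isfinite(h_state)):
        raise IntegrationError("non-finite hemodynamic state")
    if f <= 0 or v <= 0 or q <= 0:
        raise ValueError("flow, volume and dHb must be strictly positive")
    kappa = float(H.decay[node])
    tau = float(H.transit[node])
    gamma = C.HEMO_AUTOREGULATION
    alpha = C.HEMO_STIFFNESS_ALPHA
    E0 = C.HEMO_OXYGEN_EXTRACTION
    ds = C.HEMO_EFFICACY * z - kappa * s - gamma * (f - 1.0)
    df = s
    outflow = v ** (1.0 / alpha)
    dv = (f - outflow) / tau
    extraction = 1.0 - (1.0 - E0) ** (1.0 / f)
    dq = (f * extraction / E0 - outflow * q / v) / tau
    return np.array([ds, df, dv, dq])


# ---------------------------------------------------------------------------
# Batched integration
# ---------------------------------------------------------------------------

def _bold_gains(epsilon: np.ndarray, TE: float):
    E0 = C.HEMO_OXYGEN_EXTRACTION
    k1 = 4.3 * C.BOLD_THETA0 * E0 * TE
    k2 = epsilon * C.BOLD_R0 * E0 * TE
    k3 = 1.0 - epsilon
    return k1, k2, k3


def bold_predictions(theta: np.ndarray, spec: ModelSpec, inputs: InputFunctions,
                     TE: float = C.DEFAULT_TE) -> np.ndarray:
    """Integrate the generative model for a batch of parameter vectors.

    Parameters
    ----------
    theta : (batch, P) or (P,) flat parameter vectors (ParameterIndex layout).
    Returns
    -------
    (batch, T, n) predicted BOLD, or (T, n) for a single vector.
    """
    theta = np.asarray(theta, float)
    single = theta.ndim == 1
    theta = np.atleast_2d(theta)
    idx = ParameterIndex(spec.n_nodes, spec.n_inputs)
    if theta.shape[1] != idx.size:
        raise ValueError(f"parameter vectors must have length {idx.size}")
    n, k = spec.n_nodes, spec.n_inputs
    bsz = theta.shape[0]

    # row-major reshape of each batch row gives [col, row]; transposing
    # recovers the column-stacked convention per vector.
    A = np.ascontiguousarray(np.transpose(
        theta[:, idx.a_slice].reshape(bsz, n, n), (0, 2, 1)))
    Bmats = None
    b_block = theta[:, idx.b_all_slice]
    if k and np.any(b_block):
        Bmats = [np.ascontiguousarray(np.transpose(
            theta[:, idx.b_slice(i)].reshape(bsz, n, n), (0, 2, 1)))
            for i in range(k)]
    Cm = np.ascontiguousarray(np.transpose(
        theta[:, idx.c_slice].reshape(bsz, k, n), (0, 2, 1))) if k else None
    kappa = C.HEMO_SIGNAL_DECAY * np.exp(theta[:, idx.decay_slice])   # (b, n)
    tau = C.HEMO_TRANSIT_TIME * np.exp(theta[:, idx.transit_slice])   # (b, n)
    epsilon = C.HEMO_EPSILON * np.exp(theta[:, idx.epsilon_index])    # (b,)

    gamma = C.HEMO_AUTOREGULATION
    inv_alpha = 1.0 / C.HEMO_STIFFNESS_ALPHA
    E0 = C.HEMO_OXYGEN_EXTRACTION
    log_1mE0 = np.log(1.0 - E0)
    k1, k2, k3 = _bold_gains(epsilon, TE)

    dt = inputs.dt_micro
    spv = inputs.steps_per_volume
    T = inputs.n_volumes
    u = inputs.u
    if u.shape[1] != k:
        raise ValueError("input count inconsistent with model spec")

    # packed state (batch, 5, n): rows are z, s (natural units) and
    # xf, xv, xq (log flow / volume / dHb, for positivity)
    X = np.zeros((bsz, 5, n))

    def deriv(X_, ut, out):
        z_ = X_[:, 0]
        s_ = X_[:, 1]
        f = np.exp(X_[:, 2])
        v = np.exp(X_[:, 3])
        q = np.exp(X_[:, 4])
        if Bmats is not None:
            A_eff = A.copy()
            for i in range(k):
                A_eff += ut[i] * Bmats[i]
            np.matmul(A_eff, z_[:, :, None], out=out[:, 0][:, :, None])
        else:
            np.matmul(A, z_[:, :, None], out=out[:, 0][:, :, None])
        if Cm is not None and k:
            out[:, 0] += Cm @ ut
        out[:, 1] = C.HEMO_EFFICACY * z_ - kappa * s_ - gamma * (f - 1.0)
        out[:, 2] = s_ / f
        outflow = np.exp(inv_alpha * X_[:, 3])
        out[:, 3] = (f - outflow) / (tau * v)
        extraction = 1.0 - np.exp(log_1mE0 / f)
        out[:, 4] = (f * extraction / E0 - outflow * q / v) / (tau * q)
        return out

    Y = np.empty((bsz, T, n))

    def record(vol, X_):
        v = np.exp(X_[:, 3])
        q = np.exp(X_[:, 4])
        Y[:, vol, :] = C.BOLD_V0 * (
            k1 * (1.0 - q)
            + k2[:, None] * (1.0 - q / v)
            + k3[:, None] * (1.0 - v))

    record(0, X)
    half = dt / 2.0
    sixth = dt / 6.0
    n_steps = (T - 1) * spv
    k1d, k2d, k3d, k4d = (np.empty_like(X) for _ in range(4))
    # divergence surfaces as non-finite state at the volume check below;
    # the intermediate overflow warnings carry no extra information
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for step in range(n_steps):
            ut = u[step] if step < u.shape[0] else u[-1]
            deriv(X, ut, k1d)
            deriv(X + half * k1d, ut, k2d)
            deriv(X + half * k2d, ut, k3d)
            deriv(X + dt * k3d, ut, k4d)
            X += sixth * (k1d + 2.0 * k2d + 2.0 * k3d + k4d)
            if (step + 1) % spv == 0:
                if not np.all(np.isfinite(X[:, 3])):
                    raise IntegrationError(
                        "state diverged during integration",
                        time_s=(step + 1) * dt)
                record((step + 1) // spv, X)

    return Y[0] if single else Y


def predict_bold(spec: ModelSpec, coupling: CouplingParameters,
                 hemo: HemodynamicParameters,
                 inputs: InputFunctions) -> TimeSeries:
    """Deterministic BOLD prediction for one parameter set."""
    coupling.validate(spec)
    idx = ParameterIndex(spec.n_nodes, spec.n_inputs)
    theta = idx.encode(coupling, hemo)
    Y = bold_predictions(theta, spec, inputs, TE=hemo.TE)
    return TimeSeries(Y=Y, TR=inputs.TR, node_labels=spec.labels)
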