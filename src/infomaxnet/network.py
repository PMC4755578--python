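"""Recurrent rate-network model: parameters, nonlinearity and steady states.

The model is a two-layer sensory network: an input layer ``x`` of N units
feeds, through a fixed matrix ``W`` (M x N, M >= N), an output layer of M
sigmoidal rate units coupled all-to-all by a recurrent matrix ``K``.  The
output dynamics relax towards a self-consistent steady state

    tau ds_i/dt = -s_i + g(sum_j W_ij x_j + sum_k K_ik s_k)

and the network "response" to an input is that steady state.  Everything
downstream (susceptibility, the infomax objective, the learning rule)
operates on these fixed points.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import json

import numpy as np
from scipy.special import expit


class DivergentDynamicsError(RuntimeError):
    """Raised when the fixed-point iteration produces non-finite activities."""


@dataclass(frozen=True)
class Nonlinearity:
    """A smooth squashing function with its first two derivatives.

    ``gamma0`` caches the slope at zero net input; it sets the linear gain
    of an unstimulated network and hence the critical coupling strength.
    """

    name: str
    eval: callable
    deriv1: callable
    deriv2: callable
    gamma0: float


def _logistic(u):
    return expit(u)


def _logistic_d1(u):
    y = expit(u)
    return y * (1.0 - y)


def _logistic_d2(u):
    y = expit(u)
    return y * (1.0 - y) * (1.0 - 2.0 * y)


LOGISTIC = Nonlinearity(
    name="logistic",
    eval=_logistic,
    deriv1=_logistic_d1,
    deriv2=_logistic_d2,
    gamma0=0.25,
)

_NONLINEARITIES = {"logistic": LOGISTIC}


def get_nonlinearity(name: str) -> Nonlinearity:
    try:
        return _NONLINEARITIES[name]
    except KeyError:
        raise ValueError(f"unknown nonlinearity {name!r}") from None


def logistic_eval(u):
    """Logistic function g(u) = 1/(1+exp(-u)) and its first two derivatives.

    Returns ``(value, deriv1, deriv2)``; accepts scalars or arrays and
    saturates gracefully for large ``|u|``.
    """
    y = expit(u)
    d1 = y * (1.0 - y)
    return y, d1, d1 * (1.0 - 2.0 * y)


@dataclass(frozen=True)
class NetworkParams:
    """Feedforward matrix W (M x N), recurrent matrix K (M x M), tau, g."""

    W: np.ndarray
    K: np.ndarray
    tau: float = 1.0
    nonlinearity: Nonlinearity = LOGISTIC

    def __post_init__(self):
        W = np.asarray(self.W, dtype=float)
        K = np.asarray(self.K, dtype=float)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "K", K)
        if W.ndim != 2:
            raise ValueError("W must be 2-D (M x N)")
        M, N = W.shape
        if K.shape != (M, M):
            raise ValueError(f"K must be {M} x {M} to match W, got {K.shape}")
        if M < N:
            raise ValueError("overcomplete map requires M >= N")
        if not (np.isfinite(W).all() and np.isfinite(K).all()):
            raise ValueError("W and K must be finite")
        if not self.tau > 0:
            raise ValueError("tau must be positive")

    @property
    def M(self) -> int:
        return self.W.shape[0]

    @property
    def N(self) -> int:
        return self.W.shape[1]

    def with_K(self, K: np.ndarray) -> "NetworkParams":
        return replace(self, K=np.asarray(K, dtype=float))

    def scaled(self, factor: float) -> "NetworkParams":
        """Same network with the recurrent matrix multiplied by ``factor``."""
        return self.with_K(factor * self.K)

    # ---- serialization ------------------------------------------------
    def save(self, directory) -> None:
        """Write W.csv, K.csv (header-free, row-major) and meta.json.

        The CSVs use repr-precision floats so a load round-trips bit-
        faithfully at double precision.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "W.csv", self.W, delimiter=",", fmt="%.17g")
        np.savetxt(directory / "K.csv", self.K, delimiter=",", fmt="%.17g")
        meta = {"tau": self.tau, "nonlinearity": self.nonlinearity.name}
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "NetworkParams":
        directory = Path(directory)
        W = np.loadtxt(directory / "W.csv", delimiter=",", ndmin=2)
        K = np.loadtxt(directory / "K.csv", delimiter=",", ndmin=2)
        meta = json.loads((directory / "meta.json").read_text())
        return cls(W=W, K=K, tau=float(meta["tau"]),
                   nonlinearity=get_nonlinearity(meta["nonlinearity"]))


@dataclass
class FixedPoint:
    """A steady state of the recurrent dynamics for one input sample."""

    s: np.ndarray
    net_input: np.ndarray
    iterations: int
    converged: bool
    per_neuron_delta: float


def _initial_state(params, init, noise_scale, rng):
    M = params.M
    if init is not None:
        s = np.array(init, dtype=float)
        if s.shape != (M,):
            raise ValueError(f"init must have shape ({M},)")
    else:
        s = np.full(M, params.nonlinearity.eval(0.0))
    if noise_scale and noise_scale > 0:
        if rng is None:
            rng = np.random.default_rng()
        s = np.clip(s + noise_scale * rng.standard_normal(M), 1e-12, 1 - 1e-12)
    return s


def solve_fixed_point(
    params: NetworkParams,
    x: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 1_000_000,
    init: np.ndarray | None = None,
    noise_scale: float = 0.0,
    seed: int | None = None,
    alpha: float = 0.5,
) -> FixedPoint:
    """Solve s = g(Wx + Ks) by damped iteration.

    The update ``s <- (1-alpha) s + alpha g(Wx + Ks)`` is forward Euler on
    the rate dynamics with step ``alpha * tau``; ``alpha=0.5`` is robust up
    to and slightly beyond the critical coupling.  Convergence is declared
    when every neuron's activity changes by less than ``tol`` in one step.

    ``noise_scale`` perturbs the initial state (seeded by ``seed``) so the
    supercritical regime can break the homogeneous symmetry and settle into
    a hill-shaped attractor.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    x = np.asarray(x, dtype=float)
    if x.shape != (params.N,):
        raise ValueError(f"x must have shape ({params.N},)")
    if not np.isfinite(x).all():
        raise ValueError("x must be finite")

    rng = np.random.default_rng(seed) if seed is not None else None
    s = _initial_state(params, init, noise_scale, rng)
    g = params.nonlinearity.eval
    drive = params.W @ x

    delta = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        target = g(drive + params.K @ s)
        if not np.isfinite(target).all():
            raise DivergentDynamicsError(
                f"non-finite activities at iteration {it}")
        s_new = (1.0 - alpha) * s + alpha * target
        delta = float(np.max(np.abs(s_new - s)))
        s = s_new
        if delta < tol:
            break
    net_input = drive + params.K @ s
    return FixedPoint(s=s, net_input=net_input, iterations=it,
                      converged=delta < tol, per_neuron_delta=delta)


def solve_fixed_point_batch(
    params: NetworkParams,
    X: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 200_000,
    alpha: float = 0.5,
    init: np.ndarray | None = None,
    noise_scale: float = 0.0,
    seed: int | None = None,
):
    """Vectorized fixed points for a batch of inputs.

    ``X`` is (B, N); returns ``(S, U, iterations, converged, deltas)`` with
    ``S``/``U`` of shape (B, M) holding steady-state activities and net
    inputs, per-sample iteration counts (the step at which each sample
    first met the tolerance), convergence flags, and each sample's last
    per-step activity change (useful to grade near-converged stragglers).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.N:
        raise ValueError(f"X must be (B, {params.N})")
    B = X.shape[0]
    M = params.M
    g = params.nonlinearity.eval
    drive = X @ params.W.T                      # (B, M)

    if init is not None:
        S = np.broadcast_to(np.asarray(init, float), (B, M)).copy()
    else:
        S = np.full((B, M), params.nonlinearity.eval(0.0))
    if noise_scale and noise_scale > 0:
        rng = np.random.default_rng(seed)
        S = np.clip(S + noise_scale * rng.standard_normal((B, M)),
                    1e-12, 1 - 1e-12)

    iters = np.full(B, max_iter, dtype=int)
    done = np.zeros(B, dtype=bool)
    deltas = np.zeros(B)
    active = np.arange(B)
    S_act = S
    drive_act = drive
    for it in range(1, max_iter + 1):
        target = g(drive_act + S_act @ params.K.T)
        if not np.isfinite(target).all():
            raise DivergentDynamicsError(
                f"non-finite activities at iteration {it}")
        S_new = (1.0 - alpha) * S_act + alpha * target
        delta = np.max(np.abs(S_new - S_act), axis=1)
        S_act = S_new
        conv = delta < tol
        if conv.any():
            hit = active[conv]
            S[hit] = S_act[conv]
            iters[hit] = it
            deltas[hit] = delta[conv]
            done[hit] = True
            keep = ~conv
            active = active[keep]
            S_act = S_act[keep]
            drive_act = drive_act[keep]
            delta = delta[keep]
            if active.size == 0:
                break
    if active.size:
        S[active] = S_act
        deltas[active] = delta
    U = drive + S @ params.K.T
    return S, U, iters, done, deltas


def integrate_dynamics(
    params: NetworkParams,
    x: np.ndarray,
    duration: float,
    dt: float,
    init: np.ndarray | None = None,
):
    """Explicit Euler integration of tau ds/dt = -s + g(Wx + Ks).

    Returns ``(times, trajectory)`` with trajectory of shape (T+1, M)
    including the initial state.  Requires ``dt < tau`` for stability of
    the explicit scheme.
    """
    if dt >= params.tau:
        raise ValueError("dt must be smaller than tau (unstable otherwise)")
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    x = np.asarray(x, dtype=float)
    if x.shape != (params.N,):
        raise ValueError(f"x must have shape ({params.N},)")

    s = _initial_state(params, init, 0.0, None)
    g = params.nonlinearity.eval
    drive = params.W @ x
    n_steps = int(np.ceil(duration / dt))
    traj = np.empty((n_steps + 1, params.M))
    traj[0] = s
    coef = dt / params.tau
    for t in range(1, n_steps + 1):
        target = g(drive + params.K @ s)
        if not np.isfinite(target).all():
            raise DivergentDynamicsError(f"non-finite activities at step {t}")
        s = s + coef * (target - s)
        traj[t] = s
    times = np.arange(n_steps + 1) * dt
    return times, traj
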