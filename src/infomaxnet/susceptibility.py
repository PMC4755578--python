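"""Susceptibility (input-output Jacobian) and the infomax objective.

For a converged steady state, the sensitivity of the outputs to the inputs
is the Jacobian chi_ij = ds_i/dx_j.  Differentiating the fixed-point
condition s = g(Wx + Ks) gives

    (I - G K) chi = G W,      G = diag(g'(u_i)),

so chi = phi W with phi = (G^-1 - K)^-1 = (I - G K)^-1 G.  Maximizing the
mutual information between input and steady-state output (the map is
deterministic, so only the output entropy varies) is equivalent to
minimizing

    eps = -1/2 < ln det(chi^T chi) >_x .

The auxiliary matrices Gamma = (chi^T chi)^-1 chi^T phi and the curvature
vector a_k = [chi Gamma]_kk g''_k / (g'_k)^3 feed the gradient of eps with
respect to K (see :mod:`infomaxnet.learning`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .network import NetworkParams, FixedPoint, solve_fixed_point_batch


class CriticalityError(RuntimeError):
    """The linearized dynamics are at/beyond criticality for this input."""


class NonConvergedSamplesError(RuntimeError):
    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(
            f"fixed point did not converge for sample indices {self.indices}")


@dataclass
class SusceptibilityBundle:
    """chi and the auxiliary matrices entering the learning rule."""

    chi: np.ndarray            # (M, N) ds/dx
    G: np.ndarray              # (M,)  diagonal gains g'(u_i)
    phi: np.ndarray            # (M, M) (G^-1 - K)^-1
    Gamma: np.ndarray          # (N, M) (chi^T chi)^-1 chi^T phi
    a: np.ndarray              # (M,)  [chi Gamma]_kk g''/(g')^3
    condition_estimate: float  # cond(I - GK)


def _bundle_from_state(params: NetworkParams, u: np.ndarray,
                       cond_threshold: float | None = 1e12
                       ) -> SusceptibilityBundle:
    nl = params.nonlinearity
    g1 = nl.deriv1(u)
    g2 = nl.deriv2(u)
    M = params.M
    A = np.eye(M) - g1[:, None] * params.K        # I - G K
    cond = float(np.linalg.cond(A))
    if cond_threshold is not None and cond > cond_threshold:
        raise CriticalityError(
            f"condition estimate {cond:.3g} exceeds {cond_threshold:.3g}: "
            "network at or beyond criticality for this input")
    lu, piv = sla.lu_factor(A, check_finite=False)
    chi = sla.lu_solve((lu, piv), g1[:, None] * params.W, check_finite=False)
    phi = sla.lu_solve((lu, piv), np.diag(g1), check_finite=False)
    ctc = chi.T @ chi
    try:
        c = sla.cho_factor(ctc, check_finite=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise CriticalityError("chi^T chi is not positive definite") from exc
    Gamma = sla.cho_solve(c, chi.T @ phi, check_finite=False)
    a = np.einsum("ij,ji->i", chi, Gamma) * g2 / g1**3
    return SusceptibilityBundle(chi=chi, G=g1, phi=phi, Gamma=Gamma, a=a,
                                condition_estimate=cond)


def susceptibility(params: NetworkParams, fp: FixedPoint,
                   cond_threshold: float | None = 1e12
                   ) -> SusceptibilityBundle:
    """Susceptibility bundle at a converged fixed point.

    ``chi`` is obtained by a linear solve of (I - GK) chi = GW; the
    condition number of (I - GK) is estimated and an error is raised above
    ``cond_threshold`` (pass ``None`` to disable, e.g. when probing the
    divergence itself).
    """
    if not fp.converged:
        raise ValueError("fixed point did not converge; susceptibility "
                         "requires a steady state")
    return _bundle_from_state(params, fp.net_input, cond_threshold)


def _logdet_psd(ctc: np.ndarray) -> float:
    """Stable log-determinant of a (small) SPD matrix via Cholesky."""
    c = np.linalg.cholesky(ctc)
    return 2.0 * float(np.sum(np.log(np.diag(c))))


@dataclass
class ObjectiveValue:
    epsilon: float
    per_sample_terms: np.ndarray
    n_samples: int


def objective_from_states(params: NetworkParams, U: np.ndarray,
                          cond_threshold: float | None = 1e12
                          ) -> ObjectiveValue:
    """eps from precomputed per-sample net-input vectors U of shape (B, M)."""
    terms = np.empty(U.shape[0])
    for b in range(U.shape[0]):
        bundle = _bundle_from_state(params, U[b], cond_threshold)
        ctc = bundle.chi.T @ bundle.chi
        try:
            terms[b] = -0.5 * _logdet_psd(ctc)
        except np.linalg.LinAlgError as exc:
            raise CriticalityError(
                f"chi^T chi not positive definite for sample {b}") from exc
    return ObjectiveValue(epsilon=float(np.mean(terms)),
                          per_sample_terms=terms, n_samples=U.shape[0])


def _batch_states(params, X, tol, max_iter, max_nonconverged_frac,
                  soft_tol=1e-6):
    """Fixed-point states for a batch, tolerant of marginal stragglers.

    Near the critical surface, samples with unusually weak inputs relax so
    slowly that they miss the strict tolerance within any reasonable
    budget.  Stragglers whose last per-step change is below ``soft_tol``
    are effectively at their steady state and are used as-is.  The soft
    tolerance must stay small: a supercritical hill that a weak stimulus
    cannot pin rotates slowly, and a generous threshold would mistake a
    point mid-rotation for a fixed point (its apparent susceptibility is
    huge and systematically biases the objective downward).  Samples that
    fail both tests are excluded up to the allowed fraction, beyond which
    the error propagates.
    """
    S, U, _, done, deltas = solve_fixed_point_batch(params, X, tol=tol,
                                                    max_iter=max_iter)
    usable = done | (deltas < soft_tol)
    if not usable.all():
        bad = np.flatnonzero(~usable)
        if bad.size > max_nonconverged_frac * X.shape[0]:
            raise NonConvergedSamplesError(bad)
        keep = np.flatnonzero(usable)
        return S[keep], U[keep]
    return S, U


def objective(params: NetworkParams, inputs: np.ndarray,
              tol: float = 1e-9, max_iter: int = 200_000,
              cond_threshold: float | None = 1e12) -> ObjectiveValue:
    """Infomax objective eps = -1/2 < ln det(chi^T chi) > over an input batch.

    Every sample's fixed point must converge; offending sample indices are
    reported otherwise.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    _, U, _, done, _ = solve_fixed_point_batch(params, X, tol=tol,
                                               max_iter=max_iter)
    if not done.all():
        raise NonConvergedSamplesError(np.flatnonzero(~done))
    return objective_from_states(params, U, cond_threshold)
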