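"""Behavioral diagnostics of the recurrent network near criticality.

Three probes characterize where a network sits relative to the pattern-
forming transition:

* **convergence time** — solver steps to reach a steady state; diverges at
  the critical point (critical slowing down);
* **population vector** — resultant of activity-weighted preference
  phasors; zero for a homogeneous response, finite once the network breaks
  symmetry into a hill-shaped attractor;
* **scaling sweep** — the objective, convergence time and population
  vector as the learned K is multiplied by a scale factor, locating the
  optimum and the transition on either side of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import (
    NetworkParams,
    solve_fixed_point,
    solve_fixed_point_batch,
)
from .susceptibility import CriticalityError, objective_from_states


def convergence_time(params: NetworkParams, x: np.ndarray,
                     tol: float = 1e-9, max_iter: int = 200_000,
                     alpha: float = 0.5, init=None, noise_scale: float = 0.0,
                     seed=None) -> tuple[int, bool]:
    """Steps of the damped iteration until every neuron moves < tol.

    Returns ``(steps, satisfied)``; ``steps == max_iter`` with
    ``satisfied=False`` if the criterion was never met.  One solver step
    corresponds to ``alpha * tau`` units of model time.
    """
    fp = solve_fixed_point(params, x, tol=tol, max_iter=max_iter,
                           alpha=alpha, init=init, noise_scale=noise_scale,
                           seed=seed)
    return fp.iterations, fp.converged


@dataclass
class PopulationVectorResult:
    magnitude: float
    phase: float
    doubling: bool


def population_vector(s: np.ndarray, angles: np.ndarray,
                      doubling: bool = False) -> PopulationVectorResult:
    """Resultant of s_i * exp(1j * angle_i) (angles doubled for orientations).

    For orientation data (period 180 degrees) pass ``doubling=True``: the
    angle is doubled before summing and the resultant phase halved back, so
    the returned phase lives on the original orientation scale.
    """
    s = np.asarray(s, dtype=float)
    angles = np.asarray(angles, dtype=float)
    if np.any(s < 0):
        raise ValueError("activities must be non-negative")
    factor = 2.0 if doubling else 1.0
    z = np.sum(s * np.exp(1j * factor * angles))
    phase = float(np.angle(z)) / factor
    return PopulationVectorResult(magnitude=float(np.abs(z)), phase=phase,
                                  doubling=doubling)


@dataclass
class ScalingSweepResult:
    scales: np.ndarray
    epsilon: np.ndarray            # NaN where supercritical/undefined
    convergence_steps: np.ndarray  # mean steps over the input batch
    popvec_magnitude: np.ndarray   # zero-drive response, symmetry probe
    argmin_scale: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "scale": self.scales, "epsilon": self.epsilon,
            "steps": self.convergence_steps,
            "popvec": self.popvec_magnitude,
        })


def scaling_sweep(params: NetworkParams, scales, inputs: np.ndarray,
                  tol: float = 1e-9, max_iter: int = 200_000,
                  angles: np.ndarray | None = None,
                  doubling: bool = False,
                  popvec_noise: float = 1e-6, seed: int = 0,
                  cond_threshold: float = 1e12) -> ScalingSweepResult:
    """Objective, convergence time and population vector versus K scale.

    The same input batch is used at every scale (paired comparison).  The
    population vector is probed at zero input with a small seeded
    perturbation of the initial state, so it detects spontaneous symmetry
    breaking: ~0 below the transition, finite above it.  Scales where the
    objective is undefined (non-convergence or singular susceptibility) are
    recorded as NaN rather than failing the sweep.
    """
    scales = np.asarray(scales, dtype=float)
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if angles is None:
        angles = 2.0 * np.pi * np.arange(params.M) / params.M
    eps = np.full(scales.shape, np.nan)
    steps = np.zeros(scales.shape)
    pv = np.zeros(scales.shape)
    x0 = np.zeros(params.N)
    for i, c in enumerate(scales):
        p_c = params.scaled(c)
        _, U, iters, done, _ = solve_fixed_point_batch(
            p_c, X, tol=tol, max_iter=max_iter)
        steps[i] = float(np.mean(iters))
        # eps only where every sample reached a true steady state: beyond
        # the critical scale weakly pinned hills rotate indefinitely and
        # their apparent susceptibility is meaningless
        try:
            if done.all():
                eps[i] = objective_from_states(p_c, U,
                                               cond_threshold).epsilon
        except (CriticalityError, np.linalg.LinAlgError):
            pass
        fp0 = solve_fixed_point(p_c, x0, tol=tol, max_iter=max_iter,
                                noise_scale=popvec_noise, seed=seed)
        pv[i] = population_vector(fp0.s, angles, doubling).magnitude
    argmin = float(scales[np.nanargmin(eps)]) if np.isfinite(eps).any() \
        else float("nan")
    return ScalingSweepResult(scales=scales, epsilon=eps,
                              convergence_steps=steps, popvec_magnitude=pv,
                              argmin_scale=argmin)


def tuning_width(angles_deg: np.ndarray, response: np.ndarray) -> float:
    """Half-width at half-height above baseline, in degrees.

    Baseline is the minimum of the curve; the width is measured by linear
    interpolation on both flanks of the (circularly shifted) peak.
    """
    angles_deg = np.asarray(angles_deg, dtype=float)
    r = np.asarray(response, dtype=float)
    M = r.size
    ipk = int(np.argmax(r))
    base = float(np.min(r))
    half = base + 0.5 * (r[ipk] - base)
    # center the peak, then walk out on both sides
    shift = M // 2 - ipk
    rc = np.roll(r, shift)
    span = angles_deg[1] - angles_deg[0]
    center = M // 2

    def _cross(side):
        idx = center
        while 0 < idx < M - 1:
            nxt = idx + side
            if rc[nxt] <= half:
                frac = (rc[idx] - half) / (rc[idx] - rc[nxt])
                return (abs(nxt - center) - 1 + frac) * span
            idx = nxt
        return (M // 2) * span

    return 0.5 * (_cross(-1) + _cross(+1))


def response_curves(params: NetworkParams, stimuli: dict,
                    angles_deg: np.ndarray | None = None,
                    tol: float = 1e-9, max_iter: int = 200_000
                    ) -> pd.DataFrame:
    """Steady-state tuning curves with and without recurrent interactions.

    ``stimuli`` maps a contrast label (float) to an input vector.  Returns
    a tidy frame with columns (PO_deg, response, condition, contrast,
    width_deg), where condition is "recurrent" or "feedforward" (K = 0)
    and width_deg is the half-width at half-height for that curve.
    """
    M = params.M
    if angles_deg is None:
        angles_deg = np.degrees(2.0 * np.pi * np.arange(M) / M)
    p_ff = params.with_K(np.zeros_like(params.K))
    rows = []
    for contrast, x in stimuli.items():
        for cond, p in (("recurrent", params), ("feedforward", p_ff)):
            fp = solve_fixed_point(p, np.asarray(x, float), tol=tol,
                                   max_iter=max_iter)
            w = tuning_width(angles_deg, fp.s)
            for po, resp in zip(angles_deg, fp.s):
                rows.append((po, resp, cond, contrast, w))
    return pd.DataFrame(rows, columns=["PO_deg", "response", "condition",
                                       "contrast", "width_deg"])
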