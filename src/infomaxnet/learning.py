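"""Gradient-descent infomax learning of the recurrent matrix K.

The update direction for K follows from differentiating the objective
eps = -1/2 < ln det(chi^T chi) > with respect to K at fixed W:

    dK / eta = -d eps / dK = < (chi Gamma)^T + phi^T a s^T >_batch

with Gamma = (chi^T chi)^-1 chi^T phi and a_k = [chi Gamma]_kk g''_k/(g'_k)^3.
The first term is the explicit dependence of chi on K; the second tracks
how moving K moves the fixed point itself (and hence the gains G).

Near the critical point the objective becomes extremely sensitive to K, so
the trainer uses a lookahead rule: the objective is re-evaluated on the
current batch after a trial update, and if it would increase, the step is
rejected and the learning rate halved (repeatedly, down to a floor).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np
import pandas as pd

from .network import NetworkParams, solve_fixed_point_batch
from .susceptibility import (
    CriticalityError,
    NonConvergedSamplesError,
    _batch_states,
    _bundle_from_state,
    _logdet_psd,
    objective_from_states,
)


class TrainingError(RuntimeError):
    """Solver failure mid-training; carries the step index and last state."""

    def __init__(self, step: int, state, message: str):
        self.step = step
        self.state = state
        super().__init__(f"step {step}: {message}")


@dataclass(frozen=True)
class TrainingConfig:
    eta0: float = 0.01
    batch_size: int = 100
    max_steps: int = 500
    seed: int = 0
    lookahead: bool = True
    halving_factor: float = 0.5
    eta_floor: float = 1e-7
    tol: float = 1e-8
    max_iter: int = 300_000
    cond_threshold: float = 1e12
    max_nonconverged_frac: float = 0.0
    grad_clip: float | None = 5.0
    max_batch_skips: int = 25
    zero_self_connections: bool = False

    def __post_init__(self):
        if self.eta0 <= 0:
            raise ValueError("eta0 must be positive")
        if not (0.0 < self.halving_factor < 1.0):
            raise ValueError("halving_factor must lie in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainingState:
    params: NetworkParams
    step: int
    eta: float
    objective_history: list = field(default_factory=list)
    accepted: int = 0
    rejected: int = 0

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.objective_history,
            columns=["step", "epsilon_pre", "epsilon_post", "eta"])

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.params.save(directory)
        self.history_frame().to_csv(directory / "objective_history.csv",
                                    index=False)
        meta = {"step": self.step, "eta": self.eta,
                "accepted": self.accepted, "rejected": self.rejected}
        (directory / "training_state.json").write_text(
            json.dumps(meta, indent=2))


def gradient_K(params: NetworkParams, batch: np.ndarray,
               tol: float = 1e-10, max_iter: int = 200_000,
               cond_threshold: float = 1e12) -> np.ndarray:
    """Batch-averaged update direction dK/eta = <(chi Gamma)^T + phi^T a s^T>.

    This equals minus the gradient of the objective with respect to K;
    adding eta times it to K is one gradient-descent step on eps.
    """
    X = np.atleast_2d(np.asarray(batch, dtype=float))
    S, U, _, done, _ = solve_fixed_point_batch(params, X, tol=tol,
                                               max_iter=max_iter)
    if not done.all():
        raise NonConvergedSamplesError(np.flatnonzero(~done))
    M = params.M
    acc = np.zeros((M, M))
    for b in range(X.shape[0]):
        try:
            bundle = _bundle_from_state(params, U[b], cond_threshold)
        except CriticalityError as exc:
            raise CriticalityError(f"sample {b}: {exc}") from exc
        acc += (bundle.chi @ bundle.Gamma).T
        acc += np.outer(bundle.phi.T @ bundle.a, S[b])
    return acc / X.shape[0]


def _grad_and_objective(params, X, tol, max_iter, cond_threshold,
                        max_nonconverged_frac=0.0):
    """Direction dK/eta and batch eps from a single fixed-point pass."""
    S, U = _batch_states(params, X, tol, max_iter, max_nonconverged_frac)
    n_kept = S.shape[0]
    M = params.M
    acc = np.zeros((M, M))
    terms = np.empty(n_kept)
    for b in range(n_kept):
        try:
            bundle = _bundle_from_state(params, U[b], cond_threshold)
        except CriticalityError as exc:
            raise CriticalityError(f"sample {b}: {exc}") from exc
        acc += (bundle.chi @ bundle.Gamma).T
        acc += np.outer(bundle.phi.T @ bundle.a, S[b])
        ctc = bundle.chi.T @ bundle.chi
        terms[b] = -0.5 * _logdet_psd(ctc)
    return acc / n_kept, float(np.mean(terms))


def _objective_on_batch(params, X, tol, max_iter, cond_threshold,
                        max_nonconverged_frac=0.0):
    _, U = _batch_states(params, X, tol, max_iter, max_nonconverged_frac)
    return objective_from_states(params, U, cond_threshold).epsilon


def train(initial: NetworkParams, sampler, config: TrainingConfig,
          callback=None) -> TrainingState:
    """Infomax training loop for the recurrent matrix.

    ``sampler(n, rng)`` must return an (n, N) array of input vectors; it is
    driven by a generator seeded from ``config.seed`` so runs reproduce
    exactly.  With ``config.lookahead`` the objective is evaluated on the
    same batch after each trial update and the step rejected (learning rate
    halved) whenever it would increase; a trial whose dynamics fail to
    settle for any sample (e.g. a step across the critical surface, where
    weakly pinned hills turn into rotating waves) counts as an increase.
    A gradient batch that fails to settle is skipped, up to
    ``config.max_batch_skips`` consecutive skips.  Training stops at
    ``max_steps`` or when the learning rate falls below ``eta_floor``.
    """
    rng = np.random.default_rng(config.seed)
    params = initial
    state = TrainingState(params=params, step=0, eta=config.eta0)
    consecutive_skips = 0

    for step in range(1, config.max_steps + 1):
        X = sampler(config.batch_size, rng)
        try:
            direction, eps_pre = _grad_and_objective(
                params, X, config.tol, config.max_iter,
                config.cond_threshold, config.max_nonconverged_frac)
            consecutive_skips = 0
        except (NonConvergedSamplesError, CriticalityError) as exc:
            # an unlucky batch (e.g. an exceptionally weak input with
            # marginal dynamics) is skipped; a persistent failure means
            # the accepted parameters themselves are pathological
            consecutive_skips += 1
            if consecutive_skips > config.max_batch_skips:
                raise TrainingError(step, state, str(exc)) from exc
            continue
        if config.zero_self_connections:
            np.fill_diagonal(direction, 0.0)
        if config.grad_clip is not None:
            # near criticality single samples can carry a near-divergent
            # susceptibility; clipping the batch direction bounds the walk
            norm = float(np.linalg.norm(direction))
            if norm > config.grad_clip:
                direction = direction * (config.grad_clip / norm)

        accepted = False
        eps_post = eps_pre
        while not accepted:
            trial = params.with_K(params.K + state.eta * direction)
            try:
                eps_trial = _objective_on_batch(
                    trial, X, config.tol, config.max_iter,
                    config.cond_threshold, config.max_nonconverged_frac)
                bad = config.lookahead and eps_trial > eps_pre
            except (NonConvergedSamplesError, CriticalityError,
                    np.linalg.LinAlgError):
                # trial stepped over the critical surface: reject
                bad = True
                eps_trial = np.nan
            if bad:
                state.rejected += 1
                state.eta *= config.halving_factor
                if state.eta < config.eta_floor:
                    state.step = step
                    state.params = params
                    return state
            else:
                params = trial
                eps_post = eps_trial
                state.accepted += 1
                accepted = True

        state.params = params
        state.step = step
        state.objective_history.append((step, eps_pre, eps_post, state.eta))
        if callback is not None:
            callback(state)
    return state


def train_annealed(initial: NetworkParams, sampler, config: TrainingConfig,
                   anneal_stages: int = 5, anneal_steps: int = 50,
                   callback=None) -> TrainingState:
    """Training followed by a short learning-rate annealing tail.

    After the main :func:`train` run, continues for ``anneal_stages``
    stages of ``anneal_steps`` steps each, halving the learning rate at
    every stage.  Stochastic gradient steps leave a noise floor in K
    proportional to the learning rate — for the ring model a small
    non-circulant residue whose effect is strongly amplified near
    criticality — and the annealing tail damps it toward zero while the
    lookahead rule keeps the learned structure in place.
    """
    state = train(initial, sampler, config, callback=callback)
    eta = min(config.eta0, state.eta)
    step_offset = state.step
    for stage in range(1, anneal_stages + 1):
        eta *= config.halving_factor
        if eta < config.eta_floor:
            break
        stage_cfg = replace(config, eta0=eta, max_steps=anneal_steps,
                            seed=config.seed + 100_000 + stage)
        stage_state = train(state.params, sampler, stage_cfg,
                            callback=callback)
        state.params = stage_state.params
        state.eta = stage_state.eta
        state.accepted += stage_state.accepted
        state.rejected += stage_state.rejected
        state.objective_history.extend(
            (step_offset + s, pre, post, e)
            for s, pre, post, e in stage_state.objective_history)
        step_offset += stage_state.step
        state.step = step_offset
    return state
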