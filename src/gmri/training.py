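"""Least-squares training of the shared parameters.

The cost is the plain sum of squared errors over the training set,

    J(θ) = Σ_i (y_i − g_i(θ))²,

with no regularization term: overfitting is controlled purely by model
selection (see :mod:`gmri.selection`).  The quality-of-fit summary is the
root mean square training error

    RMSTE = sqrt( (1/N_T) Σ_i (y_i − g_i(θ))² ),

so RMSTE² · N_T = J(θ) exactly.  Minimization uses a Levenberg–Marquardt
loop (damped Gauss–Newton, well suited to problems with a moderate number
of parameters); training is repeated from many random initializations and
the resulting models are ranked later by their virtual leave-one-out score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.linalg

from .chem_graph import RootedDAG
from .gm_core import Architecture, GraphBatch, parameter_count


@dataclass
class TrainingSet:
    """Encoded molecules with their measured refractive indices."""

    dags: list[RootedDAG]
    y: np.ndarray
    arch: Architecture
    _batch: Optional[GraphBatch] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if len(self.dags) != self.y.size:
            raise ValueError("dags and y must have equal length")
        if self.y.size < 1:
            raise ValueError("training set must contain at least one example")

    @property
    def n_examples(self) -> int:
        return self.y.size

    @property
    def batch(self) -> GraphBatch:
        if self._batch is None:
            self._batch = GraphBatch(self.dags, self.arch)
        return self._batch

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        """y_i − g_i(θ)."""
        return self.y - self.batch.outputs(theta)

    def jacobian_of_residuals(self, theta: np.ndarray) -> np.ndarray:
        return -self.batch.jacobian(theta)


def cost(tset: TrainingSet, theta: np.ndarray) -> float:
    """Sum of squared errors J(θ); raises if any output is non-finite."""
    out = tset.batch.outputs(theta)
    bad = np.nonzero(~np.isfinite(out))[0]
    if bad.size:
        raise FloatingPointError(
            f"non-finite model output for example index {int(bad[0])}"
        )
    r = tset.y - out
    return float(r @ r)


def rmste(measured: Sequence[float], estimated: Sequence[float]) -> float:
    """Root mean square training error between two equal-length vectors."""
    m = np.asarray(measured, dtype=float)
    e = np.asarray(estimated, dtype=float)
    if m.size == 0:
        raise ValueError("rmste of empty input is undefined")
    if m.shape != e.shape:
        raise ValueError("measured and estimated must have equal length")
    return float(np.sqrt(np.mean((m - e) ** 2)))


@dataclass(frozen=True)
class LMOptions:
    """Levenberg–Marquardt schedule (declared defaults, see methods note)."""

    lambda0: float = 1e-3
    factor: float = 10.0
    gtol: float = 1e-6          # infinity norm of the cost gradient
    ftol: float = 1e-9          # relative decrease of J on an accepted step
    max_iter: int = 500
    lambda_max: float = 1e12


@dataclass
class LMResult:
    theta: np.ndarray
    cost: float
    converged: bool
    iterations: int
    cost_history: list[float] = field(default_factory=list)


def levenberg_marquardt(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    jacobian_fn: Callable[[np.ndarray], np.ndarray],
    theta0: np.ndarray,
    opts: LMOptions = LMOptions(),
    log: Optional[Callable[[str], None]] = None,
) -> LMResult:
    """Minimize ‖r(θ)‖² by damped Gauss–Newton steps.

    Steps solve (JᵀJ + λI) δ = −Jᵀr; λ is multiplied by ``opts.factor`` on
    rejection and divided by it on acceptance, so accepted steps never
    increase the cost.  Singular normal equations are handled by damping
    escalation (and a least-squares fallback), never by raising.
    """
    theta = np.asarray(theta0, dtype=float).copy()
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta0 must be finite")
    r = residual_fn(theta)
    c = float(r @ r)
    lam = opts.lambda0
    history = [c]
    converged = False
    it = 0
    while it < opts.max_iter:
        it += 1
        J = jacobian_fn(theta)
        g = J.T @ r  # gradient of J(θ)/2
        if np.max(np.abs(2.0 * g)) < opts.gtol:
            converged = True
            it -= 1
            break
        A = J.T @ J
        accepted = False
        while lam <= opts.lambda_max:
            M = A + lam * np.eye(A.shape[0])
            try:
                with warnings.catch_warnings():
                    # weight-sharing symmetries make JᵀJ nearly singular at
                    # small damping; escalation handles it
                    warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
                    delta = scipy.linalg.solve(M, -g, assume_a="pos")
            except (scipy.linalg.LinAlgError, ValueError):
                delta = np.linalg.lstsq(M, -g, rcond=None)[0]
            theta_new = theta + delta
            r_new = residual_fn(theta_new)
            c_new = float(r_new @ r_new)
            if np.isfinite(c_new) and c_new <= c:
                rel_drop = (c - c_new) / max(c, 1e-300)
                theta, r, c = theta_new, r_new, c_new
                lam = max(lam / opts.factor, 1e-15)
                accepted = True
                history.append(c)
                if log is not None:
                    log(f"iter={it} J={c:.6e} lambda={lam:.2e}")
                if rel_drop < opts.ftol:
                    converged = True
                break
            lam *= opts.factor
        if not accepted:
            break  # damping exhausted: stuck at a stationary-ish point
        if converged:
            break
    return LMResult(theta=theta, cost=c, converged=converged,
                    iterations=it, cost_history=history)


@dataclass
class TrainedModel:
    """One trained graph machine: θ_m with its training diagnostics."""

    theta: np.ndarray
    arch: Architecture
    residuals: np.ndarray
    rmste: float
    converged: bool
    seed: int
    iterations: int
    vloo: Optional[float] = None
    leverages: Optional[np.ndarray] = None

    @property
    def n_parameters(self) -> int:
        return parameter_count(self.arch)


def initialize_parameters(
    arch: Architecture, rng: np.random.Generator, scale: float = 0.3
) -> np.ndarray:
    """Uniform initialization on [−scale, scale], standard for tanh units."""
    return rng.uniform(-scale, scale, parameter_count(arch))


def train(
    tset: TrainingSet,
    theta0: np.ndarray,
    opts: LMOptions = LMOptions(),
    seed: int = -1,
    log: Optional[Callable[[str], None]] = None,
) -> TrainedModel:
    """Train one model from a given initialization."""
    res = levenberg_marquardt(
        tset.residuals, tset.jacobian_of_residuals, theta0, opts, log=log
    )
    r = tset.residuals(res.theta)
    return TrainedModel(
        theta=res.theta,
        arch=tset.arch,
        residuals=r,
        rmste=float(np.sqrt(res.cost / tset.n_examples)),
        converged=res.converged,
        seed=seed,
        iterations=res.iterations,
    )


def multistart_train(
    tset: TrainingSet,
    n_starts: int = 100,
    seed: int = 0,
    opts: LMOptions = LMOptions(),
    init_scale: float = 0.3,
) -> list[TrainedModel]:
    """Independently initialized full trainings, reproducible given seed.

    Each start draws its parameters from a sub-stream spawned from
    ``seed``, so the i-th model is identical no matter how many starts are
    requested.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_starts)
    models = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        theta0 = initialize_parameters(tset.arch, rng, init_scale)
        models.append(train(tset, theta0, opts, seed=i))
    return models
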