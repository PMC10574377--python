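"""Virtual leave-one-out model selection and ensemble prediction.

Retraining N_T times to compute an exact leave-one-out (LOO) score is
prohibitive, so generalization is estimated by the *virtual* LOO score:
the model is linearized at the trained parameters θ_m, the Jacobian
Z (∂g_i/∂θ) gives the hat-matrix diagonal ("leverages") h_i of the
linearized model, and each training residual is inflated into the
first-order LOO residual r_i / (1 − h_i):

    VLOO = sqrt( (1/N_T) Σ_i ( r_i / (1 − h_i) )² ).

For a model that is exactly linear in its parameters this is the PRESS
statistic and equals the exact LOO error; the test suite verifies that
identity by brute force.  Since 0 ≤ h_i ≤ 1, VLOO ≥ RMSTE always, and a
VLOO that keeps rising with model complexity signals overtraining.

The selection protocol trains ``n_starts`` models per complexity (number
of hidden neurons) for several independent initialization repetitions,
keeps the k models of smallest VLOO per repetition, and recommends the
most parsimonious complexity whose mean VLOO is within tolerance of the
floor.  Predictions average the kept models per repetition and then the
repetitions (the ensemble protocol).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem_graph import RootedDAG
from .gm_core import Architecture, GraphBatch, evaluate
from .training import LMOptions, TrainedModel, TrainingSet, multistart_train

#: 1 − h is clamped at this value when inflating residuals.
LEVERAGE_CLAMP = 1e-6

#: VLOO improvement below this between complexities counts as "the floor".
VLOO_FLOOR_TOL = 5e-4


@dataclass
class LeverageSet:
    """Hat-matrix diagonal of the model linearized at θ_m."""

    h: np.ndarray
    jacobian_rank: int


def leverages(Z: np.ndarray) -> LeverageSet:
    """Leverages from the Jacobian of model outputs w.r.t. θ.

    h_i is the squared norm of row i of an orthonormal basis of Z's column
    space, computed by rank-revealing SVD so that exact or near parameter
    redundancy (e.g. weight-sharing symmetries) is handled; Σ h_i equals
    the Jacobian rank and every h_i lies in [0, 1].
    """
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise FloatingPointError("non-finite Jacobian")
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    tol = s.max(initial=0.0) * max(Z.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    h = np.sum(U[:, :rank] ** 2, axis=1)
    return LeverageSet(h=np.clip(h, 0.0, 1.0), jacobian_rank=rank)


def virtual_residuals(
    residuals: np.ndarray, lev: LeverageSet, clamp: float = LEVERAGE_CLAMP
) -> tuple[np.ndarray, np.ndarray]:
    """First-order LOO residuals r_i/(1−h_i) and the clamped-example mask."""
    r = np.asarray(residuals, dtype=float)
    if r.size != lev.h.size:
        raise ValueError("residuals and leverages must have equal length")
    denom = 1.0 - lev.h
    clamped = denom < clamp
    return r / np.maximum(denom, clamp), clamped


def vloo_score(
    residuals: np.ndarray, lev: LeverageSet, clamp: float = LEVERAGE_CLAMP
) -> float:
    """Root-mean-square of the virtual LOO residuals (≥ RMSTE)."""
    vr, clamped = virtual_residuals(residuals, lev, clamp)
    if clamped.all():
        warnings.warn(
            "all examples hit the leverage clamp; VLOO score is unreliable",
            UserWarning,
            stacklevel=2,
        )
    return float(np.sqrt(np.mean(vr**2)))


def attach_vloo(model: TrainedModel, tset: TrainingSet) -> TrainedModel:
    """Compute and store leverages + VLOO for a trained model."""
    Z = tset.batch.jacobian(model.theta)
    lev = leverages(Z)
    model.leverages = lev.h
    model.vloo = vloo_score(model.residuals, lev)
    return model


@dataclass
class Ensemble:
    """Top-k-by-VLOO models of each initialization repetition."""

    members_by_rep: list[list[TrainedModel]]
    k: int

    @property
    def members(self) -> list[TrainedModel]:
        return [m for rep in self.members_by_rep for m in rep]


def top_k_by_vloo(models: Sequence[TrainedModel], k: int) -> list[TrainedModel]:
    scored = sorted(
        models, key=lambda m: (m.vloo if m.vloo is not None else np.inf)
    )
    return list(scored[:k])


def ensemble_predict(ens: Ensemble, dag: RootedDAG) -> float:
    """Mean over repetitions of the mean over that repetition's members."""
    if not ens.members:
        raise ValueError("empty ensemble")
    rep_means = []
    for rep in ens.members_by_rep:
        if not rep:
            continue
        rep_means.append(
            float(np.mean([evaluate(dag, m.theta, m.arch) for m in rep]))
        )
    return float(np.mean(rep_means))


def ensemble_predict_many(
    ens: Ensemble, dags: Sequence[RootedDAG]
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ensemble prediction; returns (means, member spreads)."""
    arch = ens.members[0].arch
    batch = GraphBatch(list(dags), arch)
    per_member = np.array([batch.outputs(m.theta) for m in ens.members])
    rep_means = []
    i = 0
    for rep in ens.members_by_rep:
        if rep:
            rep_means.append(per_member[i : i + len(rep)].mean(axis=0))
            i += len(rep)
    preds = np.mean(rep_means, axis=0)
    spread = per_member.max(axis=0) - per_member.min(axis=0)
    return preds, spread


@dataclass
class SelectionReport:
    """Per-complexity summary of the scan (one row per hidden-layer size).

    Columns mirror the selection protocol: means of RMSTE and VLOO over
    the k best-by-VLOO models of each repetition, and the means of the
    largest negative (MIN) and positive (MAX) training-set deviations of
    those models.  ``recommended`` is the most parsimonious complexity
    whose VLOO is within ``tol`` of the observed floor.
    """

    table: pd.DataFrame
    recommended: int
    tol: float
    models_by_complexity: dict[int, list[list[TrainedModel]]] = field(
        default_factory=dict, repr=False
    )

    def ensemble_for(self, n_hidden: int, k: Optional[int] = None) -> Ensemble:
        reps = self.models_by_complexity[n_hidden]
        k = k if k is not None else len(reps[0])
        return Ensemble(
            members_by_rep=[top_k_by_vloo(rep, k) for rep in reps], k=k
        )


def complexity_scan(
    tset_dags: Sequence[RootedDAG],
    y: Sequence[float],
    arch_template: Architecture,
    hidden_list: Sequence[int],
    n_starts: int = 100,
    k: int = 10,
    repetitions: int = 3,
    seed: int = 0,
    lm_opts: LMOptions = LMOptions(),
    tol: float = VLOO_FLOOR_TOL,
) -> SelectionReport:
    """Train over a grid of complexities and pick the parsimonious one.

    For every entry of ``hidden_list``, ``repetitions × n_starts`` full
    trainings are run (seeds derived deterministically from ``seed``); the
    report row averages the k smallest-VLOO models of each repetition.
    """
    if not hidden_list:
        raise ValueError("hidden_list must be nonempty")
    if k > n_starts:
        raise ValueError("k cannot exceed n_starts")
    rows = []
    models_by_complexity: dict[int, list[list[TrainedModel]]] = {}
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 ss.spawn(len(hidden_list) * repetitions)]
    si = 0
    for n_hidden in hidden_list:
        from dataclasses import replace as _replace

        arch = _replace(arch_template, n_hidden=n_hidden)
        reps: list[list[TrainedModel]] = []
        for _rep in range(repetitions):
            tset = TrainingSet(list(tset_dags), np.asarray(y, float), arch)
            models = multistart_train(
                tset, n_starts=n_starts, seed=rep_seeds[si], opts=lm_opts
            )
            si += 1
            for m in models:
                attach_vloo(m, tset)
            reps.append(models)
        models_by_complexity[n_hidden] = reps
        top = [top_k_by_vloo(r, k) for r in reps]
        rows.append(
            {
                "n_hidden": n_hidden,
                "rmste": float(np.mean([m.rmste for r in top for m in r])),
                "vloo": float(np.mean([m.vloo for r in top for m in r])),
                "min_dev": float(
                    np.mean([(-m.residuals).min() for r in top for m in r])
                ),
                "max_dev": float(
                    np.mean([(-m.residuals).max() for r in top for m in r])
                ),
            }
        )
    table = pd.DataFrame(rows)
    floor = table["vloo"].min()
    ok = table[table["vloo"] <= floor + tol]
    recommended = int(ok["n_hidden"].iloc[0])
    return SelectionReport(
        table=table,
        recommended=recommended,
        tol=tol,
        models_by_complexity=models_by_complexity,
    )
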