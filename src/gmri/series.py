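"""Homologous-series law for the refractive index.

Within a homologous series (members differing by N copies of a repeat
unit such as CH2, CF2 or Si(CH3)2O), additivity of polarizability and
molar volume in the Lorentz–Lorenz relation implies

    n(N) = sqrt( (n_repeat² · N + B) / (N + C) ),

where ``n_repeat`` is the refractive index of the infinite polymer of the
repeat unit and B, C are series constants: B/C is n² of the initial member
(N = 0) and n(N) → n_repeat as N → ∞.  n(N) is monotone in N, increasing
exactly when n_repeat² > B/C, and the whole series is constant when
B = n_repeat²·C.  The law serves both to validate experimental series and
as a closed-form check of the package's numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.optimize


class SeriesDomainError(ValueError):
    """The model parameters make n(N) undefined (negative radicand)."""


@dataclass(frozen=True)
class SeriesModel:
    """Fitted (n_repeat, B, C) of the homologous-series law."""

    n_repeat: float
    B: float
    C: float
    fixed_n_repeat: bool = False
    residual_norm: float = 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.n_repeat <= 1:
            raise ValueError("n_repeat must exceed 1 (denser than vacuum)")

    @property
    def n_at_zero(self) -> float:
        """n of the initial member, sqrt(B/C)."""
        return float(np.sqrt(self.B / self.C))

    @property
    def b_over_c(self) -> float:
        """B/C, the squared refractive index of the initial member."""
        return self.B / self.C


@dataclass(frozen=True)
class SeriesPoint:
    """One member of the series: repeat count N and measured n."""

    N: int
    n_obs: float

    def __post_init__(self) -> None:
        if self.N < 0:
            raise ValueError("N must be >= 0")
        if not 1.2 < self.n_obs < 2.0:
            raise ValueError(
                f"n_obs {self.n_obs} outside the 1.2–2.0 sanity window"
            )


def series_n(N, model: SeriesModel):
    """Evaluate n(N) = sqrt((n_repeat²·N + B)/(N + C)); scalar or array."""
    N = np.asarray(N, dtype=float)
    num = model.n_repeat**2 * N + model.B
    den = N + model.C
    if np.any(den <= 0) or np.any(num < 0):
        raise SeriesDomainError(
            f"n(N) undefined for N={N} with B={model.B}, C={model.C}"
        )
    out = np.sqrt(num / den)
    return float(out) if out.ndim == 0 else out


def _as_arrays(points: Sequence[SeriesPoint]):
    N = np.array([p.N for p in points], dtype=float)
    n = np.array([p.n_obs for p in points], dtype=float)
    return N, n


def fit_series(
    points: Sequence[SeriesPoint],
    fix_n_repeat: Optional[float] = None,
) -> SeriesModel:
    """Least-squares fit of the series law to (N, n) points, on n not n².

    With ``fix_n_repeat`` given (e.g. 1.476 for a CH2 repeat unit, the
    polyethylene value) only B and C vary and two distinct N values
    suffice; with n_repeat free at least three are required.  Initial
    values come from the exact linearization n²(N + C) = n_repeat²N + B,
    then a bounded nonlinear refinement minimizes the residuals on n.
    """
    Ns = sorted({p.N for p in points})
    need = 2 if fix_n_repeat is not None else 3
    if len(Ns) < need:
        raise ValueError(
            f"need at least {need} distinct N values, got {len(Ns)}"
        )
    N, n = _as_arrays(points)

    # Linear initialization: n²·N = n_repeat²·N + B − C·n²
    if fix_n_repeat is None:
        A = np.column_stack([N, np.ones_like(N), -(n**2)])
        sol, *_ = np.linalg.lstsq(A, n**2 * N, rcond=None)
        nrep2, B0, C0 = sol
        nrep0 = float(np.sqrt(max(nrep2, 1.0201)))  # keep n_repeat > 1.01
    else:
        nrep0 = float(fix_n_repeat)
        A = np.column_stack([np.ones_like(N), -(n**2)])
        sol, *_ = np.linalg.lstsq(A, n**2 * N - nrep0**2 * N, rcond=None)
        B0, C0 = sol
    B0 = float(max(B0, 1e-6))
    C0 = float(max(C0, 1e-6))

    def resid(p):
        if fix_n_repeat is None:
            nrep, B, C = p
        else:
            nrep = nrep0
            B, C = p
        num = nrep**2 * N + B
        den = N + C
        return np.sqrt(np.maximum(num, 0.0) / den) - n

    if fix_n_repeat is None:
        p0 = np.array([nrep0, B0, C0])
        lb = np.array([1.0 + 1e-9, 0.0, 1e-12])
        ub = np.array([np.inf, np.inf, np.inf])
    else:
        p0 = np.array([B0, C0])
        lb = np.array([0.0, 1e-12])
        ub = np.array([np.inf, np.inf])
    res = scipy.optimize.least_squares(
        resid, p0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    if fix_n_repeat is None:
        nrep, B, C = res.x
    else:
        nrep = nrep0
        B, C = res.x
    return SeriesModel(
        n_repeat=float(nrep),
        B=float(B),
        C=float(C),
        fixed_n_repeat=fix_n_repeat is not None,
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=bool(res.success),
    )
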