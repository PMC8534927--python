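"""Mean-field phase analysis of the multi-step exclusion process.

Factorizing site occupancies at bulk density rho gives the probability v_i of
a realized jump of exactly i sites (a jump of length i requires i empty sites
ahead, or a longer intended jump truncated by an occupied site):

    v4 = R4
    v3 = R4 rho + R3
    v2 = (R4 + R3) rho + R2
    v1 = (R4 + R3 + R2) rho + R1

and the bulk current

    J(rho) = rho * sum_{i=1..4} i v_i(rho) (1 - rho)^i .

The maximal-current (MC) bulk density rho_max is the interior maximizer of J.
The MC phase occupies alpha > alpha* and beta > beta* with

    beta*  = 1 - rho_max,
    alpha* = J(rho_max) / (1 - rho_max)
           = rho_max * sum_i i v_i(rho_max) (1 - rho_max)^{i-1},

the influx at which the entry-limited (LD) branch density reaches rho_max.
In the unit-step limit (R1 = r, R2 = R3 = R4 = 0) everything reduces to the
standard open TASEP: J = r rho (1 - rho), rho_max = 1/2, thresholds
(r/2, 1/2), which :func:`tasep_phase` provides as the reference phase map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .motor import MeanFieldRates, closed_form_rates
from .params import KineticsParams

__all__ = [
    "effective_velocities",
    "MeanFieldModel",
    "tasep_phase",
    "TasepReference",
]


def effective_velocities(rates: MeanFieldRates, rho) -> np.ndarray:
    """Density-dependent probabilities (v1, v2, v3, v4) of realized jump
    lengths 1..4 at bulk density rho (mean-field closure)."""
    rho = np.asarray(rho, dtype=float)
    if np.any((rho < 0) | (rho > 1)):
        raise ValueError("density must lie in [0, 1]")
    R1, R2, R3, R4 = rates.R1, rates.R2, rates.R3, rates.R4
    v4 = R4 * np.ones_like(rho)
    v3 = R4 * rho + R3
    v2 = (R4 + R3) * rho + R2
    v1 = (R4 + R3 + R2) * rho + R1
    return np.stack([v1, v2, v3, v4])


@dataclass
class MeanFieldModel:
    """Current-density relation J(rho) and MC-phase thresholds for one set of
    jump rates.  `px` scales all rates by the forward-direction probability
    (the transverse channel carries no stationary current); it rescales J but
    leaves rho_max unchanged."""

    rates: MeanFieldRates
    px: float = 1.0

    @classmethod
    def from_params(cls, params: KineticsParams, mode: str = "binomial",
                    include_px: bool = False) -> "MeanFieldModel":
        return cls(rates=closed_form_rates(params, mode=mode),
                   px=params.Px if include_px else 1.0)

    def current(self, rho) -> np.ndarray | float:
        """Bulk current J(rho), particles per bond per MCS."""
        rho_arr = np.asarray(rho, dtype=float)
        v = effective_velocities(self.rates, rho_arr)
        i = np.arange(1, 5).reshape((4,) + (1,) * rho_arr.ndim)
        J = self.px * rho_arr * np.sum(i * v * (1.0 - rho_arr) ** i, axis=0)
        return float(J) if np.isscalar(rho) or rho_arr.ndim == 0 else J

    def rho_max(self) -> float:
        """Interior maximizer of J on (0, 1): coarse bracket + bounded scalar
        minimization of -J to absolute tolerance well below 1e-6."""
        if self.rates.as_array().sum() <= 0.0:
            raise ValueError("degenerate rates: J is identically zero")
        grid = np.linspace(1e-4, 1 - 1e-4, 1001)
        k = int(np.argmax(self.current(grid)))
        lo, hi = grid[max(k - 2, 0)], grid[min(k + 2, len(grid) - 1)]
        res = minimize_scalar(lambda r: -self.current(r), bounds=(lo, hi),
                              method="bounded", options={"xatol": 1e-9})
        return float(res.x)

    def mc_thresholds(self) -> tuple[float, float]:
        """(alpha*, beta*) beyond which the stationary state is in the MC
        phase: alpha* = J(rho_max)/(1 - rho_max), beta* = 1 - rho_max."""
        rm = self.rho_max()
        return self.current(rm) / (1.0 - rm), 1.0 - rm


_COEX_TOL = 1e-9


def tasep_phase(alpha: float, beta: float, r: float) -> tuple[str, float, float]:
    """Reference phase map of the 1D open TASEP with hop rate r.

    Returns (label, bulk density, current).  Labels: "LD" (rho = alpha/r),
    "HD" (rho = 1 - beta), "MC" (rho = 1/2, J = r/4) and "coexistence" on the
    first-order line beta = alpha/r below r/2.
    """
    if not (0.0 <= alpha <= 1.0 and 0.0 <= beta <= 1.0):
        raise ValueError("alpha and beta must lie in [0, 1]")
    if r <= 0:
        raise ValueError("hop rate r must be positive")
    if abs(beta - alpha / r) <= _COEX_TOL and alpha < r / 2:
        rho = 0.5 * ((alpha / r) + (1 - beta))  # mixed state; mean of branches
        return "coexistence", rho, alpha * (1 - alpha / r)
    if alpha < beta * r and alpha < r / 2:
        return "LD", alpha / r, alpha * (1 - alpha / r)
    if beta * r < alpha and beta < 0.5:
        return "HD", 1 - beta, r * beta * (1 - beta)
    return "MC", 0.5, r / 4


@dataclass(frozen=True)
class TasepReference:
    """Convenience wrapper: the TASEP phase map at fixed hop rate r."""

    r: float

    def phase(self, alpha: float, beta: float) -> tuple[str, float, float]:
        return tasep_phase(alpha, beta, self.r)

    @property
    def j_max(self) -> float:
        return self.r / 4

    def coexistence_beta(self, alpha: float) -> float:
        return alpha / self.r
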