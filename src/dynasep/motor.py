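"""Internal ATP kinetics of a single motor and its jump-length rates.

A motor carries one primary (hydrolysis) binding site and three secondary
(load) sites.  Each MCS every site undergoes exactly one trial: an empty site
attaches ATP (Patt for the primary, Satt per secondary), an occupied site
detaches it (Pdet / Sdet); the two trials are mutually exclusive per site.
A motor with a fueled primary site intends to hop 4 - s steps, where s is the
number of occupied secondary sites, so heavy load (large s) means short steps.

The per-MCS probability R_i that an unobstructed motor performs a jump of
length i follows from stationarity of the site chains:

    R_i = p_occ * P(s = 4 - i),   p_occ = Patt / (Patt + Pdet),
    s ~ Binomial(3, Satt / (Satt + Sdet)),

because the three secondary chains are independent two-state processes.  This
binomial form is the authoritative rate source (mode="binomial").  A second
mode ("printed") evaluates the closed-form product formulas for R1, R2 and R4
published for this model; the published R3 is incomplete, so that entry always
falls back to the binomial expression (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ConfigError, KineticsParams

__all__ = [
    "MotorState",
    "MeanFieldRates",
    "update_internal_state",
    "intended_steps",
    "secondary_stationary_dist",
    "closed_form_rates",
]

MAX_STEP = 4  # longest jump; one step per ATP-free secondary site + 1


@dataclass
class MotorState:
    """ATP occupancy of one motor: primary site flag and secondary count s."""

    primary_occupied: bool = False
    s: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.s <= 3):
            raise ValueError(f"secondary count s must be in 0..3, got {self.s}")


@dataclass(frozen=True)
class MeanFieldRates:
    """Per-MCS probabilities of an unobstructed jump of length 1..4."""

    R1: float
    R2: float
    R3: float
    R4: float

    def __post_init__(self) -> None:
        for name in ("R1", "R2", "R3", "R4"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.R1, self.R2, self.R3, self.R4])


def update_internal_state(
    state: MotorState, params: KineticsParams, rng: np.random.Generator
) -> MotorState:
    """One MCS of attachment/detachment trials on all four binding sites.

    The primary site flips empty->occupied with probability Patt or
    occupied->empty with Pdet; each of the three secondary sites independently
    flips with Satt / Sdet.  Exactly one trial per site per call.
    """
    if state.primary_occupied:
        primary = rng.random() >= params.Pdet
    else:
        primary = rng.random() < params.Patt
    # s -> s - Binomial(s, Sdet) + Binomial(3 - s, Satt)
    s = state.s
    s -= int(rng.binomial(state.s, params.Sdet)) if state.s else 0
    s += int(rng.binomial(3 - state.s, params.Satt)) if state.s < 3 else 0
    return MotorState(primary_occupied=bool(primary), s=s)


def intended_steps(state: MotorState) -> int:
    """Intended jump length: 0 without primary ATP, else 4 - s."""
    return 0 if not state.primary_occupied else MAX_STEP - state.s


def secondary_stationary_dist(params: KineticsParams) -> np.ndarray:
    """Stationary distribution of the secondary count s in {0, 1, 2, 3}.

    With three independent attach/detach chains this is Binomial(3, p) with
    p = Satt / (Satt + Sdet).  Degenerate kinetics (Satt = Sdet = 0) freeze s
    and have no unique stationary law.
    """
    if params.Satt + params.Sdet <= 0.0:
        raise ConfigError(["Satt + Sdet = 0: secondary sites are frozen"])
    p = params.Satt / (params.Satt + params.Sdet)
    k = np.arange(4)
    from scipy.stats import binom

    dist = binom.pmf(k, 3, p)
    return dist / dist.sum()


def _printed_rates(params: KineticsParams) -> tuple[float, float, float]:
    """The published closed-form products for R4, R2, R1 (R3 is unavailable).

    R4 = Patt (1-Pdet) sum_{i=0..3} (Satt Sdet)^i (1-Satt)^{3-i}
    R2 = Patt (1-Pdet/4) Satt^2 (1-Sdet)^2 [ Satt Sdet + (1-Satt) ]
    R1 = Patt (1-Pdet) Satt^3 (1-Sdet)^3
    """
    Patt, Pdet, Satt, Sdet = params.Patt, params.Pdet, params.Satt, params.Sdet
    r4 = Patt * (1.0 - Pdet) * sum((Satt * Sdet) ** i * (1.0 - Satt) ** (3 - i) for i in range(4))
    r2 = Patt * (1.0 - Pdet / 4.0) * Satt**2 * (1.0 - Sdet) ** 2 * (Satt * Sdet + (1.0 - Satt))
    r1 = Patt * (1.0 - Pdet) * Satt**3 * (1.0 - Sdet) ** 3
    return r4, r2, r1


def closed_form_rates(params: KineticsParams, mode: str = "binomial") -> MeanFieldRates:
    """Unobstructed jump rates R1..R4 for the given kinetics.

    mode="binomial" (default, authoritative): R_i = p_occ * P(s = 4 - i) with
    the binomial stationary law of the secondary sites.
    mode="printed": the published product formulas for R1, R2, R4, kept as a
    cross-check; R3 is always taken from the binomial form because its
    published expression is incomplete.
    """
    if mode not in ("binomial", "printed"):
        raise ValueError(f"mode must be 'binomial' or 'printed', got {mode!r}")
    p_occ = params.hop_ready_prob
    dist = secondary_stationary_dist(params)  # index = s
    binomial = [p_occ * dist[MAX_STEP - i] for i in range(1, 5)]  # R1..R4
    if mode == "binomial":
        r1, r2, r3, r4 = binomial
    else:
        r4, r2, r1 = _printed_rates(params)
        r3 = binomial[2]
    return MeanFieldRates(R1=float(np.clip(r1, 0, 1)), R2=float(np.clip(r2, 0, 1)),
                          R3=float(np.clip(r3, 0, 1)), R4=float(np.clip(r4, 0, 1)))
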