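"""Phase classification and (alpha, beta) phase-diagram scans.

The stationary phases are defined by which boundary controls the bulk:
entry-limited LD (bulk density tracks alpha), exit-limited HD (bulk density
pinned at 1 - beta, insensitive to alpha), bulk-limited MC (density at the
mean-field current maximizer rho_max, insensitive to both rates), and the
first-order LD/HD coexistence where a domain wall separates the branches.
Classification is perturbative: besides the central run, probe runs at
alpha +/- delta and beta +/- delta decide which boundary the bulk listens
to.  Tolerances: a density "matches" a reference within 0.02 plus 3 block
standard errors; stationarity requires the first- and second-half window
densities to agree within 2 combined standard errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .engine import run
from .meanfield import MeanFieldModel
from .observables import bulk_slice, measure_current, measure_density
from .params import BoundaryRates, RunConfig

__all__ = [
    "PhasePoint",
    "TransitionResult",
    "classify_phase",
    "locate_transition",
    "scan_grid",
    "mc_onset_from_sweep",
]

MATCH_TOL = 0.02     # absolute density tolerance (plus 3 SE)
PROBE_DELTA = 0.05   # boundary-rate perturbation for the probe runs


@dataclass
class PhasePoint:
    alpha: float
    beta: float
    density: float
    density_se: float
    current: float
    current_se: float
    label: str                      # LD / HD / MC / coexistence / unclassified
    evidence: dict = field(default_factory=dict)


@dataclass
class TransitionResult:
    alpha_c: float
    uncertainty: float
    density_jump: float
    alphas: np.ndarray
    densities: np.ndarray
    currents: np.ndarray


def _bulk(config: RunConfig) -> tuple[float, float, float, float, bool, np.ndarray]:
    """Run and reduce: bulk density +- SE, current +- SE, stationarity flag,
    profile."""
    res = run(config)
    prof = measure_density(res)
    cur = measure_current(res)
    # stationarity: first vs second half of the sampling blocks
    nb = res.n_blocks
    sl = bulk_slice(res.Lx)
    bm = res.dens[:, :, sl].mean(axis=(1, 2)) / _block_len(res.sampling, nb)
    h1, h2 = bm[: nb // 2], bm[nb // 2:]
    se = np.hypot(h1.std(ddof=1) / np.sqrt(len(h1)), h2.std(ddof=1) / np.sqrt(len(h2)))
    # absolute floor: block means are autocorrelated, so the bare SE
    # underestimates the drift scale in very quiet (deep-phase) states
    stationary = abs(h1.mean() - h2.mean()) <= 2.0 * se + MATCH_TOL / 4
    return prof.bulk, prof.bulk_se, cur.mean, cur.se, stationary, prof.rho


def _block_len(sampling: int, nb: int) -> np.ndarray:
    return np.bincount((np.arange(sampling) * nb) // sampling, minlength=nb).astype(float)


def _probe_rates(value: float, delta: float) -> float:
    """Perturbed boundary rate, stepping away from the nearer limit."""
    return value + delta if value + delta <= 1.0 else value - delta


def classify_phase(alpha: float, beta: float, config: RunConfig,
                   model: Optional[MeanFieldModel] = None,
                   delta: float = PROBE_DELTA, tol: float = MATCH_TOL) -> PhasePoint:
    """Classify the stationary phase at (alpha, beta) from simulation.

    `config` supplies geometry, kinetics and run control; its boundary rates
    are overridden.  A mean-field model (for rho_max) is built from the
    config kinetics when not supplied.  Ambiguous evidence yields the label
    "unclassified" — never a forced phase.
    """
    if model is None:
        model = MeanFieldModel.from_params(config.kinetics)
    rho_max = model.rho_max()
    base = config.replace(boundary=BoundaryRates(alpha, beta))
    rho, rho_se, J, J_se, stat, profile = _bulk(base)
    a_p = _probe_rates(alpha, delta)
    b_p = _probe_rates(beta, delta)
    rho_a, se_a, *_ = _bulk(base.replace(boundary=BoundaryRates(a_p, beta),
                                         seed=config.seed + 104729))
    rho_b, se_b, *_ = _bulk(base.replace(boundary=BoundaryRates(alpha, b_p),
                                         seed=config.seed + 1299709))

    def match(x, y, sx, sy):
        return abs(x - y) <= tol + 3.0 * float(np.hypot(sx, sy))

    a_sensitive = not match(rho_a, rho, se_a, rho_se)
    b_sensitive = not match(rho_b, rho, se_b, rho_se)
    evidence = {
        "stationary": bool(stat),
        "alpha_probe": a_p, "beta_probe": b_p,
        "rho": rho, "rho_alpha_probe": rho_a, "rho_beta_probe": rho_b,
        "alpha_sensitive": bool(a_sensitive), "beta_sensitive": bool(b_sensitive),
        "rho_max_mf": rho_max,
        "matches_hd": match(rho, 1.0 - beta, rho_se, 0.0),
        "matches_mc": match(rho, rho_max, rho_se, 0.0),
    }
    sl = bulk_slice(len(profile))
    spread = float(profile[sl].max() - profile[sl].min())
    evidence["bulk_spread"] = spread
    # density rise across the middle half: a bulk profile that climbs from
    # entry towards exit is a domain-wall (LD|HD) mixture — pure phases are
    # flat (LD, HD) or falling (MC tangent profile)
    x = np.arange(len(profile))[sl]
    rise = float(np.polyfit(x, profile[sl], 1)[0] * (x[-1] - x[0]))
    evidence["bulk_rise"] = rise

    if not stat:
        label = "unclassified"
    elif rise > 2 * tol:
        label = "coexistence"
    elif b_sensitive and not a_sensitive and evidence["matches_hd"]:
        label = "HD"
    elif a_sensitive and not b_sensitive:
        label = "LD"
    elif not a_sensitive and not b_sensitive and evidence["matches_mc"]:
        label = "MC"
    elif a_sensitive and b_sensitive:
        # both boundaries move the bulk: a wandering domain wall does that
        label = "coexistence" if spread > 2 * tol else "unclassified"
    elif not a_sensitive and not b_sensitive and evidence["matches_hd"]:
        # deep HD: the alpha probe may be too small to register
        label = "HD"
    else:
        label = "unclassified"
    return PhasePoint(alpha=alpha, beta=beta, density=rho, density_se=rho_se,
                      current=J, current_se=J_se, label=label, evidence=evidence)


def locate_transition(beta: float, alphas: Sequence[float], config: RunConfig,
                      refine: int = 3, min_jump: float = 0.1) -> TransitionResult:
    """Locate the first-order LD/HD transition along an alpha sweep at fixed
    beta: largest bulk-density increment between adjacent sweep points,
    refined by bisection.  Raises if no increment exceeds `min_jump`
    (sweep does not bracket the transition)."""
    alphas = np.asarray(sorted(alphas), dtype=float)
    if len(alphas) < 2:
        raise ValueError("need at least two sweep points")
    dens, curs = [], []
    for i, a in enumerate(alphas):
        r, _, J, _, _, _ = _bulk(config.replace(
            boundary=BoundaryRates(float(a), beta), seed=config.seed + 7 * i))
        dens.append(r)
        curs.append(J)
    dens_arr, curs_arr = np.array(dens), np.array(curs)
    jumps = np.diff(dens_arr)
    k = int(np.argmax(jumps))
    if jumps[k] < min_jump:
        raise ValueError(
            f"no density jump > {min_jump} found along the sweep "
            f"(max increment {jumps[k]:.3f}); the transition is not bracketed")
    lo, hi = alphas[k], alphas[k + 1]
    rho_lo, rho_hi = dens_arr[k], dens_arr[k + 1]
    for j in range(refine):
        mid = 0.5 * (lo + hi)
        r, _, _, _, _, _ = _bulk(config.replace(
            boundary=BoundaryRates(mid, beta), seed=config.seed + 1013 * (j + 1)))
        if abs(r - rho_lo) < abs(r - rho_hi):
            lo = mid
        else:
            hi = mid
    return TransitionResult(alpha_c=0.5 * (lo + hi), uncertainty=0.5 * (hi - lo),
                            density_jump=float(rho_hi - rho_lo),
                            alphas=alphas, densities=dens_arr, currents=curs_arr)


def scan_grid(alphas: Sequence[float], betas: Sequence[float], config: RunConfig,
              model: Optional[MeanFieldModel] = None,
              cache_dir: Optional[str | Path] = None) -> pd.DataFrame:
    """classify_phase on every (alpha, beta) grid node.

    Node seeds derive deterministically from the config seed and the node
    index.  With `cache_dir`, completed nodes are stored as JSON and reused,
    so an interrupted scan resumes.  Individual node failures are recorded
    (label "error") and the scan continues.
    """
    if model is None:
        model = MeanFieldModel.from_params(config.kinetics)
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, a in enumerate(alphas):
        for j, b in enumerate(betas):
            key = f"node_a{a:.4f}_b{b:.4f}.json"
            if cache and (cache / key).exists():
                rows.append(json.loads((cache / key).read_text()))
                continue
            node_cfg = config.replace(seed=config.seed + 15485863 * (i * len(betas) + j + 1))
            try:
                p = classify_phase(float(a), float(b), node_cfg, model=model)
                row = {"alpha": p.alpha, "beta": p.beta, "density": p.density,
                       "density_se": p.density_se, "current": p.current,
                       "current_se": p.current_se, "label": p.label}
            except Exception as err:  # noqa: BLE001 - record and continue
                row = {"alpha": float(a), "beta": float(b), "density": np.nan,
                       "density_se": np.nan, "current": np.nan,
                       "current_se": np.nan, "label": "error", "error": str(err)}
            if cache:
                (cache / key).write_text(json.dumps(row))
            rows.append(row)
    return pd.DataFrame(rows)


def mc_onset_from_sweep(alphas: Sequence[float], densities: Sequence[float],
                        ses: Sequence[float], tol: float = MATCH_TOL) -> float:
    """Smallest alpha beyond which the bulk density stops tracking alpha.

    Adjacent sweep points are compared; an increment within tol + 3 combined
    SE counts as flat.  Returns the left edge of the first flat increment
    after which every later increment is also flat.  Raises if the density
    still tracks alpha at the end of the sweep.
    """
    alphas = np.asarray(alphas, float)
    d = np.asarray(densities, float)
    s = np.asarray(ses, float)
    inc = np.abs(np.diff(d))
    thr = tol + 3.0 * np.hypot(s[:-1], s[1:])
    flat = inc <= thr
    for k in range(len(flat)):
        if flat[k:].all():
            return float(alphas[k])
    raise ValueError("bulk density tracks alpha over the whole sweep; "
                     "no maximal-current onset inside the range")
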