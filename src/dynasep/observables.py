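"""Measurement layer: density profiles, currents, jump statistics, tagged
trajectories, MSD and dwell-time fits.

All functions consume the block-resolved accumulators of
:class:`dynasep.engine.RunResult`; statistical errors are block standard
errors (the sampling window is split into `n_blocks` equal blocks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .engine import RunResult
from .params import LatticeConfig

__all__ = [
    "DensityProfile",
    "CurrentRecord",
    "JumpHistogram",
    "TaggedTrajectory",
    "MSDCurve",
    "MSDFit",
    "DwellHistogram",
    "ProfileFit",
    "measure_density",
    "measure_current",
    "jump_histogram",
    "default_tag_times",
    "tag_particles",
    "msd",
    "fit_msd",
    "dwell_statistics",
    "fit_profile",
    "oscillation_period",
]


def _block_lengths(sampling: int, n_blocks: int) -> np.ndarray:
    return np.bincount((np.arange(sampling) * n_blocks) // sampling, minlength=n_blocks)


# ---------------------------------------------------------------------------
# density
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Time-averaged occupancy per column (and per lane)."""

    x: np.ndarray          # 1-based column index
    rho: np.ndarray        # lane-averaged occupancy per column
    rho_se: np.ndarray     # block standard error per column
    rho_lane: np.ndarray   # (Ly, Lx) per-lane occupancy
    bulk: float            # mean over the middle half of the columns
    bulk_se: float
    window: tuple[int, int]  # (start MCS, end MCS) of the sampling window

    @property
    def Lx(self) -> int:
        return len(self.x)


def bulk_slice(Lx: int) -> slice:
    """Middle 50% of the columns (the bulk-density estimator window)."""
    return slice(Lx // 4, Lx - Lx // 4)


def measure_density(result: RunResult, warmup: Optional[int] = None) -> DensityProfile:
    """Stationary density profile from a run.

    `warmup` (MCS from the start of the run) defaults to the run's configured
    warmup; a larger value additionally discards leading sampling blocks.
    """
    cfg = result.config
    total = cfg.warmup + result.sampling
    if warmup is None:
        warmup = cfg.warmup
    if warmup >= total:
        raise ValueError(f"warmup {warmup} >= run length {total}")
    if warmup < cfg.warmup:
        raise ValueError(f"warmup {warmup} below the already-discarded {cfg.warmup}")
    nb = result.n_blocks
    blen = _block_lengths(result.sampling, nb)
    bstart = cfg.warmup + np.concatenate([[0], np.cumsum(blen)[:-1]])
    keep = bstart >= warmup if warmup > cfg.warmup else np.ones(nb, bool)
    if not keep.any():
        raise ValueError("warmup discards the entire sampling window")
    dens = result.dens[keep]
    blen = blen[keep]
    T = blen.sum()
    rho_lane = dens.sum(axis=0) / T
    rho = rho_lane.mean(axis=0)
    # per-column block means -> standard error
    bm = dens.mean(axis=1) / blen[:, None]  # (nb_kept, Lx)
    nb_k = keep.sum()
    rho_se = bm.std(axis=0, ddof=1) / np.sqrt(nb_k) if nb_k > 1 else np.full(rho.shape, np.nan)
    sl = bulk_slice(rho.size)
    bulk_blocks = bm[:, sl].mean(axis=1)
    bulk_se = bulk_blocks.std(ddof=1) / np.sqrt(nb_k) if nb_k > 1 else float("nan")
    return DensityProfile(
        x=np.arange(1, rho.size + 1),
        rho=rho, rho_se=rho_se, rho_lane=rho_lane,
        bulk=float(rho[sl].mean()), bulk_se=float(bulk_se),
        window=(int(warmup), int(total)),
    )


# ---------------------------------------------------------------------------
# current
# ---------------------------------------------------------------------------

@dataclass
class CurrentRecord:
    """Bond-resolved longitudinal current and the transverse analogue.

    Currents are particles per bond per lane per MCS.  Bond index 0 is the
    entry bond, Lx the exit bond, 1..Lx-1 the interior bonds.  For ring
    (periodic) runs the interior average comes from the total forward
    displacement instead.
    """

    bond_rates: np.ndarray
    mean: float
    se: float
    entry_rate: float
    exit_rate: float
    transverse: float      # net signed crossings per transverse bond per MCS
    transverse_se: float
    transverse_abs: float  # activity: |crossings| per transverse bond per MCS


def measure_current(result: RunResult, warmup: Optional[int] = None) -> CurrentRecord:
    cfg = result.config
    Ly, Lx = result.Ly, result.Lx
    nb = result.n_blocks
    blen = _block_lengths(result.sampling, nb).astype(float)
    T = result.sampling
    if result.config.periodic:
        per_block = result.fwd_disp / (blen * Lx * Ly)
        bond_rates = np.full(Lx + 1, np.nan)
    else:
        per_block = result.bond[:, 1:-1].mean(axis=1) / (blen * Ly)
        bond_rates = result.bond.sum(axis=0) / (T * Ly)
    mean = float(per_block @ blen / blen.sum())
    se = float(per_block.std(ddof=1) / np.sqrt(nb)) if nb > 1 else float("nan")
    n_tb = Lx * Ly  # transverse ring bonds
    tr_block = result.trans_net / (blen * n_tb)
    tr = float(tr_block @ blen / blen.sum())
    tr_se = float(tr_block.std(ddof=1) / np.sqrt(nb)) if nb > 1 else float("nan")
    return CurrentRecord(
        bond_rates=bond_rates, mean=mean, se=se,
        entry_rate=float(result.inj_b.sum() / (T * Ly)),
        exit_rate=float(result.ext_b.sum() / (T * Ly)),
        transverse=tr, transverse_se=tr_se,
        transverse_abs=float(result.trans_abs.sum() / (T * n_tb)),
    )


# ---------------------------------------------------------------------------
# jump statistics
# ---------------------------------------------------------------------------

@dataclass
class JumpHistogram:
    """Counts of realized displacements 1..4 over the sampling window."""

    forward: np.ndarray   # index = displacement (0 unused)
    transverse: np.ndarray
    exits: np.ndarray     # exit displacements (sites traversed incl. exit bond)
    blocked: int          # fueled attempts with zero realized displacement
    window_mcs: int
    Ly: int

    @property
    def total_crossings(self) -> int:
        """In-lattice longitudinal bond crossings implied by the histogram
        (bookkeeping identity with the bond counters, exact per seed)."""
        d = np.arange(5)
        return int((d * self.forward).sum() + (d * self.exits).sum())

    def probabilities(self, which: str = "forward") -> np.ndarray:
        h = getattr(self, which)[1:]
        return h / h.sum() if h.sum() else np.zeros(4)


def jump_histogram(result: RunResult) -> JumpHistogram:
    return JumpHistogram(
        forward=result.hist_x.copy(), transverse=result.hist_y.copy(),
        exits=result.hist_exit.copy(), blocked=result.blocked,
        window_mcs=result.sampling, Ly=result.Ly,
    )


# ---------------------------------------------------------------------------
# tagged particles
# ---------------------------------------------------------------------------

@dataclass
class TaggedTrajectory:
    """Displacement history of one tagged particle, clocked from its entry.

    dx/dy hold the cumulative longitudinal / unwrapped-transverse
    displacement after 1, 2, ... sweeps since entry; values freeze at the
    final displacement once the particle exits.
    """

    label: str
    uid: int
    entry_time: int
    exit_time: int  # -1 while on the lattice at the end of the run
    threshold: int
    dx: np.ndarray
    dy: np.ndarray

    def displacement(self, axis: str) -> np.ndarray:
        if axis not in ("longitudinal", "transverse"):
            raise ValueError("axis must be 'longitudinal' or 'transverse'")
        return self.dx if axis == "longitudinal" else self.dy

    def jump_times(self) -> np.ndarray:
        """Sweeps (since entry, 1-based) in which a realized jump occurred.
        Multiple jumps within one sweep register as one (1-MCS resolution)."""
        dx = np.concatenate([[0], self.dx])
        dy = np.concatenate([[0], self.dy])
        moved = (np.diff(dx) != 0) | (np.diff(dy) != 0)
        return np.nonzero(moved)[0] + 1

    def dwell_intervals(self) -> np.ndarray:
        """Waiting times (MCS) between consecutive realized jumps."""
        jt = self.jump_times()
        return np.diff(jt)


def default_tag_times(lattice: LatticeConfig, c_B: float = 1.0, c_C: float = 1.0
                      ) -> tuple[int, int, int]:
    """Entry-time thresholds for the canonical particle classes: A = first
    entrant, B = first entrant after c_B*Lx MCS, C = first after c_C*Lx^2."""
    return (0, int(c_B * lattice.Lx), int(c_C * lattice.Lx**2))


def tag_particles(result: RunResult, labels: Optional[Sequence[str]] = None
                  ) -> list[TaggedTrajectory]:
    """Extract the tagged trajectories recorded during a run.

    Tags whose threshold was never reached by an entering particle are
    dropped with a warning.  Default labels are A, B, C, ... in threshold
    order (the run's tag_times order).
    """
    K = len(result.tag_t)
    if labels is None:
        labels = [chr(ord("A") + k) if k < 26 else f"tag{k}" for k in range(K)]
    total = result.config.warmup + result.sampling
    out = []
    for k in range(K):
        if result.tag_uid[k] < 0:
            warnings.warn(
                f"tag {labels[k]} (threshold {int(result.tag_t[k])} MCS): "
                "no particle entered after the threshold; class empty",
                stacklevel=2,
            )
            continue
        n_rec = min(result.traj_x.shape[1], total - int(result.tag_entry[k]))
        if n_rec <= 0:
            continue
        out.append(TaggedTrajectory(
            label=labels[k], uid=int(result.tag_uid[k]),
            entry_time=int(result.tag_entry[k]), exit_time=int(result.tag_exit[k]),
            threshold=int(result.tag_t[k]),
            dx=result.traj_x[k, :n_rec].copy(), dy=result.traj_y[k, :n_rec].copy(),
        ))
    return out


# ---------------------------------------------------------------------------
# mean-square displacement
# ---------------------------------------------------------------------------

@dataclass
class MSDCurve:
    t: np.ndarray     # sweeps since entry
    msd: np.ndarray
    n: np.ndarray     # trajectories contributing at each t
    axis: str


@dataclass
class MSDFit:
    exponent: float
    stderr: float
    amplitude: float
    log_correction: bool   # model t^xi / ln t instead of pure t^xi
    window: tuple[float, float]


MIN_FIT_REALIZATIONS = 100
MIN_FIT_DECADES = 1.5


def msd(trajectories: Iterable[TaggedTrajectory], axis: str = "longitudinal") -> MSDCurve:
    """Ensemble MSD versus time since entry.

    Each trajectory is one independent realization (average over runs, not
    over particles within a run).  Displacements freeze at exit, so the MSD
    of an open finite track saturates once typical particles have traversed
    it."""
    trajs = list(trajectories)
    if not trajs:
        raise ValueError("no trajectories supplied")
    tmax = max(len(tr.dx) for tr in trajs)
    s = np.zeros(tmax)
    n = np.zeros(tmax, dtype=int)
    for tr in trajs:
        d = tr.displacement(axis).astype(float)
        s[: len(d)] += d * d
        n[: len(d)] += 1
    ok = n > 0
    return MSDCurve(t=np.arange(1, tmax + 1)[ok], msd=s[ok] / n[ok], n=n[ok], axis=axis)


def fit_msd(curve: MSDCurve, t_min: float, t_max: float,
            log_correction: bool = True, n_points: int = 60) -> MSDFit:
    """Least-squares power-law fit of the MSD over [t_min, t_max].

    The window must span at least 1.5 decades; sampling is uniform in log t
    so late times are not over-weighted.  With log_correction the model is
    MSD = A t^xi / ln t (ln t > 0 requires t_min > 1), otherwise A t^xi.
    """
    if t_max / t_min < 10**MIN_FIT_DECADES * (1 - 1e-9):
        raise ValueError(
            f"fit window [{t_min}, {t_max}] spans less than {MIN_FIT_DECADES} decades")
    if int(np.min(curve.n[(curve.t >= t_min) & (curve.t <= t_max)])) < MIN_FIT_REALIZATIONS:
        raise ValueError(
            f"fewer than {MIN_FIT_REALIZATIONS} realizations in the fit window")
    tp = np.unique(np.round(np.geomspace(max(t_min, 2.0), t_max, n_points)).astype(int))
    mask = np.isin(curve.t, tp) & (curve.msd > 0)
    t = curve.t[mask].astype(float)
    y = np.log(curve.msd[mask])
    if log_correction:
        y = y + np.log(np.log(t))
    X = np.vstack([np.log(t), np.ones_like(t)]).T
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    xi, loga = coef
    dof = len(t) - 2
    if dof > 0 and len(res):
        s2 = res[0] / dof
        cov = s2 * np.linalg.inv(X.T @ X)
        se = float(np.sqrt(cov[0, 0]))
    else:
        se = float("nan")
    return MSDFit(exponent=float(xi), stderr=se, amplitude=float(np.exp(loga)),
                  log_correction=log_correction, window=(t_min, t_max))


# ---------------------------------------------------------------------------
# dwell times
# ---------------------------------------------------------------------------

@dataclass
class DwellHistogram:
    """Inter-jump waiting-time statistics and their geometric-law fits.

    Waiting times are integer MCS; fits use the discrete (geometric)
    likelihood, P(k) = p (1-p)^(k-1), but decay rates are reported as the
    continuous-exponential analogue lambda = -ln(1 - p).  The double model is
    a two-component geometric mixture fitted by EM.
    """

    intervals: np.ndarray
    counts: np.ndarray           # histogram over waiting time (index = MCS)
    model: Optional[str]         # "single", "double", or None (histogram only)
    single: dict = field(default_factory=dict)
    double: dict = field(default_factory=dict)
    aic: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.intervals)


MIN_DWELL_INTERVALS = 500


def _geom_loglik(k: np.ndarray, p: float) -> float:
    return float(len(k) * np.log(p) + (k - 1).sum() * np.log1p(-p))


def _fit_geometric(k: np.ndarray) -> dict:
    p = min(1.0 / k.mean(), 1.0 - 1e-12)  # all-ones samples stay finite
    return {"p": p, "rate": -np.log1p(-p), "loglik": _geom_loglik(k, p)}


def _fit_double_geometric(k: np.ndarray) -> dict:
    """MLE of the signed two-component geometric law

        P(j) = w_f Geom(p_f)(j) + w_s Geom(p_s)(j),  w_f + w_s = 1,

    with p_f > p_s (fast/slow) and w_f allowed to be NEGATIVE, in which case
    short waiting times are suppressed (the motor must re-fuel and its gap
    must reopen after a jump) — the discrete analogue of the double
    exponential with signed amplitudes seen in congested dwell data.  The
    minimum of the pmf over j sits at j = 1 whenever w_f < 0, so positivity
    of P(1) suffices for a valid law.
    """
    from scipy.optimize import minimize

    counts = np.bincount(k.astype(int))
    js = np.nonzero(counts)[0].astype(float)
    cs = counts[np.nonzero(counts)].astype(float)

    # |weights| capped at 50: the physically relevant fits have O(1)
    # amplitudes, and an unbounded weight with p_f -> p_s degenerates into a
    # numerically ill-conditioned derivative family
    def unpack(x):
        pf = 1.0 / (1.0 + np.exp(-x[0]))
        ps = pf / (1.0 + np.exp(-x[1]))
        ws = np.exp(np.clip(x[2], -30.0, np.log(50.0)))
        return pf, ps, 1.0 - ws, ws  # pf, ps, wf, ws

    def nll(x):
        pf, ps, wf, ws = unpack(x)
        if ps >= pf or ps <= 1e-9 or pf >= 1 - 1e-12:
            return 1e12
        p1 = wf * pf + ws * ps
        if p1 <= 1e-12:
            return 1e12
        pm = wf * pf * (1 - pf) ** (js - 1) + ws * ps * (1 - ps) ** (js - 1)
        if np.any(pm <= 0):
            return 1e12
        return -float(cs @ np.log(pm))

    m = k.mean()
    p0 = min(1.0 / m, 0.95)
    starts = [
        # positive mixture (fast head + slow tail)
        np.array([np.log(3 * p0 / (1 - min(3 * p0, 0.94))), 2.0, np.log(0.6)]),
        # suppressed head (w_f = -1, mirroring the signed published fit)
        np.array([np.log(3 * p0 / (1 - min(3 * p0, 0.94))), 2.0, np.log(2.0)]),
        # near-single
        np.array([np.log(p0 / (1 - p0)) + 0.5, 4.0, np.log(1.05)]),
    ]
    best = None
    for x0 in starts:
        r = minimize(nll, x0, method="Nelder-Mead",
                     options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        if best is None or r.fun < best.fun:
            best = r
    pf, ps, wf, ws = unpack(best.x)
    return {"w_fast": wf, "w_slow": ws, "p_fast": pf, "p_slow": ps,
            "rate_fast": -np.log1p(-pf), "rate_slow": -np.log1p(-ps),
            "loglik": -float(best.fun)}


def dwell_statistics(source, model: str = "auto",
                     min_intervals: int = MIN_DWELL_INTERVALS) -> DwellHistogram:
    """Waiting-time histogram plus maximum-likelihood model fit.

    `source` is either an iterable of TaggedTrajectory or an array of integer
    waiting times.  model: "single", "double", or "auto" (selection by AIC).
    With fewer than `min_intervals` waiting times only the histogram is
    returned (model None).
    """
    if model not in ("single", "double", "auto"):
        raise ValueError("model must be 'single', 'double' or 'auto'")
    if hasattr(source, "__iter__") and not isinstance(source, np.ndarray):
        src = list(source)
        if src and isinstance(src[0], TaggedTrajectory):
            parts = [tr.dwell_intervals() for tr in src]
            intervals = np.concatenate(parts) if parts else np.zeros(0, int)
        else:
            intervals = np.asarray(src, dtype=int)
    else:
        intervals = np.asarray(source, dtype=int)
    if len(intervals) and intervals.min() < 1:
        raise ValueError("waiting times must be >= 1 MCS")
    counts = np.bincount(intervals) if len(intervals) else np.zeros(1, int)
    if len(intervals) < min_intervals:
        warnings.warn(
            f"only {len(intervals)} waiting times (< {min_intervals}): "
            "returning histogram without a fit", stacklevel=2)
        return DwellHistogram(intervals=intervals, counts=counts, model=None)
    k = intervals.astype(float)
    single = _fit_geometric(k)
    double = _fit_double_geometric(k)
    n = len(k)
    ic = {
        "aic_single": 2 * 1 - 2 * single["loglik"],
        "aic_double": 2 * 3 - 2 * double["loglik"],
        "bic_single": np.log(n) * 1 - 2 * single["loglik"],
        "bic_double": np.log(n) * 3 - 2 * double["loglik"],
    }
    if model == "auto":  # BIC: conservative information criterion
        chosen = "single" if ic["bic_single"] <= ic["bic_double"] else "double"
    else:
        chosen = model
    return DwellHistogram(intervals=intervals, counts=counts, model=chosen,
                          single=single, double=double, aic=ic)


# ---------------------------------------------------------------------------
# profile fits
# ---------------------------------------------------------------------------

@dataclass
class ProfileFit:
    model: str
    params: dict
    perr: dict
    rss: float
    linear_rss: float
    n_points: int


def _tangent(u, a, q, u0):
    return a * (1.0 - q * np.tan(q * (u - u0)))


def _tanh_wall(u, c0, c1, u0, w):
    return c0 + c1 * np.tanh((u - u0) / w)


def fit_profile(profile: DensityProfile, phase: str = "MC",
                exclude: float = 0.1) -> ProfileFit:
    """Least-squares fit of the bulk density profile.

    phase="MC": rho(u) = rho_m (1 - q tan[q (u - u0)]) on the normalized
    coordinate u = (x - 1/2)/Lx; phase="coexistence": a tanh domain-wall
    profile c0 + c1 tanh[(u - u0)/w].  `exclude` trims that fraction of
    columns at each boundary.  Raises RuntimeError (with diagnostics) on
    non-convergence; a flat profile is fine (q -> 0).
    """
    Lx = profile.Lx
    cut = int(round(exclude * Lx))
    sl = slice(cut, Lx - cut)
    u = (profile.x[sl] - 0.5) / Lx
    y = profile.rho[sl]
    lin = np.polyfit(u, y, 1)
    linear_rss = float(((np.polyval(lin, u) - y) ** 2).sum())
    try:
        if phase == "MC":
            p0 = (max(y.mean(), 1e-3), 0.5, 0.5)
            popt, pcov = curve_fit(_tangent, u, y, p0=p0, maxfev=20000,
                                   bounds=([0, 1e-9, -1.0], [1.0, 3.0, 2.0]))
            names = ("rho_max", "q", "u0")
            f = _tangent
        elif phase == "coexistence":
            amp = (y.max() - y.min()) / 2
            p0 = (y.mean(), max(amp, 1e-3), 0.5, 0.1)
            popt, pcov = curve_fit(_tanh_wall, u, y, p0=p0, maxfev=20000)
            names = ("rho0", "amplitude", "u0", "width")
            f = _tanh_wall
        else:
            raise ValueError("phase must be 'MC' or 'coexistence'")
    except RuntimeError as err:
        raise RuntimeError(
            f"profile fit ({phase}) did not converge on {len(u)} points "
            f"(bulk={profile.bulk:.3f}, spread={y.max() - y.min():.3f}): {err}"
        ) from err
    perr = np.sqrt(np.diag(pcov))
    rss = float(((f(u, *popt) - y) ** 2).sum())
    return ProfileFit(model=phase, params=dict(zip(names, popt)),
                      perr=dict(zip(names, perr)), rss=rss,
                      linear_rss=linear_rss, n_points=len(u))


def oscillation_period(profile: DensityProfile, n_cols: int = 50,
                       max_lag: int = 12) -> int:
    """Dominant spatial period (columns) of entrance-side density
    oscillations: first local maximum of the autocorrelation of
    rho(x) - rho_bulk over the first `n_cols` columns."""
    s = profile.rho[:n_cols] - profile.bulk
    s = s - s.mean()
    ac = np.array([np.dot(s[: len(s) - k], s[k:]) for k in range(max_lag + 1)])
    for k in range(2, max_lag):
        if ac[k] > ac[k - 1] and ac[k] >= ac[k + 1]:
            return k
    return int(np.argmax(ac[2:max_lag]) + 2)
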