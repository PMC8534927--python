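"""Open-boundary cylinder lattice and its Monte Carlo dynamics.

Two layers live here:

* a transparent pure-Python reference implementation of the elementary moves
  (:func:`slide_target`, :func:`inject`, :func:`extract`,
  :func:`attempt_move`, :func:`sweep`) operating on a :class:`SystemState`
  with an explicit particle registry — convenient for unit tests and for
  reading the rules;
* a production driver, :func:`run`, that executes the same dynamics through
  the compiled kernel in :mod:`dynasep._kernel` and returns a
  :class:`RunResult` with block-resolved accumulators for the observables
  layer.

Update schedule (both layers): random-sequential kinetic Monte Carlo — one
MCS consists of N0 + Ly elementary events (N0 = particle count at the start
of the step), each picking uniformly at random among the live particles and
the Ly entrance channels.  A particle pick applies the internal ATP update
followed by the move attempt; an entrance pick attempts an injection.  Every
particle and entrance channel is thus visited once per MCS on average, with
replacement, which reproduces the continuous-time exclusion-process
reference results (see dynasep._kernel and docs/methods.md for the measured
artifacts of the synchronous alternatives).  Extraction is folded into the move
attempt: a fueled forward attempt that would carry the particle beyond the
last column triggers a single Bernoulli(beta) exit trial.  Gating the exit on
the motor's own hop machinery is what makes the unit-step limit reproduce the
standard open-TASEP phase boundaries (bulk HD density 1 - beta with hop rate
r; see docs/methods.md).

Columns are 1-based in this reference layer ("the first lattice site" is
column 1); the compiled kernel and the raw arrays in RunResult use 0-based
columns internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernel
from .motor import MotorState, intended_steps, update_internal_state
from .params import BoundaryRates, KineticsParams, RunConfig

__all__ = [
    "SystemState",
    "Particle",
    "RunResult",
    "slide_target",
    "inject",
    "extract",
    "attempt_move",
    "sweep",
    "run",
]


# ---------------------------------------------------------------------------
# reference implementation
# ---------------------------------------------------------------------------

@dataclass
class Particle:
    lane: int
    col: int  # 1-based
    motor: MotorState
    entry_time: int
    jump_log: list = field(default_factory=list)  # (clock, displacement, axis)


@dataclass
class SystemState:
    """Full lattice occupancy plus the particle registry and the MCS clock."""

    Lx: int
    Ly: int
    rng: np.random.Generator
    occupancy: np.ndarray = None  # (Ly, Lx) int32, -1 empty, else particle id
    particles: dict[int, Particle] = field(default_factory=dict)
    clock: int = 0
    next_id: int = 0
    n_injected: int = 0
    n_extracted: int = 0

    def __post_init__(self) -> None:
        if self.occupancy is None:
            self.occupancy = np.full((self.Ly, self.Lx), -1, dtype=np.int32)

    @classmethod
    def empty(cls, Lx: int, Ly: int, seed: int = 0) -> "SystemState":
        return cls(Lx=Lx, Ly=Ly, rng=np.random.default_rng(seed))

    def add_particle(self, lane: int, col: int, motor: Optional[MotorState] = None) -> int:
        if self.occupancy[lane, col - 1] >= 0:
            raise ValueError(f"site (lane={lane}, col={col}) already occupied")
        pid = self.next_id
        self.next_id += 1
        self.particles[pid] = Particle(lane, col, motor or MotorState(), self.clock)
        self.occupancy[lane, col - 1] = pid
        return pid

    def remove_particle(self, pid: int) -> Particle:
        p = self.particles.pop(pid)
        self.occupancy[p.lane, p.col - 1] = -1
        return p

    def check_consistency(self) -> None:
        occupied = {(l, c + 1) for l, c in zip(*np.nonzero(self.occupancy >= 0))}
        registered = {(p.lane, p.col) for p in self.particles.values()}
        if occupied != registered:
            raise AssertionError("occupancy grid and particle registry disagree")
        for pid, p in self.particles.items():
            if self.occupancy[p.lane, p.col - 1] != pid:
                raise AssertionError(f"registry entry {pid} not found on grid")


def slide_target(lane_occupancy: np.ndarray, position: int, n: int) -> int:
    """Landing column of a forward jump of intended length n from `position`.

    `lane_occupancy` is the boolean occupied-mask of one lane (index 0 is
    column 1).  The mover slides to position + min(n, g), where g is the
    number of contiguous empty sites immediately ahead, capped at the last
    column; with g = 0 the position is unchanged (no overtaking).
    """
    if not (1 <= n <= 4):
        raise ValueError(f"intended steps must be 1..4, got {n}")
    Lx = len(lane_occupancy)
    g = 0
    while g < n and position + g + 1 <= Lx and not lane_occupancy[position + g]:
        g += 1
    return min(position + min(n, g), Lx)


def inject(system: SystemState, rates: BoundaryRates, params: KineticsParams) -> SystemState:
    """Entrance trials: each lane independently receives a fresh particle at
    column 1 with probability alpha, provided the site is empty.  Fresh
    particles carry no ATP on any binding site."""
    for lane in range(system.Ly):
        if system.occupancy[lane, 0] < 0 and system.rng.random() < rates.alpha:
            system.add_particle(lane, 1, MotorState())
            system.n_injected += 1
    return system


def extract(system: SystemState, rates: BoundaryRates) -> SystemState:
    """One bare exit opportunity per particle at the last column
    (Bernoulli(beta) each).

    This is the elementary boundary drain; during a production sweep the exit
    opportunities arise inside :func:`attempt_move`, gated by a fueled
    forward attempt, so that the unit-step limit matches the open-TASEP
    closed forms.
    """
    for pid in [pid for pid, p in system.particles.items() if p.col == system.Lx]:
        if system.rng.random() < rates.beta:
            system.remove_particle(pid)
            system.n_extracted += 1
    return system


def attempt_move(
    system: SystemState, particle_id: int, params: KineticsParams, rates: BoundaryRates
) -> SystemState:
    """One move attempt for one particle (direction draw, slide, boundary).

    With zero intended steps nothing happens.  Otherwise a direction is drawn
    (forward Px, up Py, down Py) and the slide rule applied; transverse moves
    wrap around the Ly-ring (the mover's own lane counts as empty, so a full
    wrap is a realized jump).  A forward attempt that would pass the last
    column triggers one Bernoulli(beta) exit trial; on failure the particle
    slides to the last column instead.  Any realized displacement >= 1
    hydrolyses the primary ATP and is appended to the particle's jump log.
    """
    if particle_id not in system.particles:
        raise KeyError(f"unknown particle id {particle_id}")
    p = system.particles[particle_id]
    n = intended_steps(p.motor)
    if n == 0:
        return system
    u = system.rng.random()
    if u < params.Px:
        row = system.occupancy[p.lane] >= 0
        target = slide_target(row, p.col, n)
        if p.col + n > system.Lx and target == system.Lx:
            # boundary opportunity (path to the last column is clear)
            if system.rng.random() < rates.beta:
                d = system.Lx - p.col + 1
                p.jump_log.append((system.clock, d, "exit"))
                system.remove_particle(particle_id)
                system.n_extracted += 1
                return system
            target = system.Lx
        d = target - p.col
        if d > 0:
            system.occupancy[p.lane, p.col - 1] = -1
            system.occupancy[p.lane, target - 1] = particle_id
            p.col = target
            p.motor.primary_occupied = False
            p.jump_log.append((system.clock, d, "x"))
    else:
        sgn = 1 if u < params.Px + params.Py else -1
        g = 0
        while g < n:
            nl = (p.lane + sgn * (g + 1)) % system.Ly
            if nl != p.lane and system.occupancy[nl, p.col - 1] >= 0:
                break
            g += 1
        d = min(n, g)
        if d > 0:
            nl = (p.lane + sgn * d) % system.Ly
            system.occupancy[p.lane, p.col - 1] = -1
            system.occupancy[nl, p.col - 1] = particle_id
            p.lane = nl
            p.motor.primary_occupied = False
            p.jump_log.append((system.clock, sgn * d, "y"))
    return system


def sweep(system: SystemState, params: KineticsParams, rates: BoundaryRates) -> SystemState:
    """Advance the clock by one MCS: N0 + Ly elementary events, each picking
    uniformly among the live particles and the Ly entrance channels (see
    dynasep._kernel for why the events are randomly interleaved)."""
    live = list(system.particles.keys())
    n_events = len(live) + system.Ly
    for _ in range(n_events):
        tot = len(live) + system.Ly
        j = int(system.rng.integers(0, tot))
        if j >= len(live):
            lane = j - len(live)
            if system.occupancy[lane, 0] < 0 and system.rng.random() < rates.alpha:
                pid = system.add_particle(lane, 1, MotorState())
                system.n_injected += 1
                live.append(pid)
            continue
        pid = live[j]
        p = system.particles[pid]
        p.motor = update_internal_state(p.motor, params, system.rng)
        attempt_move(system, pid, params, rates)
        if pid not in system.particles:  # exited during its own visit
            live.remove(pid)
    system.clock += 1
    return system


# ---------------------------------------------------------------------------
# production driver
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Raw output of one kernel run: block-resolved accumulators plus the
    final microscopic state.  Interpretation lives in dynasep.observables."""

    config: RunConfig
    sampling: int
    # accumulators (see _kernel.run_sweeps for layouts)
    dens: np.ndarray
    bond: np.ndarray
    trans_net: np.ndarray
    trans_abs: np.ndarray
    hist_x: np.ndarray
    hist_y: np.ndarray
    hist_exit: np.ndarray
    blocked: int
    inj_b: np.ndarray
    ext_b: np.ndarray
    fwd_disp: np.ndarray
    # tagged particles
    tag_t: np.ndarray
    tag_uid: np.ndarray
    tag_entry: np.ndarray
    tag_exit: np.ndarray
    traj_x: np.ndarray
    traj_y: np.ndarray
    # event log
    events: Optional[np.ndarray]
    events_overflowed: bool
    # bookkeeping
    n_final: int
    n_injected: int
    n_extracted: int
    final_occupancy: np.ndarray

    @property
    def n_blocks(self) -> int:
        return self.dens.shape[0]

    @property
    def Lx(self) -> int:
        return self.config.lattice.Lx

    @property
    def Ly(self) -> int:
        return self.config.lattice.Ly


class _KernelState:
    """Preallocated array bundle backing one kernel run."""

    def __init__(self, config: RunConfig):
        lat = config.lattice
        M = lat.n_sites
        self.M = M
        self.occ = np.full((lat.Ly, lat.Lx), -1, dtype=np.int32)
        self.lane = np.zeros(M, dtype=np.int32)
        self.col = np.zeros(M, dtype=np.int32)
        self.primary = np.zeros(M, dtype=np.uint8)
        self.snum = np.zeros(M, dtype=np.uint8)
        self.active = np.zeros(M, dtype=np.uint8)
        self.uid = np.full(M, -1, dtype=np.int64)
        self.entry_t = np.zeros(M, dtype=np.int64)
        self.free_stack = np.arange(M - 1, -1, -1, dtype=np.int32)
        self.alist = np.zeros(M, dtype=np.int32)
        self.apos = np.zeros(M, dtype=np.int32)
        # [free_top, n_active, clock, next_uid, total_inj, total_ext]
        self.scal = np.array([M, 0, 0, 0, 0, 0], dtype=np.int64)

    def place(self, lane: int, col0: int, primary: int = 0, s: int = 0) -> int:
        """Place a particle at 0-based (lane, col0); returns its slot."""
        if self.occ[lane, col0] >= 0:
            raise ValueError("site occupied")
        self.scal[0] -= 1
        sl = self.free_stack[self.scal[0]]
        self.active[sl] = 1
        self.lane[sl] = lane
        self.col[sl] = col0
        self.primary[sl] = primary
        self.snum[sl] = s
        self.uid[sl] = self.scal[3]
        self.entry_t[sl] = 0
        self.occ[lane, col0] = sl
        self.alist[self.scal[1]] = sl
        self.apos[sl] = self.scal[1]
        self.scal[1] += 1
        self.scal[3] += 1
        return sl


def _spread_initial(state: _KernelState, config: RunConfig, rng: np.random.Generator) -> None:
    lat = config.lattice
    n = config.n_init
    if n <= 0:
        return
    p_occ = config.kinetics.hop_ready_prob
    ssum = config.kinetics.Satt + config.kinetics.Sdet
    p_s = config.kinetics.Satt / ssum if ssum > 0 else 0.0
    for i in range(n):
        k = (i * lat.n_sites) // n
        lane, col0 = k % lat.Ly, k // lat.Ly
        if config.entry_state == "stationary":
            state.place(lane, col0, int(rng.random() < p_occ), int(rng.binomial(3, p_s)))
        else:
            state.place(lane, col0, 0, 0)


def run(config: RunConfig) -> RunResult:
    """Execute warmup + sampling sweeps for `config`; bit-reproducible given
    (config, seed)."""
    lat, kin, bnd = config.lattice, config.kinetics, config.boundary
    state = _KernelState(config)
    # the host rng only draws the initial condition; the kernel stream is
    # seeded separately so results do not depend on allocation details
    _spread_initial(state, config, np.random.default_rng(config.seed))

    K = len(config.tag_times)
    tag_t = np.asarray(config.tag_times, dtype=np.int64) if K else np.zeros(0, dtype=np.int64)
    tag_uid = np.full(K, -1, dtype=np.int64)
    tag_slot = np.full(K, -1, dtype=np.int64)
    tag_entry = np.zeros(K, dtype=np.int64)
    tag_dx = np.zeros(K, dtype=np.int64)
    tag_dy = np.zeros(K, dtype=np.int64)
    tag_exit = np.full(K, -1, dtype=np.int64)
    rec_len = config.tag_record_len if K else 0
    traj_x = np.zeros((K, rec_len), dtype=np.int64)
    traj_y = np.zeros((K, rec_len), dtype=np.int64)
    # pre-placed particles can satisfy threshold-0 tags immediately
    if config.n_init > 0 and K:
        first = int(np.argmax(state.active))
        for k in range(K):
            if tag_t[k] <= 0:
                tag_uid[k] = state.uid[first]
                tag_slot[k] = first
                tag_entry[k] = 0

    cap = config.event_capacity
    ev = np.zeros((max(cap, 1), 6), dtype=np.int64)
    ev_meta = np.array([0, 0, cap], dtype=np.int64)

    nb = config.n_blocks
    dens = np.zeros((nb, lat.Ly, lat.Lx), dtype=np.int64)
    bond = np.zeros((nb, lat.Lx + 1), dtype=np.int64)
    trans_net = np.zeros(nb, dtype=np.int64)
    trans_abs = np.zeros(nb, dtype=np.int64)
    hist_x = np.zeros(5, dtype=np.int64)
    hist_y = np.zeros(5, dtype=np.int64)
    hist_exit = np.zeros(5, dtype=np.int64)
    blocked = np.zeros(1, dtype=np.int64)
    inj_b = np.zeros(nb, dtype=np.int64)
    ext_b = np.zeros(nb, dtype=np.int64)
    fwd_disp = np.zeros(nb, dtype=np.int64)

    entry_mode = 1 if config.entry_state == "stationary" else 0
    p_occ = kin.hop_ready_prob
    ssum = kin.Satt + kin.Sdet
    p_s = kin.Satt / ssum if ssum > 0 else 0.0

    common = (
        state.occ, state.lane, state.col, state.primary, state.snum,
        state.active, state.uid, state.entry_t, state.free_stack,
        state.alist, state.apos, state.scal,
        lat.Lx, lat.Ly, bnd.alpha, bnd.beta,
        kin.Patt, kin.Pdet, kin.Satt, kin.Sdet, kin.Px, kin.Py,
        1 if config.periodic else 0, entry_mode, p_occ, p_s,
    )
    tail = (
        tag_t, tag_uid, tag_slot, tag_entry, tag_dx, tag_dy, tag_exit,
        traj_x, traj_y, rec_len, ev, ev_meta,
    )
    _kernel.seed_kernel_rng(config.seed % (2**32 - 1))
    n_inj0 = 0
    if config.warmup > 0:
        _kernel.run_sweeps(
            *common, config.warmup, 0, nb,
            dens, bond, trans_net, trans_abs, hist_x, hist_y, hist_exit,
            blocked, inj_b, ext_b, fwd_disp, *tail,
        )
    _kernel.run_sweeps(
        *common, config.sampling, 1, nb,
        dens, bond, trans_net, trans_abs, hist_x, hist_y, hist_exit,
        blocked, inj_b, ext_b, fwd_disp, *tail,
    )
    code = _kernel.check_consistency(state.occ, state.lane, state.col, state.active)
    if code != 0:
        raise AssertionError(f"post-run consistency audit failed (code {code})")
    if int(state.scal[1]) != config.n_init + int(state.scal[4]) - int(state.scal[5]):
        raise AssertionError("particle-number bookkeeping violated")

    events = ev[: ev_meta[0]].copy() if cap > 0 else None
    return RunResult(
        config=config,
        sampling=config.sampling,
        dens=dens, bond=bond, trans_net=trans_net, trans_abs=trans_abs,
        hist_x=hist_x, hist_y=hist_y, hist_exit=hist_exit,
        blocked=int(blocked[0]),
        inj_b=inj_b, ext_b=ext_b, fwd_disp=fwd_disp,
        tag_t=tag_t, tag_uid=tag_uid, tag_entry=tag_entry, tag_exit=tag_exit,
        traj_x=traj_x, traj_y=traj_y,
        events=events, events_overflowed=bool(ev_meta[1]),
        n_final=int(state.scal[1]),
        n_injected=int(state.scal[4]),
        n_extracted=int(state.scal[5]),
        final_occupancy=(state.occ >= 0).astype(np.int8),
    )
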