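"""Compiled Monte Carlo sweep kernel.

One Monte Carlo step (MCS) = N0 + Ly elementary events, where N0 is the
particle count at the start of the step and Ly the number of entrance
channels (one per lane; zero on a ring).  Each event picks uniformly at
random among the particles currently on the lattice plus the entrance
channels: a particle pick applies the internal ATP update followed by a move
attempt; an entrance pick attempts an injection (probability alpha, first
column of that lane, only if empty).  Every particle and every entrance
channel is therefore visited once per MCS on average, with replacement — the
standard kinetic-Monte-Carlo discretization of continuous-time dynamics.

Two tempting simplifications are deliberately avoided because they distort
the stationary state measurably: (i) a random permutation that visits each
particle exactly once per MCS lets entire convoys advance within a single
sweep and inflates the unit-step-limit current ~50% above J_max = r/4;
(ii) synchronous injection at the start of every sweep over-weights the
entry channel (the entrance site has usually been vacated by sweep start)
and lifts the low-density bulk above alpha/r.

Geometry is a cylinder: columns 0..Lx-1 (open ends; the public API reports
1-based columns), lanes 0..Ly-1 with periodic transverse arithmetic.  A fueled
motor (primary ATP present) intends n = 4 - s steps in a single drawn
direction (forward with probability Px, up/down with Py each) and slides to
the last empty site before the first obstacle in that direction (no
overtaking within a lane).  A forward attempt that would carry the particle
beyond the last column triggers a single Bernoulli(beta) exit trial; on
failure the particle advances to the last column (possibly not moving).
A realized displacement >= 1 hydrolyses the primary ATP (the site empties);
blocked attempts keep it.

Bond bookkeeping: bond index b in 0..Lx separates columns b-1 and b, with
b = 0 the entry bond and b = Lx the exit bond; a move of d sites from column
c increments bonds c+1 .. c+d, an exit from column c increments c+1 .. Lx.

The kernel is deliberately monolithic: all state lives in preallocated arrays
owned by the Python driver (see engine.py), and the same compiled function
serves warmup (measure=0) and sampling (measure=1) calls.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# event type codes for the optional event log
EV_INJECT = 0
EV_JUMP_X = 1
EV_JUMP_Y = 2
EV_EXIT = 3


@njit(cache=True)
def seed_kernel_rng(seed):
    """Seed the compiled code's global random stream (numpy MT19937)."""
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _log_event(ev, ev_meta, t, pid, l, c, disp, kind):
    if ev_meta[2] > 0:
        if ev_meta[0] < ev_meta[2]:
            i = ev_meta[0]
            ev[i, 0] = t
            ev[i, 1] = pid
            ev[i, 2] = l
            ev[i, 3] = c
            ev[i, 4] = disp
            ev[i, 5] = kind
            ev_meta[0] += 1
        else:
            ev_meta[1] = 1  # overflow


@njit(cache=True)
def forward_gap(occ_lane, c, n, Lx, periodic):
    """Number of contiguous empty sites ahead (up to n) in a lane.

    Open geometry stops at the last column; on a ring the particle's own
    origin counts as empty, so a full wrap is possible.
    """
    g = 0
    if periodic:
        while g < n:
            nc = (c + g + 1) % Lx
            if nc != c and occ_lane[nc] >= 0:
                break
            g += 1
    else:
        while g < n and c + g + 1 < Lx and occ_lane[c + g + 1] < 0:
            g += 1
    return g


@njit(cache=True)
def ring_gap(occ, c, l, sgn, n, Ly):
    """Contiguous empty lanes (up to n) in transverse direction sgn = +/-1,
    treating the mover's own lane as empty (full wraps allowed)."""
    g = 0
    while g < n:
        nl = (l + sgn * (g + 1)) % Ly
        if nl != l and occ[nl, c] >= 0:
            break
        g += 1
    return g


@njit(cache=True)
def run_sweeps(
    # mutable system state -------------------------------------------------
    occ,          # (Ly, Lx) int32: particle slot or -1
    lane, col,    # int32[M]
    primary,      # uint8[M]
    snum,         # uint8[M] occupied secondary sites, 0..3
    active,       # uint8[M]
    uid,          # int64[M] unique particle id
    entry_t,      # int64[M]
    free_stack,   # int32[M]
    alist,        # int32[M] compact list of active slots
    apos,         # int32[M] position of each slot in alist
    scal,         # int64[6]: [free_top, n_active, clock, next_uid,
                  #           total_injections, total_extractions]
    # static parameters ----------------------------------------------------
    Lx, Ly, alpha, beta, Patt, Pdet, Satt, Sdet, Px, Py,
    periodic,     # 0/1: ring in x (no injection/extraction)
    entry_mode,   # 0: empty ATP sites at entry; 1: stationary sample
    p_occ_entry, p_s_entry,
    n_mcs, measure, n_blocks,
    # accumulators (filled only when measure=1) ----------------------------
    dens,         # int64 (n_blocks, Ly, Lx) occupancy counts
    bond,         # int64 (n_blocks, Lx+1) longitudinal bond crossings
    trans_net,    # int64 (n_blocks,) signed transverse displacement
    trans_abs,    # int64 (n_blocks,) absolute transverse displacement
    hist_x,       # int64 (5,) realized forward jump lengths (index 1..4)
    hist_y,       # int64 (5,) realized transverse jump lengths
    hist_exit,    # int64 (5,) exit displacements (sites traversed incl. exit bond)
    blocked,      # int64 (1,) fueled attempts with zero realized displacement
    inj_b, ext_b, # int64 (n_blocks,) injections / extractions
    fwd_disp,     # int64 (n_blocks,) total forward displacement (ring current)
    # tagged-particle tracking (always on) ---------------------------------
    tag_t,        # int64 (K,) entry-time thresholds
    tag_uid,      # int64 (K,) assigned particle uid or -1
    tag_slot,     # int64 (K,) slot while on lattice, -1 unassigned, -2 done
    tag_entry,    # int64 (K,)
    tag_dx, tag_dy,   # int64 (K,) cumulative displacements
    tag_exit,     # int64 (K,) exit clock or -1
    traj_x, traj_y,   # int64 (K, rec_len) displacement after j sweeps since entry
    rec_len,
    # optional event log ---------------------------------------------------
    ev,           # int64 (cap, 6): t, uid, lane, col, disp, kind
    ev_meta,      # int64 (3,): count, overflow, capacity
):
    K = tag_t.shape[0]
    n_chan = 0 if periodic else Ly  # entrance channels
    for t_local in range(n_mcs):
        clock = scal[2]
        block = (t_local * n_blocks) // n_mcs
        # -- N0 + Ly random events: particle visits and entrance trials -----
        n_events = scal[1] + n_chan
        for _ev in range(n_events):
            tot = scal[1] + n_chan
            if tot == 0:
                break
            j = np.random.randint(0, tot)
            if j >= scal[1]:
                # entrance channel of lane l
                l = j - scal[1]
                if occ[l, 0] < 0 and np.random.random() < alpha:
                    scal[0] -= 1
                    sl = free_stack[scal[0]]
                    active[sl] = 1
                    lane[sl] = l
                    col[sl] = 0
                    if entry_mode == 1:
                        primary[sl] = 1 if np.random.random() < p_occ_entry else 0
                        s0 = 0
                        for _ in range(3):
                            if np.random.random() < p_s_entry:
                                s0 += 1
                        snum[sl] = s0
                    else:
                        primary[sl] = 0
                        snum[sl] = 0
                    uid[sl] = scal[3]
                    entry_t[sl] = clock
                    occ[l, 0] = sl
                    alist[scal[1]] = sl
                    apos[sl] = scal[1]
                    scal[1] += 1
                    scal[3] += 1
                    scal[4] += 1
                    if measure:
                        inj_b[block] += 1
                        bond[block, 0] += 1
                    for k in range(K):
                        if tag_slot[k] == -1 and clock >= tag_t[k]:
                            tag_uid[k] = uid[sl]
                            tag_slot[k] = sl
                            tag_entry[k] = clock
                            tag_dx[k] = 0
                            tag_dy[k] = 0
                    _log_event(ev, ev_meta, clock, uid[sl], l, 0, 0, EV_INJECT)
                continue
            sl = alist[j]
            # internal ATP update: one trial per site, mutually exclusive
            if primary[sl]:
                if np.random.random() < Pdet:
                    primary[sl] = 0
            else:
                if np.random.random() < Patt:
                    primary[sl] = 1
            s0 = snum[sl]
            s = s0
            for _ in range(s0):
                if np.random.random() < Sdet:
                    s -= 1
            for _ in range(3 - s0):
                if np.random.random() < Satt:
                    s += 1
            snum[sl] = s
            if primary[sl] == 0:
                continue
            nsteps = 4 - s
            u = np.random.random()
            c = col[sl]
            l = lane[sl]
            if u < Px:
                # ---- forward ----
                g = forward_gap(occ[l], c, nsteps, Lx, periodic)
                if periodic == 0 and c + nsteps > Lx - 1 and c + g == Lx - 1:
                    # boundary opportunity: one beta trial
                    if np.random.random() < beta:
                        d = Lx - c
                        occ[l, c] = -1
                        active[sl] = 0
                        free_stack[scal[0]] = sl
                        scal[0] += 1
                        i = apos[sl]
                        last = scal[1] - 1
                        alist[i] = alist[last]
                        apos[alist[last]] = i
                        scal[1] -= 1
                        scal[5] += 1
                        if measure:
                            ext_b[block] += 1
                            hist_exit[d] += 1
                            for b in range(c + 1, Lx + 1):
                                bond[block, b] += 1
                        for k in range(K):
                            if tag_slot[k] == sl:
                                tag_dx[k] += d
                                tag_exit[k] = clock
                                tag_slot[k] = -2
                        _log_event(ev, ev_meta, clock, uid[sl], l, c, d, EV_EXIT)
                    else:
                        d = Lx - 1 - c
                        if d > 0:
                            occ[l, c] = -1
                            occ[l, c + d] = sl
                            col[sl] = c + d
                            primary[sl] = 0
                            if measure:
                                hist_x[d] += 1
                                for b in range(c + 1, c + d + 1):
                                    bond[block, b] += 1
                            for k in range(K):
                                if tag_slot[k] == sl:
                                    tag_dx[k] += d
                            _log_event(ev, ev_meta, clock, uid[sl], l, c, d, EV_JUMP_X)
                        elif measure:
                            blocked[0] += 1
                else:
                    d = g if g < nsteps else nsteps
                    if d > 0:
                        nc = (c + d) % Lx if periodic else c + d
                        occ[l, c] = -1
                        occ[l, nc] = sl
                        col[sl] = nc
                        primary[sl] = 0
                        if measure:
                            hist_x[d] += 1
                            fwd_disp[block] += d
                            if periodic == 0:
                                for b in range(c + 1, c + d + 1):
                                    bond[block, b] += 1
                        for k in range(K):
                            if tag_slot[k] == sl:
                                tag_dx[k] += d
                        _log_event(ev, ev_meta, clock, uid[sl], l, c, d, EV_JUMP_X)
                    elif measure:
                        blocked[0] += 1
            else:
                # ---- transverse ----
                sgn = 1 if u < Px + Py else -1
                g = ring_gap(occ, c, l, sgn, nsteps, Ly)
                d = g if g < nsteps else nsteps
                if d > 0:
                    nl = (l + sgn * d) % Ly
                    occ[l, c] = -1
                    occ[nl, c] = sl
                    lane[sl] = nl
                    primary[sl] = 0
                    if measure:
                        hist_y[d] += 1
                        trans_net[block] += sgn * d
                        trans_abs[block] += d
                    for k in range(K):
                        if tag_slot[k] == sl:
                            tag_dy[k] += sgn * d
                    _log_event(ev, ev_meta, clock, uid[sl], nl, c, sgn * d, EV_JUMP_Y)
                elif measure:
                    blocked[0] += 1
        # -- per-sweep accumulation ----------------------------------------
        if measure:
            for l in range(Ly):
                for c in range(Lx):
                    if occ[l, c] >= 0:
                        dens[block, l, c] += 1
        for k in range(K):
            if tag_slot[k] != -1:
                j = clock + 1 - tag_entry[k]
                if 1 <= j <= rec_len:
                    traj_x[k, j - 1] = tag_dx[k]
                    traj_y[k, j - 1] = tag_dy[k]
        scal[2] += 1


@njit(cache=True)
def check_consistency(occ, lane, col, active):
    """Exclusion/registry audit: returns 0 if consistent, else a defect code."""
    M = lane.shape[0]
    n_occ = 0
    for l in range(occ.shape[0]):
        for c in range(occ.shape[1]):
            sl = occ[l, c]
            if sl >= 0:
                n_occ += 1
                if not active[sl]:
                    return 1
                if lane[sl] != l or col[sl] != c:
                    return 2
    n_act = 0
    for sl in range(M):
        if active[sl]:
            n_act += 1
            if occ[lane[sl], col[sl]] != sl:
                return 3
    if n_act != n_occ:
        return 4
    return 0
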