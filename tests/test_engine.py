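"""Lattice dynamics: sliding, boundaries, exclusion, conservation,
determinism, and the unit-step (TASEP) reference limit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynasep import (
    BoundaryRates,
    KineticsParams,
    LatticeConfig,
    MotorState,
    RunConfig,
    SystemState,
    run,
    slide_target,
    sweep,
)
from dynasep.engine import attempt_move, extract, inject
from dynasep.observables import measure_current, measure_density

TASEP_R = 0.8  # effective unit-step hop rate for Patt=0.8, Pdet=0.2


class TestSlideTarget:
    def test_clear_path_full_jump(self):
        row = np.zeros(20, bool)
        row[4] = True  # the mover itself
        assert slide_target(row, 5, 4) == 9

    def test_adjacent_obstacle_blocks(self):
        row = np.zeros(20, bool)
        row[4] = row[5] = True
        assert slide_target(row, 5, 2) == 5

    def test_truncates_to_last_empty_site_before_obstacle(self):
        # intending 4, nearest particle 3 ahead: land on the last empty site
        row = np.zeros(20, bool)
        row[4] = row[7] = True
        assert slide_target(row, 5, 4) == 7

    def test_capped_at_last_column(self):
        row = np.zeros(10, bool)
        row[7] = True
        assert slide_target(row, 8, 4) == 10

    def test_invalid_step_count(self):
        with pytest.raises(ValueError):
            slide_target(np.zeros(10, bool), 1, 5)

    @given(occ=st.lists(st.booleans(), min_size=8, max_size=30),
           pos=st.integers(1, 8), n=st.integers(1, 4))
    @settings(max_examples=200, deadline=None)
    def test_never_lands_on_occupied_or_beyond(self, occ, pos, n):
        row = np.array(occ + [False] * 8, dtype=bool)
        pos = min(pos, len(row))
        row[pos - 1] = True  # mover
        tgt = slide_target(row, pos, n)
        assert pos <= tgt <= min(pos + n, len(row))
        if tgt != pos:
            assert not row[tgt - 1]
            assert not row[pos: tgt - 1].any()  # slid through empty sites only


class TestBoundaries:
    def test_no_injection_at_zero_alpha(self):
        sys = SystemState.empty(20, 2, seed=0)
        for _ in range(50):
            inject(sys, BoundaryRates(0.0, 1.0), KineticsParams())
        assert not sys.particles

    def test_forced_injection_fills_every_lane(self):
        sys = SystemState.empty(20, 3, seed=0)
        inject(sys, BoundaryRates(1.0, 1.0), KineticsParams())
        assert (sys.occupancy[:, 0] >= 0).all()

    def test_occupied_entrance_blocks_injection(self):
        sys = SystemState.empty(20, 1, seed=0)
        sys.add_particle(0, 1)
        inject(sys, BoundaryRates(1.0, 1.0), KineticsParams())
        assert len(sys.particles) == 1

    def test_exit_waiting_time_geometric(self):
        # bare exit opportunities at the last column: geometric(beta), mean 2
        waits = []
        sys = SystemState.empty(10, 1, seed=5)
        for _ in range(4000):
            pid = sys.add_particle(0, 10)
            t = 0
            while pid in sys.particles:
                t += 1
                extract(sys, BoundaryRates(0.0, 0.5))
            waits.append(t)
        assert np.mean(waits) == pytest.approx(2.0, abs=0.1)

    def test_mid_jump_exit_with_certain_beta(self):
        sys = SystemState.empty(10, 1, seed=1)
        pid = sys.add_particle(0, 8, MotorState(primary_occupied=True, s=1))
        k = KineticsParams(Px=1.0, Py=0.0)
        attempt_move(sys, pid, k, BoundaryRates(0.0, 1.0))
        assert pid not in sys.particles  # 3 intended steps from column 8 pass Lx=10

    def test_unknown_particle_id(self):
        sys = SystemState.empty(10, 1, seed=1)
        with pytest.raises(KeyError):
            attempt_move(sys, 99, KineticsParams(), BoundaryRates(0.5, 0.5))


class TestTransverseMoves:
    def test_full_wrap_returns_to_same_lane(self):
        # Ly=4, intended 4 transverse steps on an empty ring: full wrap
        sys = SystemState.empty(10, 4, seed=2)
        pid = sys.add_particle(1, 5, MotorState(primary_occupied=True, s=0))
        k = KineticsParams(Px=0.0, Py=0.5)
        attempt_move(sys, pid, k, BoundaryRates(0.0, 0.0))
        p = sys.particles[pid]
        assert p.lane == 1 and p.col == 5
        assert len(p.jump_log) == 1
        assert abs(p.jump_log[0][1]) == 4  # realized ring displacement
        assert not p.motor.primary_occupied  # the jump consumed the ATP

    def test_blocked_lane_truncates_ring_slide(self):
        sys = SystemState.empty(10, 4, seed=3)
        pid = sys.add_particle(0, 5, MotorState(primary_occupied=True, s=0))
        sys.add_particle(2, 5)  # obstacle two lanes up
        k = KineticsParams(Px=0.0, Py=0.5)
        attempt_move(sys, pid, k, BoundaryRates(0.0, 0.0))
        p = sys.particles[pid]
        assert p.col == 5
        assert p.lane in (1, 3)  # one step up (blocked at 2) or slide down past 3


class TestSweep:
    def test_empty_lattice_only_advances_clock(self):
        sys = SystemState.empty(16, 2, seed=0)
        sweep(sys, KineticsParams(), BoundaryRates(0.0, 1.0))
        assert sys.clock == 1 and not sys.particles

    def test_particle_number_conserved_without_boundaries(self):
        sys = SystemState.empty(16, 2, seed=4)
        for col in (3, 7, 11):
            sys.add_particle(0, col)
            sys.add_particle(1, col)
        for _ in range(60):
            sweep(sys, KineticsParams(), BoundaryRates(0.0, 0.0))
            sys.check_consistency()
        assert len(sys.particles) == 6

    def test_full_lattice_is_frozen(self):
        cfg = RunConfig(lattice=LatticeConfig(Lx=10, Ly=2),
                        kinetics=KineticsParams(),
                        boundary=BoundaryRates(0.0, 0.0),
                        warmup=0, sampling=200, n_blocks=1, n_init=20, seed=8)
        res = run(cfg)
        assert res.hist_x.sum() == res.hist_y.sum() == res.hist_exit.sum() == 0
        assert (res.dens.sum(axis=0) == 200).all()


class TestKernelInvariants:
    def test_particle_number_bookkeeping_exact(self):
        cfg = RunConfig(lattice=LatticeConfig(Lx=80, Ly=3),
                        kinetics=KineticsParams.low_load(),
                        boundary=BoundaryRates(0.7, 0.4),
                        warmup=0, sampling=3000, seed=12)
        res = run(cfg)
        assert res.n_final == res.n_injected - res.n_extracted
        assert res.final_occupancy.max() <= 1  # hard-core exclusion

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_bookkeeping_holds_for_any_seed(self, seed):
        cfg = RunConfig(lattice=LatticeConfig(Lx=40, Ly=2),
                        kinetics=KineticsParams.high_load(),
                        boundary=BoundaryRates(0.5, 0.5),
                        warmup=0, sampling=400, n_blocks=4, seed=seed)
        res = run(cfg)
        assert res.n_final == res.n_injected - res.n_extracted

    def test_bit_reproducibility(self):
        cfg = RunConfig(lattice=LatticeConfig(Lx=60, Ly=2),
                        kinetics=KineticsParams.intermediate_load(),
                        boundary=BoundaryRates(0.6, 0.6),
                        warmup=500, sampling=2000, seed=99, event_capacity=100_000)
        a, b = run(cfg), run(cfg)
        np.testing.assert_array_equal(a.dens, b.dens)
        np.testing.assert_array_equal(a.bond, b.bond)
        np.testing.assert_array_equal(a.events, b.events)

    def test_reference_and_kernel_agree_statistically(self):
        """The pure-Python engine and the compiled kernel implement the same
        dynamics: stationary bulk density agrees within combined errors."""
        k = KineticsParams.tasep_limit()
        bnd = BoundaryRates(0.45, 0.8)
        sys = SystemState.empty(40, 1, seed=21)
        dens = []
        for t in range(5000):
            sweep(sys, k, bnd)
            if t >= 1000:
                dens.append(len(sys.particles) / 40)
        py_rho = np.mean(dens)
        cfg = RunConfig(lattice=LatticeConfig(Lx=40, Ly=1), kinetics=k,
                        boundary=bnd, warmup=5000, sampling=50_000, seed=22)
        kern_rho = measure_density(run(cfg)).rho.mean()
        assert py_rho == pytest.approx(kern_rho, abs=0.02)


class TestTasepLimit:
    """With unit steps (Satt=1, Sdet=0) and one lane the engine is an open
    TASEP with hop rate r = 0.8; stationary states follow the closed forms."""

    def test_maximal_current_phase(self, tasep_runs):
        prof = measure_density(tasep_runs["mc"])
        cur = measure_current(tasep_runs["mc"])
        assert prof.bulk == pytest.approx(0.5, abs=0.02)
        assert cur.mean == pytest.approx(TASEP_R / 4, abs=max(3 * cur.se, 0.004))

    def test_low_density_phase(self, tasep_runs):
        prof = measure_density(tasep_runs["ld"])
        assert prof.bulk == pytest.approx(0.2 / TASEP_R, abs=0.01 + 3 * prof.bulk_se)

    def test_high_density_phase(self, tasep_runs):
        prof = measure_density(tasep_runs["hd"])
        assert prof.bulk == pytest.approx(1 - 0.3, abs=0.01 + 3 * prof.bulk_se)

    def test_current_equal_across_bonds(self, tasep_runs):
        cur = measure_current(tasep_runs["mc"])
        interior = cur.bond_rates[1:-1]
        assert interior.std() < 0.02 * interior.mean() + 1e-3
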