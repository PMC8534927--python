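"""Measurement layer: profiles, currents, jump statistics, tagged
trajectories, MSD and dwell fits (including the generator-recovery
oracles)."""

import numpy as np
import pytest

from dynasep import BoundaryRates, KineticsParams, LatticeConfig, RunConfig, run
from dynasep.observables import (
    DensityProfile,
    TaggedTrajectory,
    default_tag_times,
    dwell_statistics,
    fit_msd,
    fit_profile,
    jump_histogram,
    measure_current,
    measure_density,
    msd,
    oscillation_period,
    tag_particles,
)


def _make_profile(rho: np.ndarray) -> DensityProfile:
    Lx = len(rho)
    sl = slice(Lx // 4, Lx - Lx // 4)
    return DensityProfile(x=np.arange(1, Lx + 1), rho=rho,
                          rho_se=np.full(Lx, 1e-3), rho_lane=rho[None, :],
                          bulk=float(rho[sl].mean()), bulk_se=1e-3, window=(0, 1))


class TestDensity:
    def test_empty_run_all_zeros(self):
        cfg = RunConfig(lattice=LatticeConfig(Lx=40, Ly=2), kinetics=KineticsParams(),
                        boundary=BoundaryRates(0.0, 1.0), warmup=10, sampling=100,
                        seed=1)
        prof = measure_density(run(cfg))
        assert (prof.rho == 0).all() and prof.bulk == 0.0

    def test_hd_bulk_near_one_minus_beta(self, hd_low_run):
        prof = measure_density(hd_low_run)
        assert prof.bulk == pytest.approx(0.7, abs=0.02 + 3 * prof.bulk_se)

    def test_extra_warmup_drops_blocks(self, hd_low_run):
        cfg = hd_low_run.config
        p_full = measure_density(hd_low_run)
        p_late = measure_density(hd_low_run, warmup=cfg.warmup + cfg.sampling // 2)
        assert p_late.window[0] >= cfg.warmup + cfg.sampling // 4
        assert p_late.bulk == pytest.approx(p_full.bulk, abs=0.02)

    def test_warmup_beyond_run_rejected(self, hd_low_run):
        with pytest.raises(ValueError):
            measure_density(hd_low_run, warmup=10**9)

    def test_lane_symmetry(self, hd_low_run):
        """Cylinder symmetry: per-lane bulk densities agree."""
        prof = measure_density(hd_low_run)
        Lx = prof.Lx
        lane_bulk = prof.rho_lane[:, Lx // 4: -(Lx // 4)].mean(axis=1)
        assert lane_bulk.max() - lane_bulk.min() < 0.02


class TestCurrentAndJumps:
    def test_frozen_jammed_system_has_zero_current(self):
        cfg = RunConfig(lattice=LatticeConfig(Lx=10, Ly=2), kinetics=KineticsParams(),
                        boundary=BoundaryRates(0.0, 0.0), warmup=0, sampling=300,
                        n_blocks=1, n_init=20, seed=2)
        cur = measure_current(run(cfg))
        assert cur.mean == 0.0 and cur.transverse == 0.0

    def test_bookkeeping_identity_exact(self, hd_low_run):
        """Histogram displacements times counts = bond crossings, per seed."""
        h = jump_histogram(hd_low_run)
        assert h.total_crossings == int(hd_low_run.bond[:, 1:].sum())

    def test_transverse_current_vanishes(self, hd_low_run):
        cur = measure_current(hd_low_run)
        assert abs(cur.transverse) < 3 * cur.transverse_se + 1e-6
        assert cur.transverse_abs > 0  # activity without net drift

    def test_unobstructed_no_load_motor_only_jumps_four(self):
        k = KineticsParams(Satt=0.0, Sdet=1.0, Px=1.0, Py=0.0)
        cfg = RunConfig(lattice=LatticeConfig(Lx=1000, Ly=1), kinetics=k,
                        boundary=BoundaryRates(0, 0), periodic=True, n_init=1,
                        warmup=100, sampling=20_000, n_blocks=1, seed=3)
        h = jump_histogram(run(cfg))
        assert h.forward[4] > 0
        assert h.forward[1:4].sum() == 0

    def test_short_jumps_dominate_in_high_load_hd(self):
        cfg = RunConfig(lattice=LatticeConfig(Lx=200, Ly=4),
                        kinetics=KineticsParams.high_load(),
                        boundary=BoundaryRates(0.9, 0.3),
                        warmup=10_000, sampling=20_000, seed=4)
        h = jump_histogram(run(cfg))
        assert h.forward[1] > h.forward[4]

    def test_long_jumps_relatively_more_frequent_in_ld(self, hd_low_run, ld_osc_run):
        p_ld = jump_histogram(ld_osc_run).probabilities()
        p_hd = jump_histogram(hd_low_run).probabilities()
        assert p_ld[3] > p_hd[3]  # displacement 4 share


class TestTagging:
    def test_default_thresholds_scale_with_lattice(self):
        t = default_tag_times(LatticeConfig(Lx=100, Ly=4))
        assert t == (0, 100, 10_000)

    def test_exactly_one_first_entrant(self, dwell_free_trajectories):
        labels = [tr.label for tr in dwell_free_trajectories]
        assert all(lab == "A" for lab in labels)
        assert len(labels) == 30

    def test_no_entrants_no_tags(self):
        cfg = RunConfig(lattice=LatticeConfig(Lx=30, Ly=2), kinetics=KineticsParams(),
                        boundary=BoundaryRates(0.0, 1.0), warmup=0, sampling=50,
                        n_blocks=1, tag_times=(0,), tag_record_len=50, seed=5)
        res = run(cfg)
        with pytest.warns(UserWarning, match="class empty"):
            assert tag_particles(res) == []

    def test_threshold_ordering_by_construction(self):
        cfg = RunConfig(lattice=LatticeConfig(Lx=30, Ly=2), kinetics=KineticsParams(),
                        boundary=BoundaryRates(0.8, 0.8), warmup=0, sampling=400,
                        n_blocks=1, tag_times=(0, 50, 200), tag_record_len=100, seed=6)
        trajs = tag_particles(run(cfg))
        entries = {tr.label: tr.entry_time for tr in trajs}
        assert entries["A"] <= entries["B"] <= entries["C"]
        assert entries["B"] >= 50 and entries["C"] >= 200


class TestMSD:
    def test_synthetic_ballistic_recovers_exponent_two(self):
        rng = np.random.default_rng(7)
        trajs = [TaggedTrajectory("A", i, 0, -1, 0,
                                  dx=np.cumsum(rng.random(2000) < 0.8),
                                  dy=np.zeros(2000, dtype=int))
                 for i in range(150)]
        fit = fit_msd(msd(trajs), 30, 2000, log_correction=False)
        assert fit.exponent == pytest.approx(2.0, abs=0.05)

    def test_synthetic_diffusive_recovers_exponent_one(self):
        rng = np.random.default_rng(8)
        trajs = [TaggedTrajectory("A", i, 0, -1, 0,
                                  dx=np.cumsum(rng.integers(0, 2, 4000) * 2 - 1),
                                  dy=np.zeros(4000, dtype=int))
                 for i in range(400)]
        fit = fit_msd(msd(trajs), 40, 4000, log_correction=False)
        assert fit.exponent == pytest.approx(1.0, abs=0.1)

    def test_transverse_axis_diffusive(self, msd_trajectories):
        curve = msd(msd_trajectories, axis="transverse")
        fit = fit_msd(curve, 2, 64, log_correction=False)
        assert fit.exponent == pytest.approx(1.0, abs=0.15)

    def test_window_must_span_decades(self, msd_trajectories):
        with pytest.raises(ValueError, match="decades"):
            fit_msd(msd(msd_trajectories), 100, 1000)

    def test_fit_refused_below_min_realizations(self):
        trajs = [TaggedTrajectory("A", i, 0, -1, 0,
                                  dx=np.arange(500), dy=np.zeros(500, int))
                 for i in range(10)]
        curve = msd(trajs)  # curve still returned
        assert len(curve.t) == 500
        with pytest.raises(ValueError, match="realizations"):
            fit_msd(curve, 10, 500)


class TestDwell:
    @pytest.mark.parametrize("p", [0.1, 0.3, 0.7])
    def test_geometric_generator_recovery(self, p):
        """Known geometric law: MLE recovers -ln(1-p) within 5%."""
        iv = np.random.default_rng(9).geometric(p, 6000)
        d = dwell_statistics(iv)
        assert d.model == "single"
        assert d.single["rate"] == pytest.approx(-np.log1p(-p), rel=0.05)

    def test_histogram_only_below_minimum(self):
        with pytest.warns(UserWarning, match="histogram"):
            d = dwell_statistics(np.array([3, 4, 5]))
        assert d.model is None and d.counts[3] == 1

    def test_intervals_start_at_one(self):
        with pytest.raises(ValueError):
            dwell_statistics(np.array([0, 1, 2] * 300))

    def test_free_particle_single_exponential(self, dwell_free_trajectories):
        d = dwell_statistics(dwell_free_trajectories)
        assert d.n >= 500
        assert d.model == "single"

    def test_congested_double_exponential(self, dwell_congested_trajectories):
        d = dwell_statistics(dwell_congested_trajectories)
        assert d.n >= 500
        assert d.model == "double"
        # suppressed head: the fast component enters with negative weight,
        # i.e. slower apparent decay at short waiting times
        assert d.double["w_fast"] < 0
        assert d.double["rate_fast"] > d.double["rate_slow"]


class TestProfileFits:
    def test_tangent_generator_recovery(self):
        """Known tangent-profile parameters recovered within 5% from 1%
        noise."""
        Lx = 400
        u = (np.arange(1, Lx + 1) - 0.5) / Lx
        true = dict(a=0.45, q=1.1, u0=0.5)
        rho = true["a"] * (1 - true["q"] * np.tan(true["q"] * (u - true["u0"])))
        rho += np.random.default_rng(10).normal(0, 0.01 * rho.mean(), Lx)
        fit = fit_profile(_make_profile(rho), phase="MC")
        assert fit.params["rho_max"] == pytest.approx(true["a"], rel=0.05)
        assert fit.params["q"] == pytest.approx(true["q"], rel=0.05)
        assert fit.params["u0"] == pytest.approx(true["u0"], rel=0.05)

    def test_flat_profile_gives_small_q(self):
        rho = np.full(300, 0.42)
        fit = fit_profile(_make_profile(rho), phase="MC")
        assert abs(fit.params["q"] * fit.params["rho_max"]) < 0.05

    def test_tanh_recovery_and_beats_linear(self):
        Lx = 400
        u = (np.arange(1, Lx + 1) - 0.5) / Lx
        rho = 0.4 + 0.25 * np.tanh((u - 0.55) / 0.08)
        rho += np.random.default_rng(11).normal(0, 0.004, Lx)
        fit = fit_profile(_make_profile(rho), phase="coexistence")
        assert fit.params["u0"] == pytest.approx(0.55, rel=0.05)
        assert fit.params["amplitude"] == pytest.approx(0.25, rel=0.05)
        assert fit.rss < fit.linear_rss

    def test_invalid_phase(self):
        with pytest.raises(ValueError):
            fit_profile(_make_profile(np.full(100, 0.3)), phase="LD")


class TestOscillations:
    def test_ld_entrance_period_four(self, ld_osc_run):
        prof = measure_density(ld_osc_run)
        assert oscillation_period(prof) == 4

    def test_synthetic_period_detection(self):
        x = np.arange(1, 301)
        rho = 0.2 + 0.05 * np.exp(-x / 30) * np.cos(2 * np.pi * x / 4)
        assert oscillation_period(_make_profile(rho)) == 4
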