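"""Canonical study conditions and deterministic fixture generators.

Each suite returns plain RunConfig objects (regenerating a suite with the
same arguments is byte-identical after serialization).  The parameter values
are the study conditions used throughout: primary-site kinetics
Patt = 0.8, Pdet = 0.2; load conditions Satt = 0.8 / 0.5 / 0.2 with
Sdet = 1 - Satt; direction probabilities Px = 0.95, Py = 0.025 unless a
suite varies Py on purpose.
"""

from __future__ import annotations

from .engine import run
from .observables import TaggedTrajectory, tag_particles
from .params import BoundaryRates, KineticsParams, LatticeConfig, RunConfig

__all__ = ["make_fixtures", "run_msd_ensemble", "SUITES",
           "MSD_RUNS", "MSD_T", "MSD_FIT_TMIN"]

# single-particle MSD protocol: every motor has left the Lx-track well before
# the run ends (transit takes ~0.4 Lx MCS), so the MSD covers the full
# ballistic-to-saturation crossover
MSD_LX, MSD_LY = 500, 4
MSD_RUNS = 1000
MSD_T = 4 * MSD_LX
# fit window for the published log-corrected MSD form: from the end of the
# few-tens-of-MCS microscopic transient to the end of the run (1.8 decades)
MSD_FIT_TMIN = 30.0


def _msd_single_configs(n_runs: int = MSD_RUNS, seed: int = 1) -> list[RunConfig]:
    base = RunConfig(
        lattice=LatticeConfig(Lx=MSD_LX, Ly=MSD_LY),
        kinetics=KineticsParams.high_load(),
        boundary=BoundaryRates(alpha=0.0, beta=1.0),
        warmup=0, sampling=MSD_T, n_blocks=1,
        n_init=1, tag_times=(0,), tag_record_len=MSD_T,
    )
    return [base.replace(seed=seed + i) for i in range(n_runs)]


def _dwell_configs(kind: str, n_runs: int = 30, seed: int = 1) -> list[RunConfig]:
    if kind == "free":
        # particle A on a filling low-density lattice: uncrowded waiting times
        base = RunConfig(
            lattice=LatticeConfig(Lx=100, Ly=4),
            kinetics=KineticsParams.high_load(),
            boundary=BoundaryRates(alpha=0.3, beta=0.9),
            warmup=0, sampling=600, n_blocks=1,
            tag_times=(0,), tag_record_len=500,
        )
    elif kind == "congested":
        # late entrant (class C, threshold ~ Lx^2) in a jammed HD state,
        # mean density ~ 0.85
        base = RunConfig(
            lattice=LatticeConfig(Lx=100, Ly=4),
            kinetics=KineticsParams.low_load(),
            boundary=BoundaryRates(alpha=0.9, beta=0.15),
            warmup=0, sampling=12_000, n_blocks=1,
            tag_times=(10_000,), tag_record_len=2_000,
        )
    else:
        raise ValueError(f"unknown dwell fixture kind {kind!r}")
    return [base.replace(seed=seed + 100 + i) for i in range(n_runs)]


SUITES = ("tasep", "mc_high", "mc_low", "ld_osc", "hd_low", "single_msd", "dwell")


def make_fixtures(suite: str) -> dict:
    """Deterministic seeded mini-run configurations for the named suite.

    Suites: "tasep" (unit-step limit, one run per TASEP phase), "mc_high" /
    "mc_low" (1D maximal-current runs under high / low load), "ld_osc"
    (quasi-2D low-load LD run with entrance oscillations), "hd_low" (quasi-2D
    low-load HD run), "single_msd" (single-motor trajectory ensemble) and
    "dwell" (free class-A and congested class-C tagged ensembles).
    """
    if suite == "tasep":
        base = RunConfig(lattice=LatticeConfig(Lx=500, Ly=1),
                         kinetics=KineticsParams.tasep_limit(),
                         warmup=20_000, sampling=50_000, seed=11)
        return {
            "mc": base.replace(boundary=BoundaryRates(0.9, 0.9)),
            "ld": base.replace(boundary=BoundaryRates(0.2, 0.9), seed=12),
            "hd": base.replace(boundary=BoundaryRates(0.9, 0.3), seed=13),
        }
    if suite == "mc_high":
        return {"mc": RunConfig(lattice=LatticeConfig(Lx=500, Ly=1),
                                kinetics=KineticsParams.high_load(Px=1.0, Py=0.0),
                                boundary=BoundaryRates(0.95, 0.95),
                                warmup=50_000, sampling=100_000, seed=21)}
    if suite == "mc_low":
        return {"mc": RunConfig(lattice=LatticeConfig(Lx=500, Ly=1),
                                kinetics=KineticsParams.low_load(Px=1.0, Py=0.0),
                                boundary=BoundaryRates(0.95, 0.95),
                                warmup=50_000, sampling=100_000, seed=22)}
    if suite == "ld_osc":
        return {"ld": RunConfig(lattice=LatticeConfig(Lx=300, Ly=4),
                                kinetics=KineticsParams.low_load(),
                                boundary=BoundaryRates(0.2, 0.9),
                                warmup=30_000, sampling=150_000, seed=31)}
    if suite == "hd_low":
        return {"hd": RunConfig(lattice=LatticeConfig(Lx=300, Ly=4),
                                kinetics=KineticsParams.low_load(),
                                boundary=BoundaryRates(0.9, 0.3),
                                warmup=30_000, sampling=60_000, seed=41)}
    if suite == "single_msd":
        return {"runs": _msd_single_configs()}
    if suite == "dwell":
        return {"free_A": _dwell_configs("free"),
                "congested_C": _dwell_configs("congested")}
    raise ValueError(f"unknown fixture suite {suite!r}; choose from {SUITES}")


def run_msd_ensemble(configs: list[RunConfig]) -> list[TaggedTrajectory]:
    """Run each config and collect its tagged trajectories (one independent
    realization per run)."""
    trajs: list[TaggedTrajectory] = []
    for cfg in configs:
        trajs.extend(tag_particles(run(cfg)))
    return trajs
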