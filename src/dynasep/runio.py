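"""Disk output for simulation runs: tidy CSV tables plus a JSON summary.

File schemas (version tag in the first header-comment line of each CSV):

* density.csv  — column, rho, rho_se, rho_lane0..rho_lane{Ly-1}
* current.csv  — bond (0 = entry, Lx = exit), crossings_per_lane_mcs
* jumps.csv    — displacement (1..4), forward, transverse, exits
* events.csv   — mcs, particle, lane, column, displacement, kind
                 (kind: inject / jump_x / jump_y / exit); only when the
                 event log is enabled
* summary.json — resolved config, seed, bulk density, mean current,
                 transverse current, injection/extraction totals

Outputs are byte-for-byte reproducible from (config, seed); wall-clock
information goes to run.log only.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._kernel import EV_EXIT, EV_INJECT, EV_JUMP_X, EV_JUMP_Y
from .engine import RunResult, run
from .observables import jump_histogram, measure_current, measure_density
from .params import RunConfig, save_config

__all__ = ["run_simulation", "write_outputs"]

SCHEMA = "dynasep-csv-v1"
_KIND = {EV_INJECT: "inject", EV_JUMP_X: "jump_x", EV_JUMP_Y: "jump_y", EV_EXIT: "exit"}


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA}\n")
        df.to_csv(fh, index=False)


def write_outputs(result: RunResult, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    save_config(cfg, outdir / "config.json")

    prof = measure_density(result)
    dens = pd.DataFrame({"column": prof.x, "rho": prof.rho, "rho_se": prof.rho_se})
    for l in range(result.Ly):
        dens[f"rho_lane{l}"] = prof.rho_lane[l]
    _write_csv(dens, outdir / "density.csv")

    cur = measure_current(result)
    _write_csv(pd.DataFrame({"bond": np.arange(result.Lx + 1),
                             "crossings_per_lane_mcs": cur.bond_rates}),
               outdir / "current.csv")

    h = jump_histogram(result)
    _write_csv(pd.DataFrame({"displacement": np.arange(1, 5),
                             "forward": h.forward[1:], "transverse": h.transverse[1:],
                             "exits": h.exits[1:]}),
               outdir / "jumps.csv")

    if result.events is not None:
        ev = pd.DataFrame(result.events,
                          columns=["mcs", "particle", "lane", "column",
                                   "displacement", "kind"])
        ev["column"] += 1  # public columns are 1-based
        ev["kind"] = ev["kind"].map(_KIND)
        _write_csv(ev, outdir / "events.csv")

    summary = {
        "schema": SCHEMA,
        "version": __version__,
        "config": cfg.to_dict(),
        "bulk_density": prof.bulk,
        "bulk_density_se": prof.bulk_se,
        "current": cur.mean,
        "current_se": cur.se,
        "transverse_current": cur.transverse,
        "transverse_current_se": cur.transverse_se,
        "injections": result.n_injected,
        "extractions": result.n_extracted,
        "final_particles": result.n_final,
        "events_overflowed": result.events_overflowed,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir


def run_simulation(config: RunConfig, outdir: str | Path) -> RunResult:
    """Execute a run and write the full output set to `outdir`.

    Identical (config, seed) produce identical files; run.log (seed and wall
    time) is the only timing-dependent artifact.
    """
    t0 = time.perf_counter()
    result = run(config)
    wall = time.perf_counter() - t0
    outdir = write_outputs(result, outdir)
    with open(Path(outdir) / "run.log", "w") as fh:
        fh.write(f"seed={config.seed} mcs={config.warmup + config.sampling} "
                 f"wall_seconds={wall:.3f}\n")
    return result
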