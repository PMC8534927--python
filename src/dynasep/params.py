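"""Parameter containers and run configuration.

Every quantity in the model is a per-trial probability: one Monte Carlo step
(MCS) is one full sweep of the lattice, and each attachment, detachment,
injection, extraction or hop trial happens at most once per particle (or lane)
per MCS.  Configurations are plain dataclasses that serialize to/from JSON and
can be read from TOML; a run is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

__all__ = [
    "ConfigError",
    "KineticsParams",
    "LatticeConfig",
    "BoundaryRates",
    "RunConfig",
    "load_config",
    "save_config",
]

_PX_TOL = 1e-9  # numerical slack on the exact constraint Px + 2*Py = 1


class ConfigError(ValueError):
    """Raised on invalid parameters; carries every detected problem."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n" + "\n".join(f"- {p}" for p in problems))


def _prob_check(problems: list[str], name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        problems.append(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class KineticsParams:
    """ATP kinetics of a single motor plus the hop-direction probabilities.

    Patt/Pdet act on the primary (hydrolysis) site, Satt/Sdet on each of the
    three load-carrying secondary sites independently.  Px is the probability
    of attempting a forward hop, Py the probability of hopping up (and,
    separately, down); the constraint Px + 2*Py = 1 is enforced exactly.
    """

    Patt: float = 0.8
    Pdet: float = 0.2
    Satt: float = 0.8
    Sdet: float = 0.2
    Px: float = 0.95
    Py: float = 0.025

    def __post_init__(self) -> None:
        problems: list[str] = []
        for name in ("Patt", "Pdet", "Satt", "Sdet", "Px", "Py"):
            _prob_check(problems, name, getattr(self, name))
        if abs(self.Px + 2.0 * self.Py - 1.0) > _PX_TOL:
            problems.append(
                f"direction probabilities must satisfy Px + 2*Py = 1, "
                f"got Px={self.Px!r}, Py={self.Py!r}"
            )
        if problems:
            raise ConfigError(problems)

    # The three load conditions studied throughout, with Sdet = 1 - Satt.
    @classmethod
    def high_load(cls, Px: float = 0.95, Py: float = 0.025) -> "KineticsParams":
        return cls(Satt=0.8, Sdet=0.2, Px=Px, Py=Py)

    @classmethod
    def intermediate_load(cls, Px: float = 0.95, Py: float = 0.025) -> "KineticsParams":
        return cls(Satt=0.5, Sdet=0.5, Px=Px, Py=Py)

    @classmethod
    def low_load(cls, Px: float = 0.95, Py: float = 0.025) -> "KineticsParams":
        return cls(Satt=0.2, Sdet=0.8, Px=Px, Py=Py)

    @classmethod
    def tasep_limit(cls, Patt: float = 0.8, Pdet: float = 0.2) -> "KineticsParams":
        """Unit-step walker: secondary sites saturate (Satt=1, Sdet=0), so
        every fueled hop has length 1 and the engine reduces to an open TASEP
        with effective hop rate r = Patt / (Patt + Pdet) once Py = 0."""
        return cls(Patt=Patt, Pdet=Pdet, Satt=1.0, Sdet=0.0, Px=1.0, Py=0.0)

    @property
    def hop_ready_prob(self) -> float:
        """Long-run probability that the primary site is fueled after the
        attachment/detachment trial of an undisturbed two-state chain,
        Patt / (Patt + Pdet)."""
        if self.Patt + self.Pdet == 0.0:
            raise ConfigError(["Patt + Pdet = 0: primary site frozen"])
        return self.Patt / (self.Patt + self.Pdet)


@dataclass(frozen=True)
class LatticeConfig:
    """Cylinder geometry: Lx columns (open ends), Ly lanes (periodic)."""

    Lx: int = 500
    Ly: int = 4

    def __post_init__(self) -> None:
        problems: list[str] = []
        if self.Lx < 8:
            problems.append(f"Lx must be >= 8, got {self.Lx}")
        if self.Ly < 1:
            problems.append(f"Ly must be >= 1, got {self.Ly}")
        if problems:
            raise ConfigError(problems)

    @property
    def n_sites(self) -> int:
        return self.Lx * self.Ly


@dataclass(frozen=True)
class BoundaryRates:
    """Injection probability alpha (per lane per MCS, first column) and
    extraction probability beta (per exit opportunity at the last column)."""

    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self) -> None:
        problems: list[str] = []
        _prob_check(problems, "alpha", self.alpha)
        _prob_check(problems, "beta", self.beta)
        if problems:
            raise ConfigError(problems)


@dataclass(frozen=True)
class RunConfig:
    """Complete description of one simulation run.

    warmup MCS are discarded; observables accumulate over the following
    sampling MCS, split into n_blocks equal blocks for error estimation.
    tag_times lists entry-time thresholds (in MCS) at which particles are
    tagged: for each threshold the first particle entering at or after it is
    tracked for tag_record_len MCS after its entry.
    """

    lattice: LatticeConfig = field(default_factory=LatticeConfig)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    boundary: BoundaryRates = field(default_factory=BoundaryRates)
    warmup: int = 10_000
    sampling: int = 20_000
    seed: int = 0
    n_blocks: int = 16
    entry_state: str = "empty"  # "empty" or "stationary" ATP state at entry
    periodic: bool = False      # ring in x: no injection/extraction
    n_init: int = 0             # initial particles (evenly spread); required if periodic
    tag_times: tuple[int, ...] = ()
    tag_record_len: int = 0
    event_capacity: int = 0     # >0 enables the per-event log

    def __post_init__(self) -> None:
        problems: list[str] = []
        if self.warmup < 0:
            problems.append(f"warmup must be >= 0, got {self.warmup}")
        if self.sampling < 1:
            problems.append(f"sampling must be >= 1, got {self.sampling}")
        if not (1 <= self.n_blocks <= self.sampling):
            problems.append(
                f"n_blocks must be in [1, sampling], got {self.n_blocks}"
            )
        if self.entry_state not in ("empty", "stationary"):
            problems.append(f"entry_state must be 'empty' or 'stationary', got {self.entry_state!r}")
        if self.lattice.Ly == 1 and self.kinetics.Py != 0.0:
            problems.append("Ly = 1 requires Py = 0 (a single lane has no transverse moves)")
        if self.periodic and self.n_init <= 0:
            problems.append("periodic runs need n_init > 0 (no injection on a ring)")
        if self.n_init > self.lattice.n_sites:
            problems.append(f"n_init = {self.n_init} exceeds lattice capacity {self.lattice.n_sites}")
        if any(t < 0 for t in self.tag_times):
            problems.append("tag_times must be non-negative")
        if self.tag_times and self.tag_record_len < 1:
            problems.append("tag_record_len must be >= 1 when tag_times is non-empty")
        if problems:
            raise ConfigError(problems)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["tag_times"] = list(self.tag_times)
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        data = dict(data)
        problems: list[str] = []
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            problems.append(f"unknown keys: {sorted(unknown)}")
        sub: dict[str, Any] = {}
        for name, klass in (
            ("lattice", LatticeConfig),
            ("kinetics", KineticsParams),
            ("boundary", BoundaryRates),
        ):
            raw = data.pop(name, {})
            if not isinstance(raw, dict):
                problems.append(f"{name} must be a table/dict")
                continue
            extra = set(raw) - {f.name for f in dataclasses.fields(klass)}
            if extra:
                problems.append(f"unknown keys in {name}: {sorted(extra)}")
                continue
            try:
                sub[name] = klass(**raw)
            except ConfigError as err:
                problems.extend(err.problems)
        if "tag_times" in data:
            data["tag_times"] = tuple(data["tag_times"])
        if problems:
            raise ConfigError(problems)
        try:
            return cls(**sub, **{k: v for k, v in data.items() if k in known})
        except ConfigError:
            raise
        except TypeError as err:  # pragma: no cover - defensive
            raise ConfigError([str(err)]) from err

    def replace(self, **kwargs: Any) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from a JSON or TOML file (by extension)."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = json.load(fh)
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a RunConfig as JSON (the round-trip format)."""
    with open(path, "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
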