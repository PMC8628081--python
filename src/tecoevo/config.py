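"""Run configuration: all model parameters plus scenario/run settings.

Defaults are the model's reference parameterisation: a 150x150
toroidal grid, 10 essential functions, per-TE fitness cost c = 0.005,
natural death d = 0.02, DNA uptake u = 0.01, within-genome transposition
opportunity j = 0.01, fragment diffusion D = 0.01 and degradation
q = 0.02, initial transposition rate phi = 0.9, full insertion damage
b = 1, point-mutation rates of 0.001 per position, and a phi-mutation of
±0.1 with probability 0.01 per TE replication.  Configurations load from
and save to flat YAML; every field is validated on load.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Any

import yaml

from .edna import EdnaParams
from .genome import FitnessParams, Genome
from .mutation import MutationRates
from .transposition import TranspositionParams
from .world import MODES, REPRODUCTION, World

__all__ = ["SimulationConfig"]


@dataclass
class SimulationConfig:
    """Complete, validated parameter set for one simulation run."""

    # grid & run
    width: int = 150
    height: int = 150
    steps: int = 10_000
    seed: int = 1
    outdir: str = "runs/out"
    sample_every: int = 50
    snapshot_every: int = 1000
    write_png: bool = True

    # fitness
    n_functions: int = 10
    c: float = 0.005

    # death & competition
    d: float = 0.02
    epsilon: float = 50.0
    mode: str = "spatial"
    reproduction: str = "asexual_hgt"

    # TE dynamics
    j: float = 0.01
    b: float = 1.0
    phi_init: float = 0.9

    # eDNA pool
    u: float = 0.01
    diffusion: float = 0.01
    q: float = 0.02

    # mutation rates
    single_dup: float = 0.001
    single_del: float = 0.001
    inactivation: float = 0.001
    large_scale: float = 0.001
    phi_mut: float = 0.01
    phi_step: float = 0.1

    # initial population
    initial_essential: int = 10
    initial_noncoding: int = 30
    inoculation: str = "block"       # "block" | "fraction" | "none"
    inoculation_block: int = 5
    inoculation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ValueError("grid must be at least 3x3")
        if self.steps < 0 or self.seed < 0:
            raise ValueError("steps and seed must be non-negative")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.reproduction not in REPRODUCTION:
            raise ValueError(f"unknown reproduction {self.reproduction!r}")
        if self.inoculation not in ("block", "fraction", "none"):
            raise ValueError(f"unknown inoculation {self.inoculation!r}")
        if not 0.0 <= self.phi_init <= 1.0:
            raise ValueError("phi_init must be in [0,1]")
        if self.initial_essential != self.n_functions:
            raise ValueError(
                "the founder genome must carry one copy of each essential "
                f"function ({self.n_functions}); got {self.initial_essential}"
            )
        # parameter-object constructors validate the remaining fields
        self.fitness_params()
        self.mutation_rates()
        self.transposition_params()
        self.edna_params()
        self.competition_params()

    # -- parameter objects ----------------------------------------------

    def fitness_params(self) -> FitnessParams:
        return FitnessParams(c=self.c, n_functions=self.n_functions)

    def mutation_rates(self) -> MutationRates:
        return MutationRates(self.single_dup, self.single_del,
                             self.inactivation, self.large_scale,
                             self.phi_mut, self.phi_step)

    def transposition_params(self) -> TranspositionParams:
        return TranspositionParams(j=self.j, b=self.b)

    def edna_params(self) -> EdnaParams:
        return EdnaParams(u=self.u, D=self.diffusion, q=self.q)

    def competition_params(self):
        from .world import CompetitionParams

        return CompetitionParams(epsilon=self.epsilon, d=self.d,
                                 mode=self.mode, reproduction=self.reproduction)

    # -- IO ---------------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def with_overrides(self, **overrides: Any) -> "SimulationConfig":
        data = self.to_dict()
        data.update(overrides)
        return self.from_dict(data)

    # -- world construction ----------------------------------------------

    def founder_genome(self) -> Genome:
        return Genome.initial(self.initial_essential, self.initial_noncoding)

    def build_world(self) -> tuple[World, list[int]]:
        """Build the initial world: a fully occupied grid of founder
        genomes, plus the configured TE inoculation.  Returns the world
        and the lineage ids founded by inoculation."""
        world = World(
            self.width, self.height,
            fitness_params=self.fitness_params(),
            rates=self.mutation_rates(),
            transposition=self.transposition_params(),
            edna=self.edna_params(),
            competition=self.competition_params(),
            seed=self.seed,
        )
        world.fill(self.founder_genome())
        new_ids: list[int] = []
        if self.inoculation == "block":
            new_ids = world.inoculate_block(self.phi_init, self.inoculation_block)
        elif self.inoculation == "fraction":
            new_ids = world.inoculate_fraction(self.phi_init, self.inoculation_fraction)
        return world, new_ids
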