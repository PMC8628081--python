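"""The toroidal world: cells on a grid, competition, reproduction, stepping.

Space is a toroidal ``width x height`` grid holding at most one cell per
site plus a local multiset of eDNA fragments.  Empty sites are the
limiting resource: each timestep, the up-to-eight Moore neighbours of an
empty site compete for it proportional to fitness,

    R_i = f_i / (f_TOTAL + epsilon),

where the regulariser ``epsilon`` leaves the site empty with probability
``epsilon / (f_TOTAL + epsilon)`` so that a lone unfit cell does not win
by default.  The winner's genome is replicated through the mutation scan
and the daughter placed on the site.  The per-timestep schedule is:
death and lysis, eDNA turnover, synchronous competition/reproduction,
DNA uptake and integration (asexual-HGT mode only), lifetime
transposition, then optional well-mixed shuffling.

Three reproduction modes are supported: ``asexual_hgt`` (clonal copying
plus eDNA uptake — the bacteria-like baseline), ``sexual`` (two parents
drawn fitness-proportionally, child formed by a single mid-genome
cross-over, no eDNA uptake) and ``clonal`` (no uptake, no sex).
``mixed_cells`` and ``mixed_edna`` modes destroy spatial structure by
scattering cells (or only fragments) to random sites each step.

This module exposes both the fast engine-backed :class:`World` and small
reference implementations of the competition and reproduction operators
(:func:`compete`, :func:`reproduce_asexual`, :func:`reproduce_sexual`)
on plain :class:`Cell` objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import _engine as eng
from .edna import EdnaParams
from .genome import TE, FitnessParams, Genome, compute_fitness
from .mutation import MutationRates, mutate_genome
from .transposition import TranspositionParams

__all__ = [
    "Cell",
    "CompetitionParams",
    "World",
    "compete",
    "reproduce_asexual",
    "reproduce_sexual",
    "crossover",
]

MODES = {"spatial": eng.MODE_SPATIAL, "mixed_cells": eng.MODE_MIXED_CELLS,
         "mixed_edna": eng.MODE_MIXED_EDNA}
REPRODUCTION = {"asexual_hgt": eng.REPRO_ASEXUAL, "sexual": eng.REPRO_SEXUAL,
                "clonal": eng.REPRO_CLONAL}


@dataclass
class Cell:
    """A single cell: genome plus cached fitness and lineage bookkeeping."""

    genome: Genome
    fitness: float = 0.0
    alive: bool = True
    lineage_id: int = -1
    infected_since: int | None = None

    @classmethod
    def from_genome(cls, genome: Genome, params: FitnessParams = FitnessParams()) -> "Cell":
        return cls(genome, fitness=compute_fitness(genome, params))


@dataclass(frozen=True)
class CompetitionParams:
    """``epsilon``: competition regulariser (default 50.0; see the methods
    note for the calibration); ``d``: baseline
    death probability (default 0.02); ``mode``/``reproduction`` select the
    spatial-structure and reproduction variants."""

    epsilon: float = 50.0
    d: float = 0.02
    mode: str = "spatial"
    reproduction: str = "asexual_hgt"

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("d must be in [0,1]")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.reproduction not in REPRODUCTION:
            raise ValueError(f"unknown reproduction {self.reproduction!r}")


# -- reference operators on Cell objects ---------------------------------


def compete(
    neighbour_cells: list[Cell],
    params: CompetitionParams,
    rng: np.random.Generator,
) -> Cell | None:
    """Fitness-proportional competition for one empty site.

    Cell ``i`` wins with probability ``f_i / (f_TOTAL + epsilon)``; with
    probability ``epsilon / (f_TOTAL + epsilon)`` nobody wins and the site
    stays empty.  Returns the winner or None.
    """
    living = [c for c in neighbour_cells if c.alive]
    if not living:
        return None
    ftot = sum(c.fitness for c in living)
    if ftot <= 0.0:
        return None
    r = rng.random() * (ftot + params.epsilon)
    acc = 0.0
    for c in living:
        acc += c.fitness
        if r < acc:
            return c
    return None


def reproduce_asexual(
    parent: Cell,
    rates: MutationRates,
    fitness_params: FitnessParams,
    rng: np.random.Generator,
    t: int = 0,
) -> Cell:
    """Clonal reproduction: daughter genome is the mutated parent genome."""
    if not parent.alive:
        raise ValueError("dead cells cannot reproduce")
    daughter = mutate_genome(parent.genome, rates, rng)
    cell = Cell.from_genome(daughter, fitness_params)
    cell.lineage_id = parent.lineage_id
    if daughter.te_count > 0:
        cell.infected_since = parent.infected_since if parent.infected_since is not None else t
    return cell


def crossover(parent1: Genome, parent2: Genome) -> Genome:
    """Single mid-genome cross-over: the left half of parent 1 (split at
    floor(len/2)) concatenated with the right half of parent 2."""
    h1 = len(parent1) // 2
    h2 = len(parent2) // 2
    codes = np.concatenate([parent1.codes[:h1], parent2.codes[h2:]])
    phis = np.concatenate([parent1.phis[:h1], parent2.phis[h2:]])
    return Genome(codes, phis)


def reproduce_sexual(
    neighbour_cells: list[Cell],
    params: CompetitionParams,
    rates: MutationRates,
    fitness_params: FitnessParams,
    rng: np.random.Generator,
) -> Cell | None:
    """Sexual reproduction for one empty site.

    The first parent wins the site under the epsilon rule; the mate is
    then drawn purely fitness-proportionally (no epsilon slack) from the
    remaining living neighbours — epsilon regulates who colonises the
    site, not whether a winner finds a mate.  The child is the parents'
    mid-genome cross-over, then mutated as usual.  A winner without any
    living neighbour of positive fitness is copied clonally.
    """
    p1 = compete(neighbour_cells, params, rng)
    if p1 is None:
        return None
    rest = [c for c in neighbour_cells if c.alive and c is not p1]
    ftot2 = sum(c.fitness for c in rest)
    p2 = None
    if ftot2 > 0.0:
        r = rng.random() * ftot2
        acc = 0.0
        for c in rest:
            acc += c.fitness
            if r < acc:
                p2 = c
                break
    if p2 is None:
        child = p1.genome
    else:
        child = crossover(p1.genome, p2.genome)
    daughter = mutate_genome(child, rates, rng)
    cell = Cell.from_genome(daughter, fitness_params)
    cell.lineage_id = p1.lineage_id
    return cell


# -- the engine-backed world ---------------------------------------------


def _moore_table(width: int, height: int) -> np.ndarray:
    """Site index -> its 8 toroidal Moore neighbours (row-major sites)."""
    n = width * height
    nbr = np.empty((n, 8), dtype=np.int32)
    xs = np.arange(n) % width
    ys = np.arange(n) // width
    a = 0
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            nbr[:, a] = ((ys + dy) % height) * width + (xs + dx) % width
            a += 1
    return nbr


@dataclass
class StepEvents:
    """Lineage-relevant events of one timestep (engine event buffers)."""

    death_lineage: np.ndarray
    death_te: np.ndarray
    death_depth: np.ndarray
    birth_lineage: np.ndarray
    new_infections: np.ndarray
    t: int = 0


class World:
    """A toroidal grid of cells and eDNA fragments, stepped by the engine.

    Construct with explicit parameter objects, or via
    :meth:`tecoevo.config.SimulationConfig.build_world` for scenario runs.
    """

    GENOME_CAP = 1024

    def __init__(
        self,
        width: int = 150,
        height: int = 150,
        *,
        fitness_params: FitnessParams = FitnessParams(),
        rates: MutationRates = MutationRates(),
        transposition: TranspositionParams = TranspositionParams(),
        edna: EdnaParams = EdnaParams(),
        competition: CompetitionParams = CompetitionParams(),
        seed: int = 0,
        fragment_capacity: int | None = None,
    ):
        self.width = int(width)
        self.height = int(height)
        self.n_sites = self.width * self.height
        self.fitness_params = fitness_params
        self.rates = rates
        self.transposition = transposition
        self.edna = edna
        self.competition = competition
        self.seed = int(seed)
        self.t = 0

        n, lmax = self.n_sites, self.GENOME_CAP
        self.occ = np.zeros(n, dtype=np.bool_)
        self.codes = np.zeros((n, lmax), dtype=np.int8)
        self.phis = np.zeros((n, lmax), dtype=np.float32)
        self.glen = np.zeros(n, dtype=np.int32)
        self.fitness = np.zeros(n, dtype=np.float64)
        self.viable = np.zeros(n, dtype=np.bool_)
        self.te_cnt = np.zeros(n, dtype=np.int32)
        self.ess_cnt = np.zeros(n, dtype=np.int32)
        self.nc_cnt = np.zeros(n, dtype=np.int32)
        self.phi_sum = np.zeros(n, dtype=np.float64)
        self.lineage = np.full(n, -1, dtype=np.int64)
        self.depth = np.zeros(n, dtype=np.int32)
        self.nbr = _moore_table(self.width, self.height)

        fcap = fragment_capacity if fragment_capacity is not None else max(200_000, 512 * n)
        self.f_site = np.zeros(fcap, dtype=np.int32)
        self.f_len = np.zeros(fcap, dtype=np.int8)
        self.f_codes = np.zeros((fcap, 8), dtype=np.int8)
        self.f_phis = np.zeros((fcap, 8), dtype=np.float32)
        self.f_te = np.zeros(fcap, dtype=np.int16)
        self.f_count = np.zeros(1, dtype=np.int64)
        self.f_dropped = np.zeros(1, dtype=np.int64)

        # scratch buffers for the engine
        self._occ_snap = np.zeros(n, dtype=np.bool_)
        self._wcodes = np.zeros(lmax, dtype=np.int8)
        self._wphis = np.zeros(lmax, dtype=np.float32)
        self._wfresh = np.zeros(lmax, dtype=np.uint8)
        self._tbuf = np.zeros(lmax, dtype=np.float32)
        self._perm = np.zeros(n, dtype=np.int64)
        self.next_lineage = np.zeros(1, dtype=np.int64)
        self._ev_death_lin = np.zeros(n, dtype=np.int64)
        self._ev_death_te = np.zeros(n, dtype=np.int32)
        self._ev_death_depth = np.zeros(n, dtype=np.int32)
        self._ev_death_t = np.zeros(n, dtype=np.int64)
        self._ev_birth_lin = np.zeros(n, dtype=np.int64)
        self._ev_inf_lin = np.zeros(n, dtype=np.int64)

        self._params_vec = self._build_params()
        eng.seed_rng(self.seed % (2**31))
        self._init_rng = np.random.default_rng(self.seed)

    # -- parameters ------------------------------------------------------

    def _build_params(self) -> np.ndarray:
        P = np.zeros(eng.NPARAMS, dtype=np.float64)
        P[eng.P_D] = self.competition.d
        P[eng.P_U] = self.edna.u
        P[eng.P_J] = self.transposition.j
        P[eng.P_DIFF] = self.edna.D
        P[eng.P_Q] = self.edna.q
        P[eng.P_B] = self.transposition.b
        P[eng.P_C] = self.fitness_params.c
        P[eng.P_EPS] = self.competition.epsilon
        P[eng.P_NFUNC] = self.fitness_params.n_functions
        P[eng.P_SDUP] = self.rates.single_dup
        P[eng.P_SDEL] = self.rates.single_del
        P[eng.P_INACT] = self.rates.inactivation
        P[eng.P_LARGE] = self.rates.large_scale
        P[eng.P_PHIMUT] = self.rates.phi_mut
        P[eng.P_PHISTEP] = self.rates.phi_step
        P[eng.P_MODE] = MODES[self.competition.mode]
        P[eng.P_REPRO] = REPRODUCTION[self.competition.reproduction]
        return P

    # -- population setup ------------------------------------------------

    def site_index(self, x: int, y: int) -> int:
        return (y % self.height) * self.width + (x % self.width)

    def place_cell(self, x: int, y: int, genome: Genome, lineage_id: int = -1) -> None:
        """Put a cell with ``genome`` at (x, y), replacing any occupant."""
        i = self.site_index(x, y)
        L = min(len(genome), self.GENOME_CAP)
        self.occ[i] = True
        self.glen[i] = L
        self.codes[i, :L] = genome.codes[:L]
        self.phis[i, :L] = genome.phis[:L]
        self.lineage[i] = lineage_id
        self.depth[i] = 0
        eng.refresh_cell(i, self.codes, self.phis, self.glen, self._params_vec,
                         self.fitness, self.viable, self.te_cnt, self.ess_cnt,
                         self.nc_cnt, self.phi_sum)

    def fill(self, genome: Genome) -> None:
        """Fully occupy the grid with clones of ``genome``."""
        for y in range(self.height):
            for x in range(self.width):
                self.place_cell(x, y, genome)

    def genome_at(self, x: int, y: int) -> Genome | None:
        i = self.site_index(x, y)
        if not self.occ[i]:
            return None
        L = self.glen[i]
        return Genome(self.codes[i, :L].copy(), self.phis[i, :L].copy())

    def inoculate_block(self, phi: float, block: int = 5) -> list[int]:
        """Insert one TE (propensity ``phi``) into every cell of a central
        ``block x block`` square, without insertion damage.  Each newly
        infected cell founds a lineage; returns the new lineage ids."""
        x0 = self.width // 2 - block // 2
        y0 = self.height // 2 - block // 2
        new_ids = []
        for y in range(y0, y0 + block):
            for x in range(x0, x0 + block):
                ids = self._infect_site(self.site_index(x, y), phi)
                new_ids.extend(ids)
        return new_ids

    def inoculate_fraction(self, phi: float, fraction: float) -> list[int]:
        """Infect a random ``fraction`` of living cells with one TE each,
        without insertion damage (ecological initial condition)."""
        occupied = np.nonzero(self.occ)[0]
        k = int(round(fraction * len(occupied)))
        chosen = self._init_rng.choice(occupied, size=k, replace=False)
        new_ids = []
        for i in chosen:
            new_ids.extend(self._infect_site(int(i), phi))
        return new_ids

    def _infect_site(self, i: int, phi: float) -> list[int]:
        if not self.occ[i] or self.glen[i] + 1 > self.GENOME_CAP:
            return []
        L = int(self.glen[i])
        pos = int(self._init_rng.integers(0, L + 1))
        self.codes[i, pos + 1 : L + 1] = self.codes[i, pos:L]
        self.phis[i, pos + 1 : L + 1] = self.phis[i, pos:L]
        self.codes[i, pos] = TE
        self.phis[i, pos] = phi
        self.glen[i] = L + 1
        eng.refresh_cell(i, self.codes, self.phis, self.glen, self._params_vec,
                         self.fitness, self.viable, self.te_cnt, self.ess_cnt,
                         self.nc_cnt, self.phi_sum)
        if self.lineage[i] < 0:
            lid = int(self.next_lineage[0])
            self.lineage[i] = lid
            self.depth[i] = 0
            self.next_lineage[0] += 1
            return [lid]
        return []

    # -- stepping --------------------------------------------------------

    def step(self) -> StepEvents:
        """Advance one timestep; returns the lineage events of the step."""
        nd, nb, ninf = eng.step(
            self.t, self.occ, self.codes, self.phis, self.glen,
            self._params_vec, self.fitness, self.viable,
            self.te_cnt, self.ess_cnt, self.nc_cnt, self.phi_sum,
            self.lineage, self.depth, self.nbr,
            self.f_site, self.f_len, self.f_codes, self.f_phis, self.f_te,
            self.f_count, self.f_dropped,
            self._occ_snap, self._wcodes, self._wphis, self._wfresh,
            self._tbuf, self._perm, self.next_lineage,
            self._ev_death_lin, self._ev_death_te, self._ev_death_depth,
            self._ev_death_t, self._ev_birth_lin, self._ev_inf_lin,
        )
        events = StepEvents(
            death_lineage=self._ev_death_lin[:nd].copy(),
            death_te=self._ev_death_te[:nd].copy(),
            death_depth=self._ev_death_depth[:nd].copy(),
            birth_lineage=self._ev_birth_lin[:nb].copy(),
            new_infections=self._ev_inf_lin[:ninf].copy(),
            t=self.t,
        )
        self.t += 1
        return events

    def run(self, steps: int, observers: list | None = None) -> None:
        """Step ``steps`` times, feeding events to any observers (objects
        with an ``observe(world, events)`` method)."""
        for _ in range(steps):
            events = self.step()
            if observers:
                for obs in observers:
                    obs.observe(self, events)

    # -- summary properties ----------------------------------------------

    @property
    def n_cells(self) -> int:
        return int(np.count_nonzero(self.occ))

    @property
    def cell_te_total(self) -> int:
        return int(self.te_cnt[self.occ].sum())

    @property
    def edna_te_total(self) -> int:
        return int(self.f_te[: self.f_count[0]].sum())

    @property
    def te_total(self) -> int:
        """All TEs in the world: inside genomes plus in the eDNA pool."""
        return self.cell_te_total + self.edna_te_total

    @property
    def n_fragments(self) -> int:
        return int(self.f_count[0])

    def write_genomes(self, path: str) -> None:
        """Dump every living cell's genome in the plain-text line format
        (one genome per line, row-major site order)."""
        with open(path, "w") as fh:
            for i in np.nonzero(self.occ)[0]:
                L = self.glen[i]
                fh.write(Genome(self.codes[i, :L], self.phis[i, :L]).to_text())
                fh.write("\n")

    # -- checkpointing ---------------------------------------------------

    def save(self, path: str) -> None:
        """Checkpoint the full world state to a self-describing .npz."""
        meta = {
            "width": self.width, "height": self.height, "t": self.t,
            "seed": self.seed,
            "fitness_params": vars(self.fitness_params).copy(),
            "rates": vars(self.rates).copy(),
            "transposition": vars(self.transposition).copy(),
            "edna": vars(self.edna).copy(),
            "competition": vars(self.competition).copy(),
        }
        fc = int(self.f_count[0])
        np.savez_compressed(
            path, meta=json.dumps(meta),
            occ=self.occ, codes=self.codes, phis=self.phis, glen=self.glen,
            lineage=self.lineage, depth=self.depth,
            f_site=self.f_site[:fc], f_len=self.f_len[:fc],
            f_codes=self.f_codes[:fc], f_phis=self.f_phis[:fc],
            f_te=self.f_te[:fc], next_lineage=self.next_lineage, t=self.t,
        )

    @classmethod
    def load(cls, path: str) -> "World":
        """Restore a checkpointed world.  The engine RNG is reseeded from
        the stored seed plus the stored timestep."""
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            w = cls(
                meta["width"], meta["height"],
                fitness_params=FitnessParams(**meta["fitness_params"]),
                rates=MutationRates(**meta["rates"]),
                transposition=TranspositionParams(**meta["transposition"]),
                edna=EdnaParams(**meta["edna"]),
                competition=CompetitionParams(**meta["competition"]),
                seed=meta["seed"],
            )
            w.t = int(z["t"])
            w.occ[:] = z["occ"]
            w.codes[:] = z["codes"]
            w.phis[:] = z["phis"]
            w.glen[:] = z["glen"]
            w.lineage[:] = z["lineage"]
            w.depth[:] = z["depth"]
            fc = len(z["f_site"])
            w.f_site[:fc] = z["f_site"]
            w.f_len[:fc] = z["f_len"]
            w.f_codes[:fc] = z["f_codes"]
            w.f_phis[:fc] = z["f_phis"]
            w.f_te[:fc] = z["f_te"]
            w.f_count[0] = fc
            w.next_lineage[:] = z["next_lineage"]
        eng.seed_rng((w.seed + 7919 * w.t) % (2**31))
        eng.refresh_all(w.occ, w.codes, w.phis, w.glen, w._params_vec,
                        w.fitness, w.viable, w.te_cnt, w.ess_cnt,
                        w.nc_cnt, w.phi_sum)
        return w
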