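"""The extracellular DNA (eDNA) pool: lysis, diffusion, degradation, uptake.

Dead cells lyse and spill their genome into the environment as short
fragments of 3–8 genetic elements, cut left to right with independent
uniform lengths (a final remainder shorter than 3 is kept, so fragments
partition the genome exactly).  Fragments sit on grid sites; every
timestep each fragment independently degrades with probability ``q`` or
moves to a random Moore neighbour with probability ``D``.

Living cells take up co-located fragments with probability ``u`` per
fragment.  Uptake is destructive: the fragment leaves the pool, and only
its TEs can cross into the recipient genome — each integrates with its own
propensity ``phi`` at a uniform position (with insertion damage ``b``),
and is offered a phi-mutation as any replication is.  Essential and
non-coding fragment content is inert and lost; there is no homologous
recombination in this model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import TE, Genome
from .mutation import MutationRates, _mutate_phi_value
from .transposition import insert_te

__all__ = [
    "Fragment",
    "EdnaParams",
    "FRAGMENT_MIN",
    "FRAGMENT_MAX",
    "lyse",
    "step_edna",
    "uptake_and_integrate",
]

#: fragment length range produced by lysis (remainder pieces may be shorter)
FRAGMENT_MIN, FRAGMENT_MAX = 3, 8

#: Moore-neighbourhood offsets (8 surrounding sites)
MOORE_OFFSETS = tuple(
    (dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)
)


@dataclass
class Fragment:
    """A short ordered stretch of genetic elements residing at one site."""

    codes: np.ndarray
    phis: np.ndarray
    site: tuple[int, int]

    def __len__(self) -> int:
        return len(self.codes)

    @property
    def te_count(self) -> int:
        return int(np.count_nonzero(self.codes == TE))


@dataclass(frozen=True)
class EdnaParams:
    """``u``: per-fragment uptake probability (default 0.01); ``D``:
    per-fragment diffusion probability (default 0.01); ``q``: per-fragment
    degradation probability (default 0.02)."""

    u: float = 0.01
    D: float = 0.01
    q: float = 0.02

    def __post_init__(self) -> None:
        for name in ("u", "D", "q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


def fragment_lengths(genome_length: int, rng: np.random.Generator) -> list[int]:
    """Cut lengths for lysing a genome: iid uniform on [3, 8] drawn left to
    right; the final piece is whatever remains (possibly < 3)."""
    lengths = []
    remaining = genome_length
    while remaining > 0:
        cut = int(rng.integers(FRAGMENT_MIN, FRAGMENT_MAX + 1))
        if cut >= remaining:
            lengths.append(remaining)
            break
        lengths.append(cut)
        remaining -= cut
    return lengths


def lyse(
    genome: Genome, site: tuple[int, int], rng: np.random.Generator
) -> list[Fragment]:
    """Fragment a dead cell's genome into the eDNA pool at its site.

    The fragments partition the genome exactly (element conservation);
    an empty genome yields no fragments.
    """
    fragments = []
    start = 0
    for length in fragment_lengths(len(genome), rng):
        fragments.append(
            Fragment(
                genome.codes[start : start + length].copy(),
                genome.phis[start : start + length].copy(),
                site,
            )
        )
        start += length
    return fragments


@dataclass
class EdnaPool:
    """Fragments of a world, with toroidal grid dimensions for diffusion."""

    width: int
    height: int
    fragments: list[Fragment] = field(default_factory=list)

    def at(self, site: tuple[int, int]) -> list[Fragment]:
        return [f for f in self.fragments if f.site == site]

    @property
    def te_count(self) -> int:
        return sum(f.te_count for f in self.fragments)


def step_edna(pool: EdnaPool, params: EdnaParams, rng: np.random.Generator) -> EdnaPool:
    """One timestep of pool turnover: each fragment independently degrades
    with probability ``q``; survivors move to a uniformly chosen Moore
    neighbour (toroidal) with probability ``D``, else stay."""
    survivors = []
    for frag in pool.fragments:
        if rng.random() < params.q:
            continue
        if rng.random() < params.D:
            dx, dy = MOORE_OFFSETS[int(rng.integers(0, 8))]
            x, y = frag.site
            frag = Fragment(frag.codes, frag.phis,
                            ((x + dx) % pool.width, (y + dy) % pool.height))
        survivors.append(frag)
    return EdnaPool(pool.width, pool.height, survivors)


def uptake_and_integrate(
    genome: Genome,
    local_fragments: list[Fragment],
    params: EdnaParams,
    b: float,
    rates: MutationRates,
    rng: np.random.Generator,
) -> tuple[Genome, list[Fragment]]:
    """Offer a living cell every co-located fragment for uptake.

    Each fragment is taken up with probability ``u``; of its content only
    TEs may integrate, each with probability equal to its own ``phi``, at
    a uniform genome position with damage ``b``, and with a phi-mutation
    offered to the integrated copy.  Returns the (possibly new) genome and
    the list of consumed fragments (to be removed from the pool).
    """
    out = genome
    consumed = []
    for frag in local_fragments:
        if rng.random() >= params.u:
            continue
        consumed.append(frag)
        for code, phi in zip(frag.codes, frag.phis):
            if code != TE:
                continue
            if rng.random() < float(phi):
                pos = int(rng.integers(0, len(out) + 1))
                new_phi = _mutate_phi_value(float(phi), rates, rng)
                out, _ = insert_te(out, new_phi, pos, b, rng)
    return (out if consumed else genome.copy()), consumed
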