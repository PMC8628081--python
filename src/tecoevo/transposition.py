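"""Within-genome TE replication and insertion-damage semantics.

Each timestep a cell survives, every TE in its genome gets one opportunity
to replicate, realised with probability ``phi * j`` (the element's own
transposition propensity times the global opportunity rate).  Replication
is copy-and-paste: the template stays put and a new copy is inserted at a
uniformly random position.  Copies made during a timestep do not
themselves replicate in that timestep.

Insertion may damage the genome: with probability ``b`` the coding element
at the insertion site (an essential gene or another TE) is inactivated —
it remains in the genome as a non-coding position.  Non-coding targets are
never damaged, and with ``b = 0`` TEs insert cleanly *next to* elements,
never into them.  Losing the last active copy of an essential gene renders
the cell non-viable; it dies at the next death phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import NONCODING, TE, Genome
from .mutation import MutationRates, _mutate_phi_value

__all__ = ["TranspositionParams", "InsertionReport", "insert_te", "lifetime_transposition"]


@dataclass(frozen=True)
class TranspositionParams:
    """``j``: per-timestep transposition-opportunity probability per TE
    (default 0.01); ``b``: probability that insertion inactivates the
    element at the insertion site (default 1.0)."""

    j: float = 0.01
    b: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.j <= 1.0 or not 0.0 <= self.b <= 1.0:
            raise ValueError("j and b must be probabilities in [0,1]")


@dataclass(frozen=True)
class InsertionReport:
    """What an insertion did to the target site."""

    damaged: bool
    essential_inactivated: bool


def insert_te(
    genome: Genome,
    phi: float,
    pos: int,
    b: float,
    rng: np.random.Generator,
) -> tuple[Genome, InsertionReport]:
    """Insert a TE copy with propensity ``phi`` at ``pos``.

    ``pos`` may equal the genome length (append).  If an element is
    displaced and it is coding, it is inactivated with probability ``b``
    (converted to a non-coding position that stays in the genome).
    Returns the new genome and a report saying whether damage occurred
    and whether an essential gene was hit.
    """
    n = len(genome)
    if not 0 <= pos <= n:
        raise IndexError(f"insertion position {pos} out of range for length {n}")
    codes = np.insert(genome.codes, pos, TE)
    phis = np.insert(genome.phis, pos, np.float32(phi))
    damaged = False
    essential_hit = False
    if pos < n:
        target = int(codes[pos + 1])  # the displaced element, now right of the TE
        if target != NONCODING and (b >= 1.0 or rng.random() < b):
            damaged = True
            essential_hit = target != TE
            codes[pos + 1] = NONCODING
            phis[pos + 1] = 0.0
    return Genome(codes, phis), InsertionReport(damaged, essential_hit)


def lifetime_transposition(
    genome: Genome,
    params: TranspositionParams,
    rates: MutationRates,
    rng: np.random.Generator,
) -> Genome:
    """One timestep of within-genome TE replication.

    TE positions are snapshotted at entry; each such TE replicates with
    probability ``phi * j``, its copy inserted at a uniform position of
    the current (growing) genome and offered one phi-mutation.  New copies
    do not replicate this timestep.
    """
    te_phis = [float(p) for p in genome.phis[genome.codes == TE]]
    out = genome
    for phi in te_phis:
        if rng.random() < phi * params.j:
            pos = int(rng.integers(0, len(out) + 1))
            new_phi = _mutate_phi_value(phi, rates, rng)
            out, _ = insert_te(out, new_phi, pos, params.b, rng)
    return out if out is not genome else genome.copy()
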