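"""Replication-time mutation operators.

When a cell reproduces, the daughter genome is produced by scanning the
parental genome left to right, offering each original position one chance
to mutate.  Four point events compete per position, drawn in fixed order —
large-scale event, single duplication, single deletion, inactivation — and
the first that fires is applied (at most one mutation per scanned
position).  Copies created by a duplication during the scan are marked
fresh and skipped for the remainder of the pass.

Large-scale events start at the scanned position and affect a contiguous
segment whose length is drawn so that on average a quarter of the genome
is covered; the segment is duplicated in tandem, deleted, or inverted in
place (each kind equally likely).  Segments running past the genome end
are truncated there (the genome is linear).

Every TE replication — transposition and host-genome replication alike —
additionally offers the TE a transposition-rate mutation: with probability
``phi_mut`` its ``phi`` steps up or down by ``phi_step`` (default ±0.1,
equal odds), clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import NONCODING, TE, Genome, GenomeElement, transposon

__all__ = [
    "MutationRates",
    "mutate_genome",
    "apply_single_duplication",
    "apply_single_deletion",
    "apply_inactivation",
    "apply_large_scale",
    "draw_segment_length",
    "mutate_phi",
]

LARGE_SCALE_KINDS = ("duplication", "deletion", "inversion")


@dataclass(frozen=True)
class MutationRates:
    """Per-position mutation probabilities applied at replication.

    All rates are probabilities per scanned position (per generation),
    except ``phi_mut`` which is per TE replication; ``phi_step`` is the
    magnitude of a transposition-rate change.
    """

    single_dup: float = 0.001
    single_del: float = 0.001
    inactivation: float = 0.001
    large_scale: float = 0.001
    phi_mut: float = 0.01
    phi_step: float = 0.1

    def __post_init__(self) -> None:
        for name in ("single_dup", "single_del", "inactivation", "large_scale", "phi_mut"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.phi_step <= 0:
            raise ValueError("phi_step must be positive")

    @classmethod
    def disabled(cls) -> "MutationRates":
        """All mutational processes switched off (ecological runs)."""
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.1)


# -- deterministic single-position operators -----------------------------


def _check_pos(genome: Genome, pos: int) -> None:
    if not 0 <= pos < len(genome):
        raise IndexError(f"position {pos} out of range for genome length {len(genome)}")


def apply_single_duplication(genome: Genome, pos: int) -> Genome:
    """Tandem-duplicate the element at ``pos`` (copy inserted right after)."""
    _check_pos(genome, pos)
    codes = np.insert(genome.codes, pos + 1, genome.codes[pos])
    phis = np.insert(genome.phis, pos + 1, genome.phis[pos])
    return Genome(codes, phis)


def apply_single_deletion(genome: Genome, pos: int) -> Genome:
    """Delete the element at ``pos``."""
    _check_pos(genome, pos)
    return Genome(np.delete(genome.codes, pos), np.delete(genome.phis, pos))


def apply_inactivation(genome: Genome, pos: int) -> Genome:
    """Inactivate the element at ``pos``: the position becomes non-coding.

    Essential genes and TEs alike lose their identity (a TE's phi is
    discarded); a non-coding position is unchanged.
    """
    _check_pos(genome, pos)
    codes = genome.codes.copy()
    phis = genome.phis.copy()
    codes[pos] = NONCODING
    phis[pos] = 0.0
    return Genome(codes, phis)


def draw_segment_length(genome_length: int, rng: np.random.Generator) -> int:
    """Length of a large-scale segment on a genome of ``genome_length``.

    Uniform integer on [1, max(1, G//2 - 1)]; the upper bound is
    calibrated so the mean segment covers a quarter of the genome
    (exactly G/4 for even G).
    """
    if genome_length < 1:
        raise ValueError("genome must be non-empty")
    hi = max(1, genome_length // 2 - 1)
    return int(rng.integers(1, hi + 1))


def apply_large_scale(
    genome: Genome,
    pos: int,
    kind: str,
    rng: np.random.Generator,
    length: int | None = None,
) -> Genome:
    """Apply a large-scale duplication, deletion or inversion at ``pos``.

    The affected segment starts at ``pos``; its length is drawn by
    :func:`draw_segment_length` unless given, and is truncated at the
    genome end.  Duplication inserts a tandem copy after the segment;
    inversion reverses the segment in place (length and element multiset
    conserved).
    """
    _check_pos(genome, pos)
    if kind not in LARGE_SCALE_KINDS:
        raise ValueError(f"unknown large-scale kind {kind!r}")
    if length is None:
        length = draw_segment_length(len(genome), rng)
    end = min(pos + length, len(genome))
    codes, phis = genome.codes, genome.phis
    if kind == "duplication":
        codes = np.concatenate([codes[:end], codes[pos:end], codes[end:]])
        phis = np.concatenate([phis[:end], phis[pos:end], phis[end:]])
    elif kind == "deletion":
        codes = np.concatenate([codes[:pos], codes[end:]])
        phis = np.concatenate([phis[:pos], phis[end:]])
    else:  # inversion
        codes = codes.copy()
        phis = phis.copy()
        codes[pos:end] = codes[pos:end][::-1]
        phis[pos:end] = phis[pos:end][::-1]
    return Genome(codes, phis)


def mutate_phi(
    te: GenomeElement, rates: MutationRates, rng: np.random.Generator
) -> GenomeElement:
    """Offer a TE one transposition-rate mutation.

    With probability ``phi_mut`` the rate steps by ±``phi_step`` (equal
    odds), clamped to [0, 1]; otherwise the element is returned unchanged.
    """
    if te.kind != "transposon":
        raise ValueError("mutate_phi requires a transposon element")
    if rng.random() >= rates.phi_mut:
        return te
    step = rates.phi_step if rng.random() < 0.5 else -rates.phi_step
    return transposon(min(1.0, max(0.0, te.phi + step)))


def _mutate_phi_value(phi: float, rates: MutationRates, rng: np.random.Generator) -> float:
    if rng.random() >= rates.phi_mut:
        return phi
    step = rates.phi_step if rng.random() < 0.5 else -rates.phi_step
    return min(1.0, max(0.0, phi + step))


# -- the replication scan ------------------------------------------------


def mutate_genome(
    genome: Genome, rates: MutationRates, rng: np.random.Generator
) -> Genome:
    """Produce a mutated daughter genome by the left-to-right scan.

    Per position the competing events are drawn in the fixed order
    large-scale, single duplication, single deletion, inactivation; the
    first that fires is applied and the cursor moves on.  Elements created
    by duplications during the pass are not re-scanned.  After the scan,
    every TE in the daughter is offered one phi-mutation (each TE copy in
    the daughter is a replication product).
    """
    codes = list(genome.codes)
    phis = list(genome.phis)
    fresh = [False] * len(codes)
    i = 0
    while i < len(codes):
        if fresh[i]:
            i += 1
            continue
        r = rng.random()
        if r < rates.large_scale:
            kind = LARGE_SCALE_KINDS[int(rng.integers(0, 3))]
            seg = draw_segment_length(len(codes), rng)
            end = min(i + seg, len(codes))
            if kind == "duplication":
                codes[end:end] = codes[i:end]
                phis[end:end] = phis[i:end]
                fresh[end:end] = [True] * (end - i)
                i += 1
            elif kind == "deletion":
                del codes[i:end], phis[i:end], fresh[i:end]
                # cursor stays: the next un-scanned element shifted onto i
            else:
                codes[i:end] = codes[i:end][::-1]
                phis[i:end] = phis[i:end][::-1]
                fresh[i:end] = fresh[i:end][::-1]
                i += 1
        elif r < rates.large_scale + rates.single_dup:
            codes.insert(i + 1, codes[i])
            phis.insert(i + 1, phis[i])
            fresh.insert(i + 1, True)
            i += 1
        elif r < rates.large_scale + rates.single_dup + rates.single_del:
            del codes[i], phis[i], fresh[i]
        elif r < rates.large_scale + rates.single_dup + rates.single_del + rates.inactivation:
            codes[i] = NONCODING
            phis[i] = 0.0
            i += 1
        else:
            i += 1
    out = Genome(
        np.array(codes, dtype=np.int8),
        np.array(phis, dtype=np.float32),
    )
    # host-genome replication replicates every TE: offer each a phi-mutation
    if rates.phi_mut > 0.0:
        for p in np.nonzero(out.codes == TE)[0]:
            out.phis[p] = _mutate_phi_value(float(out.phis[p]), rates, rng)
    return out
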