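"""Linear genomes of discrete genetic elements, viability and fitness.

A genome is an ordered sequence of three kinds of elements:

* **essential genes** — one of ``n_functions`` distinct host functions
  (labelled ``a``–``j`` by default); a cell is viable only if every
  function is encoded by at least one active gene;
* **transposable elements (TEs)** — selfish elements that replicate
  independently of the host, each carrying its own transposition
  propensity ``phi`` in [0, 1];
* **non-coding elements** — neutral filler with neither function nor cost.

Fitness depends only on the element census: ``0`` for a non-viable genome,
otherwise ``max(0, 1 - c * T)`` where ``T`` is the TE count and ``c`` the
per-TE fitness penalty.  Redundant gene copies and non-coding DNA are free;
there is no explicit cost on genome size.

Internally genomes are a pair of parallel NumPy arrays (``codes``/``phis``)
so mutation and transposition operators can be expressed as array slicing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "NONCODING",
    "TE",
    "GenomeElement",
    "Genome",
    "FitnessParams",
    "ElementCensus",
    "count_elements",
    "is_viable",
    "compute_fitness",
]

#: integer code of a non-coding element
NONCODING: int = 0
#: integer code of a transposable element
TE: int = 127

_GENE_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class GenomeElement:
    """A single genetic element.

    ``kind`` is one of ``"essential"``, ``"transposon"``, ``"noncoding"``.
    ``gene_type`` (a letter) is present iff essential; ``phi`` (in [0, 1])
    iff transposon.
    """

    kind: str
    gene_type: str | None = None
    phi: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "essential":
            if self.gene_type is None or self.phi is not None:
                raise ValueError("essential elements carry gene_type, not phi")
            if self.gene_type not in _GENE_LETTERS:
                raise ValueError(f"unknown gene type {self.gene_type!r}")
        elif self.kind == "transposon":
            if self.phi is None or self.gene_type is not None:
                raise ValueError("transposons carry phi, not gene_type")
            if not 0.0 <= self.phi <= 1.0:
                raise ValueError(f"phi must be in [0,1], got {self.phi}")
        elif self.kind == "noncoding":
            if self.gene_type is not None or self.phi is not None:
                raise ValueError("noncoding elements carry no attributes")
        else:
            raise ValueError(f"unknown element kind {self.kind!r}")

    @property
    def code(self) -> int:
        if self.kind == "noncoding":
            return NONCODING
        if self.kind == "transposon":
            return TE
        return _GENE_LETTERS.index(self.gene_type) + 1


def essential(letter: str) -> GenomeElement:
    """Shorthand constructor for an essential gene element."""
    return GenomeElement("essential", gene_type=letter)


def transposon(phi: float) -> GenomeElement:
    """Shorthand constructor for a TE with transposition propensity ``phi``."""
    return GenomeElement("transposon", phi=float(phi))


def noncoding() -> GenomeElement:
    """Shorthand constructor for a non-coding element."""
    return GenomeElement("noncoding")


class Genome:
    """An ordered, linear sequence of genetic elements.

    Order is meaningful: mutation operators and sexual cross-over act
    positionally.  A genome may be empty (it is then never viable).
    """

    __slots__ = ("codes", "phis")

    def __init__(self, codes: np.ndarray, phis: np.ndarray):
        codes = np.asarray(codes, dtype=np.int8)
        phis = np.asarray(phis, dtype=np.float32)
        if codes.shape != phis.shape or codes.ndim != 1:
            raise ValueError("codes and phis must be 1-D arrays of equal length")
        self.codes = codes
        self.phis = phis

    # -- construction ----------------------------------------------------

    @classmethod
    def from_elements(cls, elements: Iterable[GenomeElement]) -> "Genome":
        elements = list(elements)
        codes = np.array([e.code for e in elements], dtype=np.int8)
        phis = np.zeros(len(elements), dtype=np.float32)
        for i, e in enumerate(elements):
            if e.kind == "transposon":
                phis[i] = e.phi
        return cls(codes, phis)

    @classmethod
    def empty(cls) -> "Genome":
        return cls(np.zeros(0, dtype=np.int8), np.zeros(0, dtype=np.float32))

    @classmethod
    def initial(cls, n_essential: int = 10, n_noncoding: int = 30) -> "Genome":
        """The canonical founder genome: one copy of each essential gene
        followed by a stretch of non-coding elements (10 + 30 by default)."""
        codes = np.concatenate(
            [
                np.arange(1, n_essential + 1, dtype=np.int8),
                np.zeros(n_noncoding, dtype=np.int8),
            ]
        )
        return cls(codes, np.zeros(len(codes), dtype=np.float32))

    # -- sequence protocol ----------------------------------------------

    def __len__(self) -> int:
        return len(self.codes)

    def __iter__(self) -> Iterator[GenomeElement]:
        for code, phi in zip(self.codes, self.phis):
            yield self._element(int(code), float(phi))

    def __getitem__(self, pos: int) -> GenomeElement:
        return self._element(int(self.codes[pos]), float(self.phis[pos]))

    @staticmethod
    def _element(code: int, phi: float) -> GenomeElement:
        if code == NONCODING:
            return noncoding()
        if code == TE:
            return transposon(phi)
        return essential(_GENE_LETTERS[code - 1])

    def copy(self) -> "Genome":
        return Genome(self.codes.copy(), self.phis.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        if not np.array_equal(self.codes, other.codes):
            return False
        te = self.codes == TE
        return np.array_equal(self.phis[te], other.phis[te])

    def __repr__(self) -> str:
        return f"Genome({self.to_text()!r})"

    # -- serialisation ---------------------------------------------------

    def to_text(self) -> str:
        """Serialise to the plain-text genome line format.

        Essential genes print as their letter, TEs as ``T:<phi>`` with phi
        to three decimals, non-coding elements as ``.``; elements are
        comma-separated.
        """
        parts = []
        for code, phi in zip(self.codes, self.phis):
            if code == NONCODING:
                parts.append(".")
            elif code == TE:
                parts.append(f"T:{phi:.3f}")
            else:
                parts.append(_GENE_LETTERS[code - 1])
        return ",".join(parts)

    @classmethod
    def from_text(cls, line: str) -> "Genome":
        line = line.strip()
        if not line:
            return cls.empty()
        elements = []
        for token in line.split(","):
            token = token.strip()
            if token == ".":
                elements.append(noncoding())
            elif token.startswith("T:"):
                elements.append(transposon(float(token[2:])))
            elif len(token) == 1 and token in _GENE_LETTERS:
                elements.append(essential(token))
            else:
                raise ValueError(f"cannot parse genome token {token!r}")
        return cls.from_elements(elements)

    # -- counts ----------------------------------------------------------

    @property
    def te_count(self) -> int:
        return int(np.count_nonzero(self.codes == TE))

    @property
    def te_phis(self) -> np.ndarray:
        return self.phis[self.codes == TE]


@dataclass(frozen=True)
class FitnessParams:
    """Parameters of the fitness function.

    ``c`` is the per-TE fitness penalty (default 0.005); ``n_functions``
    the number of distinct essential functions a genome must encode
    (default 10, making the minimal viable genome size 10).
    """

    c: float = 0.005
    n_functions: int = 10

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError("c must be non-negative")
        if self.n_functions < 1:
            raise ValueError("n_functions must be >= 1")


@dataclass
class ElementCensus:
    """Per-class and per-gene-type element counts of one genome."""

    essential: int
    transposon: int
    noncoding: int
    per_gene_type: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.essential + self.transposon + self.noncoding


def count_elements(genome: Genome, n_functions: int = 10) -> ElementCensus:
    """Census of a genome: counts per element class and per gene type."""
    codes = genome.codes
    n_te = int(np.count_nonzero(codes == TE))
    n_nc = int(np.count_nonzero(codes == NONCODING))
    per_type = {
        _GENE_LETTERS[t - 1]: int(np.count_nonzero(codes == t))
        for t in range(1, n_functions + 1)
    }
    n_ess = len(codes) - n_te - n_nc
    return ElementCensus(n_ess, n_te, n_nc, per_type)


def is_viable(genome: Genome, params: FitnessParams = FitnessParams()) -> bool:
    """True iff every essential function 1..n_functions is encoded at
    least once.  Inactivated genes are non-coding and do not count."""
    codes = genome.codes
    for t in range(1, params.n_functions + 1):
        if not np.any(codes == t):
            return False
    return True


def compute_fitness(genome: Genome, params: FitnessParams = FitnessParams()) -> float:
    """Fitness of a genome: 0 if non-viable, else ``max(0, 1 - c*T)``.

    Non-coding elements and redundant gene copies are free.  The linear
    TE penalty is clamped at zero because fitness is used as a
    competition weight and must stay non-negative.
    """
    if not is_viable(genome, params):
        return 0.0
    return max(0.0, 1.0 - params.c * genome.te_count)
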