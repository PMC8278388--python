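"""Combinatorial peptide sequence space: enumeration, counting, filtering.

The search space for a chain length ``L`` is the full Cartesian product of the
20 proteinogenic amino acids, ``20**L`` sequences — 400 dipeptides up to
2.56e10 octapeptides.  Everything here streams: the space is never
materialised unless the caller collects it.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Sequence

#: Canonical one-letter amino-acid alphabet, alphabetical (enumeration order).
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_SET = frozenset(ALPHABET)

#: Supported chain-length range for this tool.
MIN_LENGTH = 1
MAX_LENGTH = 8


def validate_peptide(sequence: str) -> str:
    """Return the canonical (uppercase) form of *sequence* or raise ValueError.

    A valid peptide is a non-empty string of 1-8 one-letter codes drawn from
    the 20-residue alphabet.
    """
    if not isinstance(sequence, str):
        raise ValueError(f"peptide must be a string, got {type(sequence).__name__}")
    seq = sequence.upper()
    if not (MIN_LENGTH <= len(seq) <= MAX_LENGTH):
        raise ValueError(
            f"peptide length {len(seq)} outside supported range "
            f"[{MIN_LENGTH}, {MAX_LENGTH}]: {sequence!r}"
        )
    bad = set(seq) - _ALPHABET_SET
    if bad:
        raise ValueError(f"invalid residue(s) {sorted(bad)} in {sequence!r}")
    return seq


def space_size(length: int) -> int:
    """Number of distinct peptides of the given chain length: ``20**length``.

    Exact integer arithmetic; ``space_size(8) == 25_600_000_000``.
    """
    if length < 0:
        raise ValueError(f"length must be >= 0, got {length}")
    return 20**length


def enumerate_space(length: int) -> Iterator[str]:
    """Yield every peptide of the given length in lexicographic order.

    Streaming: constant memory, ``space_size(length)`` items total.
    """
    if not (MIN_LENGTH <= length <= MAX_LENGTH):
        raise ValueError(
            f"length {length} outside supported range [{MIN_LENGTH}, {MAX_LENGTH}]"
        )
    for combo in itertools.product(ALPHABET, repeat=length):
        yield "".join(combo)


def sample_space(length: int, n: int, rng: random.Random) -> list[str]:
    """Draw *n* distinct peptides of the given length uniformly at random.

    Index-based sampling, so the space is never enumerated; mirrors the use
    of 800-peptide random sets for characterising large spaces.
    """
    total = space_size(length)
    if n > total:
        raise ValueError(f"cannot sample {n} distinct peptides from a space of {total}")
    indices = rng.sample(range(total), n)
    return [index_to_peptide(i, length) for i in indices]


def index_to_peptide(index: int, length: int) -> str:
    """Map a lexicographic rank in ``[0, 20**length)`` to its sequence."""
    if not 0 <= index < space_size(length):
        raise ValueError(f"index {index} out of range for length {length}")
    out = []
    for _ in range(length):
        index, r = divmod(index, 20)
        out.append(ALPHABET[r])
    return "".join(reversed(out))


def polyhomopeptide(residue: str, length: int) -> str:
    """Homopolymer of one residue, e.g. ``polyhomopeptide("A", 3) == "AAA"``.

    Polyalanine of the search length is the conventional single-member seed
    for the active-learning loop.
    """
    if residue not in _ALPHABET_SET:
        raise ValueError(f"invalid residue {residue!r}")
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    return residue * length


def unique_union(list_a: Sequence[str], list_b: Sequence[str]) -> int:
    """Count of distinct sequences across both lists (set-union cardinality)."""
    return len(set(list_a) | set(list_b))


_OPS: dict[str, Callable[[float, float], bool]] = {
    "lt": lambda v, b: v < b,
    "le": lambda v, b: v <= b,
    "gt": lambda v, b: v > b,
    "ge": lambda v, b: v >= b,
}


@dataclass(frozen=True)
class Bound:
    """One restriction on a Judred descriptor, e.g. ``Bound("logP_WW", "lt", 0)``."""

    field: str
    op: str  # lt | le | gt | ge
    value: float

    def __post_init__(self) -> None:
        if self.op not in _OPS:
            raise ValueError(f"unknown bound op {self.op!r}; expected one of {sorted(_OPS)}")

    def holds(self, value: float) -> bool:
        return _OPS[self.op](value, self.value)


@dataclass(frozen=True)
class RestrictionFilter:
    """Conjunction of descriptor bounds used to curate the search space.

    An empty bound list is the identity filter.  Field names must resolve
    against the 10-component Judred vector; unknown names raise KeyError at
    application time so configuration mistakes surface immediately.
    """

    bounds: tuple[Bound, ...] = field(default_factory=tuple)

    @classmethod
    def from_specs(cls, specs: Iterable[dict]) -> "RestrictionFilter":
        """Build from config entries ``{"field": ..., "op": ..., "value": ...}``."""
        return cls(tuple(Bound(s["field"], s["op"], float(s["value"])) for s in specs))

    @classmethod
    def parse(cls, *expressions: str) -> "RestrictionFilter":
        """Parse shorthand expressions like ``"logP_WW<0"`` or ``"Z>=2"``."""
        sym = {"<=": "le", ">=": "ge", "<": "lt", ">": "gt"}
        bounds = []
        for expr in expressions:
            for s, op in sym.items():
                if s in expr:
                    name, val = expr.split(s, 1)
                    bounds.append(Bound(name.strip(), op, float(val)))
                    break
            else:
                raise ValueError(f"cannot parse restriction {expr!r}")
        return cls(tuple(bounds))

    @property
    def is_identity(self) -> bool:
        return not self.bounds

    def admits(self, descriptors: dict[str, float]) -> bool:
        for b in self.bounds:
            if b.field not in descriptors:
                raise KeyError(
                    f"restriction field {b.field!r} not a descriptor "
                    f"(have {sorted(descriptors)})"
                )
            if not b.holds(descriptors[b.field]):
                return False
        return True

    def __and__(self, other: "RestrictionFilter") -> "RestrictionFilter":
        return RestrictionFilter(self.bounds + other.bounds)


def apply_restriction(
    peptides: Iterable[str],
    filt: RestrictionFilter,
    descriptor_supplier: Callable[[str], dict[str, float]],
) -> Iterator[str]:
    """Stream the peptides whose descriptors satisfy every bound, order preserved.

    *descriptor_supplier* maps a sequence to its named Judred values (see
    :func:`pepal.judred.judred_dict`).  The identity filter short-circuits.
    """
    if filt.is_identity:
        yield from peptides
        return
    for pep in peptides:
        if filt.admits(descriptor_supplier(pep)):
            yield pep


def read_peptide_list(path) -> list[str]:
    """Read a plain-text peptide list (one uppercase sequence per line).

    Blank lines are skipped; any line with characters outside the alphabet
    raises ValueError naming the line.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            seq = line.strip()
            if not seq:
                continue
            try:
                out.append(validate_peptide(seq))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return out


def write_peptide_list(path, peptides: Iterable[str]) -> None:
    with open(path, "w") as fh:
        for pep in peptides:
            fh.write(pep + "\n")
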