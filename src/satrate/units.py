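"""Canonical tandem-repeat units.

A repeat unit read off a sequencing read is arbitrary in phase (any rotation
describes the same array) and in strand (the array is sequenced from either
side), and a non-primitive unit such as ``ACAC`` describes the same array as
``AC``.  All count and rate tables therefore key on a *canonical* unit: the
primitive period of the sequence, represented by the lexicographically
smallest string among all rotations of the unit and all rotations of its
reverse complement.  Under this convention CAG, AGC, GCA, CTG, TGC and GCT
all collapse to ``AGC``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

MAX_UNIT_LENGTH = 20

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def primitive_period(seq: str) -> str:
    """Shortest unit whose whole-number repetition equals ``seq``."""
    n = len(seq)
    for p in range(1, n + 1):
        if n % p == 0 and seq[:p] * (n // p) == seq:
            return seq[:p]
    return seq  # unreachable


def _rotations(seq: str):
    doubled = seq + seq
    n = len(seq)
    for i in range(n):
        yield doubled[i : i + n]


@dataclass(frozen=True)
class RepeatUnit:
    """A canonical tandem-repeat unit (1-20 bp, primitive, rotation/strand-minimal)."""

    sequence: str

    def __post_init__(self) -> None:
        canon = _canonical_sequence(self.sequence)
        if canon != self.sequence:
            raise ValueError(
                f"{self.sequence!r} is not canonical (expected {canon!r}); "
                "use canonical_unit()"
            )

    @property
    def is_primitive(self) -> bool:
        return True  # enforced at construction

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence

    @property
    def gc_fraction(self) -> Fraction:
        """Exact GC fraction (#G + #C) / |unit|."""
        s = self.sequence
        return Fraction(s.count("G") + s.count("C"), len(s))


def _validate(seq: str) -> None:
    if not seq:
        raise ValueError("empty unit sequence")
    if len(seq) > MAX_UNIT_LENGTH:
        raise ValueError(
            f"unit length {len(seq)} exceeds maximum of {MAX_UNIT_LENGTH}"
        )
    for i, base in enumerate(seq):
        if base not in "ACGT":
            raise ValueError(
                f"non-ACGT character {base!r} at position {i} in {seq!r}"
            )


def _canonical_sequence(seq: str) -> str:
    _validate(seq)
    core = primitive_period(seq)
    rc = reverse_complement(core)
    return min(min(_rotations(core)), min(_rotations(rc)))


def canonical_unit(seq: str) -> RepeatUnit:
    """Canonical representative of ``seq`` under rotation, strand and primitivity.

    >>> canonical_unit("CAG").sequence
    'AGC'
    >>> canonical_unit("ACAC").sequence
    'AC'
    """
    return RepeatUnit(_canonical_sequence(seq))


def unit_gc(unit: RepeatUnit | str) -> Fraction:
    """GC fraction of a unit, exact; rounded to a bin only at profile lookup."""
    if isinstance(unit, str):
        unit = canonical_unit(unit)
    return unit.gc_fraction
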