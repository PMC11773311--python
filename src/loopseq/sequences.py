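"""RNA sequence primitives for the tetraloop overhang assay.

The unit of analysis is the 4-nt randomized overhang (the ``NNNN`` of the
construct): a string over the RNA alphabet ``{A, C, G, U}``. This module
fixes the enumeration order of the 256 overhangs, the six allowed closing
base pairs, and the degenerate (IUPAC-style) pattern alphabet used for
consensus groups such as ``UNNG`` or ``RNNY``.
"""

from __future__ import annotations

from itertools import product
from typing import Iterable

RNA_BASES: str = "ACGU"

OVERHANG_LENGTH: int = 4

#: All 256 overhang sequences, lexicographic in A < C < G < U.
ALL_OVERHANGS: tuple[str, ...] = tuple(
    "".join(p) for p in product(RNA_BASES, repeat=OVERHANG_LENGTH)
)

#: The six closing base pairs assayed in parallel reactions.
CLOSING_PAIRS: tuple[str, ...] = ("C:G", "G:C", "U:A", "A:U", "U:G", "G:U")

#: Degenerate symbols: N = any base, R = purine, Y = pyrimidine.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "U": frozenset("U"),
    "N": frozenset("ACGU"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
}

_COMPLEMENT = str.maketrans("ACGU", "UGCA")


def to_rna(seq: str) -> str:
    """Uppercase and map DNA T to RNA U. Does not validate the alphabet."""
    return seq.upper().replace("T", "U")


def is_valid_overhang(seq: str) -> bool:
    """True for a 4-mer strictly over {A, C, G, U}."""
    return len(seq) == OVERHANG_LENGTH and all(b in RNA_BASES for b in seq)


def complement(seq: str) -> str:
    """Watson-Crick complement (no wobble), preserving orientation."""
    return seq.translate(_COMPLEMENT)


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an RNA string."""
    return complement(seq)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming requires equal lengths, got {len(a)} and {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def validate_pattern(pattern: str) -> None:
    """Raise ValueError unless ``pattern`` is a length-4 consensus pattern."""
    if len(pattern) != OVERHANG_LENGTH:
        raise ValueError(f"pattern must have length {OVERHANG_LENGTH}: {pattern!r}")
    bad = [s for s in pattern if s not in IUPAC_SETS]
    if bad:
        raise ValueError(f"pattern {pattern!r} has symbols outside ACGUNRY: {bad}")


def match_pattern(seq: str, pattern: str) -> bool:
    """Position-wise membership of a 4-mer in a degenerate consensus pattern.

    >>> match_pattern("UUCG", "UNNG")
    True
    >>> match_pattern("UUCG", "RNNY")
    False
    """
    validate_pattern(pattern)
    if not is_valid_overhang(seq):
        raise ValueError(f"not a valid overhang sequence: {seq!r}")
    return all(b in IUPAC_SETS[s] for b, s in zip(seq, pattern))


def expand_pattern(pattern: str) -> list[str]:
    """All overhang sequences matching a consensus pattern, in canonical order."""
    validate_pattern(pattern)
    return [s for s in ALL_OVERHANGS if all(b in IUPAC_SETS[p] for b, p in zip(s, pattern))]


def first_matching_pattern(seq: str, patterns: Iterable[str]) -> str | None:
    """First pattern in an ordered collection that matches ``seq``, else None."""
    for p in patterns:
        if match_pattern(seq, p):
            return p
    return None


def variant_space_size(n_overhangs: int = len(ALL_OVERHANGS),
                       n_closing_pairs: int = len(CLOSING_PAIRS)) -> int:
    """Total number of assayed variants: overhangs x closing pairs (256 x 6 = 1536)."""
    return n_overhangs * n_closing_pairs
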