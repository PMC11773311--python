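"""Construct layout shared by the read simulator and the demultiplexer.

Each sequenced ligation product is modelled as a single-end read with the
fixed architecture::

    5'-handle | donor tag (A or B) | stem | NNNN overhang | acceptor tag (a or b) | 3'-handle

The donor tag identifies the duplex contributing the activated 5'-phosphate
strand and the acceptor tag the duplex contributing the 3'-overhang strand;
the (donor, acceptor) combination defines the four junction products P1-P4.
Handle, stem and tag sequences are configurable plumbing with invented
defaults; demultiplexing depends only on this spec, never on particular
laboratory oligos.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .sequences import CLOSING_PAIRS, OVERHANG_LENGTH, hamming, to_rna

_DEFAULT_HANDLE5 = "ACGCAGUCAG"
_DEFAULT_HANDLE3 = "GACUGACGUC"
_DEFAULT_STEM = "GCAGUCCGAUGC"  # 12-nt core stem
_DEFAULT_DONOR_TAGS = {"A": "AAGGCC", "B": "CCUUAA"}
_DEFAULT_ACCEPTOR_TAGS = {"a": "GGAAUU", "b": "UUCCGG"}


@dataclass(frozen=True)
class ConstructSpec:
    """Geometry and tag sequences of the four-strand sequencing construct.

    Coordinates exposed by this class are 1-based inclusive, matching the
    convention used in configuration files.
    """

    handle5: str = _DEFAULT_HANDLE5
    handle3: str = _DEFAULT_HANDLE3
    stem: str = _DEFAULT_STEM
    closing_pair: str = "C:G"
    donor_tags: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_DONOR_TAGS))
    acceptor_tags: dict[str, str] = field(default_factory=lambda: dict(_DEFAULT_ACCEPTOR_TAGS))

    def __post_init__(self) -> None:
        object.__setattr__(self, "handle5", to_rna(self.handle5))
        object.__setattr__(self, "handle3", to_rna(self.handle3))
        object.__setattr__(self, "stem", to_rna(self.stem))
        object.__setattr__(self, "donor_tags", {k: to_rna(v) for k, v in self.donor_tags.items()})
        object.__setattr__(
            self, "acceptor_tags", {k: to_rna(v) for k, v in self.acceptor_tags.items()}
        )
        if self.closing_pair not in CLOSING_PAIRS:
            raise ValueError(
                f"closing_pair must be one of {CLOSING_PAIRS}, got {self.closing_pair!r}"
            )
        if set(self.donor_tags) != {"A", "B"}:
            raise ValueError("donor_tags must have exactly the keys 'A' and 'B'")
        if set(self.acceptor_tags) != {"a", "b"}:
            raise ValueError("acceptor_tags must have exactly the keys 'a' and 'b'")
        if len(self.donor_tags["A"]) != len(self.donor_tags["B"]):
            raise ValueError("donor tags must have equal length")
        if len(self.acceptor_tags["a"]) != len(self.acceptor_tags["b"]):
            raise ValueError("acceptor tags must have equal length")
        if self.donor_tags["A"] == self.donor_tags["B"]:
            raise ValueError("donor tags must be distinct")
        if self.acceptor_tags["a"] == self.acceptor_tags["b"]:
            raise ValueError("acceptor tags must be distinct")

    # ---- 0-based half-open internal spans (never exposed in configs) ----

    @property
    def _donor_span(self) -> tuple[int, int]:
        start = len(self.handle5)
        return start, start + len(self.donor_tags["A"])

    @property
    def _overhang_span(self) -> tuple[int, int]:
        start = self._donor_span[1] + len(self.stem)
        return start, start + OVERHANG_LENGTH

    @property
    def _acceptor_span(self) -> tuple[int, int]:
        start = self._overhang_span[1]
        return start, start + len(self.acceptor_tags["a"])

    # ---- public 1-based inclusive coordinates ----

    @property
    def overhang_coords(self) -> tuple[int, int]:
        """(start, end) of the overhang window, 1-based inclusive."""
        s, e = self._overhang_span
        return s + 1, e

    @property
    def read_length(self) -> int:
        return (
            len(self.handle5)
            + len(self.donor_tags["A"])
            + len(self.stem)
            + OVERHANG_LENGTH
            + len(self.acceptor_tags["a"])
            + len(self.handle3)
        )

    def min_tag_distance(self) -> int:
        """Smaller of the two within-role tag Hamming distances."""
        return min(
            hamming(self.donor_tags["A"], self.donor_tags["B"]),
            hamming(self.acceptor_tags["a"], self.acceptor_tags["b"]),
        )

    def build_read(self, donor: str, acceptor: str, overhang: str) -> str:
        """Assemble the full read sequence for one junction product."""
        if donor not in self.donor_tags:
            raise ValueError(f"unknown donor strand {donor!r}")
        if acceptor not in self.acceptor_tags:
            raise ValueError(f"unknown acceptor strand {acceptor!r}")
        if len(overhang) != OVERHANG_LENGTH:
            raise ValueError(f"overhang must be {OVERHANG_LENGTH} nt, got {overhang!r}")
        return (
            self.handle5
            + self.donor_tags[donor]
            + self.stem
            + to_rna(overhang)
            + self.acceptor_tags[acceptor]
            + self.handle3
        )
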