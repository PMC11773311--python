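"""Demultiplex product reads into the four junction classes P1-P4.

Each read is classified by matching its donor-side tag (A vs B) and
acceptor-side tag (a vs b) within a Hamming-distance budget at the fixed
coordinates given by a :class:`~loopseq.construct.ConstructSpec`; the
(donor, acceptor) combination maps to the product class. The randomized
overhang is then extracted from its window. Reads that cannot be assigned
are tallied by rejection reason. P2 (A-b) and P3 (B-a) can only arise from
splinted ligation between the two duplexes, so their read share is a lower
limit on the splinted contribution.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .construct import ConstructSpec
from .sequences import ALL_OVERHANGS, hamming, is_valid_overhang, to_rna
from .synthetic import PRODUCT_CLASSES, PRODUCT_STRANDS

logger = logging.getLogger(__name__)

REJECT_REASONS: tuple[str, ...] = ("no_donor_tag", "no_acceptor_tag", "ambiguous", "bad_overhang")

_CLASS_BY_STRANDS = {v: k for k, v in PRODUCT_STRANDS.items()}


@dataclass(frozen=True)
class ReadCall:
    """Outcome of classifying one read: a product class and overhang, or a
    rejection reason."""

    product_class: str | None
    overhang: str | None
    reject_reason: str | None

    @property
    def accepted(self) -> bool:
        return self.product_class is not None


def _check_spec(spec: ConstructSpec, max_mismatch: int) -> None:
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    if spec.min_tag_distance() <= 2 * max_mismatch:
        raise ValueError(
            "construct tags are not distinguishable at this max_mismatch: "
            f"minimum tag distance {spec.min_tag_distance()} requires "
            f"max_mismatch < {spec.min_tag_distance() / 2:g}"
        )


def _match_tag(segment: str, tags: dict[str, str], max_mismatch: int) -> str | None:
    """Name of the unique tag within ``max_mismatch`` of ``segment``.

    Returns None when no tag matches; raises no error on ties — the caller
    treats a tie as ambiguous (cannot happen when the spec precondition
    holds, but mutated reads may still tie at equal distance)."""
    hits = [
        (hamming(segment, tag), name)
        for name, tag in tags.items()
        if len(segment) == len(tag)
    ]
    hits = [(d, name) for d, name in hits if d <= max_mismatch]
    if not hits:
        return None
    hits.sort()
    if len(hits) > 1 and hits[0][0] == hits[1][0]:
        return "__tie__"
    return hits[0][1]


def classify_read(seq: str, spec: ConstructSpec, max_mismatch: int = 0) -> ReadCall:
    """Classify one read sequence into P1-P4 or reject it with a reason."""
    _check_spec(spec, max_mismatch)
    read = to_rna(seq)
    ds, de = spec._donor_span
    as_, ae = spec._acceptor_span
    if len(read) < ae:
        return ReadCall(None, None, "bad_overhang")
    donor = _match_tag(read[ds:de], spec.donor_tags, max_mismatch)
    if donor is None:
        return ReadCall(None, None, "no_donor_tag")
    acceptor = _match_tag(read[as_:ae], spec.acceptor_tags, max_mismatch)
    if acceptor is None:
        return ReadCall(None, None, "no_acceptor_tag")
    if donor == "__tie__" or acceptor == "__tie__":
        return ReadCall(None, None, "ambiguous")
    overhang = extract_overhang(read, spec)
    if overhang is None:
        return ReadCall(None, None, "bad_overhang")
    return ReadCall(_CLASS_BY_STRANDS[(donor, acceptor)], overhang, None)


def extract_overhang(read: str, spec: ConstructSpec) -> str | None:
    """The 4-mer at the spec's overhang window, T mapped to U.

    Returns None when the read is too short or the window contains any
    character outside {A, C, G, U} (e.g. a literal N base call)."""
    s, e = spec._overhang_span
    read = to_rna(read)
    if len(read) < e:
        return None
    window = read[s:e]
    return window if is_valid_overhang(window) else None


@dataclass
class ProductCountTable:
    """Read counts indexed by (product class, overhang) for one reaction,
    plus rejection tallies by reason."""

    reaction: str
    closing_pair: str
    counts: pd.DataFrame  # index P1-P4, columns the 256 overhangs
    rejections: Counter

    @classmethod
    def empty(cls, reaction: str = "rxn", closing_pair: str = "C:G") -> "ProductCountTable":
        counts = pd.DataFrame(
            0,
            index=pd.Index(PRODUCT_CLASSES, name="product_class"),
            columns=pd.Index(ALL_OVERHANGS, name="overhang"),
        )
        return cls(reaction, closing_pair, counts, Counter())

    @property
    def total_classified(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def total_rejected(self) -> int:
        return int(sum(self.rejections.values()))

    def class_counts(self, product_class: str) -> pd.Series:
        if product_class not in PRODUCT_CLASSES:
            raise KeyError(f"unknown product class {product_class!r}")
        return self.counts.loc[product_class]

    def to_tsv(self, path) -> None:
        tidy = (
            self.counts.stack()
            .rename("count")
            .reset_index()
            .assign(reaction=self.reaction, closing_pair=self.closing_pair)
        )[["reaction", "closing_pair", "product_class", "overhang", "count"]]
        tidy.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ProductCountTable":
        tidy = pd.read_csv(path, sep="\t")
        required = {"reaction", "closing_pair", "product_class", "overhang", "count"}
        missing = required - set(tidy.columns)
        if missing:
            raise ValueError(f"count table missing columns: {sorted(missing)}")
        reaction = str(tidy["reaction"].iloc[0])
        pair = str(tidy["closing_pair"].iloc[0])
        table = cls.empty(reaction, pair)
        pivot = tidy.pivot_table(
            index="product_class", columns="overhang", values="count", aggfunc="sum"
        )
        table.counts.update(pivot)
        table.counts = table.counts.astype(int)
        return table

    def rejection_report(self) -> pd.DataFrame:
        rows = [{"reason": r, "count": self.rejections.get(r, 0)} for r in REJECT_REASONS]
        return pd.DataFrame(rows)


def _iter_reads(reads, fmt: str | None) -> Iterator[tuple[str, str]]:
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        if fmt is None:
            name = path.name.removesuffix(".gz")
            fmt = "fasta" if name.endswith((".fa", ".fasta")) else "fastq"
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as handle:
            for rec in SeqIO.parse(handle, fmt):
                yield rec.id, str(rec.seq)
    else:
        for item in reads:
            if isinstance(item, tuple):
                yield item
            else:  # SeqRecord
                yield item.id, str(item.seq)


def tabulate(
    reads: Iterable | str | Path,
    spec: ConstructSpec,
    max_mismatch: int = 0,
    reaction: str = "rxn",
    fmt: str | None = None,
) -> ProductCountTable:
    """One-pass tabulation of a read stream (or FASTQ/FASTA path) into a
    :class:`ProductCountTable`. Order-independent and deterministic."""
    _check_spec(spec, max_mismatch)
    table = ProductCountTable.empty(reaction, spec.closing_pair)
    cells: Counter = Counter()
    for _, seq in _iter_reads(reads, fmt):
        call = classify_read(seq, spec, max_mismatch)
        if call.accepted:
            cells[(call.product_class, call.overhang)] += 1
        else:
            table.rejections[call.reject_reason] += 1
    for (cls, overhang), n in cells.items():
        table.counts.loc[cls, overhang] = n
    if table.total_rejected:
        logger.info(
            "tabulate(%s): %d classified, %d rejected (%s)",
            reaction,
            table.total_classified,
            table.total_rejected,
            dict(table.rejections),
        )
    return table


def splinted_fraction(table: ProductCountTable) -> float:
    """(P2+P3) / (P1+P2+P3+P4) over all overhangs of one reaction — the
    lower-limit estimate of the splinted-ligation contribution."""
    totals = table.counts.sum(axis=1)
    denom = float(totals.sum())
    if denom == 0:
        raise ValueError("splinted_fraction undefined: no classified reads")
    return float((totals["P2"] + totals["P3"]) / denom)
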