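"""Input-bias normalization and sequence-activity profiling.

Synthesizer-made randomized libraries are not uniform over the 256 possible
4-nt overhangs, so raw product read counts confound reactivity with input
abundance. The correction follows the normalization-factor scheme: from a
control ligation driven nearly to completion, per-sequence input
frequencies ``f_i`` are estimated and converted to factors
``alpha_i = f_i / (1/256)`` (``alpha_i = 1`` for a sequence at exactly the
even-library frequency). Product counts are divided by ``alpha_i`` and
renormalized, giving a frequency profile whose ranking tracks relative
ligation efficiency.

The module also provides the profile summaries used throughout the
analysis: rank tables, max/min fold-ranges, frequency-weighted positional
base composition, per-position information content (0-2 bits), and
consensus-group classification of the top-ranked sequences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import ALL_OVERHANGS, RNA_BASES, first_matching_pattern, validate_pattern

_SEQ_INDEX = pd.Index(ALL_OVERHANGS, name="overhang")
N_SEQUENCES = len(ALL_OVERHANGS)


@dataclass(frozen=True)
class InputDistribution:
    """Per-strand input frequencies f_i over the 256 overhangs."""

    frequencies: pd.Series
    n_reads: int
    strand: str = ""

    def __post_init__(self) -> None:
        f = self.frequencies.reindex(_SEQ_INDEX)
        if f.isna().any():
            raise ValueError("input distribution must cover all 256 overhangs")
        if (f < 0).any():
            raise ValueError("input frequencies must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"input frequencies must sum to 1, got {f.sum()}")
        object.__setattr__(self, "frequencies", f)


def input_frequencies(
    control_counts: pd.Series, pseudocount: float = 0.0, strand: str = ""
) -> InputDistribution:
    """Estimate the input distribution from control-ligation read counts.

    ``f_i = (c_i + pseudocount) / sum_j (c_j + pseudocount)``. With
    pseudocount 0, sequences absent from the control get frequency 0 and a
    warning — their normalization factor is undefined until a pseudocount
    is applied.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    c = control_counts.reindex(_SEQ_INDEX).fillna(0.0).astype(float)
    total = float(c.sum())
    if total <= 0:
        raise ValueError("control table is empty: no reads to estimate input frequencies")
    if pseudocount == 0 and (c == 0).any():
        n0 = int((c == 0).sum())
        warnings.warn(
            f"{n0} overhang sequence(s) have zero control counts; their "
            "normalization factors are undefined (consider a pseudocount)",
            stacklevel=2,
        )
    adj = c + pseudocount
    return InputDistribution(adj / adj.sum(), n_reads=int(total), strand=strand)


def alpha_factors(dist: InputDistribution) -> pd.Series:
    """Normalization factors alpha_i = f_i / (1/256) = 256 * f_i.

    The mean of alpha over all sequences is 1 by construction; alpha_i = 1
    exactly when a sequence sits at the even-library frequency 1/256.
    """
    f = dist.frequencies
    zero = f.index[f == 0]
    if len(zero):
        raise ValueError(
            "alpha undefined for sequence(s) with zero input frequency: "
            + ", ".join(zero[:5])
            + ("..." if len(zero) > 5 else "")
        )
    return (N_SEQUENCES * f).rename("alpha")


@dataclass(frozen=True)
class FrequencyProfile:
    """Normalized per-sequence frequencies with ranks for one product class.

    ``table`` columns: count, alpha, norm_freq, raw_freq, rank (1 = most
    frequent, ties broken lexicographically by sequence), indexed by
    overhang in canonical order.
    """

    table: pd.DataFrame
    reaction: str = ""
    product_class: str = ""
    closing_pair: str = ""

    @property
    def norm_freq(self) -> pd.Series:
        return self.table["norm_freq"]

    @property
    def ranks(self) -> pd.Series:
        return self.table["rank"]

    def top_k(self, k: int) -> pd.DataFrame:
        """The k best-ranked sequences, in rank order."""
        return self.table.sort_values("rank").head(k)

    def to_tsv(self, path, pattern_groups: tuple[str, ...] = ()) -> None:
        out = self.table.copy()
        if pattern_groups:
            out["pattern_group"] = [
                first_matching_pattern(s, pattern_groups) or "other" for s in out.index
            ]
        out = out.sort_values("rank").reset_index()
        out.insert(0, "reaction", self.reaction)
        out.insert(1, "product_class", self.product_class)
        out.to_csv(path, sep="\t", index=False)


def _rank_desc(freq: pd.Series) -> pd.Series:
    """Dense 1..256 ranking by descending frequency, ties lexicographic."""
    order = sorted(freq.index, key=lambda s: (-freq[s], s))
    return pd.Series(
        np.arange(1, len(order) + 1), index=pd.Index(order, name="overhang")
    ).reindex(freq.index)


def normalize_counts(
    counts: pd.Series,
    alpha: pd.Series,
    reaction: str = "",
    product_class: str = "",
    closing_pair: str = "",
) -> FrequencyProfile:
    """Alpha-normalized frequency profile for one (reaction, product class).

    Normalized frequency is proportional to ``count_i / alpha_i``,
    renormalized to sum to 1. Sequences with zero counts get frequency 0
    and rank after all observed sequences.
    """
    c = counts.reindex(_SEQ_INDEX).fillna(0.0).astype(float)
    if c.sum() <= 0:
        raise ValueError("cannot normalize an all-zero count table")
    a = alpha.reindex(_SEQ_INDEX)
    observed = c > 0
    if a[observed].isna().any() or (a[observed] <= 0).any():
        bad = c.index[observed & (a.isna() | (a <= 0))]
        raise ValueError(
            "alpha undefined for sequence(s) with nonzero counts: " + ", ".join(bad[:5])
        )
    weighted = c.where(~observed, c / a)
    norm = weighted / weighted.sum()
    raw = c / c.sum()
    table = pd.DataFrame(
        {
            "count": c.astype(int),
            "alpha": a,
            "norm_freq": norm,
            "raw_freq": raw,
            "rank": _rank_desc(norm),
            "raw_rank": _rank_desc(raw),
        }
    )
    return FrequencyProfile(table, reaction, product_class, closing_pair)


@dataclass(frozen=True)
class FoldRange:
    """Max / min-nonzero frequency ratio, with zero-frequency tally."""

    ratio: float
    n_zero: int


def fold_range(profile: FrequencyProfile) -> FoldRange:
    """Ratio of the most to the least frequent (nonzero) sequence.

    Zero-frequency sequences are excluded from the denominator and counted
    separately.
    """
    f = profile.norm_freq
    pos = f[f > 0]
    if pos.empty:
        raise ValueError("fold_range undefined: no positive frequencies")
    return FoldRange(float(pos.max() / pos.min()), int((f == 0).sum()))


@dataclass(frozen=True)
class PositionProfile:
    """4 x 4 positional base-frequency matrix (rows = positions 1-4 from the
    5' end, columns = A, C, G, U) with per-position information content."""

    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (4, 4):
            raise ValueError("position profile must be 4x4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's composition must sum to 1")

    def information_content(self) -> pd.Series:
        return information_content(self)

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="position")


def position_composition(freqs: pd.Series | FrequencyProfile) -> PositionProfile:
    """Frequency-weighted base composition at overhang positions 1-4
    (sequence-logo semantics: each sequence contributes its profile weight,
    not one count per unique sequence)."""
    if isinstance(freqs, FrequencyProfile):
        f = freqs.norm_freq
    else:
        f = freqs.reindex(_SEQ_INDEX).fillna(0.0).astype(float)
    total = f.sum()
    if total <= 0:
        raise ValueError("position composition undefined for an all-zero profile")
    w = (f / total).to_numpy()
    mat = np.zeros((4, 4))
    for seq, weight in zip(ALL_OVERHANGS, w):
        if weight == 0:
            continue
        for j, b in enumerate(seq):
            mat[j, RNA_BASES.index(b)] += weight
    frame = pd.DataFrame(
        mat, index=pd.Index([1, 2, 3, 4], name="position"), columns=list(RNA_BASES)
    )
    return PositionProfile(frame)


def information_content(positions: PositionProfile) -> pd.Series:
    """Per-position information content IC_j = 2 + sum_b p_bj log2 p_bj, in
    bits, with 0*log(0) = 0. Ranges from 0 (uniform) to 2 (invariant)."""
    m = positions.matrix.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(m > 0, m * np.log2(m), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    ic = np.clip(ic, 0.0, 2.0)  # guard the endpoints against rounding
    return pd.Series(ic, index=positions.matrix.index, name="information_bits")


@dataclass(frozen=True)
class TopKClassification:
    """Consensus-group breakdown of the top-k ranked sequences."""

    k: int
    assignments: pd.DataFrame  # columns: rank, norm_freq, pattern_group
    pattern_counts: dict[str, int]
    unclassified: tuple[str, ...]
    cumulative_share: float = field(default=0.0)


def classify_top_k(
    profile: FrequencyProfile, patterns: tuple[str, ...], k: int
) -> TopKClassification:
    """Assign each of the k top-ranked sequences to the first matching
    consensus pattern (ordered, first match wins) or to "other"; report the
    cumulative normalized-read share of the top k."""
    if k < 0 or k > N_SEQUENCES:
        raise ValueError(f"k must be in [0, {N_SEQUENCES}], got {k}")
    for p in patterns:
        validate_pattern(p)
    top = profile.top_k(k)
    groups = [first_matching_pattern(s, patterns) or "other" for s in top.index]
    assignments = pd.DataFrame(
        {"rank": top["rank"], "norm_freq": top["norm_freq"], "pattern_group": groups}
    )
    counts = {p: groups.count(p) for p in patterns}
    counts["other"] = groups.count("other")
    unclassified = tuple(s for s, g in zip(top.index, groups) if g == "other")
    return TopKClassification(
        k=k,
        assignments=assignments,
        pattern_counts=counts,
        unclassified=unclassified,
        cumulative_share=float(top["norm_freq"].sum()),
    )
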