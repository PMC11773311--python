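"""Overlap of high-efficiency loop sequences with biological tetraloops.

A biological tetraloop reference (loop, closing pair, context, frequency)
is deduplicated by pairwise context similarity (remove entries > 90 %
identical at >= 70 % alignment coverage to an already-kept entry), grouped
by the six closing base pairs, and ranked by summed loop frequency. The
top-K loops per group are then intersected with the top-K sequences of a
ligation profile, and the overlap is scored against the hypergeometric
null: drawing the profile's top K at random from the N = 256 possible
tetraloops, the expected overlap with a fixed reference top K is
K*K/N (6.25 for K = 40), and enrichment/depletion significance is the
exact one-sided inclusive tail of the hypergeometric distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy.special import gammaln, logsumexp

from .sequences import CLOSING_PAIRS, is_valid_overhang

N_POPULATION_DEFAULT = 256


# ---------------------------------------------------------------------------
# reference processing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DedupParams:
    """Similarity thresholds for redundancy removal."""

    identity: float = 0.90
    coverage: float = 0.70

    def __post_init__(self) -> None:
        for name, v in (("identity", self.identity), ("coverage", self.coverage)):
            if not 0 < v <= 1:
                raise ValueError(f"{name} threshold must be in (0, 1], got {v}")


def _make_aligner(mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    # end gaps free: identity is assessed on the overlapping span only
    if hasattr(aligner, "end_insertion_score"):
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    else:  # older biopython naming
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def pairwise_similarity(
    a: str, b: str, mismatch: float = -1.0, gap: float = -1.0
) -> tuple[float, float]:
    """(identity, coverage) of the best global alignment of two contexts.

    Identity is matches / aligned columns excluding end gaps; coverage is
    the shorter sequence's share of positions inside the end-gap-trimmed
    span. End gaps are not penalized.
    """
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(mismatch, gap)
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    # trim end-gap columns: the region where both sequences have started
    # and neither has ended
    def span(g: str) -> tuple[int, int]:
        return len(g) - len(g.lstrip("-")), len(g.rstrip("-"))
    sa, ea = span(ga)
    sb, eb = span(gb)
    lo, hi = max(sa, sb), min(ea, eb)
    if hi <= lo:
        return 0.0, 0.0
    matches = sum(x == y and x != "-" for x, y in zip(ga[lo:hi], gb[lo:hi]))
    identity = matches / (hi - lo)
    shorter = min(len(a), len(b))
    cov_a = sum(c != "-" for c in ga[lo:hi])
    cov_b = sum(c != "-" for c in gb[lo:hi])
    coverage = (cov_a if len(a) <= len(b) else cov_b) / shorter
    return float(identity), float(coverage)


def _validate_entries(entries: pd.DataFrame) -> pd.DataFrame:
    required = {"loop", "closing_pair", "context", "frequency"}
    missing = required - set(entries.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    if entries.empty:
        raise ValueError("reference table is empty")
    bad_loops = [s for s in entries["loop"] if not is_valid_overhang(str(s))]
    if bad_loops:
        raise ValueError(f"invalid loop sequence(s): {bad_loops[:5]}")
    unknown = set(entries["closing_pair"]) - set(CLOSING_PAIRS)
    if unknown:
        raise ValueError(f"unknown closing pair(s): {sorted(unknown)}")
    if (entries["frequency"] < 1).any():
        raise ValueError("reference frequencies must be >= 1")
    return entries


def dedup(entries: pd.DataFrame, params: DedupParams = DedupParams()) -> pd.DataFrame:
    """Greedy redundancy removal on context sequences.

    Entries are scanned in descending frequency (ties broken
    lexicographically by context); an entry is dropped when its context has
    identity > ``params.identity`` at coverage >= ``params.coverage``
    against any already-kept entry. Dropped entries' frequencies are not
    merged into the kept representative.
    """
    _validate_entries(entries)
    ordered = entries.sort_values(
        ["frequency", "context"], ascending=[False, True], kind="mergesort"
    )
    kept_idx: list = []
    kept_ctx: list[str] = []
    for idx, row in ordered.iterrows():
        ctx = str(row["context"])
        redundant = False
        for other in kept_ctx:
            identity, coverage = pairwise_similarity(ctx, other)
            if identity > params.identity and coverage >= params.coverage:
                redundant = True
                break
        if not redundant:
            kept_idx.append(idx)
            kept_ctx.append(ctx)
    return ordered.loc[kept_idx]


def group_rank(entries: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-closing-pair loop rankings.

    Within each of the six groups, loops are aggregated by summed frequency
    and ranked descending (ties lexicographic by loop). Returns a dict
    keyed by closing pair; groups absent from the input map to empty
    frames.
    """
    _validate_entries(entries)
    out: dict[str, pd.DataFrame] = {}
    for pair in CLOSING_PAIRS:
        sub = entries[entries["closing_pair"] == pair]
        agg = (
            sub.groupby("loop", as_index=False)["frequency"]
            .sum()
            .sort_values(["frequency", "loop"], ascending=[False, True], kind="mergesort")
            .reset_index(drop=True)
        )
        agg["rank"] = np.arange(1, len(agg) + 1)
        out[pair] = agg
    return out


# ---------------------------------------------------------------------------
# hypergeometric overlap statistics
# ---------------------------------------------------------------------------

def overlap_top_k(ranked_a: Sequence[str], ranked_b: Sequence[str], k: int) -> int:
    """|topK(A) ∩ topK(B)| as plain set intersection of loop sequences."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return len(set(ranked_a[:k]) & set(ranked_b[:k]))


def hypergeom_expected(N: int, K: int, n: int) -> float:
    """Expected overlap n*K/N of a random size-n subset with a fixed size-K
    subset of an N-element population (6.25 for N=256, K=n=40)."""
    _check_hypergeom_params(N, K, n)
    return n * K / N


def _check_hypergeom_params(N: int, K: int, n: int) -> None:
    if N <= 0:
        raise ValueError("population size N must be positive")
    if not 0 <= K <= N:
        raise ValueError(f"K must be in [0, N={N}], got {K}")
    if not 0 <= n <= N:
        raise ValueError(f"n must be in [0, N={N}], got {n}")


def hypergeom_logpmf(k: np.ndarray | int, N: int, K: int, n: int) -> np.ndarray:
    """Log pmf of the hypergeometric distribution via log-gamma."""
    k = np.asarray(k)
    return (
        gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
        + gammaln(N - K + 1) - gammaln(n - k + 1) - gammaln(N - K - n + k + 1)
        - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1))
    )


def hypergeom_tail(k_obs: int, N: int, K: int, n: int, direction: str) -> float:
    """Exact one-sided inclusive tail of the hypergeometric distribution.

    ``direction="enrichment"`` gives P(X >= k_obs); ``"depletion"`` gives
    P(X <= k_obs). The tail is an exact pmf sum accumulated in log space.
    """
    _check_hypergeom_params(N, K, n)
    lo, hi = max(0, n + K - N), min(K, n)
    if not lo <= k_obs <= hi:
        raise ValueError(f"k_obs must be in the support [{lo}, {hi}], got {k_obs}")
    if direction == "enrichment":
        ks = np.arange(k_obs, hi + 1)
    elif direction == "depletion":
        ks = np.arange(lo, k_obs + 1)
    else:
        raise ValueError("direction must be 'enrichment' or 'depletion'")
    p = float(np.exp(logsumexp(hypergeom_logpmf(ks, N, K, n))))
    return min(p, 1.0)


@dataclass(frozen=True)
class EnrichmentResult:
    """Fold over- or under-representation relative to the null expectation."""

    fold: float
    direction: str
    reported_fold: float


def enrichment(k_obs: int, expected: float) -> EnrichmentResult:
    """Fold enrichment/depletion of an observed overlap.

    Fold = k_obs/expected; overlaps above expectation are "enriched" and
    reported as that ratio, overlaps below are "depleted" and reported as
    expected/k_obs (infinite for k_obs = 0).
    """
    if expected <= 0:
        raise ValueError("expected overlap must be positive")
    if k_obs < 0:
        raise ValueError("k_obs must be >= 0")
    fold = k_obs / expected
    if fold > 1:
        return EnrichmentResult(fold, "enriched", fold)
    reported = float("inf") if k_obs == 0 else expected / k_obs
    return EnrichmentResult(fold, "depleted", reported)


@dataclass(frozen=True)
class OverlapResult:
    """Observed vs expected top-K overlap with exact significance."""

    group: str
    k: int
    population: int
    k_obs: int
    expected: float
    fold: float
    direction: str
    reported_fold: float
    p_value: float


def overlap_analysis(
    ranked_profile: Sequence[str],
    ranked_reference: Sequence[str],
    k: int,
    population: int = N_POPULATION_DEFAULT,
    group: str = "",
    direction: str = "auto",
) -> OverlapResult:
    """Full top-K overlap analysis of one profile against one reference group.

    With ``direction="auto"`` the tested tail follows the sign of the
    observed deviation from expectation (enrichment when k_obs exceeds it).
    """
    k_obs = overlap_top_k(ranked_profile, ranked_reference, k)
    expected = hypergeom_expected(population, k, k)
    if direction == "auto":
        direction = "enrichment" if k_obs >= expected else "depletion"
    enr = enrichment(k_obs, expected)
    p = hypergeom_tail(k_obs, population, k, k, direction)
    return OverlapResult(
        group=group,
        k=k,
        population=population,
        k_obs=k_obs,
        expected=expected,
        fold=enr.fold,
        direction=direction,
        reported_fold=enr.reported_fold,
        p_value=p,
    )
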