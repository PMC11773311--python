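"""Ground-truth-labelled simulation of competing RNA ligation pathways.

The generator emulates the statistical structure of the four-strand deep
sequencing assay for nonenzymatic hairpin formation:

* a randomized input library whose positional base composition is biased
  the way synthesizer-made NNNN libraries are;
* sequence-dependent loop-closing efficiencies spanning roughly 300-fold,
  organized by consensus groups (UNCG best, RNNY worst);
* a competing splinted (nicked-duplex) ligation pathway whose propensity
  grows with strand concentration and with the C:G content of the annealed
  overhang pair;
* a hydrolysis sink that consumes activated material without ligation.

Every molecule partitions among {loop closing, splinted ligation,
unreacted/hydrolyzed} by mass action; sequenced reads are a multinomial
draw over the ligated products only. Products are labelled P1-P4 by the
(donor, acceptor) strand combination; P2 and P3 can only arise from
splinted ligation between the two duplexes, which is what makes the
observed (P2+P3) share a lower limit on the true splinted fraction.

All outputs are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .construct import ConstructSpec
from .sequences import (
    ALL_OVERHANGS,
    CLOSING_PAIRS,
    RNA_BASES,
    expand_pattern,
    first_matching_pattern,
    reverse_complement,
    validate_pattern,
)

PRODUCT_CLASSES: tuple[str, ...] = ("P1", "P2", "P3", "P4")

#: donor/acceptor strand combination per junction product
PRODUCT_STRANDS: dict[str, tuple[str, str]] = {
    "P1": ("A", "a"),
    "P2": ("A", "b"),
    "P3": ("B", "a"),
    "P4": ("B", "b"),
}

_SEQ_INDEX = pd.Index(ALL_OVERHANGS, name="overhang")


# ---------------------------------------------------------------------------
# input library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PositionBaseFrequencies:
    """Positional base composition of the randomized 4-nt overhang library.

    ``matrix`` is 4 positions x 4 bases (columns ordered A, C, G, U);
    positions are numbered 1-4 from the 5' end. Each row is a probability
    vector; the library model assumes positional independence, so the
    probability of a full overhang is the product of its positional base
    frequencies.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"expected a 4x4 frequency matrix, got shape {m.shape}")
        if (m < 0).any():
            raise ValueError("base frequencies must be non-negative")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position's base frequencies must sum to 1")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def uniform(cls) -> "PositionBaseFrequencies":
        return cls(np.full((4, 4), 0.25))

    @classmethod
    def default(cls) -> "PositionBaseFrequencies":
        """Synthesizer-style bias: positions 1-3 favor A, position 4 favors C."""
        first3 = [0.33, 0.19, 0.26, 0.22]   # A, C, G, U
        fourth = [0.28, 0.33, 0.21, 0.18]
        return cls(np.array([first3, first3, first3, fourth]))

    def sequence_probability(self, seq: str) -> float:
        """P(seq) under positional independence."""
        idx = [RNA_BASES.index(b) for b in seq]
        return float(np.prod([self.matrix[j, i] for j, i in enumerate(idx)]))

    def probabilities(self) -> pd.Series:
        """Probabilities of all 256 overhangs (sums to 1)."""
        rows = self.matrix
        p = np.einsum("i,j,k,l->ijkl", rows[0], rows[1], rows[2], rows[3]).ravel()
        return pd.Series(p, index=_SEQ_INDEX)


def per_sequence_concentration(total_nM: float, n_sequences: int = len(ALL_OVERHANGS)) -> float:
    """Concentration of each unique overhang in an even randomized pool
    (e.g. 5 nM total / 256 sequences = 0.02 nM each)."""
    if total_nM <= 0:
        raise ValueError("total concentration must be positive")
    return total_nM / n_sequences


def sample_input_library(
    freqs: PositionBaseFrequencies, n_molecules: int, seed: int
) -> pd.Series:
    """Multinomial draw of ``n_molecules`` overhangs from the library model.

    Returns counts over all 256 overhang sequences (zeros included).
    """
    if n_molecules <= 0:
        raise ValueError(f"n_molecules must be positive, got {n_molecules}")
    rng = np.random.default_rng(seed)
    p = freqs.probabilities().to_numpy()
    counts = rng.multinomial(n_molecules, p)
    return pd.Series(counts, index=_SEQ_INDEX)


# ---------------------------------------------------------------------------
# loop-closing efficiencies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EfficiencyModel:
    """Consensus-group model of per-sequence loop-closing efficiency.

    ``patterns`` is an ordered list of (consensus pattern, mean efficiency,
    lognormal sd); the first matching pattern wins. Sequences matching no
    pattern receive ``fallback``. Per-sequence values are the group mean
    perturbed by multiplicative lognormal noise, clipped to (0, 1].
    """

    patterns: tuple[tuple[str, float, float], ...]
    fallback: float = 0.05
    seed: int = 0

    DEFAULT_NOISE_SD = 0.25

    def __post_init__(self) -> None:
        for pat, mean, sd in self.patterns:
            validate_pattern(pat)
            if not 0 < mean <= 1:
                raise ValueError(f"mean efficiency for {pat} must be in (0,1], got {mean}")
            if sd < 0:
                raise ValueError(f"noise sd for {pat} must be >= 0, got {sd}")
        if not 0 < self.fallback <= 1:
            raise ValueError(f"fallback efficiency must be in (0,1], got {self.fallback}")

    @classmethod
    def default(cls, noise_sd: float | None = None, seed: int = 0) -> "EfficiencyModel":
        """Group means from the validated consensus groups: UNCG 62 %,
        CNNG 30 %, GNNA 28 %, UNNC 20 %, RNNY 0.2 %; everything else 5 %."""
        sd = cls.DEFAULT_NOISE_SD if noise_sd is None else noise_sd
        return cls(
            patterns=(
                ("UNCG", 0.62, sd),
                ("CNNG", 0.30, sd),
                ("GNNA", 0.28, sd),
                ("UNNC", 0.20, sd),
                ("RNNY", 0.002, sd),
            ),
            fallback=0.05,
            seed=seed,
        )

    def with_seed(self, seed: int) -> "EfficiencyModel":
        return replace(self, seed=seed)

    def resolve(self) -> pd.Series:
        """Per-sequence efficiencies over all 256 overhangs, in (0, 1]."""
        rng = np.random.default_rng(self.seed)
        order = [p for p, _, _ in self.patterns]
        means = np.empty(len(ALL_OVERHANGS))
        sds = np.empty(len(ALL_OVERHANGS))
        fallback_sd = self.patterns[0][2] if self.patterns else 0.0
        for i, seq in enumerate(ALL_OVERHANGS):
            pat = first_matching_pattern(seq, order)
            if pat is None:
                means[i], sds[i] = self.fallback, fallback_sd
            else:
                j = order.index(pat)
                means[i], sds[i] = self.patterns[j][1], self.patterns[j][2]
        noise = np.exp(rng.normal(0.0, 1.0, size=len(means)) * sds)
        eff = np.clip(means * noise, None, 1.0)
        return pd.Series(eff, index=_SEQ_INDEX)


def resolve_efficiencies(model: EfficiencyModel) -> pd.Series:
    """Functional alias for :meth:`EfficiencyModel.resolve`."""
    return model.resolve()


# ---------------------------------------------------------------------------
# splinted-ligation propensity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplintModel:
    """Mass-action propensity of nicked-duplex (splinted) ligation.

    The 4-bp splint formed by a Watson-Crick complementary overhang pair
    gets a pairing weight equal to the product of per-pair weights (C:G
    pairs are stronger than A:U), scaled linearly by total strand
    concentration. No wobble pairing in the splint.
    """

    w_gc: float = 3.0
    w_au: float = 1.0
    conc_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.w_gc <= 0 or self.w_au <= 0:
            raise ValueError("pairing weights must be positive")
        if self.conc_scale < 0:
            raise ValueError("conc_scale must be >= 0")

    def pairing_weight(self, seq: str) -> float:
        """Product of the four per-pair weights of the splint made by ``seq``."""
        w = 1.0
        for b in seq:
            w *= self.w_gc if b in "GC" else self.w_au
        return w

    def propensity(self, seq: str, concentration_nM: float) -> float:
        """Splint-formation propensity of ``seq`` at a given total strand
        concentration (its unique Watson-Crick partner's abundance is applied
        separately by the reaction model)."""
        if concentration_nM <= 0:
            raise ValueError("concentration must be positive")
        return self.pairing_weight(seq) * self.conc_scale * concentration_nM


# ---------------------------------------------------------------------------
# the reaction model
# ---------------------------------------------------------------------------

def _partition_rates(
    freqs: pd.Series,
    efficiencies: pd.Series,
    splint: SplintModel,
    concentration_nM: float,
    k_loop: float,
    k_hyd: float,
) -> pd.DataFrame:
    """Per-sequence mass-action rates for the three fates of one molecule.

    Columns ``loop``, ``splint``, ``hyd`` hold unnormalized propensities;
    ``p_loop``/``p_splint``/``p_hyd`` the normalized partition (rows sum to 1).
    """
    f = freqs.reindex(_SEQ_INDEX).fillna(0.0)
    eff = efficiencies.reindex(_SEQ_INDEX)
    if eff.isna().any():
        raise ValueError("efficiencies must cover all 256 overhangs")
    weights = np.array([splint.pairing_weight(s) for s in ALL_OVERHANGS])
    partner = f.loc[[reverse_complement(s) for s in ALL_OVERHANGS]].to_numpy()
    loop = k_loop * eff.to_numpy()
    spl = splint.conc_scale * concentration_nM * weights * partner
    hyd = np.full(len(ALL_OVERHANGS), k_hyd)
    total = loop + spl + hyd
    if (total <= 0).any():
        raise ValueError("degenerate input: zero total propensity for some sequence")
    out = pd.DataFrame(
        {
            "loop": loop,
            "splint": spl,
            "hyd": hyd,
            "p_loop": loop / total,
            "p_splint": spl / total,
            "p_hyd": hyd / total,
        },
        index=_SEQ_INDEX,
    )
    return out


def expected_splinted_fraction(
    freqs: pd.Series,
    efficiencies: pd.Series,
    splint: SplintModel,
    concentration_nM: float,
    k_loop: float = 0.25,
    k_hyd: float = 1.0,
) -> float:
    """True fraction of ligated molecules that ligated via the splinted
    pathway, under the mass-action partition (the simulator's ground truth)."""
    rates = _partition_rates(freqs, efficiencies, splint, concentration_nM, k_loop, k_hyd)
    f = freqs.reindex(_SEQ_INDEX).fillna(0.0).to_numpy()
    f = f / f.sum()
    spl = float((f * rates["p_splint"]).sum())
    lig = float((f * (rates["p_loop"] + rates["p_splint"])).sum())
    if lig == 0:
        raise ValueError("degenerate input: no ligation under these parameters")
    return spl / lig


def calibrate_splint_scale(
    target_fraction: float,
    freqs: pd.Series,
    efficiencies: pd.Series,
    concentration_nM: float,
    w_gc: float = 3.0,
    w_au: float = 1.0,
    k_loop: float = 0.25,
    k_hyd: float = 1.0,
) -> float:
    """Concentration scale at which the true splinted fraction equals
    ``target_fraction`` at the given concentration (bisection; the fraction
    is monotone increasing in the scale)."""
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")

    def objective(log_scale: float) -> float:
        model = SplintModel(w_gc=w_gc, w_au=w_au, conc_scale=10.0 ** log_scale)
        return (
            expected_splinted_fraction(
                freqs, efficiencies, model, concentration_nM, k_loop, k_hyd
            )
            - target_fraction
        )

    log_scale = brentq(objective, -12.0, 6.0, xtol=1e-12)
    return float(10.0 ** log_scale)


def default_splint_model(
    freqs: pd.Series,
    efficiencies: pd.Series,
    observed_fraction: float = 0.44,
    concentration_nM: float = 250.0,
    w_gc: float = 3.0,
    w_au: float = 1.0,
    k_loop: float = 0.25,
    k_hyd: float = 1.0,
) -> SplintModel:
    """Splint model calibrated so the *observed* (P2+P3) read share equals
    ``observed_fraction`` at the reference concentration.

    In the symmetric two-duplex design exactly half of splinted events yield
    the diagnostic P2/P3 junctions, so the true splinted fraction is twice
    the observed share.
    """
    scale = calibrate_splint_scale(
        2.0 * observed_fraction, freqs, efficiencies, concentration_nM,
        w_gc=w_gc, w_au=w_au, k_loop=k_loop, k_hyd=k_hyd,
    )
    return SplintModel(w_gc=w_gc, w_au=w_au, conc_scale=scale)


@dataclass(frozen=True)
class SyntheticBatch:
    """One simulated reaction with full ground truth.

    ``counts`` is a (product class x 256 overhangs) table of emitted read
    counts; ``true_efficiencies`` and ``true_splinted_fraction`` are the
    generating truth against which recovery is scored.
    """

    reaction: str
    closing_pair: str
    counts: pd.DataFrame
    true_efficiencies: pd.Series
    true_splinted_fraction: float
    library_freqs: pd.Series
    concentration_nM: float
    read_depth: int
    seed: int
    params: dict = field(default_factory=dict)

    def class_counts(self, product_class: str) -> pd.Series:
        return self.counts.loc[product_class]

    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def reads(self):
        """Yield (read_id, product_class, overhang) for every emitted read."""
        i = 0
        for cls in PRODUCT_CLASSES:
            row = self.counts.loc[cls]
            for seq, n in row[row > 0].items():
                for _ in range(int(n)):
                    yield f"{self.reaction}:{cls}:{i:07d}", cls, seq
                    i += 1


def simulate_reaction(
    library_counts: pd.Series,
    efficiencies: pd.Series,
    splint: SplintModel,
    concentration_nM: float,
    read_depth: int,
    seed: int,
    k_loop: float = 0.25,
    k_hyd: float = 1.0,
    reaction: str = "rxn",
    closing_pair: str = "C:G",
) -> SyntheticBatch:
    """Simulate one four-strand competition reaction.

    Both duplexes (A:a and B:b) carry overhangs drawn from the same input
    library. Each molecule partitions among loop closing, splinted ligation
    and hydrolysis by mass action; a splinted event pairs the tracked duplex
    with either duplex type with equal probability, so only half of splinted
    events produce the diagnostic P2/P3 junctions. Reads are a single
    multinomial draw of size ``read_depth`` over the ligated product mass.
    """
    if concentration_nM <= 0:
        raise ValueError("concentration must be positive")
    if read_depth <= 0:
        raise ValueError("read_depth must be positive")
    if closing_pair not in CLOSING_PAIRS:
        raise ValueError(f"unknown closing pair {closing_pair!r}")
    f = library_counts.reindex(_SEQ_INDEX).fillna(0.0).astype(float)
    if f.sum() <= 0:
        raise ValueError("library counts must have positive total")
    f = f / f.sum()
    rates = _partition_rates(f, efficiencies, splint, concentration_nM, k_loop, k_hyd)
    fv = f.to_numpy()
    loop_mass = fv * rates["p_loop"].to_numpy()
    spl_mass = fv * rates["p_splint"].to_numpy()
    # duplex A:a -> P1 (loop or same-duplex splint) and P2 (cross splint);
    # duplex B:b -> P4 and P3, symmetrically.
    mass = {
        "P1": loop_mass + 0.5 * spl_mass,
        "P2": 0.5 * spl_mass,
        "P3": 0.5 * spl_mass,
        "P4": loop_mass + 0.5 * spl_mass,
    }
    flat = np.concatenate([mass[c] for c in PRODUCT_CLASSES])
    total = flat.sum()
    if total <= 0:
        raise ValueError("degenerate input: no ligated product mass")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(read_depth, flat / total)
    counts = pd.DataFrame(
        draws.reshape(len(PRODUCT_CLASSES), -1),
        index=pd.Index(PRODUCT_CLASSES, name="product_class"),
        columns=_SEQ_INDEX,
    )
    true_spl = float(spl_mass.sum() / (loop_mass.sum() + spl_mass.sum()))
    return SyntheticBatch(
        reaction=reaction,
        closing_pair=closing_pair,
        counts=counts,
        true_efficiencies=efficiencies.reindex(_SEQ_INDEX),
        true_splinted_fraction=true_spl,
        library_freqs=f,
        concentration_nM=concentration_nM,
        read_depth=read_depth,
        seed=seed,
        params={
            "k_loop": k_loop,
            "k_hyd": k_hyd,
            "w_gc": splint.w_gc,
            "w_au": splint.w_au,
            "conc_scale": splint.conc_scale,
        },
    )


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------

def write_reads(
    batch: SyntheticBatch,
    spec: ConstructSpec,
    fastq_path,
    truth_path=None,
    quality: int = 40,
    error_rate: float = 0.0,
) -> int:
    """Write the batch as a Sanger FASTQ plus an optional TSV truth sidecar.

    Reads follow the :class:`ConstructSpec` layout with constant quality.
    ``error_rate`` > 0 applies uniform per-base substitutions (seeded from
    the batch seed) for demultiplexer robustness testing. Returns the number
    of reads written.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng([batch.seed, 0xE44])
    qline = chr(quality + 33) * spec.read_length
    n = 0
    truth_rows = []
    with open(fastq_path, "w") as fq:
        for read_id, cls, seq in batch.reads():
            donor, acceptor = PRODUCT_STRANDS[cls]
            read = spec.build_read(donor, acceptor, seq)
            if error_rate > 0:
                read = _mutate(read, error_rate, rng)
            fq.write(f"@{read_id}\n{read}\n+\n{qline}\n")
            truth_rows.append((read_id, batch.reaction, cls, seq))
            n += 1
    if truth_path is not None:
        pd.DataFrame(
            truth_rows, columns=["read_id", "reaction", "product_class", "overhang"]
        ).to_csv(truth_path, sep="\t", index=False)
    return n


def _mutate(read: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(read)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alt = [b for b in RNA_BASES if b != chars[i]]
        chars[i] = alt[rng.integers(len(alt))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# mock biological tetraloop reference
# ---------------------------------------------------------------------------

def generate_reference(
    seed: int,
    n_entries: int = 300,
    uncg_weight: float = 30.0,
    gnra_weight: float = 15.0,
    dup_fraction: float = 0.2,
    context_length: tuple[int, int] = (30, 80),
) -> pd.DataFrame:
    """Mock biological tetraloop reference table.

    Emulates a redundancy-laden tetraloop census: loops sampled with
    UNCG/GNRA over-representation, each embedded in a random structural
    context of 30-80 nt, with a configurable fraction of near-duplicate
    contexts (>= 90 % identity to a parent entry, at reduced frequency) to
    exercise deduplication. Byte-identical for a fixed seed.
    """
    if n_entries <= 0:
        raise ValueError(f"n_entries must be positive, got {n_entries}")
    if not 0 <= dup_fraction < 1:
        raise ValueError("dup_fraction must be in [0, 1)")
    lo, hi = context_length
    if not (4 <= lo <= hi):
        raise ValueError("context_length bounds must satisfy 4 <= lo <= hi")
    rng = np.random.default_rng(seed)
    weights = np.ones(len(ALL_OVERHANGS))
    for i, s in enumerate(ALL_OVERHANGS):
        if s in _UNCG_SET:
            weights[i] = uncg_weight
        elif s in _GNRA_SET:
            weights[i] = gnra_weight
    p = weights / weights.sum()
    n_dup = int(round(dup_fraction * n_entries))
    n_base = n_entries - n_dup
    if n_base <= 0:
        raise ValueError("dup_fraction leaves no base entries")
    rows = []
    for _ in range(n_base):
        loop = ALL_OVERHANGS[rng.choice(len(ALL_OVERHANGS), p=p)]
        pair = CLOSING_PAIRS[rng.integers(len(CLOSING_PAIRS))]
        length = int(rng.integers(lo, hi + 1))
        flank = "".join(RNA_BASES[i] for i in rng.integers(0, 4, size=length - 4))
        insert_at = int(rng.integers(0, length - 4 + 1))
        context = flank[:insert_at] + loop + flank[insert_at:]
        base_w = weights[ALL_OVERHANGS.index(loop)]
        freq = max(1, int(round(base_w * float(np.exp(rng.normal(0.0, 0.5))))))
        rows.append({"loop": loop, "closing_pair": pair, "context": context, "frequency": freq})
    for _ in range(n_dup):
        parent = rows[int(rng.integers(n_base))]  # duplicates derive from base entries only
        ctx = list(parent["context"])
        n_sub = max(1, int(0.05 * len(ctx)))  # keeps identity >= 95 % > the 90 % threshold
        for i in rng.choice(len(ctx), size=n_sub, replace=False):
            alt = [b for b in RNA_BASES if b != ctx[i]]
            ctx[i] = alt[rng.integers(len(alt))]
        rows.append(
            {
                "loop": parent["loop"],
                "closing_pair": parent["closing_pair"],
                "context": "".join(ctx),
                "frequency": max(1, parent["frequency"] // 2),
            }
        )
    return pd.DataFrame(rows, columns=["loop", "closing_pair", "context", "frequency"])


_UNCG_SET = frozenset(expand_pattern("UNCG"))
_GNRA_SET = frozenset(expand_pattern("GNRA"))
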