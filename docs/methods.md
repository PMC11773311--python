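# Methods

This note documents the models behind `loopseq`: what the synthetic data
generator emulates, the normalization and statistics applied downstream,
the numerical conventions, and what passing tests do and do not establish.

## The assay being modelled

A core duplex (12-bp stem plus a variable closing base pair) carries a
randomized 4-nt 3′-overhang and an activated 5′-phosphate across the nick.
Intramolecular loop-closing ligation seals the hairpin; intermolecular
splinted ligation proceeds through annealing of complementary overhangs on
two duplexes. Two duplex variants (A:a and B:b) are mixed so that the four
junction products P1 (A-a), P2 (A-b), P3 (B-a), P4 (B-b) identify the
pathway: cross-duplex products P2/P3 arise only from splinted ligation.
Because same-duplex splinted events still produce P1/P4, the observed
(P2+P3)/(P1+P2+P3+P4) read share is a lower limit on the true splinted
fraction; in the symmetric two-duplex model it equals exactly half of it in
expectation.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed and not
adjusted per experiment.

**Input library.** Positional independence with per-position base
frequencies A 0.33, G 0.26, U 0.22, C 0.19 at overhang positions 1–3 and
C 0.33, A 0.28, G 0.21, U 0.18 at position 4 (the last coupling position of
solid-phase synthesis behaves differently). Only these marginals are
constrained; independence is the simplest model consistent with them. The
implied most/least common sequence ratio is (0.33³·0.33)/(0.19³·0.18) ≈ 9.6,
the same order as the observed ~12-fold average input spread. Libraries are
multinomial samples of a configurable molecule count (default 10⁶).

**Loop-closing efficiencies.** An ordered consensus-group model
(first match wins): UNCG 0.62, CNNG 0.30, GNNA 0.28, UNNC 0.20, RNNY 0.002,
all other sequences 0.05. The group means are the validated yield averages;
the 0.05 fallback places unclassified sequences in the observed middle of
the ranking. Within-group dispersion is not constrained by any published
per-sequence table, so it is exposed as a multiplicative lognormal noise
parameter (default σ = 0.25 on the log scale, clipped to (0, 1]); per-batch
values are deterministic given the seed.

**Splinted pathway.** A molecule's splint propensity is the product of four
per-base-pair weights over its Watson–Crick complementary 4-bp splint
(w_GC = 3, w_AU = 1; no wobble pairing in the splint), times the abundance
of the complementary partner in the library, times concentration and a
global scale. The scale is calibrated by bisection so that the observed
(P2+P3) share is 0.44 at 250 nM — the high-concentration anchor. With
strictly first-order concentration dependence this calibration yields an
observed share of ~0.07 at 5 nM rather than the ~0.03 seen in the real
assay, whose effective concentration dependence is evidently steeper than
first order; the model keeps the simpler mass-action form and reports the
consequence honestly. Monotonicity of the splinted fraction in
concentration and the lower-limit property hold analytically and are
tested.

**Fates and reads.** Each molecule partitions among loop closing
(k_loop·efficiency, k_loop = 0.25), splinted ligation, and a hydrolysis
sink (k_hyd = 1.0) that consumes activated material; the rate constants
place total ligated yield in the observed few-percent range. Splinted
events choose the partner duplex type uniformly. Reads are one multinomial
draw of the requested depth over the ligated (product class × overhang)
mass — unreacted material is never sequenced. FASTQ output uses a fixed
read architecture (5′ handle, donor tag, stem, overhang, acceptor tag, 3′
handle) with constant Phred 40 qualities; an optional uniform substitution
error rate exercises demultiplexer robustness. A TSV truth sidecar carries
per-read labels.

**Mock tetraloop reference.** Loops are sampled with UNCG (weight 30) and
GNRA (weight 15) over-represented against a uniform background, embedded in
random 30–80-nt contexts, with frequencies proportional to the sampling
weight under lognormal scatter; a configurable fraction of entries are
near-duplicates (5 % context substitutions, ≥95 % identity) of base entries
at reduced frequency, to exercise deduplication. The reference emulates the
redundancy structure of a curated tetraloop census, not any real database's
contents.

What the generator does **not** emulate: RT/PCR amplification bias, indels
or quality-dependent errors, kinetic time courses or nearest-neighbor
thermodynamics, paired-end read structure, and the real assay's exact
oligonucleotide sequences. Passing recovery tests therefore shows that the
analysis inverts the generative model it assumes — not that it would be
robust to amplification artifacts absent from that model.

## Normalization

Input frequencies f_i come from a control ligation driven nearly to
completion, with an optional pseudocount (default 0.5 in the pipeline, 0 at
the library level) guarding zero cells. Factors α_i = f_i/(1/256) anchor
α = 1 at the even-library frequency; product counts are divided by α_i and
renormalized. The ratio form is the only definition consistent with the
α = 1 anchor and multiplicative input bias. Each overhang-bearing strand
gets its own input distribution; the pipeline applies the distribution of
the strand contributing the overhang. Both α-normalized and raw rankings
are computed and exported, since published ranking tables do not always say
which convention they use.

Ranks are assigned by descending frequency with lexicographic tie-breaks —
determinism is worth more than any unknowable laboratory tie convention.
Zero-count sequences rank last, are excluded from the fold-range
denominator, and are tallied separately (real data had reads for every
sequence; zeros are a synthetic edge case at low depth).

## Profile summaries

Positional composition is frequency-weighted (sequence-logo semantics).
Information content is IC_j = 2 + Σ_b p log₂ p bits with 0·log 0 = 0,
clipped to [0, 2] against rounding. Top-K consensus classification assigns
each of the K best-ranked sequences to the first matching pattern in an
ordered list (default UNNG, CNNG, GNNA) or to "other", and reports the
cumulative read share of the top K.

## Overlap statistics

Context deduplication is a greedy scan in descending frequency
(lexicographic tie-break): an entry is dropped when identity exceeds 0.90
at coverage ≥0.70 against an already-kept entry. Identity is computed on a
global alignment with unit match, −1 mismatch/gap and free end gaps,
as matches over aligned columns excluding end gaps; coverage is the shorter
sequence's share of positions inside that span. Dropped entries'
frequencies are discarded, not merged — keeping the most frequent
representative, with thresholds strict (>) on identity and inclusive (≥) on
coverage. Dedup is idempotent.

The top-K overlap of a profile with a reference group is a plain set
intersection. Under the null of an unrelated ranking, the overlap is
hypergeometric with expectation nK/N = 6.25 for K = n = 40 of N = 256
(rounding to the conventional 6). Tails are exact pmf sums accumulated in
log space (log-gamma), one-sided and inclusive: enrichment P(X ≥ k),
depletion P(X ≤ k). The exact tail at the rounded cross-reaction average of
12 is 0.0093 ≈ 0.009, and at the splinted average of 2 it is 0.0288 ≈ 0.03,
which is how those two conventional significance levels arise; the package
reports per-group tails plus the tail at the rounded mean. Fold enrichment
is k_obs/expected; depletion is reported as the inverse ratio (3.1-fold for
2 vs 6.25). Directional one-sided tests match the directional claims being
made; no two-sided construction is used.

## Validation

Spearman's ρ is the Pearson correlation of midranks (scipy `rankdata`),
with constant input treated as an error rather than NaN, since a constant
vector has no rank ordering. Rank order is reversed before correlating so
that high yield at a numerically small (good) rank reports positive ρ. The
packaged 34-sequence yield panel is synthetic: group membership and group
means (62/30/28/20/5/0.2 %) are anchored, per-sequence values are not.
Reported values of ρ for this assay cluster around 0.83–0.84 and differ by
tie convention in a way that cannot be resolved without the raw panel;
neither endpoint is asserted exactly.

## Problem sizes and determinism

Default pipeline runs use 10⁶ library molecules, 2×10⁵ control reads and
5×10⁴–2×10⁵ product reads per reaction with a 600-entry reference; the test
suite and acceptance script use these or smaller sizes, with recovery
properties evaluated at 10⁶–10⁷ reads where the asymptotic claims are made.
All randomness flows from a single config seed through named child seeds;
serialized floats are rounded to 10 significant digits so reports are
byte-stable across runs and platforms. Outputs are TSV and JSON only,
written atomically.

## Known limitations

* First-order splint concentration dependence under-shoots the real
  steepness between 250 nM and 5 nM (see above).
* The simulated product fold-range (~300–700 at default noise) exceeds the
  70–280-fold observed range, because lognormal efficiency dispersion and
  finite-depth sampling both widen the extremes.
* The mock reference's splinted-profile overlap is only mildly depleted
  (≈5 of 40 against an expectation of 6.25) compared with the strong
  depletion in real data; a product-weight splint model shares more
  sequences with a UNCG/GNRA-enriched reference than real splinted
  chemistry apparently does.
* Dedup is O(n²) in reference size; intended for curated tables of
  hundreds to a few thousand entries, not genome-scale censuses.
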