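# loopseq

Sequence–reactivity profiling of nonenzymatic RNA loop-closing ligation
from deep-sequencing counts.

## The scientific problem

RNA hairpins are the most common RNA secondary structure, and the most
common hairpin loops in biology — four-nucleotide "tetraloops" such as the
UNCG and GNRA families — are exceptionally stable. Template-free
**loop-closing ligation** can build a hairpin in one chemical step: a short
duplex with a randomized 4-nt 3′-overhang (5′-NNNN-3′) and an activated
5′-phosphate on the opposing strand ligates across the loop. The competing
pathway is **splinted (nicked-duplex) ligation**, in which two duplexes
anneal through complementary overhangs and ligate across the nick; it is
concentration dependent and favors C:G-rich overhangs.

`loopseq` implements the full computational analysis of a four-strand
sequencing assay for this competition, for people studying prebiotic RNA
assembly or engineering template-free RNA ligation:

* **synthetic data** — a ground-truth-labelled simulator of the assay
  (biased input libraries, consensus-group loop-closing efficiencies,
  mass-action competition with a splinted pathway and a hydrolysis sink,
  FASTQ emission) plus a mock biological tetraloop reference;
* **demultiplexing** — classification of reads into the four junction
  products P1 (A-a), P2 (A-b), P3 (B-a), P4 (B-b) by donor/acceptor tag
  matching. P2 and P3 can only arise from splinted ligation, so
  (P2+P3)/(P1+P2+P3+P4) is a lower limit on the splinted contribution;
* **normalization and profiling** — per-sequence input frequencies *f_i*
  from a control ligation, normalization factors *α_i = f_i/(1/256)*
  (α_i = 1 at the even-library frequency), α-corrected frequency profiles
  with ranks, fold-ranges, positional base composition, information content
  *IC_j = 2 + Σ_b p_bj log₂ p_bj* (0–2 bits), and IUPAC consensus-group
  classification (UNNG/CNNG/GNNA vs RNNY/ANNR/CNNU);
* **reference overlap** — deduplication of a tetraloop reference
  (drop contexts >90 % identical at ≥70 % alignment coverage), per
  closing-pair ranking, and exact hypergeometric statistics for the top-*K*
  overlap: expectation *nK/N* (6.25 for *K = n = 40*, *N = 256*),
  one-sided inclusive tail p-values computed in log space, and fold
  enrichment/depletion;
* **validation** — Spearman rank correlation (midrank ties) between
  measured ligation yields and sequencing rank, consensus-group mean yields
  and fold differences (e.g. 62 % / 0.2 % = 310-fold between UNCG and RNNY
  group means).

All 256 overhangs × 6 closing base pairs (C:G, G:C, U:A, A:U, U:G, G:U)
give 1536 assayed variants.

## Worked example

```python
from loopseq.config import demo_config
from loopseq.pipeline import run_all

report = run_all(demo_config(seed=7, outdir="demo_out"))
rxn = report["reactions"]["C:G"]
print(rxn["splinted_fraction_observed"])   # 0.0738
print(rxn["recovery_spearman"])            # 0.9135160053
print(rxn["top_k_pattern_counts"])         # {'UNNG': 4, 'CNNG': 16, 'GNNA': 15, 'other': 5}
print(report["overlap_summary"])
# {'expected_overlap': 6.25, 'mean_overlap_loop': 10.0,
#  'mean_overlap_splint': 5.0, 'p_loop_at_rounded_mean': 0.06651524692,
#  'p_splint_at_rounded_mean': 0.3742504223}
```

Reading the numbers: at 5 nM the observed (P2+P3) read share is 0.074 — the
lower-limit estimate of the splinted contribution at low concentration; the
α-normalized P1 frequency profile recovers the simulator's true
loop-closing efficiency ranking with Spearman ρ = 0.91 at this modest read
depth; 35 of the top-40 loop sequences fall in the favored UNNG/CNNG/GNNA
consensus groups, carrying ~54 % of the normalized reads; and the top-40
loop-closing sequences share 10 loops with the top-40 of the mock
biological tetraloop reference, against a chance expectation of 6.25.

The same pipeline is available from a shell:

```
loopseq make-demo-config --seed 7 --out demo.yaml
loopseq run-all --config demo.yaml
loopseq demux --config demo.yaml --reads demo_out/reads_CG.fastq --out counts.tsv
```

## Layout

```
src/loopseq/
  sequences.py   overhang alphabet, IUPAC patterns, closing pairs
  construct.py   read architecture (handles, tags, stem, overhang window)
  synthetic.py   reaction simulator + mock tetraloop reference
  demux.py       P1-P4 classification and count tables
  profiles.py    alpha normalization, ranks, composition, information content
  overlap.py     dedup, grouping, exact hypergeometric overlap tests
  validation.py  Spearman, group means, fold differences
  config.py      schema-validated YAML configuration
  pipeline.py    end-to-end runner with deterministic reports
  cli.py         `loopseq` command-line interface
docs/methods.md  model assumptions, parameter choices, limitations
```
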