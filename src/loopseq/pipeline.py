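"""End-to-end pipeline: simulate -> demux -> profile -> overlap -> validate.

Every stage is driven by one :class:`~loopseq.config.PipelineConfig`; all
randomness derives from its seed, so a fixed config reproduces the report
bit-for-bit. Serialized floats are rounded to 10 significant digits to keep
report hashes platform-stable.
"""

from __future__ import annotations

import json
import logging
import math
import os
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .construct import ConstructSpec
from .demux import ProductCountTable, splinted_fraction, tabulate
from .overlap import DedupParams, dedup, group_rank, hypergeom_tail, overlap_analysis
from .profiles import (
    alpha_factors,
    classify_top_k,
    fold_range,
    information_content,
    input_frequencies,
    normalize_counts,
    position_composition,
)
from .synthetic import (
    EfficiencyModel,
    PositionBaseFrequencies,
    default_splint_model,
    generate_reference,
    sample_input_library,
    simulate_reaction,
    write_reads,
)
from .validation import example_yield_panel, rank_yield_correlation, spearman

logger = logging.getLogger(__name__)

_STAGE_KEYS = {"library": 1, "control": 2, "reaction": 3, "reference": 4, "efficiency": 5}


def _child_seed(seed: int, stage: str, index: int = 0) -> int:
    ss = np.random.SeedSequence([seed, _STAGE_KEYS[stage], index])
    return int(ss.generate_state(1)[0] % (2**31))


def _round_floats(obj, sig: int = 10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (float, np.floating)):
        x = float(obj)
        if x == 0 or not math.isfinite(x):
            return x
        return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _atomic_write_json(payload: dict, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    os.replace(tmp, path)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _prepare_models(config: PipelineConfig):
    """Library bias, resolved efficiencies and calibrated splint model."""
    gen = config.generator
    freqs = (
        PositionBaseFrequencies.uniform()
        if gen.library_bias == "uniform"
        else PositionBaseFrequencies.default()
    )
    eff_model = EfficiencyModel.default(
        noise_sd=gen.efficiency_noise_sd, seed=_child_seed(config.seed, "efficiency")
    )
    efficiencies = eff_model.resolve()
    try:
        splint = default_splint_model(
            freqs.probabilities(),
            efficiencies,
            observed_fraction=gen.target_splinted_share,
            concentration_nM=gen.reference_concentration_nM,
            w_gc=gen.w_gc,
            w_au=gen.w_au,
            k_loop=gen.k_loop,
            k_hyd=gen.k_hyd,
        )
    except Exception as exc:
        raise StageError(f"simulate: splint calibration failed: {exc}") from exc
    return freqs, efficiencies, splint


def _construct_for(config: PipelineConfig, pair: str) -> ConstructSpec:
    return ConstructSpec(
        handle5=config.construct_spec.handle5,
        handle3=config.construct_spec.handle3,
        stem=config.construct_spec.stem,
        closing_pair=pair,
        donor_tags=config.construct_spec.donor_tags,
        acceptor_tags=config.construct_spec.acceptor_tags,
    )


def generate_reads(config: PipelineConfig) -> dict[str, dict[str, Path]]:
    """Generation stage only: write per-reaction FASTQ, truth sidecar and
    control-ligation count TSVs under ``config.outdir``.

    Uses the same derived seeds as :func:`run_all`, so the emitted reads are
    identical to those of a full run with the same config.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen = config.generator
    freqs, efficiencies, splint = _prepare_models(config)
    paths: dict[str, dict[str, Path]] = {}
    for i, pair in enumerate(config.closing_pairs):
        spec = _construct_for(config, pair)
        library = sample_input_library(
            freqs, gen.n_molecules, _child_seed(config.seed, "library", i)
        )
        control = sample_input_library(
            freqs, gen.control_depth, _child_seed(config.seed, "control", i)
        )
        batch = simulate_reaction(
            library, efficiencies, splint, gen.concentration_nM, gen.read_depth,
            _child_seed(config.seed, "reaction", i),
            k_loop=gen.k_loop, k_hyd=gen.k_hyd, reaction=pair, closing_pair=pair,
        )
        tag = pair.replace(":", "")
        fastq = outdir / f"reads_{tag}.fastq"
        truth = outdir / f"truth_{tag}.tsv"
        ctrl = outdir / f"control_counts_{tag}.tsv"
        write_reads(batch, spec, fastq, truth, error_rate=gen.error_rate)
        control.rename("count").to_frame().reset_index().to_csv(ctrl, sep="\t", index=False)
        paths[pair] = {"fastq": fastq, "truth": truth, "control": ctrl}
    return paths


def run_all(config: PipelineConfig, write_fastq: bool = True) -> dict:
    """Execute the full pipeline and return (and write) the run report.

    Stages run in order simulate -> demux -> profile -> overlap -> validate;
    the first failure aborts with a stage-tagged :class:`StageError`.
    Outputs (count tables, profiles, reference, report.json) are written
    under ``config.outdir``; JSON files are written atomically.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen = config.generator
    thr = config.thresholds

    logger.info(
        "run_all: seed=%d pairs=%s depth=%d top_k=%d max_mismatch=%d pseudocount=%g",
        config.seed, config.closing_pairs, gen.read_depth, thr.top_k,
        thr.max_mismatch, thr.pseudocount,
    )

    freqs, efficiencies, splint = _prepare_models(config)

    reactions: dict[str, dict] = {}
    loop_rank_lists: dict[str, list[str]] = {}
    splint_rank_lists: dict[str, list[str]] = {}
    profile_cg = None
    truth_by_pair: dict[str, pd.Series] = {}

    for i, pair in enumerate(config.closing_pairs):
        try:
            spec = _construct_for(config, pair)
            library = sample_input_library(
                freqs, gen.n_molecules, _child_seed(config.seed, "library", i)
            )
            control = sample_input_library(
                freqs, gen.control_depth, _child_seed(config.seed, "control", i)
            )
            batch = simulate_reaction(
                library,
                efficiencies,
                splint,
                gen.concentration_nM,
                gen.read_depth,
                _child_seed(config.seed, "reaction", i),
                k_loop=gen.k_loop,
                k_hyd=gen.k_hyd,
                reaction=pair,
                closing_pair=pair,
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"simulate[{pair}]: {exc}") from exc

        tag = pair.replace(":", "")
        try:
            if write_fastq:
                fastq = outdir / f"reads_{tag}.fastq"
                truth = outdir / f"truth_{tag}.tsv"
                write_reads(batch, spec, fastq, truth, error_rate=gen.error_rate)
                table = tabulate(fastq, spec, thr.max_mismatch, reaction=pair)
            else:
                table = ProductCountTable.empty(pair, pair)
                table.counts = batch.counts.copy()
            table.to_tsv(outdir / f"counts_{tag}.tsv")
            sf = splinted_fraction(table)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"demux[{pair}]: {exc}") from exc

        try:
            dist = input_frequencies(control, thr.pseudocount, strand=f"{pair}:a")
            alpha = alpha_factors(dist)
            prof1 = normalize_counts(
                table.class_counts("P1"), alpha, pair, "P1", pair
            )
            prof2_counts = table.class_counts("P2")
            prof2 = (
                normalize_counts(prof2_counts, alpha, pair, "P2", pair)
                if prof2_counts.sum() > 0
                else None
            )
            fr1 = fold_range(prof1)
            topk = classify_top_k(prof1, tuple(config.top_patterns), thr.top_k)
            pos = position_composition(prof1)
            ic = information_content(pos)
            prof1.to_tsv(outdir / f"profile_P1_{tag}.tsv", tuple(config.top_patterns))
            pos.to_tsv(outdir / f"logo_P1_{tag}.tsv")
            recovery = spearman(
                batch.true_efficiencies.to_numpy(), prof1.norm_freq.to_numpy()
            )
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"profile[{pair}]: {exc}") from exc

        loop_rank_lists[pair] = list(prof1.top_k(256).index)
        if prof2 is not None:
            splint_rank_lists[pair] = list(prof2.top_k(256).index)
        if pair == "C:G" or profile_cg is None:
            profile_cg = prof1
        truth_by_pair[pair] = batch.true_efficiencies

        reactions[pair] = {
            "reads_total": table.total_classified + table.total_rejected,
            "reads_classified": table.total_classified,
            "reads_rejected": table.total_rejected,
            "splinted_fraction_observed": sf,
            "splinted_fraction_true": batch.true_splinted_fraction,
            "fold_range_P1": fr1.ratio,
            "zero_count_sequences": fr1.n_zero,
            "top_k_share": topk.cumulative_share,
            "top_k_pattern_counts": topk.pattern_counts,
            "information_bits": [float(x) for x in ic],
            "recovery_spearman": recovery.rho,
        }

    # ---- reference overlap ----
    try:
        ref = generate_reference(
            _child_seed(config.seed, "reference"),
            n_entries=config.reference.n_entries,
            uncg_weight=config.reference.uncg_weight,
            gnra_weight=config.reference.gnra_weight,
            dup_fraction=config.reference.dup_fraction,
        )
        ref.to_csv(outdir / "reference_raw.tsv", sep="\t", index=False)
        dd = dedup(ref, DedupParams(thr.dedup_identity, thr.dedup_coverage))
        dd.to_csv(outdir / "reference_dedup.tsv", sep="\t", index=False)
        ref_ranks = group_rank(dd)
        overlaps_loop = {}
        overlaps_splint = {}
        for pair in config.closing_pairs:
            ref_loops = list(ref_ranks[pair]["loop"])
            res = overlap_analysis(
                loop_rank_lists[pair], ref_loops, thr.top_k, group=pair
            )
            overlaps_loop[pair] = res.__dict__
            if pair in splint_rank_lists:
                res2 = overlap_analysis(
                    splint_rank_lists[pair], ref_loops, thr.top_k, group=pair
                )
                overlaps_splint[pair] = res2.__dict__
        expected = thr.top_k * thr.top_k / 256
        mean_loop = float(np.mean([o["k_obs"] for o in overlaps_loop.values()]))
        overlap_summary = {
            "expected_overlap": expected,
            "mean_overlap_loop": mean_loop,
            "p_loop_at_rounded_mean": hypergeom_tail(
                int(round(mean_loop)), 256, thr.top_k, thr.top_k, "enrichment"
            ),
        }
        if overlaps_splint:
            mean_spl = float(np.mean([o["k_obs"] for o in overlaps_splint.values()]))
            overlap_summary["mean_overlap_splint"] = mean_spl
            overlap_summary["p_splint_at_rounded_mean"] = hypergeom_tail(
                int(round(mean_spl)), 256, thr.top_k, thr.top_k, "depletion"
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"overlap: {exc}") from exc

    # ---- validation ----
    try:
        panel = example_yield_panel()
        rho_panel = rank_yield_correlation(profile_cg, panel)
        validation = {
            "panel_n": int(len(panel)),
            "panel_spearman_rho": rho_panel.rho,
        }
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"validate: {exc}") from exc

    report = _round_floats(
        {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "thresholds": config.thresholds.model_dump(),
            "splint_conc_scale": splint.conc_scale,
            "reactions": reactions,
            "overlap_loop": overlaps_loop,
            "overlap_splint": overlaps_splint,
            "overlap_summary": overlap_summary,
            "validation": validation,
        }
    )
    _atomic_write_json(report, outdir / "report.json")
    return report
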