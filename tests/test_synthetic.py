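"""Synthetic reaction generator: library bias, efficiencies, partitioning."""

import numpy as np
import pandas as pd
import pytest

from loopseq.sequences import ALL_OVERHANGS, expand_pattern
from loopseq.synthetic import (
    EfficiencyModel,
    PositionBaseFrequencies,
    SplintModel,
    calibrate_splint_scale,
    expected_splinted_fraction,
    generate_reference,
    per_sequence_concentration,
    sample_input_library,
    simulate_reaction,
)


class TestPositionBaseFrequencies:
    def test_rows_must_be_distributions(self):
        bad = np.full((4, 4), 0.3)
        with pytest.raises(ValueError):
            PositionBaseFrequencies(bad)
        with pytest.raises(ValueError):
            PositionBaseFrequencies(np.array([[1.5, -0.5, 0, 0]] * 4))

    def test_default_bias_matches_stated_composition(self):
        m = PositionBaseFrequencies.default().matrix
        # A, C, G, U columns
        assert m[0].tolist() == [0.33, 0.19, 0.26, 0.22]
        assert m[3].tolist() == [0.28, 0.33, 0.21, 0.18]

    def test_extreme_sequence_probability_ratio(self):
        """Most/least likely overhang differ ~10-fold under the default bias,
        the same order as the observed 12-fold average input spread."""
        f = PositionBaseFrequencies.default()
        ratio = f.sequence_probability("AAAC") / f.sequence_probability("CCCU")
        expected = (0.33**3 * 0.33) / (0.19**3 * 0.18)  # direct arithmetic
        assert ratio == pytest.approx(expected)
        assert 8 < ratio < 12
        p = f.probabilities()
        assert p.idxmax() == "AAAC" and p.sum() == pytest.approx(1.0)
        assert p.max() / p.min() == pytest.approx(expected)


class TestSampleInputLibrary:
    def test_uniform_limit(self):
        counts = sample_input_library(PositionBaseFrequencies.uniform(), 256_000, seed=0)
        assert counts.sum() == 256_000
        assert len(counts) == 256
        assert counts.mean() == pytest.approx(1000.0)
        assert counts.max() / counts.min() < 1.6  # tightens to 1 as n grows

    def test_rejects_empty_sample(self):
        with pytest.raises(ValueError):
            sample_input_library(PositionBaseFrequencies.uniform(), 0, seed=0)

    def test_seed_determinism(self):
        f = PositionBaseFrequencies.default()
        a = sample_input_library(f, 10_000, seed=5)
        b = sample_input_library(f, 10_000, seed=5)
        pd.testing.assert_series_equal(a, b)


class TestEfficiencyModel:
    def test_zero_noise_reproduces_group_means(self):
        eff = EfficiencyModel.default(noise_sd=0.0).resolve()
        assert eff["UUCG"] == pytest.approx(0.62)
        assert eff["AAAC"] == pytest.approx(0.002)  # RNNY
        assert eff["CAAG"] == pytest.approx(0.30)   # CNNG
        assert eff["GAAA"] == pytest.approx(0.28)   # GNNA
        assert eff["UAAC"] == pytest.approx(0.20)   # UNNC

    def test_first_matching_pattern_wins(self):
        # UACG is both UNCG and would otherwise fall through; the ordered
        # model must assign the UNCG mean
        eff = EfficiencyModel.default(noise_sd=0.0).resolve()
        for s in expand_pattern("UNCG"):
            assert eff[s] == pytest.approx(0.62)

    def test_noise_is_seeded_and_bounded(self):
        m = EfficiencyModel.default(noise_sd=0.5, seed=3)
        a, b = m.resolve(), m.resolve()
        pd.testing.assert_series_equal(a, b)
        assert ((a > 0) & (a <= 1)).all()
        assert not np.allclose(a, EfficiencyModel.default(noise_sd=0.0).resolve())


class TestSplintPartition:
    def test_pairing_weight_is_base_pair_product(self):
        m = SplintModel(w_gc=3.0, w_au=1.0, conc_scale=1.0)
        assert m.pairing_weight("GGCC") == 81.0
        assert m.pairing_weight("AAUU") == 1.0
        assert m.pairing_weight("GAUC") == 9.0

    def test_disabled_splint_routes_everything_to_hairpins(
        self, library_freqs, noiseless_efficiencies
    ):
        off = SplintModel(conc_scale=0.0)
        batch = simulate_reaction(
            library_freqs, noiseless_efficiencies, off, 250.0, 20_000, seed=1
        )
        assert batch.true_splinted_fraction == 0.0
        assert batch.class_counts("P2").sum() == 0
        assert batch.class_counts("P3").sum() == 0
        assert batch.total_reads() == 20_000

    def test_calibration_hits_observed_share_at_high_concentration(
        self, library_freqs, noiseless_efficiencies, calibrated_splint
    ):
        """The concentration scale found by bisection puts the observed
        (P2+P3) share at 0.44 at 250 nM, i.e. a true splinted fraction of
        0.88 in the symmetric two-duplex design."""
        true = expected_splinted_fraction(
            library_freqs, noiseless_efficiencies, calibrated_splint, 250.0
        )
        assert true == pytest.approx(0.88, abs=1e-9)

    def test_per_molecule_enumeration_oracle(self, noiseless_efficiencies):
        """The analytic partition agrees with direct per-sequence enumeration
        of the mass-action fates."""
        from loopseq.sequences import reverse_complement

        f = pd.Series(1 / 256, index=pd.Index(ALL_OVERHANGS, name="overhang"))
        model = SplintModel(w_gc=3.0, w_au=1.0, conc_scale=0.01)
        k_loop, k_hyd, conc = 0.25, 1.0, 50.0
        num = 0.0
        den = 0.0
        for s in ALL_OVERHANGS:
            loop = k_loop * noiseless_efficiencies[s]
            spl = 0.01 * conc * model.pairing_weight(s) * f[reverse_complement(s)]
            tot = loop + spl + k_hyd
            num += f[s] * spl / tot
            den += f[s] * (loop + spl) / tot
        oracle = num / den
        got = expected_splinted_fraction(f, noiseless_efficiencies, model, conc, k_loop, k_hyd)
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_splinted_fraction_monotone_in_concentration(
        self, library_freqs, noiseless_efficiencies, calibrated_splint
    ):
        grid = [1.0, 5.0, 25.0, 100.0, 250.0, 1000.0]
        vals = [
            expected_splinted_fraction(
                library_freqs, noiseless_efficiencies, calibrated_splint, c
            )
            for c in grid
        ]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_recovered_fractions_match_truth_within_binomial_error(
        self, library_freqs, noiseless_efficiencies, calibrated_splint
    ):
        """Sampled (P2+P3) share tracks half the true splinted fraction
        (the other half of splinted events hides in P1/P4) within 3 sd."""
        for conc in (250.0, 5.0):
            batch = simulate_reaction(
                library_freqs, noiseless_efficiencies, calibrated_splint,
                conc, 50_000, seed=17,
            )
            observed = (
                batch.class_counts("P2").sum() + batch.class_counts("P3").sum()
            ) / batch.total_reads()
            expected = batch.true_splinted_fraction / 2
            sd = np.sqrt(expected * (1 - expected) / batch.total_reads())
            assert abs(observed - expected) < 3 * sd

    def test_batches_are_deterministic(self, library_freqs, noiseless_efficiencies):
        m = SplintModel(conc_scale=0.01)
        a = simulate_reaction(library_freqs, noiseless_efficiencies, m, 5.0, 10_000, seed=2)
        b = simulate_reaction(library_freqs, noiseless_efficiencies, m, 5.0, 10_000, seed=2)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_degenerate_inputs_raise(self, library_freqs, noiseless_efficiencies):
        m = SplintModel(conc_scale=0.0)
        with pytest.raises(ValueError):
            simulate_reaction(library_freqs, noiseless_efficiencies, m, 0.0, 100, seed=0)
        with pytest.raises(ValueError):
            simulate_reaction(library_freqs, noiseless_efficiencies, m, 5.0, 0, seed=0)
        with pytest.raises(ValueError):
            simulate_reaction(
                library_freqs, noiseless_efficiencies, m, 5.0, 100, seed=0,
                k_loop=0.0, k_hyd=0.0,
            )


def test_calibration_is_invertible(library_freqs, noiseless_efficiencies):
    scale = calibrate_splint_scale(0.5, library_freqs, noiseless_efficiencies, 100.0)
    model = SplintModel(conc_scale=scale)
    assert expected_splinted_fraction(
        library_freqs, noiseless_efficiencies, model, 100.0
    ) == pytest.approx(0.5, abs=1e-9)


def test_per_sequence_concentration():
    assert per_sequence_concentration(5.0) == pytest.approx(5.0 / 256)
    assert round(per_sequence_concentration(5.0), 2) == 0.02
    with pytest.raises(ValueError):
        per_sequence_concentration(0.0)


class TestReferenceGenerator:
    def test_enriched_loops_occupy_top_ranks(self):
        ref = generate_reference(seed=1, n_entries=400, dup_fraction=0.0)
        by_loop = ref.groupby("loop")["frequency"].sum().sort_values(ascending=False)
        top10 = set(by_loop.head(10).index)
        special = set(expand_pattern("UNCG")) | set(expand_pattern("GNRA"))
        assert len(top10 & special) >= 8

    def test_fixed_seed_is_byte_identical(self, tmp_path):
        a = generate_reference(seed=9, n_entries=50)
        b = generate_reference(seed=9, n_entries=50)
        pa, pb = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.to_csv(pa, sep="\t", index=False)
        b.to_csv(pb, sep="\t", index=False)
        assert pa.read_bytes() == pb.read_bytes()

    def test_near_duplicates_have_high_identity(self):
        from loopseq.overlap import pairwise_similarity

        ref = generate_reference(seed=3, n_entries=40, dup_fraction=0.25)
        n_dup = 10
        parents = ref.iloc[: len(ref) - n_dup]
        dups = ref.iloc[len(ref) - n_dup:]
        # each duplicate matches some earlier context above the dedup threshold
        for ctx in dups["context"]:
            best = max(
                pairwise_similarity(ctx, p)[0] for p in parents["context"]
            )
            assert best > 0.90

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_reference(seed=0, n_entries=0)
        with pytest.raises(ValueError):
            generate_reference(seed=0, n_entries=10, dup_fraction=1.0)
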