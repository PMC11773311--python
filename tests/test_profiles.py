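"""Input-bias normalization, frequency profiles, composition and IC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from loopseq.profiles import (
    PositionProfile,
    alpha_factors,
    classify_top_k,
    fold_range,
    information_content,
    input_frequencies,
    normalize_counts,
    position_composition,
)
from loopseq.sequences import ALL_OVERHANGS
from loopseq.synthetic import (
    PositionBaseFrequencies,
    sample_input_library,
    simulate_reaction,
    SplintModel,
)

SEQ_INDEX = pd.Index(ALL_OVERHANGS, name="overhang")


def uniform_counts(n_per_seq=100):
    return pd.Series(n_per_seq, index=SEQ_INDEX)


class TestInputFrequencies:
    def test_uniform_counts_give_even_distribution(self):
        dist = input_frequencies(uniform_counts())
        assert np.allclose(dist.frequencies, 1 / 256)

    def test_biased_counts_reproduce_generator_spread(self):
        """High-depth sampling from the default library bias recovers the
        ~10-fold analytic max/min frequency ratio."""
        counts = sample_input_library(PositionBaseFrequencies.default(), 5_000_000, seed=2)
        dist = input_frequencies(counts)
        ratio = dist.frequencies.max() / dist.frequencies.min()
        analytic = (0.33**3 * 0.33) / (0.19**3 * 0.18)
        assert ratio == pytest.approx(analytic, rel=0.25)

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError):
            input_frequencies(pd.Series(0, index=SEQ_INDEX))

    def test_zero_cells_warn_without_pseudocount(self):
        c = uniform_counts()
        c.iloc[0] = 0
        with pytest.warns(UserWarning):
            dist = input_frequencies(c, pseudocount=0.0)
        with pytest.raises(ValueError):
            alpha_factors(dist)
        # pseudocount repairs it
        dist2 = input_frequencies(c, pseudocount=0.5)
        assert (alpha_factors(dist2) > 0).all()


class TestAlphaFactors:
    def test_even_frequency_anchors_alpha_at_one(self):
        dist = input_frequencies(uniform_counts())
        alpha = alpha_factors(dist)
        assert np.allclose(alpha, 1.0)
        assert alpha.mean() == pytest.approx(1.0)

    def test_alpha_is_frequency_ratio(self):
        c = uniform_counts().astype(float)
        c["AAAA"] *= 2  # twice the even frequency, approximately
        dist = input_frequencies(c)
        alpha = alpha_factors(dist)
        assert alpha["AAAA"] == pytest.approx(2 * 256 / 257, rel=1e-9)
        assert alpha.mean() == pytest.approx(1.0)


class TestNormalizeCounts:
    def test_counts_proportional_to_alpha_flatten(self):
        c = sample_input_library(PositionBaseFrequencies.default(), 1_000_000, seed=4)
        dist = input_frequencies(c, pseudocount=0.5)
        alpha = alpha_factors(dist)
        # product formation sequence-independent: counts proportional to alpha
        counts = (alpha * 1000).round().astype(int)
        prof = normalize_counts(counts, alpha)
        fr = fold_range(prof)
        assert fr.ratio < 1.15
        assert prof.norm_freq.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_count_sequences_rank_last(self):
        counts = uniform_counts().copy()
        counts["UUCG"] = 0
        prof = normalize_counts(counts, alpha_factors(input_frequencies(uniform_counts())))
        assert prof.norm_freq["UUCG"] == 0.0
        assert prof.ranks["UUCG"] == 256
        assert prof.norm_freq.sum() == pytest.approx(1.0)

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            normalize_counts(
                pd.Series(0, index=SEQ_INDEX),
                alpha_factors(input_frequencies(uniform_counts())),
            )

    def test_rank_ties_break_lexicographically_and_deterministically(self):
        counts = uniform_counts()
        alpha = alpha_factors(input_frequencies(uniform_counts()))
        p1 = normalize_counts(counts, alpha)
        p2 = normalize_counts(counts.sample(frac=1, random_state=0), alpha)
        pd.testing.assert_series_equal(p1.ranks, p2.ranks)
        assert p1.ranks["AAAA"] == 1 and p1.ranks["UUUU"] == 256

    def test_parameter_recovery_from_deep_sequencing(
        self, library_freqs, noiseless_efficiencies
    ):
        """Normalized P1 frequency recovers the true efficiency ranking
        (Spearman >= 0.9 at 1e6 reads)."""
        from loopseq.validation import spearman

        counts = sample_input_library(PositionBaseFrequencies.default(), 2_000_000, seed=6)
        batch = simulate_reaction(
            counts, noiseless_efficiencies, SplintModel(conc_scale=0.0),
            5.0, 1_000_000, seed=7,
        )
        control = sample_input_library(PositionBaseFrequencies.default(), 1_000_000, seed=8)
        alpha = alpha_factors(input_frequencies(control, pseudocount=0.5))
        prof = normalize_counts(batch.class_counts("P1"), alpha)
        rho = spearman(
            batch.true_efficiencies.to_numpy(), prof.norm_freq.to_numpy()
        ).rho
        assert rho >= 0.9


class TestFoldRange:
    def test_flat_profile(self):
        prof = normalize_counts(
            uniform_counts(), alpha_factors(input_frequencies(uniform_counts()))
        )
        fr = fold_range(prof)
        assert fr.ratio == pytest.approx(1.0)
        assert fr.n_zero == 0

    def test_two_point_profile(self):
        counts = pd.Series(0, index=SEQ_INDEX)
        counts["AAAA"], counts["UUUU"] = 900, 100
        prof = normalize_counts(counts, alpha_factors(input_frequencies(uniform_counts())))
        fr = fold_range(prof)
        assert fr.ratio == pytest.approx(9.0)
        assert fr.n_zero == 254

    def test_high_contrast_simulation_recovers_efficiency_ratio(
        self, noiseless_efficiencies
    ):
        """At high depth the profile's fold-range approaches the true
        310-fold efficiency spread (within 2-fold)."""
        counts = uniform_counts(10_000)
        batch = simulate_reaction(
            counts, noiseless_efficiencies, SplintModel(conc_scale=0.0),
            5.0, 10_000_000, seed=9,
        )
        prof = normalize_counts(
            batch.class_counts("P1"),
            alpha_factors(input_frequencies(uniform_counts())),
        )
        fr = fold_range(prof)
        true_ratio = (
            noiseless_efficiencies.max() / noiseless_efficiencies.min()
        )  # 0.62 / 0.002 = 310
        assert true_ratio == pytest.approx(310.0)
        assert true_ratio / 2 <= fr.ratio <= true_ratio * 2


class TestPositionComposition:
    def test_point_mass_profile(self):
        f = pd.Series(0.0, index=SEQ_INDEX)
        f["UUCG"] = 1.0
        pos = position_composition(f)
        assert pos.matrix.loc[1, "U"] == 1.0
        assert pos.matrix.loc[3, "C"] == 1.0
        ic = information_content(pos)
        assert np.allclose(ic, 2.0)

    def test_uniform_profile(self):
        f = pd.Series(1 / 256, index=SEQ_INDEX)
        pos = position_composition(f)
        assert np.allclose(pos.matrix, 0.25)
        assert np.allclose(information_content(pos), 0.0)

    def test_input_library_composition_matches_generator_bias(self):
        """Composition of a deep input sample reproduces the stated marginal
        base frequencies at every position."""
        counts = sample_input_library(PositionBaseFrequencies.default(), 2_000_000, seed=10)
        pos = position_composition(counts.astype(float))
        expected = PositionBaseFrequencies.default().matrix
        assert np.allclose(pos.matrix.to_numpy(), expected, atol=0.005)


class TestInformationContent:
    def test_half_half_composition_is_one_bit(self):
        m = pd.DataFrame(
            [[0.5, 0.5, 0, 0]] * 4,
            index=pd.Index([1, 2, 3, 4], name="position"),
            columns=list("ACGU"),
        )
        ic = information_content(PositionProfile(m))
        assert np.allclose(ic, 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    def test_bounds_and_relabeling_invariance(self, raw):
        row = np.array(raw) / np.sum(raw)
        m = pd.DataFrame(
            [row] * 4, index=pd.Index([1, 2, 3, 4], name="position"), columns=list("ACGU")
        )
        ic = information_content(PositionProfile(m))
        assert ((ic >= 0) & (ic <= 2)).all()
        perm = m[["G", "A", "U", "C"]]
        perm.columns = list("ACGU")
        ic2 = information_content(PositionProfile(perm))
        assert np.allclose(ic, ic2)


class TestClassifyTopK:
    def test_single_catchall_pattern_covers_everything(self):
        prof = normalize_counts(
            uniform_counts(), alpha_factors(input_frequencies(uniform_counts()))
        )
        res = classify_top_k(prof, ("NNNN",), 256)
        assert res.pattern_counts["NNNN"] == 256
        assert res.pattern_counts["other"] == 0
        assert res.cumulative_share == pytest.approx(1.0)

    def test_k_zero_is_empty(self):
        prof = normalize_counts(
            uniform_counts(), alpha_factors(input_frequencies(uniform_counts()))
        )
        res = classify_top_k(prof, ("UNNG",), 0)
        assert res.k == 0
        assert res.cumulative_share == 0.0
        assert len(res.assignments) == 0

    def test_simulated_top40_is_dominated_by_favored_groups(
        self, noiseless_efficiencies
    ):
        """With the default efficiency groups the top 40 of a deep profile is
        dominated by UNNG/CNNG/GNNA and carries roughly half the reads."""
        batch = simulate_reaction(
            uniform_counts(10_000), noiseless_efficiencies,
            SplintModel(conc_scale=0.0), 5.0, 2_000_000, seed=12,
        )
        prof = normalize_counts(
            batch.class_counts("P1"),
            alpha_factors(input_frequencies(uniform_counts())),
        )
        res = classify_top_k(prof, ("UNNG", "CNNG", "GNNA"), 40)
        classified = 40 - res.pattern_counts["other"]
        assert classified >= 30
        assert 0.3 < res.cumulative_share < 0.7
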