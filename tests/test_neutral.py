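"""Neutral model: 96/32 profiles, recalibration, sampling, profile recovery."""

import numpy as np
import pytest

from ribosnitch.annotation import (
    MappedMutation,
    MutationRecord,
    classify_substitution,
    context_class_of,
)
from ribosnitch.folding import FoldConfig
from ribosnitch.neutral import (
    MutationProfile96,
    NeutralModelError,
    TriComposition32,
    build_profile,
    expected_ribo_count,
    recalibrate,
    sample_mutations,
    simulate,
    transcript_composition,
)
from ribosnitch.structure_diff import scores_to_frame


def _intronic(tri, ref, alt):
    c96, c32 = classify_substitution(tri, ref, alt)
    rec = MutationRecord("chr1", 1, "A", "G", "s")  # genomic detail irrelevant
    return MappedMutation(rec, "T1", None, ref, alt, tri, "intron", c96, c32)


class TestComposition:
    def test_hand_classified_acag(self):
        comp = transcript_composition("ACAG")
        # ACA -> center C flanks A,A -> class 0; CAG center A -> rc CTG ->
        # center T flanks C,G
        expect = np.zeros(32, int)
        expect[0] += 1
        expect[16 + 1 * 4 + 2] += 1
        np.testing.assert_array_equal(comp.count, expect)

    def test_polya_collapses_to_ttt(self):
        comp = transcript_composition("A" * 10)
        assert comp.count.sum() == 8
        assert comp.count[16 + 3 * 4 + 3] == 8  # TTT class

    def test_counts_sum_to_length_minus_two(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=57))
        assert transcript_composition(seq).count.sum() == 55

    def test_n_containing_windows_skipped(self):
        assert transcript_composition("ANAA").count.sum() == 0  # both 3-mers hit N

    def test_short_sequence_raises(self):
        with pytest.raises(NeutralModelError):
            transcript_composition("AC")

    def test_position_restriction(self):
        full = transcript_composition("ACGTACGT")
        sub = transcript_composition("ACGTACGT", positions=[1, 2])
        assert sub.count.sum() == 2 <= full.count.sum()


class TestBuildProfile:
    def test_single_mutation_concentrates_rate(self):
        prof = build_profile([_intronic("ACA", "C", "T")], np.ones(32),
                             normalization="frequency")
        assert prof.rate.sum() == pytest.approx(1.0)
        assert prof.rate[2 * 16] == 1.0

    def test_frequency_mode_scale_invariant(self):
        muts = [_intronic("ACA", "C", "T"), _intronic("TCG", "C", "A")]
        one = build_profile(muts, np.ones(32), "frequency")
        two = build_profile(muts * 2, np.ones(32), "frequency")
        np.testing.assert_allclose(one.rate, two.rate)

    def test_per_context_rate_divides_by_context_count(self):
        ctx = np.ones(32)
        ctx[0] = 4.0  # ACA context seen 4x
        prof = build_profile([_intronic("ACA", "C", "T")], ctx,
                             normalization="per_context_rate")
        assert prof.rate[2 * 16] == pytest.approx(0.25)

    def test_zero_context_with_observed_mutation_raises(self):
        ctx = np.ones(32)
        ctx[0] = 0.0
        with pytest.raises(NeutralModelError, match="context"):
            build_profile([_intronic("ACA", "C", "T")], ctx,
                          normalization="per_context_rate")

    def test_frequency_profile_must_sum_to_one(self):
        with pytest.raises(NeutralModelError):
            MutationProfile96(np.ones(96), "frequency")


class TestRecalibrate:
    def test_flat_composition_returns_profile_shape(self):
        rate = np.arange(1, 97, dtype=float)
        prof = MutationProfile96(rate / rate.sum(), "frequency")
        dist = recalibrate(prof, TriComposition32(np.ones(32, int)))
        np.testing.assert_allclose(dist, prof.rate / prof.rate.sum())

    def test_degenerate_composition_restricts_support(self):
        prof = MutationProfile96(np.full(96, 1 / 96), "frequency")
        comp = np.zeros(32, int)
        comp[0] = 5  # only ACA present
        dist = recalibrate(prof, TriComposition32(comp))
        support = {c for c in range(96) if dist[c] > 0}
        assert support == {c for c in range(96) if context_class_of(c) == 0}
        assert dist.sum() == pytest.approx(1.0)

    def test_two_context_hand_example(self):
        rate = np.zeros(96)
        rate[0] = 0.3   # class with context 0
        rate[16] = 0.7  # C>G same flanks -> also context 0? no: 16 -> si=1
        # choose classes in distinct contexts
        rate = np.zeros(96)
        rate[0] = 0.3           # (C>A, A_A) context 0
        rate[1] = 0.7           # (C>A, A_C) context 1
        prof = MutationProfile96(rate / rate.sum(), "frequency")
        comp = np.zeros(32, int)
        comp[0], comp[1] = 2, 1
        dist = recalibrate(prof, TriComposition32(comp))
        assert dist[0] == pytest.approx(0.3 * 2 / (0.3 * 2 + 0.7 * 1))
        assert dist[1] == pytest.approx(0.7 * 1 / (0.3 * 2 + 0.7 * 1))

    def test_incompatible_transcript_raises(self):
        rate = np.zeros(96)
        rate[0] = 1.0
        prof = MutationProfile96(rate, "frequency")
        comp = np.zeros(32, int)
        comp[31] = 3
        with pytest.raises(NeutralModelError, match="incompatible"):
            recalibrate(prof, TriComposition32(comp))


class TestSampling:
    def test_single_class_single_site(self, rng):
        seq = "AACAA"  # position 2 is C in ACA context
        dist = np.zeros(96)
        dist[2 * 16] = 1.0  # A[C>T]A
        draws = sample_mutations(seq, dist, 5, rng)
        assert all(d == (2, "C", "T", 32) for d in draws)

    def test_class_frequencies_match_distribution(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=400))
        comp = transcript_composition(seq)
        prof = MutationProfile96(np.full(96, 1 / 96), "frequency")
        dist = recalibrate(prof, comp)
        n = 100_000
        draws = sample_mutations(seq, dist, n, rng)
        counts = np.bincount([d[3] for d in draws], minlength=96)
        # 4-sigma multinomial bound per class (max |z| over 96 classes
        # is ~3.2 in expectation, so 3 sigma would flag ordinary noise)
        sd = np.sqrt(n * dist * (1 - dist))
        assert np.all(np.abs(counts - n * dist) <= 4 * sd + 3)

    def test_profile_recovery_from_samples(self, rng):
        """Frequencies rebuilt from 1e5 draws recover the generator (TV < 0.02)."""
        seq = "".join(rng.choice(list("ACGT"), size=600))
        comp = transcript_composition(seq)
        target = rng.random(96) + 0.05
        prof = MutationProfile96(target / target.sum(), "frequency")
        dist = recalibrate(prof, comp)
        draws = sample_mutations(seq, dist, 100_000, rng)
        mapped = []
        for (k, ref, alt, c96) in draws:
            tri = seq[k - 1:k + 2]
            rec = MutationRecord("chr1", k + 1, "A", "G", "s")
            c96b, c32b = classify_substitution(tri, ref, alt)
            assert c96b == c96  # sampler and classifier agree
            mapped.append(MappedMutation(rec, "T", None, ref, alt, tri,
                                         "intron", c96b, c32b))
        rebuilt = build_profile(mapped, comp.count, "frequency")
        tv = 0.5 * np.abs(rebuilt.rate - dist).sum()
        assert tv < 0.02

    def test_ref_always_matches_sequence(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=100))
        dist = recalibrate(MutationProfile96(np.full(96, 1 / 96), "frequency"),
                           transcript_composition(seq))
        for (k, ref, alt, c96) in sample_mutations(seq, dist, 500, rng):
            assert seq[k] == ref and ref != alt

    def test_impossible_class_errors_after_retries(self, rng):
        seq = "AACAA"
        dist = np.zeros(96)
        dist[3 * 16] = 1.0  # T-centered class, no matching site
        with pytest.raises(NeutralModelError, match="no matching site"):
            sample_mutations(seq, dist, 1, rng, max_retries=5)


class TestSimulate:
    CFG = FoldConfig(max_span_L=30)

    def _setup(self, rng, n=60):
        seq = "".join(rng.choice(list("ACGT"), size=n))
        dist = recalibrate(MutationProfile96(np.full(96, 1 / 96), "frequency"),
                           transcript_composition(seq))
        return seq, dist

    def test_fixed_seed_reproducible(self, rng):
        seq, dist = self._setup(rng)
        a = simulate("T1", seq, dist, R=10, seed=42, fold_config=self.CFG, w=10)
        b = simulate("T1", seq, dist, R=10, seed=42, fold_config=self.CFG, w=10)
        assert [(s.k, s.mean_diff, s.euc_diff) for s in a] == \
            [(s.k, s.mean_diff, s.euc_diff) for s in b]

    def test_origin_marked_simulated(self, rng):
        seq, dist = self._setup(rng)
        scores = simulate("T1", seq, dist, R=5, seed=1, fold_config=self.CFG, w=10)
        assert all(s.origin == "simulated" for s in scores)

    def test_expected_ribo_pooled_fraction_bounded(self, rng):
        seq, dist = self._setup(rng, n=80)
        scores = simulate("T1", seq, dist, R=120, seed=3,
                          fold_config=self.CFG, w=10)
        df = scores_to_frame(scores)
        cutoffs, labels, per, rand = expected_ribo_count(df, 0.025, 0.025)
        assert rand[0].expected_total == 120 and rand[0].transcript_id == "T1"
        assert per.loc[0, "expected_total"] == 120
        # intersection of two 2.5% tails can never exceed one tail
        assert per.loc[0, "expected_ribo"] <= np.ceil(0.025 * 120) + 1

    def test_r_must_be_positive(self, rng):
        seq, dist = self._setup(rng)
        with pytest.raises(NeutralModelError):
            simulate("T1", seq, dist, R=0, seed=1)
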