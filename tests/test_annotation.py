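"""Annotation: isoform selection, splicing arithmetic, mutation mapping,
trinucleotide classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ribosnitch import annotation as ann
from ribosnitch.annotation import (
    MutationRecord,
    Transcript,
    classify_substitution,
    context_class_of,
    extract_mature_sequence,
    filter_blacklist,
    map_mutation,
    select_principal_transcript,
)


def _t(tid="T1", gene="G1", strand="+", exons=((0, 10),), **kw):
    defaults = dict(gene_name="GENE", biotype="lncRNA", chrom="chr1")
    defaults.update(kw)
    return Transcript(transcript_id=tid, gene_id=gene, strand=strand,
                      exons=list(exons), **defaults)


class TestPrincipalSelection:
    def test_lower_appris_rank_wins(self):
        a = _t("A", appris_rank=1)
        b = _t("B", appris_rank=2)
        assert select_principal_transcript([b, a]).transcript_id == "A"

    def test_single_transcript_is_identity(self):
        a = _t("A")
        assert select_principal_transcript([a]) is a

    def test_longest_wins_when_other_keys_tie(self):
        short = _t("S", exons=[(0, 900)])
        long = _t("L", exons=[(0, 1200)])
        assert select_principal_transcript([short, long]).transcript_id == "L"

    def test_priority_cascade(self):
        # appris > ccds > level > length
        best = _t("A", appris_rank=2, has_ccds=False)
        ccds = _t("B", appris_rank=None, has_ccds=True, transcript_level=1,
                  exons=[(0, 5000)])
        assert select_principal_transcript([ccds, best]).transcript_id == "A"
        lvl1 = _t("C", has_ccds=True, transcript_level=1)
        lvl2 = _t("D", has_ccds=True, transcript_level=2, exons=[(0, 5000)])
        assert select_principal_transcript([lvl2, lvl1]).transcript_id == "C"

    def test_missing_appris_ranks_after_present(self):
        ranked = _t("A", appris_rank=5)
        unranked = _t("B", appris_rank=None, has_ccds=True)
        assert select_principal_transcript([unranked, ranked]).transcript_id == "A"

    def test_selection_is_permutation_invariant(self):
        ts = [
            _t("A", appris_rank=2, transcript_level=1),
            _t("B", appris_rank=2, transcript_level=2),
            _t("C", appris_rank=None, has_ccds=True),
            _t("D", appris_rank=2, transcript_level=1, exons=[(0, 11)]),
        ]
        picks = {
            select_principal_transcript(list(p)).transcript_id
            for p in itertools.permutations(ts)
        }
        assert len(picks) == 1

    def test_empty_list_raises(self):
        with pytest.raises(ann.AnnotationError, match="no transcripts"):
            select_principal_transcript([])

    def test_mixed_genes_raise(self):
        with pytest.raises(ann.AnnotationError):
            select_principal_transcript([_t("A", gene="G1"), _t("B", gene="G2")])


class TestMatureSequence:
    def test_plus_strand_single_exon(self, toy_genome):
        t = _t(exons=[(0, 4)])
        assert extract_mature_sequence(t, toy_genome) == "ACGT"

    def test_minus_strand_reverse_complements(self):
        t = _t(strand="-", exons=[(0, 4)])
        assert extract_mature_sequence(t, {"chr1": "AAGTGG"}) == "ACTT"

    def test_two_exons_spliced(self):
        t = _t(exons=[(0, 3), (5, 8)])
        assert extract_mature_sequence(t, {"chr1": "ACGTTGGA"}) == "ACGGGA"

    def test_exon_outside_chromosome_raises(self):
        t = _t(exons=[(0, 99)])
        with pytest.raises(ann.AnnotationError):
            extract_mature_sequence(t, {"chr1": "ACGT"})

    def test_non_acgtn_base_raises(self):
        t = _t(exons=[(0, 4)])
        with pytest.raises(ann.AnnotationError):
            extract_mature_sequence(t, {"chr1": "ACXT"})


class TestTranscriptInvariants:
    def test_overlapping_exons_rejected(self):
        with pytest.raises(ann.AnnotationError):
            _t(exons=[(0, 10), (5, 20)])

    def test_mature_length_is_exon_sum(self):
        t = _t(exons=[(0, 10), (20, 25)])
        assert t.mature_length == 15

    def test_region_outside_mature_rejected(self):
        with pytest.raises(ann.AnnotationError):
            _t(exons=[(0, 10)], biotype="protein_coding",
               regions={"CDS": [(0, 11)]})


class TestBlacklistFilter:
    def _m(self, pos):
        return MutationRecord("chr1", pos, "A", "G", "s1")

    def test_contained_position_removed(self):
        assert filter_blacklist([self._m(100)], [("chr1", 99, 101)]) == []

    def test_half_open_boundary(self):
        # pos 100 is 0-based 99, not in [100, 200)
        kept = filter_blacklist([self._m(100)], [("chr1", 100, 200)])
        assert len(kept) == 1
        # but 0-based 100 (pos 101) is
        assert filter_blacklist([self._m(101)], [("chr1", 100, 200)]) == []

    def test_empty_blacklist_is_identity(self):
        muts = [self._m(1), self._m(2)]
        assert filter_blacklist(muts, []) == muts

    def test_order_preserved(self):
        muts = [self._m(5), self._m(3), self._m(9)]
        kept = filter_blacklist(muts, [("chr1", 2, 3)])  # removes pos 3 only
        assert [m.pos for m in kept] == [5, 9]


class TestMapMutation:
    def test_plus_strand_exonic_coordinate(self, toy_genome):
        t = _t(exons=[(0, 10)])
        rec = MutationRecord("chr1", 3, "G", "A", "s")
        m = map_mutation(rec, t, toy_genome)
        assert m.k == 2 and m.ref_t == "G" and m.alt_t == "A"

    def test_reference_mismatch_raises(self, toy_genome):
        t = _t(exons=[(0, 10)])
        rec = MutationRecord("chr1", 3, "C", "A", "s")
        with pytest.raises(ann.ReferenceMismatchError, match="reference mismatch"):
            map_mutation(rec, t, toy_genome)

    def test_intronic_mutation_has_no_k(self, toy_genome):
        t = _t(exons=[(0, 4), (8, 12)])
        rec = MutationRecord("chr1", 6, "G", "T", "s")
        m = map_mutation(rec, t, toy_genome)
        assert m.region == "intron" and m.k is None

    def test_outside_span_returns_none(self, toy_genome):
        t = _t(exons=[(0, 4)])
        rec = MutationRecord("chr1", 20, "T", "A", "s")
        assert map_mutation(rec, t, toy_genome) is None

    def test_other_chromosome_returns_none(self, toy_genome):
        t = _t(exons=[(0, 4)])
        rec = MutationRecord("chr2", 2, "A", "C", "s")
        assert map_mutation(rec, t, toy_genome) is None

    @given(st.integers(0, 199), st.data())
    @settings(max_examples=60, deadline=None)
    def test_mapping_round_trip_reproduces_ref(self, seed, data):
        """Transcript base at k always equals the strand-corrected ref."""
        rng = np.random.default_rng(seed)
        chrom_seq = "".join(rng.choice(list("ACGT"), size=60))
        genome = {"chr1": chrom_seq}
        strand = data.draw(st.sampled_from("+-"))
        t = _t(strand=strand, exons=[(5, 20), (30, 50)])
        g = data.draw(st.sampled_from(
            [g for s, e in t.exons for g in range(s, e)]))
        ref = chrom_seq[g]
        alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref]))
        m = map_mutation(MutationRecord("chr1", g + 1, ref, alt, "s"), t, genome)
        mature = extract_mature_sequence(t, genome)
        assert mature[m.k] == m.ref_t
        if strand == "-":
            assert m.ref_t == ann.complement(ref)

    def test_minus_strand_reflection(self):
        # single-exon minus transcript of length L: genomic offset o -> L-1-o
        genome = {"chr1": "AAGTGGCCTT"}
        t = _t(strand="-", exons=[(0, 10)])
        for o in range(10):
            ref = genome["chr1"][o]
            alt = "A" if ref != "A" else "C"
            m = map_mutation(MutationRecord("chr1", o + 1, ref, alt, "s"), t, genome)
            assert m.k == 10 - 1 - o


class TestSubstitutionClassifier:
    def test_pyrimidine_center_direct(self):
        c96, c32 = classify_substitution("ACA", "C", "T")
        # C>T is type index 2; flanks A,A
        assert c96 == 2 * 16 + 0 and c32 == 0

    def test_strand_collapse_equivalence(self):
        assert classify_substitution("TGT", "G", "A") == \
            classify_substitution("ACA", "C", "T")

    @given(st.sampled_from("ACGT"), st.sampled_from("ACGT"),
           st.sampled_from("ACGT"), st.data())
    @settings(max_examples=100, deadline=None)
    def test_collapse_is_involution_consistent(self, f5, center, f3, data):
        alt = data.draw(st.sampled_from([b for b in "ACGT" if b != center]))
        tri = f5 + center + f3
        rc_tri = ann.reverse_complement(tri)
        assert classify_substitution(tri, center, alt) == classify_substitution(
            rc_tri, ann.complement(center), ann.complement(alt))

    def test_enumeration_yields_96_and_32_classes(self):
        c96s, c32s = set(), set()
        for f5 in "ACGT":
            for center in "ACGT":
                for f3 in "ACGT":
                    for alt in "ACGT":
                        if alt == center:
                            continue
                        c96, c32 = classify_substitution(f5 + center + f3,
                                                         center, alt)
                        c96s.add(c96)
                        c32s.add(c32)
        assert c96s == set(range(96))
        assert c32s == set(range(32))

    def test_n_in_context_excluded_not_fatal(self):
        assert classify_substitution("NCA", "C", "T") is None

    def test_context_class_consistency(self):
        for c96 in range(96):
            assert 0 <= context_class_of(c96) < 32

    def test_identity_substitution_raises(self):
        with pytest.raises(ann.AnnotationError):
            classify_substitution("ACA", "C", "C")


class TestReaders:
    def test_gtf_round_trip(self, fixture_dir):
        genes = ann.load_annotation(fixture_dir["gtf"])
        assert len(genes) == fixture_dir["spec"].n_genes
        for ts in genes.values():
            for t in ts:
                assert t.mature_length == sum(e - s for s, e in t.exons)

    def test_multi_isoform_gene_has_distinct_priorities(self, fixture_dir):
        genes = ann.load_annotation(fixture_dir["gtf"])
        multi = [ts for ts in genes.values() if len(ts) >= 3]
        assert multi, "fixture should contain a >=3-isoform gene"
        keys = {(t.appris_rank, t.has_ccds, t.transcript_level)
                for t in multi[0]}
        assert len(keys) == len(multi[0])

    def test_protein_coding_regions_partition_mature(self, fixture_dir):
        genes = ann.load_annotation(fixture_dir["gtf"])
        coding = [t for ts in genes.values() for t in ts
                  if t.biotype == "protein_coding" and t.regions]
        assert coding
        for t in coding:
            covered = sorted(
                (s, e) for ivals in t.regions.values() for s, e in ivals)
            assert covered[0][0] == 0
            assert covered[-1][1] == t.mature_length
            for (_, e0), (s1, _) in zip(covered, covered[1:]):
                assert e0 == s1

    def test_tsv_mutations_parse_and_validate(self, fixture_dir):
        muts = ann.read_mutations(fixture_dir["somatic"], cohort="somatic")
        assert muts and all(m.ref != m.alt for m in muts)

    def test_vcf_reader_splits_multiallelic(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=SAMPLE,Number=1,Type=String,Description="x">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t5\t.\tA\tG,T\t.\t.\tSAMPLE=s1\n"
            "chr1\t7\t.\tAT\tA\t.\t.\tSAMPLE=s1\n"  # indel: dropped
        )
        muts = ann.read_mutations(vcf)
        assert [(m.pos, m.alt) for m in muts] == [(5, "G"), (5, "T")]
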