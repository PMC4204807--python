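import warnings
from collections import defaultdict

import pytest

import mosaicfam as mf
from mosaicfam.mosaic import CONSENSUS_NAME, alpha_name, greek_name


class TestNaming:
    @pytest.mark.parametrize(
        "i,name", [(0, "A"), (25, "Z"), (26, "AA"), (28, "AC"), (27, "AB")]
    )
    def test_alphabetic_names(self, i, name):
        assert alpha_name(i) == name

    def test_greek_names(self):
        assert [greek_name(i) for i in range(4)] == ["α", "β", "γ", "δ"]

    def test_names_are_unique(self):
        names = [alpha_name(i) for i in range(200)]
        assert len(set(names)) == 200


class TestSegmentation:
    def test_shared_gap_block_gives_three_elements(self, toy_alignment):
        emap = mf.segment_alignment(toy_alignment)
        assert [(e.start, e.end) for e in emap.elements] == [
            (0, 20), (20, 38), (38, 60)
        ]

    def test_ungapped_alignment_single_element(self):
        aln = mf.MsAlignment(
            [mf.SequenceRecord(f"s{i}", "ACGT" * 10, "dna") for i in range(3)]
        )
        emap = mf.segment_alignment(aln)
        assert emap.n_elements == 1
        assert (emap[0].start, emap[0].end) == (0, 40)

    def test_all_gap_column_dropped_with_warning(self):
        rows = ["ACGTA-CGTACGTACGTAC", "ACGTA-CGTACGTACGTAC"]
        aln = mf.MsAlignment(
            [mf.SequenceRecord(f"s{i}", r, "dna") for i, r in enumerate(rows)]
        )
        with pytest.warns(UserWarning, match="all-gap"):
            emap = mf.segment_alignment(aln)
        assert emap.retained_columns is not None
        assert emap.ncols == 18

    def test_tiling_invariant(self, default_family):
        emap = mf.segment_alignment(default_family.alignment)
        total = sum(e.end - e.start for e in emap.elements)
        assert total == default_family.alignment.ncols
        assert emap[0].start == 0
        for a, b in zip(emap.elements, emap.elements[1:]):
            assert a.end == b.start

    def test_min_element_len_respected(self, default_family):
        emap = mf.segment_alignment(default_family.alignment)
        assert all(len(e) >= 15 for e in emap.elements)

    def test_determinism(self, default_family):
        e1 = mf.segment_alignment(default_family.alignment)
        e2 = mf.segment_alignment(default_family.alignment)
        assert [(e.element_id, e.start, e.end) for e in e1] == [
            (e.element_id, e.start, e.end) for e in e2
        ]

    def test_leader_annotation(self, default_family):
        emap = mf.segment_alignment(default_family.alignment, leader_len=63)
        assert emap[0].element_id == "L"
        assert (emap[0].start, emap[0].end) == (0, 63)


class TestPatterns:
    def test_consensus_emitted_first(self, toy_alignment):
        emap = mf.segment_alignment(toy_alignment)
        pats = mf.assign_patterns(toy_alignment, emap)
        assert pats[0].pattern_name == CONSENSUS_NAME
        assert all(pats[0].presence)

    def test_presence_vector_for_gapped_element(self, toy_alignment):
        emap = mf.segment_alignment(toy_alignment)
        pats = {p.seq_id: p for p in mf.assign_patterns(toy_alignment, emap)}
        assert pats["t1"].presence == (True, True, True)
        assert pats["t3"].presence == (True, False, True)

    def test_identical_vectors_share_names(self, toy_alignment):
        emap = mf.segment_alignment(toy_alignment)
        pats = mf.assign_patterns(toy_alignment, emap)
        assert pats[1].pattern_name == pats[2].pattern_name == "A"
        assert pats[3].pattern_name == pats[4].pattern_name == "B"

    def test_reconstruction_invariant(self, default_family):
        """Concatenating residues over present elements and dropping gaps
        reproduces each ungapped sequence."""
        aln = default_family.alignment
        emap = mf.segment_alignment(aln)
        pats = {p.seq_id: p for p in mf.assign_patterns(aln, emap)}
        for rec in aln:
            pieces = []
            for e, present in zip(emap.elements, pats[rec.id].presence):
                pieces.append(rec.seq[e.start : e.end])
            rebuilt = "".join(pieces).replace("-", "")
            assert rebuilt == rec.ungapped()


class TestIntrons:
    def test_requires_splice_coordinates(self, gene_family):
        with pytest.raises(ValueError, match="splice"):
            mf.segment_introns(gene_family.gene_alignment, None)

    def test_ungapped_intron_single_alpha_pattern(self):
        rows = ["ACGT" * 10] * 3
        aln = mf.MsAlignment(
            [mf.SequenceRecord(f"s{i}", r, "dna") for i, r in enumerate(rows)]
        )
        emap, pats = mf.segment_introns(aln, (0, 40))
        assert emap.n_elements == 1 and emap[0].element_id == "i1"
        assert {p.pattern_name for p in pats} == {CONSENSUS_NAME, "α"}

    def test_recovers_intron_patterns_from_truth(self, gene_family):
        emap, pats = mf.segment_introns(
            gene_family.gene_alignment, gene_family.intron_span
        )
        assert all(e.element_id.startswith("i") for e in emap.elements)
        truth_by = {
            t.seq_id: t.intron_pattern_index for t in gene_family.truth.per_seq
        }
        groups = defaultdict(set)
        for p in pats:
            if p.seq_id == CONSENSUS_NAME:
                continue
            groups[truth_by[p.seq_id]].add(p.pattern_name)
        # recovered patterns partition the sequences exactly like the truth
        assert all(len(v) == 1 for v in groups.values())
        assert len({frozenset(v) for v in groups.values()}) == len(groups)


class TestGenePatterns:
    def test_cross_product_toy(self):
        ep = [
            mf.ElementPattern("a", (True,), "A"),
            mf.ElementPattern("b", (True,), "A"),
            mf.ElementPattern("c", (True,), "B"),
            mf.ElementPattern("d", (True,), "B"),
        ]
        ip = [
            mf.ElementPattern("a", (True,), "α"),
            mf.ElementPattern("b", (True,), "β"),
            mf.ElementPattern("c", (True,), "α"),
            mf.ElementPattern("d", (True,), "β"),
        ]
        gps = mf.combine_gene_patterns(ep, ip)
        assert {g.combined_name for g in gps} == {"A-α", "A-β", "B-α", "B-β"}

    def test_id_mismatch_errors(self):
        ep = [mf.ElementPattern("a", (True,), "A")]
        ip = [mf.ElementPattern("b", (True,), "α")]
        with pytest.raises(ValueError, match="unmatched.*'a'"):
            mf.combine_gene_patterns(ep, ip)

    def test_compound_recovery_matches_truth(self, gene_family):
        fam = gene_family
        exon_map = mf.segment_alignment(fam.alignment)
        epats = mf.assign_patterns(fam.alignment, exon_map)
        imap, ipats = mf.segment_introns(fam.gene_alignment, fam.intron_span)
        gps = mf.combine_gene_patterns(epats, ipats)
        truth = {
            (t.pattern_index, t.intron_pattern_index)
            for t in fam.truth.per_seq
        }
        assert len({g.combined_name for g in gps}) == len(truth)
        tally = mf.gene_pattern_tally(gps)
        assert tally["n_sequences"].sum() == len(fam.truth.per_seq)


class TestNamingProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(i=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_alpha_name_is_injective_and_ordered(self, i):
        a, b = alpha_name(i), alpha_name(i + 1)
        assert a != b
        # Excel ordering: shorter names sort before longer ones
        assert (len(a), a) < (len(b), b)
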