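"""Block I/O and alignment-hygiene filters."""

import numpy as np
import pytest

from oriscan.blocks import (
    AlignedBlock,
    AnnotationTable,
    BlockFormatError,
    BlockRow,
    Gene,
    GAP,
    codon_consistency_filter,
    gap_fraction_trim,
    read_blocks,
    select_universal_blocks,
    split_into_segments,
    trim_to_codons,
    write_xmfa,
)

TWO_BLOCK_XMFA = """\
> a:1-8 + chr
ACGTAC-T
> b:11-18 + chr
ACGTACGT
> c:21-28 + chr
AC--ACGT
=
> a:101-104 + chr
ACGT
> b:111-114 - chr
ACGT
=
"""


class TestReadBlocks:
    def test_parses_blocks_and_position_maps(self, tmp_path):
        path = tmp_path / "aln.xmfa"
        path.write_text(TWO_BLOCK_XMFA)
        blocks = read_blocks(path)
        assert len(blocks) == 2
        b1, b2 = blocks
        assert b1.taxa == ["a", "b", "c"]
        # gaps are the sentinel; ungapped positions ascend from start
        assert list(b1.position_maps["a"]) == [1, 2, 3, 4, 5, 6, GAP, 7]
        assert list(b1.position_maps["c"]) == [21, 22, GAP, GAP, 23, 24, 25, 26]

    def test_reverse_strand_map_descends(self, tmp_path):
        path = tmp_path / "aln.xmfa"
        path.write_text(TWO_BLOCK_XMFA)
        b2 = read_blocks(path)[1]
        assert list(b2.position_maps["b"]) == [114, 113, 112, 111]

    def test_coordinates_beyond_replicon_rejected(self, tmp_path):
        path = tmp_path / "aln.xmfa"
        path.write_text(TWO_BLOCK_XMFA)
        with pytest.raises(BlockFormatError):
            read_blocks(path, replicon_lengths={"b": 100})

    def test_ragged_rows_rejected(self):
        with pytest.raises(BlockFormatError):
            AlignedBlock(id="bad", rows=[BlockRow("a", "ACGT", 1), BlockRow("b", "ACG", 1)])

    def test_round_trip_through_xmfa(self, tmp_path):
        path = tmp_path / "aln.xmfa"
        path.write_text(TWO_BLOCK_XMFA)
        blocks = read_blocks(path)
        out = tmp_path / "out.xmfa"
        write_xmfa(blocks, out)
        again = read_blocks(out)
        for b, b2 in zip(blocks, again):
            assert [r.seq for r in b.rows] == [r.seq for r in b2.rows]
            for t in b.taxa:
                assert list(b.position_maps[t]) == list(b2.position_maps[t])

    def test_position_map_round_trip(self, tmp_path):
        path = tmp_path / "aln.xmfa"
        path.write_text(TWO_BLOCK_XMFA)
        b = read_blocks(path)[0]
        for t in b.taxa:
            pm = b.position_maps[t]
            for col, pos in enumerate(pm):
                if pos != GAP:
                    assert b.column_of(t, int(pos)) == col


class TestSelectUniversal:
    def _blocks(self):
        def mk(bid, taxa):
            return AlignedBlock(id=bid, rows=[BlockRow(t, "ACGT", 1) for t in taxa])

        return [mk("b1", "abc"), mk("b2", "ab"), mk("b3", "abc")]

    def test_keeps_only_fully_shared_blocks(self):
        kept = select_universal_blocks(self._blocks(), ["a", "b", "c"])
        assert [b.id for b in kept] == ["b1", "b3"]

    def test_single_required_taxon(self):
        assert len(select_universal_blocks(self._blocks(), ["a"])) == 3

    def test_unmatchable_requirement_warns_empty(self):
        assert select_universal_blocks(self._blocks(), list("abcd")) == []


class TestGapFractionTrim:
    def test_gapped_column_removed(self):
        rows = [BlockRow(t, s, 1) for t, s in zip("abcd", ["A-GT", "A-GT", "ACGT", "ACGT"])]
        trimmed = gap_fraction_trim(AlignedBlock(id="x", rows=rows), 0.2)
        assert trimmed.rows[0].seq == "AGT"

    def test_gap_free_block_unchanged(self):
        rows = [BlockRow(t, "ACGT", 1) for t in "ab"]
        b = AlignedBlock(id="x", rows=rows)
        assert gap_fraction_trim(b).rows[0].seq == "ACGT"

    def test_all_gap_column_always_removed(self):
        rows = [BlockRow(t, "A-T", 1) for t in "ab"]
        assert gap_fraction_trim(AlignedBlock(id="x", rows=rows), 0.99).rows[0].seq == "AT"


def _simple_annotations(n_taxa=3, start=1, end=300, strand="+"):
    return AnnotationTable(
        {t: [Gene("g1", start, end, strand)] for t in ["a", "b", "c"][:n_taxa]}
    )


class TestCodonConsistency:
    def test_agreeing_columns_kept_disagreeing_removed(self):
        # taxa a,b start the gene at 1; taxon c's copy starts at 2 -> frames disagree
        rows = [BlockRow("a", "ACGTAA", 1), BlockRow("b", "ACGTAA", 1), BlockRow("c", "ACGTAA", 2)]
        block = AlignedBlock(id="x", rows=rows)
        ann = AnnotationTable(
            {
                "a": [Gene("g1", 1, 300, "+")],
                "b": [Gene("g1", 1, 300, "+")],
                "c": [Gene("g1", 2, 301, "+")],
            }
        )
        assert codon_consistency_filter(block, ann) == list(range(6))
        ann_shifted = AnnotationTable(
            {
                "a": [Gene("g1", 1, 300, "+")],
                "b": [Gene("g1", 1, 300, "+")],
                "c": [Gene("g1", 1, 300, "+")],
            }
        )
        # now c's bases sit one codon position off at every column
        assert codon_consistency_filter(block, ann_shifted) == []

    def test_intergenic_column_removed(self):
        rows = [BlockRow(t, "ACG", 1) for t in "ab"]
        block = AlignedBlock(id="x", rows=rows)
        ann = AnnotationTable({"a": [Gene("g1", 1, 3, "+")], "b": [Gene("g1", 2, 4, "+")]})
        # column 0 is intergenic in b (gene starts at 2)
        assert 0 not in codon_consistency_filter(block, ann)

    def test_missing_annotation_is_an_error(self):
        rows = [BlockRow(t, "ACG", 1) for t in "ab"]
        block = AlignedBlock(id="x", rows=rows)
        with pytest.raises(KeyError):
            codon_consistency_filter(block, AnnotationTable({"a": [Gene("g1", 1, 3, "+")]}))

    def test_filters_invariant_under_row_order(self):
        rows = [BlockRow("a", "ACGTAA", 1), BlockRow("b", "ACGTAA", 1), BlockRow("c", "ACGTAA", 1)]
        ann = _simple_annotations()
        fwd = codon_consistency_filter(AlignedBlock(id="x", rows=rows), ann)
        rev = codon_consistency_filter(AlignedBlock(id="x", rows=rows[::-1]), ann)
        assert fwd == rev


def _gene_block(seq_len=250, gap_cols=(), n_taxa=3, min_len=100):
    """A block covering one forward gene of seq_len bp starting at position 1."""
    rng = np.random.default_rng(1)
    bases = rng.choice(list("ACGT"), size=seq_len)
    taxa = ["a", "b", "c"][:n_taxa]
    rows = []
    for t in taxa:
        seq = bases.copy()
        rows.append(BlockRow(t, "".join(seq), 1))
    block = AlignedBlock(id="x", rows=rows)
    if gap_cols:
        for r in block.rows[:1]:  # gap in one taxon severs the column for all
            s = list(r.seq)
            for c in gap_cols:
                s[c] = "N"
            r.taxon  # keep
            block.rows[0] = BlockRow(r.taxon, "".join(s), r.start, r.strand)
        block._maps = None
    ann = AnnotationTable({t: [Gene("g1", 1, seq_len + (3 - seq_len % 3) % 3, "+")] for t in taxa})
    return block, ann


class TestSplitIntoSegments:
    def test_interior_break_keeps_both_long_halves(self):
        block, ann = _gene_block(250, gap_cols=(119,))
        segs = split_into_segments(block, ann)
        assert sorted(s.length for s in segs) == [119, 130]

    def test_short_fragment_discarded(self):
        block, ann = _gene_block(250, gap_cols=(59,))
        segs = split_into_segments(block, ann)
        assert [s.length for s in segs] == [190]

    def test_gene_below_minimum_yields_nothing(self):
        block, ann = _gene_block(99)
        assert split_into_segments(block, ann) == []

    def test_no_gaps_full_gene_survives(self):
        block, ann = _gene_block(240)
        segs = split_into_segments(block, ann)
        assert len(segs) == 1 and segs[0].length == 240
        # genomic position round-trip
        assert list(segs[0].position_maps["a"]) == list(range(1, 241))


class TestTrimToCodons:
    def _segment(self, labels):
        n = len(labels)
        return split_codon_stub(labels)

    def test_trims_to_first_complete_codon(self):
        seg = split_codon_stub([2, 3, 1, 2, 3, 1, 2, 3])
        trimmed = trim_to_codons(seg)
        assert list(trimmed.codon_pos) == [1, 2, 3, 1, 2, 3]
        assert trimmed.length % 3 == 0

    def test_already_codon_complete_unchanged(self):
        seg = split_codon_stub([1, 2, 3])
        assert list(trim_to_codons(seg).codon_pos) == [1, 2, 3]

    def test_no_complete_codon_gives_none(self):
        assert trim_to_codons(split_codon_stub([2, 3])) is None


def split_codon_stub(labels):
    from oriscan.blocks import GeneSegment

    n = len(labels)
    seq = ("ACGTGA" * n)[:n]
    return GeneSegment(
        id="stub.seg1",
        seqs={"a": seq, "b": seq},
        position_maps={t: np.arange(1, n + 1) for t in "ab"},
        strands={"a": "+", "b": "+"},
        codon_pos=np.array(labels, dtype=np.int8),
    )
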