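"""Annotation parsing, promoter-window coordinates, deduplication."""

from __future__ import annotations

import pytest

from coordx.genome_io import (
    GeneModel,
    GenePredError,
    dedupe_by_symbol,
    extract_promoter_window,
    read_fasta,
    read_genepred,
    reverse_complement,
    structural_lengths,
    write_fasta,
    write_genepred,
)


def _gene(**kw) -> GeneModel:
    base = dict(
        accession="NM_X", symbol="X", chrom="chr1", strand="+",
        tx_start=100, tx_end=1100, cds_start=200, cds_end=1000,
        exon_count=1, exon_starts=(100,), exon_ends=(1100,),
    )
    base.update(kw)
    return GeneModel(**base)


class TestGeneModel:
    def test_gene_length_is_span_difference(self):
        assert _gene().gene_length == 1000

    def test_inverted_transcript_rejected(self):
        with pytest.raises(GenePredError, match="inverted"):
            _gene(tx_start=1100, tx_end=100, cds_start=1100, cds_end=1100,
                  exon_starts=(1100,), exon_ends=(100,))

    def test_exon_count_mismatch_rejected(self):
        with pytest.raises(GenePredError, match="exonCount"):
            _gene(exon_count=2)

    def test_cds_outside_exons_rejected(self):
        with pytest.raises(GenePredError, match="exon union"):
            _gene(exon_count=2, exon_starts=(100, 600), exon_ends=(400, 1100),
                  cds_start=450, cds_end=1000)

    def test_spliced_cds_length_sums_exonic_overlap(self):
        g = _gene(exon_count=2, exon_starts=(100, 600), exon_ends=(400, 1100),
                  cds_start=200, cds_end=1000)
        assert g.cds_length == (400 - 200) + (1000 - 600)

    def test_structural_lengths_passthrough(self, three_genes):
        out = structural_lengths(three_genes[0])
        assert out == {"gene_length": 5000, "exon_count": 3}


class TestGenePredIO:
    def test_round_trip_is_byte_identical(self, three_genes, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_genepred(three_genes, p1)
        genes, errors = read_genepred(p1)
        assert errors == []
        assert genes == three_genes
        write_genepred(genes, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_malformed_lines_reported_with_line_number(self, three_genes, tmp_path):
        p = tmp_path / "a.tsv"
        write_genepred(three_genes, p)
        lines = p.read_text().splitlines()
        lines.insert(2, "BAD\tNM_BAD\tchr1\t+\t500\t100\t100\t100\t1\t100,\t500,")
        lines.append("short\tline")
        p.write_text("\n".join(lines) + "\n")
        genes, errors = read_genepred(p)
        assert len(genes) == 3
        assert {e.line_number for e in errors} == {3, 6}
        assert any("inverted" in e.message for e in errors)

    def test_header_required(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("X\tNM_X\tchr1\t+\t0\t10\t0\t10\t1\t0,\t10,\n")
        with pytest.raises(GenePredError, match="header"):
            read_genepred(p)


class TestPromoterWindow:
    def test_plus_strand_slice_matches_offset_enumeration(self):
        # genome where base at index i encodes i mod 4, so the slice is checkable
        contig = "".join("ACGT"[i % 4] for i in range(2000))
        g = _gene(tx_start=1000, tx_end=1900, cds_start=1000, cds_end=1900,
                  exon_starts=(1000,), exon_ends=(1900,))
        w = extract_promoter_window(g, {"chr1": contig})
        # oracle: bases at TSS-40 .. TSS-15 inclusive, 5'->3'
        expected = "".join(contig[1000 - k] for k in range(40, 14, -1))
        assert w == expected
        assert len(w) == 26
        assert w == contig[960:986]

    def test_minus_strand_is_reverse_complement_of_mirror_slice(self):
        contig = "".join("ACGT"[i % 4] for i in range(3000))
        g = _gene(strand="-", tx_start=1100, tx_end=2000, cds_start=1100,
                  cds_end=2000, exon_starts=(1100,), exon_ends=(2000,))
        w = extract_promoter_window(g, {"chr1": contig})
        expected = reverse_complement(contig[2014:2040])
        assert w == expected
        # oracle mirrored: position -k is tx_end-1+k on the genome
        oracle = "".join(
            reverse_complement(contig[1999 + k]) for k in range(40, 14, -1)
        )
        assert w == oracle

    def test_window_off_contig_start_excluded_with_warning(self):
        g = _gene(tx_start=10, tx_end=900, cds_start=10, cds_end=900,
                  exon_starts=(10,), exon_ends=(900,))
        with pytest.warns(UserWarning, match="outside contig"):
            assert extract_promoter_window(g, {"chr1": "A" * 1000}) is None

    def test_strand_symmetry_on_palindromic_genome(self):
        # a reverse-complement-palindromic contig: both strands read the same
        half = "".join("ACGT"[i % 4] for i in range(500))
        contig = half + reverse_complement(half)
        plus = _gene(tx_start=500, tx_end=900, cds_start=500, cds_end=900,
                     exon_starts=(500,), exon_ends=(900,))
        minus = _gene(strand="-", tx_start=100, tx_end=500, cds_start=100,
                      cds_end=500, exon_starts=(100,), exon_ends=(500,))
        w_plus = extract_promoter_window(plus, {"chr1": contig})
        w_minus = extract_promoter_window(minus, {"chr1": contig})
        assert w_plus == w_minus


class TestDedupe:
    def test_longest_cds_kept(self):
        a = _gene(accession="NM_A", cds_start=200, cds_end=1100)  # CDS 900
        b = _gene(accession="NM_B", tx_end=1400, cds_start=200, cds_end=1400,
                  exon_ends=(1400,))  # CDS 1200
        assert dedupe_by_symbol([a, b]) == [b]
        assert dedupe_by_symbol([b, a]) == [b]

    def test_tie_broken_by_smaller_accession(self):
        a = _gene(accession="NM_B")
        b = _gene(accession="NM_A")
        assert dedupe_by_symbol([a, b])[0].accession == "NM_A"
        assert dedupe_by_symbol([b, a])[0].accession == "NM_A"

    def test_unique_symbols_pass_through_in_order(self, three_genes):
        assert dedupe_by_symbol(three_genes) == three_genes

    def test_idempotent_and_order_independent(self, three_genes):
        dup = three_genes + [
            _gene(accession="NM_010", symbol="ALPHA", tx_start=1000, tx_end=2000,
                  cds_start=1000, cds_end=2000, exon_starts=(1000,), exon_ends=(2000,))
        ]
        once = dedupe_by_symbol(dup)
        assert dedupe_by_symbol(once) == once
        reversed_set = {g.accession for g in dedupe_by_symbol(dup[::-1])}
        assert reversed_set == {g.accession for g in once}


class TestFasta:
    def test_round_trip_uppercases(self, tmp_path):
        p = tmp_path / "x.fa"
        write_fasta({"g1": "ACGTACGT" * 20, "g2": "", "g3": "NNNACGT"}, p)
        back = read_fasta(p)
        assert back["g1"] == "ACGTACGT" * 20
        assert back["g2"] == ""
        assert back["g3"] == "NNNACGT"
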