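"""Gene-model invariants, strand-aware coordinate conversion, GTF loading."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from m1ascan.reference_io import (
    GeneModel,
    GenomePosition,
    Genome,
    fetch_context,
    load_gene_models,
)


class TestSingleExonSegmentation:
    def test_plus_strand_spans(self, single_exon_plus):
        m = single_exon_plus
        assert m.transcript_length == 300
        assert m.utr5_span == (0, 50)
        assert m.cds_span == (50, 250)
        assert m.utr3_span == (250, 300)

    def test_minus_strand_utr5_maps_to_high_coordinates(self, single_exon_minus):
        # offset 0..49 (5'UTR) corresponds to genomic 399 down to 350
        g = single_exon_minus.transcript_to_genomic(0)
        assert g.pos == 399
        assert single_exon_minus.transcript_to_genomic(49).pos == 350

    def test_first_transcribed_base_offset_zero(self, single_exon_plus, single_exon_minus):
        assert (
            single_exon_plus.genomic_to_transcript(GenomePosition("chr1", 100, "+"))
            == 0
        )
        assert (
            single_exon_minus.genomic_to_transcript(GenomePosition("chr1", 399, "-"))
            == 0
        )

    def test_intronic_and_outside_positions_unmapped(self, single_exon_plus):
        assert single_exon_plus.genomic_to_transcript(
            GenomePosition("chr1", 99, "+")
        ) is None
        assert single_exon_plus.genomic_to_transcript(
            GenomePosition("chr1", 400, "+")
        ) is None


class TestTwoExonModel:
    def test_cds_split_across_junction(self):
        # exons [0,100) + [200,300); CDS genomic [50,100)+[200,250)
        # hand computation: transcript offsets 50..150 => cds length 100
        m = GeneModel(
            "g2", "chr1", "+", [(0, 100), (200, 300)],
            cds_span=(50, 150), utr5_span=(0, 50), utr3_span=(150, 200),
        )
        assert m.cds_span[1] - m.cds_span[0] == 100
        # junction: offset 99 is genomic 99, offset 100 is genomic 200
        assert m.transcript_to_genomic(99).pos == 99
        assert m.transcript_to_genomic(100).pos == 200
        # intron position unmapped
        assert m.genomic_to_transcript(GenomePosition("chr1", 150, "+")) is None

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            GeneModel("bad", "chr1", "+", [(10, 10)], (0, 0), (0, 0), (0, 0))
        with pytest.raises(ValueError):
            GeneModel(
                "bad", "chr1", "+", [(0, 100)],
                cds_span=(40, 90), utr5_span=(0, 30), utr3_span=(90, 100),
            )  # gap between utr5 end and cds start


@st.composite
def gene_models(draw):
    strand = draw(st.sampled_from("+-"))
    n_exons = draw(st.integers(1, 3))
    lengths = [draw(st.integers(10, 120)) for _ in range(n_exons)]
    gaps = [draw(st.integers(5, 60)) for _ in range(n_exons)]
    start = draw(st.integers(0, 500))
    exons = []
    cursor = start
    for L, gap in zip(lengths, gaps):
        exons.append((cursor, cursor + L))
        cursor += L + gap
    if strand == "-":
        exons = exons[::-1]
    total = sum(L for L in lengths)
    a = draw(st.integers(0, total))
    b = draw(st.integers(a, total))
    return GeneModel(
        "g", "chr1", strand, exons,
        cds_span=(a, b), utr5_span=(0, a), utr3_span=(b, total),
    )


class TestCoordinateRoundTrip:
    @settings(max_examples=200, deadline=None)
    @given(gene_models(), st.data())
    def test_roundtrip_identity(self, model, data):
        off = data.draw(st.integers(0, model.transcript_length - 1))
        g = model.transcript_to_genomic(off)
        assert model.genomic_to_transcript(g) == off

    @settings(max_examples=100, deadline=None)
    @given(gene_models())
    def test_minus_strand_monotonicity(self, model):
        gpos = [model.transcript_to_genomic(o).pos
                for o in range(model.transcript_length)]
        diffs = np.diff(gpos)
        if model.strand == "-":
            # increasing offset strictly decreases genomic coordinate
            assert (diffs < 0).all() or len(gpos) == 1
        # spans partition the transcript
        regions = [model.region_of(o) for o in range(model.transcript_length)]
        if model.is_coding:
            assert all(r is not None for r in regions)


class TestFetchContext:
    def _setup(self):
        seq = "TTTTGCATTTT"  # gene exon [2,9): transcript "TTGCATT" on +
        genome = Genome({"chr1": seq})
        m = GeneModel("g", "chr1", "+", [(2, 9)], (0, 0), (0, 0), (0, 0))
        return genome, m

    def test_plus_strand_upstream_window(self):
        genome, m = self._setup()
        # site at offset 4 (base 'A'), upstream 3 => 'TGC' + 'A'
        ctx, truncated = fetch_context(genome, m, 4, 3, 0)
        assert ctx == "TGCA"
        assert not truncated

    def test_minus_strand_reverse_complement(self):
        seq = "TTTTGCATTTT"
        genome = Genome({"chr1": seq})
        m = GeneModel("g", "chr1", "-", [(2, 9)], (0, 0), (0, 0), (0, 0))
        # transcript = revcomp("TTGCATT") = "AATGCAA"
        ctx, truncated = fetch_context(genome, m, 3, 2, 2)
        assert ctx == "ATGCA"

    def test_truncation_at_transcript_end(self):
        genome, m = self._setup()
        ctx, truncated = fetch_context(genome, m, 1, 3, 0)
        assert truncated
        assert ctx == "TTG"[: len(ctx)]  # only 1 upstream base available
        assert len(ctx) == 2


class TestGtfLoading:
    def test_load_models_from_files(self, tmp_path):
        fasta = tmp_path / "g.fa"
        gtf = tmp_path / "a.gtf"
        fasta.write_text(">chr1\n" + "ACGT" * 150 + "\n")
        attrs = 'gene_id "gX"; transcript_id "gX.t1";'
        gtf.write_text(
            "\n".join(
                [
                    f"chr1\tt\ttranscript\t101\t400\t.\t+\t.\t{attrs}",
                    f"chr1\tt\texon\t101\t400\t.\t+\t.\t{attrs}",
                    f"chr1\tt\tCDS\t151\t350\t.\t+\t0\t{attrs}",
                ]
            )
            + "\n"
        )
        genome = Genome(fasta)
        models = load_gene_models(gtf, genome)
        m = models["gX"]
        assert m.utr5_span == (0, 50)
        assert m.cds_span == (50, 250)
        assert m.utr3_span == (250, 300)

    def test_malformed_and_unknown_chrom_rejected(self, tmp_path, caplog):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chr1\n" + "A" * 100 + "\n")
        attrs1 = 'gene_id "bad1"; transcript_id "bad1.t";'
        attrs2 = 'gene_id "bad2"; transcript_id "bad2.t";'
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            "\n".join(
                [
                    f"chr1\tt\ttranscript\t50\t10\t.\t+\t.\t{attrs1}",
                    f"chr1\tt\texon\t50\t10\t.\t+\t.\t{attrs1}",
                    f"chr9\tt\ttranscript\t1\t50\t.\t+\t.\t{attrs2}",
                    f"chr9\tt\texon\t1\t50\t.\t+\t.\t{attrs2}",
                ]
            )
            + "\n"
        )
        models = load_gene_models(gtf, Genome(fasta))
        assert models == {}

    def test_cds_only_gene_is_coding_without_utrs(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chr1\n" + "ACGT" * 50 + "\n")
        attrs = 'gene_id "gC"; transcript_id "gC.t";'
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            "\n".join(
                [
                    f"chr1\tt\ttranscript\t1\t90\t.\t+\t.\t{attrs}",
                    f"chr1\tt\texon\t1\t90\t.\t+\t.\t{attrs}",
                    f"chr1\tt\tCDS\t1\t90\t.\t+\t0\t{attrs}",
                ]
            )
            + "\n"
        )
        m = load_gene_models(gtf, Genome(fasta))["gC"]
        assert m.is_coding
        assert m.utr5_span == (0, 0) and m.utr3_span == (90, 90)
        assert m.region_of(0) == "CDS"
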