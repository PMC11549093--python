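"""Genome and gene-model access with strand-aware coordinate conversion.

Gene models are collapsed to one representative transcript per gene (the
longest annotated one) and segmented into 5'UTR / CDS / 3'UTR spans in
transcript coordinates.  All internal coordinates are 0-based half-open;
GTF input is converted from its native 1-based inclusive convention on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

REGION_5UTR = "5UTR"
REGION_CDS = "CDS"
REGION_3UTR = "3UTR"
REGIONS = (REGION_5UTR, REGION_CDS, REGION_3UTR)


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomePosition:
    """A 0-based genomic position with the strand of the transcript it serves."""

    chrom: str
    pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative genomic position {self.pos}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class GeneModel:
    """One representative transcript of a gene.

    ``exons`` are genomic half-open intervals sorted 5'->3' in transcript
    orientation (descending genomic start for minus-strand genes).  The three
    region spans are half-open intervals in transcript coordinates that
    partition ``[0, transcript_length)``; any span may be empty.  A gene with
    no CDS annotation has an empty ``cds_span`` and ``is_coding`` False.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_span: tuple[int, int]
    utr5_span: tuple[int, int]
    utr3_span: tuple[int, int]
    transcript_length: int = field(default=0)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: malformed exon [{s},{e})")
        total = sum(e - s for s, e in self.exons)
        if self.transcript_length == 0:
            self.transcript_length = total
        elif self.transcript_length != total:
            raise ValueError(
                f"{self.gene_id}: transcript_length {self.transcript_length} "
                f"!= summed exon length {total}"
            )
        self._check_partition()

    def _check_partition(self) -> None:
        spans = [self.utr5_span, self.cds_span, self.utr3_span]
        cursor = 0
        for span in spans:
            s, e = span
            if e < s:
                raise ValueError(f"{self.gene_id}: inverted span {span}")
            if s != e:  # empty spans may carry any anchor; skip
                if s != cursor:
                    raise ValueError(
                        f"{self.gene_id}: spans do not tile the transcript "
                        f"(expected start {cursor}, got {s})"
                    )
                cursor = e
        if cursor not in (0, self.transcript_length):
            raise ValueError(
                f"{self.gene_id}: spans end at {cursor}, "
                f"transcript length {self.transcript_length}"
            )

    # -- coordinate conversion ------------------------------------------------

    @property
    def is_coding(self) -> bool:
        return self.cds_span[1] > self.cds_span[0]

    def genomic_to_transcript(self, g: GenomePosition) -> int | None:
        """Map a genomic position to a transcript offset, or None if intronic
        or outside the gene (or on the wrong chromosome)."""
        if g.chrom != self.chrom:
            return None
        offset = 0
        for s, e in self.exons:
            if s <= g.pos < e:
                if self.strand == "+":
                    return offset + (g.pos - s)
                return offset + (e - 1 - g.pos)
            offset += e - s
        return None

    def transcript_to_genomic(self, offset: int) -> GenomePosition:
        if not 0 <= offset < self.transcript_length:
            raise ValueError(
                f"{self.gene_id}: offset {offset} outside "
                f"[0,{self.transcript_length})"
            )
        cursor = offset
        for s, e in self.exons:
            length = e - s
            if cursor < length:
                pos = s + cursor if self.strand == "+" else e - 1 - cursor
                return GenomePosition(self.chrom, pos, self.strand)
            cursor -= length
        raise AssertionError("unreachable")  # pragma: no cover

    def region_of(self, offset: int) -> str | None:
        """Region label of a transcript offset; None for non-coding models."""
        if not self.is_coding:
            return None
        for name, (s, e) in zip(
            REGIONS, (self.utr5_span, self.cds_span, self.utr3_span)
        ):
            if s <= offset < e:
                return name
        return None

    def genomic_exon_positions(self) -> Iterable[int]:
        """All genomic positions covered by exons, in transcript order."""
        for s, e in self.exons:
            rng = range(s, e) if self.strand == "+" else range(e - 1, s - 1, -1)
            yield from rng


class Genome:
    """Thin FASTA wrapper giving spliced, strand-corrected transcript sequence."""

    def __init__(self, fasta: str | Path | Mapping[str, str]):
        if isinstance(fasta, Mapping):
            self._seqs = {k: str(v).upper() for k, v in fasta.items()}
            self._fasta = None
        else:
            self._fasta = Fasta(str(fasta), as_raw=True, sequence_always_upper=True)
            self._seqs = None

    def contig_length(self, chrom: str) -> int:
        if self._seqs is not None:
            return len(self._seqs[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice of the plus strand."""
        if self._seqs is not None:
            return self._seqs[chrom][start:end]
        return str(self._fasta[chrom][start:end])

    def base(self, g: GenomePosition) -> str:
        """Transcript-strand base at a position."""
        b = self.fetch(g.chrom, g.pos, g.pos + 1)
        return b if g.strand == "+" else b.translate(COMPLEMENT)

    def transcript_sequence(self, model: GeneModel) -> str:
        parts = []
        for s, e in model.exons:
            chunk = self.fetch(model.chrom, s, e)
            parts.append(chunk if model.strand == "+" else reverse_complement(chunk))
        return "".join(parts)


def fetch_context(
    genome: Genome,
    model: GeneModel,
    offset: int,
    upstream: int,
    downstream: int,
) -> tuple[str, bool]:
    """Transcript-orientation sequence window around a site.

    Returns ``(sequence, truncated)`` where the sequence covers
    ``[offset-upstream, offset+downstream]`` on the spliced transcript,
    truncated (never padded) at transcript ends.
    """
    tx = genome.transcript_sequence(model)
    lo = offset - upstream
    hi = offset + downstream + 1
    truncated = lo < 0 or hi > len(tx)
    return tx[max(lo, 0) : min(hi, len(tx))], truncated


# -- GTF loading ---------------------------------------------------------------


def load_gene_models(
    annotation_source: str | Path,
    genome: Genome | None = None,
) -> dict[str, GeneModel]:
    """Load gene models from GTF/GFF, one representative (longest) transcript
    per gene.

    Records with malformed intervals, or on chromosomes absent from ``genome``
    (when a genome is supplied), are rejected with a logged warning.  Genes
    without CDS features are kept as non-coding models (empty spans) and are
    excluded from region statistics downstream.
    """
    db = gffutils.create_db(
        str(annotation_source),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_gene: dict[str, GeneModel] = {}
    per_gene_len: dict[str, int] = {}
    for tx in db.features_of_type(("transcript", "mRNA")):
        gene_id = tx.attributes.get("gene_id", [tx.id])[0]
        try:
            model = _build_model(db, tx, gene_id, genome)
        except ValueError as exc:
            logger.warning("rejecting %s: %s", tx.id, exc)
            continue
        if model is None:
            continue
        if (
            gene_id not in per_gene
            or model.transcript_length > per_gene_len[gene_id]
        ):
            per_gene[gene_id] = model
            per_gene_len[gene_id] = model.transcript_length
    return per_gene


def _build_model(db, tx, gene_id: str, genome: Genome | None) -> GeneModel | None:
    exons = []
    for ex in db.children(tx, featuretype="exon", order_by="start"):
        start, end = ex.start - 1, ex.end  # GTF 1-based inclusive -> half-open
        if end <= start:
            raise ValueError(f"malformed exon interval ({ex.start},{ex.end})")
        exons.append((start, end))
    if not exons:
        return None
    if genome is not None:
        try:
            clen = genome.contig_length(tx.seqid)
        except KeyError:
            raise ValueError(f"unknown chromosome {tx.seqid}")
        if exons[-1][1] > clen:
            raise ValueError(f"exon beyond contig end of {tx.seqid}")
    strand = tx.strand if tx.strand in "+-" else "+"
    if strand == "-":
        exons = exons[::-1]  # transcript orientation

    cds = [
        (c.start - 1, c.end)
        for c in db.children(tx, featuretype="CDS", order_by="start")
    ]
    tlen = sum(e - s for s, e in exons)
    if not cds:
        empty = (0, 0)
        return GeneModel(gene_id, tx.seqid, strand, exons, empty, empty, empty, tlen)

    # CDS bounds in transcript coordinates: map the genomic extremes.
    gmin = min(s for s, _ in cds)
    gmax = max(e for _, e in cds) - 1
    probe = GeneModel(
        gene_id, tx.seqid, strand, exons, (0, 0), (0, 0), (0, 0), tlen
    )
    o1 = probe.genomic_to_transcript(GenomePosition(tx.seqid, gmin, strand))
    o2 = probe.genomic_to_transcript(GenomePosition(tx.seqid, gmax, strand))
    if o1 is None or o2 is None:
        raise ValueError("CDS bounds fall outside annotated exons")
    cds_lo, cds_hi = min(o1, o2), max(o1, o2) + 1
    return GeneModel(
        gene_id,
        tx.seqid,
        strand,
        exons,
        cds_span=(cds_lo, cds_hi),
        utr5_span=(0, cds_lo),
        utr3_span=(cds_hi, tlen),
        transcript_length=tlen,
    )


def validate(genome: Genome, models: Mapping[str, GeneModel]) -> dict[str, int]:
    """Cross-check models against the genome; returns summary counts."""
    n_coding = sum(m.is_coding for m in models.values())
    for m in models.values():
        genome.contig_length(m.chrom)  # raises KeyError on unknown contig
    return {
        "n_genes": len(models),
        "n_coding": n_coding,
        "n_noncoding": len(models) - n_coding,
    }
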