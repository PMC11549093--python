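"""Pileup ingestion: decode per-base text pileups into strand-aware adenosine
observations restricted to annotated exons.

Two input dialects are supported: samtools-mpileup text (chrom, 1-based pos,
ref base, depth, read-base string, qualities) and a pre-tabulated 6-column TSV
(chrom, pos1, ref_base, sample, coverage, mismatches).  A mismatch is any
non-reference base call; indel runs, read start/end marks and deletion
placeholders are consumed per the mpileup grammar and never counted as
mismatches.  'N' calls are ambiguous and excluded from both coverage and
mismatch counts.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .reference_io import GeneModel, Genome

logger = logging.getLogger(__name__)

TSV_COLUMNS = ["chrom", "pos1", "ref_base", "sample", "coverage", "mismatches"]


class PileupFormatError(ValueError):
    pass


def decode_read_bases(bases: str) -> tuple[int, int]:
    """Decode one mpileup read-base string into (coverage, mismatches).

    '.'/',' are matches; ACGT (either case) are mismatches; '^' consumes the
    following mapping-quality character; '$' is an end mark; '+N'/'-N' start
    an indel run of N bases which is skipped; '*' (deletion spanning the site)
    and 'N'/'n' reduce coverage rather than counting as calls.

    Raises :class:`PileupFormatError` on a dangling '^' or malformed indel
    length.
    """
    i = 0
    n = len(bases)
    coverage = 0
    mismatches = 0
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupFormatError("dangling '^' at end of base string")
            i += 2
        elif c == "$":
            i += 1
        elif c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupFormatError(f"indel without length at column {i}")
            run = int(bases[i + 1 : j])
            if j + run > n:
                raise PileupFormatError("indel run exceeds base string")
            i = j + run
        elif c in ".,":
            coverage += 1
            i += 1
        elif c in "ACGTacgt":
            coverage += 1
            mismatches += 1
            i += 1
        elif c in "*Nn><":
            i += 1  # deletion span / ambiguous / refskip: not a base call
        else:
            raise PileupFormatError(f"unexpected character {c!r} at column {i}")
    return coverage, mismatches


def parse_mpileup(
    stream: IO[str] | str | Path, sample: str
) -> pd.DataFrame:
    """Parse samtools-mpileup text for one sample into the standard table.

    Malformed lines are rejected with a logged warning; the depth column of
    the input is ignored and recomputed from the decoded base string.
    """
    close = False
    if isinstance(stream, (str, Path)):
        stream = open(stream)
        close = True
    rows = []
    try:
        for lineno, line in enumerate(stream, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                logger.warning("line %d: too few columns, skipped", lineno)
                continue
            chrom, pos1, ref = fields[0], fields[1], fields[2].upper()
            try:
                cov, mm = decode_read_bases(fields[4])
            except PileupFormatError as exc:
                logger.warning("line %d rejected: %s", lineno, exc)
                continue
            rows.append((chrom, int(pos1), ref, sample, cov, mm))
    finally:
        if close:
            stream.close()
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def parse_pileup_tsv(path: str | Path | IO[str]) -> pd.DataFrame:
    """Read the 6-column TSV dialect (all samples in one file)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TSV_COLUMNS) - set(df.columns)
    if missing:
        raise PileupFormatError(f"pileup TSV missing columns: {sorted(missing)}")
    bad = df["mismatches"] > df["coverage"]
    if bad.any():
        logger.warning("%d rows with mismatches > coverage rejected", bad.sum())
        df = df[~bad]
    return df[TSV_COLUMNS].copy()


def parse_pileup(
    sources: Mapping[str, str | Path] | str | Path, dialect: str = "auto"
) -> pd.DataFrame:
    """Load pileups: either one TSV path, or a {sample: mpileup path} map."""
    if isinstance(sources, (str, Path)):
        return parse_pileup_tsv(sources)
    frames = [parse_mpileup(path, sample) for sample, path in sources.items()]
    return pd.concat(frames, ignore_index=True)


def exonic_adenosine_table(
    models: Mapping[str, GeneModel], genome: Genome
) -> pd.DataFrame:
    """All exonic positions whose transcript-strand base is A.

    Columns: chrom, pos (0-based), gene_id, offset, strand.  Positions shared
    by overlapping genes appear once per gene.
    """
    rows = []
    for m in models.values():
        tx = genome.transcript_sequence(m)
        arr = np.frombuffer(tx.encode(), dtype="u1")
        offs = np.nonzero(arr == ord("A"))[0]
        gpos = np.fromiter(
            (m.transcript_to_genomic(int(o)).pos for o in offs),
            dtype=np.int64,
            count=len(offs),
        )
        rows.append(
            pd.DataFrame(
                {
                    "chrom": m.chrom,
                    "pos": gpos,
                    "gene_id": m.gene_id,
                    "offset": offs,
                    "strand": m.strand,
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos", "gene_id", "offset", "strand"])
    return pd.concat(rows, ignore_index=True)


def extract_adenosine_observations(
    table: pd.DataFrame,
    models: Mapping[str, GeneModel],
    genome: Genome,
) -> pd.DataFrame:
    """Restrict a decoded pileup table to exonic transcript-strand adenosines.

    Keeps positions that fall in an exon of a gene model and whose
    transcript-strand base is A (reference A under plus-strand genes,
    reference T under minus-strand genes).  Returns one observation per
    (gene, position, sample) with columns: gene_id, chrom, pos, offset,
    strand, sample, coverage, mismatches, mismatch_rate.
    """
    ade = exonic_adenosine_table(models, genome)
    df = table.copy()
    df["pos"] = df["pos1"] - 1
    merged = df.merge(ade, on=["chrom", "pos"], how="inner")
    # transcript-strand A check against the declared reference base
    keep = ((merged["strand"] == "+") & (merged["ref_base"] == "A")) | (
        (merged["strand"] == "-") & (merged["ref_base"] == "T")
    )
    merged = merged[keep].copy()
    cov = merged["coverage"].to_numpy(dtype=float)
    merged["mismatch_rate"] = np.divide(
        merged["mismatches"],
        cov,
        out=np.zeros(len(merged)),
        where=cov > 0,
    )
    cols = [
        "gene_id",
        "chrom",
        "pos",
        "offset",
        "strand",
        "sample",
        "coverage",
        "mismatches",
        "mismatch_rate",
    ]
    return merged[cols].sort_values(["gene_id", "offset", "sample"]).reset_index(
        drop=True
    )
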