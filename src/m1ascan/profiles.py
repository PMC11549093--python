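"""Site annotation: transcript regions, metagene profile, sequence context
and per-gene sequence features.

The metagene axis rescales each transcript region (5'UTR, CDS, 3'UTR) to a
segment whose width is proportional to the average annotated length of that
region over all coding models, so a site's coordinate is its fractional
position within its region mapped onto the shared axis.  Motif summaries
report the upstream 3-mer (positions -3..-1, and the alternative -2..0 window
that includes the site) and a column-stochastic position frequency matrix
over a window around the site.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from typing import Mapping, Protocol

import numpy as np
import pandas as pd

from .reference_io import (
    REGION_3UTR,
    REGION_5UTR,
    REGION_CDS,
    REGIONS,
    GeneModel,
    Genome,
    fetch_context,
)

UNPARTITIONED = "unpartitioned"


# -- region assignment ---------------------------------------------------------


def assign_regions(
    sites: pd.DataFrame, models: Mapping[str, GeneModel]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label each site 5UTR/CDS/3UTR from its transcript offset.

    Sites in non-coding models are labeled 'unpartitioned' and excluded from
    the percentage table (counted separately).  Returns ``(sites_with_region,
    percentages)`` where percentages has columns region/count/percent and the
    percents over the three regions sum to 100.
    """
    labels = []
    for row in sites.itertuples(index=False):
        m = models.get(row.gene_id)
        label = m.region_of(int(row.offset)) if m is not None else None
        labels.append(label if label is not None else UNPARTITIONED)
    out = sites.copy()
    out["region"] = labels
    coding = out[out["region"] != UNPARTITIONED]
    counts = coding["region"].value_counts().reindex(REGIONS, fill_value=0)
    total = counts.sum()
    pct = pd.DataFrame(
        {
            "region": counts.index,
            "count": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / total if total else 0.0,
        }
    )
    n_unpart = int((out["region"] == UNPARTITIONED).sum())
    pct.attrs["n_unpartitioned"] = n_unpart
    return out, pct


# -- metagene ------------------------------------------------------------------


@dataclass
class MetageneProfile:
    """Unit-area site density over the length-normalized transcript axis."""

    bin_edges: np.ndarray  # on [0, 1]
    density: np.ndarray
    boundaries: tuple[float, float]  # 5'UTR/CDS and CDS/3'UTR junctions
    segment_widths: tuple[float, float, float]

    def area(self) -> float:
        return float(np.sum(self.density * np.diff(self.bin_edges)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "density": self.density,
            }
        )


def metagene(
    sites: pd.DataFrame,
    models: Mapping[str, GeneModel],
    bins_per_region: int = 30,
) -> MetageneProfile:
    """Average-length-normalized metagene profile of labeled sites.

    Segment widths are proportional to the mean 5'UTR/CDS/3'UTR lengths over
    all coding models; an empty region class yields a zero-width segment.
    The histogram is normalized so the density integrates to exactly 1.
    """
    coding = [m for m in models.values() if m.is_coding]
    if not coding:
        raise ValueError("no coding models: metagene axis undefined")
    means = np.array(
        [
            np.mean([m.utr5_span[1] - m.utr5_span[0] for m in coding]),
            np.mean([m.cds_span[1] - m.cds_span[0] for m in coding]),
            np.mean([m.utr3_span[1] - m.utr3_span[0] for m in coding]),
        ],
        dtype=float,
    )
    if means.sum() == 0:
        raise ValueError("all region classes empty")
    widths = means / means.sum()
    seg_start = {
        REGION_5UTR: 0.0,
        REGION_CDS: widths[0],
        REGION_3UTR: widths[0] + widths[1],
    }
    seg_width = dict(zip(REGIONS, widths))

    labeled = sites[sites.get("region", pd.Series(dtype=object)).isin(REGIONS)]
    if labeled.empty:
        raise ValueError("metagene requires at least one labeled site")
    coords = []
    for row in labeled.itertuples(index=False):
        m = models[row.gene_id]
        spans = {
            REGION_5UTR: m.utr5_span,
            REGION_CDS: m.cds_span,
            REGION_3UTR: m.utr3_span,
        }
        lo, hi = spans[row.region]
        frac = (row.offset - lo) / (hi - lo)
        coords.append(seg_start[row.region] + frac * seg_width[row.region])

    edges = np.concatenate(
        [
            np.linspace(0.0, seg_start[REGION_CDS], bins_per_region, endpoint=False),
            np.linspace(
                seg_start[REGION_CDS],
                seg_start[REGION_3UTR],
                bins_per_region,
                endpoint=False,
            ),
            np.linspace(seg_start[REGION_3UTR], 1.0, bins_per_region + 1),
        ]
    )
    edges = np.unique(edges)  # zero-width segments collapse duplicate edges
    hist, _ = np.histogram(coords, bins=edges)
    bin_w = np.diff(edges)
    density = hist / (hist.sum() * bin_w)
    return MetageneProfile(
        bin_edges=edges,
        density=density,
        boundaries=(seg_start[REGION_CDS], seg_start[REGION_3UTR]),
        segment_widths=tuple(widths),
    )


# -- motif ---------------------------------------------------------------------


@dataclass
class MotifSummary:
    """Upstream 3-mer frequencies and a PFM around the site (RNA alphabet)."""

    trimer_upstream: pd.Series  # bases -3..-1
    trimer_with_site: pd.Series  # bases -2..0 (NNCA-style window)
    pfm: pd.DataFrame  # rows A/C/G/U, columns relative positions
    n_sites: int
    n_truncated: int


def motif_summary(
    sites: pd.DataFrame,
    models: Mapping[str, GeneModel],
    genome: Genome,
    window_up: int = 5,
    window_down: int = 5,
) -> MotifSummary:
    """Sequence-context summary of called sites in transcript orientation.

    Sites whose window is truncated by a transcript end are excluded from the
    PFM (and from whichever 3-mer lacks its bases) and counted in
    ``n_truncated``.
    """
    tx_cache: dict[str, str] = {}
    up3: list[str] = []
    with_site: list[str] = []
    windows: list[str] = []
    n_trunc = 0
    for row in sites.itertuples(index=False):
        m = models[row.gene_id]
        tx = tx_cache.setdefault(row.gene_id, genome.transcript_sequence(m))
        off = int(row.offset)
        if off - 3 >= 0:
            up3.append(tx[off - 3 : off])
        if off - 2 >= 0:
            with_site.append(tx[off - 2 : off + 1])
        lo, hi = off - window_up, off + window_down + 1
        if lo < 0 or hi > len(tx):
            n_trunc += 1
        else:
            windows.append(tx[lo:hi])

    def freq(kmers: list[str]) -> pd.Series:
        s = pd.Series(kmers, dtype=object).str.replace("T", "U")
        f = s.value_counts(normalize=True).sort_index() if len(s) else pd.Series(dtype=float)
        f.name = "frequency"
        return f

    positions = list(range(-window_up, window_down + 1))
    pfm = pd.DataFrame(0.0, index=list("ACGU"), columns=positions)
    if windows:
        arr = np.array([list(w.replace("T", "U")) for w in windows])
        for j, pos in enumerate(positions):
            col = pd.Series(arr[:, j]).value_counts(normalize=True)
            for b in "ACGU":
                pfm.loc[b, pos] = col.get(b, 0.0)
    return MotifSummary(
        trimer_upstream=freq(up3),
        trimer_with_site=freq(with_site),
        pfm=pfm,
        n_sites=len(sites),
        n_truncated=n_trunc,
    )


# -- folding providers ---------------------------------------------------------


class FoldingProvider(Protocol):
    def energy(self, sequence: str) -> float:
        """Minimum free energy (kcal/mol, negative) of an RNA sequence."""
        ...


class ToyStemFolding:
    """Deterministic toy folding score for tests: fold the sequence in half
    by pairing ends inward and charge -1 per G-C pair formed.

    Not thermodynamically meaningful; it exists so the feature pipeline is
    testable without an external folding engine.
    """

    def energy(self, sequence: str) -> float:
        s = sequence.upper().replace("U", "T")
        e = 0
        i, j = 0, len(s) - 1
        while i < j:
            if {s[i], s[j]} == {"G", "C"}:
                e -= 1
            i += 1
            j -= 1
        return float(e)


class ViennaRNAFolding:
    """Production provider shelling out to the RNAfold executable."""

    def __init__(self, binary: str = "RNAfold"):
        if shutil.which(binary) is None:
            raise RuntimeError(f"{binary} not found on PATH")
        self.binary = binary

    def energy(self, sequence: str) -> float:
        proc = subprocess.run(
            [self.binary, "--noPS"],
            input=sequence + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
        # last line: "((...)). (-12.30)"
        tail = proc.stdout.strip().splitlines()[-1]
        return float(tail.rsplit("(", 1)[1].rstrip(")").strip())


# -- per-gene sequence features ------------------------------------------------


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def sequence_features(
    models: Mapping[str, GeneModel],
    genome: Genome,
    sites: pd.DataFrame | None = None,
    neighborhood: int = 50,
    folding: FoldingProvider | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene 3'UTR features and per-site neighborhood GC.

    Per gene: 3'UTR length, 3'UTR GC fraction, and (when a folding provider
    is given) the 3'UTR folding energy normalized per nucleotide.  Genes
    without a 3'UTR get nulls.  Per site: GC fraction of the +-neighborhood
    window around the site (truncated at transcript ends).
    """
    gene_rows = []
    for gid, m in models.items():
        lo, hi = m.utr3_span
        if hi <= lo:
            gene_rows.append(
                {"gene_id": gid, "utr3_length": np.nan, "utr3_gc": np.nan,
                 "utr3_mfe_norm": np.nan}
            )
            continue
        utr3 = genome.transcript_sequence(m)[lo:hi]
        mfe = folding.energy(utr3) / len(utr3) if folding is not None else np.nan
        gene_rows.append(
            {
                "gene_id": gid,
                "utr3_length": hi - lo,
                "utr3_gc": gc_fraction(utr3),
                "utr3_mfe_norm": mfe,
            }
        )
    gene_df = pd.DataFrame(gene_rows)

    site_rows = []
    if sites is not None:
        for row in sites.itertuples(index=False):
            m = models[row.gene_id]
            ctx, truncated = fetch_context(
                genome, m, int(row.offset), neighborhood, neighborhood
            )
            site_rows.append(
                {
                    "gene_id": row.gene_id,
                    "offset": int(row.offset),
                    "neighborhood_gc": gc_fraction(ctx),
                    "truncated": truncated,
                }
            )
    site_df = pd.DataFrame(
        site_rows, columns=["gene_id", "offset", "neighborhood_gc", "truncated"]
    )
    return gene_df, site_df


def attach_context(
    sites: pd.DataFrame,
    models: Mapping[str, GeneModel],
    genome: Genome,
    upstream: int = 5,
    downstream: int = 5,
) -> pd.DataFrame:
    """Add the transcript-orientation sequence window around each site."""
    out = sites.copy()
    ctxs = []
    for row in sites.itertuples(index=False):
        ctx, _ = fetch_context(
            genome, models[row.gene_id], int(row.offset), upstream, downstream
        )
        ctxs.append(ctx)
    out["context"] = ctxs
    return out
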