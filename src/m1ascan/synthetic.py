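"""Ground-truthed synthetic inputs for the m1A analysis pipeline.

Generates a small genome with segmented gene models, IP/input misincorporation
pileups with planted m1A sites, MeRIP peak intervals with per-sample counts,
RNA-seq / Ribo-seq count tables for two growth conditions, and poly(A)-length
tables — all fully determined by one seed.

The defaults encode the biology the analysis is designed to detect: sites
placed 4.4% / 14.2% / 81.4% across 5'UTR / CDS / 3'UTR, a C at the -1
position of 80% of sites (the NNCA context), a 20% misincorporation rate in
IP libraries against 2% antibody-free carry-through in input and a 0.5%
background, and a multiplicative translation-efficiency penalty per site so
that transcripts with more sites translate less efficiently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .reference_io import GeneModel, Genome, reverse_complement

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines every output."""

    n_genes: int = 200
    seed: int = 0
    # gene architecture (nt)
    utr5_mean: int = 100
    cds_mean: int = 900
    utr3_mean: int = 400
    two_exon_fraction: float = 0.2
    intron_length: int = 80
    spacer_length: int = 60
    # methylation truth
    frac_methylated: float = 0.5
    mean_extra_sites: float = 1.0  # sites per methylated gene = 1 + Poisson(.)
    region_placement: tuple[float, float, float] = (0.044, 0.142, 0.814)
    p_c_minus1: float = 0.8
    # misincorporation pileup model
    ip_misincorporation: float = 0.2
    input_misincorporation: float = 0.02
    background_rate: float = 0.005
    mean_coverage: float = 100.0
    n_ip_replicates: int = 2
    n_input_replicates: int = 2
    adenosine_only: bool = True
    # expression / translation model
    te_effect: float = 0.6
    dispersion: float = 0.1
    mean_rna_count: float = 500.0
    abundance_boost_methylated: float = 1.5
    polyA_mean: float = 120.0
    polyA_sd: float = 25.0
    polyA_shift: float = -20.0
    # stress condition
    stress_te_factor: float = 0.7
    stress_extra_repression: float = 0.6
    # MeRIP peaks
    peak_width: int = 200
    peak_mean_count: float = 200.0
    peak_dispersion: float = 0.05
    peak_input_fraction: float = 0.25
    dmr_up_fraction: float = 0.1
    dmr_down_fraction: float = 0.2
    dmr_fold: float = 3.0

    def validate(self) -> None:
        probs = list(self.region_placement)
        if any(p < 0 or p > 1 for p in probs) or abs(sum(probs) - 1) > 1e-9:
            raise ValueError("region placement must be probabilities summing to 1")
        for name in (
            "p_c_minus1",
            "ip_misincorporation",
            "input_misincorporation",
            "background_rate",
            "frac_methylated",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0,1]")
        means = (self.utr5_mean, self.cds_mean, self.utr3_mean)
        for mean_len, p in zip(means, probs):
            if p > 0 and mean_len <= 0:
                raise ValueError(
                    "site placement requested in a region with zero length"
                )
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")


@dataclass
class SyntheticReference:
    """Genome + gene models + planted-site truth table."""

    config: SimulationConfig
    sequences: dict[str, str]
    models: dict[str, GeneModel]
    truth_sites: pd.DataFrame  # gene_id, offset, chrom, pos, strand, region,
    #                            ip_rate, input_rate
    truth_genes: pd.DataFrame  # gene_id, n_sites, regions, te_multiplier

    @property
    def genome(self) -> Genome:
        return Genome(self.sequences)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")

    def write_gtf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for m in self.models.values():
                exons_sorted = sorted(m.exons)
                g0, g1 = exons_sorted[0][0], exons_sorted[-1][1]
                attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.gene_id}.t1";'
                fh.write(
                    f"{m.chrom}\tsim\ttranscript\t{g0 + 1}\t{g1}\t.\t"
                    f"{m.strand}\t.\t{attrs}\n"
                )
                for s, e in exons_sorted:
                    fh.write(
                        f"{m.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t"
                        f"{m.strand}\t.\t{attrs}\n"
                    )
                if m.is_coding:
                    for s, e in self._cds_genomic_intervals(m):
                        fh.write(
                            f"{m.chrom}\tsim\tCDS\t{s + 1}\t{e}\t.\t"
                            f"{m.strand}\t0\t{attrs}\n"
                        )

    @staticmethod
    def _cds_genomic_intervals(m: GeneModel) -> list[tuple[int, int]]:
        lo, hi = m.cds_span
        out: list[tuple[int, int]] = []
        start = None
        prev = None
        for off in range(lo, hi):
            g = m.transcript_to_genomic(off).pos
            if start is None:
                start = prev = g
            elif g == prev + 1:
                prev = g
            elif g == prev - 1:
                prev = g
            else:
                out.append((min(start, prev), max(start, prev) + 1))
                start = prev = g
        if start is not None:
            out.append((min(start, prev), max(start, prev) + 1))
        return sorted(out)


def _draw_lengths(rng: np.random.Generator, mean: int, n: int) -> np.ndarray:
    """Gene-part lengths: uniform in [0.5, 1.5] x mean, floor 12 nt."""
    lo, hi = max(12, mean // 2), max(13, mean + mean // 2)
    return rng.integers(lo, hi + 1, size=n)


def simulate_reference(cfg: SimulationConfig) -> SyntheticReference:
    """Build genome FASTA-equivalent sequences, gene models, and the truth
    table skeleton of planted sites.  Deterministic given ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    u5 = _draw_lengths(rng, cfg.utr5_mean, n)
    cds = _draw_lengths(rng, cfg.cds_mean, n)
    cds -= cds % 3
    u3 = _draw_lengths(rng, cfg.utr3_mean, n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    two_exon = rng.random(n) < cfg.two_exon_fraction
    methylated = rng.random(n) < cfg.frac_methylated
    n_sites = np.where(methylated, 1 + rng.poisson(cfg.mean_extra_sites, n), 0)

    chrom = "chr1"
    parts: list[str] = []
    cursor = 0
    models: dict[str, GeneModel] = {}
    site_rows: list[dict] = []
    gene_rows: list[dict] = []

    for i in range(n):
        gene_id = f"g{i:04d}"
        L = int(u5[i] + cds[i] + u3[i])
        tx = rng.choice(BASES, size=L)

        # plant sites: region by placement probs, offset uniform in region
        spans = {
            "5UTR": (0, int(u5[i])),
            "CDS": (int(u5[i]), int(u5[i] + cds[i])),
            "3UTR": (int(u5[i] + cds[i]), L),
        }
        chosen: list[tuple[int, str]] = []
        if n_sites[i] > 0:
            regions = rng.choice(
                ["5UTR", "CDS", "3UTR"], size=n_sites[i], p=cfg.region_placement
            )
            taken: set[int] = set()
            for reg in regions:
                lo, hi = spans[reg]
                # keep 1 nt off each edge so the -1 context exists
                for _ in range(50):
                    off = int(rng.integers(lo + 1, hi - 1))
                    if off not in taken and off - 1 not in taken and off + 1 not in taken:
                        break
                else:  # pragma: no cover - pathological tiny regions
                    continue
                taken.add(off)
                chosen.append((off, reg))
                tx[off] = "A"
                if rng.random() < cfg.p_c_minus1:
                    tx[off - 1] = "C"
                else:
                    tx[off - 1] = rng.choice(np.array(list("AGT")))

        tx_str = "".join(tx)

        # genomic layout (plus-orientation segment, then strand flip)
        if two_exon[i] and L > 40:
            split = int(rng.integers(20, L - 20))
            intron = "".join(rng.choice(BASES, size=cfg.intron_length))
            seg = tx_str[:split] + intron + tx_str[split:]
            rel_exons = [(0, split), (split + cfg.intron_length, len(seg))]
        else:
            seg = tx_str
            rel_exons = [(0, L)]
        if strands[i] == "-":
            seg = reverse_complement(seg)
            sl = len(seg)
            rel_exons = [(sl - e, sl - s) for s, e in rel_exons]
            # transcript order = descending genomic start
            rel_exons = sorted(rel_exons, reverse=True)
        exons = [(cursor + s, cursor + e) for s, e in rel_exons]

        model = GeneModel(
            gene_id,
            chrom,
            str(strands[i]),
            exons,
            cds_span=spans["CDS"],
            utr5_span=spans["5UTR"],
            utr3_span=(spans["CDS"][1], L),
            transcript_length=L,
        )
        models[gene_id] = model
        parts.append(seg)
        parts.append("".join(rng.choice(BASES, size=cfg.spacer_length)))
        cursor += len(seg) + cfg.spacer_length

        regions_hit = sorted({r for _, r in chosen})
        gene_rows.append(
            {
                "gene_id": gene_id,
                "n_sites": len(chosen),
                "regions": ",".join(regions_hit),
                "te_multiplier": cfg.te_effect ** len(chosen),
            }
        )
        for off, reg in chosen:
            g = model.transcript_to_genomic(off)
            site_rows.append(
                {
                    "gene_id": gene_id,
                    "offset": off,
                    "chrom": g.chrom,
                    "pos": g.pos,
                    "strand": g.strand,
                    "region": reg,
                    "ip_rate": cfg.ip_misincorporation,
                    "input_rate": cfg.input_misincorporation,
                }
            )

    truth_sites = pd.DataFrame(
        site_rows,
        columns=[
            "gene_id",
            "offset",
            "chrom",
            "pos",
            "strand",
            "region",
            "ip_rate",
            "input_rate",
        ],
    )
    truth_genes = pd.DataFrame(gene_rows)
    return SyntheticReference(
        cfg, {chrom: "".join(parts)}, models, truth_sites, truth_genes
    )


# -- pileups -------------------------------------------------------------------


def simulate_pileups(
    cfg: SimulationConfig, ref: SyntheticReference
) -> pd.DataFrame:
    """Per-base coverage/mismatch tables for every IP and input replicate.

    Returns a long table (chrom, pos1, ref_base, sample, coverage, mismatches)
    in the TSV dialect :mod:`m1ascan.pileup` consumes; ``pos1`` is 1-based and
    ``ref_base`` is the plus-strand reference base.  Coverage is Poisson with
    the configured mean; mismatches are Binomial(coverage, rate) where rate is
    the planted IP/input rate at modified sites and the background elsewhere.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    genome = ref.genome

    rows = []
    for m in ref.models.values():
        tx = genome.transcript_sequence(m)
        offs = np.arange(m.transcript_length)
        if cfg.adenosine_only:
            offs = offs[np.frombuffer(tx.encode(), dtype="u1") == ord("A")]
        gpos = np.fromiter(
            (m.transcript_to_genomic(int(o)).pos for o in offs),
            dtype=np.int64,
            count=len(offs),
        )
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": m.gene_id,
                    "chrom": m.chrom,
                    "pos": gpos,
                    "offset": offs,
                    "strand": m.strand,
                }
            )
        )
    base = pd.concat(rows, ignore_index=True)
    seq = ref.sequences["chr1"]
    base["ref_base"] = [seq[p] for p in base["pos"]]

    key = base["gene_id"] + ":" + base["offset"].astype(str)
    truth = ref.truth_sites
    tkey = set(truth["gene_id"] + ":" + truth["offset"].astype(str))
    is_site = key.isin(tkey).to_numpy()

    out = []
    samples = [(f"IP{r + 1}", "IP") for r in range(cfg.n_ip_replicates)] + [
        (f"IN{r + 1}", "input") for r in range(cfg.n_input_replicates)
    ]
    for sample, kind in samples:
        rate = np.full(len(base), cfg.background_rate)
        planted = (
            cfg.ip_misincorporation if kind == "IP" else cfg.input_misincorporation
        )
        rate[is_site] = planted
        cov = rng.poisson(cfg.mean_coverage, size=len(base))
        mm = rng.binomial(cov, rate)
        df = base[["chrom", "pos", "ref_base"]].copy()
        df["pos1"] = df.pop("pos") + 1
        df["sample"] = sample
        df["coverage"] = cov
        df["mismatches"] = mm
        out.append(df[["chrom", "pos1", "ref_base", "sample", "coverage", "mismatches"]])
    return pd.concat(out, ignore_index=True)


def write_pileup_tsv(pileups: pd.DataFrame, path: str | Path) -> None:
    pileups.to_csv(path, sep="\t", index=False)


def write_mpileup(
    pileups: pd.DataFrame,
    path: str | Path,
    sample: str,
    seed: int = 0,
    decorate: bool = True,
) -> None:
    """Render one sample as samtools-mpileup text (chrom, pos, ref, depth,
    bases, quals), optionally decorated with read-start/end marks and the
    occasional indel run to exercise the parser."""
    rng = np.random.default_rng(seed)
    sub = pileups[pileups["sample"] == sample]
    with open(path, "w") as fh:
        for row in sub.itertuples(index=False):
            cov, mm = int(row.coverage), int(row.mismatches)
            alts = [b for b in "ACGT" if b != row.ref_base]
            calls = []
            for j in range(cov):
                if j < mm:
                    b = alts[int(rng.integers(0, 3))]
                    calls.append(b if rng.random() < 0.5 else b.lower())
                else:
                    calls.append("." if rng.random() < 0.5 else ",")
            if decorate and cov:
                k = int(rng.integers(0, cov))
                calls[k] = "^I" + calls[k]
                k = int(rng.integers(0, cov))
                calls[k] = calls[k] + "$"
                if rng.random() < 0.1:
                    calls[int(rng.integers(0, cov))] += "+2AG"
            quals = "I" * cov
            fh.write(
                f"{row.chrom}\t{row.pos1}\t{row.ref_base}\t{cov}\t"
                f"{''.join(calls)}\t{quals}\n"
            )


# -- expression ----------------------------------------------------------------


def _nb(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws parameterised by mean and dispersion phi
    (var = mu + phi mu^2); phi = 0 degenerates to Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_expression(
    cfg: SimulationConfig,
    ref: SyntheticReference,
    condition: str = "control",
    dmr_status: pd.Series | None = None,
) -> pd.DataFrame:
    """RNA counts, RPF counts and poly(A) lengths per gene.

    Expected TE of a gene with k planted sites is ``te_effect ** k`` relative
    to baseline.  Under ``condition='stress'`` a global slowdown multiplies TE
    by ``stress_te_factor``; genes whose ``dmr_status`` is 'down'
    (methylation lost) are exempt from the slowdown, and 'up' genes suffer
    ``stress_extra_repression`` on top.  Methylated genes draw poly(A) lengths
    from a distribution shifted by ``polyA_shift`` and have
    ``abundance_boost_methylated``-fold higher expected mRNA abundance.
    """
    if condition not in ("control", "stress"):
        raise ValueError(f"unknown condition {condition!r}")
    salt = 2 if condition == "control" else 3
    rng = np.random.default_rng(cfg.seed + salt)
    genes = ref.truth_genes.set_index("gene_id")
    gene_ids = list(ref.models)
    k = genes.loc[gene_ids, "n_sites"].to_numpy()
    lengths = np.array([ref.models[g].transcript_length for g in gene_ids])

    abundance = rng.lognormal(mean=0.0, sigma=0.7, size=len(gene_ids))
    abundance *= np.where(k > 0, cfg.abundance_boost_methylated, 1.0)
    mu_rna = cfg.mean_rna_count * abundance * lengths / lengths.mean()

    te = cfg.te_effect ** k.astype(float)
    if condition == "stress":
        mult = np.full(len(gene_ids), cfg.stress_te_factor)
        if dmr_status is not None:
            status = dmr_status.reindex(gene_ids).fillna("unchanged")
            mult[(status == "down").to_numpy()] = 1.0
            mult[(status == "up").to_numpy()] = (
                cfg.stress_te_factor * cfg.stress_extra_repression
            )
        te = te * mult
    mu_rpf = mu_rna * te

    rna = _nb(rng, mu_rna, cfg.dispersion)
    rpf = _nb(rng, mu_rpf, cfg.dispersion)
    polya = rng.normal(
        cfg.polyA_mean + np.where(k > 0, cfg.polyA_shift, 0.0), cfg.polyA_sd
    ).clip(10)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "length": lengths,
            "rna_count": rna,
            "rpf_count": rpf,
            "polyA_median": np.round(polya, 1),
            "true_sites": k,
            "true_te": te,
        }
    )


# -- MeRIP peaks ---------------------------------------------------------------


def simulate_merip_peaks(
    cfg: SimulationConfig, ref: SyntheticReference
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Consensus MeRIP peak intervals plus per-sample IP/input counts.

    One peak is centred on the first planted site of each methylated gene
    (so it overlaps that site); unmethylated genes get an off-site peak over
    their CDS midpoint, modelling antibody noise.  A planted fraction of
    site-overlapping peaks is up- or down-methylated under stress by
    ``dmr_fold``; counts are negative binomial with common dispersion.

    Returns ``(peaks, counts)``: peaks with columns chrom/start/end/strand/
    peak_id/gene_id/true_status; counts indexed by peak_id with one column per
    sample (IP_ctrl_1..2, IP_str_1..2, IN_ctrl_1..2, IN_str_1..2).
    """
    rng = np.random.default_rng(cfg.seed + 4)
    half = cfg.peak_width // 2
    clen = len(ref.sequences["chr1"])

    rows = []
    for gid, m in ref.models.items():
        sites = ref.truth_sites[ref.truth_sites["gene_id"] == gid]
        if len(sites):
            center = int(sites.iloc[0]["pos"])
            status_pool = True
        else:
            mid_off = (m.cds_span[0] + m.cds_span[1]) // 2 if m.is_coding else 0
            center = m.transcript_to_genomic(mid_off).pos
            status_pool = False
        start = max(0, center - half)
        end = min(clen, center + half)
        rows.append(
            {
                "chrom": m.chrom,
                "start": start,
                "end": end,
                "strand": m.strand,
                "peak_id": f"peak_{gid}",
                "gene_id": gid,
                "eligible": status_pool,
            }
        )
    peaks = pd.DataFrame(rows)

    status = np.full(len(peaks), "unchanged", dtype=object)
    elig = peaks["eligible"].to_numpy()
    r = rng.random(len(peaks))
    status[elig & (r < cfg.dmr_up_fraction)] = "up"
    status[
        elig
        & (r >= cfg.dmr_up_fraction)
        & (r < cfg.dmr_up_fraction + cfg.dmr_down_fraction)
    ] = "down"
    peaks["true_status"] = status
    peaks = peaks.drop(columns="eligible")

    base = rng.lognormal(0.0, 0.3, size=len(peaks)) * cfg.peak_mean_count
    fold = np.ones(len(peaks))
    fold[status == "up"] = cfg.dmr_fold
    fold[status == "down"] = 1.0 / cfg.dmr_fold
    counts = {}
    for rep in range(2):
        counts[f"IP_ctrl_{rep + 1}"] = _nb(rng, base, cfg.peak_dispersion)
        counts[f"IP_str_{rep + 1}"] = _nb(rng, base * fold, cfg.peak_dispersion)
        counts[f"IN_ctrl_{rep + 1}"] = _nb(
            rng, base * cfg.peak_input_fraction, cfg.peak_dispersion
        )
        counts[f"IN_str_{rep + 1}"] = _nb(
            rng, base * cfg.peak_input_fraction, cfg.peak_dispersion
        )
    counts_df = pd.DataFrame(counts, index=peaks["peak_id"])
    return peaks, counts_df


# -- bundle --------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """Everything one end-to-end run needs, generated from one seed."""

    config: SimulationConfig
    reference: SyntheticReference
    pileups: pd.DataFrame
    expression_control: pd.DataFrame
    expression_stress: pd.DataFrame
    peaks: pd.DataFrame
    peak_counts: pd.DataFrame
    dmr_status: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.dmr_status = self.peaks.set_index("gene_id")["true_status"]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "gtf": out / "genes.gtf",
            "pileups": out / "pileups.tsv",
            "expression_control": out / "expression_control.tsv",
            "expression_stress": out / "expression_stress.tsv",
            "peaks": out / "peaks.bed",
            "peak_counts": out / "peak_counts.tsv",
            "truth_sites": out / "truth_sites.tsv",
            "truth_genes": out / "truth_genes.tsv",
        }
        self.reference.write_fasta(paths["genome"])
        self.reference.write_gtf(paths["gtf"])
        write_pileup_tsv(self.pileups, paths["pileups"])
        self.expression_control.to_csv(
            paths["expression_control"], sep="\t", index=False
        )
        self.expression_stress.to_csv(
            paths["expression_stress"], sep="\t", index=False
        )
        self.peaks[["chrom", "start", "end", "peak_id", "gene_id", "strand"]].to_csv(
            paths["peaks"], sep="\t", index=False, header=False
        )
        self.peak_counts.to_csv(paths["peak_counts"], sep="\t")
        self.reference.truth_sites.to_csv(paths["truth_sites"], sep="\t", index=False)
        self.reference.truth_genes.to_csv(paths["truth_genes"], sep="\t", index=False)
        return paths


def simulate_dataset(cfg: SimulationConfig | None = None, **overrides) -> SyntheticDataset:
    """One-call generator for a complete, consistent dataset."""
    cfg = replace(cfg, **overrides) if cfg is not None else SimulationConfig(**overrides)
    ref = simulate_reference(cfg)
    pileups = simulate_pileups(cfg, ref)
    peaks, peak_counts = simulate_merip_peaks(cfg, ref)
    dmr_status = peaks.set_index("gene_id")["true_status"]
    expr_ctrl = simulate_expression(cfg, ref, "control")
    expr_str = simulate_expression(cfg, ref, "stress", dmr_status=dmr_status)
    return SyntheticDataset(cfg, ref, pileups, expr_ctrl, expr_str, peaks, peak_counts)
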