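# Methods

## The detection problem

N1-methyladenosine carries its methyl group on the Watson–Crick face, so a
thermostable group II intron reverse transcriptase reads through the lesion
and leaves elevated mismatch rates at the modified position. Comparing an
anti-m¹A-enriched (IP) library against its input control separates true
modification signal from sequence- and enzyme-dependent background: both
libraries share the background process, but only the IP library concentrates
modified fragments. The pipeline operationalizes this as a per-adenosine
two-sample proportion problem.

## Site calling

For each exonic position whose transcript-strand base is A (reference A
under plus-strand genes, reference T under minus-strand genes), coverage and
mismatch counts are decoded from pileup text. A mismatch is any
non-reference base call; indel runs, read start/end marks, deletion
placeholders and N calls are consumed by the grammar but never counted as
base calls. Deletions and Ns reduce coverage — an ambiguous call carries no
evidence either way.

Candidate positions must show, in at least one IP replicate, coverage
strictly above 10 reads, at least 2 mismatches, and a mismatch rate strictly
above 10%. Candidates from all IP replicates are pooled (union). The
candidate threshold ("at least 2") intentionally differs from the calling
threshold ("more than 2"); both are kept exactly as defined.

Calling sums counts across IP replicates and across input replicates (the
highest-power reading of an IP-vs-input comparison at n = 2; a
`per_replicate` mode instead requires the criteria in every replicate) and
applies the one-sided pooled two-proportion Z-test with alternative
"IP rate greater". A site is called when p < 0.05, coverage exceeds 10 in
both pooled libraries, the IP mismatch count exceeds 2, and the IP mismatch
count strictly exceeds the input's. When the pooled proportion is 0 or 1 the
variance vanishes; both rates are then necessarily equal and p is set to 1
with a degeneracy flag. p-values are raw by design — the procedure is
reproduced as defined; a Benjamini–Hochberg option is deliberately not the
default.

Under the default synthetic conditions (IP misincorporation 0.2, input
0.02, background 0.005, ~100× coverage per replicate) the planted and
background populations are separated by many standard deviations, which is
why measured precision and recall sit at or near 1.0; the interesting
regimes (low coverage, partial stoichiometry) can be explored by lowering
`mean_coverage` or `ip_misincorporation`.

## Annotation

Gene models keep one representative transcript per gene — the longest
annotated — because all downstream quantities are per-gene; the 5′UTR/CDS/
3′UTR spans partition the transcript exactly (half-open intervals,
0-based internally; GTF is converted from 1-based inclusive on load, pileup
positions from 1-based, BED consumed as 0-based half-open). A site exactly
on the stop codon falls in CDS by the half-open convention; the site-level
region split is strictly three-way. Sites in models without CDS annotation
are labeled `unpartitioned` and excluded from percentages but counted.

The metagene axis concatenates three segments with widths proportional to
the mean annotated 5′UTR, CDS and 3′UTR lengths over all coding models; each
site maps to its fractional position within its own region. The histogram is
normalized to integrate to exactly 1. An empty region class collapses to a
zero-width segment.

Motif summaries report the upstream 3-mer at positions −3..−1 and, because
an NNCA-style context can equally be read as −2..0 including the site, that
window too. The position frequency matrix spans ±5 nt by default; windows
truncated by a transcript end are excluded from the PFM and counted.

Per-gene sequence features: 3′UTR length and GC, neighborhood GC over ±50 nt
around each site (the window size is a modeling choice, exposed in config),
and per-nucleotide 3′UTR folding energy (MFE / length — normalization per
nucleotide makes genes of different 3′UTR lengths comparable). Folding is an
interface: the production provider shells out to RNAfold; the built-in
`ToyStemFolding` scorer (−1 per G–C pair folding ends inward) is
deterministic and dependency-free, exists for tests, and is not
thermodynamically meaningful.

## MeRIP integration

A peak supports a site when the half-open window [site − 100,
site + 100 + 1) intersects the peak interval; genes owning at least one such
pair are "shared methylated genes". Differential methylation between
conditions is computed on the consensus peak set: samples are scaled to the
mean library size (total-count; a median-ratio option exists — total-count
is the default for determinism on synthetic counts), fold change is the
ratio of normalized condition means of IP counts (not IP/input enrichment,
matching differential-binding convention; the alternative is configurable),
and significance comes from a conditional negative-binomial exact test with
one common dispersion estimated by pooled method of moments
(φ = Σ(s² − m̄)/Σ m̄² over within-condition cells, floored at 0; φ = 0
degenerates to the conditional binomial/Poisson test). The conditional total
is built from the rounded per-condition sums so that swapping condition
labels is an exact symmetry (up↔down with identical p). Status "up" requires
fold change strictly above 1.5 and p strictly below 0.05; "down" is
symmetric. Only site-supported peaks are reported as altered methylation
regions; others keep their statistics but stay "unchanged".

## Expression and translation efficiency

TPM_i = 10⁶·(c_i/ℓ_i)/Σ_j(c_j/ℓ_j) with effective length equal to the
representative transcript length (no fragment-length correction — the read
length scale is not part of the model). TE = RPF TPM / RNA TPM, defined only
when RNA TPM > 5 (strict) and RPF TPM > 0; ineligible genes carry a reason
code. Group comparisons report medians, quartiles, 1.5×IQR whisker bounds,
and empirical CDFs; the headline test is Welch's two-sided t on
log2-transformed values because TE is ratio-scaled and right-skewed, with
the raw-scale test reported alongside. Strata: methylated vs not; site-count
bins 0/1/2/3+; region of methylation (each X-only class and mixed, tested
against unmethylated); DMR classes for ΔTE = log2(TE_stress/TE_control)
restricted to genes eligible in both conditions.

A consequence of the TPM definition worth stating: a condition-wide
multiplicative TE change is absorbed by within-sample normalization, so ΔTE
class effects are identifiable only relative to one another. The planted
stress structure (global ×0.7 slowdown, exemption for methylation-loss
genes, extra ×0.6 repression for methylation-gain genes) therefore appears
as the class ordering up < unchanged < down with
(down − unchanged) ≈ −log2 0.7 ≈ 0.51, not as absolute medians at log2 0.7.

## Synthetic data generator

The generator emulates the statistical skeleton of a TGIRT-misincorporation
study on a dinoflagellate-like transcriptome; one integer seed determines
every output byte.

Defaults and what they encode:

| parameter | default | meaning |
|---|---|---|
| region placement | 4.4 / 14.2 / 81.4 % | site probability per 5′UTR/CDS/3′UTR |
| p(C at −1) | 0.8 | NNCA-type context (else uniform over A/G/T) |
| IP misincorporation | 0.20 | mismatch rate at modified sites in IP |
| input misincorporation | 0.02 | antibody-free carry-through, keeps the IP>input test meaningful |
| background | 0.005 | shared mismatch floor at unmodified adenosines |
| mean coverage | 100× | Poisson per position per replicate |
| replicates | 2 IP + 2 input | matching the two-replicate design |
| TE effect | 0.6 per site | expected TE of a gene with k sites = baseline × 0.6^k |
| poly(A) shift | −20 nt | methylated genes draw shorter tails (Normal 120 ± 25) |
| abundance boost | 1.5× | methylated genes are more highly expressed |
| NB dispersion | 0.1 (counts), 0.05 (peaks) | var = μ + φμ² |
| stress TE factor | 0.7 | global slowdown; ×0.6 extra for up-methylated, exempt for down |
| DMR fold | 3× | planted peak-count change for up/down peaks |

Gene architecture: 5′UTR/CDS/3′UTR lengths uniform in [0.5, 1.5]× their
means (100/900/400 nt; CDS rounded to codons), ~20% two-exon genes, random
strand, genes laid head-to-tail on one contig with spacers. Sites are
planted on forced adenosines at least 1 nt from region edges so the −1
context exists. Coverage is Poisson; mismatches are Binomial(coverage,
rate) — misincorporation is a single aggregate mismatch count, not a
substitution spectrum, because the calling criteria are base-agnostic.
MeRIP peak counts are negative binomial per peak (one peak per gene,
centred on the first site of methylated genes, off-site for unmethylated
ones); peak calling itself is consumed, never simulated. Pileup tables are
emitted for adenosine positions only by default (`adenosine_only=False`
restores all exonic positions); both the 6-column TSV and decorated
samtools-mpileup text renderings are supported.

What the generator does **not** model — and hence what passing tests do not
show about real data: alignment and mapping artifacts, base-quality
structure, substitution spectra, sequence-dependent background (the real
background is not uniform), isoform mixtures, partial stoichiometry at
sites, overlapping genes, and rRNA contamination. Recovery rates measured
here are upper bounds for field data.

## Numerical and design choices

- All randomness flows from the one seed in the simulation config; analysis
  stages are deterministic, and a rerun with identical inputs and config is
  bit-identical.
- Strict inequalities everywhere a threshold is defined as "greater than";
  boundary cases (coverage exactly 10, rate exactly 10%, fold change exactly
  1.5, RNA TPM exactly 5) fail by construction and are pinned by tests.
- Degenerate inputs: zero pooled variance → p = 1 with flag; all-zero count
  vectors abort with a diagnostic; a condition with zero total peak counts
  aborts; groups under 2 observations skip their comparison with a warning;
  genes without a 3′UTR yield null features.
- No base- or mapping-quality floor is applied during pileup ingestion (none
  is part of the procedure); the pre-tabulated pileup is the contract.
- Candidate pooling is across IP replicates only; input plays no role in
  candidacy.
- Multi-isoform genes are collapsed to the longest transcript before any
  region statistic.

## Problem sizes

Test and acceptance runs use 40–2000 genes (roughly 6 × 10³ to 3 × 10⁵
adenosine observations per sample at the defaults): large enough that the
binomial checks on planted fractions operate at their stated tolerances
(e.g. ±3% absolute on region placement needs ~2000 sites), small enough to
keep every individual check in the seconds-to-a-minute range.
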