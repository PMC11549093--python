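"""MeRIP peak reconciliation and differential methylation regions.

Antibody-based MeRIP yields peak intervals rather than single-base sites;
this module (a) flags peaks that intersect the 100-nt flanks of
misincorporation-called sites ("shared methylated genes"), and (b) calls
differential methylation regions (DMRs) between two conditions on a fixed
consensus peak set: library-size-normalized IP counts, fold change of the
normalized condition means, and a negative-binomial exact test with one
common method-of-moments dispersion shared across peaks (dispersion 0
degenerates to a Poisson/conditional-binomial test).  A peak is 'up' when its
fold change strictly exceeds 1.5 with p < 0.05, symmetrically 'down'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# -- overlap -------------------------------------------------------------------


def overlap_peaks_sites(
    peaks: pd.DataFrame, sites: pd.DataFrame, flank: int = 100
) -> tuple[pd.DataFrame, set[str]]:
    """Flag peaks intersecting the flanked window of any called site.

    A site at position p defines the half-open window [p - flank,
    p + flank + 1); a peak [start, end) overlaps iff the intervals intersect.
    Returns the peak table with an ``overlaps_site`` column and the set of
    shared genes (genes owning at least one overlapping peak).
    """
    out = peaks.copy()
    flags = np.zeros(len(peaks), dtype=bool)
    for chrom, sub in sites.groupby("chrom"):
        pos = np.sort(sub["pos"].to_numpy())
        mask = (peaks["chrom"] == chrom).to_numpy()
        if not mask.any() or len(pos) == 0:
            continue
        starts = peaks.loc[mask, "start"].to_numpy()
        ends = peaks.loc[mask, "end"].to_numpy()
        # window [p-flank, p+flank+1) intersects [s,e) iff p > s-flank-1 and p < e+flank
        lo = np.searchsorted(pos, starts - flank, side="left")
        hi = np.searchsorted(pos, ends + flank - 1, side="right")
        flags[mask] = hi > lo
    out["overlaps_site"] = flags
    shared = set(out.loc[out["overlaps_site"], "gene_id"]) if "gene_id" in out else set()
    return out, shared


# -- differential methylation --------------------------------------------------


@dataclass
class DmrDesign:
    """Sample-to-condition map over the columns of the count matrix."""

    condition_a: list[str]  # e.g. stress IP replicates (numerator)
    condition_b: list[str]  # e.g. control IP replicates (denominator)


def estimate_common_dispersion(norm_counts: pd.DataFrame, design: DmrDesign) -> float:
    """Method-of-moments NB dispersion pooled over all peaks and conditions:
    phi = sum(var - mean) / sum(mean^2) over within-condition cells,
    floored at 0."""
    num = 0.0
    den = 0.0
    for cols in (design.condition_a, design.condition_b):
        if len(cols) < 2:
            continue
        block = norm_counts[cols].to_numpy(dtype=float)
        m = block.mean(axis=1)
        v = block.var(axis=1, ddof=1)
        num += np.sum(v - m)
        den += np.sum(m**2)
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def _nb_logpmf(x: np.ndarray, mean: float, phi: float) -> np.ndarray:
    if phi <= 0:
        return stats.poisson.logpmf(x, mean)
    size = 1.0 / phi
    p = size / (size + mean)
    return stats.nbinom.logpmf(x, size, p)


def nb_exact_test(
    sum_a: float, n_a: int, sum_b: float, n_b: int, dispersion: float
) -> float:
    """Two-sided exact test for a difference between condition sums.

    Under the null both conditions share mean mu = (sum_a + sum_b)/(n_a +
    n_b) per replicate; the summed counts are NB with mean n*mu and
    dispersion phi/n.  Conditional on the total t, the p-value is the
    probability mass of all splits (x, t - x) no more likely than the
    observed one.  With dispersion 0 this is the conditional binomial test.
    """
    obs = int(round(sum_a))
    t = obs + int(round(sum_b))  # rounded parts keep the test swap-symmetric
    if t == 0:
        return 1.0
    mu = (sum_a + sum_b) / (n_a + n_b)
    x = np.arange(t + 1)
    la = _nb_logpmf(x, n_a * mu, dispersion / n_a)
    lb = _nb_logpmf(x[::-1], n_b * mu, dispersion / n_b)
    logp = la + lb
    logp -= logp.max()
    w = np.exp(logp)
    total = w.sum()
    p = w[w <= w[obs] * (1 + 1e-12)].sum() / total
    return float(min(1.0, p))


def differential_regions(
    peaks: pd.DataFrame,
    counts: pd.DataFrame,
    design: DmrDesign,
    fc_threshold: float = 1.5,
    alpha: float = 0.05,
    normalization: str = "total",
    require_site_overlap: bool = True,
) -> pd.DataFrame:
    """Call DMR status per peak between condition A (numerator) and B.

    ``counts`` is a peak x sample matrix of IP counts indexed like
    ``peaks['peak_id']``.  Samples are normalized to the mean library size
    (total-count; 'median' ratio offered as the alternative), condition means
    are compared by fold change, and significance comes from the common-
    dispersion NB exact test.  Status 'up' requires fold change strictly
    above ``fc_threshold`` AND p strictly below ``alpha``; 'down' is
    symmetric (fold change below 1/threshold).  When
    ``require_site_overlap`` is set, peaks lacking ``overlaps_site`` keep
    their statistics but are reported as 'unchanged' — only site-supported
    peaks count as altered methylation regions.
    """
    cols = design.condition_a + design.condition_b
    mat = counts.loc[peaks["peak_id"], cols].to_numpy(dtype=float)
    libsize = mat.sum(axis=0)
    if np.any(libsize == 0):
        raise ValueError("a sample has zero total counts over the peak set")
    if normalization == "total":
        factors = libsize / libsize.mean()
    elif normalization == "median":
        ref = np.exp(np.log(np.maximum(mat, 0.5)).mean(axis=1))
        factors = np.median(mat / ref[:, None], axis=0)
        factors /= factors.mean()
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    norm = pd.DataFrame(mat / factors, columns=cols, index=peaks["peak_id"])

    phi = estimate_common_dispersion(norm, design)
    n_a, n_b = len(design.condition_a), len(design.condition_b)
    sum_a = norm[design.condition_a].sum(axis=1).to_numpy()
    sum_b = norm[design.condition_b].sum(axis=1).to_numpy()
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_b > 0, mean_a / np.where(mean_b > 0, mean_b, 1.0), np.inf)
        log2fc = np.log2(np.where(fc > 0, fc, np.nan))
    pvals = np.array(
        [
            nb_exact_test(a, n_a, b, n_b, phi)
            for a, b in zip(sum_a, sum_b)
        ]
    )
    status = np.full(len(peaks), "unchanged", dtype=object)
    status[(fc > fc_threshold) & (pvals < alpha)] = "up"
    status[(fc < 1.0 / fc_threshold) & (pvals < alpha)] = "down"
    if require_site_overlap and "overlaps_site" in peaks.columns:
        status[~peaks["overlaps_site"].to_numpy(dtype=bool)] = "unchanged"

    out = peaks.copy()
    out["mean_a"] = mean_a
    out["mean_b"] = mean_b
    out["fold_change"] = fc
    out["log2fc"] = log2fc
    out["p"] = pvals
    out["status"] = status
    out.attrs["dispersion"] = phi
    return out


def gene_dmr_status(dmr: pd.DataFrame) -> pd.Series:
    """Collapse peak-level DMR calls to one status per gene.

    A gene is 'up' if any of its peaks is up and none down; 'down'
    symmetric; genes with conflicting or no significant peaks are
    'unchanged'.
    """
    def collapse(s: pd.Series) -> str:
        has_up = (s == "up").any()
        has_down = (s == "down").any()
        if has_up and not has_down:
            return "up"
        if has_down and not has_up:
            return "down"
        return "unchanged"

    return dmr.groupby("gene_id")["status"].apply(collapse)
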