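"""TPM, translation efficiency, and methylation-stratified comparisons.

TE is the ratio of Ribo-seq (ribosome-protected fragment) abundance to mRNA
abundance per gene, both expressed in TPM; genes enter TE analysis only when
RNA TPM strictly exceeds 5 and RPF TPM is positive.  Group comparisons report
medians, quartiles, 1.5 x IQR whisker bounds, empirical CDFs, and a Welch
two-sided t-test — run on log2-transformed values by default because TE is a
ratio-scaled, right-skewed quantity (the raw-scale test is also reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

RNA_TPM_MIN = 5.0  # strict: rna_tpm must exceed this


def compute_tpm(counts, effective_lengths) -> np.ndarray:
    """Transcripts per million: 1e6 * (c_i/l_i) / sum_j (c_j/l_j)."""
    c = np.asarray(counts, dtype=float)
    l = np.asarray(effective_lengths, dtype=float)
    if np.any(l <= 0):
        raise ValueError("effective lengths must be positive")
    rate = c / l
    total = rate.sum()
    if total == 0:
        raise ValueError("all-zero counts: TPM undefined")
    return 1e6 * rate / total


def compute_te(
    expr: pd.DataFrame,
    rna_tpm_min: float = RNA_TPM_MIN,
) -> pd.DataFrame:
    """Add rna_tpm, rpf_tpm, te and eligibility columns to an expression table.

    ``expr`` needs gene_id, length, rna_count, rpf_count.  TE is defined only
    for genes with rna_tpm > ``rna_tpm_min`` and rpf_tpm > 0; others carry
    NaN TE and an ``ineligible_reason``.
    """
    out = expr.copy()
    out["rna_tpm"] = compute_tpm(out["rna_count"], out["length"])
    out["rpf_tpm"] = compute_tpm(out["rpf_count"], out["length"])
    eligible = (out["rna_tpm"] > rna_tpm_min) & (out["rpf_tpm"] > 0)
    out["te"] = np.where(eligible, out["rpf_tpm"] / out["rna_tpm"], np.nan)
    out["te_eligible"] = eligible
    reason = np.full(len(out), "", dtype=object)
    reason[(out["rna_tpm"] <= rna_tpm_min).to_numpy()] = "rna_tpm<=threshold"
    reason[(out["rpf_tpm"] <= 0).to_numpy()] = "rpf_tpm==0"
    reason[eligible.to_numpy()] = ""
    out["ineligible_reason"] = reason
    return out


# -- group comparisons ---------------------------------------------------------


@dataclass
class GroupComparison:
    """Two-or-more-group comparison of one quantity."""

    variable: str
    groups: list[str]
    sizes: list[int]
    medians: list[float]
    q1: list[float]
    q3: list[float]
    whisker_low: list[float]
    whisker_high: list[float]
    t: float  # Welch t between the first two groups (log scale when log=True)
    p: float
    t_raw: float
    p_raw: float
    log_scale: bool
    cdf: dict[str, pd.DataFrame] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.groups,
                "n": self.sizes,
                "median": self.medians,
                "q1": self.q1,
                "q3": self.q3,
                "whisker_low": self.whisker_low,
                "whisker_high": self.whisker_high,
            }
        )


def _box_stats(v: np.ndarray) -> tuple[float, float, float, float, float]:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_bound, hi_bound = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_bound) & (v <= hi_bound)]
    return med, q1, q3, float(inside.min()), float(inside.max())


def compare_groups(
    values: pd.Series,
    labels: pd.Series,
    order: list[str],
    variable: str = "te",
    log: bool = True,
    min_group: int = 2,
) -> GroupComparison | None:
    """Welch two-sided t-test (first two groups) plus per-group box/CDF stats.

    Groups smaller than ``min_group`` cause the comparison to be skipped
    (returns None).  NaN values are dropped per group.
    """
    data = {}
    for g in order:
        v = values[labels == g].dropna().to_numpy(dtype=float)
        if log:
            v = v[v > 0]
        data[g] = v
    if any(len(data[g]) < min_group for g in order[:2]):
        return None
    med, q1, q3, wlo, whi = [], [], [], [], []
    cdf = {}
    for g in order:
        v = data[g]
        if len(v) == 0:
            med.append(np.nan); q1.append(np.nan); q3.append(np.nan)
            wlo.append(np.nan); whi.append(np.nan)
            continue
        m, a, b, lo, hi = _box_stats(v)
        med.append(m); q1.append(a); q3.append(b); wlo.append(lo); whi.append(hi)
        vs = np.sort(v)
        cdf[g] = pd.DataFrame(
            {"value": vs, "cdf": np.arange(1, len(vs) + 1) / len(vs)}
        )
    a, b = data[order[0]], data[order[1]]
    t_raw, p_raw = stats.ttest_ind(a, b, equal_var=False)
    if log:
        t_log, p_log = stats.ttest_ind(np.log2(a), np.log2(b), equal_var=False)
    else:
        t_log, p_log = t_raw, p_raw
    return GroupComparison(
        variable=variable,
        groups=order,
        sizes=[len(data[g]) for g in order],
        medians=med,
        q1=q1,
        q3=q3,
        whisker_low=wlo,
        whisker_high=whi,
        t=float(t_log),
        p=float(p_log),
        t_raw=float(t_raw),
        p_raw=float(p_raw),
        log_scale=log,
    )


# -- stratifiers ---------------------------------------------------------------


def site_count_bins(n_sites: pd.Series, top: int = 3) -> pd.Series:
    """Bin site counts as '0', '1', ..., 'top+'."""
    def lab(k):
        return f"{top}+" if k >= top else str(int(k))

    return n_sites.map(lab)


def region_class(regions: pd.Series) -> pd.Series:
    """Collapse per-gene methylated-region sets to
    none / 5UTR-only / CDS-only / 3UTR-only / mixed."""
    def lab(r):
        if not isinstance(r, str) or r == "":
            return "none"
        parts = r.split(",")
        return f"{parts[0]}-only" if len(parts) == 1 else "mixed"

    return regions.map(lab)


def stratified_compare(
    features: pd.DataFrame,
    stratifier: str,
    variable: str = "te",
    log: bool = True,
) -> list[GroupComparison]:
    """Run the methylation-stratified comparisons on a feature table.

    ``features`` needs the ``variable`` column plus ``m1a_site_count`` (and
    ``m1a_regions`` for region strata).  Stratifiers:

    - 'methylated': genes with >= 1 site vs none;
    - 'site_count': bins 0 / 1 / 2 / 3+ — consecutive-bin tests, first entry
      compares 0 vs 1;
    - 'region': none vs 5UTR-only vs CDS-only vs 3UTR-only vs mixed, each
      methylated class tested against 'none'.
    """
    vals = features[variable]
    out: list[GroupComparison] = []
    if stratifier == "methylated":
        labels = np.where(features["m1a_site_count"] > 0, "m1A", "non-m1A")
        cmp = compare_groups(
            vals, pd.Series(labels, index=features.index), ["m1A", "non-m1A"],
            variable, log,
        )
        if cmp:
            out.append(cmp)
    elif stratifier == "site_count":
        bins = site_count_bins(features["m1a_site_count"])
        order = ["0", "1", "2", "3+"]
        present = [g for g in order if (bins == g).sum() >= 2]
        for a, b in zip(present[:-1], present[1:]):
            cmp = compare_groups(vals, bins, [a, b], variable, log)
            if cmp:
                out.append(cmp)
    elif stratifier == "region":
        classes = region_class(features.get("m1a_regions", pd.Series("", index=features.index)))
        for cls in ["5UTR-only", "CDS-only", "3UTR-only", "mixed"]:
            if (classes == cls).sum() < 2:
                continue
            cmp = compare_groups(vals, classes, [cls, "none"], variable, log)
            if cmp:
                out.append(cmp)
    else:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    return out


def te_change_by_dmr(
    te_control: pd.DataFrame,
    te_stress: pd.DataFrame,
    dmr_classes: pd.Series,
    log: bool = True,
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Per-gene log2 TE change between conditions, compared across DMR classes.

    Genes must be TE-eligible in both conditions.  Returns the per-gene
    table (gene_id, delta_te = log2(te_stress/te_control), dmr_class) and
    pairwise comparisons of each class against 'unchanged'.
    """
    a = te_control.set_index("gene_id")
    b = te_stress.set_index("gene_id")
    common = a.index[a["te_eligible"]].intersection(b.index[b["te_eligible"]])
    delta = np.log2(b.loc[common, "te"] / a.loc[common, "te"])
    classes = dmr_classes.reindex(common).fillna("unchanged")
    table = pd.DataFrame(
        {"gene_id": common, "delta_te": delta.to_numpy(), "dmr_class": classes.to_numpy()}
    )
    comparisons = []
    for cls in ["up", "down"]:
        if (table["dmr_class"] == cls).sum() < 2:
            continue
        cmp = compare_groups(
            table["delta_te"],
            table["dmr_class"],
            [cls, "unchanged"],
            variable="delta_te",
            log=False,  # delta is already on log2 scale
        )
        if cmp:
            comparisons.append(cmp)
    return table, comparisons
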