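"""Putative m1A site calling from misincorporation signatures.

The procedure has two stages.  Candidate filtering keeps adenosines where, in
at least one IP replicate, coverage exceeds 10 reads with at least 2
mismatches and a mismatch rate above 10%; candidates from all IP replicates
are pooled.  Calling then compares IP against input with a one-sided pooled
two-proportion Z-test (alternative: IP rate greater) and keeps candidates
meeting all four criteria: p < 0.05, coverage above 10 in both IP and input,
IP mismatch count above 2, and IP mismatch count strictly higher than input.

Replicates are summed within IP and within input before testing by default
(the highest-power reading of an IP-vs-input comparison with n = 2);
``per_replicate=True`` instead requires the calling criteria in every
replicate pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_THRESHOLDS = dict(
    candidate_coverage=10,  # strictly greater than
    candidate_mismatches=2,  # at least
    candidate_rate=0.10,  # strictly greater than
    alpha=0.05,
    call_coverage=10,  # strictly greater than, both libraries
    call_mismatches=2,  # strictly greater than
)

KEY = ["gene_id", "chrom", "pos", "offset", "strand"]


@dataclass
class CallingThresholds:
    candidate_coverage: int = 10
    candidate_mismatches: int = 2
    candidate_rate: float = 0.10
    alpha: float = 0.05
    call_coverage: int = 10
    call_mismatches: int = 2


def filter_candidates(
    ip_obs: pd.DataFrame, thresholds: CallingThresholds | None = None
) -> pd.DataFrame:
    """Candidate adenosines: pass the per-replicate filter in >= 1 IP sample.

    ``ip_obs`` is the observation table from
    :func:`m1ascan.pileup.extract_adenosine_observations` restricted to IP
    samples.  Returns the unique (gene, position) keys, pooled across
    replicates.
    """
    t = thresholds or CallingThresholds()
    ok = (
        (ip_obs["coverage"] > t.candidate_coverage)
        & (ip_obs["mismatches"] >= t.candidate_mismatches)
        & (ip_obs["mismatch_rate"] > t.candidate_rate)
    )
    return ip_obs.loc[ok, KEY].drop_duplicates().reset_index(drop=True)


def proportion_z_test(
    ip_m, ip_c, in_m, in_c
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-sided pooled two-proportion Z-test (alternative: IP > input).

    z = (p1 - p2) / sqrt(phat (1-phat) (1/c1 + 1/c2)) with
    phat = (m1 + m2) / (c1 + c2); p is the upper-tail standard-normal
    probability.  When the pooled proportion is 0 or 1 the variance vanishes
    and both rates are necessarily equal; p is set to 1 by convention and the
    returned ``degenerate`` flag marks those entries.

    Accepts scalars or arrays; requires positive coverages.
    """
    ip_m = np.asarray(ip_m, dtype=float)
    ip_c = np.asarray(ip_c, dtype=float)
    in_m = np.asarray(in_m, dtype=float)
    in_c = np.asarray(in_c, dtype=float)
    if np.any(ip_c <= 0) or np.any(in_c <= 0):
        raise ValueError("coverages must be positive")
    p1 = ip_m / ip_c
    p2 = in_m / in_c
    pooled = (ip_m + in_m) / (ip_c + in_c)
    var = pooled * (1.0 - pooled) * (1.0 / ip_c + 1.0 / in_c)
    degenerate = var <= 0
    z = np.divide(p1 - p2, np.sqrt(var, where=~degenerate, out=np.ones_like(var)),
                  where=~degenerate, out=np.zeros_like(var))
    p = stats.norm.sf(z)
    p = np.where(degenerate, 1.0, p)
    z = np.where(degenerate, 0.0, z)
    if z.ndim == 0:
        return float(z), float(p), bool(degenerate)
    return z, p, degenerate


def _aggregate(obs: pd.DataFrame, prefix: str) -> pd.DataFrame:
    agg = (
        obs.groupby(KEY, as_index=False)[["coverage", "mismatches"]]
        .sum()
        .rename(
            columns={
                "coverage": f"{prefix}_coverage",
                "mismatches": f"{prefix}_mismatches",
            }
        )
    )
    return agg


def call_sites(
    candidates: pd.DataFrame,
    ip_obs: pd.DataFrame,
    input_obs: pd.DataFrame,
    thresholds: CallingThresholds | None = None,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Apply the four calling criteria to candidate positions.

    Returns one row per called site with summed IP/input counts, rates, the
    Z statistic and its one-sided p-value.  A candidate with no input
    coverage fails the input-coverage criterion and is excluded.
    """
    t = thresholds or CallingThresholds()
    if candidates.empty:
        return _empty_sites()

    merged = candidates.merge(_aggregate(ip_obs, "ip"), on=KEY, how="left")
    merged = merged.merge(_aggregate(input_obs, "input"), on=KEY, how="left")
    merged[["ip_coverage", "ip_mismatches", "input_coverage", "input_mismatches"]] = (
        merged[
            ["ip_coverage", "ip_mismatches", "input_coverage", "input_mismatches"]
        ].fillna(0)
    )

    ok_cov = (merged["ip_coverage"] > t.call_coverage) & (
        merged["input_coverage"] > t.call_coverage
    )
    testable = ok_cov  # z-test requires both coverages positive anyway
    z = np.zeros(len(merged))
    p = np.ones(len(merged))
    if testable.any():
        zt, pt, _ = proportion_z_test(
            merged.loc[testable, "ip_mismatches"],
            merged.loc[testable, "ip_coverage"],
            merged.loc[testable, "input_mismatches"],
            merged.loc[testable, "input_coverage"],
        )
        z[testable.to_numpy()] = zt
        p[testable.to_numpy()] = pt
    merged["z"] = z
    merged["p"] = p

    called = (
        (merged["p"] < t.alpha)
        & ok_cov
        & (merged["ip_mismatches"] > t.call_mismatches)
        & (merged["ip_mismatches"] > merged["input_mismatches"])
    )
    if per_replicate:
        called &= _per_replicate_mask(merged, ip_obs, input_obs, t)

    out = merged[called].copy()
    out["ip_rate"] = out["ip_mismatches"] / out["ip_coverage"]
    out["input_rate"] = np.where(
        out["input_coverage"] > 0,
        out["input_mismatches"] / out["input_coverage"].replace(0, 1),
        0.0,
    )
    return out.sort_values(["chrom", "pos"]).reset_index(drop=True)


def _per_replicate_mask(
    merged: pd.DataFrame,
    ip_obs: pd.DataFrame,
    input_obs: pd.DataFrame,
    t: CallingThresholds,
) -> pd.Series:
    """Require the coverage/mismatch calling criteria in every IP replicate
    against every input replicate (the conservative reading)."""
    ip_ok = (
        ip_obs.assign(
            ok=(ip_obs["coverage"] > t.call_coverage)
            & (ip_obs["mismatches"] > t.call_mismatches)
        )
        .groupby(KEY)["ok"]
        .all()
    )
    in_ok = (
        input_obs.assign(ok=input_obs["coverage"] > t.call_coverage)
        .groupby(KEY)["ok"]
        .all()
    )
    keys = pd.MultiIndex.from_frame(merged[KEY])
    return pd.Series(
        ip_ok.reindex(keys, fill_value=False).to_numpy()
        & in_ok.reindex(keys, fill_value=False).to_numpy(),
        index=merged.index,
    )


def _empty_sites() -> pd.DataFrame:
    cols = KEY + [
        "ip_coverage",
        "ip_mismatches",
        "input_coverage",
        "input_mismatches",
        "z",
        "p",
        "ip_rate",
        "input_rate",
    ]
    return pd.DataFrame(columns=cols)


def call_pipeline(
    obs: pd.DataFrame,
    ip_samples: list[str],
    input_samples: list[str],
    thresholds: CallingThresholds | None = None,
    per_replicate: bool = False,
) -> pd.DataFrame:
    """Convenience wrapper: split observations by sample role, filter
    candidates on the IP replicates, and call sites."""
    ip_obs = obs[obs["sample"].isin(ip_samples)]
    input_obs = obs[obs["sample"].isin(input_samples)]
    cands = filter_candidates(ip_obs, thresholds)
    return call_sites(cands, ip_obs, input_obs, thresholds, per_replicate)


def sites_to_bed(sites: pd.DataFrame, models=None) -> pd.DataFrame:
    """BED6+ representation: name = gene:region (when region present),
    score = -log10 p capped at 1000."""
    name = sites["gene_id"].astype(str)
    if "region" in sites.columns:
        name = name + ":" + sites["region"].fillna("NA").astype(str)
    score = np.minimum(-np.log10(np.maximum(sites["p"], 1e-300)), 1000.0)
    return pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "start": sites["pos"],
            "end": sites["pos"] + 1,
            "name": name,
            "score": np.round(score, 3),
            "strand": sites["strand"],
            "ip_coverage": sites["ip_coverage"],
            "ip_mismatches": sites["ip_mismatches"],
            "input_coverage": sites["input_coverage"],
            "input_mismatches": sites["input_mismatches"],
        }
    )
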