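"""Candidate filter, pooled two-proportion Z-test, and the four calling
criteria — checked against closed-form values, an independent statsmodels
oracle, and a brute-force re-evaluation over all exonic adenosines."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from m1ascan import calling, pileup, synthetic
from m1ascan.calling import CallingThresholds, proportion_z_test


def _obs(rows):
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "pos", "offset", "strand", "sample",
                 "coverage", "mismatches"],
    )
    df["mismatch_rate"] = np.where(
        df["coverage"] > 0, df["mismatches"] / df["coverage"], 0.0
    )
    return df


class TestCandidateFilter:
    @pytest.mark.parametrize(
        "coverage,mismatches,accepted",
        [
            (10, 2, False),   # coverage must exceed 10, not equal it
            (100, 2, False),  # rate 0.02 <= 10%
            (11, 2, True),    # all strict bounds met (rate 2/11 ~ 0.18)
            (50, 1, False),   # fewer than 2 mismatches
            (50, 5, False),   # rate exactly 0.10 is not greater than 10%
        ],
    )
    def test_printed_thresholds(self, coverage, mismatches, accepted):
        obs = _obs([("g", "chr1", 5, 5, "+", "IP1", coverage, mismatches)])
        got = calling.filter_candidates(obs)
        assert (len(got) == 1) is accepted

    def test_candidates_pooled_across_replicates(self):
        obs = _obs(
            [
                ("g", "chr1", 5, 5, "+", "IP1", 5, 0),     # fails in IP1
                ("g", "chr1", 5, 5, "+", "IP2", 50, 10),   # passes in IP2
                ("g", "chr1", 9, 9, "+", "IP1", 50, 10),   # passes in IP1 only
            ]
        )
        got = calling.filter_candidates(obs)
        assert set(got["pos"]) == {5, 9}


class TestProportionZTest:
    def test_closed_form_value(self):
        # pooled phat = 22/200; z = (0.20-0.02)/sqrt(phat(1-phat)(1/100+1/100))
        z, p, _ = proportion_z_test(20, 100, 2, 100)
        assert z == pytest.approx(4.06790, abs=1e-4)
        assert p == pytest.approx(2.37e-5, rel=0.01)

    def test_equal_proportions(self):
        z, p, _ = proportion_z_test(5, 100, 5, 100)
        assert z == 0.0
        assert p == pytest.approx(0.5)

    def test_input_excess_gives_large_p(self):
        z, p, _ = proportion_z_test(2, 100, 20, 100)
        assert z < 0 and p > 0.5

    def test_degenerate_pooled_proportion(self):
        z, p, flag = proportion_z_test(0, 50, 0, 80)
        assert p == 1.0 and flag
        z, p, flag = proportion_z_test(50, 50, 80, 80)
        assert p == 1.0 and flag

    def test_matches_statsmodels_oracle(self):
        from statsmodels.stats.proportion import proportions_ztest

        rng = np.random.default_rng(42)
        for _ in range(50):
            c1, c2 = rng.integers(20, 500, size=2)
            m1 = rng.integers(1, c1)
            m2 = rng.integers(1, c2)
            z, p, _ = proportion_z_test(m1, c1, m2, c2)
            z_ref, p_ref = proportions_ztest(
                [m1, m2], [c1, c2], alternative="larger"
            )
            assert z == pytest.approx(z_ref, abs=1e-9)
            assert p == pytest.approx(p_ref, abs=1e-9)


class TestCallCriteria:
    def _pair(self, ip_c, ip_m, in_c, in_m):
        ip = _obs([("g", "chr1", 5, 5, "+", "IP1", ip_c, ip_m)])
        inp = _obs([("g", "chr1", 5, 5, "+", "IN1", in_c, in_m)])
        cands = ip[calling.KEY].drop_duplicates()
        return calling.call_sites(cands, ip, inp)

    def test_all_criteria_hold(self):
        got = self._pair(50, 8, 50, 1)
        assert len(got) == 1
        assert got.iloc[0]["p"] < 0.05

    def test_ip_mismatch_count_must_exceed_two(self):
        # "greater than 2": exactly 2 fails even when everything else passes
        got = self._pair(50, 2, 50, 0)
        assert got.empty

    def test_ip_mismatches_must_exceed_input(self):
        ip = _obs([("g", "chr1", 5, 5, "+", "IP1", 400, 4)])
        inp = _obs([("g", "chr1", 5, 5, "+", "IN1", 40, 4)])
        got = calling.call_sites(ip[calling.KEY], ip, inp)
        assert got.empty

    def test_input_coverage_criterion(self):
        got = self._pair(50, 10, 10, 0)  # input coverage not > 10
        assert got.empty

    def test_candidate_without_input_excluded(self):
        ip = _obs([("g", "chr1", 5, 5, "+", "IP1", 50, 10)])
        inp = _obs([("g2", "chr1", 99, 9, "+", "IN1", 50, 1)])
        got = calling.call_sites(ip[calling.KEY], ip, inp)
        assert got.empty

    def test_monotone_in_ip_mismatches(self):
        base = None
        for m in range(3, 40):
            got = self._pair(100, m, 100, 2)
            if base is None and len(got):
                base = m
            if base is not None:
                assert len(got) == 1, f"site lost at ip_m={m}"


def brute_force_call(obs, ip_samples, input_samples, t=None):
    """Naive re-evaluation of all criteria over every observed position."""
    t = t or CallingThresholds()
    keys = obs[calling.KEY].drop_duplicates()
    out = []
    for key in keys.itertuples(index=False):
        sub = obs[(obs["gene_id"] == key.gene_id) & (obs["pos"] == key.pos)]
        ip = sub[sub["sample"].isin(ip_samples)]
        inp = sub[sub["sample"].isin(input_samples)]
        candidate = any(
            (r.coverage > t.candidate_coverage)
            and (r.mismatches >= t.candidate_mismatches)
            and (r.coverage > 0 and r.mismatches / r.coverage > t.candidate_rate)
            for r in ip.itertuples(index=False)
        )
        if not candidate:
            continue
        ic, im = ip["coverage"].sum(), ip["mismatches"].sum()
        nc, nm = inp["coverage"].sum(), inp["mismatches"].sum()
        if not (ic > t.call_coverage and nc > t.call_coverage):
            continue
        if not (im > t.call_mismatches and im > nm):
            continue
        pooled = (im + nm) / (ic + nc)
        var = pooled * (1 - pooled) * (1 / ic + 1 / nc)
        p = 1.0 if var <= 0 else sps.norm.sf((im / ic - nm / nc) / np.sqrt(var))
        if p < t.alpha:
            out.append((key.gene_id, key.pos))
    return set(out)


class TestOracleEquivalence:
    def test_matches_brute_force_on_synthetic_genome(self, small_observations):
        obs = small_observations
        expected = brute_force_call(obs, ["IP1", "IP2"], ["IN1", "IN2"])
        got = calling.call_pipeline(obs, ["IP1", "IP2"], ["IN1", "IN2"])
        assert set(zip(got["gene_id"], got["pos"])) == expected

    def test_per_replicate_mode_is_stricter(self, small_observations):
        obs = small_observations
        pooled = calling.call_pipeline(obs, ["IP1", "IP2"], ["IN1", "IN2"])
        strict = calling.call_pipeline(
            obs, ["IP1", "IP2"], ["IN1", "IN2"], per_replicate=True
        )
        assert set(zip(strict["gene_id"], strict["pos"])) <= set(
            zip(pooled["gene_id"], pooled["pos"])
        )


class TestPlantedRecovery:
    def test_precision_recall_on_defaults(self, small_dataset, small_observations):
        ds = small_dataset
        got = calling.call_pipeline(
            small_observations, ["IP1", "IP2"], ["IN1", "IN2"]
        )
        truth = set(zip(ds.reference.truth_sites["gene_id"],
                        ds.reference.truth_sites["offset"]))
        called = set(zip(got["gene_id"], got["offset"]))
        tp = len(truth & called)
        assert tp / max(len(called), 1) >= 0.95
        assert tp / len(truth) >= 0.90
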