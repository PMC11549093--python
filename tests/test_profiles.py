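"""Region assignment, metagene normalization, motif summaries, sequence
features and the folding-provider interface."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from m1ascan import profiles
from m1ascan.profiles import (
    MotifSummary,
    ToyStemFolding,
    assign_regions,
    gc_fraction,
    metagene,
    motif_summary,
    sequence_features,
)
from m1ascan.reference_io import GeneModel, Genome


def _model(gene_id="g", u5=50, cds=200, u3=50, strand="+", start=0):
    L = u5 + cds + u3
    return GeneModel(
        gene_id, "chr1", strand, [(start, start + L)],
        cds_span=(u5, u5 + cds), utr5_span=(0, u5), utr3_span=(u5 + cds, L),
    )


def _sites(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "pos", "offset", "strand"])


class TestAssignRegions:
    def test_half_open_region_boundaries(self):
        m = _model()
        sites = _sites(
            [
                ("g", "chr1", 0, 49, "+"),    # last 5'UTR base
                ("g", "chr1", 0, 50, "+"),    # first CDS base
                ("g", "chr1", 0, 249, "+"),   # last CDS base (incl. stop)
                ("g", "chr1", 0, 250, "+"),   # first 3'UTR base
            ]
        )
        labeled, pct = assign_regions(sites, {"g": m})
        assert list(labeled["region"]) == ["5UTR", "CDS", "CDS", "3UTR"]
        assert pct["percent"].sum() == pytest.approx(100.0)

    def test_noncoding_model_site_unpartitioned(self):
        nc = GeneModel("nc", "chr1", "+", [(0, 100)], (0, 0), (0, 0), (0, 0))
        labeled, pct = assign_regions(_sites([("nc", "chr1", 0, 10, "+")]), {"nc": nc})
        assert labeled.iloc[0]["region"] == profiles.UNPARTITIONED
        assert pct.attrs["n_unpartitioned"] == 1
        assert pct["count"].sum() == 0

    def test_placement_recovery_with_truth(self, small_dataset):
        ref = small_dataset.reference
        labeled, _ = assign_regions(
            ref.truth_sites[["gene_id", "chrom", "pos", "offset", "strand"]],
            ref.models,
        )
        assert (labeled["region"] == ref.truth_sites["region"]).all()


class TestMetagene:
    def test_unit_area_and_boundaries(self):
        models = {"g": _model(u5=100, cds=200, u3=100)}
        sites = _sites([("g", "chr1", 0, off, "+") for off in (10, 150, 350)])
        labeled, _ = assign_regions(sites, models)
        prof = metagene(labeled, models, bins_per_region=10)
        assert prof.area() == pytest.approx(1.0)
        assert prof.boundaries == (pytest.approx(0.25), pytest.approx(0.75))

    def test_uniform_3utr_sites_give_flat_3utr_density(self):
        rng = np.random.default_rng(0)
        models = {f"g{i}": _model(f"g{i}") for i in range(20)}
        rows = []
        for i in range(20):
            for off in rng.integers(250, 300, size=50):
                rows.append((f"g{i}", "chr1", 0, int(off), "+"))
        labeled, _ = assign_regions(_sites(rows), models)
        prof = metagene(labeled, models, bins_per_region=10)
        frame = prof.to_frame()
        utr3 = frame[frame["bin_start"] >= prof.boundaries[1] - 1e-9]
        other = frame[frame["bin_start"] < prof.boundaries[1] - 1e-9]
        assert np.allclose(other["density"], 0.0)
        counts = (utr3["density"] * np.diff(prof.bin_edges)[-len(utr3):] * 1000).round()
        # expected bin masses from the 50 possible discrete site coordinates,
        # binned with the same histogram edges (offsets are integers, so bins
        # do not receive exactly equal probability after float rounding)
        one_gene = assign_regions(
            _sites([("g0", "chr1", 0, 250 + k, "+") for k in range(50)]),
            models,
        )[0]
        ref_prof = metagene(one_gene, models, bins_per_region=10)
        ref_frame = ref_prof.to_frame()
        ref_utr3 = ref_frame[ref_frame["bin_start"] >= ref_prof.boundaries[1] - 1e-9]
        expected = (
            ref_utr3["density"].to_numpy()
            * np.diff(ref_prof.bin_edges)[-len(ref_utr3):]
            * 1000
        )
        chi2 = ((counts.to_numpy() - expected) ** 2 / expected).sum()
        assert chi2 < sps.chi2.ppf(0.999, df=len(counts) - 1)

    def test_invariant_under_uniform_length_rescaling(self):
        sites = []
        models_a, models_b = {}, {}
        for i in range(5):
            models_a[f"g{i}"] = _model(f"g{i}", u5=20, cds=100, u3=40)
            models_b[f"g{i}"] = _model(f"g{i}", u5=60, cds=300, u3=120)
            sites.append((f"g{i}", "chr1", 0, 30 + i, "+"))  # CDS in model A
        la, _ = assign_regions(_sites(sites), models_a)
        sites_b = [(g, c, p, off * 3, s) for g, c, p, off, s in sites]
        lb, _ = assign_regions(_sites(sites_b), models_b)
        pa = metagene(la, models_a, bins_per_region=8)
        pb = metagene(lb, models_b, bins_per_region=8)
        assert np.allclose(pa.density, pb.density)
        assert np.allclose(pa.bin_edges, pb.bin_edges)


class TestMotifSummary:
    def _genome_models(self, tx="GGGCATTTTT"):
        genome = Genome({"chr1": tx})
        m = GeneModel("g", "chr1", "+", [(0, len(tx))], (0, 0), (0, 0), (0, 0))
        return genome, {"g": m}

    def test_single_site_upstream_trimer(self):
        genome, models = self._genome_models("GGCATTTTTT")  # site at offset 3
        sites = _sites([("g", "chr1", 3, 3, "+")])
        ms = motif_summary(sites, models, genome, window_up=3, window_down=3)
        assert ms.trimer_upstream.to_dict() == {"GGC": 1.0}
        assert ms.trimer_with_site.to_dict() == {"GCA": 1.0}

    def test_site_column_is_all_A(self, small_dataset):
        ref = small_dataset.reference
        ms = motif_summary(ref.truth_sites, ref.models, ref.genome)
        assert ms.pfm.loc["A", 0] == pytest.approx(1.0)

    def test_pfm_columns_stochastic(self, small_dataset):
        ref = small_dataset.reference
        ms = motif_summary(ref.truth_sites, ref.models, ref.genome)
        assert np.allclose(ms.pfm.sum(axis=0), 1.0)

    def test_planted_c_minus1_frequency(self):
        from m1ascan import synthetic

        cfg = synthetic.SimulationConfig(n_genes=600, seed=31, p_c_minus1=0.9)
        ref = synthetic.simulate_reference(cfg)
        ms = motif_summary(ref.truth_sites, ref.models, ref.genome)
        assert ms.pfm.loc["C", -1] == pytest.approx(0.9, abs=0.05)

    def test_truncated_windows_counted_and_excluded(self):
        genome, models = self._genome_models("ATTTTTTTTT")  # site at offset 0
        ms = motif_summary(
            _sites([("g", "chr1", 0, 0, "+")]), models, genome, 3, 3
        )
        assert ms.n_truncated == 1
        assert ms.pfm.sum().sum() == 0.0


class TestSequenceFeatures:
    def test_gc_extremes(self):
        assert gc_fraction("GCGC") == 1.0
        assert gc_fraction("ATAT") == 0.0

    def test_toy_folding_energy_per_nucleotide(self):
        # declared toy model: -1 per G-C pair folding ends inward
        genome = Genome({"chr1": "TTGGGAAACCC"})
        m = GeneModel(
            "g", "chr1", "+", [(0, 11)],
            cds_span=(0, 2), utr5_span=(0, 0), utr3_span=(2, 11),
        )
        gene_df, _ = sequence_features(
            {"g": m}, genome, folding=ToyStemFolding()
        )
        assert gene_df.iloc[0]["utr3_mfe_norm"] == pytest.approx(-3 / 9)

    def test_missing_utr3_gives_nulls(self):
        m = GeneModel("g", "chr1", "+", [(0, 9)],
                      cds_span=(0, 9), utr5_span=(0, 0), utr3_span=(9, 9))
        genome = Genome({"chr1": "ATGAAATAG"})
        gene_df, _ = sequence_features({"g": m}, genome, folding=ToyStemFolding())
        assert np.isnan(gene_df.iloc[0]["utr3_gc"])
        assert np.isnan(gene_df.iloc[0]["utr3_mfe_norm"])

    def test_neighborhood_gc_window(self):
        genome = Genome({"chr1": "GGGGGAGGGGG"})
        m = GeneModel("g", "chr1", "+", [(0, 11)], (0, 0), (0, 0), (0, 0))
        _, site_df = sequence_features(
            {"g": m}, genome, sites=_sites([("g", "chr1", 5, 5, "+")]),
            neighborhood=5,
        )
        assert site_df.iloc[0]["neighborhood_gc"] == pytest.approx(10 / 11)
        assert not site_df.iloc[0]["truncated"]
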