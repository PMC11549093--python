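"""End-to-end orchestration: ingest -> call -> annotate -> integrate -> TE.

`RunConfig` carries every file path and threshold (defaults are the
procedure's standard values: candidate coverage 10, mismatch count 2, rate
0.10, alpha 0.05, DMR fold change 1.5, flank 100 nt, RNA TPM 5); every
override is echoed into the run manifest together with input checksums and
per-stage row counts, so a rerun with identical inputs and config is
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import calling, expression, merip, pileup, profiles, reference_io

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome: str = ""
    gtf: str = ""
    pileups: str = ""  # 6-column TSV (all samples)
    ip_samples: list[str] = field(default_factory=lambda: ["IP1", "IP2"])
    input_samples: list[str] = field(default_factory=lambda: ["IN1", "IN2"])
    peaks: str = ""  # BED: chrom start end peak_id gene_id strand
    peak_counts: str = ""  # TSV matrix peak_id x samples
    dmr_condition_a: list[str] = field(
        default_factory=lambda: ["IP_str_1", "IP_str_2"]
    )
    dmr_condition_b: list[str] = field(
        default_factory=lambda: ["IP_ctrl_1", "IP_ctrl_2"]
    )
    expression_control: str = ""
    expression_stress: str = ""
    out_dir: str = "m1a_out"
    seed: int = 0
    # thresholds (procedure defaults)
    candidate_coverage: int = 10
    candidate_mismatches: int = 2
    candidate_rate: float = 0.10
    alpha: float = 0.05
    call_coverage: int = 10
    call_mismatches: int = 2
    dmr_fc: float = 1.5
    dmr_alpha: float = 0.05
    flank: int = 100
    rna_tpm_min: float = 5.0
    bins_per_region: int = 30

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def thresholds(self) -> calling.CallingThresholds:
        return calling.CallingThresholds(
            candidate_coverage=self.candidate_coverage,
            candidate_mismatches=self.candidate_mismatches,
            candidate_rate=self.candidate_rate,
            alpha=self.alpha,
            call_coverage=self.call_coverage,
            call_mismatches=self.call_mismatches,
        )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _checksum(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages in dependency order; returns the manifest.

    Stages whose inputs are not configured are skipped and recorded as such.
    On stage failure a :class:`StageError` names the failing stage; outputs
    written so far stay on disk with a ``.partial`` marker file.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    marker.touch()
    manifest: dict = {
        "config": asdict(cfg),
        "inputs": {},
        "stages": {},
    }
    for key in ("genome", "gtf", "pileups", "peaks", "peak_counts",
                "expression_control", "expression_stress"):
        p = getattr(cfg, key)
        if p:
            if not Path(p).exists():
                raise StageError("reference_io" if key in ("genome", "gtf") else key,
                                 FileNotFoundError(p))
            manifest["inputs"][key] = {"path": str(p), "md5": _checksum(p)}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                counts = fn()
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - report failing stage
                raise StageError(name, exc) from exc
            manifest["stages"][name] = {
                "elapsed_s": round(time.time() - t0, 3),
                **(counts or {}),
            }
            logger.info("stage %s done in %.2fs %s", name,
                        time.time() - t0, counts)
            return counts

        return deco

    state: dict = {}

    @stage("reference_io")
    def _load_ref():
        if not cfg.genome or not cfg.gtf:
            raise FileNotFoundError("genome and gtf are required")
        genome = reference_io.Genome(cfg.genome)
        models = reference_io.load_gene_models(cfg.gtf, genome)
        state["genome"], state["models"] = genome, models
        return {"n_genes": len(models)}

    @stage("pileup_ingest")
    def _ingest():
        if not cfg.pileups:
            return {"skipped": True}
        table = pileup.parse_pileup(cfg.pileups)
        obs = pileup.extract_adenosine_observations(
            table, state["models"], state["genome"]
        )
        state["obs"] = obs
        return {"n_rows": len(table), "n_observations": len(obs)}

    @stage("site_calling")
    def _call():
        if "obs" not in state:
            return {"skipped": True}
        sites = calling.call_pipeline(
            state["obs"], cfg.ip_samples, cfg.input_samples, cfg.thresholds()
        )
        state["sites"] = sites
        return {"n_sites": len(sites)}

    @stage("annotation_profiles")
    def _annotate():
        if "sites" not in state:
            return {"skipped": True}
        sites, pct = profiles.assign_regions(state["sites"], state["models"])
        sites = profiles.attach_context(sites, state["models"], state["genome"])
        state["sites"] = sites
        sites.to_csv(out / "sites.tsv", sep="\t", index=False)
        calling.sites_to_bed(sites).to_csv(
            out / "sites.bed", sep="\t", index=False, header=False
        )
        pct.to_csv(out / "region_percentages.tsv", sep="\t", index=False)
        info = {"n_sites": len(sites)}
        if len(sites):
            prof = profiles.metagene(sites, state["models"], cfg.bins_per_region)
            prof.to_frame().to_csv(out / "metagene.tsv", sep="\t", index=False)
            motif = profiles.motif_summary(sites, state["models"], state["genome"])
            motif.pfm.to_csv(out / "pfm.tsv", sep="\t")
            motif.trimer_upstream.to_csv(out / "trimer_upstream.tsv", sep="\t")
            info["metagene_area"] = prof.area()
        return info

    @stage("merip_integration")
    def _integrate():
        if not cfg.peaks or not cfg.peak_counts or "sites" not in state:
            return {"skipped": True}
        peaks = pd.read_csv(
            cfg.peaks,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "peak_id", "gene_id", "strand"],
        )
        counts = pd.read_csv(cfg.peak_counts, sep="\t", index_col=0)
        peaks, shared = merip.overlap_peaks_sites(peaks, state["sites"], cfg.flank)
        dmr = merip.differential_regions(
            peaks,
            counts,
            merip.DmrDesign(cfg.dmr_condition_a, cfg.dmr_condition_b),
            fc_threshold=cfg.dmr_fc,
            alpha=cfg.dmr_alpha,
        )
        state["dmr"] = dmr
        dmr.to_csv(out / "dmr.tsv", sep="\t", index=False)
        return {
            "n_peaks": len(peaks),
            "n_shared_genes": len(shared),
            "n_up": int((dmr["status"] == "up").sum()),
            "n_down": int((dmr["status"] == "down").sum()),
        }

    @stage("expression_te")
    def _te():
        if not cfg.expression_control:
            return {"skipped": True}
        expr = pd.read_csv(cfg.expression_control, sep="\t")
        te_ctrl = expression.compute_te(expr, cfg.rna_tpm_min)
        if "sites" in state:
            per_gene = state["sites"].groupby("gene_id").size()
            te_ctrl["m1a_site_count"] = (
                te_ctrl["gene_id"].map(per_gene).fillna(0).astype(int)
            )
            if "region" in state["sites"].columns:
                regions = (
                    state["sites"].groupby("gene_id")["region"]
                    .apply(lambda s: ",".join(
                        sorted(set(s) - {None, profiles.UNPARTITIONED})))
                )
                te_ctrl["m1a_regions"] = te_ctrl["gene_id"].map(regions).fillna("")
        te_ctrl.to_csv(out / "te_control.tsv", sep="\t", index=False)
        state["te_control"] = te_ctrl
        info = {"n_genes": len(te_ctrl),
                "n_te_eligible": int(te_ctrl["te_eligible"].sum())}
        if cfg.expression_stress:
            te_str = expression.compute_te(
                pd.read_csv(cfg.expression_stress, sep="\t"), cfg.rna_tpm_min
            )
            te_str.to_csv(out / "te_stress.tsv", sep="\t", index=False)
            state["te_stress"] = te_str
            if "dmr" in state:
                table, comps = expression.te_change_by_dmr(
                    te_ctrl, te_str, merip.gene_dmr_status(state["dmr"])
                )
                table.to_csv(out / "delta_te.tsv", sep="\t", index=False)
                info["n_delta_te"] = len(table)
        return info

    manifest["stages_order"] = list(manifest["stages"])
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    marker.unlink(missing_ok=True)
    state["manifest"] = manifest
    return state
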