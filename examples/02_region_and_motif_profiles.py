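"""Annotate called sites: region split, metagene profile, sequence context.

Reproduces the distributional fingerprints the analysis looks for: the strong
3'UTR bias of site placement, the length-normalized metagene density, and the
C-rich -1 position that forms the NNCA context.
"""

from m1ascan import calling, pileup, profiles, synthetic

ds = synthetic.simulate_dataset(synthetic.SimulationConfig(n_genes=300, seed=42))
obs = pileup.extract_adenosine_observations(
    ds.pileups, ds.reference.models, ds.reference.genome
)
sites = calling.call_pipeline(obs, ["IP1", "IP2"], ["IN1", "IN2"])

labeled, pct = profiles.assign_regions(sites, ds.reference.models)
print("region split of called sites (percent):")
print(pct.to_string(index=False))

prof = profiles.metagene(labeled, ds.reference.models)
print(f"\nmetagene density area: {prof.area():.6f} (unit by construction)")
print(f"5'UTR/CDS and CDS/3'UTR junctions on the axis: "
      f"{prof.boundaries[0]:.3f}, {prof.boundaries[1]:.3f}")

motif = profiles.motif_summary(labeled, ds.reference.models, ds.reference.genome)
print(f"\nC frequency at position -1: {motif.pfm.loc['C', -1]:.3f}")
print("top upstream 3-mers (positions -3..-1):")
print(motif.trimer_upstream.sort_values(ascending=False).head(5).to_string())
print()
print("The -1 C enrichment is the planted NNCA-style context; segment widths")
print("on the metagene axis are proportional to mean annotated region lengths.")
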