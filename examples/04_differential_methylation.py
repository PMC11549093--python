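"""MeRIP peak reconciliation and stress-response differential methylation.

Flags MeRIP peaks that intersect the 100-nt flanks of single-base sites,
calls differential methylation regions between stress and control with the
common-dispersion NB exact test, and compares per-gene TE changes across the
DMR classes: genes that lose methylation under stress escape the global
translational slowdown, genes that gain it are repressed hardest.
"""

from m1ascan import expression, merip, synthetic

ds = synthetic.simulate_dataset(synthetic.SimulationConfig(n_genes=400, seed=42))
peaks, shared = merip.overlap_peaks_sites(ds.peaks, ds.reference.truth_sites, flank=100)
print(f"peaks: {len(peaks)}; overlapping a site flank: "
      f"{int(peaks['overlaps_site'].sum())}; shared genes: {len(shared)}")

design = merip.DmrDesign(["IP_str_1", "IP_str_2"], ["IP_ctrl_1", "IP_ctrl_2"])
dmr = merip.differential_regions(peaks, ds.peak_counts, design)
print(f"DMRs (fold change > 1.5, p < 0.05, site-supported): "
      f"{int((dmr['status'] == 'up').sum())} up, "
      f"{int((dmr['status'] == 'down').sum())} down")
print(f"common NB dispersion (method of moments): {dmr.attrs['dispersion']:.4f}")

te_c = expression.compute_te(ds.expression_control)
te_s = expression.compute_te(ds.expression_stress)
table, comps = expression.te_change_by_dmr(te_c, te_s, merip.gene_dmr_status(dmr))
print("\nmedian log2 TE change (stress vs control) by DMR class:")
print(table.groupby("dmr_class")["delta_te"].median().round(3).to_string())
for cmp in comps:
    print(f"  {cmp.groups[0]} vs unchanged: p = {cmp.p:.3g}")
print()
print("Ordering up < unchanged < down reflects the planted structure: added")
print("methylation represses translation further, lost methylation exempts a")
print("gene from the global stress slowdown (classes are relative to the")
print("within-sample TPM normalization).")
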