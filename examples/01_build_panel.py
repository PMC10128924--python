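"""Build a diagnostic SNV panel from two parental call sets.

A site is diagnostic when both (isogenized, effectively haploid)
parental lines have a confident call and the alleles differ; only such
sites can assign parental origin in offspring.  Sparse regions are
masked because short conversion tracts cannot be detected there.
"""

from invrec import (
    ParentalCallSet,
    build_diagnostic_panel,
    mask_low_density,
    snv_density_windows,
    synthetic_panel,
)

# a tiny hand-made pair of call sets
p1 = ParentalCallSet.from_pairs("chrX", [(100, b"A"), (200, b"C"), (300, b"G"), (400, b"T")])
p2 = ParentalCallSet.from_pairs("chrX", [(100, b"A"), (200, b"T"), (300, b"C")])
panel = build_diagnostic_panel(p1, p2, chrom_length=1000)
print(f"hand-made example: {panel.n_sites} diagnostic sites at {panel.positions.tolist()}")
print("  (site 100 is shared-identical, site 400 lacks a P2 call: both dropped)")

# a realistic chromosome: ~1 marker per 367 bp, with a sparse distal
# region (~1 per 81.5 kb) emulating shared ancestry near the telomere
panel = synthetic_panel(seed=1)
profile = snv_density_windows(panel)  # 50 kb windows, 25 kb step
masked = mask_low_density(panel, profile, min_sites_per_window=10)
print(f"\nsynthetic chrX: {panel.n_sites} sites, "
      f"mean spacing {panel.mean_spacing(6_000_000, 7_000_000):.0f} bp in the dense region")
spans = masked.masked_spans()
print(f"masked {masked.n_sites - masked.n_unmasked} sites in the sparse region "
      f"({spans[0][0]/1e6:.2f}-{spans[-1][1]/1e6:.2f} Mb): too few markers to see ~400 bp tracts")
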