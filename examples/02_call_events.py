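"""Call crossovers and gene conversions from an offspring origin vector.

A persistent switch in parental origin is a crossover (CO); a short
tract of the other parent flanked by the original origin is a
noncrossover gene conversion (NCOGC).  Events carry flanking-marker
uncertainty intervals; weakly supported switches are left unresolved.
"""

import numpy as np

from invrec import MarkerPanel, OffspringObservation, assign_parental_origin, call_events

positions = np.arange(1, 13) * 1000
panel = MarkerPanel(
    "chrX", 14_000, positions,
    allele_p1=np.full(12, b"A"), allele_p2=np.full(12, b"T"),
)

# offspring genotype: P1 background, a 2-site conversion tract at
# 4-5 kb, then a crossover at ~9.5 kb (switches to P2 for good)
alleles = np.array(list("AAATTAAAATTT")).astype("S1")
vec = assign_parental_origin(OffspringObservation("off1", alleles), panel)
print("origin vector:", "".join("12"[c] for c in vec.calls))

result = call_events(vec, panel, min_support_co=2, max_ncogc_span=10_000)
for e in result.events:
    print(f"{e.event_class}: interval ({e.left_flank}, {e.right_flank}] bp, "
          f"{e.n_support} supporting sites"
          + (f", converted sites {e.converted_sites}" if e.converted_sites else ""))
print("the NCOGC is the 2-site island returning to P1; the CO switch persists to the end")
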