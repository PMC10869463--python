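"""Design KASP assays for flanked SNP sites and QC genotyped markers.

Builds random 100-bp flanks, searches primer lengths and placements under the
assay constraints (GC < 60%, Tm 55-62 degC, product <= 120 bp), and prints
the transformation rate plus one example assay. Then classifies a marker's
genotype calls into the QC categories used to screen a candidate panel.
"""

from radfp import FlankedSite, design_assay, classify_marker, simulate_flanks

sites = [FlankedSite(sid, ref, alt, up, down)
         for sid, up, ref, alt, down in simulate_flanks(100, seed=7)]
assays = [design_assay(s) for s in sites]
feasible = [a for a in assays if a.feasible]
print(f"transformation rate: {len(feasible)}/{len(assays)} "
      f"({len(feasible) / len(assays):.0%})")

a = feasible[0]
print(f"example assay for {a.site_id}: product {a.product_size} bp, "
      f"Tm(common) {a.tm['common']:.1f} C, GC(common) {a.gc['common']:.2f}")
print(f"  FAM primer: {a.fam_primer}")
print(f"  HEX primer: {a.hex_primer}")

calls = ["AA"] * 150 + ["AG"] * 120 + ["GG"] * 50 + ["NN"] * 36
verdict = classify_marker(calls)
print(f"marker QC: {verdict.category} (no-call rate {verdict.no_call_rate:.1%})")
# Markers with >10% no-calls are excluded from the core panel, mirroring
# post-genotyping screening of KASP candidates.
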