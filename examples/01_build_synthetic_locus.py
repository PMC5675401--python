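"""Build the default synthetic locus and inspect its architecture.

The generator emulates a ~10 kb multicopy maize gene: a distal enhancer with
no siRNA source ~5 kb upstream, a proximal enhancer carrying a MULE fragment
with inverted repeats just upstream of the TSS, three exons, and intron-2
sub-regions with a Stowaway-like MITE. The planted truth (per-region
methylation probabilities, siRNA sources, expression effects) is what the
analysis stages later recover.
"""

from epilocus import build_locus

locus, truth = build_locus(seed=7)

print(f"locus {locus.id}: {len(locus)} bp, TSS at array position {locus.tss_array_pos}")
print(f"{'feature':<18}{'class':<18}{'start':>7}{'end':>7}")
for feat in locus.features:
    print(f"{feat.name:<18}{feat.klass.value:<18}{feat.start:>7}{feat.end:>7}")

print("\nplanted 24-nt siRNA sources (wild-type vs mutant weight):")
for src in truth.sirna_sources:
    if src.size_mix.get(24, 0) > 0:
        print(f"  {src.name:<10} [{src.start:>6}, {src.end:>6}]  "
              f"wt={src.weights['wildtype']:<5} mut={src.weights['mutant']}")

de = truth.region_meth["Int2-2"]
print("\nplanted Int2-2 methylation probabilities:")
for ctx in ("CG", "CHG", "CHH"):
    print(f"  {ctx:<4} wild-type {de[ctx]['wildtype']:.2f}  mutant {de[ctx]['mutant']:.2f}")
# Coordinates are TSS-relative and skip 0 (the TSS is +1, the base upstream
# of it is -1); the mutant genotype models loss of the 24-nt siRNA pathway.
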