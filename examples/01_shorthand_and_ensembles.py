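"""Genotype shorthand and resistance-ensemble classification.

Kdr genotypes concatenate unordered allele pairs at sodium-channel residues
989/1016/1534 ("SSGIFC"), or at 1016/1534 only when 989 was not assayed
("GIFC").  Two resistance ensembles are tracked: 1016I+1534C (Western
Hemisphere) and 989P+1016G (Indopacific).
"""

from kdrcall import classify_ensemble, format_shorthand, parse_shorthand

for text in ["SSVVFF", "SSIICC", "PPGGFF", "SPGIFC", "GIFC", "VGFC"]:
    g = parse_shorthand(text)
    label = classify_ensemble(g).value
    print(f"{text:>7}  ->  {g.to_dict()}  [{label}]")

# Pairs are unordered; formatting always uses the canonical print order.
g = parse_shorthand("SSGIFC")
print("\nround-trip:", format_shorthand(g), "== SSGIFC")
print("1016 alleles (unordered):", g["1016"].alleles)
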