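# kdrcall

Multi-assay knockdown-resistance (kdr) genotyping for *Aedes aegypti*.

Pyrethroid resistance in *Ae. aegypti* is driven by substitutions in the
voltage-gated sodium channel, tracked at three residues (standard *Musca
domestica* numbering): 989 (S→P), 1016 (V→I or V→G) and 1534 (F→C).  Two
ensembles dominate: **1016I + 1534C** in the Western Hemisphere and
**989P + 1016G** in the Indopacific.  Surveillance labs genotype these loci
with allele-specific melt-curve assays (MCA), allele-specific PCR (AS-PCR),
Sanger sequencing and barcoded amplicon sequencing — and each surrogate
assay can be fooled by an allele it was not designed for: the 1016G product
co-melts with 1016V in the V1016I MCA, 1016I reads as non-G in the V1016G
MCA, and 1016I amplifies weakly in the 1016V AS-PCR reaction.  A very
resistant allele can masquerade as wild type.

`kdrcall` is a library for doing this genotyping defensibly:

- **Genotype model** — unordered diploid allele pairs at 989/1016/1534,
  the field's shorthand strings (`SSGIFC`, `VGFC`), and resistance-ensemble
  classification (`western_hemisphere` / `indopacific` / `mixed` / …).
- **Melt-curve calling** — derivative-peak detection and the ±0.3 °C
  control-window rule, with run validation against homozygous,
  heterozygous and negative controls.
- **Assay confusability logic** — each assay is modelled as an
  allele→observable-class map; an observation constrains the genotype to a
  set, and `resolve_1016` intersects constraints across methods.  The two
  1016 MCAs together are provably injective over all six diploid genotypes
  (each alone is not); alleles are *confirmed* when independently detected
  by ≥ 2 methods.
- **Amplicon-read genotyping** — mean-Q10 read filtering, both-end barcode
  demultiplexing (> 37 aligned bases at > 95 % identity per end), internal
  semi-global alignment to a reference panel, per-codon pileups with the
  100× coverage rule, and COI-consensus species verification at 99 %
  identity.
- **Screening workflows** — control-panel completeness checks, and the
  reflex ("gatekeeper") strategy that exploits the G–F / I–C haplotype
  linkage: first-tier V1016I + F1534C, with 1534F-bearing samples reflexed
  to V1016G and S989P.
- **Synthetic data** — generators for melt curves, Hardy–Weinberg cohorts
  (with haplotype linkage), barcoded diploid amplicon reads and
  multi-method observation records, plus a packaged transcription of an
  18-row multi-method genotyping comparison table used as the worked
  example throughout.

## Worked example

```bash
python examples/04_amplicon_genotyping.py
```

```
true genotype:   SPGIFC
called genotype: SPGIFC (called)
reads: 800 total, 800 pass Q10, 705 assigned
aligned coverage: {'M1': 176, 'M2': 182, 'M3': 175, 'COI': 172}
  1016: GI  fractions {'G': 0.422, 'I': 0.53, 'V': 0.006, 'other': 0.042}
  1534: FC  fractions {'C': 0.509, 'F': 0.449, 'other': 0.042}
  989: SP  fractions {'P': 0.358, 'S': 0.556, 'other': 0.086}
species: Aedes aegypti (synthetic) (AAEG-SYN-1) at 100.00% identity, pass=True
```

A mixed-ensemble heterozygote (989 S/P, 1016 G/I, 1534 F/C) is simulated at
200× per amplicon with 5 % substitution error and recovered exactly:
allele fractions near 0.5 mark heterozygous loci, the small `other`
fraction is residual sequencing error, and the sample would have been
excluded had any amplicon dropped below 100× aligned coverage.  The other
examples (`examples/01…05`) walk through shorthand parsing, melt-curve
calling, cross-assay resolution, and reflex screening, each printing the
numbers it computes.

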