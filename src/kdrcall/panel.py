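"""Amplicon reference panel with annotated kdr codon positions.

The panel holds the four amplicons pooled per sample — M1 (carries codon
989), M2 (1016), M3 (1534) and the COI barcode — plus a local COI reference
set for species identification.  The packaged default panel is *synthetic*:
codon positions and per-locus codon tables are real (standard sodium-channel
codons: 1016 GTA=V / ATA=I / GGA=G, 1534 TTC=F / TGC=C, 989 TCC=S / CCC=P),
but the flanking sequence is random at a fixed seed, standing in for genome
slices the user can supply as FASTA.  Codon tables are data, not code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Amplicon",
    "CoiReference",
    "ReferencePanel",
    "CODON_TABLES",
    "REFERENCE_CODONS",
    "default_panel",
    "write_panel",
    "load_panel",
]

#: codon -> amino-acid symbol per locus; unknown codons pool as "other".
CODON_TABLES: Mapping[str, Mapping[str, str]] = {
    "989": {"TCC": "S", "CCC": "P"},
    "1016": {"GTA": "V", "ATA": "I", "GGA": "G"},
    "1534": {"TTC": "F", "TGC": "C"},
}

#: sense-strand codon of the susceptible reference allele at each locus.
REFERENCE_CODONS: Mapping[str, str] = {"989": "TCC", "1016": "GTA", "1534": "TTC"}

#: fixed seed for the synthetic panel flanks — panel identity, not a tunable.
_PANEL_SEED = 15_00863


@dataclass(frozen=True)
class Amplicon:
    """One reference amplicon; ``codon_starts`` maps locus name to the
    0-based sense-strand start of its codon."""

    name: str
    sequence: str
    codon_starts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if set(seq) - set("ACGTN"):
            raise ValueError(f"{self.name}: non-ACGTN characters in sequence")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "codon_starts", dict(self.codon_starts))
        for locus, start in self.codon_starts.items():
            if not (0 <= start and start + 3 <= len(seq)):
                raise ValueError(f"{self.name}: codon for {locus} out of bounds")

    def codon(self, locus: str) -> str:
        start = self.codon_starts[locus]
        return self.sequence[start : start + 3]


@dataclass(frozen=True)
class CoiReference:
    taxon: str
    accession: str
    sequence: str


@dataclass(frozen=True)
class ReferencePanel:
    amplicons: tuple[Amplicon, ...]
    coi_references: tuple[CoiReference, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplicons", tuple(self.amplicons))
        object.__setattr__(self, "coi_references", tuple(self.coi_references))
        names = [a.name for a in self.amplicons]
        if len(set(names)) != len(names):
            raise ValueError("duplicate amplicon names")
        carriers: dict[str, str] = {}
        for amp in self.amplicons:
            for locus in amp.codon_starts:
                if locus in carriers:
                    raise ValueError(f"locus {locus} annotated on two amplicons")
                carriers[locus] = amp.name

    def amplicon(self, name: str) -> Amplicon:
        for a in self.amplicons:
            if a.name == name:
                return a
        raise KeyError(name)

    def carrier(self, locus: str) -> Amplicon:
        """The amplicon carrying a locus's codon."""
        for a in self.amplicons:
            if locus in a.codon_starts:
                return a
        raise KeyError(f"locus {locus} not annotated on this panel")

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(l for a in self.amplicons for l in a.codon_starts)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _with_codon(rng: np.random.Generator, length: int, codon: str, start: int) -> str:
    seq = list(_random_seq(rng, length))
    seq[start : start + 3] = codon
    return "".join(seq)


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    out = list(seq)
    sites = rng.choice(len(seq), size=n_subs, replace=False)
    for i in sites:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def default_panel() -> ReferencePanel:
    """The packaged synthetic panel (deterministic).

    Amplicon sizes bracket typical kdr/COI amplicons (COI is the 658-bp
    barcode region); each kdr codon sits mid-amplicon.  COI references: two
    synthetic *Ae. aegypti* haplotypes (the amplicon itself and a 6-
    substitution variant) and a ~12%-divergent congener stand-in, labelled
    with synthetic accessions.
    """
    rng = np.random.default_rng(_PANEL_SEED)
    m1 = Amplicon("M1", _with_codon(rng, 420, REFERENCE_CODONS["989"], 198), {"989": 198})
    m2 = Amplicon("M2", _with_codon(rng, 650, REFERENCE_CODONS["1016"], 301), {"1016": 301})
    m3 = Amplicon("M3", _with_codon(rng, 400, REFERENCE_CODONS["1534"], 187), {"1534": 187})
    coi_seq = _random_seq(rng, 658)
    coi = Amplicon("COI", coi_seq)
    refs = (
        CoiReference("Aedes aegypti (synthetic)", "AAEG-SYN-1", coi_seq),
        CoiReference("Aedes aegypti (synthetic)", "AAEG-SYN-2", _mutate(rng, coi_seq, 6)),
        CoiReference("Aedes albopictus (synthetic)", "AALB-SYN-1", _mutate(rng, coi_seq, 80)),
    )
    return ReferencePanel((m1, m2, m3, coi), refs)


def write_panel(panel: ReferencePanel, fasta_path: str | Path, json_path: str | Path) -> None:
    """Write the panel as FASTA plus a JSON sidecar of codon annotations."""
    records = [
        SeqRecord(Seq(a.sequence), id=a.name, description="amplicon")
        for a in panel.amplicons
    ] + [
        SeqRecord(Seq(r.sequence), id=r.accession, description=f"COI {r.taxon}")
        for r in panel.coi_references
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    meta = {
        "amplicons": {a.name: a.codon_starts for a in panel.amplicons},
        "coi_references": [
            {"taxon": r.taxon, "accession": r.accession} for r in panel.coi_references
        ],
    }
    Path(json_path).write_text(json.dumps(meta, indent=2))


def load_panel(fasta_path: str | Path, json_path: str | Path) -> ReferencePanel:
    meta = json.loads(Path(json_path).read_text())
    seqs = {r.id: str(r.seq) for r in SeqIO.parse(str(fasta_path), "fasta")}
    amplicons = tuple(
        Amplicon(name, seqs[name], starts) for name, starts in meta["amplicons"].items()
    )
    refs = tuple(
        CoiReference(r["taxon"], r["accession"], seqs[r["accession"]])
        for r in meta["coi_references"]
    )
    return ReferencePanel(amplicons, refs)
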