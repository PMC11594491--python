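"""Core domain types for kdr loci, alleles, and diploid genotypes.

Knockdown resistance (kdr) in *Aedes aegypti* is tracked at three residues of
the voltage-gated sodium channel, numbered by the standard *Musca domestica*
convention: 989 (S/P), 1016 (V/I/G) and 1534 (F/C).  Genotypes are written as
concatenated unordered allele pairs in a fixed per-locus print order, e.g.
``SSGIFC`` (989 S/S, 1016 G/I, 1534 F/C) or the 4-letter form ``GIFC`` when
989 was not assayed.  Two geographically structured resistance ensembles are
distinguished: 1016I + 1534C (Western Hemisphere) and 989P + 1016G
(Indopacific).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

__all__ = [
    "Locus",
    "DiploidGenotype",
    "MultiLocusGenotype",
    "EnsembleClass",
    "ShorthandError",
    "IncompleteGenotypeError",
    "LOCUS_989",
    "LOCUS_1016",
    "LOCUS_1534",
    "LOCI",
    "parse_shorthand",
    "format_shorthand",
    "classify_ensemble",
    "enumerate_diploid_genotypes",
]


class ShorthandError(ValueError):
    """Raised for a malformed shorthand genotype string.

    ``position`` is the 1-based index of the offending letter, or ``None``
    when the length itself is wrong.
    """

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class IncompleteGenotypeError(ValueError):
    """Raised when a required locus call is missing."""


@dataclass(frozen=True)
class Locus:
    """A sodium-channel residue under surveillance.

    ``canonical_order`` fixes the print order of alleles in shorthand strings
    (it is data, not code: the order is inferred from how field reports print
    genotypes, e.g. "VGFC" and "GIFC" imply V < G < I at 1016).
    """

    name: str
    residue_number: int
    reference_allele: str
    alternate_alleles: tuple[str, ...]
    canonical_order: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.reference_allele in self.alternate_alleles:
            raise ValueError(f"reference allele {self.reference_allele} repeated in alternates")
        expected = {self.reference_allele, *self.alternate_alleles}
        if set(self.canonical_order) != expected or len(self.canonical_order) != len(expected):
            raise ValueError(f"canonical_order must be a permutation of {sorted(expected)}")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset(self.canonical_order)

    def allele_rank(self, allele: str) -> int:
        try:
            return self.canonical_order.index(allele)
        except ValueError:
            raise ValueError(f"{allele!r} is not an allele of locus {self.name}") from None


LOCUS_989 = Locus("989", 989, "S", ("P",), ("S", "P"))
LOCUS_1016 = Locus("1016", 1016, "V", ("I", "G"), ("V", "G", "I"))
LOCUS_1534 = Locus("1534", 1534, "F", ("C",), ("F", "C"))

#: Packaged loci keyed by name, in genomic (shorthand) order.
LOCI: Mapping[str, Locus] = {"989": LOCUS_989, "1016": LOCUS_1016, "1534": LOCUS_1534}

_SHORTHAND_6 = (LOCUS_989, LOCUS_1016, LOCUS_1534)
_SHORTHAND_4 = (LOCUS_1016, LOCUS_1534)


@dataclass(frozen=True)
class DiploidGenotype:
    """An unordered pair of alleles at one locus.

    The pair is stored in the locus's canonical order so that equality and
    hashing ignore input order: ``DiploidGenotype(L1016, ("I", "G")) ==
    DiploidGenotype(L1016, ("G", "I"))``.
    """

    locus: Locus
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        a, b = self.alleles
        for sym in (a, b):
            if sym not in self.locus.alleles:
                raise ValueError(f"{sym!r} is not an allele of locus {self.locus.name}")
        ordered = tuple(sorted((a, b), key=self.locus.allele_rank))
        object.__setattr__(self, "alleles", ordered)

    def __contains__(self, allele: str) -> bool:
        return allele in self.alleles

    def count(self, allele: str) -> int:
        return self.alleles.count(allele)

    @property
    def is_homozygous(self) -> bool:
        return self.alleles[0] == self.alleles[1]

    def format(self) -> str:
        return "".join(self.alleles)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.locus.name}:{self.format()}"


class EnsembleClass(Enum):
    """Resistance-ensemble classification of a multi-locus genotype."""

    SUSCEPTIBLE_LIKE = "susceptible_like"
    WESTERN_HEMISPHERE = "western_hemisphere"
    INDOPACIFIC = "indopacific"
    MIXED = "mixed"
    OTHER = "other"


@dataclass(frozen=True)
class MultiLocusGenotype:
    """Unordered diploid calls at 989 (optional), 1016 and 1534.

    A missing 989 call means "not assayed", not "989 S/S": the 4-letter
    shorthand used for melt-curve results never asserts 989.
    """

    calls: tuple[DiploidGenotype, ...]

    def __init__(self, calls: Iterable[DiploidGenotype]):
        by_locus: dict[str, DiploidGenotype] = {}
        for c in calls:
            if c.locus.name in by_locus:
                raise ValueError(f"duplicate call for locus {c.locus.name}")
            by_locus[c.locus.name] = c
        ordered = tuple(
            by_locus[loc.name] for loc in _SHORTHAND_6 if loc.name in by_locus
        )
        if len(ordered) != len(by_locus):
            unknown = set(by_locus) - {loc.name for loc in _SHORTHAND_6}
            raise ValueError(f"unknown loci: {sorted(unknown)}")
        object.__setattr__(self, "calls", ordered)

    def get(self, locus: str | Locus) -> DiploidGenotype | None:
        name = locus.name if isinstance(locus, Locus) else locus
        for c in self.calls:
            if c.locus.name == name:
                return c
        return None

    def __getitem__(self, locus: str | Locus) -> DiploidGenotype:
        call = self.get(locus)
        if call is None:
            name = locus.name if isinstance(locus, Locus) else locus
            raise KeyError(name)
        return call

    def has_allele(self, locus: str, allele: str) -> bool:
        call = self.get(locus)
        return call is not None and allele in call

    def to_dict(self) -> dict[str, str]:
        """JSON-friendly form with explicit locus keys, e.g. {"1016": "GI"}."""
        return {c.locus.name: c.format() for c in self.calls}

    @classmethod
    def from_dict(cls, data: Mapping[str, str]) -> "MultiLocusGenotype":
        calls = []
        for name, pair in data.items():
            locus = LOCI[name]
            if len(pair) != 2:
                raise ValueError(f"locus {name}: expected two letters, got {pair!r}")
            calls.append(DiploidGenotype(locus, (pair[0], pair[1])))
        return cls(calls)

    def __str__(self) -> str:
        return format_shorthand(self)


def parse_shorthand(text: str) -> MultiLocusGenotype:
    """Parse a 4- or 6-letter shorthand genotype string.

    6 letters cover 989/1016/1534 ("SSGIFC"); 4 letters cover 1016/1534 only
    ("GIFC"), leaving 989 unset.  Letters must come from each locus's allele
    alphabet in positional order; pairs are unordered.
    """
    if len(text) == 6:
        loci = _SHORTHAND_6
    elif len(text) == 4:
        loci = _SHORTHAND_4
    else:
        raise ShorthandError(
            f"shorthand must be 4 or 6 letters, got {len(text)}: {text!r}"
        )
    calls = []
    for i, locus in enumerate(loci):
        pair = []
        for j in range(2):
            pos = 2 * i + j
            sym = text[pos]
            if sym not in locus.alleles:
                raise ShorthandError(
                    f"position {pos + 1}: {sym!r} is not an allele of locus "
                    f"{locus.name} (expected one of {''.join(locus.canonical_order)})",
                    position=pos + 1,
                )
            pair.append(sym)
        calls.append(DiploidGenotype(locus, (pair[0], pair[1])))
    return MultiLocusGenotype(calls)


def format_shorthand(g: MultiLocusGenotype) -> str:
    """Format a genotype as its canonical shorthand string.

    Requires 1016 and 1534 calls; includes 989 when present.  Within each
    locus the pair is printed in the locus's canonical order (989 S<P,
    1016 V<G<I, 1534 F<C), so formatting is deterministic and round-trips
    through :func:`parse_shorthand`.
    """
    for required in ("1016", "1534"):
        if g.get(required) is None:
            raise IncompleteGenotypeError(f"missing required locus {required}")
    return "".join(c.format() for c in g.calls)


def classify_ensemble(g: MultiLocusGenotype) -> EnsembleClass:
    """Classify a genotype into a resistance-ensemble class.

    The Western-Hemisphere ensemble pairs 1016I with 1534C; the Indopacific
    ensemble pairs 989P with 1016G.  Genotypes carrying alleles of both
    ensembles (e.g. "SPGIFC") are ``MIXED``.
    """
    if g.get("1016") is None or g.get("1534") is None:
        raise IncompleteGenotypeError("classification requires 1016 and 1534 calls")
    has_i = g.has_allele("1016", "I")
    has_g = g.has_allele("1016", "G")
    has_p = g.has_allele("989", "P")
    has_c = g.has_allele("1534", "C")
    indo = has_g or has_p
    if indo and has_i:
        return EnsembleClass.MIXED
    if indo:
        return EnsembleClass.INDOPACIFIC
    if has_i and has_c:
        return EnsembleClass.WESTERN_HEMISPHERE
    call_989 = g.get("989")
    if (
        g["1016"].alleles == ("V", "V")
        and g["1534"].alleles == ("F", "F")
        and (call_989 is None or call_989.alleles == ("S", "S"))
    ):
        return EnsembleClass.SUSCEPTIBLE_LIKE
    return EnsembleClass.OTHER


def enumerate_diploid_genotypes(locus: Locus) -> list[DiploidGenotype]:
    """All k(k+1)/2 unordered diploid genotypes at a locus, canonical order."""
    return [
        DiploidGenotype(locus, pair)
        for pair in itertools.combinations_with_replacement(locus.canonical_order, 2)
    ]
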