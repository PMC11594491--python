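"""Synthetic-data generators for every pipeline stage.

The generators emulate the statistical structure the analysis assumes: melt
curves are sums of Gaussian derivative peaks (one per allele product, centre
jittered, class-level dropout); cohorts are Hardy-Weinberg draws with an
optional haplotype-linkage mode in which every 1016G allele rides an 1534F
background and every 1016I a 1534C background; amplicon reads are diploid
(binomial haplotype split), barcoded at both ends, with uniform
substitution/indel errors; and per-method observation dropout produces the
"no call" entries seen in real multi-method tables.  Only the +/-0.3 degC
calling window, the 0.8 degC I-vs-V product offset, the Q10 read filter, the
100x coverage rule and the 37-base/95% barcode rule are measured constraints;
all other constants here are documented fixture values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .amplicon import BarcodeSpec, ReadRecord
from .assays import MCA_MODELS, predict_aspcr, predict_assay_outcome, resolve_1016
from .melt import McaCall
from .melt import MeltCurve
from .model import (
    LOCI,
    LOCUS_1016,
    DiploidGenotype,
    MultiLocusGenotype,
    format_shorthand,
)
from .panel import CODON_TABLES, ReferencePanel
from .records import CoiMatch, Missing, SampleRecord, SangerObservation

__all__ = [
    "GeneratorConfig",
    "gen_melt_curve",
    "gen_cohort",
    "gen_reads",
    "gen_observations",
    "make_barcodes",
]

#: allele -> sense codon, inverted from the packaged codon tables.
_ALLELE_CODONS: Mapping[str, Mapping[str, str]] = {
    locus: {a: c for c, a in table.items()} for locus, table in CODON_TABLES.items()
}


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic study, with the fixture defaults.

    ``assay_allele_tms`` places each allele's PCR product on the temperature
    axis per assay; within the V1016I assay the G product sits 0.2 degC above
    V (inside the calling window — the confusability), and within the V1016G
    assay the I product sits 0.8 degC below V.  ``allele_freqs_1016`` with
    ``linkage=True`` emulates a Western-Hemisphere population with a rare
    introgressed G: I common, G rare, 1534C nearly fixed on V/I backgrounds.
    """

    seed: int = 0
    assay_allele_tms: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "V1016I_MCA": {"V": 79.0, "G": 79.2, "I": 81.0},
            "V1016G_MCA": {"V": 84.0, "I": 83.2, "G": 80.0},
            "F1534C_MCA": {"F": 86.0, "C": 84.5},
        }
    )
    tm_noise_sd: float = 0.1
    peak_width_sd: float = 0.25
    height_jitter: float = 0.2
    baseline_noise_sd: float = 0.01
    temp_start: float = 70.0
    temp_stop: float = 95.0
    temp_step: float = 0.05
    #: assay -> observable class -> probability the class's peak vanishes
    mca_class_dropout: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    #: method -> probability an observation (or gel band) drops out
    method_dropout: Mapping[str, float] = field(default_factory=dict)
    sub_rate: float = 0.05
    ins_rate: float = 0.005
    del_rate: float = 0.005
    flank_error_rate: float = 0.01
    #: per-amplicon read depth
    coverage: Mapping[str, int] = field(
        default_factory=lambda: {"M1": 200, "M2": 200, "M3": 200, "COI": 200}
    )
    allele_freqs_1016: Mapping[str, float] = field(
        default_factory=lambda: {"V": 0.15, "I": 0.80, "G": 0.05}
    )
    #: independent-locus frequencies, used when linkage is off
    allele_freqs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "989": {"S": 0.95, "P": 0.05},
            "1016": {"V": 0.15, "I": 0.80, "G": 0.05},
            "1534": {"F": 0.10, "C": 0.90},
        }
    )
    linkage: bool = True
    p_989P_given_G: float = 0.5
    p_1534C_on_V_haplotype: float = 0.8

    def __post_init__(self) -> None:
        for locus, freqs in [("1016", self.allele_freqs_1016), *self.allele_freqs.items()]:
            total = sum(freqs.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"allele frequencies at {locus} sum to {total}, not 1")
            if any(not 0 <= f <= 1 for f in freqs.values()):
                raise ValueError(f"allele frequencies at {locus} outside [0, 1]")

    def class_dropout(self, assay_id: str, cls: str) -> float:
        return self.mca_class_dropout.get(assay_id, {}).get(cls, 0.0)


def gen_melt_curve(
    assay_id: str,
    genotype: DiploidGenotype,
    cfg: GeneratorConfig = GeneratorConfig(),
    seed: int | np.random.Generator | None = None,
    tm_shift: float = 0.0,
) -> MeltCurve:
    """Simulate one derivative melt curve for a genotype in one assay.

    One Gaussian peak per distinct allele product of the observable classes
    the assay would show (centres jittered by ``tm_noise_sd``, heights 1.0
    +/- ``height_jitter``), plus clipped white noise; a whole observable
    class may drop out with its configured probability.  ``tm_shift``
    translates every peak (instrument drift experiments).
    """
    rng = _rng(cfg.seed if seed is None else seed)
    model = MCA_MODELS[assay_id]
    tms = cfg.assay_allele_tms[assay_id]
    classes = predict_assay_outcome(genotype, model)
    dropped = {c for c in classes if rng.random() < cfg.class_dropout(assay_id, c)}
    temps = np.arange(cfg.temp_start, cfg.temp_stop + cfg.temp_step / 2, cfg.temp_step)
    values = np.zeros_like(temps)
    for allele in sorted(set(genotype.alleles)):
        if model.allele_to_class[allele] in dropped:
            continue
        centre = tms[allele] + tm_shift + rng.normal(0.0, cfg.tm_noise_sd)
        height = 1.0 * (1.0 + cfg.height_jitter * rng.uniform(-1.0, 1.0))
        values += height * np.exp(-0.5 * ((temps - centre) / cfg.peak_width_sd) ** 2)
    if cfg.baseline_noise_sd > 0:
        values = values + rng.normal(0.0, cfg.baseline_noise_sd, temps.size)
    return MeltCurve(temps, np.clip(values, 0.0, None))


def _sample_haplotype(cfg: GeneratorConfig, rng: np.random.Generator) -> dict[str, str]:
    """One linked haplotype: 1016 allele first, 1534/989 conditioned on it."""
    alleles = list(cfg.allele_freqs_1016)
    probs = [cfg.allele_freqs_1016[a] for a in alleles]
    a1016 = str(rng.choice(alleles, p=probs))
    if a1016 == "I":
        a1534 = "C"
    elif a1016 == "G":
        a1534 = "F"
    else:
        a1534 = "C" if rng.random() < cfg.p_1534C_on_V_haplotype else "F"
    a989 = "P" if (a1016 == "G" and rng.random() < cfg.p_989P_given_G) else "S"
    return {"989": a989, "1016": a1016, "1534": a1534}


def gen_cohort(
    n: int,
    cfg: GeneratorConfig = GeneratorConfig(),
    seed: int | np.random.Generator | None = None,
) -> list[MultiLocusGenotype]:
    """Sample ``n`` diploid multi-locus genotypes.

    In linkage mode whole haplotypes are drawn, so every G allele co-occurs
    with an F at 1534 and every I with a C; otherwise loci are independent
    Hardy-Weinberg draws from ``allele_freqs``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(cfg.seed if seed is None else seed)
    cohort = []
    for _ in range(n):
        if cfg.linkage:
            h1, h2 = _sample_haplotype(cfg, rng), _sample_haplotype(cfg, rng)
            calls = [
                DiploidGenotype(LOCI[name], (h1[name], h2[name]))
                for name in ("989", "1016", "1534")
            ]
        else:
            calls = []
            for name, freqs in cfg.allele_freqs.items():
                alleles = list(freqs)
                probs = [freqs[a] for a in alleles]
                pair = rng.choice(alleles, size=2, p=probs)
                calls.append(DiploidGenotype(LOCI[name], (str(pair[0]), str(pair[1]))))
        cohort.append(MultiLocusGenotype(calls))
    return cohort


_TO_CODE = str.maketrans("ACGT", "\x00\x01\x02\x03")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.translate(_TO_CODE).encode("latin1"), dtype=np.uint8).copy()


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _apply_errors(
    codes: np.ndarray, rng: np.random.Generator, sub: float, ins: float, dele: float
) -> np.ndarray:
    n = codes.size
    out = codes.copy()
    if sub > 0:
        mask = rng.random(n) < sub
        out[mask] = (out[mask] + rng.integers(1, 4, int(mask.sum()))) % 4
    if dele > 0:
        out = out[rng.random(out.size) >= dele]
    if ins > 0:
        repeats = np.where(rng.random(out.size) < ins, 2, 1)
        expanded = np.repeat(out, repeats)
        ends = np.cumsum(repeats) - 1
        inserted = ends[repeats == 2]
        expanded[inserted] = rng.integers(0, 4, inserted.size)
        out = expanded
    return out


def make_barcodes(
    n: int,
    length: int = 40,
    seed: int | np.random.Generator | None = None,
    **spec_kwargs,
) -> list[BarcodeSpec]:
    """Draw ``n`` distinct random barcode flank constructs (default 40 bp,
    comfortably above the 37-aligned-base acceptance rule)."""
    rng = _rng(seed)
    seen: set[str] = set()
    out = []
    while len(out) < n:
        seq = _decode(rng.integers(0, 4, length).astype(np.uint8))
        if seq in seen:
            continue
        seen.add(seq)
        out.append(BarcodeSpec(f"BC{len(out) + 1:02d}", seq, **spec_kwargs))
    return out


def _haplotype_amplicon(panel_amp, hap: Mapping[str, str]) -> str:
    seq = panel_amp.sequence
    for locus, start in panel_amp.codon_starts.items():
        codon = _ALLELE_CODONS[locus][hap[locus]]
        seq = seq[:start] + codon + seq[start + 3 :]
    return seq


def gen_reads(
    genotype: MultiLocusGenotype,
    panel: ReferencePanel,
    cfg: GeneratorConfig = GeneratorConfig(),
    seed: int | np.random.Generator | None = None,
    barcode: BarcodeSpec | None = None,
) -> list[ReadRecord]:
    """Simulate one sample's barcoded diploid amplicon reads.

    Per amplicon, ``coverage`` reads are drawn with a binomial haplotype
    split; substitutions/insertions/deletions hit the amplicon body at the
    configured rates and the barcode flanks at ``flank_error_rate``
    (substitutions only); strand is random; the constant quality string
    encodes the total error rate.  Fixed seed + inputs give byte-identical
    reads.
    """
    rng = _rng(cfg.seed if seed is None else seed)
    missing = [l for l in panel.loci if genotype.get(l) is None]
    if missing:
        raise ValueError(f"genotype lacks calls for panel loci {missing}")
    hap1 = {locus: genotype[locus].alleles[0] for locus in genotype.to_dict()}
    hap2 = {locus: genotype[locus].alleles[1] for locus in genotype.to_dict()}
    total_err = cfg.sub_rate + cfg.ins_rate + cfg.del_rate
    q = max(2, round(-10.0 * math.log10(total_err))) if total_err > 0 else 40
    bc_codes = _codes(barcode.sequence) if barcode is not None else None
    bc_rc_codes = _codes(
        barcode.sequence.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    ) if barcode is not None else None
    reads = []
    for amp in panel.amplicons:
        n = int(cfg.coverage.get(amp.name, 0))
        if n == 0:
            continue
        templates = [_codes(_haplotype_amplicon(amp, h)) for h in (hap1, hap2)]
        n_h1 = int(rng.binomial(n, 0.5))
        for i in range(n):
            core = _apply_errors(
                templates[0 if i < n_h1 else 1], rng, cfg.sub_rate, cfg.ins_rate, cfg.del_rate
            )
            if bc_codes is not None:
                head = _apply_errors(bc_codes, rng, cfg.flank_error_rate, 0.0, 0.0)
                tail = _apply_errors(bc_rc_codes, rng, cfg.flank_error_rate, 0.0, 0.0)
                full = np.concatenate([head, core, tail])
            else:
                full = core
            if rng.random() < 0.5:
                full = (3 - full)[::-1]  # reverse complement in code space
            prefix = barcode.barcode_id if barcode is not None else "read"
            reads.append(
                ReadRecord(
                    f"{prefix}|{amp.name}|{i:04d}",
                    _decode(full),
                    np.full(full.size, q, dtype=np.int16),
                )
            )
    return reads


def _combine_mca_patterns(
    classes_i: frozenset[str], classes_g: frozenset[str]
) -> DiploidGenotype | None:
    """Combine the two 1016 MCA class patterns into the analyst's call.

    Putting the two assays together is a constraint intersection; the 1016
    genotype is reported only when it is uniquely determined (after class
    dropout the intersection may stay ambiguous — or, as with the mis-called
    heterozygous control, resolve cleanly to the wrong genotype)."""
    calls = []
    for assay_id, classes in (("V1016I_MCA", classes_i), ("V1016G_MCA", classes_g)):
        if classes:
            calls.append(McaCall(assay_id, classes, "called"))
    if not calls:
        return None
    return resolve_1016(calls).genotype


def gen_observations(
    genotype: MultiLocusGenotype,
    cfg: GeneratorConfig = GeneratorConfig(),
    seed: int | np.random.Generator | None = None,
    sample_id: str = "sim",
    site: str = "Simulated",
) -> SampleRecord:
    """Produce a multi-method sample record for a known true genotype.

    The virtual assay models supply each method's ideal observation; the
    configured class/method dropout probabilities then thin them, yielding
    the "no call" / single-band patterns real tables show.
    """
    rng = _rng(cfg.seed if seed is None else seed)
    g1016 = genotype["1016"]
    g1534 = genotype["1534"]

    def surviving(assay_id: str, g: DiploidGenotype) -> frozenset[str]:
        classes = predict_assay_outcome(g, MCA_MODELS[assay_id])
        return frozenset(
            c for c in classes if rng.random() >= cfg.class_dropout(assay_id, c)
        )

    pair_1016 = _combine_mca_patterns(
        surviving("V1016I_MCA", g1016), surviving("V1016G_MCA", g1016)
    )
    classes_1534 = surviving("F1534C_MCA", g1534)
    alleles_1534 = sorted(
        (a for a in "FC" if MCA_MODELS["F1534C_MCA"].allele_to_class[a] in classes_1534),
        key=LOCI["1534"].allele_rank,
    )
    if pair_1016 is not None and alleles_1534:
        pair = alleles_1534 if len(alleles_1534) == 2 else alleles_1534 * 2
        mca = format_shorthand(
            MultiLocusGenotype(
                [pair_1016, DiploidGenotype(LOCI["1534"], (pair[0], pair[1]))]
            )
        )
    else:
        mca = Missing.NO_CALL

    p_drop = cfg.method_dropout
    aspcr = predict_aspcr(g1016)
    bands = {"band_V": aspcr.band_V, "band_G": aspcr.band_G}
    for key in bands:
        if bands[key] != "absent" and rng.random() < p_drop.get("AS-PCR", 0.0):
            bands[key] = "absent"
    aspcr_obs = (
        Missing.NO_CALL
        if bands["band_V"] == "absent" and bands["band_G"] == "absent"
        else type(aspcr)(**bands)
    )

    sanger = (
        Missing.NO_CALL
        if rng.random() < p_drop.get("Sanger", 0.0)
        else SangerObservation(g1016.alleles)
    )
    ngs = (
        Missing.NO_CALL
        if rng.random() < p_drop.get("NGS", 0.0)
        else format_shorthand(genotype)
    )
    coi = (
        Missing.NO_CALL
        if rng.random() < p_drop.get("COI", 0.0)
        else CoiMatch("AAEG-SYN-1", round(99.4 + 0.6 * rng.random(), 2))
    )
    return SampleRecord(
        sample_id=sample_id,
        site=site,
        mca=mca,
        aspcr=aspcr_obs,
        sanger=sanger,
        ngs=ngs,
        coi=coi,
    )
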