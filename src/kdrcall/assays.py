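"""Assay confusability models and cross-assay genotype resolution.

The central problem: each 1016 assay groups the three alleles (V, I, G) into
only two observable classes, so a non-target allele can masquerade as the
wild type.  In the V1016I melt-curve assay the G product co-melts with V
(classes: V-like vs I); in the V1016G assay the I product falls with V into
the non-G class (classes: G vs non-G); in the V/G allele-specific PCR the I
allele can amplify weakly in the V reaction.  Each observation therefore
constrains, rather than determines, the diploid genotype.  Resolution is the
intersection of the per-observation constraint sets: the two 1016 MCAs run
together are jointly injective over all six diploid genotypes, so combining
them determines the genotype uniquely.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .melt import McaCall
from .model import (
    LOCUS_1016,
    LOCUS_1534,
    DiploidGenotype,
    enumerate_diploid_genotypes,
    parse_shorthand,
)
from .records import (
    AsPcrObservation,
    Missing,
    SampleRecord,
    SangerObservation,
    format_aspcr,
    format_sanger,
)

__all__ = [
    "VirtualAssayModel",
    "MCA_MODELS",
    "ResolutionResult",
    "AlleleSupport",
    "DisambiguationReport",
    "ConcordanceTable",
    "predict_assay_outcome",
    "predict_mca_call",
    "predict_aspcr",
    "constraint_set",
    "resolve_1016",
    "disambiguation_check",
    "build_concordance",
    "record_observations",
]

@dataclass(frozen=True)
class VirtualAssayModel:
    """What one assay reports for each allele of its locus.

    ``allele_to_class`` is total over the locus alphabet; several alleles
    mapping to one class is exactly the confusability being modelled.
    ``dropout_classes`` lists classes that may fail to appear despite the
    allele being present (with probability; used only by the simulator).
    """

    assay_id: str
    locus: object  # Locus; typed loosely to avoid a frozen-hash pitfall
    allele_to_class: Mapping[str, str]
    dropout_classes: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = self.locus.alleles - set(self.allele_to_class)
        if missing:
            raise ValueError(
                f"{self.assay_id}: allele_to_class not total, missing {sorted(missing)}"
            )
        object.__setattr__(self, "allele_to_class", MappingProxyType(dict(self.allele_to_class)))
        object.__setattr__(self, "dropout_classes", MappingProxyType(dict(self.dropout_classes)))

    def unambiguous_allele(self, cls: str) -> str | None:
        """The single allele mapping to ``cls``, or None if several do."""
        pre = [a for a, c in self.allele_to_class.items() if c == cls]
        return pre[0] if len(pre) == 1 else None


#: Packaged confusability maps for the melt-curve assays.
MCA_MODELS: Mapping[str, VirtualAssayModel] = MappingProxyType(
    {
        "V1016I_MCA": VirtualAssayModel(
            "V1016I_MCA", LOCUS_1016, {"V": "Vclass", "G": "Vclass", "I": "Iclass"}
        ),
        "V1016G_MCA": VirtualAssayModel(
            "V1016G_MCA", LOCUS_1016, {"G": "Gclass", "V": "nonG", "I": "nonG"}
        ),
        "F1534C_MCA": VirtualAssayModel(
            "F1534C_MCA", LOCUS_1534, {"F": "Fclass", "C": "Cclass"}
        ),
    }
)


def predict_assay_outcome(g: DiploidGenotype, model: VirtualAssayModel) -> frozenset[str]:
    """Image of a diploid allele pair under the assay's allele->class map."""
    if g.locus.name != model.locus.name:
        raise ValueError(f"genotype at {g.locus.name} fed to {model.assay_id}")
    return frozenset(model.allele_to_class[a] for a in g.alleles)


def predict_mca_call(g: DiploidGenotype, model: VirtualAssayModel) -> McaCall:
    """The McaCall an ideal (dropout-free) run would report for ``g``."""
    return McaCall(model.assay_id, predict_assay_outcome(g, model), "called")


def predict_aspcr(g: DiploidGenotype) -> AsPcrObservation:
    """Expected 1016 AS-PCR bands: V amplifies strongly in the V reaction,
    I amplifies weakly there (off-target), G gives the G band."""
    if g.locus.name != "1016":
        raise ValueError("AS-PCR model covers locus 1016 only")
    if "V" in g:
        band_v = "strong"
    elif "I" in g:
        band_v = "weak"
    else:
        band_v = "absent"
    return AsPcrObservation(band_V=band_v, band_G="strong" if "G" in g else "absent")


def _aspcr_compatible(g: DiploidGenotype, obs: AsPcrObservation, strict: bool) -> bool:
    # Band semantics: strong V => >=1 V; weak V => >=1 V or >=1 I; any G band
    # => >=1 G.  An absent band excludes nothing (band dropout is observed in
    # real data) unless strict mode is requested.
    if obs.band_V == "strong" and "V" not in g:
        return False
    if obs.band_V == "weak" and not ("V" in g or "I" in g):
        return False
    if obs.band_G in ("weak", "strong") and "G" not in g:
        return False
    if strict:
        if obs.band_V == "absent" and "V" in g:
            return False
        if obs.band_G == "absent" and "G" in g:
            return False
    return True


def constraint_set(
    observation,
    model: VirtualAssayModel | None = None,
    strict_bands: bool = False,
) -> frozenset[DiploidGenotype]:
    """Genotypes at 1016 compatible with one observation.

    A no-call constrains nothing and returns the full genotype set.  MCA
    observations require the predicted class set to equal the observed one;
    AS-PCR uses band-presence semantics; a two-symbol Sanger call pins the
    genotype, a single symbol only asserts presence.
    """
    if isinstance(observation, McaCall):
        if model is None:
            model = MCA_MODELS[observation.assay_id]
        universe = enumerate_diploid_genotypes(model.locus)
        if observation.status != "called":
            return frozenset(universe)
        return frozenset(
            g for g in universe
            if predict_assay_outcome(g, model) == observation.detected_classes
        )
    universe = enumerate_diploid_genotypes(LOCUS_1016)
    if isinstance(observation, AsPcrObservation):
        if observation.is_no_call:
            return frozenset(universe)
        return frozenset(
            g for g in universe if _aspcr_compatible(g, observation, strict_bands)
        )
    if isinstance(observation, SangerObservation):
        exact = observation.as_genotype
        if exact is not None:
            return frozenset({exact})
        (sym,) = observation.alleles
        return frozenset(g for g in universe if sym in g)
    if isinstance(observation, DiploidGenotype):
        return frozenset({observation})
    if isinstance(observation, Missing):
        return frozenset(universe)
    raise TypeError(f"unsupported observation type {type(observation).__name__}")


def _method_label(observation) -> str:
    if isinstance(observation, McaCall):
        return "MCA"
    if isinstance(observation, AsPcrObservation):
        return "AS-PCR"
    if isinstance(observation, SangerObservation):
        return "Sanger"
    if isinstance(observation, DiploidGenotype):
        return "NGS"
    raise TypeError(type(observation).__name__)


def _unambiguous_detections(observation, model: VirtualAssayModel | None) -> set[str]:
    """Alleles this observation detects via their own dedicated signal."""
    if isinstance(observation, McaCall):
        if observation.status != "called":
            return set()
        if model is None:
            model = MCA_MODELS[observation.assay_id]
        out = set()
        for cls in observation.detected_classes:
            allele = model.unambiguous_allele(cls)
            if allele is not None:
                out.add(allele)
        return out
    if isinstance(observation, AsPcrObservation):
        out = set()
        if observation.band_V == "strong":
            out.add("V")
        if observation.band_G in ("weak", "strong"):
            out.add("G")
        return out
    if isinstance(observation, SangerObservation):
        return set(observation.alleles)
    if isinstance(observation, DiploidGenotype):
        return set(observation.alleles)
    return set()


@dataclass(frozen=True)
class AlleleSupport:
    detected_by: frozenset[str]
    confirmed: bool


@dataclass(frozen=True)
class ResolutionResult:
    """Outcome of intersecting multi-method constraints at 1016.

    ``status``: ``resolved`` (single candidate), ``ambiguous`` (several),
    ``conflict`` (empty intersection; ``conflict_methods`` names a minimal
    conflicting method pair) or ``no_call`` (nothing observed).  An allele is
    ``confirmed`` when it is present in every candidate genotype and was
    detected by its own dedicated signal in at least ``min_methods`` distinct
    methods.
    """

    status: str
    candidates: frozenset[DiploidGenotype]
    support: Mapping[str, AlleleSupport]
    conflict_methods: tuple[str, ...] | None = None

    @property
    def genotype(self) -> DiploidGenotype | None:
        if self.status == "resolved":
            (g,) = self.candidates
            return g
        return None

    def confirmed_alleles(self) -> frozenset[str]:
        return frozenset(a for a, s in self.support.items() if s.confirmed)


def resolve_1016(
    observations: Sequence,
    models: Mapping[str, VirtualAssayModel] = MCA_MODELS,
    min_methods: int = 2,
    strict_bands: bool = False,
) -> ResolutionResult:
    """Intersect per-method constraints to resolve the 1016 genotype.

    ``observations`` may mix :class:`~kdrcall.melt.McaCall`,
    :class:`~kdrcall.records.AsPcrObservation`,
    :class:`~kdrcall.records.SangerObservation` and direct
    :class:`~kdrcall.model.DiploidGenotype` (NGS) entries.
    """
    universe = frozenset(enumerate_diploid_genotypes(LOCUS_1016))

    def model_for(obs):
        if isinstance(obs, McaCall):
            return models.get(obs.assay_id, MCA_MODELS.get(obs.assay_id))
        return None

    informative = []  # (method label, constraint set, observation)
    detected_by: dict[str, set[str]] = {a: set() for a in LOCUS_1016.canonical_order}
    any_called = False
    for obs in observations:
        if isinstance(obs, Missing):
            continue
        cs = constraint_set(obs, model_for(obs), strict_bands)
        called = not (
            (isinstance(obs, McaCall) and obs.status != "called")
            or (isinstance(obs, AsPcrObservation) and obs.is_no_call)
        )
        if called:
            any_called = True
            informative.append((_method_label(obs), cs, obs))
            for allele in _unambiguous_detections(obs, model_for(obs)):
                detected_by[allele].add(_method_label(obs))

    if not any_called:
        support = {
            a: AlleleSupport(frozenset(), False) for a in LOCUS_1016.canonical_order
        }
        return ResolutionResult("no_call", universe, support)

    candidates = universe
    for _, cs, _ in informative:
        candidates = candidates & cs

    conflict_methods: tuple[str, ...] | None = None
    if not candidates:
        for (m1, c1, _), (m2, c2, _) in itertools.combinations(informative, 2):
            if not (c1 & c2):
                conflict_methods = (m1, m2)
                break
        if conflict_methods is None:
            conflict_methods = tuple(m for m, _, _ in informative)
        status = "conflict"
    elif len(candidates) == 1:
        status = "resolved"
    else:
        status = "ambiguous"

    support = {}
    for allele in LOCUS_1016.canonical_order:
        in_all = bool(candidates) and all(allele in g for g in candidates)
        methods = frozenset(detected_by[allele])
        support[allele] = AlleleSupport(methods, in_all and len(methods) >= min_methods)
    return ResolutionResult(status, candidates, support, conflict_methods)


@dataclass(frozen=True)
class DisambiguationReport:
    injective: bool
    collisions: tuple[frozenset[DiploidGenotype], ...]


def disambiguation_check(models: Sequence[VirtualAssayModel]) -> DisambiguationReport:
    """Is the joint outcome map of these assays injective over the 6 diploid
    1016 genotypes?  If not, report the colliding genotype groups."""
    if not models:
        raise ValueError("need at least one assay model")
    groups: dict[tuple, list[DiploidGenotype]] = {}
    for g in enumerate_diploid_genotypes(LOCUS_1016):
        key = tuple(predict_assay_outcome(g, m) for m in models)
        groups.setdefault(key, []).append(g)
    collisions = tuple(
        frozenset(v) for v in groups.values() if len(v) > 1
    )
    return DisambiguationReport(not collisions, collisions)


def record_observations(rec: SampleRecord) -> list:
    """Translate a sample record into resolver observations at 1016.

    The record's MCA genotype string is the analyst's combined call from the
    two 1016 MCAs, so it is re-expanded into the two class patterns those
    assays must have shown.
    """
    obs: list = []
    if isinstance(rec.mca, str):
        g1016 = parse_shorthand(rec.mca)["1016"]
        for assay_id in ("V1016I_MCA", "V1016G_MCA"):
            obs.append(predict_mca_call(g1016, MCA_MODELS[assay_id]))
    if isinstance(rec.aspcr, AsPcrObservation):
        obs.append(rec.aspcr)
    if isinstance(rec.sanger, SangerObservation):
        obs.append(rec.sanger)
    if isinstance(rec.ngs, str):
        obs.append(parse_shorthand(rec.ngs)["1016"])
    return obs


@dataclass(frozen=True)
class ConcordanceTable:
    """Per-sample multi-method table plus tallied summary counts.

    ``summary`` keys (counts over the supplied records):

    - ``n_samples``, ``n_field_samples`` (sites not labelled ``Control``)
    - ``mca_genotype_counts`` overall and ``mca_genotype_counts_by_site``
    - ``field_g_positive_by_method``: field samples with >=1 1016G seen by
      each method (MCA / AS-PCR / Sanger / NGS)
    - ``n_field_ngs_g_with_989p``: NGS-confirmed G carriers also carrying 989P
    - ``n_ngs_no_call``: tested samples without adequate NGS coverage
    - ``n_coi_tested`` / ``n_coi_pass``: COI identities at/above threshold
    """

    table: pd.DataFrame
    summary: Mapping[str, object]
    coi_threshold: float


def build_concordance(
    records: Sequence[SampleRecord],
    models: Mapping[str, VirtualAssayModel] = MCA_MODELS,
    coi_threshold: float = 99.0,
) -> ConcordanceTable:
    """Tabulate multi-method genotyping records and tally summary counts."""
    ids = [r.sample_id for r in records]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ValueError(f"duplicate sample ids: {sorted(dup)}")

    rows = []
    for rec in records:
        res = resolve_1016(record_observations(rec), models)
        rows.append(
            {
                "sample_id": rec.sample_id,
                "site": rec.site,
                "mca": str(rec.mca) if isinstance(rec.mca, Missing) else rec.mca,
                "aspcr": format_aspcr(rec.aspcr),
                "sanger": format_sanger(rec.sanger),
                "ngs": str(rec.ngs) if isinstance(rec.ngs, Missing) else rec.ngs,
                "coi": "" if isinstance(rec.coi, Missing) else rec.coi.accession,
                "coi_pct": (
                    float("nan") if isinstance(rec.coi, Missing) else rec.coi.percent_identity
                ),
                "resolved_1016": res.genotype.format() if res.genotype else res.status,
                "n_candidates": len(res.candidates),
                "confirmed_alleles": "".join(sorted(res.confirmed_alleles(), key=LOCUS_1016.allele_rank)),
            }
        )
    table = pd.DataFrame(rows)

    field = [r for r in records if not r.is_control]

    def mca_has_g(r: SampleRecord) -> bool:
        return isinstance(r.mca, str) and "G" in parse_shorthand(r.mca)["1016"]

    def aspcr_has_g(r: SampleRecord) -> bool:
        return isinstance(r.aspcr, AsPcrObservation) and r.aspcr.band_G != "absent"

    def sanger_has_g(r: SampleRecord) -> bool:
        return isinstance(r.sanger, SangerObservation) and "G" in r.sanger.alleles

    def ngs_has_g(r: SampleRecord) -> bool:
        return isinstance(r.ngs, str) and "G" in parse_shorthand(r.ngs)["1016"]

    ngs_g_field = [r for r in field if ngs_has_g(r)]
    mca_counts = Counter(r.mca for r in records if isinstance(r.mca, str))
    by_site: dict[str, Counter] = {}
    for r in records:
        if isinstance(r.mca, str):
            by_site.setdefault(r.site, Counter())[r.mca] += 1

    coi_tested = [r for r in records if not isinstance(r.coi, Missing)]

    summary = {
        "n_samples": len(records),
        "n_field_samples": len(field),
        "mca_genotype_counts": dict(mca_counts),
        "mca_genotype_counts_by_site": {s: dict(c) for s, c in by_site.items()},
        "field_g_positive_by_method": {
            "MCA": sum(mca_has_g(r) for r in field),
            "AS-PCR": sum(aspcr_has_g(r) for r in field),
            "Sanger": sum(sanger_has_g(r) for r in field),
            "NGS": sum(ngs_has_g(r) for r in field),
        },
        "n_field_ngs_g_with_989p": sum(
            1 for r in ngs_g_field if parse_shorthand(r.ngs).has_allele("989", "P")
        ),
        "n_ngs_no_call": sum(1 for r in records if r.ngs is Missing.NO_CALL),
        "n_coi_tested": len(coi_tested),
        "n_coi_pass": sum(
            1 for r in coi_tested if r.coi.percent_identity >= coi_threshold
        ),
    }
    return ConcordanceTable(table, MappingProxyType(summary), coi_threshold)
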