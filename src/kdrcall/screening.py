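"""Control-panel validation and reflex (gatekeeper) screening workflows.

Surveillance programmes rarely run every assay on every mosquito.  Two
strategies are encoded here.  ``full_1016`` always runs both 1016 melt-curve
assays, the only combination that resolves all three 1016 alleles
unambiguously.  ``legacy_reflex`` keeps the historical first tier (V1016I +
F1534C) and exploits the strong unidirectional linkage of 1016G with 1534F:
any sample showing at least one 1534F allele is reflexed to V1016G and S989P
testing, while the common all-C samples need no further work.  Panel
validation enforces the control discipline that makes the calls trustworthy:
a control material for every allele of every assayed locus, heterozygous
mixes to prove the competitive primers are balanced, and a negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .assays import MCA_MODELS, VirtualAssayModel, resolve_1016, record_observations
from .model import (
    LOCI,
    MultiLocusGenotype,
    classify_ensemble,
    parse_shorthand,
)
from .records import Missing, SampleRecord

__all__ = [
    "PanelDefinition",
    "PanelValidity",
    "ScreeningStrategy",
    "FULL_1016",
    "LEGACY_REFLEX",
    "ReflexDecision",
    "validate_panel",
    "next_assays",
    "screen_cohort",
]

#: locus assayed by each supported assay id
ASSAY_LOCI: Mapping[str, str] = {
    "V1016I_MCA": "1016",
    "V1016G_MCA": "1016",
    "F1534C_MCA": "1534",
    "S989P_MCA": "989",
}


@dataclass(frozen=True)
class PanelDefinition:
    """The assays a lab runs and the control materials available to them.

    ``controls`` maps a control name to its genotype shorthand (6- or
    4-letter), or ``None`` for the negative control.  ``required_het_pairs``
    lists, per locus, the heterozygous allele mixes a valid run must include
    (data, not code: the packaged default mirrors the mixes used to balance
    competitive primers at 1016 and 1534).
    """

    assays: tuple[str, ...]
    controls: Mapping[str, str | None]
    required_het_pairs: Mapping[str, tuple[frozenset[str], ...]] = field(
        default_factory=lambda: {
            "1016": (frozenset({"V", "I"}), frozenset({"G", "I"})),
            "1534": (frozenset({"F", "C"}),),
        }
    )

    def __post_init__(self) -> None:
        unknown = [a for a in self.assays if a not in ASSAY_LOCI]
        if unknown:
            raise ValueError(f"unknown assays: {unknown}")
        object.__setattr__(self, "controls", dict(self.controls))
        object.__setattr__(
            self, "required_het_pairs", dict(self.required_het_pairs)
        )


@dataclass(frozen=True)
class PanelValidity:
    valid: bool
    missing_allele_controls: tuple[tuple[str, str], ...]  # (assay, allele)
    missing_het_controls: tuple[tuple[str, str], ...]  # (locus, pair string)
    missing_negative: bool


def validate_panel(panel: PanelDefinition) -> PanelValidity:
    """Check that every (assay, allele) pair and every required heterozygous
    mix is backed by a control material, and that a negative is present."""
    genotypes: list[MultiLocusGenotype] = []
    has_negative = False
    for name, shorthand in panel.controls.items():
        if shorthand is None:
            has_negative = True
        else:
            genotypes.append(parse_shorthand(shorthand))

    missing_alleles: list[tuple[str, str]] = []
    for assay in panel.assays:
        locus_name = ASSAY_LOCI[assay]
        alleles = LOCI[locus_name].canonical_order
        for allele in alleles:
            if not any(g.has_allele(locus_name, allele) for g in genotypes):
                missing_alleles.append((assay, allele))

    tested_loci = {ASSAY_LOCI[a] for a in panel.assays}
    missing_hets: list[tuple[str, str]] = []
    for locus_name, pairs in panel.required_het_pairs.items():
        if locus_name not in tested_loci:
            continue
        for pair in pairs:
            found = any(
                (call := g.get(locus_name)) is not None
                and frozenset(call.alleles) == pair
                for g in genotypes
            )
            if not found:
                missing_hets.append((locus_name, "/".join(sorted(pair))))

    return PanelValidity(
        valid=not missing_alleles and not missing_hets and has_negative,
        missing_allele_controls=tuple(missing_alleles),
        missing_het_controls=tuple(missing_hets),
        missing_negative=not has_negative,
    )


@dataclass(frozen=True)
class ScreeningStrategy:
    """A tiered screening rule.

    ``legacy_reflex``: first tier V1016I + F1534C; any 1534F allele triggers
    the reflex assays (V1016G then S989P, in that order).  ``full_1016``:
    both 1016 assays are always required; ``next_assays`` returns whichever
    has not been run yet.
    """

    name: str
    first_tier: tuple[str, ...]
    reflex_assays: tuple[str, ...] = ()
    trigger_locus: str = "1534"
    trigger_allele: str = "F"

    def __post_init__(self) -> None:
        overlap = set(self.first_tier) & set(self.reflex_assays)
        if overlap:
            raise ValueError(f"reflex assays overlap first tier: {sorted(overlap)}")


FULL_1016 = ScreeningStrategy(
    "full_1016", first_tier=("V1016I_MCA", "V1016G_MCA", "F1534C_MCA")
)
LEGACY_REFLEX = ScreeningStrategy(
    "legacy_reflex",
    first_tier=("V1016I_MCA", "F1534C_MCA"),
    reflex_assays=("V1016G_MCA", "S989P_MCA"),
)


@dataclass(frozen=True)
class ReflexDecision:
    status: str  # "reflex" | "none" | "needs_data"
    assays: tuple[str, ...] = ()
    reason: str = ""


def next_assays(
    first_tier_results: MultiLocusGenotype,
    strategy: ScreeningStrategy,
    already_run: Sequence[str] = (),
) -> ReflexDecision:
    """Decide which assays a sample still needs.

    For ``legacy_reflex`` the decision keys on the trigger allele (1534F by
    default); an absent trigger-locus call yields ``needs_data`` rather than
    a guess.
    """
    if strategy.name == "full_1016":
        pending = tuple(
            a for a in ("V1016I_MCA", "V1016G_MCA") if a not in set(already_run)
        )
        return ReflexDecision("reflex" if pending else "none", pending)
    call = first_tier_results.get(strategy.trigger_locus)
    if call is None:
        return ReflexDecision(
            "needs_data",
            reason=f"no {strategy.trigger_locus} call in first-tier results",
        )
    if strategy.trigger_allele in call:
        return ReflexDecision(
            "reflex",
            tuple(a for a in strategy.reflex_assays if a not in set(already_run)),
            reason=f"{strategy.trigger_locus}{strategy.trigger_allele} present",
        )
    return ReflexDecision("none")


def screen_cohort(
    records: Sequence[SampleRecord],
    strategy: ScreeningStrategy = LEGACY_REFLEX,
    models: Mapping[str, VirtualAssayModel] = MCA_MODELS,
) -> tuple[pd.DataFrame, dict[str, object]]:
    """Apply a screening strategy across a cohort of first-tier records.

    Returns a per-sample disposition table (resolved 1016 status, reflex
    assays indicated, ensemble class when resolvable) and a workload summary
    counting the reflex tests triggered.
    """
    rows = []
    n_reflex_samples = 0
    n_reflex_tests = 0
    for rec in records:
        res = resolve_1016(record_observations(rec), models)
        if isinstance(rec.mca, str):
            decision = next_assays(
                parse_shorthand(rec.mca), strategy, already_run=strategy.first_tier
            )
        else:
            decision = ReflexDecision("needs_data", reason="no first-tier MCA result")
        if decision.status == "reflex":
            n_reflex_samples += 1
            n_reflex_tests += len(decision.assays)
        ensemble = ""
        if isinstance(rec.mca, str):
            ensemble = classify_ensemble(parse_shorthand(rec.mca)).value
        rows.append(
            {
                "sample_id": rec.sample_id,
                "site": rec.site,
                "first_tier_mca": str(rec.mca) if isinstance(rec.mca, Missing) else rec.mca,
                "resolved_1016": res.genotype.format() if res.genotype else res.status,
                "reflex": decision.status,
                "reflex_assays": ",".join(decision.assays),
                "ensemble": ensemble,
            }
        )
    summary = {
        "strategy": strategy.name,
        "n_samples": len(records),
        "n_reflex_samples": n_reflex_samples,
        "n_reflex_tests": n_reflex_tests,
    }
    return pd.DataFrame(rows), summary
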