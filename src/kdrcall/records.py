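"""Per-sample multi-method observation records and their TSV grammar.

One :class:`SampleRecord` holds everything observed for one organism across
the four genotyping methods (melt-curve assay, allele-specific PCR, Sanger,
amplicon NGS) plus the COI species-verification result — one row of the
multi-method comparison table.  Cell strings round-trip losslessly, including
compound AS-PCR entries such as ``"weakV G"`` (a weak 1016V band alongside a
strong 1016G band) and COI entries such as ``"MN299016.1-99.72%"``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import IO, Iterable

import pandas as pd

from .model import LOCUS_1016, DiploidGenotype, parse_shorthand

__all__ = [
    "Missing",
    "AsPcrObservation",
    "SangerObservation",
    "CoiMatch",
    "SampleRecord",
    "parse_aspcr",
    "format_aspcr",
    "parse_sanger",
    "format_sanger",
    "read_records_tsv",
    "write_records_tsv",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = (
    "Sample",
    "MCA 1016/1534",
    "AS-PCR 1016",
    "Sanger 1016",
    "NGS 989/1016/1534",
    "COI Accession-%ID",
)


class Missing(enum.Enum):
    """Why a method has no usable observation for a sample."""

    NO_CALL = "no call"
    NOT_TESTED = "not tested"

    def __str__(self) -> str:
        return self.value


_BAND_STATES = ("absent", "weak", "strong")


@dataclass(frozen=True)
class AsPcrObservation:
    """Gel-band record of the 1016 allele-specific PCR (V and G reactions)."""

    band_V: str = "absent"
    band_G: str = "absent"

    def __post_init__(self) -> None:
        for b in (self.band_V, self.band_G):
            if b not in _BAND_STATES:
                raise ValueError(f"band state must be one of {_BAND_STATES}, got {b!r}")

    @property
    def is_no_call(self) -> bool:
        return self.band_V == "absent" and self.band_G == "absent"


@dataclass(frozen=True)
class SangerObservation:
    """Sanger base call at the 1016 codon.

    ``alleles`` holds an unordered pair for a clean diploid call, or a single
    symbol when only one allele was legible at the SNP site (a single symbol
    asserts presence, not homozygosity).
    """

    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError("Sanger observation carries one or two allele symbols")
        for sym in self.alleles:
            if sym not in LOCUS_1016.alleles:
                raise ValueError(f"{sym!r} is not a 1016 allele")
        object.__setattr__(
            self, "alleles", tuple(sorted(self.alleles, key=LOCUS_1016.allele_rank))
        )

    @property
    def as_genotype(self) -> DiploidGenotype | None:
        if len(self.alleles) == 2:
            return DiploidGenotype(LOCUS_1016, (self.alleles[0], self.alleles[1]))
        return None


@dataclass(frozen=True)
class CoiMatch:
    """Best COI reference match for species verification."""

    accession: str
    percent_identity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent identity must lie in [0, 100]")


@dataclass(frozen=True)
class SampleRecord:
    """All observations for one organism across methods.

    ``mca`` and ``ngs`` are shorthand genotype strings (4- and 6-letter
    respectively) or :class:`Missing` markers.  ``site`` is the collection
    label; control wells use sites starting with ``Control``.
    """

    sample_id: str
    site: str
    mca: str | Missing = Missing.NOT_TESTED
    aspcr: AsPcrObservation | Missing = Missing.NOT_TESTED
    sanger: SangerObservation | Missing = Missing.NOT_TESTED
    ngs: str | Missing = Missing.NOT_TESTED
    coi: CoiMatch | Missing = Missing.NOT_TESTED

    def __post_init__(self) -> None:
        values = (self.mca, self.aspcr, self.sanger, self.ngs, self.coi)
        if all(v is Missing.NOT_TESTED for v in values):
            raise ValueError(f"sample {self.sample_id}: no method observed")
        for sh in (self.mca, self.ngs):
            if isinstance(sh, str):
                parse_shorthand(sh)  # validates

    @property
    def is_control(self) -> bool:
        return self.site.startswith("Control")


def parse_aspcr(cell: str) -> AsPcrObservation | Missing:
    """Parse an AS-PCR cell: tokens are ``V``/``G`` with optional ``weak`` prefix."""
    cell = cell.strip()
    if cell == str(Missing.NO_CALL):
        return Missing.NO_CALL
    if cell == str(Missing.NOT_TESTED):
        return Missing.NOT_TESTED
    bands = {"V": "absent", "G": "absent"}
    for token in cell.split():
        strength = "strong"
        if token.startswith("weak"):
            strength, token = "weak", token[4:]
        if token not in bands:
            raise ValueError(f"unrecognised AS-PCR band token {token!r} in {cell!r}")
        bands[token] = strength
    return AsPcrObservation(band_V=bands["V"], band_G=bands["G"])


def format_aspcr(obs: AsPcrObservation | Missing) -> str:
    if isinstance(obs, Missing):
        return str(obs)
    if obs.is_no_call:
        return str(Missing.NO_CALL)
    tokens = []
    for allele, state in (("V", obs.band_V), ("G", obs.band_G)):
        if state == "strong":
            tokens.append(allele)
        elif state == "weak":
            tokens.append(f"weak{allele}")
    return " ".join(tokens)


def parse_sanger(cell: str) -> SangerObservation | Missing:
    cell = cell.strip()
    if cell == str(Missing.NO_CALL):
        return Missing.NO_CALL
    if cell == str(Missing.NOT_TESTED):
        return Missing.NOT_TESTED
    return SangerObservation(tuple(cell))


def format_sanger(obs: SangerObservation | Missing) -> str:
    if isinstance(obs, Missing):
        return str(obs)
    return "".join(obs.alleles)


def _parse_shorthand_cell(cell: str) -> str | Missing:
    cell = cell.strip()
    if cell == str(Missing.NO_CALL):
        return Missing.NO_CALL
    if cell == str(Missing.NOT_TESTED):
        return Missing.NOT_TESTED
    parse_shorthand(cell)
    return cell


def _parse_coi(cell: str) -> CoiMatch | Missing:
    cell = cell.strip()
    if cell == str(Missing.NO_CALL):
        return Missing.NO_CALL
    if cell == str(Missing.NOT_TESTED):
        return Missing.NOT_TESTED
    if not cell.endswith("%") or "-" not in cell:
        raise ValueError(f"malformed COI cell {cell!r}")
    accession, pct = cell[:-1].rsplit("-", 1)
    return CoiMatch(accession, float(pct))


def _format_coi(obs: CoiMatch | Missing) -> str:
    if isinstance(obs, Missing):
        return str(obs)
    return f"{obs.accession}-{obs.percent_identity:g}%"


def _format_shorthand_cell(value: str | Missing) -> str:
    return str(value) if isinstance(value, Missing) else value


def records_from_rows(rows: Iterable[dict[str, str]]) -> list[SampleRecord]:
    """Build records from table rows, de-duplicating repeated site labels.

    The comparison table labels rows by collection site, so the same label
    may appear several times; sample ids are formed as ``"<site> #<k>"``.
    """
    counts: dict[str, int] = {}
    records = []
    for row in rows:
        site = row["Sample"].strip()
        counts[site] = counts.get(site, 0) + 1
        records.append(
            SampleRecord(
                sample_id=f"{site} #{counts[site]}",
                site=site,
                mca=_parse_shorthand_cell(row["MCA 1016/1534"]),
                aspcr=parse_aspcr(row["AS-PCR 1016"]),
                sanger=parse_sanger(row["Sanger 1016"]),
                ngs=_parse_shorthand_cell(row["NGS 989/1016/1534"]),
                coi=_parse_coi(row["COI Accession-%ID"]),
            )
        )
    return records


def record_to_row(rec: SampleRecord) -> dict[str, str]:
    return {
        "Sample": rec.site,
        "MCA 1016/1534": _format_shorthand_cell(rec.mca),
        "AS-PCR 1016": format_aspcr(rec.aspcr),
        "Sanger 1016": format_sanger(rec.sanger),
        "NGS 989/1016/1534": _format_shorthand_cell(rec.ngs),
        "COI Accession-%ID": _format_coi(rec.coi),
    }


def read_records_tsv(path_or_buf: str | IO[str]) -> list[SampleRecord]:
    """Read sample records from a TSV laid out like the comparison table."""
    df = pd.read_csv(path_or_buf, sep="\t", dtype=str).fillna("")
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records TSV missing columns: {sorted(missing)}")
    return records_from_rows(df.to_dict(orient="records"))


def write_records_tsv(records: Iterable[SampleRecord], path_or_buf: str | IO[str]) -> None:
    df = pd.DataFrame([record_to_row(r) for r in records], columns=list(RECORD_COLUMNS))
    df.to_csv(path_or_buf, sep="\t", index=False)
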