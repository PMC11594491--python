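"""Amplicon-read genotyping: filtering, demultiplexing, alignment, pileup.

The pipeline mirrors a barcoded amplicon sequencing run: reads passing a
mean-quality filter are assigned to samples by requiring a barcode flank
match (> ``min_match_length`` aligned bases at > ``min_identity``) at *both*
read ends, aligned to a small amplicon reference panel, and genotyped by
tallying the read 3-mer over each annotated kdr codon.  A sample is excluded
whenever any amplicon's coverage falls below ``min_coverage`` (default
100x).  The COI amplicon's per-column majority consensus is matched against
a local reference set for species verification (pass at >= 99% identity).

Alignment is performed internally: the edit-distance-optimal semi-global
alignment (bit-parallel) is found for each read against every reference and
both strands, and that alignment is then scored under a documented affine
scheme (match +2, mismatch -4, gap open -4, gap extend -2) whose score floor
(default 40% of read length x match score) rejects spurious hits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .model import LOCI, DiploidGenotype, MultiLocusGenotype
from .panel import CODON_TABLES, Amplicon, CoiReference, ReferencePanel

__all__ = [
    "ReadRecord",
    "BarcodeSpec",
    "AlignScores",
    "ReadAlignment",
    "CodonPileup",
    "PileupGenotypeCall",
    "SpeciesCall",
    "GenotypingParams",
    "SampleGenotypeResult",
    "read_fastq",
    "write_fastq",
    "reverse_complement",
    "quality_filter",
    "demultiplex",
    "align_read",
    "codon_pileup",
    "call_genotype",
    "coi_consensus",
    "identify_species",
    "genotype_sample",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ReadRecord:
    """A sequencing read with per-base Phred quality scores."""

    read_id: str
    bases: str
    quals: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.quals, dtype=np.int16)
        if len(self.bases) != q.size:
            raise ValueError(f"{self.read_id}: bases and quals differ in length")
        if set(self.bases) - set("ACGTN"):
            raise ValueError(f"{self.read_id}: alphabet must be ACGTN")
        object.__setattr__(self, "quals", q)

    @property
    def mean_quality(self) -> float:
        return float(self.quals.mean()) if self.quals.size else 0.0


def read_fastq(path_or_buf: str | Path | IO[str]) -> list[ReadRecord]:
    """Read Phred+33 FASTQ.  Out-of-range quality characters are refused
    (biopython's sanger parser raises), never reinterpreted."""
    handle = str(path_or_buf) if isinstance(path_or_buf, (str, Path)) else path_or_buf
    out = []
    for rec in SeqIO.parse(handle, "fastq"):
        out.append(
            ReadRecord(
                rec.id,
                str(rec.seq).upper(),
                np.array(rec.letter_annotations["phred_quality"], dtype=np.int16),
            )
        )
    return out


def write_fastq(reads: Iterable[ReadRecord], path_or_buf: str | Path | IO[str]) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.quals]
        records.append(rec)
    handle = str(path_or_buf) if isinstance(path_or_buf, (str, Path)) else path_or_buf
    SeqIO.write(records, handle, "fastq")


def quality_filter(
    reads: Iterable[ReadRecord],
    min_mean_q: float = 10.0,
    rejected: list | None = None,
) -> list[ReadRecord]:
    """Keep reads with mean Phred quality >= ``min_mean_q``.

    When a list is passed as ``rejected``, (read_id, reason) pairs for the
    dropped reads are appended to it.
    """
    kept = []
    for r in reads:
        if r.mean_quality >= min_mean_q:
            kept.append(r)
        elif rejected is not None:
            rejected.append((r.read_id, f"mean quality {r.mean_quality:.1f} < {min_mean_q}"))
    return kept


# ---------------------------------------------------------------------------
# internal semi-global alignment helper (edit-distance path, then rescoring)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class _PathStats:
    matches: int
    mismatches: int
    gap_runs: int
    gap_bases: int
    blocks: tuple[tuple[int, int, int], ...]  # (query_pos, target_pos, length)

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gap_bases

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


def _walk_cigar(cigar: str, q_start: int, t_start: int) -> _PathStats:
    matches = mismatches = gap_runs = gap_bases = 0
    blocks: list[tuple[int, int, int]] = []
    q, t = q_start, t_start
    for n_s, op in _CIGAR_RE.findall(cigar):
        n = int(n_s)
        if op in "=XM":
            if blocks and blocks[-1][0] + blocks[-1][2] == q and blocks[-1][1] + blocks[-1][2] == t:
                q0, t0, n0 = blocks[-1]
                blocks[-1] = (q0, t0, n0 + n)  # contiguous run: merge
            else:
                blocks.append((q, t, n))
            if op == "X":
                mismatches += n
            else:
                matches += n
            q += n
            t += n
        elif op == "I":  # bases present in query only
            gap_runs += 1
            gap_bases += n
            q += n
        else:  # "D": bases present in target only
            gap_runs += 1
            gap_bases += n
            t += n
    return _PathStats(matches, mismatches, gap_runs, gap_bases, tuple(blocks))


def _semiglobal(query: str, target: str, k: int = -1) -> tuple[int, _PathStats, int, int] | None:
    """Best edit-distance alignment of the full ``query`` inside ``target``.

    Returns (edit distance, path stats with query/target coordinates,
    target_start, target_end_exclusive), or None if no alignment exists
    within the edit-distance bound ``k`` (unbounded when negative).
    """
    res = edlib.align(query, target, mode="HW", task="path", k=k)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    t_start, t_end = res["locations"][0]
    stats = _walk_cigar(res["cigar"], 0, t_start)
    return res["editDistance"], stats, t_start, t_end + 1


def _semiglobal_distance(query: str, target: str, k: int = -1) -> int | None:
    res = edlib.align(query, target, mode="HW", task="distance", k=k)
    d = res["editDistance"]
    return None if d < 0 else d


@dataclass(frozen=True)
class AlignScores:
    """Affine scoring used to vet and report alignments."""

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -4.0
    gap_extend: float = -2.0

    def score(self, stats: _PathStats) -> float:
        gap_score = stats.gap_runs * self.gap_open + (
            stats.gap_bases - stats.gap_runs
        ) * self.gap_extend
        return stats.matches * self.match + stats.mismatches * self.mismatch + gap_score


@dataclass(frozen=True)
class ReadAlignment:
    """A read placed on one panel reference.

    ``blocks`` are gap-free runs as (ref_start, read_start, length) in the
    coordinates of ``oriented_bases`` — the read in reference-sense
    orientation (reverse-complemented when ``strand`` is ``-``).
    """

    read_id: str
    reference: str
    strand: str  # "+" | "-"
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    score: float
    identity: float
    edit_distance: int
    blocks: tuple[tuple[int, int, int], ...]
    oriented_bases: str

    def read_base_at(self, ref_pos: int, length: int = 1) -> str | None:
        """Read bases aligned to ``ref_pos .. ref_pos+length`` if that span
        lies gap-free within one aligned block, else None."""
        for rs, qs, n in self.blocks:
            if rs <= ref_pos and ref_pos + length <= rs + n:
                off = ref_pos - rs
                return self.oriented_bases[qs + off : qs + off + length]
        return None


def align_read(
    read: ReadRecord,
    panel: ReferencePanel,
    scores: AlignScores = AlignScores(),
    min_score_fraction: float = 0.4,
) -> ReadAlignment | None:
    """Best placement of a read across all panel amplicons and both strands.

    The shorter sequence is aligned semi-globally inside the longer (so both
    full-amplicon reads with barcode flanks and amplicon substrings place
    correctly); the edit-distance-optimal path is rescored under ``scores``
    and rejected below ``min_score_fraction * len(read) * match``.
    """
    # distance-only prescreen across references and strands, bounded by the
    # divergence the score floor could accept anyway (score ~ 2L - 6d).
    rc = reverse_complement(read.bases)
    best_cand: tuple[int, str, Amplicon, str] | None = None  # (dist, strand, amp, oriented)
    for amp in panel.amplicons:
        for strand, oriented in (("+", read.bases), ("-", rc)):
            if len(oriented) >= len(amp.sequence):
                query, target = amp.sequence, oriented
            else:
                query, target = oriented, amp.sequence
            bound = max(60, int(0.35 * len(query)))
            dist = _semiglobal_distance(query, target, k=bound)
            if dist is not None and (best_cand is None or dist < best_cand[0]):
                best_cand = (dist, strand, amp, oriented)
    if best_cand is None:
        return None
    _, strand, amp, oriented = best_cand
    if len(oriented) >= len(amp.sequence):
        hit = _semiglobal(amp.sequence, oriented)
        if hit is None:
            return None
        dist, stats, t0, t1 = hit
        # query was the reference: block coordinates are already (ref, read)
        blocks = stats.blocks
        ref_start, ref_end = 0, len(amp.sequence)
        read_start, read_end = t0, t1
    else:
        hit = _semiglobal(oriented, amp.sequence)
        if hit is None:
            return None
        dist, stats, t0, t1 = hit
        blocks = tuple((ts, qs, n) for qs, ts, n in stats.blocks)
        ref_start, ref_end = t0, t1
        read_start, read_end = 0, len(oriented)
    aln = ReadAlignment(
        read_id=read.read_id,
        reference=amp.name,
        strand=strand,
        ref_start=ref_start,
        ref_end=ref_end,
        read_start=read_start,
        read_end=read_end,
        score=scores.score(stats),
        identity=stats.identity,
        edit_distance=dist,
        blocks=blocks,
        oriented_bases=oriented,
    )
    if aln.score < min_score_fraction * len(read.bases) * scores.match:
        return None
    return aln


@dataclass(frozen=True)
class BarcodeSpec:
    """A sample barcode flank construct and its acceptance thresholds.

    A read end matches when the flank construct (either orientation) aligns
    with more than ``min_match_length`` aligned bases at more than
    ``min_identity``; assignment requires a match at each end by default.
    """

    barcode_id: str
    sequence: str
    min_match_length: int = 37
    min_identity: float = 0.95
    require_both_ends: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ValueError("min_identity must lie in (0, 1]")
        object.__setattr__(self, "sequence", self.sequence.upper())


def _end_matches(region: str, bc: BarcodeSpec) -> bool:
    for query in (bc.sequence, reverse_complement(bc.sequence)):
        if len(query) > len(region):
            continue
        hit = _semiglobal(query, region)
        if hit is None:
            continue
        _, stats, _, _ = hit
        aligned_bases = stats.matches + stats.mismatches
        if aligned_bases > bc.min_match_length and stats.identity > bc.min_identity:
            return True
    return False


def demultiplex(
    reads: Iterable[ReadRecord],
    barcodes: Sequence[BarcodeSpec],
    window_pad: int = 20,
) -> tuple[dict[str, list[ReadRecord]], list[ReadRecord]]:
    """Assign reads to barcodes; ambiguous or unmatched reads go unassigned.

    Each read end is scanned over a window of barcode length plus
    ``window_pad`` bases; a read is assigned only when exactly one barcode
    matches (both ends, unless ``require_both_ends`` is off).
    """
    seqs = [b.sequence for b in barcodes]
    if len(set(seqs)) != len(seqs):
        raise ValueError("barcode sequences must be pairwise distinct")
    assigned: dict[str, list[ReadRecord]] = {b.barcode_id: [] for b in barcodes}
    unassigned: list[ReadRecord] = []
    for read in reads:
        hits = []
        for bc in barcodes:
            w = len(bc.sequence) + window_pad
            head, tail = read.bases[:w], read.bases[-w:]
            ok_head = _end_matches(head, bc)
            ok_tail = _end_matches(tail, bc)
            ok = (ok_head and ok_tail) if bc.require_both_ends else (ok_head or ok_tail)
            if ok:
                hits.append(bc.barcode_id)
        if len(hits) == 1:
            assigned[hits[0]].append(read)
        else:
            unassigned.append(read)
    return assigned, unassigned


@dataclass(frozen=True)
class CodonPileup:
    """Per-locus tally of read 3-mers over the annotated codon (sense strand)."""

    locus: str
    codon_counts: Mapping[str, int]
    coverage: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "codon_counts", dict(self.codon_counts))
        if self.coverage != sum(self.codon_counts.values()):
            raise ValueError("coverage must equal the sum of codon counts")


def codon_pileup(
    alignments: Iterable[ReadAlignment], panel: ReferencePanel, locus: str
) -> CodonPileup:
    """Count read codons at a locus from alignments to its carrier amplicon.

    Only reads whose alignment spans all three codon positions without a gap
    contribute; minus-strand reads were already re-oriented to the sense
    strand by :func:`align_read`.
    """
    amp = panel.carrier(locus)
    start = amp.codon_starts[locus]
    counts: dict[str, int] = {}
    for aln in alignments:
        if aln.reference != amp.name:
            continue
        codon = aln.read_base_at(start, 3)
        if codon is None:
            continue
        counts[codon] = counts.get(codon, 0) + 1
    return CodonPileup(locus, counts, sum(counts.values()))


@dataclass(frozen=True)
class PileupGenotypeCall:
    """Diploid genotype call (or reasoned no-call) from a codon pileup."""

    locus: str
    genotype: DiploidGenotype | None
    no_call_reason: str | None  # low_coverage | ambiguous_fraction | unknown_codon
    allele_fractions: Mapping[str, float]
    coverage: int

    @property
    def is_called(self) -> bool:
        return self.genotype is not None


def _classify_codon(
    codon: str, codon_table: Mapping[str, str], max_mismatch: int
) -> str:
    """Assign a codon to an allele, tolerating up to ``max_mismatch``
    sequencing errors when the nearest allele codon is unique."""
    allele = codon_table.get(codon)
    if allele is not None:
        return allele
    if max_mismatch > 0 and len(codon) == 3:
        dists = {}
        for ref_codon, a in codon_table.items():
            d = sum(x != y for x, y in zip(codon, ref_codon))
            dists.setdefault(d, []).append(a)
        best = min(dists)
        if best <= max_mismatch and len(set(dists[best])) == 1:
            return dists[best][0]
    return "other"


def call_genotype(
    pileup: CodonPileup,
    codon_table: Mapping[str, str] | None = None,
    min_coverage: int = 100,
    het_min_fraction: float = 0.20,
    hom_min_fraction: float = 0.80,
    max_codon_mismatch: int = 1,
) -> PileupGenotypeCall:
    """Translate codon counts to allele fractions and call the genotype.

    Homozygous when the top allele holds >= ``hom_min_fraction`` of spanning
    reads; heterozygous when the top two alleles each hold >=
    ``het_min_fraction``; otherwise a reasoned no-call.  Codons absent from
    the table are attributed to the unique nearest allele codon within
    ``max_codon_mismatch`` substitutions — the algorithmic counterpart of
    reading a pileup by eye, where one miscalled base does not unseat the
    evident codon — and pool as ``other`` when ambiguous or too far; an
    ``other`` fraction exceeding ``1 - hom_min_fraction`` is a no-call too.
    """
    if codon_table is None:
        codon_table = CODON_TABLES[pileup.locus]
    locus = LOCI[pileup.locus]
    cov = pileup.coverage

    def no_call(reason: str, fractions=None) -> PileupGenotypeCall:
        return PileupGenotypeCall(pileup.locus, None, reason, fractions or {}, cov)

    if cov < min_coverage:
        return no_call("low_coverage")
    allele_counts: dict[str, int] = {}
    for codon, n in pileup.codon_counts.items():
        allele = _classify_codon(codon, codon_table, max_codon_mismatch)
        allele_counts[allele] = allele_counts.get(allele, 0) + n
    fractions = {a: n / cov for a, n in allele_counts.items()}
    if fractions.get("other", 0.0) > 1 - hom_min_fraction:
        return no_call("unknown_codon", fractions)
    ranked = sorted(
        ((f, a) for a, f in fractions.items() if a != "other"), reverse=True
    )
    if ranked and ranked[0][0] >= hom_min_fraction:
        a = ranked[0][1]
        return PileupGenotypeCall(pileup.locus, DiploidGenotype(locus, (a, a)), None, fractions, cov)
    if len(ranked) >= 2 and ranked[0][0] >= het_min_fraction and ranked[1][0] >= het_min_fraction:
        g = DiploidGenotype(locus, (ranked[0][1], ranked[1][1]))
        return PileupGenotypeCall(pileup.locus, g, None, fractions, cov)
    return no_call("ambiguous_fraction", fractions)


_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def coi_consensus(
    alignments: Iterable[ReadAlignment],
    reference_length: int,
    min_coverage: int = 100,
) -> str | None:
    """Per-column majority consensus over the COI reference interval covered
    by >= ``min_coverage`` reads.  Ties and under-covered interior columns
    become N; returns None when no column reaches the coverage floor."""
    counts = np.zeros((reference_length, 4), dtype=np.int64)
    for aln in alignments:
        for rs, qs, n in aln.blocks:
            seg = aln.oriented_bases[qs : qs + n]
            idx = np.array([_BASE_INDEX.get(b, -1) for b in seg])
            pos = np.arange(rs, rs + n)
            keep = idx >= 0
            np.add.at(counts, (pos[keep], idx[keep]), 1)
    coverage = counts.sum(axis=1)
    passing = np.nonzero(coverage >= min_coverage)[0]
    if passing.size == 0:
        return None
    lo, hi = int(passing[0]), int(passing[-1]) + 1
    window = counts[lo:hi]
    top = window.max(axis=1)
    argtop = window.argmax(axis=1)
    ties = (window == top[:, None]).sum(axis=1) > 1
    bases = np.array(list("ACGT"))[argtop]
    bases[ties | (coverage[lo:hi] < min_coverage)] = "N"
    return "".join(bases)


@dataclass(frozen=True)
class SpeciesCall:
    """Best COI reference match for a consensus sequence."""

    taxon: str
    accession: str
    percent_identity: float
    passed: bool
    low_confidence: bool = False


def identify_species(
    consensus: str,
    coi_references: Sequence[CoiReference],
    pass_threshold: float = 99.0,
) -> SpeciesCall:
    """Match a COI consensus to the reference set by end-gap-free percent
    identity (aligned columns including internal gaps).  A consensus shorter
    than half the matched reference is flagged low-confidence."""
    if not coi_references:
        raise ValueError("need at least one COI reference")
    best: tuple[float, CoiReference] | None = None
    for ref in coi_references:
        query, target = (
            (consensus, ref.sequence)
            if len(consensus) <= len(ref.sequence)
            else (ref.sequence, consensus)
        )
        hit = _semiglobal(query, target)
        pct = 100.0 * hit[1].identity if hit is not None else 0.0
        if best is None or pct > best[0]:
            best = (pct, ref)
    pct, ref = best
    return SpeciesCall(
        taxon=ref.taxon,
        accession=ref.accession,
        percent_identity=pct,
        passed=pct >= pass_threshold,
        low_confidence=len(consensus) < 0.5 * len(ref.sequence),
    )


@dataclass(frozen=True)
class GenotypingParams:
    """End-to-end pipeline thresholds (defaults follow the calling rules
    described in the module docstring)."""

    min_mean_q: float = 10.0
    min_coverage: int = 100
    het_min_fraction: float = 0.20
    hom_min_fraction: float = 0.80
    min_score_fraction: float = 0.4
    coi_pass_threshold: float = 99.0
    scores: AlignScores = field(default_factory=AlignScores)


@dataclass(frozen=True)
class SampleGenotypeResult:
    """Outcome of genotyping one sample's read pool."""

    sample_id: str
    status: str  # "called" | "no_call"
    no_call_reason: str | None
    genotype: MultiLocusGenotype | None
    locus_calls: Mapping[str, PileupGenotypeCall]
    species: SpeciesCall | None
    metrics: Mapping[str, object]


def genotype_sample(
    reads: Sequence[ReadRecord],
    barcode: BarcodeSpec,
    panel: ReferencePanel,
    params: GenotypingParams = GenotypingParams(),
) -> SampleGenotypeResult:
    """Quality-filter, demultiplex, align, and genotype one sample.

    The sample is a no-call when any amplicon's aligned coverage falls below
    ``params.min_coverage`` — including the COI amplicon — or when any kdr
    locus cannot be called from its pileup.
    """
    passing = quality_filter(reads, params.min_mean_q)
    assigned, unassigned = demultiplex(passing, [barcode])
    mine = assigned[barcode.barcode_id]
    alignments = []
    for read in mine:
        aln = align_read(read, panel, params.scores, params.min_score_fraction)
        if aln is not None:
            alignments.append(aln)
    by_ref: dict[str, list[ReadAlignment]] = {a.name: [] for a in panel.amplicons}
    for aln in alignments:
        by_ref[aln.reference].append(aln)
    coverage = {name: len(alns) for name, alns in by_ref.items()}
    metrics = {
        "n_reads": len(reads),
        "n_pass_quality": len(passing),
        "n_assigned": len(mine),
        "n_unassigned": len(unassigned),
        "n_aligned": len(alignments),
        "coverage": coverage,
    }

    low = [name for name, cov in coverage.items() if cov < params.min_coverage]
    locus_calls: dict[str, PileupGenotypeCall] = {}
    for locus in panel.loci:
        pile = codon_pileup(by_ref[panel.carrier(locus).name], panel, locus)
        locus_calls[locus] = call_genotype(
            pile,
            min_coverage=params.min_coverage,
            het_min_fraction=params.het_min_fraction,
            hom_min_fraction=params.hom_min_fraction,
        )

    species = None
    if "COI" in by_ref:
        consensus = coi_consensus(
            by_ref["COI"], len(panel.amplicon("COI").sequence), params.min_coverage
        )
        if consensus is not None and panel.coi_references:
            species = identify_species(
                consensus, panel.coi_references, params.coi_pass_threshold
            )

    if low:
        reason = f"low_coverage: {', '.join(sorted(low))} < {params.min_coverage}x"
        return SampleGenotypeResult(
            barcode.barcode_id, "no_call", reason, None, locus_calls, species, metrics
        )
    uncalled = [l for l, c in locus_calls.items() if not c.is_called]
    if uncalled:
        reasons = "; ".join(f"{l}: {locus_calls[l].no_call_reason}" for l in sorted(uncalled))
        return SampleGenotypeResult(
            barcode.barcode_id, "no_call", reasons, None, locus_calls, species, metrics
        )
    genotype = MultiLocusGenotype([locus_calls[l].genotype for l in panel.loci])
    return SampleGenotypeResult(
        barcode.barcode_id, "called", None, genotype, locus_calls, species, metrics
    )
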