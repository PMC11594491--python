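"""Read filtering, demultiplexing, internal alignment, and codon calling."""

import numpy as np
import pytest

from kdrcall import (
    AlignScores,
    BarcodeSpec,
    CodonPileup,
    ReadRecord,
    align_read,
    call_genotype,
    codon_pileup,
    coi_consensus,
    demultiplex,
    genotype_sample,
    identify_species,
    parse_shorthand,
    quality_filter,
    read_fastq,
    reverse_complement,
    write_fastq,
)
from kdrcall.amplicon import GenotypingParams
from kdrcall.panel import CoiReference, default_panel
from kdrcall.simulate import GeneratorConfig, gen_reads, make_barcodes


def make_read(bases, q=20, read_id="r1"):
    return ReadRecord(read_id, bases, np.full(len(bases), q, dtype=np.int16))


def mutate(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestQualityFilter:
    def test_threshold_behaviour(self):
        keep = make_read("ACGT" * 50, q=20, read_id="hi")
        drop = make_read("ACGT" * 50, q=9, read_id="lo")
        rejected = []
        kept = quality_filter([keep, drop], min_mean_q=10, rejected=rejected)
        assert [r.read_id for r in kept] == ["hi"]
        assert rejected[0][0] == "lo"

    def test_empty_input(self):
        assert quality_filter([]) == []


class TestFastqIO:
    def test_roundtrip(self, tmp_path):
        reads = [make_read("ACGTN" * 30, q=q, read_id=f"r{q}") for q in (5, 20, 38)]
        path = tmp_path / "x.fastq"
        write_fastq(reads, path)
        back = read_fastq(path)
        assert [r.bases for r in back] == [r.bases for r in reads]
        assert all((a.quals == b.quals).all() for a, b in zip(back, reads))


class TestDemultiplex:
    def _insert(self, rng, n=300):
        return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])

    def test_exact_flanks_both_ends_assigned(self):
        rng = np.random.default_rng(0)
        bc = make_barcodes(2, seed=1)
        read = make_read(bc[0].sequence + self._insert(rng) + reverse_complement(bc[0].sequence))
        assigned, unassigned = demultiplex([read], bc)
        assert [r.read_id for r in assigned[bc[0].barcode_id]] == ["r1"]
        assert unassigned == []

    def test_one_end_only_goes_unassigned(self):
        rng = np.random.default_rng(0)
        bc = make_barcodes(1, seed=1)
        read = make_read(bc[0].sequence + self._insert(rng))
        assigned, unassigned = demultiplex([read], bc)
        assert assigned[bc[0].barcode_id] == [] and len(unassigned) == 1

    def test_short_flank_match_fails_length_rule(self):
        """A 36-base barcode fragment cannot satisfy the >37 aligned-base rule."""
        rng = np.random.default_rng(0)
        spec = make_barcodes(1, seed=1)[0]
        frag = spec.sequence[:36]
        read = make_read(frag + self._insert(rng) + reverse_complement(frag))
        bc36 = BarcodeSpec(spec.barcode_id, frag)
        assigned, unassigned = demultiplex([read], [bc36])
        assert len(unassigned) == 1

    def test_degraded_flank_fails_identity_rule(self):
        rng = np.random.default_rng(0)
        spec = make_barcodes(1, seed=1)[0]
        bad = mutate(spec.sequence, [3, 11, 17])  # 37/40 = 92.5% identity
        read = make_read(bad + self._insert(rng) + reverse_complement(bad))
        assigned, unassigned = demultiplex([read], [spec])
        assert len(unassigned) == 1


class TestAlignRead:
    def test_error_free_substring_aligns_perfectly(self, panel):
        m2 = panel.amplicon("M2").sequence
        aln = align_read(make_read(m2[20:620]), panel)
        assert aln.reference == "M2" and aln.strand == "+"
        assert aln.identity == 1.0
        assert (aln.ref_start, aln.ref_end) == (20, 620)

    def test_reverse_complement_maps_to_same_interval(self, panel):
        m2 = panel.amplicon("M2").sequence
        fwd = align_read(make_read(m2[20:620]), panel)
        rev = align_read(make_read(reverse_complement(m2[20:620])), panel)
        assert rev.strand == "-"
        assert (rev.reference, rev.ref_start, rev.ref_end) == ("M2", 20, 620)
        assert rev.oriented_bases == fwd.oriented_bases

    def test_random_reads_stay_below_score_floor(self, panel):
        """Empirical null: none of 200 random 500-mers reaches the score
        floor, so chance hits cannot enter pileups."""
        rng = np.random.default_rng(99)
        for i in range(200):
            bases = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
            assert align_read(make_read(bases), panel) is None

    def test_affine_score_matches_pairwise_aligner_oracle(self, panel):
        """On substitution-only reads the reported score equals the optimal
        local affine alignment score from an independent implementation."""
        Align = pytest.importorskip("Bio.Align")
        oracle = Align.PairwiseAligner(
            mode="local",
            match_score=2,
            mismatch_score=-4,
            open_gap_score=-4,
            extend_gap_score=-2,
        )
        m2 = panel.amplicon("M2").sequence
        read = mutate(m2[100:400], [10, 57, 141, 260])
        aln = align_read(make_read(read), panel)
        assert aln.score == oracle.score(m2, read)
        assert aln.identity == pytest.approx(296 / 300)


class TestCodonPileup:
    def _aligned(self, panel, reads):
        return [align_read(r, panel) for r in reads]

    def test_error_free_homozygote_counts(self, panel, barcode):
        cfg = GeneratorConfig(
            sub_rate=0, ins_rate=0, del_rate=0, flank_error_rate=0,
            coverage={"M2": 150},
        )
        reads = gen_reads(parse_shorthand("SSVVFF"), panel, cfg, seed=3, barcode=barcode)
        pile = codon_pileup(self._aligned(panel, reads), panel, "1016")
        assert pile.codon_counts == {"GTA": 150}
        assert pile.coverage == 150

    def test_heterozygote_splits_roughly_evenly(self, panel, barcode):
        cfg = GeneratorConfig(
            sub_rate=0, ins_rate=0, del_rate=0, flank_error_rate=0,
            coverage={"M2": 100},
        )
        reads = gen_reads(parse_shorthand("SSGIFC"), panel, cfg, seed=5, barcode=barcode)
        pile = codon_pileup(self._aligned(panel, reads), panel, "1016")
        assert set(pile.codon_counts) == {"GGA", "ATA"}
        assert pile.coverage == 100
        assert 30 <= pile.codon_counts["GGA"] <= 70  # binomial split, seeded

    def test_deletion_inside_codon_excluded(self, panel):
        m2 = panel.amplicon("M2")
        start = m2.codon_starts["1016"]
        clean = m2.sequence
        gapped = clean[: start + 1] + clean[start + 2 :]  # deletes codon base 2
        piles = codon_pileup(
            self._aligned(panel, [make_read(clean, read_id="a"), make_read(gapped, read_id="b")]),
            panel,
            "1016",
        )
        assert piles.coverage == 1

    def test_unknown_locus_rejected(self, panel):
        with pytest.raises(KeyError):
            codon_pileup([], panel, "410")


class TestCallGenotype:
    def _pileup(self, counts):
        return CodonPileup("1016", counts, sum(counts.values()))

    def test_low_coverage_is_a_no_call(self):
        call = call_genotype(self._pileup({"GTA": 80}))
        assert call.genotype is None and call.no_call_reason == "low_coverage"

    def test_heterozygote_in_the_noisy_regime(self):
        counts = {"GGA": 110, "ATA": 86, "TTT": 4}  # G 0.55 / I 0.43 / other 0.02
        call = call_genotype(self._pileup(counts), max_codon_mismatch=0)
        assert call.genotype.format() == "GI"

    def test_clean_homozygote(self):
        call = call_genotype(self._pileup({"GTA": 194, "ATA": 6}))
        assert call.genotype.format() == "VV"

    def test_ambiguous_fractions_are_a_no_call(self):
        counts = {"GTA": 150, "ATA": 30, "GGA": 20}  # 0.75 / 0.15 / 0.10
        call = call_genotype(self._pileup(counts))
        assert call.no_call_reason == "ambiguous_fraction"

    def test_unknown_codon_flood_is_a_no_call(self):
        counts = {"GTA": 140, "TTT": 60}
        call = call_genotype(self._pileup(counts), max_codon_mismatch=0)
        assert call.no_call_reason == "unknown_codon"

    def test_single_error_codons_attributed_to_nearest_allele(self):
        # GTC is one substitution from GTA (V) and >=2 from ATA/GGA
        counts = {"GTA": 150, "GTC": 40, "ATA": 10}
        call = call_genotype(self._pileup(counts))
        assert call.genotype.format() == "VV"
        assert call.allele_fractions["V"] == pytest.approx(0.95)

    def test_raising_min_coverage_never_creates_a_call(self):
        counts = {"GGA": 110, "ATA": 86, "TTT": 4}
        for low, high in [(100, 150), (150, 300)]:
            a = call_genotype(self._pileup(counts), min_coverage=low)
            b = call_genotype(self._pileup(counts), min_coverage=high)
            if a.genotype is None:
                assert b.genotype is None


class TestCoiAndSpecies:
    def test_error_free_consensus_equals_template(self, panel, barcode):
        cfg = GeneratorConfig(
            sub_rate=0, ins_rate=0, del_rate=0, flank_error_rate=0,
            coverage={"COI": 120},
        )
        reads = gen_reads(parse_shorthand("SSVVFF"), panel, cfg, seed=9, barcode=barcode)
        alns = [align_read(r, panel) for r in reads]
        consensus = coi_consensus(alns, 658, min_coverage=100)
        assert consensus == panel.amplicon("COI").sequence

    def test_noisy_consensus_still_equals_template(self, panel, barcode):
        """5% substitutions at 200x: the per-column majority is the template
        base with overwhelming probability."""
        cfg = GeneratorConfig(
            sub_rate=0.05, ins_rate=0, del_rate=0, flank_error_rate=0,
            coverage={"COI": 200},
        )
        reads = gen_reads(parse_shorthand("SSVVFF"), panel, cfg, seed=10, barcode=barcode)
        alns = [align_read(r, panel) for r in reads]
        consensus = coi_consensus(alns, 658, min_coverage=100)
        assert consensus == panel.amplicon("COI").sequence

    def test_no_reads_no_consensus(self):
        assert coi_consensus([], 658, min_coverage=100) is None

    def test_identity_percentages(self, panel):
        coi = panel.amplicon("COI").sequence
        refs = [CoiReference("Aedes aegypti (synthetic)", "AAEG-SYN-1", coi)]
        assert identify_species(coi, refs).percent_identity == 100.0
        two = identify_species(mutate(coi, [5, 600]), refs)
        assert two.percent_identity == pytest.approx(100 * 656 / 658)
        assert two.passed
        thirteen = identify_species(mutate(coi, list(range(40, 300, 20))), refs)
        assert thirteen.percent_identity == pytest.approx(100 * 645 / 658)
        assert not thirteen.passed

    def test_best_reference_wins(self, panel):
        coi = panel.amplicon("COI").sequence
        call = identify_species(coi, panel.coi_references)
        assert call.accession == "AAEG-SYN-1"
        assert call.taxon.startswith("Aedes aegypti")

    def test_short_consensus_flagged_low_confidence(self, panel):
        coi = panel.amplicon("COI").sequence
        call = identify_species(coi[:200], panel.coi_references)
        assert call.low_confidence


class TestGenotypeSample:
    def test_recovers_mixed_ensemble_genotype(self, panel, barcode):
        cfg = GeneratorConfig(coverage={"M1": 300, "M2": 300, "M3": 300, "COI": 300})
        reads = gen_reads(parse_shorthand("SSGIFC"), panel, cfg, seed=21, barcode=barcode)
        res = genotype_sample(reads, barcode, panel)
        assert res.status == "called"
        assert str(res.genotype) == "SSGIFC"
        assert res.species.passed

    def test_low_coverage_amplicon_excludes_sample(self, panel, barcode, cfg):
        low = GeneratorConfig(coverage={"M1": 50, "M2": 200, "M3": 200, "COI": 200})
        reads = gen_reads(parse_shorthand("SSVVFF"), panel, low, seed=22, barcode=barcode)
        res = genotype_sample(reads, barcode, panel)
        assert res.status == "no_call"
        assert "M1" in res.no_call_reason and "low_coverage" in res.no_call_reason

    def test_water_blank_is_a_no_call(self, panel, barcode):
        res = genotype_sample([], barcode, panel)
        assert res.status == "no_call"
        assert res.metrics["n_assigned"] == 0
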