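"""Confusability predictions, constraint intersection, and concordance."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kdrcall import (
    LOCUS_1016,
    AsPcrObservation,
    DiploidGenotype,
    McaCall,
    SangerObservation,
    build_concordance,
    constraint_set,
    disambiguation_check,
    load_table1,
    predict_aspcr,
    predict_assay_outcome,
    predict_mca_call,
    resolve_1016,
)
from kdrcall.assays import MCA_MODELS, record_observations
from kdrcall.model import enumerate_diploid_genotypes

G1016 = {g.format(): g for g in enumerate_diploid_genotypes(LOCUS_1016)}
ALL_1016 = frozenset(G1016.values())


def gset(*names):
    return frozenset(G1016[n] for n in names)


class TestPredictions:
    @pytest.mark.parametrize(
        "genotype,assay,classes",
        [
            ("GG", "V1016I_MCA", {"Vclass"}),   # G masquerades as V
            ("II", "V1016G_MCA", {"nonG"}),     # I masquerades as non-G
            ("VG", "V1016I_MCA", {"Vclass"}),
            ("GI", "V1016G_MCA", {"Gclass", "nonG"}),
            ("VI", "V1016I_MCA", {"Vclass", "Iclass"}),
        ],
    )
    def test_mca_outcomes(self, genotype, assay, classes):
        assert predict_assay_outcome(G1016[genotype], MCA_MODELS[assay]) == frozenset(classes)

    @pytest.mark.parametrize(
        "genotype,band_v,band_g",
        [
            ("VV", "strong", "absent"),
            ("II", "weak", "absent"),  # off-target weak amplification of I
            ("GI", "weak", "strong"),
            ("VG", "strong", "strong"),
            ("GG", "absent", "strong"),
        ],
    )
    def test_aspcr_outcomes(self, genotype, band_v, band_g):
        obs = predict_aspcr(G1016[genotype])
        assert (obs.band_V, obs.band_G) == (band_v, band_g)


class TestConstraintSets:
    def test_vclass_homozygous_pattern(self):
        obs = McaCall("V1016I_MCA", frozenset({"Vclass"}), "called")
        assert constraint_set(obs) == gset("VV", "VG", "GG")

    def test_g_heterozygous_pattern(self):
        obs = McaCall("V1016G_MCA", frozenset({"Gclass", "nonG"}), "called")
        assert constraint_set(obs) == gset("VG", "GI")

    def test_weakv_plus_gband(self):
        obs = AsPcrObservation(band_V="weak", band_G="strong")
        assert constraint_set(obs) == gset("VG", "GI")

    def test_no_call_constrains_nothing(self):
        obs = McaCall("V1016I_MCA", frozenset(), "no_call", "no amplification")
        assert constraint_set(obs) == ALL_1016

    def test_single_sanger_symbol_asserts_presence_only(self):
        assert constraint_set(SangerObservation(("G",))) == gset("VG", "GG", "GI")

    def test_strict_band_mode_excludes_missing_bands(self):
        obs = AsPcrObservation(band_V="strong", band_G="absent")
        assert constraint_set(obs) == gset("VV", "VG", "VI")
        assert constraint_set(obs, strict_bands=True) == gset("VV", "VI")

    def test_oracle_equivalence_for_every_mca_outcome(self):
        """The declarative constraint rule equals brute-force filtering of the
        genotype universe through the forward prediction, for every
        observable outcome of every packaged MCA model."""
        for model in MCA_MODELS.values():
            universe = enumerate_diploid_genotypes(model.locus)
            outcomes = {frozenset(predict_assay_outcome(g, model)) for g in universe}
            for outcome in outcomes:
                obs = McaCall(model.assay_id, outcome, "called")
                brute = frozenset(
                    g for g in universe if predict_assay_outcome(g, model) == outcome
                )
                assert constraint_set(obs, model) == brute

    def test_oracle_equivalence_for_every_aspcr_outcome(self):
        """AS-PCR constraint sets contain exactly the genotypes whose
        predicted bands are compatible with the observation (band dropout
        allowed)."""

        def compatible(pred: AsPcrObservation, obs: AsPcrObservation) -> bool:
            rank = {"absent": 0, "weak": 1, "strong": 2}
            return rank[obs.band_V] <= rank[pred.band_V] and (
                rank[obs.band_G] <= rank[pred.band_G]
            )

        states = ("absent", "weak", "strong")
        for bv, bg in itertools.product(states, states):
            obs = AsPcrObservation(band_V=bv, band_G=bg)
            if obs.is_no_call:
                continue
            brute = frozenset(
                g for g in ALL_1016 if compatible(predict_aspcr(g), obs)
            )
            assert constraint_set(obs) == brute


class TestResolve1016:
    def test_het_patterns_resolve_gi_uniquely(self):
        obs = [
            McaCall("V1016I_MCA", frozenset({"Vclass", "Iclass"}), "called"),
            McaCall("V1016G_MCA", frozenset({"Gclass", "nonG"}), "called"),
        ]
        res = resolve_1016(obs)
        assert res.status == "resolved"
        assert res.genotype == G1016["GI"]

    def test_double_homozygous_patterns_resolve_vv(self):
        obs = [
            McaCall("V1016I_MCA", frozenset({"Vclass"}), "called"),
            McaCall("V1016G_MCA", frozenset({"nonG"}), "called"),
        ]
        assert resolve_1016(obs).genotype == G1016["VV"]

    def test_both_mcas_resolve_every_genotype(self):
        """Running both 1016 assays determines the genotype uniquely for all
        six diploid genotypes — the joint-assay disambiguation theorem."""
        for g in ALL_1016:
            obs = [
                predict_mca_call(g, MCA_MODELS["V1016I_MCA"]),
                predict_mca_call(g, MCA_MODELS["V1016G_MCA"]),
            ]
            res = resolve_1016(obs)
            assert res.status == "resolved" and res.genotype == g

    def test_three_method_confirmation(self):
        """MCA GIFC + Sanger GI + NGS GI: G is confirmed by three methods."""
        g = G1016["GI"]
        obs = [
            predict_mca_call(g, MCA_MODELS["V1016I_MCA"]),
            predict_mca_call(g, MCA_MODELS["V1016G_MCA"]),
            SangerObservation(("G", "I")),
            g,  # NGS
        ]
        res = resolve_1016(obs)
        assert res.genotype == g
        assert res.support["G"].detected_by == frozenset({"MCA", "Sanger", "NGS"})
        assert res.support["G"].confirmed and res.support["I"].confirmed

    def test_single_method_detection_is_not_confirmation(self):
        res = resolve_1016([SangerObservation(("G", "I"))])
        assert res.genotype == G1016["GI"]
        assert not res.support["G"].confirmed

    def test_conflict_names_a_minimal_method_pair(self):
        obs = [
            McaCall("V1016G_MCA", frozenset({"Gclass"}), "called"),  # GG
            SangerObservation(("I", "I")),
        ]
        res = resolve_1016(obs)
        assert res.status == "conflict"
        assert set(res.conflict_methods) == {"MCA", "Sanger"}

    def test_no_called_observation_gives_no_call(self):
        res = resolve_1016([McaCall("V1016I_MCA", frozenset(), "no_call", "x")])
        assert res.status == "no_call"
        assert res.candidates == ALL_1016

    @given(st.lists(st.sampled_from(sorted(G1016)), min_size=1, max_size=4))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_adding_observations_never_enlarges_candidates(self, names):
        """Constraint intersection is monotone in the observation list."""
        g = G1016[names[0]]
        obs = [
            predict_mca_call(g, MCA_MODELS["V1016I_MCA"]),
            predict_mca_call(g, MCA_MODELS["V1016G_MCA"]),
            predict_aspcr(g),
            SangerObservation(g.alleles),
        ]
        prev = ALL_1016
        for i in range(1, len(obs) + 1):
            cand = resolve_1016(obs[:i]).candidates
            assert cand <= prev
            prev = cand
        assert g in prev


class TestDisambiguation:
    def test_joint_assays_injective(self):
        report = disambiguation_check(
            [MCA_MODELS["V1016I_MCA"], MCA_MODELS["V1016G_MCA"]]
        )
        assert report.injective and report.collisions == ()

    @pytest.mark.parametrize(
        "assay,hom_collision,het_collision",
        [
            ("V1016I_MCA", {"VV", "VG", "GG"}, {"VI", "GI"}),
            ("V1016G_MCA", {"VV", "VI", "II"}, {"VG", "GI"}),
        ],
    )
    def test_single_assay_collisions(self, assay, hom_collision, het_collision):
        """Each assay alone collapses the three genotypes of its blind class
        and cannot separate the two heterozygote patterns."""
        report = disambiguation_check([MCA_MODELS[assay]])
        assert not report.injective
        groups = {frozenset(g.format() for g in c) for c in report.collisions}
        assert groups == {frozenset(hom_collision), frozenset(het_collision)}


class TestConcordance:
    def test_published_table_counts(self):
        ct = build_concordance(load_table1())
        s = ct.summary
        assert s["mca_genotype_counts"]["GIFC"] == 7
        assert s["field_g_positive_by_method"] == {
            "MCA": 8,
            "AS-PCR": 5,
            "Sanger": 4,
            "NGS": 6,
        }
        assert s["n_field_ngs_g_with_989p"] == 3
        assert s["n_ngs_no_call"] == 4
        assert s["n_coi_tested"] == 14 and s["n_coi_pass"] == 12

    def test_mislabelled_control_resolves_against_observations(self):
        """The SPGIFC-labelled control that every method saw as II resolves
        cleanly to II: the resolver trusts observations, not labels."""
        rec = next(r for r in load_table1() if r.site == "Control-SPGIFC")
        res = resolve_1016(record_observations(rec))
        assert res.status == "resolved"
        assert res.genotype == G1016["II"]

    def test_duplicate_sample_ids_rejected(self):
        recs = load_table1()
        twice = [recs[0], recs[0]]
        with pytest.raises(ValueError):
            build_concordance(twice)

    def test_empty_record_list(self):
        ct = build_concordance([])
        assert ct.table.empty
        assert ct.summary["n_samples"] == 0
        assert ct.summary["mca_genotype_counts"] == {}
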