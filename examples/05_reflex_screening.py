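"""Control-panel validation and reflex (gatekeeper) screening.

Because 1016G rides 1534F backgrounds, a lab running the legacy first tier
(V1016I + F1534C) can reflex only the 1534F-bearing samples to V1016G and
S989P testing instead of screening everything for the Indopacific alleles.
"""

from kdrcall import (
    LEGACY_REFLEX,
    PanelDefinition,
    load_table1,
    screen_cohort,
    validate_panel,
)

# A panel must control every allele of every assayed locus, plus het mixes.
panel = PanelDefinition(
    assays=("V1016I_MCA", "V1016G_MCA", "F1534C_MCA"),
    controls={
        "ROCK": "SSVVFF",     # susceptible
        "PR": "SSIICC",       # Western-Hemisphere resistant
        "CKR": "PPGGFF",      # Indopacific resistant
        "ROCKxPR": "SSVIFC",  # het mix
        "PRxCKR": "SPGIFC",   # het mix
        "NFW": None,          # negative
    },
)
report = validate_panel(panel)
print("panel valid:", report.valid)

incomplete = PanelDefinition(
    assays=("V1016I_MCA", "V1016G_MCA"), controls={"ROCK": "SSVVFF", "PR": "SSIICC"}
)
bad = validate_panel(incomplete)
print("without a G control:", bad.missing_allele_controls, "negative missing:", bad.missing_negative)

# Reflex workload over the packaged field samples.
field = [r for r in load_table1() if not r.is_control]
table, summary = screen_cohort(field, LEGACY_REFLEX)
print(f"\nlegacy_reflex over {summary['n_samples']} field samples: "
      f"{summary['n_reflex_samples']} reflexed, {summary['n_reflex_tests']} extra tests")
print(table[["sample_id", "first_tier_mca", "reflex", "ensemble"]].to_string(index=False))
print("\nEvery F-bearing first-tier string (GIFC, VGFC) is reflexed; all-C samples are not.")
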