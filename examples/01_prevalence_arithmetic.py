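"""Carrier-family prevalence: pooling screening cohorts for one variant.

An initial 15-family WGS screen found the ACAD9 A326T variant in three
families; a 31-family Sanger extension found one more carrier family.
"""

from pedseg import ValidationCohort, VariantKey, family_prevalence, merge_cohorts

ACAD9 = VariantKey("3", 128622922, "G", "A")

initial = ValidationCohort(
    "ACAD9", ACAD9, families_tested=15,
    carrier_families=frozenset({"25-4-46", "25-1-91", "25-9-113"}),
)
extension = ValidationCohort(
    "ACAD9", ACAD9, families_tested=31, carrier_families=frozenset({"25-2-209"}),
)

merged = merge_cohorts(initial, [extension])
rec = family_prevalence(merged)
print(f"ACAD9 carrier families: {rec.fraction_display} ({rec.percent_display}%)")

atm = family_prevalence(
    ValidationCohort("ATM", VariantKey("11", 108365000, "G", "T"), 36, frozenset({"02-5-0382"}))
)
print(f"ATM carrier families:   {atm.fraction_display} ({atm.percent_display}%)")

# The percentages are the fraction of screened families carrying the
# variant — the study-level evidence that a candidate recurs beyond the
# family in which it was discovered.
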