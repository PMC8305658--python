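"""Carrier-family counting, prevalence arithmetic and summary reporting.

A :class:`ValidationCohort` records, for one gene variant, how many families
were screened and which carried it.  Prevalence percentages are reported to
one decimal with banker's (round-half-even) rounding; the display form
suppresses a trailing ``.0`` so that 1/49 prints as ``2%`` while 4/46 prints
as ``8.7%``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .variants import AFBand, VariantKey, af_band

__all__ = [
    "ValidationCohort",
    "PrevalenceRecord",
    "CandidateSummary",
    "family_prevalence",
    "merge_cohorts",
    "build_summary_table",
    "SUMMARY_COLUMNS",
]


@dataclass(frozen=True)
class ValidationCohort:
    gene: str
    variant: VariantKey
    families_tested: int
    carrier_families: frozenset[str]
    label: str = ""

    def __post_init__(self):
        if self.families_tested <= 0:
            raise ValueError("families_tested must be positive")
        if len(self.carrier_families) > self.families_tested:
            raise ValueError(
                f"{self.gene}: {len(self.carrier_families)} carrier families exceed "
                f"{self.families_tested} tested"
            )


@dataclass(frozen=True)
class PrevalenceRecord:
    gene: str
    numerator: int
    denominator: int
    percent: float

    @property
    def fraction_display(self) -> str:
        return f"{self.numerator}/{self.denominator}"

    @property
    def percent_display(self) -> str:
        """One decimal, trailing '.0' suppressed (8.7 -> '8.7', 2.0 -> '2')."""
        if self.percent == int(self.percent):
            return str(int(self.percent))
        return f"{self.percent:.1f}"


def family_prevalence(cohort: ValidationCohort) -> PrevalenceRecord:
    """Carrier-family prevalence as a percent, one decimal, round-half-even."""
    num = len(cohort.carrier_families)
    den = cohort.families_tested
    return PrevalenceRecord(
        gene=cohort.gene,
        numerator=num,
        denominator=den,
        percent=round(100.0 * num / den, 1),
    )


def merge_cohorts(
    initial: ValidationCohort, extensions: Sequence[ValidationCohort]
) -> ValidationCohort:
    """Pool an initial screen with extension screens of the same variant.

    Tested counts are summed and carrier sets unioned; overlapping carrier
    family ids (a family counted twice) are an error.
    """
    tested = initial.families_tested
    carriers = set(initial.carrier_families)
    for ext in extensions:
        if ext.gene != initial.gene or ext.variant != initial.variant:
            raise ValueError(
                f"cannot merge cohorts for different variants: "
                f"{initial.gene} {initial.variant} vs {ext.gene} {ext.variant}"
            )
        overlap = carriers & ext.carrier_families
        if overlap:
            raise ValueError(f"overlapping carrier families: {sorted(overlap)}")
        tested += ext.families_tested
        carriers |= ext.carrier_families
    return ValidationCohort(
        gene=initial.gene,
        variant=initial.variant,
        families_tested=tested,
        carrier_families=frozenset(carriers),
        label=initial.label,
    )


@dataclass
class CandidateSummary:
    """One row of the cohort-level findings table."""

    gene: str
    variant: VariantKey
    family_ids: list[str]
    family_types: list[str]
    hgvs_c: str | None
    hgvs_p: str | None
    mutation_type: str
    significance: str  # curated pass-through label (pathogenic/deleterious/VUS)
    segregation: bool
    prevalence: PrevalenceRecord | None = None
    population_af: float | None = None


SUMMARY_COLUMNS = (
    "gene",
    "family_ids",
    "family_type",
    "variant",
    "hgvs_c",
    "hgvs_p",
    "mutation_type",
    "significance",
    "segregation",
    "families_with_variant",
    "maf",
    "af_band",
)


def build_summary_table(candidates: Iterable[CandidateSummary]) -> pd.DataFrame:
    """Build the per-gene findings table (TSV-serializable, fixed columns)."""
    rows = []
    for c in sorted(candidates, key=lambda c: (c.gene, c.variant)):
        band, imputed = af_band(c.population_af)
        rows.append(
            {
                "gene": c.gene,
                "family_ids": ";".join(c.family_ids),
                "family_type": ";".join(c.family_types),
                "variant": str(c.variant),
                "hgvs_c": c.hgvs_c or ".",
                "hgvs_p": c.hgvs_p or ".",
                "mutation_type": c.mutation_type,
                "significance": c.significance,
                "segregation": "yes" if c.segregation else "no",
                "families_with_variant": (
                    c.prevalence.fraction_display if c.prevalence else "."
                ),
                "maf": "." if c.population_af is None else format(c.population_af, "g"),
                "af_band": band.value + ("(imputed)" if imputed else ""),
            }
        )
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
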