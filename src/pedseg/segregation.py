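"""Per-family co-segregation verdicts with incomplete-penetrance handling.

A candidate variant *co-segregates* with a phenotype in a family when every
genotyped affected member carries it.  An affected non-carrier beyond the
allowed maximum eliminates the candidate (verdict ``fails``).  Unaffected
carriers never eliminate a candidate under the default rule — dominant
cancer-predisposition alleles are incompletely penetrant, so a healthy
elderly carrier and a carrier too young to have developed disease are both
expected observations.  Such carriers are listed as exemptions annotated by
age relative to the typical onset age (65 years for familial pancreatic
cancer).

Only germline genotypes of genotyped individuals are counted; ungenotyped
members are uninformative, and obligate-carrier inference is deliberately
not performed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .pedigree import Family, Phenotype
from .prioritize import TriagedVariant
from .variants import AnnotatedVariant, Genotype, VariantKey

__all__ = [
    "PhenotypeSpec",
    "PenetranceRule",
    "Verdict",
    "Exemption",
    "SegregationResult",
    "PANCREATIC",
    "PANCREATIC_MELANOMA",
    "BREAST",
    "evaluate_segregation",
    "evaluate_cross_phenotype",
    "mendelian_consistency",
    "MendelianViolation",
    "count_cosegregating_candidates",
    "family_view",
]


@dataclass(frozen=True)
class PhenotypeSpec:
    """A named set of phenotypes counted as 'affected' for segregation."""

    name: str
    target_phenotypes: frozenset[Phenotype]

    def __post_init__(self):
        if not self.target_phenotypes:
            raise ValueError("target_phenotypes must be non-empty")


#: PDAC or its high-grade precursor lesions (PanIN2/3) — the default target.
PANCREATIC = PhenotypeSpec(
    "pancreatic_disease",
    frozenset({Phenotype.PDAC, Phenotype.PRECURSOR_HIGH_GRADE}),
)

#: Pancreatic disease plus melanoma, for pancreatic cancer-melanoma
#: syndrome (PCMS) families where the melanoma case is a segregating case.
PANCREATIC_MELANOMA = PhenotypeSpec(
    "pancreatic_melanoma",
    frozenset({Phenotype.PDAC, Phenotype.PRECURSOR_HIGH_GRADE, Phenotype.MELANOMA}),
)

BREAST = PhenotypeSpec("breast_cancer", frozenset({Phenotype.BREAST_CANCER}))


@dataclass(frozen=True)
class PenetranceRule:
    allow_unaffected_carriers: bool = True
    #: annotation threshold only: exemptions at/above it are tagged
    #: ``elderly_carrier``, below it ``young_carrier``
    exemption_age_threshold: float = 65.0
    max_affected_noncarriers: int = 0

    def __post_init__(self):
        if self.exemption_age_threshold < 0:
            raise ValueError("exemption_age_threshold must be >= 0")
        if self.max_affected_noncarriers < 0:
            raise ValueError("max_affected_noncarriers must be >= 0")


class Verdict(str, enum.Enum):
    COMPLETE = "complete"
    INCOMPLETE_PENETRANCE = "incomplete_penetrance"
    FAILS = "fails"

    @property
    def passing(self) -> bool:
        return self is not Verdict.FAILS


@dataclass(frozen=True)
class Exemption:
    individual_id: str
    age_years: float | None
    category: str  # elderly_carrier | young_carrier | unknown_age_carrier


@dataclass
class SegregationResult:
    family_id: str
    key: VariantKey
    phenotype: str
    verdict: Verdict
    affected_carriers: int
    affected_genotyped: int
    affected_noncarriers: int
    unaffected_carriers: int
    exemptions: list[Exemption] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def exempted_unaffected_carriers(self) -> int:
        """Healthy (phenotype-free) carriers exempted under the rule."""
        return len(self.exemptions)


def _exemption_category(age: float | None, rule: PenetranceRule) -> str:
    if age is None:
        return "unknown_age_carrier"
    return "elderly_carrier" if age >= rule.exemption_age_threshold else "young_carrier"


def family_view(variant: AnnotatedVariant, family: Family) -> AnnotatedVariant:
    """Copy of a variant whose genotype map is restricted to one family.

    Cohort-wide genotype maps (as read from a multi-family VCF) must be
    subset before per-family evaluation.
    """
    from dataclasses import replace

    return replace(
        variant,
        genotypes={i: g for i, g in variant.genotypes.items() if i in family.members},
        tumor_genotypes={
            i: g for i, g in variant.tumor_genotypes.items() if i in family.members
        },
    )


def evaluate_segregation(
    family: Family,
    variant: AnnotatedVariant,
    phenotype: PhenotypeSpec = PANCREATIC,
    rule: PenetranceRule = PenetranceRule(),
) -> SegregationResult:
    """Evaluate whether a variant co-segregates with a phenotype in a family.

    Counts only members with a non-missing germline genotype.  Verdicts:

    - ``fails`` when genotyped affected non-carriers exceed
      ``rule.max_affected_noncarriers``, or no genotyped affected member
      exists (note ``no_informative_affected``);
    - ``complete`` when additionally no genotyped unaffected member carries
      the variant;
    - ``incomplete_penetrance`` otherwise, when unaffected carriers are
      allowed; each phenotype-free carrier is recorded as an exemption with
      its age annotation, carriers affected by a non-target phenotype are
      noted.
    """
    for iid in variant.genotypes:
        if iid not in family.members:
            raise KeyError(
                f"genotype for unknown individual {iid!r} in family {family.family_id!r}"
            )
    genotyped = [
        m
        for m in family
        if variant.genotype(m.individual_id) is not Genotype.MISSING
        and m.individual_id in variant.genotypes
    ]
    targets = phenotype.target_phenotypes
    affected = [m for m in genotyped if m.has_phenotype(targets)]
    unaffected = [m for m in genotyped if not m.has_phenotype(targets)]
    carriers = {
        m.individual_id
        for m in genotyped
        if variant.genotype(m.individual_id).carries_alt
    }

    affected_carriers = sum(1 for m in affected if m.individual_id in carriers)
    affected_noncarriers = len(affected) - affected_carriers
    unaffected_carrier_members = [m for m in unaffected if m.individual_id in carriers]

    notes: list[str] = []
    exemptions: list[Exemption] = []
    for m in unaffected_carrier_members:
        if m.phenotypes:
            # affected by a non-target phenotype (e.g. breast cancer when
            # evaluating pancreatic disease): not a 'healthy' exemption
            notes.append(
                "nontarget_phenotype_carrier:"
                + m.individual_id
                + ":"
                + ";".join(sorted(p.value for p in m.phenotypes))
            )
        else:
            exemptions.append(
                Exemption(
                    m.individual_id,
                    m.age_years,
                    _exemption_category(m.age_years, rule),
                )
            )

    if not carriers:
        notes.append("no_carriers")

    if not affected:
        verdict = Verdict.FAILS
        notes.append("no_informative_affected")
    elif affected_noncarriers > rule.max_affected_noncarriers:
        verdict = Verdict.FAILS
    elif not unaffected_carrier_members:
        verdict = Verdict.COMPLETE
    elif rule.allow_unaffected_carriers:
        verdict = Verdict.INCOMPLETE_PENETRANCE
    else:
        verdict = Verdict.FAILS
        notes.append("unaffected_carrier_disallowed")

    if verdict is Verdict.FAILS:
        exemptions = []

    return SegregationResult(
        family_id=family.family_id,
        key=variant.key,
        phenotype=phenotype.name,
        verdict=verdict,
        affected_carriers=affected_carriers,
        affected_genotyped=len(affected),
        affected_noncarriers=affected_noncarriers,
        unaffected_carriers=len(unaffected_carrier_members),
        exemptions=exemptions,
        notes=notes,
    )


def evaluate_cross_phenotype(
    family: Family,
    variant: AnnotatedVariant,
    phenotypes: Iterable[PhenotypeSpec],
    rule: PenetranceRule = PenetranceRule(),
) -> dict[str, SegregationResult]:
    """Evaluate one variant against several phenotype definitions.

    A variant may fail one phenotype while passing another (e.g. a variant
    tracking breast cancer but not pancreatic disease in the same family).
    """
    specs = list(phenotypes)
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"phenotype specs must be disjointly named: {names}")
    return {s.name: evaluate_segregation(family, variant, s, rule) for s in specs}


@dataclass(frozen=True)
class MendelianViolation:
    family_id: str
    key: VariantKey
    individual_id: str
    description: str


def mendelian_consistency(family: Family, variant: AnnotatedVariant) -> list[MendelianViolation]:
    """QC guard: flag transmissions impossible under Mendelian inheritance.

    Flags (1) an alt-carrying child both of whose parents are genotyped
    homozygous reference, and (2) a homozygous-alt child with any genotyped
    homozygous-reference parent (each parent must contribute one alt allele).
    Missing genotypes never trigger a flag — transmission from an
    ungenotyped parent cannot be excluded.
    """
    violations: list[MendelianViolation] = []
    for ind in family:
        g = variant.genotype(ind.individual_id)
        if not g.carries_alt:
            continue
        father, mother = family.parents_of(ind.individual_id)
        pg = [variant.genotype(p.individual_id) for p in (father, mother) if p is not None]
        both_known_ref = (
            len(pg) == 2 and all(x is Genotype.HOM_REF for x in pg)
        )
        if both_known_ref:
            violations.append(
                MendelianViolation(
                    family.family_id,
                    variant.key,
                    ind.individual_id,
                    f"{g.value} child of two hom_ref parents",
                )
            )
            continue
        if g is Genotype.HOM_ALT and any(x is Genotype.HOM_REF for x in pg):
            violations.append(
                MendelianViolation(
                    family.family_id,
                    variant.key,
                    ind.individual_id,
                    "hom_alt child of a hom_ref parent",
                )
            )
    return violations


def count_cosegregating_candidates(
    family: Family,
    triaged_variants: Iterable[TriagedVariant],
    phenotype: PhenotypeSpec = PANCREATIC,
    rule: PenetranceRule = PenetranceRule(),
) -> tuple[int, list[str]]:
    """Count triaged variants passing segregation in one family.

    Returns the number of candidates with verdict complete or
    incomplete_penetrance, together with the sorted gene list.
    """
    genes: list[str] = []
    for tv in triaged_variants:
        result = evaluate_segregation(family, family_view(tv.variant, family), phenotype, rule)
        if result.verdict.passing:
            genes.append(tv.gene)
    return len(genes), sorted(genes)
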