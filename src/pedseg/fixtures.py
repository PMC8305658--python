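"""Curated reference cohort: seven-candidate-gene FPC case study.

This module hand-encodes a 15-family familial pancreatic cancer cohort in
which seven families carry co-segregating candidate variants in seven genes
(ATM, SUFU, DAB1, POLQ, FGFBP3, MAP3K3, ACAD9), one family additionally
carries a FANCM variant tracking breast cancer rather than pancreatic
disease, and eight families carry no retained candidate.  Per-gene
validation-cohort counts (families screened / carrier families) and curated
biological-significance labels accompany the pedigrees.

The bundle is **synthetic**: pedigree structure, ages and genotypes encode
the narrated co-segregation pattern of each family (who was tested, who
carried, who was affected), and per-tool predictor calls are synthetic
stand-ins consistent with each variant's curated deleteriousness label.
Individuals not characterized in the narratives — and the eight
candidate-free filler families in their entirety — are invented, as the
manifest records.  The bundle passes Mendelian-consistency QC and
round-trips through the package's PED/VCF/TSV I/O.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .pedigree import (
    AgeKind,
    Cohort,
    Family,
    FamilyType,
    Individual,
    Phenotype,
    Sex,
    write_pedigree,
)
from .prevalence import ValidationCohort
from .variants import (
    AnnotatedVariant,
    Consequence,
    Genotype,
    MutationTasterCall,
    PolyPhenCall,
    PredictorCalls,
    ProveanCall,
    SiftCall,
    VariantKey,
    write_annotation_table,
    write_vcf,
)

__all__ = ["FixtureBundle", "build_fixture_bundle", "write_fixture_bundle"]

HET = Genotype.HET
REF = Genotype.HOM_REF

#: curated biological-significance labels (pass-through inputs, not computed)
SIGNIFICANCE = {
    "ATM": "deleterious",
    "SUFU": "pathogenic",
    "FANCM": "deleterious",
    "DAB1": "pathogenic",
    "POLQ": "VUS",
    "FGFBP3": "deleterious",
    "MAP3K3": "deleterious",
    "ACAD9": "VUS",
}

# all-tools-damaging call sets encode a curated "deleterious"/"pathogenic"
# label; mixed call sets encode "VUS".  CADD 20.5 for the SUFU promoter
# variant is the one reported tool value; the rest are synthetic.
_DAMAGING5 = dict(
    sift=SiftCall.DELETERIOUS,
    polyphen2=PolyPhenCall.PROBABLY_DAMAGING,
    mutation_taster=MutationTasterCall.DISEASE_CAUSING,
    provean=ProveanCall.DELETERIOUS,
)

VARIANT_DEFS: dict[str, AnnotatedVariant] = {
    "ATM": AnnotatedVariant(
        key=VariantKey("11", 108365000, "G", "T"),
        gene="ATM",
        consequence=Consequence.MISSENSE,
        hgvs_c="c.5385G>T",
        hgvs_p="p.(W1795C)",
        calls=PredictorCalls(**_DAMAGING5, cadd_phred=25.8),
        population_af=None,
    ),
    "SUFU": AnnotatedVariant(
        key=VariantKey("10", 104263000, "C", "T"),
        gene="SUFU",
        consequence=Consequence.PROMOTER,
        hgvs_c="c.-8C>T",
        hgvs_p=None,
        calls=PredictorCalls(**_DAMAGING5, cadd_phred=20.5),
        population_af=0.000024,
    ),
    "FANCM": AnnotatedVariant(
        key=VariantKey("14", 45170000, "C", "G"),
        gene="FANCM",
        consequence=Consequence.MISSENSE,
        hgvs_c="c.4375C>G",
        hgvs_p="p.(P1459A)",
        calls=PredictorCalls(
            sift=SiftCall.DELETERIOUS,
            polyphen2=PolyPhenCall.POSSIBLY_DAMAGING,
            mutation_taster=MutationTasterCall.DISEASE_CAUSING,
            provean=ProveanCall.NEUTRAL,
            cadd_phred=22.0,
        ),
        population_af=0.0005,
    ),
    "DAB1": AnnotatedVariant(
        key=VariantKey("1", 57460000, "G", "A"),
        gene="DAB1",
        consequence=Consequence.SPLICE_SITE,
        hgvs_c="c.786+1G>A",
        hgvs_p=None,
        calls=PredictorCalls(**_DAMAGING5, cadd_phred=34.0),
        population_af=0.00001,
    ),
    "POLQ": AnnotatedVariant(
        key=VariantKey("3", 121150000, "C", "A"),
        gene="POLQ",
        consequence=Consequence.MISSENSE,
        hgvs_c="c.4141C>A",
        hgvs_p="p.(P1381T)",
        calls=PredictorCalls(
            sift=SiftCall.TOLERATED,
            polyphen2=PolyPhenCall.BENIGN,
            mutation_taster=MutationTasterCall.DISEASE_CAUSING,
            provean=ProveanCall.NEUTRAL,
            cadd_phred=15.2,
        ),
        population_af=0.015,
    ),
    "FGFBP3": AnnotatedVariant(
        key=VariantKey("10", 93670000, "G", "A"),
        gene="FGFBP3",
        consequence=Consequence.MISSENSE,
        hgvs_c="c.724G>A",
        hgvs_p="p.(A242T)",
        calls=PredictorCalls(**_DAMAGING5, cadd_phred=26.3),
        population_af=0.000004,
    ),
    "MAP3K3": AnnotatedVariant(
        key=VariantKey("17", 63580000, "T", "C"),
        gene="MAP3K3",
        consequence=Consequence.MISSENSE,
        hgvs_c="c.1511T>C",
        hgvs_p="p.(I504T)",
        calls=PredictorCalls(**_DAMAGING5, cadd_phred=24.1),
        population_af=0.00001,
    ),
    "ACAD9": AnnotatedVariant(
        key=VariantKey("3", 128622922, "G", "A"),
        gene="ACAD9",
        consequence=Consequence.MISSENSE,
        hgvs_c="c.976G>A",
        hgvs_p="p.(A326T)",
        calls=PredictorCalls(
            sift=SiftCall.DELETERIOUS,
            polyphen2=PolyPhenCall.POSSIBLY_DAMAGING,
            mutation_taster=MutationTasterCall.DISEASE_CAUSING,
            provean=ProveanCall.NEUTRAL,
            cadd_phred=23.4,
        ),
        population_af=0.0152,
    ),
}


@dataclass
class FixtureBundle:
    cohort: Cohort
    variants: list[AnnotatedVariant]
    #: per gene: [initial screen, extension screens...]
    validation_cohorts: dict[str, list[ValidationCohort]]
    significance: dict[str, str] = field(default_factory=lambda: dict(SIGNIFICANCE))
    manifest: dict = field(default_factory=dict)


def _ind(
    fam: Family,
    iid: str,
    sex: Sex,
    father: str | None = None,
    mother: str | None = None,
    phenos: frozenset[Phenotype] = frozenset(),
    age: float | None = None,
    dna: bool = False,
    tumor: bool = False,
    dead: bool = False,
) -> str:
    full = f"{fam.family_id}_{iid}"
    fam.add(
        Individual(
            individual_id=full,
            family_id=fam.family_id,
            father_id=f"{fam.family_id}_{father}" if father else None,
            mother_id=f"{fam.family_id}_{mother}" if mother else None,
            sex=sex,
            phenotypes=phenos,
            age_years=age,
            age_kind=AgeKind.CURRENT if age is not None else AgeKind.MISSING,
            has_blood_dna=dna,
            has_tumor_dna=tumor,
            deceased=dead,
        )
    )
    return full


def _geno(family_id: str, assignment: dict[str, Genotype]) -> dict[str, Genotype]:
    return {f"{family_id}_{iid}": g for iid, g in assignment.items()}


P_PDAC = frozenset({Phenotype.PDAC})
P_PREC = frozenset({Phenotype.PRECURSOR_HIGH_GRADE})
P_BREAST = frozenset({Phenotype.BREAST_CANCER})
P_MELANOMA = frozenset({Phenotype.MELANOMA})
P_LEUK = frozenset({Phenotype.LEUKEMIA})


def _family_atm() -> tuple[Family, dict[str, dict[str, Genotype]]]:
    """ATM family: index and 22-year-old son carry; affected father/uncle and
    the leukemia daughter were never germline-genotyped; the mother's tumor
    was wild type (tumor genotype only, never germline)."""
    fam = Family("02-5-0382", family_type=FamilyType.FPC)
    _ind(fam, "GF", Sex.MALE, dead=True)
    _ind(fam, "GM", Sex.FEMALE, dead=True)
    _ind(fam, "F", Sex.MALE, "GF", "GM", P_PDAC, age=72, dead=True)
    _ind(fam, "U", Sex.MALE, "GF", "GM", P_PDAC, age=69, dead=True)
    _ind(fam, "M", Sex.FEMALE, phenos=P_PDAC, age=70, tumor=True, dead=True)
    _ind(fam, "I", Sex.MALE, "F", "M", P_PDAC, age=55, dna=True)
    _ind(fam, "SP", Sex.FEMALE, age=52)
    _ind(fam, "S", Sex.MALE, "I", "SP", age=22, dna=True)
    _ind(fam, "D", Sex.FEMALE, "I", "SP", P_LEUK, age=24, dead=True)
    germline = _geno(fam.family_id, {"I": HET, "S": HET})
    tumor = _geno(fam.family_id, {"M": REF})
    return fam, {"ATM": germline, "ATM_tumor": tumor}


def _family_sufu_fancm() -> tuple[Family, dict[str, dict[str, Genotype]]]:
    """PDAC/breast-cancer family: SUFU promoter variant carried by all 3 PDAC
    and all 4 precursor cases plus 3 healthy elderly relatives and 1 of 5
    breast-cancer cases; FANCM carried by 4 of 5 breast-cancer cases and
    nobody without breast cancer."""
    fam = Family("25-5-67", family_type=FamilyType.FPC_BREAST)
    _ind(fam, "G1", Sex.MALE, dead=True)
    _ind(fam, "G2", Sex.FEMALE, dead=True)
    _ind(fam, "H1", Sex.MALE, "G1", "G2", age=90, dna=True)
    _ind(fam, "H2", Sex.MALE, "G1", "G2", age=87, dna=True)
    _ind(fam, "H3", Sex.MALE, "G1", "G2", age=84, dna=True)
    _ind(fam, "S1", Sex.FEMALE, age=88, dead=True)
    _ind(fam, "S2", Sex.FEMALE, age=85)
    _ind(fam, "S3", Sex.FEMALE, age=83)
    _ind(fam, "P1", Sex.MALE, "H1", "S1", P_PDAC, age=70, dna=True, dead=True)
    _ind(fam, "P2", Sex.MALE, "H1", "S1", P_PDAC, age=67, dna=True)
    _ind(fam, "L1", Sex.MALE, "H1", "S1", P_PREC, age=65, dna=True)
    _ind(fam, "P3", Sex.MALE, "H2", "S2", P_PDAC, age=72, dna=True)
    _ind(fam, "L2", Sex.FEMALE, "H2", "S2", P_PREC, age=63, dna=True)
    _ind(fam, "L3", Sex.FEMALE, "H3", "S3", P_PREC, age=61, dna=True)
    _ind(fam, "L4", Sex.FEMALE, "H3", "S3", P_PREC, age=59, dna=True)
    _ind(fam, "SP1", Sex.FEMALE, age=68)
    _ind(fam, "SP2", Sex.FEMALE, age=70)
    _ind(fam, "SP3", Sex.FEMALE, age=63)
    _ind(fam, "B1", Sex.FEMALE, "P1", "SP1", P_BREAST, age=50, dna=True)
    _ind(fam, "B2", Sex.FEMALE, "P1", "SP1", P_BREAST, age=48, dna=True)
    _ind(fam, "B3", Sex.FEMALE, "P3", "SP2", P_BREAST, age=46, dna=True)
    _ind(fam, "B4", Sex.FEMALE, "L1", "SP3", P_BREAST, age=52, dna=True)
    _ind(fam, "B5", Sex.FEMALE, "L1", "SP3", P_BREAST, age=45, dna=True)
    sufu = _geno(
        fam.family_id,
        {
            "H1": HET, "H2": HET, "H3": HET,
            "P1": HET, "P2": HET, "P3": HET,
            "L1": HET, "L2": HET, "L3": HET, "L4": HET,
            "B1": HET, "B2": REF, "B3": REF, "B4": REF, "B5": REF,
        },
    )
    fancm = _geno(
        fam.family_id,
        {
            "H1": REF, "H2": REF, "H3": REF,
            "P1": REF, "P2": REF, "P3": REF,
            "L1": REF, "L2": REF, "L3": REF, "L4": REF,
            "B1": HET, "B2": HET, "B3": HET, "B4": HET, "B5": REF,
        },
    )
    return fam, {"SUFU": sufu, "FANCM": fancm}


def _family_dab1_polq_fgfbp3() -> tuple[Family, dict[str, dict[str, Genotype]]]:
    """PCMS family: DAB1 (splice), POLQ and FGFBP3 all carried by the three
    PDAC cases and the melanoma case; a 42-year-old healthy male carries
    POLQ only, two elderly healthy relatives carry FGFBP3 only; no healthy
    member carries all three."""
    fam = Family("25-9-44", family_type=FamilyType.PCMS)
    _ind(fam, "F1", Sex.MALE, dead=True)
    _ind(fam, "F2", Sex.FEMALE, dead=True)
    _ind(fam, "A1", Sex.MALE, "F1", "F2", P_PDAC, age=66, dna=True)
    _ind(fam, "A2", Sex.FEMALE, "F1", "F2", P_PDAC, age=63, dna=True)
    _ind(fam, "A3", Sex.MALE, "F1", "F2", P_PDAC, age=69, dna=True, dead=True)
    _ind(fam, "O1", Sex.FEMALE, "F1", "F2", age=78, dna=True)
    _ind(fam, "O2", Sex.MALE, "F1", "F2", age=75, dna=True)
    _ind(fam, "SA1", Sex.FEMALE, age=64)
    _ind(fam, "SA2", Sex.MALE, age=66)
    _ind(fam, "M1", Sex.FEMALE, "A1", "SA1", P_MELANOMA, age=40, dna=True)
    _ind(fam, "Y1", Sex.MALE, "A1", "SA1", age=35, dna=True)
    _ind(fam, "N1", Sex.MALE, "SA2", "A2", age=42, dna=True)
    _ind(fam, "Y2", Sex.FEMALE, "SA2", "A2", age=33, dna=True)
    dab1 = _geno(
        fam.family_id,
        {
            "A1": HET, "A2": HET, "A3": HET, "M1": HET,
            "O1": REF, "O2": REF, "N1": REF, "Y1": REF, "Y2": REF,
        },
    )
    polq = _geno(
        fam.family_id,
        {
            "A1": HET, "A2": HET, "A3": HET, "M1": HET, "N1": HET,
            "O1": REF, "O2": REF, "Y1": REF, "Y2": REF,
        },
    )
    fgfbp3 = _geno(
        fam.family_id,
        {
            "A1": HET, "A2": HET, "A3": HET, "M1": HET,
            "O1": HET, "O2": HET,
            "N1": REF, "Y1": REF, "Y2": REF,
        },
    )
    return fam, {"DAB1": dab1, "POLQ": polq, "FGFBP3": fgfbp3}


def _family_map3k3_acad9() -> tuple[Family, dict[str, dict[str, Genotype]]]:
    """Seven-member family: the PDAC case and the precursor-lesion case carry
    MAP3K3 and ACAD9; the five members without pancreatic findings do not;
    all seven genotyped."""
    fam = Family("25-4-46", family_type=FamilyType.FPC)
    _ind(fam, "P", Sex.MALE, phenos=P_PDAC, age=64, dna=True)
    _ind(fam, "U1", Sex.FEMALE, age=62, dna=True)
    _ind(fam, "L", Sex.FEMALE, "P", "U1", P_PREC, age=58, dna=True)
    _ind(fam, "U2", Sex.MALE, "P", "U1", age=55, dna=True)
    _ind(fam, "U3", Sex.FEMALE, "P", "U1", age=52, dna=True)
    _ind(fam, "U4", Sex.MALE, age=60, dna=True)
    _ind(fam, "U5", Sex.MALE, "U4", "L", age=30, dna=True)
    carriers = {"P": HET, "L": HET, "U1": REF, "U2": REF, "U3": REF, "U4": REF, "U5": REF}
    geno = _geno(fam.family_id, carriers)
    return fam, {"MAP3K3": geno, "ACAD9": dict(geno)}


def _family_acad9(
    family_id: str, ages_affected: tuple, young_carriers: int
) -> tuple[Family, dict[str, dict[str, Genotype]]]:
    """ACAD9 A326T carrier family: all pancreatic cases carry the variant;
    ``young_carriers`` unaffected members below 65 carry it as well."""
    fam = Family(family_id, family_type=FamilyType.FPC)
    _ind(fam, "GF", Sex.MALE, dead=True)
    _ind(fam, "GM", Sex.FEMALE, dead=True)
    a1, a2, a3 = ages_affected
    _ind(fam, "A1", Sex.MALE, "GF", "GM", P_PDAC, age=a1, dna=True)
    _ind(fam, "A2", Sex.FEMALE, "GF", "GM", P_PDAC, age=a2, dna=True)
    _ind(fam, "A3", Sex.FEMALE, "GF", "GM", P_PREC, age=a3, dna=True)
    _ind(fam, "S", Sex.FEMALE, age=a1 - 2, dna=True)
    assignment = {"A1": HET, "A2": HET, "A3": HET, "S": REF}
    n_children = max(young_carriers + 1, 2)
    for j in range(n_children):
        iid = f"Y{j + 1}"
        _ind(
            fam,
            iid,
            Sex.MALE if j % 2 == 0 else Sex.FEMALE,
            "A1",
            "S",
            age=44 - 3 * j,
            dna=True,
        )
        assignment[iid] = HET if j < young_carriers else REF
    return fam, {"ACAD9": _geno(fam.family_id, assignment)}


#: synthetic filler variants for candidate-free families
_FILLER_HIGH = PredictorCalls(**_DAMAGING5, cadd_phred=28.0)
_FILLER_LOW = PredictorCalls(
    sift=SiftCall.TOLERATED,
    polyphen2=PolyPhenCall.BENIGN,
    mutation_taster=MutationTasterCall.DISEASE_CAUSING,
    provean=ProveanCall.NEUTRAL,
    cadd_phred=12.0,
)


def _family_filler(index: int) -> tuple[Family, list[AnnotatedVariant]]:
    """Synthetic candidate-free filler family.

    Fillers 1-3 carry a high-scoring variant that fails co-segregation
    (one affected sibling is a non-carrier), fillers 4-6 carry only a
    low-scoring variant, filler 7 a synonymous variant (dropped at the
    consequence prefilter) and filler 8 no variant at all.
    """
    fid = f"25-0-9{index:02d}"
    fam = Family(fid, family_type=FamilyType.FPC)
    _ind(fam, "F", Sex.MALE, age=82, dna=True)
    _ind(fam, "M", Sex.FEMALE, age=80, dna=True)
    _ind(fam, "A1", Sex.MALE, "F", "M", P_PDAC, age=58, dna=True)
    _ind(fam, "A2", Sex.FEMALE, "F", "M", P_PDAC, age=55, dna=True)
    _ind(fam, "A3", Sex.MALE, "F", "M", P_PDAC, age=52, dna=True)
    _ind(fam, "U1", Sex.FEMALE, "F", "M", age=50, dna=True)
    variants: list[AnnotatedVariant] = []
    if index <= 3:
        # father transmits to A1 but the affected A2 is a non-carrier
        geno = _geno(fid, {"F": HET, "M": REF, "A1": HET, "A2": REF, "A3": HET, "U1": REF})
        variants.append(
            AnnotatedVariant(
                key=VariantKey("5", 10_000_000 + index * 1000, "A", "G"),
                gene=f"NONSEG{index}",
                consequence=Consequence.MISSENSE,
                calls=_FILLER_HIGH,
                population_af=0.002,
                genotypes=geno,
            )
        )
    elif index <= 6:
        geno = _geno(fid, {"F": REF, "M": HET, "A1": HET, "A2": HET, "A3": HET, "U1": REF})
        variants.append(
            AnnotatedVariant(
                key=VariantKey("6", 20_000_000 + index * 1000, "T", "C"),
                gene=f"LOWSCORE{index}",
                consequence=Consequence.MISSENSE,
                calls=_FILLER_LOW,
                population_af=0.02,
                genotypes=geno,
            )
        )
    elif index == 7:
        geno = _geno(fid, {"F": HET, "M": REF, "A1": HET, "A2": HET, "A3": HET, "U1": REF})
        variants.append(
            AnnotatedVariant(
                key=VariantKey("7", 30_000_000, "G", "C"),
                gene="SYN7",
                consequence=Consequence.SYNONYMOUS,
                calls=_FILLER_HIGH,
                population_af=0.03,
                genotypes=geno,
            )
        )
    return fam, variants


def _validation_cohorts() -> dict[str, list[ValidationCohort]]:
    keys = {g: v.key for g, v in VARIANT_DEFS.items()}
    fs = frozenset
    return {
        "ATM": [
            ValidationCohort("ATM", keys["ATM"], 15, fs({"02-5-0382"}), "initial_wgs"),
            ValidationCohort("ATM", keys["ATM"], 21, fs(), "sanger_extension"),
        ],
        "SUFU": [
            ValidationCohort("SUFU", keys["SUFU"], 15, fs({"25-5-67"}), "initial_wgs"),
        ],
        "DAB1": [
            ValidationCohort("DAB1", keys["DAB1"], 32, fs({"25-9-44"}), "pcms"),
            ValidationCohort("DAB1", keys["DAB1"], 17, fs(), "fpc"),
        ],
        "POLQ": [
            ValidationCohort("POLQ", keys["POLQ"], 15, fs({"25-9-44"}), "initial_wgs"),
            ValidationCohort("POLQ", keys["POLQ"], 14, fs(), "sanger_extension"),
        ],
        "FGFBP3": [
            ValidationCohort("FGFBP3", keys["FGFBP3"], 15, fs({"25-9-44"}), "initial_wgs"),
            ValidationCohort("FGFBP3", keys["FGFBP3"], 14, fs(), "sanger_extension"),
        ],
        "MAP3K3": [
            ValidationCohort("MAP3K3", keys["MAP3K3"], 15, fs({"25-4-46"}), "initial_wgs"),
            ValidationCohort("MAP3K3", keys["MAP3K3"], 14, fs(), "sanger_extension"),
        ],
        "ACAD9": [
            ValidationCohort(
                "ACAD9", keys["ACAD9"], 15,
                fs({"25-4-46", "25-1-91", "25-9-113"}), "initial_wgs",
            ),
            ValidationCohort(
                "ACAD9", keys["ACAD9"], 31, fs({"25-2-209"}), "sanger_extension",
            ),
        ],
    }


def build_fixture_bundle() -> FixtureBundle:
    """Assemble the 15-family reference cohort with its variant set."""
    cohort = Cohort(label="reference_fpc_cohort")
    gene_genotypes: dict[str, dict[str, Genotype]] = {g: {} for g in VARIANT_DEFS}
    tumor_genotypes: dict[str, dict[str, Genotype]] = {g: {} for g in VARIANT_DEFS}

    builders = [
        _family_atm(),
        _family_sufu_fancm(),
        _family_dab1_polq_fgfbp3(),
        _family_map3k3_acad9(),
        _family_acad9("25-1-91", (68, 64, 61), young_carriers=1),
        _family_acad9("25-9-113", (71, 66, 63), young_carriers=2),
        _family_acad9("25-2-209", (69, 65, 60), young_carriers=1),
    ]
    for fam, genos in builders:
        fam.validate()
        cohort.add(fam)
        for gene, mapping in genos.items():
            if gene.endswith("_tumor"):
                tumor_genotypes[gene[: -len("_tumor")]].update(mapping)
            else:
                gene_genotypes[gene].update(mapping)

    variants: list[AnnotatedVariant] = []
    for gene, proto in VARIANT_DEFS.items():
        variants.append(
            AnnotatedVariant(
                key=proto.key,
                gene=proto.gene,
                consequence=proto.consequence,
                hgvs_c=proto.hgvs_c,
                hgvs_p=proto.hgvs_p,
                calls=proto.calls,
                population_af=proto.population_af,
                genotypes=gene_genotypes[gene],
                tumor_genotypes=tumor_genotypes[gene],
            )
        )

    for index in range(1, 9):
        fam, fillers = _family_filler(index)
        fam.validate()
        cohort.add(fam)
        variants.extend(fillers)

    cohort.validate()
    manifest = {
        "n_families": len(cohort),
        "candidate_families": [
            "02-5-0382", "25-5-67", "25-9-44", "25-4-46",
            "25-1-91", "25-9-113", "25-2-209",
        ],
        "filler_families": [f"25-0-9{i:02d}" for i in range(1, 9)],
        "filler_families_synthetic": True,
        "notes": [
            "Filler families and all per-tool predictor calls are synthetic "
            "stand-ins; candidate-family genotypes encode the narrated "
            "co-segregation patterns.",
            "02-5-0382_M carries a tumor-tissue genotype only (wild type); "
            "tumor genotypes never enter germline segregation analysis.",
        ],
    }
    return FixtureBundle(
        cohort=cohort,
        variants=variants,
        validation_cohorts=_validation_cohorts(),
        manifest=manifest,
    )


def write_fixture_bundle(out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle as ped_extended / VCF / annotation TSV / JSON files."""
    bundle = build_fixture_bundle()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ped = write_pedigree(bundle.cohort, out_dir / "cohort.ped")
    samples = sorted(
        ind.individual_id for ind in bundle.cohort.individuals() if ind.has_blood_dna
    )
    vcf = write_vcf(bundle.variants, samples, out_dir / "genotypes.vcf")
    ann = write_annotation_table(bundle.variants, out_dir / "annotations.tsv")
    counts = out_dir / "validation_cohorts.json"
    counts.write_text(
        json.dumps(
            {
                gene: [
                    {
                        "label": vc.label,
                        "families_tested": vc.families_tested,
                        "carrier_families": sorted(vc.carrier_families),
                    }
                    for vc in cohorts
                ]
                for gene, cohorts in bundle.validation_cohorts.items()
            },
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    sig = out_dir / "significance.json"
    sig.write_text(json.dumps(bundle.significance, indent=2) + "\n", encoding="utf-8")
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(bundle.manifest, indent=2) + "\n", encoding="utf-8")
    return {
        "pedigree": ped,
        "vcf": vcf,
        "annotations": ann,
        "validation_cohorts": counts,
        "significance": sig,
        "manifest": manifest,
    }
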