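"""Synthetic pedigree/cohort generator for dominant, late-onset disease.

Generates multi-generation pedigrees, drops alleles through them under
Mendelian transmission, assigns an age-dependent incompletely-penetrant
pancreatic phenotype, and fabricates predictor annotations whose damaging
rates differ between the planted (causal) variant and background variants.
The output files round-trip through the package's own I/O, so the whole
prioritization/segregation pipeline can be exercised end to end with no
external data.

Model sketch:

* one founder couple per family; sibship sizes are ``1 + Poisson(mean - 1)``
  so the mean sibship is exactly ``mean_sibship``; every non-terminal child
  marries an unrelated founder spouse; ages decrease by a fixed
  per-generation gap with Gaussian jitter;
* the causal variant is planted heterozygous in one top founder and
  gene-dropped (each het parent transmits with probability 1/2); background
  variants draw founder genotypes from Hardy-Weinberg at their population
  allele frequency and are dropped the same way, so every simulated
  genotype is Mendelian-consistent;
* a carrier whose age reached their (sampled) onset age develops PDAC or a
  high-grade precursor lesion with probability ``penetrance_by_target_age``;
  non-carriers past onset age develop sporadic disease with probability
  ``phenocopy_rate`` (sporadic PDAC is likewise a late-onset disease);
* causal families are rejection-sampled until they satisfy registry-style
  eligibility (>= 3 genotyped affected and >= 2 genotyped unaffected
  members), emulating how multiplex families are ascertained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np

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

__all__ = [
    "SimulationConfig",
    "SimulatedCohort",
    "simulate_pedigree",
    "gene_drop",
    "drop_alleles",
    "assign_phenotypes",
    "simulate_annotations",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_families: int = 15
    generations: int = 3
    mean_sibship: float = 2.5
    #: fraction of families given a planted dominant variant
    causal_fraction: float = 0.5
    penetrance_by_target_age: float = 0.8
    onset_age_median: float = 65.0
    onset_age_range: tuple[float, float] = (42.0, 78.0)
    phenocopy_rate: float = 0.01
    n_background_variants: int = 200
    #: log-uniform sampling range for background population AFs
    background_af_range: tuple[float, float] = (1e-5, 0.05)
    predictor_damaging_rate_causal: float = 0.9
    predictor_damaging_rate_background: float = 0.1
    genotyping_missingness: float = 0.2
    seed: int = 0
    # --- secondary knobs -------------------------------------------------
    #: affected carriers present as high-grade precursor rather than PDAC
    precursor_fraction: float = 0.3
    youngest_generation_age: float = 32.0
    generation_age_gap: float = 27.0
    age_jitter_sd: float = 5.0
    cadd_cutoff: float = 20.0
    min_genotyped_affected: int = 3
    min_genotyped_unaffected: int = 2
    #: registry-style sequencing budget: at most ~4 cases and ~4 controls
    #: are genotyped per family
    max_genotyped_affected: int = 4
    max_genotyped_unaffected: int = 4
    max_eligibility_tries: int = 2000

    def __post_init__(self):
        for name in (
            "causal_fraction",
            "penetrance_by_target_age",
            "phenocopy_rate",
            "predictor_damaging_rate_causal",
            "predictor_damaging_rate_background",
            "genotyping_missingness",
            "precursor_fraction",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {val}")
        if self.generations < 2:
            raise ValueError("generations must be >= 2")
        if self.mean_sibship < 1.0:
            raise ValueError("mean_sibship must be >= 1")


@dataclass
class SimulatedCohort:
    cohort: Cohort
    variants: list[AnnotatedVariant]
    #: per family: the planted causal variant key, or None
    truth: dict[str, VariantKey | None]


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def _sibship_size(config: SimulationConfig, rng: np.random.Generator) -> int:
    return 1 + int(rng.poisson(config.mean_sibship - 1.0))


def simulate_pedigree(
    config: SimulationConfig, rng: np.random.Generator, family_id: str = "SIM"
) -> Family:
    """Simulate one multi-generation pedigree (no phenotypes yet).

    The pedigree is acyclic by construction, founders are unrelated, and
    ages decrease down the generations.  DNA availability is drawn per
    member with probability ``1 - genotyping_missingness``.
    """
    fam = Family(family_id)
    counter = 0

    def age_for(generation: int) -> float:
        mean = config.youngest_generation_age + config.generation_age_gap * (
            config.generations - 1 - generation
        )
        return max(18.0, float(rng.normal(mean, config.age_jitter_sd)))

    def new_individual(
        sex: Sex, generation: int, father: str | None = None, mother: str | None = None
    ) -> Individual:
        nonlocal counter
        counter += 1
        age = age_for(generation)
        ind = Individual(
            individual_id=f"{family_id}_{counter:02d}",
            family_id=family_id,
            father_id=father,
            mother_id=mother,
            sex=sex,
            age_years=round(age, 1),
            age_kind=AgeKind.CURRENT,
            has_blood_dna=bool(rng.random() >= config.genotyping_missingness),
            deceased=bool(age >= 80 and rng.random() < 0.5),
        )
        fam.add(ind)
        return ind

    father0 = new_individual(Sex.MALE, 0)
    mother0 = new_individual(Sex.FEMALE, 0)
    unions: list[tuple[Individual, Individual, int]] = [(father0, mother0, 0)]
    while unions:
        f, m, gen = unions.pop(0)
        for _ in range(_sibship_size(config, rng)):
            sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
            child = new_individual(sex, gen + 1, father=f.individual_id, mother=m.individual_id)
            if gen + 1 < config.generations - 1:
                spouse_sex = Sex.FEMALE if sex is Sex.MALE else Sex.MALE
                spouse = new_individual(spouse_sex, gen + 1)
                couple = (child, spouse) if sex is Sex.MALE else (spouse, child)
                unions.append((couple[0], couple[1], gen + 1))
    fam.validate()
    return fam


# ---------------------------------------------------------------------------
# Allele dropping
# ---------------------------------------------------------------------------

def _topological_members(family: Family) -> list[Individual]:
    order: list[Individual] = []
    placed: set[str] = set()
    pending = list(family.members.values())
    while pending:
        progressed = False
        rest = []
        for ind in pending:
            ready = all(
                pid is None or pid in placed
                for pid in (ind.father_id, ind.mother_id)
            )
            if ready:
                order.append(ind)
                placed.add(ind.individual_id)
                progressed = True
            else:
                rest.append(ind)
        if not progressed:  # cyclic pedigrees are rejected by validate()
            raise ValueError(f"cannot topologically order family {family.family_id}")
        pending = rest
    return order


_DOSAGE_TO_GT = {0: Genotype.HOM_REF, 1: Genotype.HET, 2: Genotype.HOM_ALT}


def drop_alleles(
    family: Family,
    founder_dosages: dict[str, int],
    rng: np.random.Generator,
) -> dict[str, Genotype]:
    """Drop alleles through a pedigree from given founder dosages.

    Founders absent from ``founder_dosages`` are homozygous reference.  Each
    parent transmits an alt allele with probability dosage/2, independently
    per child — the classic gene-drop.  The output is Mendelian-consistent
    by construction.
    """
    dosage: dict[str, int] = {}
    for ind in _topological_members(family):
        iid = ind.individual_id
        if ind.father_id is None and ind.mother_id is None:
            dosage[iid] = founder_dosages.get(iid, 0)
            continue
        d = 0
        for pid in (ind.father_id, ind.mother_id):
            p_dosage = dosage.get(pid, 0) if pid else 0
            if p_dosage and rng.random() < p_dosage / 2.0:
                d += 1
        dosage[iid] = d
    return {iid: _DOSAGE_TO_GT[d] for iid, d in dosage.items()}


def gene_drop(
    family: Family, founder_carrier: str, rng: np.random.Generator
) -> dict[str, Genotype]:
    """Drop a single heterozygous founder allele through the pedigree."""
    if founder_carrier not in family.members:
        raise KeyError(f"founder {founder_carrier!r} not in family {family.family_id!r}")
    return drop_alleles(family, {founder_carrier: 1}, rng)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _sample_onset_age(config: SimulationConfig, rng: np.random.Generator) -> float:
    """Truncated normal around the onset median, clipped to the onset range."""
    low, high = config.onset_age_range
    sd = (high - low) / 4.0
    for _ in range(1000):
        x = rng.normal(config.onset_age_median, sd)
        if low <= x <= high:
            return float(x)
    return float(config.onset_age_median)


def assign_phenotypes(
    family: Family,
    genotypes: dict[str, Genotype],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Family:
    """Assign age-dependent phenotypes given planted-variant genotypes.

    A carrier whose current age reached their sampled onset age becomes a
    PDAC or high-grade-precursor case with probability
    ``penetrance_by_target_age``; a non-carrier past onset age becomes a
    sporadic (phenocopy) case with probability ``phenocopy_rate``.
    """
    members: dict[str, Individual] = {}
    for ind in family:
        onset = _sample_onset_age(config, rng)
        carrier = genotypes.get(ind.individual_id, Genotype.HOM_REF).carries_alt
        affected = False
        age = ind.age_years if ind.age_years is not None else 0.0
        if age >= onset:
            p = config.penetrance_by_target_age if carrier else config.phenocopy_rate
            affected = bool(rng.random() < p)
        if affected:
            pheno = (
                Phenotype.PRECURSOR_HIGH_GRADE
                if rng.random() < config.precursor_fraction
                else Phenotype.PDAC
            )
            members[ind.individual_id] = replace(ind, phenotypes=frozenset({pheno}))
        else:
            members[ind.individual_id] = replace(ind, phenotypes=frozenset())
    return Family(
        family_id=family.family_id,
        members=members,
        family_type=family.family_type,
        known_predisposition_mutation=family.known_predisposition_mutation,
    )


def _cap_genotyping(
    family: Family, config: SimulationConfig, rng: np.random.Generator
) -> Family:
    """Keep blood DNA on at most ~4 cases and ~4 controls per family.

    Mirrors the sequencing budget of registry studies (a handful of cases
    and controls per family); members beyond the caps keep their phenotype
    but are not genotyped.
    """
    aff = sorted(m.individual_id for m in family if m.affected and m.has_blood_dna)
    unaff = sorted(m.individual_id for m in family if not m.affected and m.has_blood_dna)
    keep: set[str] = set()
    for ids, cap in ((aff, config.max_genotyped_affected), (unaff, config.max_genotyped_unaffected)):
        order = [ids[i] for i in rng.permutation(len(ids))]
        keep.update(order[:cap])
    members = {
        iid: (m if (iid in keep or not m.has_blood_dna) else replace(m, has_blood_dna=False))
        for iid, m in family.members.items()
    }
    return Family(
        family_id=family.family_id,
        members=members,
        family_type=family.family_type,
        known_predisposition_mutation=family.known_predisposition_mutation,
    )


def _eligible(family: Family, config: SimulationConfig) -> bool:
    aff = sum(1 for m in family if m.affected and m.has_blood_dna)
    unaff = sum(1 for m in family if not m.affected and m.has_blood_dna)
    return aff >= config.min_genotyped_affected and unaff >= config.min_genotyped_unaffected


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def simulate_annotations(
    variants: Iterable[AnnotatedVariant],
    truth_keys: set[VariantKey],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[AnnotatedVariant]:
    """Fabricate predictor calls and AFs correlated with true causality.

    Each of the five predictors votes damaging with
    ``predictor_damaging_rate_causal`` for planted variants and
    ``predictor_damaging_rate_background`` otherwise (independently); CADD is
    drawn above/below the cutoff with the same rates.  Background AFs are
    sampled log-uniformly from ``background_af_range``; planted variants are
    forced rare.
    """
    out = []
    lo, hi = config.background_af_range
    for var in variants:
        causal = var.key in truth_keys
        rate = (
            config.predictor_damaging_rate_causal
            if causal
            else config.predictor_damaging_rate_background
        )
        damaging = rng.random(5) < rate
        cadd = (
            float(rng.uniform(config.cadd_cutoff, config.cadd_cutoff + 15))
            if damaging[4]
            else float(rng.uniform(0, config.cadd_cutoff))
        )
        calls = PredictorCalls(
            sift=SiftCall.DELETERIOUS if damaging[0] else SiftCall.TOLERATED,
            polyphen2=PolyPhenCall.PROBABLY_DAMAGING if damaging[1] else PolyPhenCall.BENIGN,
            mutation_taster=(
                MutationTasterCall.DISEASE_CAUSING if damaging[2] else MutationTasterCall.POLYMORPHISM
            ),
            provean=ProveanCall.DELETERIOUS if damaging[3] else ProveanCall.NEUTRAL,
            cadd_phred=round(cadd, 2),
        )
        if causal:
            af = float(10 ** rng.uniform(-6, -3))  # forced rare
        else:
            af = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        out.append(replace(var, calls=calls, population_af=round(af, 8)))
    return out


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def _genotyped_subset(family: Family, genotypes: dict[str, Genotype]) -> dict[str, Genotype]:
    return {
        iid: g
        for iid, g in genotypes.items()
        if family.members[iid].has_blood_dna
    }


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate a full cohort: pedigrees, genotypes, phenotypes, annotations.

    All randomness flows from ``config.seed``; identical configs give
    identical cohorts (and identical files via :func:`write_cohort`).
    """
    rng = np.random.default_rng(config.seed)
    cohort = Cohort(label=f"simulated_seed{config.seed}")
    truth: dict[str, VariantKey | None] = {}
    causal_geno: dict[str, dict[str, Genotype]] = {}
    n_causal = int(round(config.causal_fraction * config.n_families))

    for i in range(config.n_families):
        fid = f"F{i + 1:03d}"
        causal = i < n_causal
        family: Family | None = None
        genotypes: dict[str, Genotype] = {}
        if causal:
            for _ in range(config.max_eligibility_tries):
                candidate = simulate_pedigree(config, rng, family_id=fid)
                founder = f"{fid}_01"
                geno = gene_drop(candidate, founder, rng)
                candidate = assign_phenotypes(candidate, geno, config, rng)
                candidate = _cap_genotyping(candidate, config, rng)
                if _eligible(candidate, config):
                    family, genotypes = candidate, geno
                    break
            if family is None:
                raise RuntimeError(
                    f"could not simulate an eligible causal family within "
                    f"{config.max_eligibility_tries} tries (family {fid})"
                )
        else:
            family = simulate_pedigree(config, rng, family_id=fid)
            family = assign_phenotypes(family, {}, config, rng)
            family = _cap_genotyping(family, config, rng)
        cohort.add(family)
        if causal:
            causal_geno[fid] = genotypes
            truth[fid] = None  # filled below once keys are assigned
        else:
            truth[fid] = None

    variants: list[AnnotatedVariant] = []
    pos = 1_000_000
    # planted variants: one per causal family, each in its own gene
    for idx, (fid, geno) in enumerate(causal_geno.items(), start=1):
        key = VariantKey("1", pos, "G", "A")
        pos += 10_000
        family = cohort.families[fid]
        variants.append(
            AnnotatedVariant(
                key=key,
                gene=f"CG{idx:03d}",
                consequence=Consequence.MISSENSE,
                genotypes=_genotyped_subset(family, geno),
            )
        )
        truth[fid] = key

    # background variants: founder Hardy-Weinberg draws + gene drop per family
    lo, hi = config.background_af_range
    for j in range(config.n_background_variants):
        af = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        key = VariantKey("2", 1_000_000 + j * 1_000, "C", "T")
        genotypes: dict[str, Genotype] = {}
        for family in cohort:
            founders = [
                m.individual_id
                for m in family
                if m.father_id is None and m.mother_id is None
            ]
            founder_dosages = {
                iid: int(rng.binomial(2, af)) for iid in founders
            }
            fam_geno = drop_alleles(family, founder_dosages, rng)
            genotypes.update(_genotyped_subset(family, fam_geno))
        variants.append(
            AnnotatedVariant(
                key=key,
                gene=f"BG{j:04d}",
                consequence=Consequence.MISSENSE,
                genotypes=genotypes,
                population_af=af,
            )
        )

    truth_keys = {k for k in truth.values() if k is not None}
    variants = simulate_annotations(variants, truth_keys, config, rng)
    # keep the sampled background AF authoritative for background variants
    return SimulatedCohort(cohort=cohort, variants=variants, truth=truth)


def write_cohort(simulated: SimulatedCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write ped_extended, VCF, annotation TSV and truth JSON.

    Files are re-readable by the package's own readers with a lossless
    round-trip for pedigree structure and genotype maps.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ped_path = write_pedigree(simulated.cohort, out_dir / "cohort.ped")
    samples = sorted(
        ind.individual_id for ind in simulated.cohort.individuals() if ind.has_blood_dna
    )
    vcf_path = write_vcf(simulated.variants, samples, out_dir / "genotypes.vcf")
    ann_path = write_annotation_table(simulated.variants, out_dir / "annotations.tsv")
    truth_path = out_dir / "truth.json"
    truth_path.write_text(
        json.dumps(
            {fid: (str(k) if k else None) for fid, k in sorted(simulated.truth.items())},
            indent=2,
        )
        + "\n",
        encoding="utf-8",
    )
    return {
        "pedigree": ped_path,
        "vcf": vcf_path,
        "annotations": ann_path,
        "truth": truth_path,
    }
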