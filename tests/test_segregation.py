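"""Co-segregation verdicts, penetrance exemptions and Mendelian QC."""

import dataclasses
import itertools

import numpy as np
import pytest

import pedseg as ps
from pedseg.pedigree import Family, Phenotype, Sex
from pedseg.segregation import (
    BREAST,
    PANCREATIC,
    PANCREATIC_MELANOMA,
    PenetranceRule,
    PhenotypeSpec,
    Verdict,
    count_cosegregating_candidates,
    evaluate_cross_phenotype,
    evaluate_segregation,
    family_view,
    mendelian_consistency,
)
from pedseg.variants import AnnotatedVariant, Genotype, VariantKey

from conftest import make_individual, random_families


def _bundle_variant(bundle, gene):
    return next(v for v in bundle.variants if v.gene == gene)


def _bundle_family(bundle, fid):
    return bundle.cohort.families[fid]


# ---------------------------------------------------------------------------
# Curated-family verdicts
# ---------------------------------------------------------------------------

def test_sufu_family_shows_incomplete_penetrance(bundle):
    """All 3 PDAC and 4 precursor cases carry the promoter variant; the three
    healthy carriers aged 84/87/90 are exempted as elderly carriers."""
    fam = _bundle_family(bundle, "25-5-67")
    res = evaluate_segregation(fam, _bundle_variant(bundle, "SUFU"), PANCREATIC)
    assert res.verdict is Verdict.INCOMPLETE_PENETRANCE
    assert res.affected_genotyped == 7 and res.affected_carriers == 7
    assert res.exempted_unaffected_carriers == 3
    assert sorted(e.age_years for e in res.exemptions) == [84, 87, 90]
    assert all(e.category == "elderly_carrier" for e in res.exemptions)
    # the breast-cancer carrier is noted but not a 'healthy' exemption
    assert any(n.startswith("nontarget_phenotype_carrier") for n in res.notes)


def test_fancm_fails_pancreatic_but_tracks_breast_cancer(bundle):
    fam = _bundle_family(bundle, "25-5-67")
    fancm = _bundle_variant(bundle, "FANCM")
    results = evaluate_cross_phenotype(
        fam, fancm, [PANCREATIC, BREAST], PenetranceRule(max_affected_noncarriers=1)
    )
    assert results["pancreatic_disease"].verdict is Verdict.FAILS
    breast = results["breast_cancer"]
    assert breast.affected_carriers == 4 and breast.affected_genotyped == 5
    assert breast.unaffected_carriers == 0
    assert breast.verdict is Verdict.COMPLETE
    # under the default zero-phenocopy rule the breast evaluation fails too
    strict = evaluate_segregation(fam, fancm, BREAST)
    assert strict.verdict is Verdict.FAILS


def test_map3k3_family_segregates_completely(bundle):
    fam = _bundle_family(bundle, "25-4-46")
    res = evaluate_segregation(fam, _bundle_variant(bundle, "MAP3K3"), PANCREATIC)
    assert res.verdict is Verdict.COMPLETE
    assert res.affected_carriers == 2
    assert res.unaffected_carriers == 0


def test_atm_family_supports_segregation_via_young_carrier_son(bundle):
    fam = _bundle_family(bundle, "02-5-0382")
    res = evaluate_segregation(fam, _bundle_variant(bundle, "ATM"), PANCREATIC)
    assert res.verdict is not Verdict.FAILS
    assert res.affected_carriers == 1  # only the index has a germline genotype
    [ex] = res.exemptions
    assert ex.age_years == 22 and ex.category == "young_carrier"


def test_polq_42_year_old_carrier_is_young_exemption(bundle):
    fam = _bundle_family(bundle, "25-9-44")
    res = evaluate_segregation(
        fam, _bundle_variant(bundle, "POLQ"), PANCREATIC_MELANOMA
    )
    assert res.verdict is Verdict.INCOMPLETE_PENETRANCE
    [ex] = res.exemptions
    assert ex.age_years == 42 and ex.category == "young_carrier"


def test_pcms_family_counts_three_cosegregating_candidates(bundle, bundle_run):
    fam = _bundle_family(bundle, "25-9-44")
    fam_triaged = [
        tv for tv in bundle_run.triaged if "25-9-44" in tv.families_with_variant
    ]
    n, genes = count_cosegregating_candidates(fam, fam_triaged, PANCREATIC_MELANOMA)
    assert n == 3
    assert genes == ["DAB1", "FGFBP3", "POLQ"]


def test_tumor_genotype_never_counts_as_germline(bundle):
    """The ATM index's mother has a wild-type tumor genotype; she must stay
    uninformative for germline segregation."""
    fam = _bundle_family(bundle, "02-5-0382")
    atm = _bundle_variant(bundle, "ATM")
    assert atm.tumor_genotypes["02-5-0382_M"] is Genotype.HOM_REF
    res = evaluate_segregation(fam, atm, PANCREATIC)
    # were her tumor call counted, the affected mother would be a
    # non-carrier and the verdict would flip to fails
    assert res.verdict is not Verdict.FAILS
    assert "02-5-0382_M" not in atm.genotypes


# ---------------------------------------------------------------------------
# Rule behavior on constructed families
# ---------------------------------------------------------------------------

def _flat_family(n_affected, n_unaffected, ages=None):
    fam = Family("FLAT")
    for i in range(n_affected):
        fam.add(make_individual(f"a{i}", fam="FLAT", phenos={Phenotype.PDAC}, age=70))
    for i in range(n_unaffected):
        age = ages[i] if ages else 50
        fam.add(make_individual(f"u{i}", fam="FLAT", age=age))
    return fam


def _var(genotypes):
    return AnnotatedVariant(key=VariantKey("9", 999, "A", "T"), genotypes=genotypes)


def test_single_affected_noncarrier_fails():
    fam = _flat_family(1, 0)
    res = evaluate_segregation(fam, _var({"a0": Genotype.HOM_REF}), PANCREATIC)
    assert res.verdict is Verdict.FAILS
    assert "no_carriers" in res.notes


def test_no_genotyped_affected_fails_with_note():
    fam = _flat_family(1, 2)
    res = evaluate_segregation(
        fam, _var({"u0": Genotype.HET, "u1": Genotype.HOM_REF}), PANCREATIC
    )
    assert res.verdict is Verdict.FAILS
    assert "no_informative_affected" in res.notes


def test_variant_carried_by_nobody_fails_all_phenotypes():
    fam = _flat_family(2, 2)
    fam.members["a1"] = dataclasses.replace(
        fam.members["a1"], phenotypes=frozenset({Phenotype.BREAST_CANCER})
    )
    geno = {iid: Genotype.HOM_REF for iid in fam.members}
    results = evaluate_cross_phenotype(fam, _var(geno), [PANCREATIC, BREAST])
    for res in results.values():
        assert res.verdict is Verdict.FAILS
        assert "no_carriers" in res.notes


def test_genotype_for_unknown_individual_is_an_error(trio):
    with pytest.raises(KeyError):
        evaluate_segregation(trio, _var({"stranger": Genotype.HET}), PANCREATIC)


def test_adding_ungenotyped_member_changes_nothing(rng):
    for fam in random_families(5, rng):
        founder = sorted(fam.members)[0]
        geno = ps.gene_drop(fam, founder, rng)
        var = _var(dict(geno))
        before = evaluate_segregation(fam, var, PANCREATIC)
        fam.add(make_individual("extra_ungenotyped", fam=fam.family_id, age=44, dna=False))
        after = evaluate_segregation(fam, var, PANCREATIC)
        assert before == after


def test_disallowing_unaffected_carriers_restricts_verdicts(rng):
    strict = PenetranceRule(allow_unaffected_carriers=False)
    for fam in random_families(10, rng):
        founder = sorted(fam.members)[0]
        var = _var(dict(ps.gene_drop(fam, founder, rng)))
        default_res = evaluate_segregation(fam, var, PANCREATIC)
        strict_res = evaluate_segregation(fam, var, PANCREATIC, strict)
        assert strict_res.verdict in (Verdict.COMPLETE, Verdict.FAILS)
        if default_res.verdict is Verdict.COMPLETE:
            assert strict_res.verdict is Verdict.COMPLETE


def test_full_penetrance_simulation_always_complete():
    """With penetrance 1, no phenocopies and every carrier past onset age,
    the planted variant segregates completely in every replicate."""
    cfg = ps.SimulationConfig(
        n_families=30,
        causal_fraction=1.0,
        penetrance_by_target_age=1.0,
        phenocopy_rate=0.0,
        youngest_generation_age=85.0,
        generation_age_gap=5.0,
        age_jitter_sd=1.0,
        n_background_variants=0,
        seed=7,
    )
    sim = ps.simulate_cohort(cfg)
    by_key = {v.key: v for v in sim.variants}
    for fam in sim.cohort:
        var = by_key[sim.truth[fam.family_id]]
        res = evaluate_segregation(fam, family_view(var, fam), PANCREATIC)
        assert res.verdict is Verdict.COMPLETE


# ---------------------------------------------------------------------------
# Null distribution of the segregation filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("a,u", [(1, 2), (2, 3), (3, 3), (4, 5)])
def test_complete_probability_matches_enumeration(a, u):
    """For independent Bernoulli(1/2) carriage, exhaustive enumeration gives
    P(complete) = (1/2)^(a+u): exactly one assignment passes."""
    fam = _flat_family(a, u)
    ids = sorted(fam.members)
    n_complete = 0
    for bits in itertools.product([Genotype.HOM_REF, Genotype.HET], repeat=len(ids)):
        var = _var(dict(zip(ids, bits)))
        res = evaluate_segregation(fam, var, PANCREATIC)
        n_complete += res.verdict is Verdict.COMPLETE
    assert n_complete == 1
    assert n_complete / 2 ** (a + u) == 0.5 ** (a + u)


def test_complete_probability_monte_carlo(rng):
    a, u = 2, 4
    fam = _flat_family(a, u)
    ids = sorted(fam.members)
    n = 20000
    hits = 0
    for _ in range(n):
        geno = {
            iid: Genotype.HET if rng.random() < 0.5 else Genotype.HOM_REF for iid in ids
        }
        res = evaluate_segregation(fam, _var(geno), PANCREATIC)
        hits += res.verdict is Verdict.COMPLETE
    p = 0.5 ** (a + u)
    se = np.sqrt(p * (1 - p) / n)
    assert abs(hits / n - p) < 4 * se


# ---------------------------------------------------------------------------
# Mendelian QC
# ---------------------------------------------------------------------------

def test_het_child_of_two_hom_ref_parents_flagged(trio):
    var = _var({"dad": Genotype.HOM_REF, "mom": Genotype.HOM_REF, "kid": Genotype.HET})
    [violation] = mendelian_consistency(trio, var)
    assert violation.individual_id == "kid"


def test_ungenotyped_parent_cannot_exclude_transmission(trio):
    var = _var({"dad": Genotype.HOM_REF, "kid": Genotype.HET})
    assert mendelian_consistency(trio, var) == []


def test_hom_alt_child_of_hom_ref_parent_flagged(trio):
    var = _var({"dad": Genotype.HOM_REF, "mom": Genotype.HET, "kid": Genotype.HOM_ALT})
    [violation] = mendelian_consistency(trio, var)
    assert "hom_alt" in violation.description


def test_count_candidates_empty_triage(bundle):
    fam = bundle.cohort.families["25-4-46"]
    assert count_cosegregating_candidates(fam, []) == (0, [])


def test_count_candidates_matches_per_variant_loop(bundle, bundle_run):
    for fam in bundle.cohort:
        n, genes = count_cosegregating_candidates(
            fam,
            bundle_run.triaged,
            PANCREATIC_MELANOMA if fam.family_type is ps.FamilyType.PCMS else PANCREATIC,
        )
        expect = 0
        for tv in bundle_run.triaged:
            spec = (
                PANCREATIC_MELANOMA
                if fam.family_type is ps.FamilyType.PCMS
                else PANCREATIC
            )
            res = evaluate_segregation(fam, family_view(tv.variant, fam), spec)
            expect += res.verdict is not Verdict.FAILS
        assert n == expect == len(genes)
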