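"""Synthetic cohort generator: structure, transmission, phenotypes, files."""

import numpy as np
import pytest

import pedseg as ps
from pedseg.pedigree import Family, Phenotype, Sex
from pedseg.segregation import family_view, mendelian_consistency
from pedseg.simulate import (
    SimulationConfig,
    assign_phenotypes,
    drop_alleles,
    gene_drop,
    simulate_annotations,
    simulate_cohort,
    simulate_pedigree,
    write_cohort,
)
from pedseg.variants import AnnotatedVariant, Genotype, VariantKey

from conftest import make_individual


def test_two_generations_single_child_is_trio(rng):
    cfg = SimulationConfig(generations=2, mean_sibship=1.0)
    fam = simulate_pedigree(cfg, rng, "T")
    assert len(fam) == 3
    kid = [m for m in fam if m.father_id is not None]
    assert len(kid) == 1


def test_fixed_seed_reproduces_pedigree():
    cfg = SimulationConfig(seed=11)
    a = simulate_pedigree(cfg, np.random.default_rng(11), "S")
    b = simulate_pedigree(cfg, np.random.default_rng(11), "S")
    assert a.members == b.members


def test_sibship_mean_matches_configuration(rng):
    cfg = SimulationConfig(mean_sibship=2.5, generations=2)
    sizes = []
    for i in range(1000):
        fam = simulate_pedigree(cfg, rng, f"S{i}")
        sizes.append(len(fam) - 2)  # children of the founder couple
    mean = np.mean(sizes)
    se = np.std(sizes, ddof=1) / np.sqrt(len(sizes))
    assert abs(mean - 2.5) < 3 * se


def test_ages_decrease_down_generations(rng):
    cfg = SimulationConfig(generations=3)
    fam = simulate_pedigree(cfg, rng, "A")
    founders = [m for m in fam if m.father_id is None and m.mother_id is None]
    children = [m for m in fam if m.father_id is not None]
    top = max(m.age_years for m in founders)
    bottom = min(m.age_years for m in children)
    assert top > bottom


# ---------------------------------------------------------------------------
# Gene drop
# ---------------------------------------------------------------------------

def _nuclear(n_children):
    fam = Family("N")
    fam.add(make_individual("f", fam="N", sex=Sex.MALE))
    fam.add(make_individual("m", fam="N", sex=Sex.FEMALE))
    for i in range(n_children):
        fam.add(make_individual(f"c{i}", fam="N", father="f", mother="m"))
    return fam


def test_het_parent_transmits_at_one_half(rng):
    """Carrier fraction among 10^4 children of a het parent lies inside the
    99% binomial confidence band around 1/2."""
    n = 10_000
    fam = _nuclear(n)
    geno = gene_drop(fam, "f", rng)
    carriers = sum(geno[f"c{i}"].carries_alt for i in range(n))
    half_width = 2.576 * np.sqrt(0.25 / n)
    assert abs(carriers / n - 0.5) < half_width


def test_hom_ref_founders_everywhere_hom_ref(rng):
    fam = _nuclear(10)
    geno = drop_alleles(fam, {}, rng)
    assert set(geno.values()) == {Genotype.HOM_REF}


def test_non_descendants_stay_hom_ref(rng):
    cfg = SimulationConfig()
    fam = simulate_pedigree(cfg, rng, "D")
    geno = gene_drop(fam, "D_02", rng)  # the founder mother
    spouses = [
        m.individual_id
        for m in fam
        if m.father_id is None and m.individual_id not in ("D_01", "D_02")
    ]
    for iid in spouses:
        assert geno[iid] is Genotype.HOM_REF


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_gene_drop_is_mendelian_consistent(seed):
    rng = np.random.default_rng(seed)
    cfg = SimulationConfig()
    for i in range(10):
        fam = simulate_pedigree(cfg, rng, f"M{i}")
        geno = gene_drop(fam, f"M{i}_01", rng)
        var = AnnotatedVariant(key=VariantKey("1", 1, "A", "G"), genotypes=geno)
        assert mendelian_consistency(fam, var) == []


def test_unknown_founder_rejected(rng):
    with pytest.raises(KeyError):
        gene_drop(_nuclear(1), "ghost", rng)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _elderly_carriers(n, rng):
    fam = Family("E")
    geno = {}
    for i in range(n):
        fam.add(make_individual(f"e{i}", fam="E", age=85))
        geno[f"e{i}"] = Genotype.HET
    return fam, geno


def test_full_penetrance_elderly_carriers_all_affected(rng):
    cfg = SimulationConfig(penetrance_by_target_age=1.0, phenocopy_rate=0.0)
    fam, geno = _elderly_carriers(50, rng)
    out = assign_phenotypes(fam, geno, cfg, rng)
    assert all(m.affected for m in out)
    assert all(
        m.phenotypes <= {Phenotype.PDAC, Phenotype.PRECURSOR_HIGH_GRADE} for m in out
    )


def test_zero_penetrance_no_carrier_affected(rng):
    cfg = SimulationConfig(penetrance_by_target_age=0.0, phenocopy_rate=0.0)
    fam, geno = _elderly_carriers(50, rng)
    out = assign_phenotypes(fam, geno, cfg, rng)
    assert not any(m.affected for m in out)


def test_penetrance_rate_recovered_in_elderly_carriers(rng):
    n = 2000
    cfg = SimulationConfig(penetrance_by_target_age=0.8, phenocopy_rate=0.0)
    fam, geno = _elderly_carriers(n, rng)
    out = assign_phenotypes(fam, geno, cfg, rng)
    frac = sum(m.affected for m in out) / n
    se = np.sqrt(0.8 * 0.2 / n)
    assert abs(frac - 0.8) < 3 * se


def test_young_carriers_below_onset_range_stay_unaffected(rng):
    cfg = SimulationConfig(penetrance_by_target_age=1.0)
    fam = Family("Y")
    geno = {}
    for i in range(20):
        fam.add(make_individual(f"y{i}", fam="Y", age=30))
        geno[f"y{i}"] = Genotype.HET
    out = assign_phenotypes(fam, geno, cfg, rng)
    assert not any(m.affected for m in out)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def _dummy_variants(n, start=0):
    return [
        AnnotatedVariant(key=VariantKey("8", 1000 + i, "A", "G")) for i in range(start, n)
    ]


def test_causal_rate_one_gives_score_five(rng):
    cfg = SimulationConfig(predictor_damaging_rate_causal=1.0)
    [var] = _dummy_variants(1)
    [annotated] = simulate_annotations([var], {var.key}, cfg, rng)
    assert ps.total_score(annotated.calls).total_score == 5
    assert annotated.population_af < 0.01  # planted variants forced rare


def test_background_rate_zero_gives_low_scores(rng):
    cfg = SimulationConfig(predictor_damaging_rate_background=0.0)
    annotated = simulate_annotations(_dummy_variants(50), set(), cfg, rng)
    assert all(ps.total_score(v.calls).total_score <= 1 for v in annotated)


def test_background_mean_score_matches_binomial(rng):
    n = 10_000
    cfg = SimulationConfig(predictor_damaging_rate_background=0.1)
    annotated = simulate_annotations(_dummy_variants(n), set(), cfg, rng)
    scores = [ps.total_score(v.calls).total_score for v in annotated]
    se = np.sqrt(5 * 0.1 * 0.9 / n)
    assert abs(np.mean(scores) - 0.5) < 3 * se


# ---------------------------------------------------------------------------
# Cohort files
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_sim():
    return simulate_cohort(
        SimulationConfig(n_families=4, causal_fraction=0.5, n_background_variants=20, seed=5)
    )


def test_cohort_roundtrip(tmp_path, small_sim):
    files = write_cohort(small_sim, tmp_path)
    back = ps.read_pedigree(files["pedigree"])
    assert set(back.families) == set(small_sim.cohort.families)
    for fid, fam in small_sim.cohort.families.items():
        assert back.families[fid].members == fam.members
    variants = ps.read_vcf_genotypes(files["vcf"], back)
    by_key = {v.key: v for v in variants}
    for v in small_sim.variants:
        got = by_key[v.key]
        for iid, g in v.genotypes.items():
            assert got.genotypes[iid] == g
        assert all(
            g is Genotype.MISSING
            for iid, g in got.genotypes.items()
            if iid not in v.genotypes
        )
    table = ps.read_annotation_table(files["annotations"])
    assert set(table) == {v.key for v in small_sim.variants}


def test_simulated_cohort_is_mendelian_consistent(small_sim):
    for fam in small_sim.cohort:
        for var in small_sim.variants:
            assert mendelian_consistency(fam, family_view(var, fam)) == []


def test_truth_keys_are_cohort_families(small_sim):
    assert set(small_sim.truth) == set(small_sim.cohort.families)
    planted = [k for k in small_sim.truth.values() if k is not None]
    assert len(planted) == 2  # causal_fraction 0.5 of 4 families
    assert len(set(planted)) == len(planted)


def test_identical_seed_gives_byte_identical_files(tmp_path):
    cfg = SimulationConfig(n_families=3, causal_fraction=1.0, n_background_variants=10, seed=9)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    f1 = write_cohort(simulate_cohort(cfg), d1)
    f2 = write_cohort(simulate_cohort(cfg), d2)
    for name in f1:
        assert f1[name].read_bytes() == f2[name].read_bytes()


def test_empty_cohort_writes_valid_headers(tmp_path):
    sim = ps.SimulatedCohort(cohort=ps.Cohort(), variants=[], truth={})
    files = write_cohort(sim, tmp_path)
    assert ps.read_pedigree(files["pedigree"]).families == {}
    assert ps.read_annotation_table(files["annotations"]) == {}
    assert files["vcf"].read_text().startswith("##fileformat")


def test_eligibility_of_causal_families(small_sim):
    for fid, key in small_sim.truth.items():
        if key is None:
            continue
        fam = small_sim.cohort.families[fid]
        aff = sum(1 for m in fam if m.affected and m.has_blood_dna)
        unaff = sum(1 for m in fam if not m.affected and m.has_blood_dna)
        assert aff >= 3 and unaff >= 2
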