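import numpy as np
import pytest
from hypothesis import settings

import pedseg as ps
from pedseg.pedigree import AgeKind, Family, Individual, Phenotype, Sex

settings.register_profile("default", derandomize=True, max_examples=100)
settings.load_profile("default")


@pytest.fixture(scope="session")
def bundle():
    return ps.build_fixture_bundle()


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    return ps.write_fixture_bundle(tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def bundle_run(bundle_dir, tmp_path_factory):
    cfg = ps.RunConfig(
        ped_path=bundle_dir["pedigree"],
        vcf_path=bundle_dir["vcf"],
        annotations_path=bundle_dir["annotations"],
        validation_counts_path=bundle_dir["validation_cohorts"],
        significance_path=bundle_dir["significance"],
        out_dir=tmp_path_factory.mktemp("bundle_run"),
    )
    return ps.run_pipeline(cfg)


def make_individual(iid, fam="FAM1", father=None, mother=None, sex=Sex.UNKNOWN,
                    phenos=(), age=None, dna=True):
    return Individual(
        individual_id=iid,
        family_id=fam,
        father_id=father,
        mother_id=mother,
        sex=sex,
        phenotypes=frozenset(phenos),
        age_years=age,
        age_kind=AgeKind.CURRENT if age is not None else AgeKind.MISSING,
        has_blood_dna=dna,
    )


def make_trio(child_phenos=(Phenotype.PDAC,)):
    fam = Family("FAM1")
    fam.add(make_individual("dad", sex=Sex.MALE, age=70))
    fam.add(make_individual("mom", sex=Sex.FEMALE, age=68))
    fam.add(make_individual("kid", father="dad", mother="mom", sex=Sex.MALE,
                            phenos=child_phenos, age=40))
    return fam


@pytest.fixture
def trio():
    return make_trio()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_families(n, rng, **config_kwargs):
    """Phenotyped random pedigrees for property tests."""
    cfg = ps.SimulationConfig(**config_kwargs)
    out = []
    for i in range(n):
        fam = ps.simulate_pedigree(cfg, rng, family_id=f"R{i:03d}")
        geno = ps.gene_drop(fam, f"R{i:03d}_01", rng)
        out.append(ps.assign_phenotypes(fam, geno, cfg, rng))
    return out
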