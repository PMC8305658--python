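# pedseg

Variant prioritization and pedigree co-segregation analysis for familial
cancer cohorts, built around the workflow used to hunt predisposition genes
in **familial pancreatic cancer (FPC)** — families with two or more
first-degree relatives with confirmed pancreatic ductal adenocarcinoma
(PDAC) and no mutation in the known predisposition genes (*BRCA1/2*,
*CDKN2A*, *PALB2*).

Because no single high-penetrance FPC gene exists, candidate discovery in
multiplex families proceeds in three steps, all implemented here as a
tested, reusable library:

1. **Ensemble deleteriousness score.** For each variant, five in-silico
   predictors vote: SIFT, PolyPhen-2, MutationTaster, PROVEAN, and CADD
   (phred ≥ 20 counts as damaging). The total score
   `S = Σᵢ 𝟙[toolᵢ = damaging] ∈ {0..5}` summarizes agreement.
2. **Three-tier triage.** A variant is retained if (T1) `S ≥ 4`; (T2) it
   lies in a configured FPC risk gene with CADD < 20 (catching risk-gene
   variants the score alone would miss); or (T3) `S ≥ 4` and it recurs in
   ≥ 2 families.
3. **Per-family co-segregation with incomplete penetrance.** A candidate
   *fails* in a family if any genotyped affected member (PDAC or a
   high-grade precursor lesion, PanIN2/3) is a non-carrier. Unaffected
   carriers never eliminate a candidate: dominant cancer-predisposition
   alleles are incompletely penetrant, so healthy elderly carriers and
   carriers too young for a disease with median onset ~65 years are both
   recorded as *exemptions*, and the verdict becomes
   `incomplete_penetrance` instead of `complete`.

Cohort-level reporting counts carrier families across validation screens
(`4/46 → 8.7%`), and a seeded synthetic-cohort generator (multi-generation
pedigrees, Mendelian gene drop, age-dependent penetrance, phenocopies,
predictor calls correlated with true causality) makes the whole pipeline
testable without patient data.

## Worked example

The package ships a curated 15-family reference cohort in which seven
families carry co-segregating candidates in seven genes. Running the full
pipeline on it (`python examples/04_full_pipeline.py`) prints:

```
           variants_in: 15
       after_prefilter: 14
          after_triage: 11
   passing_segregation: 10
    candidate_families: 7

  gene                        family_ids significance segregation families_with_variant       af_band
 ACAD9 25-1-91;25-2-209;25-4-46;25-9-113          VUS         yes                  4/46 low_frequency
   ATM                         02-5-0382  deleterious         yes                  1/36 rare(imputed)
  DAB1                           25-9-44   pathogenic         yes                  1/49          rare
FGFBP3                           25-9-44  deleterious         yes                  1/29          rare
MAP3K3                           25-4-46  deleterious         yes                  1/29          rare
  POLQ                           25-9-44          VUS         yes                  1/29 low_frequency
  SUFU                           25-5-67   pathogenic         yes                  1/15          rare
```

Reading the output: 15 variants enter, a synonymous variant falls at the
consequence prefilter, low-scoring non-risk-gene variants fall at triage,
and one triaged variant (FANCM) is eliminated because an affected member
does not carry it — leaving 7 of 15 families with at least one candidate
that co-segregates with pancreatic disease. `families_with_variant` pools
the initial screen with follow-up validation cohorts: ACAD9 A326T was found
in 4 of 46 screened families (8.7%). One family carries three
co-segregating candidates at once (DAB1, POLQ, FGFBP3) — consistent with
FPC being a heterogeneous, possibly polygenic trait driven by rare and
low-frequency variants.

Other entry points:

```sh
python examples/01_prevalence_arithmetic.py   # carrier-family percentages
python examples/02_segregation_verdicts.py    # incomplete penetrance & cross-phenotype
python examples/03_simulate_and_recover.py    # synthetic cohort round trip
pedseg fixtures --out bundle/                 # write the reference cohort files
pedseg run --ped ... --vcf ... --annotations ... --out run/
pedseg simulate --seed 1 --out sim/
```

## Layout

- `src/pedseg/pedigree.py` — pedigree model, PED dialects, relationship
  queries, FPC/WGS eligibility filters
- `src/pedseg/variants.py` — VCF genotypes (pysam), predictor-annotation
  table, allele-frequency bands
- `src/pedseg/prioritize.py` — damaging votes, total score, three-tier triage
- `src/pedseg/segregation.py` — co-segregation verdicts, penetrance
  exemptions, Mendelian-consistency QC
- `src/pedseg/prevalence.py` — carrier-family counting and summary tables
- `src/pedseg/simulate.py` — seeded synthetic cohort generator
- `src/pedseg/fixtures.py` — curated reference cohort (synthetic encodings)
- `src/pedseg/pipeline.py`, `src/pedseg/cli.py` — orchestration and CLI

See `docs/methods.md` for the model, its assumptions and limitations.
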