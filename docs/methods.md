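# Methods

## The analysis model

pedseg formalizes the candidate-gene workflow for dominant, late-onset
familial cancer: rank variants by agreement among in-silico deleteriousness
predictors, triage candidates by score / risk-gene membership / recurrence,
and keep only those consistent with co-segregation in the family in which
they were found.

### Ensemble score

Each variant carries categorical calls from SIFT
(deleterious/tolerated), PolyPhen-2 (probably/possibly damaging, benign),
MutationTaster (disease-causing [automatic], polymorphism), PROVEAN
(deleterious/neutral) and a CADD phred value. Each predictor casts one vote:
damaging, benign, or missing. The total score is the count of damaging
votes (0–5). Two conventions are configurable because the field uses both:

- `polyphen_possibly_counts` (default true): PolyPhen-2 "possibly damaging"
  counts as a damaging vote, matching the common D/P collapsing.
- CADD votes damaging at `cadd_high_cutoff` (default phred 20, i.e. the
  top 1% of genome-wide substitutions).

### Triage tiers

- **T1** total score ≥ `high_score_threshold` (default 4 of 5 — a strict
  majority-plus; the literature rarely publishes an explicit cutoff, so the
  value is exposed in `TriageConfig`).
- **T2** variant in a configured FPC risk-gene list *and* CADD below the
  high cutoff. This deliberately complements T1: a risk-gene variant with
  unimpressive tool support is still worth segregation testing. The shipped
  list (`src/pedseg/data/risk_genes.txt`) seeds the genes recurrently
  implicated in FPC (ATM, POLQ, BUB1B, CPA1, FANCC, FANCG, BRCA1/2, PALB2,
  CDKN2A) and is a plain editable text file.
- **T3** high-scoring variant carried by ≥ `recurrence_min_families`
  families (families, not carriers, are counted).

### Co-segregation with incomplete penetrance

For a phenotype specification (default: PDAC ∪ high-grade precursor
lesions PanIN2/3; melanoma is added for pancreatic cancer–melanoma-syndrome
families; breast cancer is a separate specification), counting only members
with a non-missing germline genotype:

- **fails** — genotyped affected non-carriers exceed
  `max_affected_noncarriers` (default 0: a single affected non-carrier
  eliminates the candidate), or no genotyped affected member exists.
- **complete** — otherwise, if no genotyped unaffected member carries.
- **incomplete_penetrance** — otherwise. Every phenotype-free carrier is
  recorded as an exemption annotated by age against
  `exemption_age_threshold` (default 65 y, the typical FPC onset age):
  `elderly_carrier` (lived past typical onset unaffected — true
  non-penetrance) vs `young_carrier` (likely pre-onset). The threshold only
  annotates; it never changes the verdict. Carriers affected by a
  *non-target* phenotype (e.g. breast cancer during a pancreatic analysis)
  are noted separately and are not "healthy" exemptions.

Deliberate restraints: obligate-carrier inference for ungenotyped ancestors
is not performed (unavailable individuals are simply uninformative), and
tumor-tissue genotypes are stored separately and never substitute for
germline calls.

Under independent Bernoulli(1/2) carriage, a family with `a` genotyped
affected and `u` genotyped unaffected members passes `complete` with
probability (1/2)^(a+u); the tests verify this by exhaustive enumeration
(a+u ≤ 10) and Monte Carlo.

### Prevalence reporting

Carrier-family prevalence is `100 · |carrier families| / families tested`,
rounded half-even to one decimal; display suppresses a trailing `.0`
(so 4/46 → "8.7", 1/49 → "2"). Screens of the same variant are poolable
when their carrier-family sets are disjoint. Biological-significance labels
(pathogenic / deleterious / VUS) are curated inputs passed through to
reports, never computed.

## File formats

- **ped_extended**: tab-separated, fixed header, extending 6-column PED
  with phenotype tokens (semicolon-separated), age, age kind, blood/tumor
  DNA flags, deceased flag and two family-level columns (family type,
  prior predisposition-mutation flag). Missing parents are `0` (PED
  convention), other missing values `.`. Round-trips losslessly.
- **VCF 4.x** via pysam; multiallelic records are split per alternate
  allele with genotypes recoded against that allele. Variant keys are
  reduced to minimal representation (shared suffix/prefix trimming) before
  joining with the annotation table, which uses the same normalization.
- **Annotation TSV**: declared header, dbNSFP-style one-letter codes
  (SIFT D/T; PolyPhen-2 D/P/B; MutationTaster A/D/N/P; PROVEAN D/N),
  remappable via `code_maps` since e.g. the PolyPhen-2 model (HDIV/HVAR)
  behind a table is often unrecorded. The table freezes upstream annotation
  output as data; no annotation tool is invoked and no network is touched.

## Synthetic cohort generator

The generator emulates the regime of a multiplex-family registry study:

- **Pedigrees**: one founder couple, `generations` (default 3) levels,
  sibship sizes `1 + Poisson(mean_sibship − 1)` (mean exactly
  `mean_sibship`, default 2.5), every non-terminal child marries an
  unrelated founder; generation mean ages step down by 27 y from a youngest
  generation at 32 y (Gaussian jitter, σ = 5). These defaults reproduce a
  median affected age of ≈ 64–65 y in accepted families.
- **Genotypes**: the causal variant is planted heterozygous in one top
  founder and gene-dropped (het parent transmits with probability 1/2);
  background variants draw founder genotypes from Hardy–Weinberg at a
  log-uniform population AF (10⁻⁵–0.05) and are dropped the same way, so
  *all* simulated genotypes are Mendelian-consistent by construction.
- **Phenotypes**: each member samples an onset age from a truncated normal
  (median 65 y, range 42–78 y). Carriers at/past onset become PDAC or
  precursor cases with `penetrance_by_target_age` (default 0.8);
  non-carriers at/past onset become sporadic (phenocopy) cases with
  `phenocopy_rate` (default 0.01). Phenocopies are age-gated like carriers
  because sporadic PDAC is itself a late-onset disease.
- **Ascertainment**: blood DNA is available per member with probability
  `1 − genotyping_missingness` (default 0.8); at most ~4 cases and ~4
  controls are genotyped per family (registry sequencing budgets); causal
  families are rejection-sampled until ≥ 3 genotyped affected and ≥ 2
  genotyped unaffected members exist, mirroring study inclusion criteria.
  Non-causal families are not conditioned (sporadic cases alone cannot
  plausibly produce three affected).
- **Annotations**: each predictor votes damaging independently with rate
  0.9 for planted variants and 0.1 for background; CADD is drawn above or
  below the cutoff at the same rates; planted variants are forced rare.

All randomness flows from a single `numpy` generator seeded by
`SimulationConfig.seed`; identical configurations give byte-identical
output files.

What the generator does **not** model — and hence what passing tests do not
establish about real data: linkage and haplotype structure (sites segregate
independently), genotyping error, de novo mutation, consanguinity,
non-Poisson family-size variation, competing mortality, and correlated
predictor errors (real tools share training data and fail together;
simulated votes are independent given causality). A documented consequence
of the independent-vote model: a truly causal variant reaches the default
triage threshold (≥ 4 of 5 damaging at rate 0.9) with probability
Binomial(5, 0.9) ≥ 4 = 0.918, and ascertainment on ≥ 3 genotyped affected
enriches families containing a sporadic phenocopy, which the
zero-tolerance segregation rule then rejects. End-to-end recovery of the
planted variant at fully default settings is therefore ≈ 0.74 rather than
near-certain; raising `max_affected_noncarriers` to 1 or lowering the
score threshold trades specificity for sensitivity.

## Reference cohort

`pedseg.fixtures` encodes a 15-family cohort — four narrative families
(ATM; SUFU + FANCM; DAB1 + POLQ + FGFBP3; MAP3K3 + ACAD9), three further
ACAD9-carrier families and eight candidate-free fillers — plus per-gene
validation-cohort counts. Genotype/phenotype assignments encode each
family's co-segregation pattern (who was tested, who carried, who was
affected); per-tool predictor calls are synthetic stand-ins consistent with
each variant's curated significance label, and filler families are entirely
synthetic, as the bundle manifest records. The bundle passes Mendelian QC
and round-trips through the package's own I/O.

## Numerical and engineering choices

- Problem sizes in tests: statistical checks use 10³–2×10⁴ replicates
  (binomial checks asserted within 3–4 standard errors); the end-to-end
  recovery property uses 200 simulated causal families with 200 background
  variants each. The whole suite runs in well under a minute on one core.
- Percent rounding is banker's rounding (Python `round`), one decimal.
- All report tables and files are emitted in deterministic sort order
  (variants by chrom/pos/ref/alt; families lexicographically), so reports
  are byte-identical across runs and invariant to input row order.
- Cohort-wide individual ids must be unique (VCF sample names are global);
  the fixture and simulator prefix ids with the family id.
- Degenerate inputs: empty cohorts produce valid header-only files;
  families with no genotyped affected yield `fails` with note
  `no_informative_affected` rather than a vacuous pass; a variant with no
  carriers is noted `no_carriers`.
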