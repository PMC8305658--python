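"""End-to-end orchestration: ingest -> score -> triage -> segregate -> report.

The pipeline reads a pedigree cohort, a genotype VCF and a predictor
annotation table, applies the consequence prefilter, the ensemble score and
the three-tier triage, evaluates per-family co-segregation against the
pancreatic phenotype (with melanoma included for pancreatic
cancer-melanoma-syndrome families by default), and writes deterministic
TSV/JSON reports with stage counts logged at every step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .pedigree import Cohort, Family, FamilyType, read_pedigree
from .prevalence import (
    CandidateSummary,
    PrevalenceRecord,
    ValidationCohort,
    build_summary_table,
    family_prevalence,
    merge_cohorts,
)
from .prioritize import (
    Tier,
    TriageConfig,
    TriagedVariant,
    load_risk_genes,
    prefilter_nonsynonymous,
    total_score,
    triage,
)
from .segregation import (
    PANCREATIC,
    PANCREATIC_MELANOMA,
    PenetranceRule,
    SegregationResult,
    Verdict,
    evaluate_segregation,
    family_view,
)
from .variants import (
    AnnotatedVariant,
    VariantKey,
    apply_annotations,
    read_annotation_table,
    read_vcf_genotypes,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    ped_path: Path
    vcf_path: Path
    annotations_path: Path
    out_dir: Path | None = None
    risk_genes_path: Path | None = None
    validation_counts_path: Path | None = None
    significance_path: Path | None = None
    triage: TriageConfig = field(default_factory=TriageConfig)
    rule: PenetranceRule = field(default_factory=PenetranceRule)
    #: evaluate PCMS families against pancreatic disease plus melanoma
    include_melanoma_for_pcms: bool = True
    strict_samples: bool = False


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    """Build a RunConfig from a YAML file (paths relative to the file)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    base = path.parent

    def resolve(key):
        return (base / raw[key]).resolve() if key in raw else None

    triage_kwargs = dict(raw.get("triage", {}))
    if "risk_genes" in triage_kwargs:
        triage_kwargs["risk_genes"] = frozenset(triage_kwargs["risk_genes"])
    rule_kwargs = raw.get("penetrance_rule", {})
    cfg = RunConfig(
        ped_path=resolve("ped"),
        vcf_path=resolve("vcf"),
        annotations_path=resolve("annotations"),
        out_dir=resolve("out_dir"),
        risk_genes_path=resolve("risk_genes"),
        validation_counts_path=resolve("validation_counts"),
        significance_path=resolve("significance"),
        triage=TriageConfig(**triage_kwargs),
        rule=PenetranceRule(**rule_kwargs),
        include_melanoma_for_pcms=raw.get("include_melanoma_for_pcms", True),
        strict_samples=raw.get("strict_samples", False),
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


@dataclass
class PipelineResult:
    cohort: Cohort
    variants: list[AnnotatedVariant]
    triaged: list[TriagedVariant]
    segregation: list[SegregationResult]
    summary: pd.DataFrame
    stage_counts: dict[str, int]
    candidate_families: list[str]
    candidate_genes: list[str]
    files: dict[str, Path] = field(default_factory=dict)


def _phenotype_for(family: Family, config: RunConfig):
    if config.include_melanoma_for_pcms and family.family_type is FamilyType.PCMS:
        return PANCREATIC_MELANOMA
    return PANCREATIC


def _load_validation(path: Path) -> dict[str, ValidationCohort]:
    raw = json.loads(path.read_text(encoding="utf-8"))
    merged: dict[str, ValidationCohort] = {}
    for gene, entries in raw.items():
        cohorts = [
            ValidationCohort(
                gene=gene,
                variant=VariantKey("NA", 1, "N", "A"),
                families_tested=e["families_tested"],
                carrier_families=frozenset(e["carrier_families"]),
                label=e.get("label", ""),
            )
            for e in entries
        ]
        merged[gene] = merge_cohorts(cohorts[0], cohorts[1:])
    return merged


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full prioritization/segregation pipeline.

    Stage counts (variants in, after prefilter, after triage, passing
    segregation, candidate families) are recorded in ``stage_counts`` and,
    when ``out_dir`` is set, logged as one JSON line per stage alongside the
    TSV reports.  Output is deterministic and invariant to input row order.
    """
    cohort = read_pedigree(config.ped_path)
    raw_variants = read_vcf_genotypes(config.vcf_path, cohort, strict=config.strict_samples)
    table = read_annotation_table(config.annotations_path)
    if config.risk_genes_path is not None:
        config.triage = TriageConfig(
            **{
                **config.triage.__dict__,
                "risk_genes": load_risk_genes(config.risk_genes_path),
            }
        )
    variants = apply_annotations(raw_variants, table)
    stage_counts: dict[str, int] = {"variants_in": len(variants)}

    kept = prefilter_nonsynonymous(variants, config.triage)
    stage_counts["after_prefilter"] = len(kept)

    by_key = {v.key: v for v in kept}
    variants_by_family = {
        fam.family_id: [
            fv
            for v in kept
            if (fv := family_view(v, fam)).carriers()
        ]
        for fam in sorted(cohort, key=lambda f: f.family_id)
    }
    triaged = triage(variants_by_family, config.triage)
    for tv in triaged:  # carry the cohort-wide genotype map, not a family view
        tv.variant = by_key[tv.key]
    stage_counts["after_triage"] = len(triaged)

    segregation: list[SegregationResult] = []
    passing_pairs = 0
    for tv in triaged:
        for fid in sorted(tv.families_with_variant):
            fam = cohort.families[fid]
            spec = _phenotype_for(fam, config)
            res = evaluate_segregation(
                fam, family_view(by_key[tv.key], fam), spec, config.rule
            )
            segregation.append(res)
            if res.verdict.passing:
                passing_pairs += 1
    stage_counts["passing_segregation"] = passing_pairs

    passing_by_key: dict[VariantKey, list[str]] = {}
    for res in segregation:
        if res.verdict.passing:
            passing_by_key.setdefault(res.key, []).append(res.family_id)
    candidate_families = sorted({fid for fids in passing_by_key.values() for fid in fids})
    stage_counts["candidate_families"] = len(candidate_families)

    validation = (
        _load_validation(config.validation_counts_path)
        if config.validation_counts_path
        else {}
    )
    significance = (
        json.loads(Path(config.significance_path).read_text(encoding="utf-8"))
        if config.significance_path
        else {}
    )

    summaries = []
    candidate_genes = []
    for tv in triaged:
        fids = sorted(passing_by_key.get(tv.key, []))
        if not fids:
            continue
        candidate_genes.append(tv.gene)
        merged = validation.get(tv.gene)
        prevalence = (
            family_prevalence(
                ValidationCohort(
                    tv.gene,
                    tv.key,
                    merged.families_tested,
                    merged.carrier_families,
                )
            )
            if merged
            else None
        )
        summaries.append(
            CandidateSummary(
                gene=tv.gene,
                variant=tv.key,
                family_ids=fids,
                family_types=[cohort.families[f].family_type.value for f in fids],
                hgvs_c=tv.variant.hgvs_c,
                hgvs_p=tv.variant.hgvs_p,
                mutation_type=tv.variant.consequence.value,
                significance=significance.get(tv.gene, "."),
                segregation=True,
                prevalence=prevalence,
                population_af=tv.variant.population_af,
            )
        )
    summary = build_summary_table(summaries)
    candidate_genes = sorted(set(candidate_genes))

    files: dict[str, Path] = {}
    if config.out_dir is not None:
        files = _write_reports(config, stage_counts, triaged, segregation, summary)

    return PipelineResult(
        cohort=cohort,
        variants=variants,
        triaged=triaged,
        segregation=segregation,
        summary=summary,
        stage_counts=stage_counts,
        candidate_families=candidate_families,
        candidate_genes=candidate_genes,
        files=files,
    )


def _write_reports(config, stage_counts, triaged, segregation, summary) -> dict[str, Path]:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    score_rows = [
        {
            "variant": str(tv.key),
            "gene": tv.gene,
            **{p: v.value for p, v in tv.score.votes.items()},
            "total_score": tv.score.total_score,
            "n_informative": tv.score.n_informative,
            "tiers": ";".join(sorted(t.value for t in tv.tiers)),
            "families_with_variant": ";".join(sorted(tv.families_with_variant)),
        }
        for tv in triaged
    ]
    triage_path = out / "triage.tsv"
    pd.DataFrame(score_rows).to_csv(triage_path, sep="\t", index=False)

    seg_rows = [
        {
            "family_id": r.family_id,
            "variant": str(r.key),
            "phenotype": r.phenotype,
            "verdict": r.verdict.value,
            "affected_carriers": r.affected_carriers,
            "affected_genotyped": r.affected_genotyped,
            "affected_noncarriers": r.affected_noncarriers,
            "unaffected_carriers": r.unaffected_carriers,
            "exemptions": ";".join(
                f"{e.individual_id}({'.' if e.age_years is None else format(e.age_years, 'g')}:{e.category})"
                for e in r.exemptions
            )
            or ".",
            "notes": ";".join(r.notes) or ".",
        }
        for r in segregation
    ]
    seg_path = out / "segregation.tsv"
    pd.DataFrame(seg_rows).to_csv(seg_path, sep="\t", index=False)

    summary_path = out / "summary.tsv"
    summary.to_csv(summary_path, sep="\t", index=False)

    log_path = out / "log.jsonl"
    with open(log_path, "w", encoding="utf-8") as fh:
        for stage, count in stage_counts.items():
            fh.write(json.dumps({"stage": stage, "count": count}) + "\n")

    return {
        "triage": triage_path,
        "segregation": seg_path,
        "summary": summary_path,
        "log": log_path,
    }
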