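"""Ensemble deleteriousness scoring and three-tier candidate triage.

The total score of a variant is the number of "damaging" votes among the
five in-silico predictors (SIFT, PolyPhen-2, MutationTaster, PROVEAN, and
CADD phred against a cutoff, 20 by default).  Candidate triage retains a
variant when it lands in at least one of three tiers:

T1  high total score (>= ``high_score_threshold``, default 4 of 5);
T2  variant in a configured FPC risk gene with CADD below the high cutoff
    (catches risk-gene variants whose ensemble score alone would miss);
T3  high-scoring variant recurring in >= ``recurrence_min_families``
    families (families are counted, not carriers).

Variants that hit no tier are dropped.  Output order is deterministic
(chrom, pos, ref, alt), independent of input order.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .variants import (
    AnnotatedVariant,
    Consequence,
    MutationTasterCall,
    PolyPhenCall,
    PredictorCalls,
    ProveanCall,
    SiftCall,
    VariantKey,
)

__all__ = [
    "Vote",
    "Tier",
    "PREDICTORS",
    "TriageConfig",
    "ScoreResult",
    "TriagedVariant",
    "damaging_vote",
    "total_score",
    "prefilter_nonsynonymous",
    "triage",
    "load_risk_genes",
    "default_risk_genes",
]

PREDICTORS = ("sift", "polyphen2", "mutation_taster", "provean", "cadd")


class Vote(str, enum.Enum):
    DAMAGING = "damaging"
    BENIGN = "benign"
    MISSING = "missing"


class Tier(str, enum.Enum):
    T1_HIGH_SCORE = "T1_high_score"
    T2_RISK_GENE = "T2_risk_gene"
    T3_RECURRENT = "T3_recurrent"


def default_risk_genes() -> frozenset[str]:
    """The FPC risk-gene list shipped with the package (editable text file)."""
    text = resources.files("pedseg.data").joinpath("risk_genes.txt").read_text()
    return frozenset(
        line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")
    )


def load_risk_genes(path: str | Path) -> frozenset[str]:
    """Load a risk-gene list: one symbol per line, ``#`` comments allowed."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return frozenset(l.strip() for l in lines if l.strip() and not l.startswith("#"))


@dataclass(frozen=True)
class TriageConfig:
    high_score_threshold: int = 4
    risk_genes: frozenset[str] = field(default_factory=default_risk_genes)
    recurrence_min_families: int = 2
    cadd_high_cutoff: float = 20.0
    #: whether PolyPhen-2 "possibly damaging" counts as a damaging vote
    polyphen_possibly_counts: bool = True
    #: whether promoter variants survive the non-synonymous prefilter
    keep_promoter: bool = True

    def __post_init__(self):
        if self.high_score_threshold < 0:
            raise ValueError("high_score_threshold must be >= 0")
        if self.recurrence_min_families < 1:
            raise ValueError("recurrence_min_families must be >= 1")


@dataclass(frozen=True)
class ScoreResult:
    key: VariantKey
    votes: dict[str, Vote]
    total_score: int
    n_informative: int


@dataclass
class TriagedVariant:
    key: VariantKey
    gene: str
    tiers: frozenset[Tier]
    families_with_variant: frozenset[str]
    score: ScoreResult
    variant: AnnotatedVariant


def damaging_vote(
    calls: PredictorCalls, predictor: str, config: TriageConfig | None = None
) -> Vote:
    """Map one predictor's categorical call (or CADD value) to a vote."""
    config = config or TriageConfig()
    if predictor == "sift":
        if calls.sift is SiftCall.MISSING:
            return Vote.MISSING
        return Vote.DAMAGING if calls.sift is SiftCall.DELETERIOUS else Vote.BENIGN
    if predictor == "polyphen2":
        if calls.polyphen2 is PolyPhenCall.MISSING:
            return Vote.MISSING
        damaging = {PolyPhenCall.PROBABLY_DAMAGING}
        if config.polyphen_possibly_counts:
            damaging.add(PolyPhenCall.POSSIBLY_DAMAGING)
        return Vote.DAMAGING if calls.polyphen2 in damaging else Vote.BENIGN
    if predictor == "mutation_taster":
        if calls.mutation_taster is MutationTasterCall.MISSING:
            return Vote.MISSING
        damaging_mt = {
            MutationTasterCall.DISEASE_CAUSING,
            MutationTasterCall.DISEASE_CAUSING_AUTOMATIC,
        }
        return Vote.DAMAGING if calls.mutation_taster in damaging_mt else Vote.BENIGN
    if predictor == "provean":
        if calls.provean is ProveanCall.MISSING:
            return Vote.MISSING
        return Vote.DAMAGING if calls.provean is ProveanCall.DELETERIOUS else Vote.BENIGN
    if predictor == "cadd":
        if calls.cadd_phred is None:
            return Vote.MISSING
        return (
            Vote.DAMAGING if calls.cadd_phred >= config.cadd_high_cutoff else Vote.BENIGN
        )
    raise ValueError(f"unknown predictor {predictor!r}")


def total_score(
    calls: PredictorCalls,
    config: TriageConfig | None = None,
    key: VariantKey | None = None,
) -> ScoreResult:
    """Sum damaging votes over the five predictors."""
    config = config or TriageConfig()
    votes = {p: damaging_vote(calls, p, config) for p in PREDICTORS}
    score = sum(1 for v in votes.values() if v is Vote.DAMAGING)
    informative = sum(1 for v in votes.values() if v is not Vote.MISSING)
    return ScoreResult(
        key=key or VariantKey("NA", 1, "N", "A"),
        votes=votes,
        total_score=score,
        n_informative=informative,
    )


def prefilter_nonsynonymous(
    variants: Iterable[AnnotatedVariant], config: TriageConfig | None = None
) -> list[AnnotatedVariant]:
    """Keep missense, splice-site and (optionally) promoter variants.

    Synonymous and other consequences are dropped; this mirrors the focus on
    exonic, possibly-damaging SNVs ahead of scoring.
    """
    config = config or TriageConfig()
    keep = {Consequence.MISSENSE, Consequence.SPLICE_SITE}
    if config.keep_promoter:
        keep.add(Consequence.PROMOTER)
    return [v for v in variants if v.consequence in keep]


def triage(
    variants_by_family: Mapping[str, Iterable[AnnotatedVariant]],
    config: TriageConfig | None = None,
) -> list[TriagedVariant]:
    """Assign triage tiers to variants grouped by family.

    A family "has" a variant when at least one genotyped member carries the
    alternate allele.  Variants with an empty tier set are dropped; retained
    variants are returned in (chrom, pos, ref, alt) order.
    """
    config = config or TriageConfig()
    by_key: dict[VariantKey, AnnotatedVariant] = {}
    families: dict[VariantKey, set[str]] = {}
    for family_id, variants in variants_by_family.items():
        for var in variants:
            member_carriers = var.carriers()
            by_key.setdefault(var.key, var)
            if member_carriers:
                families.setdefault(var.key, set()).add(family_id)
    out: list[TriagedVariant] = []
    for key in sorted(by_key):
        var = by_key[key]
        score = total_score(var.calls, config, key=key)
        fams = frozenset(families.get(key, set()))
        tiers: set[Tier] = set()
        if score.total_score >= config.high_score_threshold:
            tiers.add(Tier.T1_HIGH_SCORE)
        if (
            var.gene in config.risk_genes
            and var.calls.cadd_phred is not None
            and var.calls.cadd_phred < config.cadd_high_cutoff
        ):
            tiers.add(Tier.T2_RISK_GENE)
        if (
            score.total_score >= config.high_score_threshold
            and len(fams) >= config.recurrence_min_families
        ):
            tiers.add(Tier.T3_RECURRENT)
        if tiers:
            out.append(
                TriagedVariant(
                    key=key,
                    gene=var.gene,
                    tiers=frozenset(tiers),
                    families_with_variant=fams,
                    score=score,
                    variant=var,
                )
            )
    return out
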