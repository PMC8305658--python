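"""Variant and genotype I/O plus harmonization of the five-predictor table.

A variant is identified by a normalized :class:`VariantKey` (chrom, 1-based
pos, ref, alt).  Genotype maps come from VCF (multiallelic records are split
per alternate allele); in-silico predictor calls (SIFT, PolyPhen-2,
MutationTaster, PROVEAN, CADD) and population allele frequencies come from a
tab-separated annotation table which freezes the output of upstream
annotation tools as data, so the pipeline needs no network access.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .pedigree import Cohort

__all__ = [
    "VariantKey",
    "Genotype",
    "Consequence",
    "SiftCall",
    "PolyPhenCall",
    "MutationTasterCall",
    "ProveanCall",
    "PredictorCalls",
    "AnnotatedVariant",
    "AFBand",
    "AnnotationRecord",
    "AnnotationError",
    "af_band",
    "read_vcf_genotypes",
    "write_vcf",
    "read_annotation_table",
    "write_annotation_table",
    "apply_annotations",
    "DEFAULT_CODE_MAPS",
]


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class VariantKey:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")

    def normalized(self) -> "VariantKey":
        """Minimal representation: trim shared suffix, then shared prefix.

        Keys from the VCF reader and the annotation-table reader are both
        normalized this way so they join exactly.
        """
        ref, alt, pos = self.ref, self.alt, self.pos
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        return VariantKey(self.chrom, pos, ref, alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT)

    @property
    def alt_dosage(self) -> int:
        return {"hom_ref": 0, "het": 1, "hom_alt": 2, "missing": 0}[self.value]


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    SPLICE_SITE = "splice_site"
    PROMOTER = "promoter"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class SiftCall(str, enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    MISSING = "missing"


class PolyPhenCall(str, enum.Enum):
    PROBABLY_DAMAGING = "probably_damaging"
    POSSIBLY_DAMAGING = "possibly_damaging"
    BENIGN = "benign"
    MISSING = "missing"


class MutationTasterCall(str, enum.Enum):
    DISEASE_CAUSING_AUTOMATIC = "disease_causing_automatic"
    DISEASE_CAUSING = "disease_causing"
    POLYMORPHISM = "polymorphism"
    MISSING = "missing"


class ProveanCall(str, enum.Enum):
    DELETERIOUS = "deleterious"
    NEUTRAL = "neutral"
    MISSING = "missing"


@dataclass(frozen=True)
class PredictorCalls:
    sift: SiftCall = SiftCall.MISSING
    polyphen2: PolyPhenCall = PolyPhenCall.MISSING
    mutation_taster: MutationTasterCall = MutationTasterCall.MISSING
    provean: ProveanCall = ProveanCall.MISSING
    cadd_phred: float | None = None

    def __post_init__(self):
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"cadd_phred must be >= 0, got {self.cadd_phred}")


class AFBand(str, enum.Enum):
    RARE = "rare"            # af < 0.01
    LOW_FREQUENCY = "low_frequency"  # 0.01 <= af < 0.05
    COMMON = "common"        # af >= 0.05


def af_band(af: float | None) -> tuple[AFBand, bool]:
    """Classify a population allele frequency into rare/low/common bands.

    Rare < 1%, low-frequency 1-5%, common >= 5% (half-open, lower-inclusive
    on the upper band).  A missing AF is treated as rare by convention and
    flagged as imputed via the second return value.
    """
    if af is None:
        return AFBand.RARE, True
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele frequency outside [0,1]: {af}")
    if af < 0.01:
        return AFBand.RARE, False
    if af < 0.05:
        return AFBand.LOW_FREQUENCY, False
    return AFBand.COMMON, False


@dataclass
class AnnotatedVariant:
    key: VariantKey
    gene: str = "."
    consequence: Consequence = Consequence.OTHER
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    calls: PredictorCalls = field(default_factory=PredictorCalls)
    population_af: float | None = None
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    # Tumor-tissue genotypes are kept separate and never substitute for
    # germline calls in segregation analysis.
    tumor_genotypes: dict[str, Genotype] = field(default_factory=dict)

    def __post_init__(self):
        if self.population_af is not None and not 0.0 <= self.population_af <= 1.0:
            raise ValueError(f"population_af outside [0,1]: {self.population_af}")

    @property
    def band(self) -> AFBand:
        return af_band(self.population_af)[0]

    @property
    def band_imputed(self) -> bool:
        return af_band(self.population_af)[1]

    def genotype(self, individual_id: str) -> Genotype:
        return self.genotypes.get(individual_id, Genotype.MISSING)

    def carriers(self) -> set[str]:
        return {iid for iid, g in self.genotypes.items() if g.carries_alt}


# ---------------------------------------------------------------------------
# VCF I/O (pysam behind the surface)
# ---------------------------------------------------------------------------

def read_vcf_genotypes(
    path: str | Path, cohort: Cohort, strict: bool = False
) -> list[AnnotatedVariant]:
    """Read genotype maps from a VCF, splitting multiallelic records.

    Each alternate allele of a record yields one :class:`AnnotatedVariant`
    whose genotypes are recoded against that allele (an unrelated alt allele
    counts as reference-like for the allele under consideration).  Samples
    not present in the cohort are skipped with a warning, or raise when
    ``strict`` is set.
    """
    known = {ind.individual_id for ind in cohort.individuals()}
    out: list[AnnotatedVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        unknown = [s for s in samples if s not in known]
        if unknown:
            msg = f"VCF samples absent from cohort: {unknown}"
            if strict:
                raise AnnotationError(msg)
            warnings.warn(msg + " (skipped)", stacklevel=2)
        keep = [s for s in samples if s in known]
        for rec in vcf:
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                genotypes: dict[str, Genotype] = {}
                for sample in keep:
                    alleles = rec.samples[sample]["GT"]
                    if alleles is None or all(a is None for a in alleles):
                        genotypes[sample] = Genotype.MISSING
                        continue
                    dosage = sum(1 for a in alleles if a == alt_index)
                    genotypes[sample] = (
                        Genotype.HOM_ALT
                        if dosage >= 2
                        else Genotype.HET
                        if dosage == 1
                        else Genotype.HOM_REF
                    )
                key = VariantKey(str(rec.chrom), int(rec.pos), str(rec.ref), str(alt)).normalized()
                out.append(AnnotatedVariant(key=key, genotypes=genotypes))
    return out


def write_vcf(
    variants: Iterable[AnnotatedVariant],
    sample_ids: list[str],
    path: str | Path,
) -> Path:
    """Write biallelic records (one per variant) for the given samples."""
    variants = sorted(variants, key=lambda v: (v.key.chrom, v.key.pos, v.key.ref, v.key.alt))
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in sorted({v.key.chrom for v in variants}):
        header.add_line(f"##contig=<ID={chrom}>")
    for sample in sample_ids:
        header.add_sample(sample)
    path = Path(path)
    gt_codes = {
        Genotype.HOM_REF: (0, 0),
        Genotype.HET: (0, 1),
        Genotype.HOM_ALT: (1, 1),
        Genotype.MISSING: (None, None),
    }
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for var in variants:
            rec = vcf.new_record(
                contig=var.key.chrom,
                start=var.key.pos - 1,
                alleles=(var.key.ref, var.key.alt),
            )
            for sample in sample_ids:
                rec.samples[sample]["GT"] = gt_codes[var.genotype(sample)]
            vcf.write(rec)
    return path


# ---------------------------------------------------------------------------
# Annotation table
# ---------------------------------------------------------------------------

#: Documented default code maps for the categorical predictor columns.
#: These follow the dbNSFP one-letter conventions; alternative maps (e.g. a
#: different PolyPhen-2 model) can be supplied via ``code_maps``.
DEFAULT_CODE_MAPS: dict[str, dict[str, enum.Enum]] = {
    "sift": {"D": SiftCall.DELETERIOUS, "T": SiftCall.TOLERATED},
    "polyphen2": {
        "D": PolyPhenCall.PROBABLY_DAMAGING,
        "P": PolyPhenCall.POSSIBLY_DAMAGING,
        "B": PolyPhenCall.BENIGN,
    },
    "mutation_taster": {
        "A": MutationTasterCall.DISEASE_CAUSING_AUTOMATIC,
        "D": MutationTasterCall.DISEASE_CAUSING,
        "N": MutationTasterCall.POLYMORPHISM,
        "P": MutationTasterCall.POLYMORPHISM,
    },
    "provean": {"D": ProveanCall.DELETERIOUS, "N": ProveanCall.NEUTRAL},
}

_MISSING_CALL = {
    "sift": SiftCall.MISSING,
    "polyphen2": PolyPhenCall.MISSING,
    "mutation_taster": MutationTasterCall.MISSING,
    "provean": ProveanCall.MISSING,
}

ANNOTATION_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "consequence",
    "hgvs_c",
    "hgvs_p",
    "sift",
    "polyphen2",
    "mutation_taster",
    "provean",
    "cadd_phred",
    "population_af",
)


@dataclass(frozen=True)
class AnnotationRecord:
    gene: str
    consequence: Consequence
    calls: PredictorCalls
    population_af: float | None
    hgvs_c: str | None = None
    hgvs_p: str | None = None


def _decode_call(column: str, token: str, code_maps, row_label: str):
    if token in (".", "", "NA"):
        return _MISSING_CALL[column]
    mapped = code_maps[column].get(token)
    if mapped is None:
        warnings.warn(
            f"unknown {column} code {token!r} at {row_label}; treated as missing",
            stacklevel=3,
        )
        return _MISSING_CALL[column]
    return mapped


def read_annotation_table(
    path: str | Path,
    code_maps: Mapping[str, Mapping[str, enum.Enum]] | None = None,
) -> dict[VariantKey, AnnotationRecord]:
    """Parse the predictor annotation TSV into normalized records.

    The table must carry the declared header; categorical predictor columns
    use the documented one-letter code maps.  Duplicate variant keys and
    malformed CADD values are errors naming the offending row.
    """
    maps = dict(DEFAULT_CODE_MAPS)
    if code_maps:
        maps.update(code_maps)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise AnnotationError(f"annotation table missing columns: {sorted(missing_cols)}")
    out: dict[VariantKey, AnnotationRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        label = f"{path} row {i}"
        key = VariantKey(row.chrom, int(row.pos), row.ref, row.alt).normalized()
        if key in out:
            raise AnnotationError(f"duplicate variant key {key} at {label}")
        cadd_tok = row.cadd_phred
        if cadd_tok in (".", "", "NA"):
            cadd = None
        else:
            try:
                cadd = float(cadd_tok)
            except ValueError:
                raise AnnotationError(f"malformed CADD value {cadd_tok!r} at {label}") from None
        af_tok = row.population_af
        af = None if af_tok in (".", "", "NA") else float(af_tok)
        calls = PredictorCalls(
            sift=_decode_call("sift", row.sift, maps, label),
            polyphen2=_decode_call("polyphen2", row.polyphen2, maps, label),
            mutation_taster=_decode_call("mutation_taster", row.mutation_taster, maps, label),
            provean=_decode_call("provean", row.provean, maps, label),
            cadd_phred=cadd,
        )
        out[key] = AnnotationRecord(
            gene=row.gene,
            consequence=Consequence(row.consequence),
            calls=calls,
            population_af=af,
            hgvs_c=None if row.hgvs_c == "." else row.hgvs_c,
            hgvs_p=None if row.hgvs_p == "." else row.hgvs_p,
        )
    return out


_CALL_CODE = {
    SiftCall.DELETERIOUS: "D",
    SiftCall.TOLERATED: "T",
    PolyPhenCall.PROBABLY_DAMAGING: "D",
    PolyPhenCall.POSSIBLY_DAMAGING: "P",
    PolyPhenCall.BENIGN: "B",
    MutationTasterCall.DISEASE_CAUSING_AUTOMATIC: "A",
    MutationTasterCall.DISEASE_CAUSING: "D",
    MutationTasterCall.POLYMORPHISM: "N",
    ProveanCall.DELETERIOUS: "D",
    ProveanCall.NEUTRAL: "N",
}


def write_annotation_table(variants: Iterable[AnnotatedVariant], path: str | Path) -> Path:
    """Serialize variant annotations in the documented TSV layout."""
    rows = []
    for v in sorted(variants, key=lambda v: v.key):
        c = v.calls
        rows.append(
            {
                "chrom": v.key.chrom,
                "pos": v.key.pos,
                "ref": v.key.ref,
                "alt": v.key.alt,
                "gene": v.gene,
                "consequence": v.consequence.value,
                "hgvs_c": v.hgvs_c or ".",
                "hgvs_p": v.hgvs_p or ".",
                "sift": _CALL_CODE.get(c.sift, "."),
                "polyphen2": _CALL_CODE.get(c.polyphen2, "."),
                "mutation_taster": _CALL_CODE.get(c.mutation_taster, "."),
                "provean": _CALL_CODE.get(c.provean, "."),
                "cadd_phred": "." if c.cadd_phred is None else format(c.cadd_phred, "g"),
                "population_af": "."
                if v.population_af is None
                else format(v.population_af, "g"),
            }
        )
    df = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def apply_annotations(
    variants: Iterable[AnnotatedVariant],
    table: Mapping[VariantKey, AnnotationRecord],
    drop_unannotated: bool = False,
) -> list[AnnotatedVariant]:
    """Join genotype-bearing variants with annotation records by key."""
    out = []
    for v in variants:
        rec = table.get(v.key.normalized())
        if rec is None:
            if drop_unannotated:
                continue
            out.append(v)
            continue
        out.append(
            replace(
                v,
                gene=rec.gene,
                consequence=rec.consequence,
                calls=rec.calls,
                population_af=rec.population_af,
                hgvs_c=rec.hgvs_c,
                hgvs_p=rec.hgvs_p,
            )
        )
    return out
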