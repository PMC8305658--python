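"""Pedigree data model, PED I/O and family-eligibility queries.

The central objects are :class:`Individual`, :class:`Family` and
:class:`Cohort`.  Families are directed acyclic parent->child graphs;
phenotypes are sets of cancer/precursor tokens so that an individual can be,
say, a breast-cancer case while remaining *unaffected* for the pancreatic
phenotype used in co-segregation analysis.

Two file dialects are supported:

``ped6``
    The classic 6-column linkage format (family, individual, father, mother,
    sex, affection status).  Affection ``2`` is mapped to the PDAC phenotype,
    ``1``/``0`` to unaffected/unknown.

``ped_extended``
    A header-carrying TSV that extends ped6 with phenotype tokens, age,
    age kind, DNA-availability flags, deceased flag and two family-level
    columns (family type, prior predisposition-gene mutation flag).  This is
    the dialect the rest of the package round-trips.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

__all__ = [
    "Sex",
    "Phenotype",
    "AgeKind",
    "FamilyType",
    "Individual",
    "Family",
    "Cohort",
    "PedigreeError",
    "read_pedigree",
    "write_pedigree",
    "first_degree_relatives",
    "meets_fpc_definition",
    "meets_wgs_inclusion",
]

MISSING = "."
MISSING_PARENT = "0"


class PedigreeError(ValueError):
    """Structured pedigree parse/validation error."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix = f"{path}:" + (f"{line}: " if line is not None else " ")
        super().__init__(prefix + message)


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Phenotype(str, enum.Enum):
    PDAC = "PDAC"
    PRECURSOR_HIGH_GRADE = "precursor_high_grade"
    BREAST_CANCER = "breast_cancer"
    MELANOMA = "melanoma"
    LEUKEMIA = "leukemia"
    OTHER_CANCER = "other_cancer"


class AgeKind(str, enum.Enum):
    CURRENT = "current"
    AT_DIAGNOSIS = "at_diagnosis"
    AT_DEATH = "at_death"
    MISSING = "missing"


class FamilyType(str, enum.Enum):
    FPC = "FPC"
    FPC_BREAST = "FPC_breast"
    PCMS = "PCMS"
    OTHER = "other"


@dataclass(frozen=True)
class Individual:
    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    phenotypes: frozenset[Phenotype] = frozenset()
    age_years: float | None = None
    age_kind: AgeKind = AgeKind.MISSING
    has_blood_dna: bool = False
    has_tumor_dna: bool = False
    deceased: bool = False

    @property
    def affected(self) -> bool:
        """Any recorded cancer or high-grade precursor phenotype."""
        return bool(self.phenotypes)

    def has_phenotype(self, targets: Iterable[Phenotype]) -> bool:
        return bool(self.phenotypes & frozenset(targets))


@dataclass
class Family:
    family_id: str
    members: dict[str, Individual] = field(default_factory=dict)
    family_type: FamilyType = FamilyType.FPC
    # Known deleterious BRCA1/2, CDKN2A or PALB2 germline mutation from prior
    # testing.  Carried as an input flag, never computed here.
    known_predisposition_mutation: bool = False

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.members.values())

    def __len__(self) -> int:
        return len(self.members)

    def add(self, individual: Individual) -> None:
        if individual.individual_id in self.members:
            raise PedigreeError(
                f"duplicate individual_id {individual.individual_id!r} in family {self.family_id!r}"
            )
        self.members[individual.individual_id] = individual

    def parents_of(self, individual_id: str) -> tuple[Individual | None, Individual | None]:
        ind = self[individual_id]
        father = self.members.get(ind.father_id) if ind.father_id else None
        mother = self.members.get(ind.mother_id) if ind.mother_id else None
        return father, mother

    def children_of(self, individual_id: str) -> list[Individual]:
        return [
            m
            for m in self.members.values()
            if individual_id in (m.father_id, m.mother_id)
        ]

    def __getitem__(self, individual_id: str) -> Individual:
        try:
            return self.members[individual_id]
        except KeyError:
            raise PedigreeError(
                f"unknown individual {individual_id!r} in family {self.family_id!r}"
            ) from None

    def validate(self) -> None:
        """Enforce structural invariants.

        Parent references must resolve to members (or be missing), fathers
        must be male and mothers female where sex is known, and the
        parent->child graph must be acyclic.
        """
        graph = nx.DiGraph()
        graph.add_nodes_from(self.members)
        for ind in self.members.values():
            for parent_id, want in ((ind.father_id, Sex.MALE), (ind.mother_id, Sex.FEMALE)):
                if parent_id is None:
                    continue
                if parent_id not in self.members:
                    raise PedigreeError(
                        f"individual {ind.individual_id!r} references unknown parent "
                        f"{parent_id!r} in family {self.family_id!r}"
                    )
                parent = self.members[parent_id]
                if parent.sex not in (want, Sex.UNKNOWN):
                    role = "father" if want is Sex.MALE else "mother"
                    raise PedigreeError(
                        f"{role} {parent_id!r} of {ind.individual_id!r} has sex "
                        f"{parent.sex.value} in family {self.family_id!r}"
                    )
                graph.add_edge(parent_id, ind.individual_id)
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise PedigreeError(
                f"cyclic pedigree in family {self.family_id!r}: {cycle}"
            )

    def affected_members(self, targets: Iterable[Phenotype] | None = None) -> list[Individual]:
        if targets is None:
            return [m for m in self.members.values() if m.affected]
        targets = frozenset(targets)
        return [m for m in self.members.values() if m.has_phenotype(targets)]


@dataclass
class Cohort:
    families: dict[str, Family] = field(default_factory=dict)
    label: str = "cohort"

    def __iter__(self) -> Iterator[Family]:
        return iter(self.families.values())

    def __len__(self) -> int:
        return len(self.families)

    def add(self, family: Family) -> None:
        if family.family_id in self.families:
            raise PedigreeError(f"duplicate family_id {family.family_id!r} in cohort")
        self.families[family.family_id] = family

    def individuals(self) -> Iterator[Individual]:
        for fam in self:
            yield from fam

    def find_family_of(self, individual_id: str) -> Family | None:
        for fam in self:
            if individual_id in fam.members:
                return fam
        return None

    def validate(self) -> None:
        seen: dict[str, str] = {}
        for fam in self:
            fam.validate()
            for iid in fam.members:
                if iid in seen:
                    raise PedigreeError(
                        f"individual_id {iid!r} appears in families "
                        f"{seen[iid]!r} and {fam.family_id!r}; ids must be "
                        "unique cohort-wide so VCF samples map unambiguously"
                    )
                seen[iid] = fam.family_id


# ---------------------------------------------------------------------------
# Relationship queries and eligibility filters
# ---------------------------------------------------------------------------

def first_degree_relatives(family: Family, individual_id: str) -> set[str]:
    """Parents, full siblings (both parents shared and known) and children.

    Half-siblings and spouses are excluded; this is the conventional
    clinical-genetics definition of a first-degree relative.
    """
    ind = family[individual_id]
    out: set[str] = set()
    for parent_id in (ind.father_id, ind.mother_id):
        if parent_id is not None and parent_id in family.members:
            out.add(parent_id)
    for other in family:
        if other.individual_id == individual_id:
            continue
        # child
        if individual_id in (other.father_id, other.mother_id):
            out.add(other.individual_id)
            continue
        # full sibling: both parents known and identical
        if (
            ind.father_id is not None
            and ind.mother_id is not None
            and other.father_id == ind.father_id
            and other.mother_id == ind.mother_id
        ):
            out.add(other.individual_id)
    return out


def meets_fpc_definition(family: Family) -> bool:
    """True iff two PDAC-affected members are first-degree relatives.

    This is the defining criterion of familial pancreatic cancer: at least
    two first-degree relatives with confirmed PDAC.
    """
    pdac = [m.individual_id for m in family if Phenotype.PDAC in m.phenotypes]
    pdac_set = set(pdac)
    for iid in pdac:
        if first_degree_relatives(family, iid) & pdac_set:
            return True
    return False


def meets_wgs_inclusion(family: Family) -> tuple[bool, list[str]]:
    """Study-style WGS inclusion check.

    Requires >=3 PDAC-affected members, blood DNA from >=2 affected and
    >=2 unaffected members, and no previously identified deleterious
    BRCA1/2, CDKN2A or PALB2 germline mutation (an input flag).  Returns the
    verdict plus the list of failed criteria.
    """
    reasons: list[str] = []
    n_pdac = sum(1 for m in family if Phenotype.PDAC in m.phenotypes)
    if n_pdac < 3:
        reasons.append("affected_count<3")
    n_aff_dna = sum(1 for m in family if m.affected and m.has_blood_dna)
    if n_aff_dna < 2:
        reasons.append("affected_with_blood_dna<2")
    n_unaff_dna = sum(1 for m in family if not m.affected and m.has_blood_dna)
    if n_unaff_dna < 2:
        reasons.append("unaffected_with_blood_dna<2")
    if family.known_predisposition_mutation:
        reasons.append("known_predisposition_mutation")
    return (not reasons), reasons


# ---------------------------------------------------------------------------
# PED I/O
# ---------------------------------------------------------------------------

EXTENDED_COLUMNS = (
    "family_id",
    "individual_id",
    "father_id",
    "mother_id",
    "sex",
    "phenotypes",
    "age",
    "age_kind",
    "blood_dna",
    "tumor_dna",
    "deceased",
    "family_type",
    "known_mutation",
)

_SEX_CODE = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_SEX_DECODE = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN, ".": Sex.UNKNOWN}


def _decode_bool(token: str) -> bool:
    return token == "1"


def read_pedigree(path: str | Path, dialect: str = "ped_extended", label: str | None = None) -> Cohort:
    """Read a pedigree file into a validated :class:`Cohort`."""
    path = Path(path)
    if dialect not in ("ped6", "ped_extended"):
        raise ValueError(f"unknown PED dialect {dialect!r}")
    cohort = Cohort(label=label or path.stem)
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    start = 0
    if dialect == "ped_extended":
        if not lines or not lines[0].startswith("family_id"):
            raise PedigreeError("ped_extended requires a header line", str(path), 1)
        header = tuple(lines[0].rstrip("\n").split("\t"))
        if header != EXTENDED_COLUMNS:
            raise PedigreeError(
                f"unexpected ped_extended header {header!r}", str(path), 1
            )
        start = 1
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.split("\t") if dialect == "ped_extended" else raw.split()
        try:
            ind, fam_type, known_mut = _parse_row(fields, dialect)
        except (ValueError, KeyError) as exc:
            raise PedigreeError(f"malformed row: {exc}", str(path), lineno) from exc
        fam = cohort.families.get(ind.family_id)
        if fam is None:
            fam = Family(ind.family_id, family_type=fam_type,
                         known_predisposition_mutation=known_mut)
            cohort.add(fam)
        fam.add(ind)
    try:
        cohort.validate()
    except PedigreeError as exc:
        raise PedigreeError(str(exc), str(path)) from exc
    return cohort


def _parse_row(fields: list[str], dialect: str) -> tuple[Individual, FamilyType, bool]:
    if dialect == "ped6":
        if len(fields) < 6:
            raise ValueError(f"expected 6 columns, got {len(fields)}")
        fam_id, iid, fid, mid, sex, status = fields[:6]
        phenos: frozenset[Phenotype] = (
            frozenset({Phenotype.PDAC}) if status == "2" else frozenset()
        )
        ind = Individual(
            individual_id=iid,
            family_id=fam_id,
            father_id=None if fid == MISSING_PARENT else fid,
            mother_id=None if mid == MISSING_PARENT else mid,
            sex=_SEX_DECODE.get(sex, Sex.UNKNOWN),
            phenotypes=phenos,
        )
        return ind, FamilyType.FPC, False
    if len(fields) != len(EXTENDED_COLUMNS):
        raise ValueError(
            f"expected {len(EXTENDED_COLUMNS)} columns, got {len(fields)}"
        )
    row = dict(zip(EXTENDED_COLUMNS, fields))
    phenos = frozenset(
        Phenotype(tok) for tok in row["phenotypes"].split(";") if tok and tok != MISSING
    )
    age = None if row["age"] == MISSING else float(row["age"])
    ind = Individual(
        individual_id=row["individual_id"],
        family_id=row["family_id"],
        father_id=None if row["father_id"] == MISSING_PARENT else row["father_id"],
        mother_id=None if row["mother_id"] == MISSING_PARENT else row["mother_id"],
        sex=_SEX_DECODE[row["sex"]],
        phenotypes=phenos,
        age_years=age,
        age_kind=AgeKind(row["age_kind"]) if row["age_kind"] != MISSING else AgeKind.MISSING,
        has_blood_dna=_decode_bool(row["blood_dna"]),
        has_tumor_dna=_decode_bool(row["tumor_dna"]),
        deceased=_decode_bool(row["deceased"]),
    )
    return ind, FamilyType(row["family_type"]), _decode_bool(row["known_mutation"])


def write_pedigree(cohort: Cohort, path: str | Path, dialect: str = "ped_extended") -> Path:
    """Write a cohort; ``ped_extended`` round-trips losslessly."""
    path = Path(path)
    rows: list[str] = []
    if dialect == "ped_extended":
        rows.append("\t".join(EXTENDED_COLUMNS))
    elif dialect != "ped6":
        raise ValueError(f"unknown PED dialect {dialect!r}")
    for fam in sorted(cohort, key=lambda f: f.family_id):
        for ind in fam.members.values():
            if dialect == "ped6":
                status = "2" if ind.affected else "1"
                rows.append(
                    " ".join(
                        (
                            fam.family_id,
                            ind.individual_id,
                            ind.father_id or MISSING_PARENT,
                            ind.mother_id or MISSING_PARENT,
                            _SEX_CODE[ind.sex],
                            status,
                        )
                    )
                )
            else:
                phenos = ";".join(sorted(p.value for p in ind.phenotypes)) or MISSING
                age = MISSING if ind.age_years is None else format(ind.age_years, "g")
                rows.append(
                    "\t".join(
                        (
                            fam.family_id,
                            ind.individual_id,
                            ind.father_id or MISSING_PARENT,
                            ind.mother_id or MISSING_PARENT,
                            _SEX_CODE[ind.sex],
                            phenos,
                            age,
                            ind.age_kind.value if ind.age_kind is not AgeKind.MISSING else MISSING,
                            "1" if ind.has_blood_dna else "0",
                            "1" if ind.has_tumor_dna else "0",
                            "1" if ind.deceased else "0",
                            fam.family_type.value,
                            "1" if fam.known_predisposition_mutation else "0",
                        )
                    )
                )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path
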