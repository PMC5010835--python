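"""Nuclear-quad pedigree model and PED file I/O.

The prioritization procedure operates on a fixed family topology: two
unaffected parents and two children, exactly one of whom is affected (the
proband).  Every genotype-comparison rule downstream keys off the four roles
defined here, so the loader is strict: anything other than a well-formed quad
is rejected with a named error rather than guessed at.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

ROLES = ("proband", "mother", "father", "sibling")

SEX_CODES = {"1": "male", "2": "female"}
AFFECTION_CODES = {"1": False, "2": True}


class PedigreeError(ValueError):
    """Base class for pedigree validation failures."""


class QuadRequiredError(PedigreeError):
    """The PED file does not describe exactly one quad (4 samples, 1 family)."""


class MultipleProbandsError(PedigreeError):
    """More than one affected child."""


class NoProbandError(PedigreeError):
    """No affected child."""


class MissingParentPointerError(PedigreeError):
    """A child row lacks a valid father/mother pointer."""


class InvalidSexCodeError(PedigreeError):
    """PED sex column is not 1 (male) or 2 (female)."""


class AffectionCodeError(PedigreeError):
    """PED phenotype column is not 1 (unaffected) or 2 (affected).

    0 and -9 (unknown affection) are deliberately rejected: the family filter
    is meaningless when affection status is ambiguous.
    """


class PedigreeInvariantError(PedigreeError):
    """Roles violate the quad invariants (e.g. an affected parent)."""


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    role: str
    sex: str
    affected: bool

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise PedigreeInvariantError("empty sample_id")
        if self.role not in ROLES:
            raise PedigreeInvariantError(f"unknown role {self.role!r}")
        if self.sex not in ("male", "female"):
            raise InvalidSexCodeError(f"unknown sex {self.sex!r}")
        if self.role == "mother" and self.sex != "female":
            raise PedigreeInvariantError("mother must be female")
        if self.role == "father" and self.sex != "male":
            raise PedigreeInvariantError("father must be male")


@dataclass(frozen=True)
class Pedigree:
    """Exactly four members, one per role; proband affected, others not."""

    members: tuple[PedigreeMember, ...]

    def __post_init__(self) -> None:
        if len(self.members) != 4:
            raise QuadRequiredError(
                f"quad required: got {len(self.members)} members"
            )
        roles = [m.role for m in self.members]
        if sorted(roles) != sorted(ROLES):
            raise PedigreeInvariantError(f"roles must be {ROLES}, got {roles}")
        ids = [m.sample_id for m in self.members]
        if len(set(ids)) != 4:
            raise PedigreeInvariantError(f"duplicate sample ids: {ids}")
        if not self.proband.affected:
            raise NoProbandError("proband must be affected")
        for role in ("mother", "father", "sibling"):
            if self.member(role).affected:
                raise PedigreeInvariantError(f"{role} must be unaffected")

    def member(self, role: str) -> PedigreeMember:
        for m in self.members:
            if m.role == role:
                return m
        raise KeyError(role)

    @property
    def proband(self) -> PedigreeMember:
        return self.member("proband")

    @property
    def mother(self) -> PedigreeMember:
        return self.member("mother")

    @property
    def father(self) -> PedigreeMember:
        return self.member("father")

    @property
    def sibling(self) -> PedigreeMember:
        return self.member("sibling")

    def sample_ids(self) -> dict[str, str]:
        """role -> sample_id mapping."""
        return {m.role: m.sample_id for m in self.members}


def _parse_rows(lines: Iterable[str]) -> list[list[str]]:
    rows = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeError(
                f"PED row needs 6 columns, got {len(fields)}: {line!r}"
            )
        rows.append(fields[:6])
    return rows


def load_pedigree(ped_path: str | Path) -> Pedigree:
    """Load a quad from a standard 6-column PED file.

    Roles are inferred from the file structure: rows with parent pointers
    ``0 0`` are founders (mother/father by sex); the affected child is the
    proband and the unaffected child the sibling.
    """
    rows = _parse_rows(Path(ped_path).read_text().splitlines())
    if len(rows) != 4:
        raise QuadRequiredError(f"quad required: PED has {len(rows)} samples")
    families = {r[0] for r in rows}
    if len(families) != 1:
        raise QuadRequiredError(f"quad required: multiple families {families}")

    parsed = []
    for fam, iid, pat, mat, sex, pheno in rows:
        if sex not in SEX_CODES:
            raise InvalidSexCodeError(f"sample {iid}: sex code {sex!r}")
        if pheno not in AFFECTION_CODES:
            raise AffectionCodeError(f"sample {iid}: phenotype code {pheno!r}")
        parsed.append(
            {
                "iid": iid,
                "pat": pat,
                "mat": mat,
                "sex": SEX_CODES[sex],
                "affected": AFFECTION_CODES[pheno],
            }
        )

    founders = [p for p in parsed if p["pat"] == "0" and p["mat"] == "0"]
    children = [p for p in parsed if p not in founders]
    if len(founders) != 2 or len(children) != 2:
        raise MissingParentPointerError(
            f"expected 2 founders and 2 children, got {len(founders)} founders"
        )
    fathers = [p for p in founders if p["sex"] == "male"]
    mothers = [p for p in founders if p["sex"] == "female"]
    if len(fathers) != 1 or len(mothers) != 1:
        raise PedigreeInvariantError("founders must be one male and one female")
    father, mother = fathers[0], mothers[0]
    for c in children:
        if c["pat"] != father["iid"] or c["mat"] != mother["iid"]:
            raise MissingParentPointerError(
                f"child {c['iid']}: parent pointers do not match founders"
            )

    affected_children = [c for c in children if c["affected"]]
    if len(affected_children) > 1:
        raise MultipleProbandsError("multiple probands: two affected children")
    if not affected_children:
        raise NoProbandError("no affected child in PED")
    proband = affected_children[0]
    sibling = next(c for c in children if c is not proband)

    return Pedigree(
        members=(
            PedigreeMember(proband["iid"], "proband", proband["sex"], True),
            PedigreeMember(mother["iid"], "mother", "female", mother["affected"]),
            PedigreeMember(father["iid"], "father", "male", father["affected"]),
            PedigreeMember(sibling["iid"], "sibling", sibling["sex"], sibling["affected"]),
        )
    )


def write_ped(pedigree: Pedigree, ped_path: str | Path, family_id: str = "FAM1") -> None:
    """Write a quad back to 6-column PED (inverse of :func:`load_pedigree`)."""
    sex_out = {"male": "1", "female": "2"}
    aff_out = {False: "1", True: "2"}
    f, m = pedigree.father, pedigree.mother
    lines = []
    for member in (f, m, pedigree.proband, pedigree.sibling):
        pat = "0" if member.role in ("father", "mother") else f.sample_id
        mat = "0" if member.role in ("father", "mother") else m.sample_id
        lines.append(
            "\t".join(
                [
                    family_id,
                    member.sample_id,
                    pat,
                    mat,
                    sex_out[member.sex],
                    aff_out[member.affected],
                ]
            )
        )
    Path(ped_path).write_text("\n".join(lines) + "\n")
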