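"""VCF reading/writing and the normalized genotype model.

Input sites are normalized before any filtering:

* multiallelic records are decomposed into one biallelic record per alternate
  allele, with genotype alleles recoded so the chosen alternate becomes 1 and
  any other alternate becomes missing;
* chromosome labels lose their ``chr`` prefix ("chrX" -> "X", "chrM" -> "MT");
* male calls on the sex chromosomes are forced haploid; a heterozygous male
  X/Y call is biologically invalid (the whole of X is treated as non-PAR) and
  becomes a missing haploid call.

Coordinates are VCF-native: 1-based, fully closed, never converted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from cyvcf2 import VCF

from .pedigree import Pedigree

logger = logging.getLogger("quadprio")

AUTOSOMES = tuple(str(i) for i in range(1, 23))


class VcfError(ValueError):
    """Malformed or unusable VCF input."""


class SampleMissingError(VcfError):
    """A pedigree sample is absent from the VCF header."""


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one biallelic site.

    ``alleles`` is a tuple of allele indices (0 = ref, 1 = alt, None =
    missing), length 2 for diploid calls and 1 for haploid (male X/Y after
    normalization).
    """

    alleles: tuple[Optional[int], ...]
    gq: Optional[int] = None
    dp: Optional[int] = None
    phased: bool = False

    def __post_init__(self) -> None:
        if len(self.alleles) not in (1, 2):
            raise VcfError(f"ploidy must be 1 or 2, got {self.alleles}")
        for a in self.alleles:
            if a not in (0, 1, None):
                raise VcfError(f"allele index must be 0/1/missing, got {a}")

    @property
    def ploidy(self) -> int:
        return len(self.alleles)

    @property
    def is_missing(self) -> bool:
        return any(a is None for a in self.alleles)

    @property
    def is_hom_ref(self) -> bool:
        return not self.is_missing and all(a == 0 for a in self.alleles)

    @property
    def is_het(self) -> bool:
        return self.ploidy == 2 and sorted(self.alleles, key=str) == [0, 1]

    @property
    def is_hom_alt(self) -> bool:
        return not self.is_missing and all(a == 1 for a in self.alleles)

    @property
    def carries_alt(self) -> bool:
        return any(a == 1 for a in self.alleles)

    def gt_string(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join("." if a is None else str(a) for a in self.alleles)


@dataclass(frozen=True)
class VariantRecord:
    """One normalized biallelic site with the four quad members' calls."""

    chrom: str
    pos: int
    ref: str
    alt: str
    calls: Mapping[str, GenotypeCall] = field(default_factory=dict)
    variant_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VcfError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise VcfError(f"ref == alt at {self.chrom}:{self.pos}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


def normalize_chrom(label: str) -> str:
    """Strip a ``chr`` prefix and canonicalize X/Y/MT labels."""
    c = label[3:] if label.lower().startswith("chr") else label
    c = c.upper() if c.lower() in ("x", "y", "m", "mt") else c
    return "MT" if c == "M" else c


_CHROM_ORDER = {c: i for i, c in enumerate(AUTOSOMES + ("X", "Y", "MT"))}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (_CHROM_ORDER.get(chrom, len(_CHROM_ORDER)), chrom)


def record_sort_key(rec: VariantRecord) -> tuple:
    return (*chrom_sort_key(rec.chrom), rec.pos, rec.alt)


def genotype_equal(a: GenotypeCall, b: GenotypeCall) -> bool:
    """Unordered allele-multiset equality; missing never asserts identity."""
    if a.is_missing or b.is_missing:
        return False
    return sorted(a.alleles) == sorted(b.alleles)


def normalize_male_sex_chrom_call(call: GenotypeCall) -> GenotypeCall:
    """Force a male X/Y call to haploid.

    Diploid homozygous calls collapse to one allele; heterozygous or
    part-missing diploid calls are invalid for a male on a non-PAR sex
    chromosome and become missing haploid.
    """
    if call.ploidy == 1:
        return call
    a, b = call.alleles
    allele = a if (a == b and a is not None) else None
    return GenotypeCall(alleles=(allele,), gq=call.gq, dp=call.dp, phased=False)


def _is_symbolic(allele: str) -> bool:
    return any(ch in allele for ch in "<>[]") or allele == "*"


def read_quad_vcf(vcf_path: str | Path, pedigree: Pedigree) -> list[VariantRecord]:
    """Read a multi-sample VCF into normalized biallelic records.

    Returns records sorted by (chrom, pos, alt).  Unsorted input is accepted.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    sample_index: dict[str, int] = {}
    for role, sid in pedigree.sample_ids().items():
        if sid not in samples:
            raise SampleMissingError(f"sample not in VCF: {sid}")
        sample_index[role] = samples.index(sid)

    male_roles = {
        m.role for m in pedigree.members if m.sex == "male"
    }
    female_roles = {m.role for m in pedigree.members if m.sex == "female"}

    records: list[VariantRecord] = []
    n_skipped = 0
    for v in vcf:
        if "GT" not in (v.FORMAT or []):
            raise VcfError(f"GT required at {v.CHROM}:{v.POS}")
        chrom = normalize_chrom(v.CHROM)
        gts = v.genotypes  # per sample: [a0, (a1,) phased]
        gqs = v.format("GQ")
        dps = v.format("DP")
        alts = list(v.ALT)
        for alt_index, alt in enumerate(alts, start=1):
            if _is_symbolic(alt) or _is_symbolic(v.REF):
                n_skipped += 1
                continue
            calls: dict[str, GenotypeCall] = {}
            for role, si in sample_index.items():
                raw = gts[si]
                raw_alleles = raw[:-1]  # last element is the phased flag
                phased = bool(raw[-1])

                def recode(a: int) -> Optional[int]:
                    if a < 0:
                        return None
                    if a == 0:
                        return 0
                    return 1 if a == alt_index else None

                alleles = tuple(recode(a) for a in raw_alleles)
                gq = None
                if gqs is not None:
                    q = float(gqs[si][0]) if gqs.ndim > 1 else float(gqs[si])
                    gq = int(q) if q >= 0 else None
                dp = None
                if dps is not None:
                    d = int(dps[si][0]) if dps.ndim > 1 else int(dps[si])
                    dp = d if d >= 0 else None
                call = GenotypeCall(alleles=alleles, gq=gq, dp=dp, phased=phased)
                if chrom in ("X", "Y") and role in male_roles:
                    call = normalize_male_sex_chrom_call(call)
                elif chrom == "Y" and role in female_roles:
                    call = GenotypeCall(alleles=(None,), gq=gq, dp=dp)
                calls[role] = call
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=v.POS,
                    ref=v.REF,
                    alt=alt,
                    calls=calls,
                    variant_id=v.ID,
                )
            )
    vcf.close()
    if n_skipped:
        logger.warning("skipped %d symbolic/star alleles", n_skipped)
    records.sort(key=record_sort_key)
    return records


VCF_HEADER_LINES = (
    "##fileformat=VCFv4.2",
    *(f"##contig=<ID={c}>" for c in AUTOSOMES + ("X", "Y", "MT")),
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">',
)

# Sample column order used whenever this package writes a VCF itself.
WRITE_ROLE_ORDER = ("father", "mother", "proband", "sibling")


def format_call(call: GenotypeCall) -> str:
    gq = "." if call.gq is None else str(call.gq)
    dp = "." if call.dp is None else str(call.dp)
    return f"{call.gt_string()}:{gq}:{dp}"


def write_quad_vcf(
    vcf_path: str | Path,
    records: Sequence[VariantRecord],
    pedigree: Pedigree,
    extra_header_lines: Sequence[str] = (),
    meta_lines: Sequence[str] | None = None,
) -> None:
    """Write normalized records as a plain-text VCF.

    ``meta_lines`` may carry the original input's ``##`` header lines so the
    filtered output preserves provenance; ``extra_header_lines`` append
    package-specific provenance (no timestamps: output is byte-stable).
    """
    ids = pedigree.sample_ids()
    sample_cols = [ids[r] for r in WRITE_ROLE_ORDER]
    lines: list[str] = []
    if meta_lines is None:
        lines.extend(VCF_HEADER_LINES)
    else:
        lines.extend(l.rstrip("\n") for l in meta_lines if l.startswith("##"))
    lines.extend(extra_header_lines)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(sample_cols)
    )
    for rec in sorted(records, key=record_sort_key):
        row = [
            rec.chrom,
            str(rec.pos),
            rec.variant_id or ".",
            rec.ref,
            rec.alt,
            ".",
            "PASS",
            ".",
            "GT:GQ:DP",
        ]
        row.extend(format_call(rec.calls[r]) for r in WRITE_ROLE_ORDER)
        lines.append("\t".join(row))
    Path(vcf_path).write_text("\n".join(lines) + "\n")
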