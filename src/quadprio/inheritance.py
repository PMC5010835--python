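"""Inheritance-model classification and the rarity rule.

Four Mendelian models are considered for a quad with unaffected parents and
an unaffected sibling:

* dominant de novo — proband heterozygous, everyone else hom-ref.  With both
  parents unaffected, an inherited dominant allele would imply an affected
  carrier parent, so the dominant model reduces to de novo here.
* autosomal recessive — proband hom-alt, both parents het carriers, sibling
  anything but hom-alt.
* compound heterozygous — two or more proband-het variants in one gene with
  opposite, unambiguous parental origins.  Origin is inferred purely from
  parental genotypes (no read-backed phasing): a variant is paternal only if
  the father carries the alternate and the mother is hom-ref, and vice versa;
  if both parents carry it the origin is ambiguous and the variant cannot
  anchor a trans pair.  A trans pair jointly carried by the unaffected
  sibling is excluded — the sibling would be affected too.
* X-linked — on chromosome X with an unaffected carrier mother and a
  hemizygous-reference father; the branch depends on proband sex.

Rarity (population MAF below the threshold; missing MAF counts as rare) is
applied after classification because the compound-het rule is evaluated at
the gene-set level: a set is retained in full if at least one member is rare.

chrY and MT variants support no model and are dropped with a logged notice.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .annotation import AnnotatedVariant
from .pedigree import Pedigree
from .vcf_io import AUTOSOMES, GenotypeCall

logger = logging.getLogger("quadprio")

MODELS = ("autosomal_recessive", "compound_het", "dominant_de_novo", "x_linked")

ORIGINS = ("maternal", "paternal", "both", "de_novo", "ambiguous")


@dataclass(frozen=True)
class RarityRule:
    """MAF threshold; a variant is rare iff maf < max_maf (strictly)."""

    max_maf: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_maf <= 1.0):
            raise ValueError(f"max_maf out of [0,1]: {self.max_maf}")

    def is_rare(self, maf: Optional[float]) -> bool:
        # A variant absent from the reference population cannot exceed the
        # threshold: missing MAF is treated as 0.
        return maf is None or maf < self.max_maf


@dataclass(frozen=True)
class Candidate:
    variant: AnnotatedVariant
    models: frozenset[str]
    parental_origin: str
    compound_partner_keys: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("Candidate requires at least one model")
        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model {m!r}")
        if self.parental_origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.parental_origin!r}")
        if bool(self.compound_partner_keys) != ("compound_het" in self.models):
            raise ValueError("compound partners iff compound_het model")
        if ("dominant_de_novo" in self.models) != (self.parental_origin == "de_novo"):
            raise ValueError("de_novo origin iff dominant_de_novo model")

    @property
    def key(self) -> str:
        return self.variant.key


def _calls(v: AnnotatedVariant) -> dict[str, GenotypeCall]:
    return dict(v.record.calls)


def classify_dominant_de_novo(v: AnnotatedVariant, ped: Pedigree) -> bool:
    """Proband het; mother, father and sibling all hom-ref (autosomes)."""
    if v.record.chrom not in AUTOSOMES:
        raise ValueError(f"autosomal model on {v.record.chrom}")
    c = _calls(v)
    return (
        c["proband"].is_het
        and c["mother"].is_hom_ref
        and c["father"].is_hom_ref
        and c["sibling"].is_hom_ref
    )


def classify_recessive(v: AnnotatedVariant, ped: Pedigree) -> bool:
    """Proband hom-alt from two het carrier parents; sibling not hom-alt."""
    if v.record.chrom not in AUTOSOMES:
        raise ValueError(f"autosomal model on {v.record.chrom}")
    c = _calls(v)
    return (
        c["proband"].is_hom_alt
        and c["mother"].is_het
        and c["father"].is_het
        and not c["sibling"].is_hom_alt
        and not c["sibling"].is_missing
    )


def classify_x_linked(v: AnnotatedVariant, ped: Pedigree) -> bool:
    """X-linked model with carrier mother and hemizygous-reference father.

    Female proband: het, from a het mother; father and a male sibling must be
    hemizygous reference (a carrier male would be affected).  Male proband:
    hemizygous alternate from a het mother; a female sibling may carry but
    not be hom-alt.
    """
    if v.record.chrom != "X":
        raise ValueError(f"x_linked model on {v.record.chrom}")
    c = _calls(v)
    mother_ok = c["mother"].is_het
    father_ok = c["father"].alleles == (0,)
    sib = c["sibling"]
    if ped.sibling.sex == "male":
        sibling_ok = sib.alleles == (0,)
    else:
        sibling_ok = not sib.is_hom_alt and not sib.is_missing
    if ped.proband.sex == "female":
        proband_ok = c["proband"].is_het
    else:
        proband_ok = c["proband"].alleles == (1,)
    return proband_ok and mother_ok and father_ok and sibling_ok


def parental_origin(v: AnnotatedVariant) -> str:
    """Infer which parent transmitted the alternate allele (unphased).

    paternal/maternal require the other parent to be hom-ref; both parents
    carrying makes the origin ambiguous; neither carrying is de novo.
    """
    c = _calls(v)
    pat = c["father"].carries_alt
    mat = c["mother"].carries_alt
    if pat and not mat and c["mother"].is_hom_ref:
        return "paternal"
    if mat and not pat and c["father"].is_hom_ref:
        return "maternal"
    if pat and mat:
        return "ambiguous"
    return "de_novo"


def find_compound_het(
    gene_variants: Sequence[AnnotatedVariant], ped: Pedigree
) -> list[Candidate]:
    """Detect unphased trans configurations within one gene.

    A gene yields candidates iff it holds at least one unambiguously paternal
    and one unambiguously maternal proband-het variant, and at least one such
    trans pair is not jointly carried by the unaffected sibling.  Partner
    keys record the opposite-origin variants that form a surviving pair.
    Input order never matters; output is sorted by variant key.
    """
    by_origin: dict[str, list[AnnotatedVariant]] = {"paternal": [], "maternal": []}
    for v in gene_variants:
        if v.record.chrom not in AUTOSOMES:
            raise ValueError(f"compound-het model on {v.record.chrom}")
        if not v.record.calls["proband"].is_het:
            continue
        origin = parental_origin(v)
        if origin in by_origin:
            by_origin[origin].append(v)

    def sib_carries(v: AnnotatedVariant) -> bool:
        return v.record.calls["sibling"].carries_alt

    partners: dict[str, set[str]] = defaultdict(set)
    variants_by_key = {}
    for p in by_origin["paternal"]:
        for m in by_origin["maternal"]:
            if sib_carries(p) and sib_carries(m):
                continue  # the unaffected sibling carries this trans pair
            partners[p.key].add(m.key)
            partners[m.key].add(p.key)
            variants_by_key[p.key] = p
            variants_by_key[m.key] = m

    out = []
    for key in sorted(partners):
        v = variants_by_key[key]
        out.append(
            Candidate(
                variant=v,
                models=frozenset({"compound_het"}),
                parental_origin=parental_origin(v),
                compound_partner_keys=frozenset(partners[key]),
            )
        )
    return out


def classify_all(
    variants: Sequence[AnnotatedVariant], ped: Pedigree
) -> list[Candidate]:
    """Run every model classifier over family-filter survivors.

    Returns one Candidate per variant that supports at least one model;
    variants supporting several models carry the union.
    """
    candidates: dict[str, Candidate] = {}
    n_excluded = 0

    for v in variants:
        chrom = v.record.chrom
        if chrom in ("Y", "MT"):
            n_excluded += 1
            continue
        models = set()
        if chrom in AUTOSOMES:
            if classify_dominant_de_novo(v, ped):
                models.add("dominant_de_novo")
            if classify_recessive(v, ped):
                models.add("autosomal_recessive")
        elif chrom == "X":
            if classify_x_linked(v, ped):
                models.add("x_linked")
        else:
            n_excluded += 1
            continue
        if models:
            origin = "de_novo" if "dominant_de_novo" in models else (
                "both" if "autosomal_recessive" in models else "maternal"
            )
            candidates[v.key] = Candidate(
                variant=v, models=frozenset(models), parental_origin=origin
            )

    by_gene: dict[str, list[AnnotatedVariant]] = defaultdict(list)
    for v in variants:
        if v.record.chrom in AUTOSOMES and v.annotation.gene is not None:
            by_gene[v.annotation.gene].append(v)
    for gene in sorted(by_gene):
        for ch in find_compound_het(by_gene[gene], ped):
            prev = candidates.get(ch.key)
            if prev is None:
                candidates[ch.key] = ch
            else:
                # merge: a single-site model and a compound role can coexist
                candidates[ch.key] = Candidate(
                    variant=ch.variant,
                    models=prev.models | ch.models,
                    parental_origin=prev.parental_origin
                    if prev.parental_origin == "de_novo"
                    else ch.parental_origin,
                    compound_partner_keys=ch.compound_partner_keys,
                )

    if n_excluded:
        logger.info("%d chrY/MT/other variants excluded from all models", n_excluded)
    return [candidates[k] for k in sorted(candidates)]


def apply_rarity(
    candidates: Sequence[Candidate], rule: RarityRule
) -> list[Candidate]:
    """Apply the MAF threshold, with the gene-set relaxation for compound
    hets: a compound gene set is kept in full iff at least one member is
    rare.  Mixed-model candidates survive if any of their models survives,
    and keep only the surviving models.
    """
    compound_by_gene: dict[Optional[str], list[Candidate]] = defaultdict(list)
    for c in candidates:
        if "compound_het" in c.models:
            compound_by_gene[c.variant.annotation.gene].append(c)
    gene_rescued = {
        gene: any(rule.is_rare(c.variant.annotation.maf) for c in members)
        for gene, members in compound_by_gene.items()
    }

    out: list[Candidate] = []
    for c in candidates:
        surviving = set()
        for m in c.models:
            if m == "compound_het":
                if gene_rescued[c.variant.annotation.gene]:
                    surviving.add(m)
            elif rule.is_rare(c.variant.annotation.maf):
                surviving.add(m)
        if not surviving:
            continue
        if surviving == c.models:
            out.append(c)
        else:
            origin = c.parental_origin
            if "dominant_de_novo" not in surviving and origin == "de_novo":
                origin = "ambiguous"
            out.append(
                replace(
                    c,
                    models=frozenset(surviving),
                    parental_origin=origin,
                    compound_partner_keys=c.compound_partner_keys
                    if "compound_het" in surviving
                    else frozenset(),
                )
            )
    return out
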