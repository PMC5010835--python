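"""Pre-model filtering cascade: quality, functional class, family genotype,
and muscle-gene restriction.

Each stage returns a verdict with at most one machine-readable failure
reason (the first failing check short-circuits), so summed failures plus
passes always reconcile with the stage's input count.

Quality is enforced per sample over all four quad members, not proband-only:
inheritance-model inference compares every member's genotype, so a single
low-confidence call invalidates the comparison.  Boundary semantics are
inclusive — GQ exactly at the minimum and DP exactly at the minimum pass;
only strictly lower values are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .annotation import AnnotatedVariant
from .pedigree import Pedigree
from .vcf_io import genotype_equal

KEPT_FUNCTIONAL_CLASSES = frozenset({"nonsynonymous", "stopgain", "stoploss"})

# Fixed order in which member calls are checked, so failure reasons are
# deterministic when several members fail.
ROLE_CHECK_ORDER = ("proband", "mother", "father", "sibling")


class ConfigError(ValueError):
    """Invalid run configuration (e.g. an empty gene list)."""


@dataclass(frozen=True)
class QualityThresholds:
    """Genotype-confidence cutoffs (Phred GQ and read depth)."""

    min_gq: int = 50
    min_dp: int = 7

    def __post_init__(self) -> None:
        if self.min_gq < 0 or self.min_dp < 0:
            raise ConfigError("quality thresholds must be >= 0")


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    stage: str
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        assert self.passed == (self.reason is None)


def _pass(stage: str) -> FilterVerdict:
    return FilterVerdict(True, stage)


def _fail(stage: str, reason: str) -> FilterVerdict:
    return FilterVerdict(False, stage, reason)


def quality_filter(v: AnnotatedVariant, t: QualityThresholds) -> FilterVerdict:
    """Pass iff every member has a called genotype with GQ and DP at or above
    the thresholds."""
    for role in ROLE_CHECK_ORDER:
        call = v.record.calls[role]
        if call.is_missing:
            return _fail("quality", f"missing-genotype:{role}")
        if call.gq is None or call.dp is None:
            return _fail("quality", f"missing-quality:{role}")
        if call.gq < t.min_gq or call.dp < t.min_dp:
            return _fail("quality", f"quality:{role}")
    return _pass("quality")


def functional_filter(v: AnnotatedVariant) -> FilterVerdict:
    """Keep protein-changing classes only (nonsynonymous / stopgain /
    stoploss); unknown is conservatively discarded."""
    fc = v.annotation.functional_class
    if fc in KEPT_FUNCTIONAL_CLASSES:
        return _pass("functional")
    return _fail("functional", f"class:{fc}")


def family_genotype_filter(v: AnnotatedVariant, ped: Pedigree) -> FilterVerdict:
    """Discard variants whose proband genotype is hom-ref, identical to the
    sibling, or identical to both parents.

    Precondition: quality filter passed, so no member call is missing.
    """
    calls = v.record.calls
    p = calls["proband"]
    if p.is_hom_ref:
        return _fail("family", "hom-ref")
    if genotype_equal(p, calls["sibling"]):
        return _fail("family", "shared-with-sibling")
    if genotype_equal(p, calls["mother"]) and genotype_equal(p, calls["father"]):
        return _fail("family", "shared-with-parents")
    return _pass("family")


def muscle_gene_filter(v: AnnotatedVariant, gene_list: frozenset[str]) -> FilterVerdict:
    """Keep variants in genes from the (case-insensitive) muscle gene list."""
    if not gene_list:
        raise ConfigError("muscle gene list is empty")
    gene = v.annotation.gene
    if gene is None:
        return _fail("muscle_gene", "no-gene")
    if gene.upper() in gene_list:
        return _pass("muscle_gene")
    return _fail("muscle_gene", "not-in-gene-list")


def load_gene_list(path: str | Path) -> frozenset[str]:
    """Load a plain-text gene list (one symbol per line, case-insensitive)."""
    genes = {
        line.strip().upper()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    if not genes:
        raise ConfigError(f"muscle gene list {path} is empty")
    return frozenset(genes)


@dataclass(frozen=True)
class TraceRow:
    """Per-variant audit row: the stage at which it failed, if any."""

    key: str
    stage: str
    passed: bool
    reason: str

    def to_tsv(self) -> str:
        verdict = "pass" if self.passed else "fail"
        return f"{self.key}\t{self.stage}\t{verdict}\t{self.reason}"
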