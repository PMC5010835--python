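"""Per-variant annotation from a tab-separated table.

The table is the pipeline's stand-in for an annotator's output: one row per
(chrom, pos, ref, alt) carrying the gene symbol, a functional class from a
closed vocabulary, and a 1000-Genomes-style population frequency of the
alternate allele.  HGVS strings and the deleteriousness flag are carried as
opaque payload and never parsed.

MAF semantics: the frequency is that of the variant's alternate (derivative)
allele; no minor/major folding is performed.  A missing MAF means the variant
is absent from the reference population and is treated downstream as rare.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .vcf_io import VariantRecord, normalize_chrom

logger = logging.getLogger("quadprio")

FUNCTIONAL_CLASSES = frozenset(
    {
        "intergenic",
        "intronic",
        "synonymous",
        "nonsynonymous",
        "stopgain",
        "stoploss",
        "splicing",
        "other_exonic",
        "unknown",
    }
)

REQUIRED_COLUMNS = ("chrom", "pos", "ref", "alt", "gene", "functional_class", "maf_1kg")
OPTIONAL_COLUMNS = ("hgvs_c", "hgvs_p", "predicted_deleterious")

AnnotationKey = tuple[str, int, str, str]


class AnnotationError(ValueError):
    """Malformed annotation table."""


@dataclass(frozen=True)
class VariantAnnotation:
    gene: Optional[str]
    functional_class: str
    maf: Optional[float] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    predicted_deleterious: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise AnnotationError(
                f"unknown functional_class {self.functional_class!r}"
            )
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise AnnotationError(f"maf out of [0,1]: {self.maf}")


UNANNOTATED = VariantAnnotation(gene=None, functional_class="unknown")


@dataclass(frozen=True)
class AnnotatedVariant:
    record: VariantRecord
    annotation: VariantAnnotation

    @property
    def key(self) -> str:
        return self.record.key


def _missing(cell: str) -> bool:
    return cell in ("", ".")


def _parse_maf(cell: str) -> Optional[float]:
    if _missing(cell):
        return None
    try:
        maf = float(cell)
    except ValueError as exc:
        raise AnnotationError(f"malformed maf {cell!r}") from exc
    if not (0.0 <= maf <= 1.0):
        raise AnnotationError(f"maf out of [0,1]: {cell!r}")
    return maf


_TRUTHY = {"1", "true", "t", "yes", "y", "d", "deleterious"}
_FALSY = {"0", "false", "f", "no", "n", "b", "benign", "tolerated"}


def _parse_deleterious(cell: str) -> Optional[bool]:
    if _missing(cell):
        return None
    low = cell.lower()
    if low in _TRUTHY:
        return True
    if low in _FALSY:
        return False
    raise AnnotationError(f"malformed predicted_deleterious {cell!r}")


def load_annotation_table(tsv_path: str | Path) -> dict[AnnotationKey, VariantAnnotation]:
    """Load the annotation TSV into a (chrom, pos, ref, alt)-keyed lookup.

    Chromosome labels are normalized the same way as VCF records, so a table
    keyed on "chr10" matches records on "10".  Duplicate keys are an error.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise AnnotationError(f"annotation table missing column {col!r}")
    lookup: dict[AnnotationKey, VariantAnnotation] = {}
    for row in df.itertuples(index=False):
        key: AnnotationKey = (
            normalize_chrom(row.chrom),
            int(row.pos),
            row.ref,
            row.alt,
        )
        if key in lookup:
            raise AnnotationError(f"duplicate annotation key {key}")
        fc = row.functional_class
        if fc not in FUNCTIONAL_CLASSES:
            raise AnnotationError(f"unknown functional_class token {fc!r}")
        get = lambda col: getattr(row, col, ".")
        lookup[key] = VariantAnnotation(
            gene=None if _missing(row.gene) else row.gene,
            functional_class=fc,
            maf=_parse_maf(row.maf_1kg),
            hgvs_c=None if _missing(get("hgvs_c")) else get("hgvs_c"),
            hgvs_p=None if _missing(get("hgvs_p")) else get("hgvs_p"),
            predicted_deleterious=_parse_deleterious(get("predicted_deleterious")),
        )
    return lookup


def annotate(
    records: Sequence[VariantRecord],
    lookup: dict[AnnotationKey, VariantAnnotation],
) -> list[AnnotatedVariant]:
    """Attach annotations to records; unmatched records become ``unknown``.

    Never drops or duplicates records: output length equals input length.
    """
    out: list[AnnotatedVariant] = []
    n_unannotated = 0
    for rec in records:
        ann = lookup.get((rec.chrom, rec.pos, rec.ref, rec.alt))
        if ann is None:
            ann = UNANNOTATED
            n_unannotated += 1
        out.append(AnnotatedVariant(record=rec, annotation=ann))
    if n_unannotated:
        logger.info("%d records had no annotation row", n_unannotated)
    return out
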