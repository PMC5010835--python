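"""End-to-end orchestration: quality -> functional -> family -> model
classification -> rarity -> muscle genes, plus report serialization and the
simulation recovery harness.

The cascade order follows the narrative of the prioritization procedure;
rarity runs after model assignment because the compound-het rarity rule is
evaluated per gene set, which requires the model labels.  The final
candidate set is order-independent between the rarity and gene stages (both
are per-candidate predicates), but intermediate stage counts reflect this
fixed order.

`prioritize` is deterministic: two runs on identical inputs produce
byte-identical report, trace and VCF outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from . import __version__ as _version
from .annotation import AnnotatedVariant, annotate, load_annotation_table
from .filters import (
    ConfigError,
    FilterVerdict,
    QualityThresholds,
    TraceRow,
    family_genotype_filter,
    functional_filter,
    load_gene_list,
    muscle_gene_filter,
    quality_filter,
)
from .inheritance import Candidate, RarityRule, apply_rarity, classify_all
from .pedigree import Pedigree, load_pedigree
from .simulate import TruthRow
from .vcf_io import read_quad_vcf, record_sort_key, write_quad_vcf

logger = logging.getLogger("quadprio")

STAGES = ("quality", "functional", "family", "model", "rarity", "muscle_gene")

REPORT_COLUMNS = (
    "key",
    "rsid",
    "gene",
    "functional_class",
    "hgvs_c",
    "hgvs_p",
    "maf",
    "models",
    "parental_origin",
    "compound_partners",
    "gt_proband",
    "gt_mother",
    "gt_father",
    "gt_sibling",
)


@dataclass(frozen=True)
class RunConfig:
    vcf: Path
    ped: Path
    annotations: Path
    genes: Path
    out_dir: Path
    thresholds: QualityThresholds = QualityThresholds()
    rarity: RarityRule = RarityRule()
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, config_path: str | Path, **overrides) -> "RunConfig":
        """Build a config from a JSON file; keyword overrides win."""
        raw = json.loads(Path(config_path).read_text())
        merged = {**raw, **{k: v for k, v in overrides.items() if v is not None}}
        return cls.build(**merged)

    @classmethod
    def build(
        cls,
        vcf,
        ped,
        annotations,
        genes,
        out_dir,
        min_gq: int = 50,
        min_dp: int = 7,
        max_maf: float = 0.01,
        log_level: str = "INFO",
    ) -> "RunConfig":
        return cls(
            vcf=Path(vcf),
            ped=Path(ped),
            annotations=Path(annotations),
            genes=Path(genes),
            out_dir=Path(out_dir),
            thresholds=QualityThresholds(min_gq=int(min_gq), min_dp=int(min_dp)),
            rarity=RarityRule(max_maf=float(max_maf)),
            log_level=log_level,
        )

    def validate(self) -> None:
        for p in (self.vcf, self.ped, self.annotations, self.genes):
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")


@dataclass(frozen=True)
class StageCount:
    stage: str
    entered: int
    passed: int
    fail_reasons: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.entered != self.passed + sum(self.fail_reasons.values()):
            raise ValueError(f"stage {self.stage}: count conservation violated")


@dataclass(frozen=True)
class ReportRow:
    key: str
    rsid: Optional[str]
    gene: Optional[str]
    functional_class: str
    hgvs_c: Optional[str]
    hgvs_p: Optional[str]
    maf: Optional[float]
    models: tuple[str, ...]
    parental_origin: str
    compound_partners: tuple[str, ...]
    genotypes: dict[str, str]

    def to_tsv(self) -> str:
        dot = lambda v: "." if v in (None, (), "") else v
        return "\t".join(
            str(x)
            for x in (
                self.key,
                dot(self.rsid),
                dot(self.gene),
                self.functional_class,
                dot(self.hgvs_c),
                dot(self.hgvs_p),
                "." if self.maf is None else format(self.maf, "g"),
                ",".join(self.models),
                self.parental_origin,
                dot(",".join(self.compound_partners)),
                self.genotypes["proband"],
                self.genotypes["mother"],
                self.genotypes["father"],
                self.genotypes["sibling"],
            )
        )


@dataclass
class CandidateReport:
    rows: list[ReportRow]
    summary: list[StageCount]
    trace: list[TraceRow] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = [f"# quadprio candidate report v1 (quadprio {_version})"]
        for s in self.summary:
            reasons = ";".join(f"{r}={n}" for r, n in sorted(s.fail_reasons.items()))
            lines.append(
                f"# stage\t{s.stage}\tentered={s.entered}\tpassed={s.passed}\t{reasons or '-'}"
            )
        lines.append("\t".join(REPORT_COLUMNS))
        lines.extend(row.to_tsv() for row in self.rows)
        return "\n".join(lines) + "\n"


def _candidate_to_row(c: Candidate) -> ReportRow:
    v = c.variant
    return ReportRow(
        key=v.key,
        rsid=v.record.variant_id,
        gene=v.annotation.gene,
        functional_class=v.annotation.functional_class,
        hgvs_c=v.annotation.hgvs_c,
        hgvs_p=v.annotation.hgvs_p,
        maf=v.annotation.maf,
        models=tuple(sorted(c.models)),
        parental_origin=c.parental_origin,
        compound_partners=tuple(sorted(c.compound_partner_keys)),
        genotypes={r: v.record.calls[r].gt_string() for r in ("proband", "mother", "father", "sibling")},
    )


def _run_stage(
    stage: str,
    variants: Sequence[AnnotatedVariant],
    verdict_fn,
    trace: list[TraceRow],
) -> tuple[list[AnnotatedVariant], StageCount]:
    survivors: list[AnnotatedVariant] = []
    reasons: dict[str, int] = {}
    for v in variants:
        verdict: FilterVerdict = verdict_fn(v)
        trace.append(TraceRow(v.key, stage, verdict.passed, verdict.reason or "-"))
        if verdict.passed:
            survivors.append(v)
        else:
            reasons[verdict.reason] = reasons.get(verdict.reason, 0) + 1
    return survivors, StageCount(stage, len(variants), len(survivors), reasons)


def prioritize(config: RunConfig) -> CandidateReport:
    """Run the full prioritization cascade and write report, trace and
    filtered-candidate VCF under ``config.out_dir``."""
    config.validate()
    pedigree = load_pedigree(config.ped)
    gene_list = load_gene_list(config.genes)
    records = read_quad_vcf(config.vcf, pedigree)
    lookup = load_annotation_table(config.annotations)
    variants = annotate(records, lookup)
    logger.info("loaded %d normalized biallelic records", len(variants))

    trace: list[TraceRow] = []
    summary: list[StageCount] = []

    variants, count = _run_stage(
        "quality", variants, lambda v: quality_filter(v, config.thresholds), trace
    )
    summary.append(count)
    variants, count = _run_stage("functional", variants, functional_filter, trace)
    summary.append(count)
    variants, count = _run_stage(
        "family", variants, lambda v: family_genotype_filter(v, pedigree), trace
    )
    summary.append(count)

    candidates = classify_all(variants, pedigree)
    classified_keys = {c.key for c in candidates}
    model_reasons: dict[str, int] = {}
    for v in variants:
        ok = v.key in classified_keys
        trace.append(TraceRow(v.key, "model", ok, "-" if ok else "no-model"))
        if not ok:
            model_reasons["no-model"] = model_reasons.get("no-model", 0) + 1
    summary.append(StageCount("model", len(variants), len(candidates), model_reasons))

    rare = apply_rarity(candidates, config.rarity)
    rare_keys = {c.key for c in rare}
    rarity_reasons: dict[str, int] = {}
    for c in candidates:
        ok = c.key in rare_keys
        trace.append(TraceRow(c.key, "rarity", ok, "-" if ok else "common"))
        if not ok:
            rarity_reasons["common"] = rarity_reasons.get("common", 0) + 1
    summary.append(StageCount("rarity", len(candidates), len(rare), rarity_reasons))

    final: list[Candidate] = []
    muscle_reasons: dict[str, int] = {}
    for c in rare:
        verdict = muscle_gene_filter(c.variant, gene_list)
        trace.append(TraceRow(c.key, "muscle_gene", verdict.passed, verdict.reason or "-"))
        if verdict.passed:
            final.append(c)
        else:
            muscle_reasons[verdict.reason] = muscle_reasons.get(verdict.reason, 0) + 1
    summary.append(StageCount("muscle_gene", len(rare), len(final), muscle_reasons))

    final.sort(key=lambda c: record_sort_key(c.variant.record))
    report = CandidateReport(
        rows=[_candidate_to_row(c) for c in final], summary=summary, trace=trace
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.tsv").write_text(report.to_tsv())
    trace_lines = ["key\tstage\tverdict\treason"]
    trace_lines.extend(t.to_tsv() for t in trace)
    (out / "filter_trace.tsv").write_text("\n".join(trace_lines) + "\n")
    provenance = (
        f"##quadprio_version={_version}",
        f"##quadprio_filters=min_gq={config.thresholds.min_gq},"
        f"min_dp={config.thresholds.min_dp},max_maf={config.rarity.max_maf}",
    )
    write_quad_vcf(
        out / "candidates.vcf",
        [c.variant.record for c in final],
        pedigree,
        extra_header_lines=provenance,
    )
    logger.info("%d candidates written to %s", len(final), out / "report.tsv")
    return report


def load_report(report_path: str | Path) -> CandidateReport:
    """Parse a report TSV back into rows (summary comments are skipped)."""
    rows: list[ReportRow] = []
    lines = Path(report_path).read_text().splitlines()
    body = [l for l in lines if not l.startswith("#")]
    for line in body[1:]:
        f = line.split("\t")
        undot = lambda v: None if v == "." else v
        rows.append(
            ReportRow(
                key=f[0],
                rsid=undot(f[1]),
                gene=undot(f[2]),
                functional_class=f[3],
                hgvs_c=undot(f[4]),
                hgvs_p=undot(f[5]),
                maf=None if f[6] == "." else float(f[6]),
                models=tuple(f[7].split(",")),
                parental_origin=f[8],
                compound_partners=tuple(f[9].split(",")) if f[9] != "." else (),
                genotypes={
                    "proband": f[10],
                    "mother": f[11],
                    "father": f[12],
                    "sibling": f[13],
                },
            )
        )
    return CandidateReport(rows=rows, summary=[])


@dataclass(frozen=True)
class ModelRecovery:
    n_planted: int
    n_recovered: int
    false_positives: int

    @property
    def sensitivity(self) -> float:
        return self.n_recovered / self.n_planted if self.n_planted else float("nan")


@dataclass(frozen=True)
class RecoveryMetrics:
    per_model: dict[str, ModelRecovery]

    def overall_sensitivity(self) -> float:
        planted = sum(m.n_planted for m in self.per_model.values())
        recovered = sum(m.n_recovered for m in self.per_model.values())
        return recovered / planted if planted else float("nan")

    def total_false_positives(self) -> int:
        return sum(m.false_positives for m in self.per_model.values())


def evaluate_recovery(
    report: CandidateReport, truth: Sequence[TruthRow]
) -> RecoveryMetrics:
    """Score a report against planted simulation truth.

    Sensitivity per model counts planted variants recovered *with the
    correct model label*; false positives per model count reported
    candidates labeled with that model but not planted under it.
    """
    planted_by_model: dict[str, set[str]] = {}
    for row in truth:
        planted_by_model.setdefault(row.model, set()).add(row.key)

    reported_by_model: dict[str, set[str]] = {}
    for row in report.rows:
        for m in row.models:
            reported_by_model.setdefault(m, set()).add(row.key)

    per_model: dict[str, ModelRecovery] = {}
    for model in sorted(set(planted_by_model) | set(reported_by_model)):
        planted = planted_by_model.get(model, set())
        reported = reported_by_model.get(model, set())
        per_model[model] = ModelRecovery(
            n_planted=len(planted),
            n_recovered=len(planted & reported),
            false_positives=len(reported - planted),
        )
    return RecoveryMetrics(per_model=per_model)
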