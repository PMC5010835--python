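"""Synthetic quad-exome generator with known ground truth.

Emulates the statistical structure the prioritization assumes: biallelic
SNVs on autosomes and chrX; parental genotypes at Hardy-Weinberg equilibrium
for a site-specific alternate-allele frequency; Mendelian transmission to a
female proband and a male sibling; male X hemizygosity; per-genotype
genotyping error and missingness; Poisson read depth; and planted variants
in the defining configuration of each inheritance model.

Sites are simulated independently — no linkage, no recombination map — so
compound-het trans configurations are planted explicitly rather than arising
from haplotypes.  GQ is a two-level caricature: ``gq_high`` for calls left
at their generated value and ``gq_low`` for calls perturbed by the error
process, which is enough to exercise the quality cutoff.

The error process redraws a genotype uniformly from the legal genotype space
*including the true genotype*, so the realized discordance is below the
nominal rate ε: for a k-genotype space the effective rate is ε·(k−1)/k
(k = 3 for diploid calls, 2 for male hemizygous X).
:func:`expected_discordance` computes the dataset-weighted value.

Defaults mirror a small exome study design on a quad: ~46x mean depth,
sub-percent genotyping error, and a handful of planted variants per model on
a background of independent polymorphic sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .pedigree import Pedigree, PedigreeMember, write_ped
from .vcf_io import (
    GenotypeCall,
    VariantRecord,
    record_sort_key,
    write_quad_vcf,
)

# Default sample ids for simulated quads (roles are inferred from the PED).
SAMPLE_IDS = {
    "father": "FATHER",
    "mother": "MOTHER",
    "proband": "PROBAND",
    "sibling": "BROTHER",
}

#: Well-known skeletal/cardiac-muscle genes used to pad emitted gene lists.
MUSCLE_GENE_PADDING = ("DES", "CRYAB", "MYOT", "LDB3", "FLNC", "TTN", "MYH10")

DIPLOID_SPACE = ((0, 0), (0, 1), (1, 1))
HAPLOID_SPACE = ((0,), (1,))


def default_quad_pedigree() -> Pedigree:
    """Female affected proband, male unaffected sibling, unaffected parents."""
    return Pedigree(
        members=(
            PedigreeMember(SAMPLE_IDS["proband"], "proband", "female", True),
            PedigreeMember(SAMPLE_IDS["mother"], "mother", "female", False),
            PedigreeMember(SAMPLE_IDS["father"], "father", "male", False),
            PedigreeMember(SAMPLE_IDS["sibling"], "sibling", "male", False),
        )
    )


@dataclass(frozen=True)
class SimulationParams:
    n_background_sites: int = 1000
    #: fixed per-site alternate-allele frequencies; if None, drawn from a
    #: Beta(maf_alpha, maf_beta) clipped to [1e-3, 0.5] (a rare-skewed site
    #: frequency spectrum).
    site_mafs: Optional[Sequence[float]] = None
    maf_alpha: float = 0.8
    maf_beta: float = 4.0
    planted: dict[str, int] = field(
        default_factory=lambda: {
            "dominant_de_novo": 1,
            "autosomal_recessive": 1,
            "compound_het": 1,  # number of compound genes (2 sites each)
            "x_linked": 1,
        }
    )
    genotype_error_rate: float = 0.005
    missing_rate: float = 0.01
    mean_depth: float = 46.0
    gq_high: int = 99
    gq_low: int = 30
    x_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genotype_error_rate", "missing_rate", "x_fraction"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} out of [0,1]: {p}")
        if self.n_background_sites < 0 or any(n < 0 for n in self.planted.values()):
            raise ValueError("counts must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one planted variant."""

    key: str
    gene: str
    model: str
    genotypes: dict[str, str]  # role -> pre-error GT string
    maf: Optional[float]


@dataclass
class SimulatedDataset:
    vcf: Path
    ped: Path
    annotations: Path
    genes: Path
    truth: Path
    truth_rows: list[TruthRow]
    #: pre-error, pre-missingness genotypes for every emitted site
    true_genotypes: dict[str, dict[str, tuple[int, ...]]]
    params: SimulationParams


def mendelian_transmit(
    mother_call: GenotypeCall,
    father_call: GenotypeCall,
    chrom: str,
    child_sex: str,
    rng: np.random.Generator,
) -> GenotypeCall:
    """Draw a child's genotype from the parents under Mendelian segregation.

    Autosomes: one uniformly chosen allele from each parent.  chrX: a
    daughter receives the father's single X allele plus one maternal allele;
    a son receives one maternal allele only (haploid).
    """
    if mother_call.is_missing or father_call.is_missing:
        raise ValueError("parental calls must be non-missing")
    maternal = mother_call.alleles[int(rng.integers(0, 2))]
    if chrom == "X":
        if father_call.ploidy != 1:
            raise ValueError("male X calls must be haploid")
        if child_sex == "female":
            return GenotypeCall(alleles=tuple(sorted((father_call.alleles[0], maternal))))
        return GenotypeCall(alleles=(maternal,))
    paternal = father_call.alleles[int(rng.integers(0, 2))]
    return GenotypeCall(alleles=tuple(sorted((maternal, paternal))))


def _hwe_parent_calls(
    maf: float, chrom: str, rng: np.random.Generator
) -> tuple[GenotypeCall, GenotypeCall]:
    """Mother and father genotypes at Hardy-Weinberg equilibrium."""
    mother = GenotypeCall(alleles=tuple(sorted(rng.binomial(1, maf, size=2))))
    if chrom == "X":
        father = GenotypeCall(alleles=(int(rng.binomial(1, maf)),))
    else:
        father = GenotypeCall(alleles=tuple(sorted(rng.binomial(1, maf, size=2))))
    return mother, father


def _legal_space(chrom: str, sex: str) -> tuple[tuple[int, ...], ...]:
    if chrom == "X" and sex == "male":
        return HAPLOID_SPACE
    return DIPLOID_SPACE


def expected_discordance(dataset: SimulatedDataset) -> float:
    """Dataset-weighted effective genotype-discordance rate ε·(k−1)/k."""
    eps = dataset.params.genotype_error_rate
    ped = default_quad_pedigree()
    sex = {m.role: m.sex for m in ped.members}
    total, acc = 0, 0.0
    for key, calls in dataset.true_genotypes.items():
        chrom = key.split(":")[0]
        for role in calls:
            k = len(_legal_space(chrom, sex[role]))
            acc += eps * (k - 1) / k
            total += 1
    return acc / total if total else 0.0


# --- planted configurations -------------------------------------------------

# role -> genotype, per model, for a female proband and male sibling.
_PLANT_AUTOSOMAL = {
    "dominant_de_novo": {
        "proband": (0, 1),
        "mother": (0, 0),
        "father": (0, 0),
        "sibling": (0, 0),
    },
    "autosomal_recessive": {
        "proband": (1, 1),
        "mother": (0, 1),
        "father": (0, 1),
        "sibling": (0, 1),
    },
}
_PLANT_COMPOUND = (
    # paternal member
    {"proband": (0, 1), "mother": (0, 0), "father": (0, 1), "sibling": (0, 0)},
    # maternal member
    {"proband": (0, 1), "mother": (0, 1), "father": (0, 0), "sibling": (0, 0)},
)
_PLANT_X = {
    "proband": (0, 1),
    "mother": (0, 1),
    "father": (0,),
    "sibling": (0,),
}

# MAFs assigned to planted variants: de novo sites are absent from the
# reference population (missing); compound genes get one rare and one common
# member to exercise the at-least-one-rare rule.
_PLANT_MAFS = {
    "dominant_de_novo": (None,),
    "autosomal_recessive": (0.005,),
    "compound_het": (0.0005, 0.3),
    "x_linked": (0.004,),
}

_PLANT_CHROM = {
    "dominant_de_novo": "7",
    "autosomal_recessive": "12",
    "compound_het": "10",
    "x_linked": "X",
}
_PLANT_GENE_PREFIX = {
    "dominant_de_novo": "DNVG",
    "autosomal_recessive": "RECG",
    "compound_het": "CHG",
    "x_linked": "XLG",
}


def simulate_quad(params: SimulationParams, out_dir: str | Path) -> SimulatedDataset:
    """Simulate a quad exome and write VCF/PED/annotations/genes/truth files.

    Deterministic for a fixed seed (byte-identical outputs).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    ped = default_quad_pedigree()
    sex = {m.role: m.sex for m in ped.members}
    n = params.n_background_sites

    if params.site_mafs is not None:
        if len(params.site_mafs) != n:
            raise ValueError("site_mafs length must equal n_background_sites")
        mafs = np.asarray(params.site_mafs, dtype=float)
    else:
        mafs = np.clip(rng.beta(params.maf_alpha, params.maf_beta, size=n), 1e-3, 0.5)
    on_x = rng.random(n) < params.x_fraction

    records: list[tuple[VariantRecord, str, str, Optional[float]]] = []
    # (record-with-true-genotypes, gene, functional_class, maf)
    bg_classes = ("nonsynonymous", "synonymous", "intronic", "other_exonic", "intergenic")
    bg_class_p = (0.4, 0.3, 0.2, 0.05, 0.05)
    pos_counter: dict[str, int] = {}

    def next_pos(chrom: str) -> int:
        pos_counter[chrom] = pos_counter.get(chrom, 10_000_000) + 1_000
        return pos_counter[chrom]

    for i in range(n):
        chrom = "X" if on_x[i] else str(int(rng.integers(1, 23)))
        maf = float(mafs[i])
        mother, father = _hwe_parent_calls(maf, chrom, rng)
        daughter = mendelian_transmit(mother, father, chrom, "female", rng)
        son = mendelian_transmit(mother, father, chrom, "male", rng)
        rec = VariantRecord(
            chrom=chrom,
            pos=next_pos(chrom),
            ref="A",
            alt="G",
            calls={
                "proband": daughter,
                "mother": mother,
                "father": father,
                "sibling": son,
            },
        )
        fclass = bg_classes[int(rng.choice(len(bg_classes), p=bg_class_p))]
        records.append((rec, f"GENE{i:05d}", fclass, maf))

    truth_rows: list[TruthRow] = []

    def plant(model: str, gene: str, configs, site_mafs) -> None:
        chrom = _PLANT_CHROM[model]
        for cfg, maf in zip(configs, site_mafs):
            calls = {role: GenotypeCall(alleles=tuple(gt)) for role, gt in cfg.items()}
            rec = VariantRecord(
                chrom=chrom, pos=next_pos(chrom), ref="C", alt="T", calls=calls
            )
            records.append((rec, gene, "nonsynonymous", maf))
            truth_rows.append(
                TruthRow(
                    key=rec.key,
                    gene=gene,
                    model=model,
                    genotypes={r: c.gt_string() for r, c in calls.items()},
                    maf=maf,
                )
            )

    for model in ("dominant_de_novo", "autosomal_recessive", "compound_het", "x_linked"):
        for j in range(params.planted.get(model, 0)):
            gene = f"{_PLANT_GENE_PREFIX[model]}{j + 1}"
            if model == "compound_het":
                plant(model, gene, _PLANT_COMPOUND, _PLANT_MAFS[model])
            elif model == "x_linked":
                plant(model, gene, (_PLANT_X,), _PLANT_MAFS[model])
            else:
                plant(model, gene, (_PLANT_AUTOSOMAL[model],), _PLANT_MAFS[model])

    # truth snapshot before the error/missingness processes
    true_genotypes = {
        rec.key: {role: call.alleles for role, call in rec.calls.items()}
        for rec, _, _, _ in records
    }

    # observation layer: genotype error, missingness, depth, GQ
    observed: list[tuple[VariantRecord, str, str, Optional[float]]] = []
    for rec, gene, fclass, maf in records:
        new_calls: dict[str, GenotypeCall] = {}
        for role, call in rec.calls.items():
            alleles = call.alleles
            gq = params.gq_high
            if params.genotype_error_rate > 0 and rng.random() < params.genotype_error_rate:
                space = _legal_space(rec.chrom, sex[role])
                alleles = space[int(rng.integers(0, len(space)))]
                gq = params.gq_low
            if params.missing_rate > 0 and rng.random() < params.missing_rate:
                alleles = (None,) * len(alleles)
            dp = int(rng.poisson(params.mean_depth))
            new_calls[role] = GenotypeCall(alleles=alleles, gq=gq, dp=dp)
        observed.append(
            (
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alt,
                    calls=new_calls,
                    variant_id=rec.variant_id,
                ),
                gene,
                fclass,
                maf,
            )
        )

    observed.sort(key=lambda t: record_sort_key(t[0]))

    vcf_path = out / "quad.vcf"
    ped_path = out / "quad.ped"
    ann_path = out / "annotations.tsv"
    genes_path = out / "genes.txt"
    truth_path = out / "truth.tsv"

    write_quad_vcf(vcf_path, [t[0] for t in observed], ped)
    write_ped(ped, ped_path)

    ann_lines = [
        "chrom\tpos\tref\talt\tgene\tfunctional_class\tmaf_1kg\thgvs_c\thgvs_p\tpredicted_deleterious"
    ]
    for rec, gene, fclass, maf in observed:
        maf_cell = "." if maf is None else format(maf, "g")
        ann_lines.append(
            f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{rec.alt}\t{gene}\t{fclass}\t{maf_cell}\t.\t.\t."
        )
    ann_path.write_text("\n".join(ann_lines) + "\n")

    planted_genes = sorted({row.gene for row in truth_rows})
    genes_path.write_text("\n".join(planted_genes + list(MUSCLE_GENE_PADDING)) + "\n")

    truth_lines = ["key\tgene\tmodel\tgt_proband\tgt_mother\tgt_father\tgt_sibling\tmaf"]
    for row in truth_rows:
        maf_cell = "." if row.maf is None else format(row.maf, "g")
        truth_lines.append(
            "\t".join(
                [
                    row.key,
                    row.gene,
                    row.model,
                    row.genotypes["proband"],
                    row.genotypes["mother"],
                    row.genotypes["father"],
                    row.genotypes["sibling"],
                    maf_cell,
                ]
            )
        )
    truth_path.write_text("\n".join(truth_lines) + "\n")

    return SimulatedDataset(
        vcf=vcf_path,
        ped=ped_path,
        annotations=ann_path,
        genes=genes_path,
        truth=truth_path,
        truth_rows=truth_rows,
        true_genotypes=true_genotypes,
        params=params,
    )


def load_truth_table(truth_path: str | Path) -> list[TruthRow]:
    rows = []
    lines = Path(truth_path).read_text().splitlines()
    for line in lines[1:]:
        key, gene, model, gp, gm, gf, gs, maf = line.split("\t")
        rows.append(
            TruthRow(
                key=key,
                gene=gene,
                model=model,
                genotypes={"proband": gp, "mother": gm, "father": gf, "sibling": gs},
                maf=None if maf == "." else float(maf),
            )
        )
    return rows


# --- worked-example fixture -------------------------------------------------

def make_worked_example(out_dir: str | Path) -> SimulatedDataset:
    """Emit the myopathy-quad worked example with one decoy per filter stage.

    Five true candidates: a de novo heterozygous BAG3 site; three NRAP sites
    forming an unphased compound-het configuration (one rare paternal, two
    common maternal — the rare member rescues the set); and an X-linked FHL1
    site inherited from the heterozygous carrier mother.  The brother is set
    hemizygous/homozygous reference at the candidate sites, the only
    configuration consistent with the family-genotype filter and his
    unaffected status.  Five decoys each violate exactly one stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped = default_quad_pedigree()

    HQ = {"gq": 99, "dp": 50}

    def dip(a, b, **kw):
        kw = {**HQ, **kw}
        return GenotypeCall(alleles=tuple(sorted((a, b))), gq=kw["gq"], dp=kw["dp"])

    def hap(a, **kw):
        kw = {**HQ, **kw}
        return GenotypeCall(alleles=(a,), gq=kw["gq"], dp=kw["dp"])

    # rec fields: chrom pos ref alt id calls gene fclass maf hgvs_c hgvs_p deleterious
    sites = [
        # -- true candidates ---------------------------------------------
        dict(
            chrom="10", pos=121436625, ref="C", alt="T", vid=None,
            calls=dict(proband=dip(0, 1), mother=dip(0, 0), father=dip(0, 0), sibling=dip(0, 0)),
            gene="BAG3", fclass="nonsynonymous", maf=None,
            hgvs_c="c.626C>T", hgvs_p="p.P209L", dele="1",
        ),
        dict(
            chrom="10", pos=115371826, ref="G", alt="A", vid="rs200747403",
            calls=dict(proband=dip(0, 1), mother=dip(0, 0), father=dip(0, 1), sibling=dip(0, 0)),
            gene="NRAP", fclass="nonsynonymous", maf=0.0004,
            hgvs_c="c.3674G>A", hgvs_p="p.A1225V", dele="1",
        ),
        dict(
            chrom="10", pos=115394615, ref="T", alt="A", vid="rs2270182",
            calls=dict(proband=dip(0, 1), mother=dip(0, 1), father=dip(0, 0), sibling=dip(0, 0)),
            gene="NRAP", fclass="nonsynonymous", maf=0.25,
            hgvs_c="c.1556T>A", hgvs_p="p.N519I", dele="0",
        ),
        dict(
            chrom="10", pos=115405600, ref="C", alt="T", vid="rs2275799",
            calls=dict(proband=dip(0, 1), mother=dip(0, 1), father=dip(0, 0), sibling=dip(0, 0)),
            gene="NRAP", fclass="nonsynonymous", maf=0.27,
            hgvs_c="c.844C>T", hgvs_p="p.A282T", dele="0",
        ),
        dict(
            chrom="X", pos=135291325, ref="G", alt="A", vid="rs151315725",
            calls=dict(proband=dip(0, 1), mother=dip(0, 1), father=hap(0), sibling=hap(0)),
            gene="FHL1", fclass="nonsynonymous", maf=0.0048,
            hgvs_c="c.823G>A", hgvs_p="p.D275N", dele="1",
        ),
        # -- decoys, one per stage ---------------------------------------
        dict(  # fails quality: proband GQ below 50
            chrom="2", pos=179400000, ref="A", alt="G", vid=None,
            calls=dict(proband=dip(0, 1, gq=40), mother=dip(0, 0), father=dip(0, 0), sibling=dip(0, 0)),
            gene="TTN", fclass="nonsynonymous", maf=None,
            hgvs_c=None, hgvs_p=None, dele=None,
        ),
        dict(  # fails functional: synonymous
            chrom="2", pos=220283099, ref="G", alt="A", vid=None,
            calls=dict(proband=dip(0, 1), mother=dip(0, 0), father=dip(0, 0), sibling=dip(0, 0)),
            gene="DES", fclass="synonymous", maf=None,
            hgvs_c=None, hgvs_p=None, dele=None,
        ),
        dict(  # fails family: shared with the unaffected brother
            chrom="11", pos=111779000, ref="C", alt="G", vid=None,
            calls=dict(proband=dip(0, 1), mother=dip(0, 1), father=dip(0, 0), sibling=dip(0, 1)),
            gene="CRYAB", fclass="nonsynonymous", maf=0.001,
            hgvs_c=None, hgvs_p=None, dele=None,
        ),
        dict(  # fails rarity: de novo configuration but MAF 5%
            chrom="5", pos=137221000, ref="T", alt="C", vid=None,
            calls=dict(proband=dip(0, 1), mother=dip(0, 0), father=dip(0, 0), sibling=dip(0, 0)),
            gene="MYOT", fclass="nonsynonymous", maf=0.05,
            hgvs_c=None, hgvs_p=None, dele=None,
        ),
        dict(  # fails muscle-gene restriction
            chrom="4", pos=74270000, ref="A", alt="T", vid=None,
            calls=dict(proband=dip(0, 1), mother=dip(0, 0), father=dip(0, 0), sibling=dip(0, 0)),
            gene="ALB", fclass="nonsynonymous", maf=None,
            hgvs_c=None, hgvs_p=None, dele=None,
        ),
    ]

    truth_model = {
        "10:121436625:C:T": "dominant_de_novo",
        "10:115371826:G:A": "compound_het",
        "10:115394615:T:A": "compound_het",
        "10:115405600:C:T": "compound_het",
        "X:135291325:G:A": "x_linked",
    }

    records = []
    truth_rows = []
    for s in sites:
        rec = VariantRecord(
            chrom=s["chrom"], pos=s["pos"], ref=s["ref"], alt=s["alt"],
            calls=s["calls"], variant_id=s["vid"],
        )
        records.append((rec, s))
        model = truth_model.get(rec.key)
        if model:
            truth_rows.append(
                TruthRow(
                    key=rec.key,
                    gene=s["gene"],
                    model=model,
                    genotypes={r: c.gt_string() for r, c in rec.calls.items()},
                    maf=s["maf"],
                )
            )

    vcf_path = out / "quad.vcf"
    ped_path = out / "quad.ped"
    ann_path = out / "annotations.tsv"
    genes_path = out / "genes.txt"
    truth_path = out / "truth.tsv"

    write_quad_vcf(vcf_path, [r for r, _ in records], ped)
    write_ped(ped, ped_path)

    ann_lines = [
        "chrom\tpos\tref\talt\tgene\tfunctional_class\tmaf_1kg\thgvs_c\thgvs_p\tpredicted_deleterious"
    ]
    for rec, s in sorted(records, key=lambda t: record_sort_key(t[0])):
        cell = lambda v: "." if v is None else (format(v, "g") if isinstance(v, float) else str(v))
        ann_lines.append(
            "\t".join(
                [
                    rec.chrom, str(rec.pos), rec.ref, rec.alt, s["gene"], s["fclass"],
                    cell(s["maf"]), cell(s["hgvs_c"]), cell(s["hgvs_p"]), cell(s["dele"]),
                ]
            )
        )
    ann_path.write_text("\n".join(ann_lines) + "\n")

    gene_list = ["BAG3", "NRAP", "FHL1", "DES", "CRYAB", "MYOT", "LDB3", "FLNC", "TTN", "MYH10"]
    genes_path.write_text("\n".join(gene_list) + "\n")

    truth_lines = ["key\tgene\tmodel\tgt_proband\tgt_mother\tgt_father\tgt_sibling\tmaf"]
    for row in truth_rows:
        maf_cell = "." if row.maf is None else format(row.maf, "g")
        truth_lines.append(
            "\t".join(
                [
                    row.key, row.gene, row.model,
                    row.genotypes["proband"], row.genotypes["mother"],
                    row.genotypes["father"], row.genotypes["sibling"], maf_cell,
                ]
            )
        )
    truth_path.write_text("\n".join(truth_lines) + "\n")

    params = SimulationParams(
        n_background_sites=0, genotype_error_rate=0.0, missing_rate=0.0, seed=0
    )
    return SimulatedDataset(
        vcf=vcf_path,
        ped=ped_path,
        annotations=ann_path,
        genes=genes_path,
        truth=truth_path,
        truth_rows=truth_rows,
        true_genotypes={
            rec.key: {role: call.alleles for role, call in rec.calls.items()}
            for rec, _ in records
        },
        params=params,
    )
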