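# Methods

## Problem setting and model

`quadprio` prioritizes rare, protein-changing variants in an affected child
against three unaffected first-degree relatives (both parents and one
sibling). The genetic logic assumes full penetrance and no phenocopies:
any genotype configuration that an unaffected relative shares with the
proband is treated as non-causal. Four Mendelian models are considered.
Because both parents are unaffected by construction, an inherited dominant
allele would imply an affected carrier parent, so the dominant model
reduces to *de novo* dominance; inherited-dominant transmission is
deliberately not modeled.

The family topology is fixed to a quad, but the proband's sex is not: the
X-linked classifier branches on it (het proband with a carrier mother for a
female; hemizygous-alternate for a male). The whole of chromosome X is
treated as non-PAR — pseudoautosomal coordinates are not modeled — and
chrY/MT variants support no model and are dropped with a logged notice.

## Normalization conventions

* Coordinates are VCF-native (1-based, closed) end to end.
* Multiallelic sites are decomposed into one biallelic record per alternate;
  in each decomposed record, alleles equal to the chosen alternate become 1
  and alleles belonging to any *other* alternate become missing. This
  conserves allele mass: each sample's non-missing alternate allele appears
  in exactly one decomposed record.
* Male calls on X/Y are forced haploid. A heterozygous male X call is
  invalid for the sample's sex and becomes a missing haploid call rather
  than being half-trusted.
* Genotype identity is allele-multiset equality; any missing allele defeats
  identity, so "identical to the brother" is never asserted on partial data.
  Haploid and diploid calls are never equal (relevant on X, where a het
  proband is compared against a hemizygous father).

## Filter cascade

Stage order: quality → functional → family genotype → model classification →
rarity → muscle-gene restriction. Rarity must follow model assignment
because the compound-het rarity rule operates on gene sets, which exist only
after classification. The final candidate set is invariant to the relative
order of the last two stages (both are per-candidate predicates); only the
intermediate stage counts depend on the order.

Quality is enforced per sample over all four members. The procedure infers
inheritance by comparing every member's genotype, so one unreliable call
invalidates the comparison; a proband-only cut would let an
erroneously hom-ref parent manufacture a de novo candidate. Thresholds are
inclusive at the boundary (GQ ≥ 50, DP ≥ 7 pass) — only strictly lower
values are discarded — and missing genotypes are hard failures, never
imputed.

The functional filter keeps {nonsynonymous, stopgain, stoploss}. Variants
with no annotation row are classed `unknown` and fail conservatively.

## Compound heterozygosity without phase

No read-backed or statistical phasing is attempted. Parental origin is
inferred from genotypes alone: a proband-het variant is *paternal* iff the
father carries the alternate and the mother is hom-ref, *maternal* in the
mirror case, and *ambiguous* when both parents carry it. Ambiguous variants
cannot anchor a trans pair — this forfeits some true pairs (when a parent
happens to carry both variants) in exchange for never asserting a false
trans configuration. A gene yields candidates iff it has at least one
unambiguously paternal and one unambiguously maternal proband-het variant.

As an extension consistent with the unaffected sibling's status, a trans
pair jointly carried by the sibling (alternate allele at both sites) is
excluded pairwise: such a sibling would carry the same two-hit genotype as
the proband. The single-site family filter cannot catch this case when the
sibling's individual genotypes differ from the proband's (e.g. hom-alt vs
het).

## Rarity

A variant is rare iff MAF < `max_maf` (default 0.01, strict inequality). A
missing MAF means the variant is absent from the reference population and
therefore cannot exceed the threshold: it counts as rare. For compound-het
gene sets the rule is evaluated at the set level — the set survives in full
if at least one member is rare — so a very rare variant in trans with common
partners keeps the whole set reportable. Mixed-model candidates keep
whichever models individually survive.

## Synthetic data generator

The simulator emulates the statistical structure the prioritizer assumes,
not raw sequencing. Per background site: an alternate-allele frequency q
(fixed list, or Beta(0.8, 4) clipped to [0.001, 0.5] — a rare-skewed
frequency spectrum typical of exome polymorphisms), parental genotypes drawn
at Hardy–Weinberg equilibrium (alleles Bernoulli(q); one allele for the
father on X), children by Mendelian transmission with male X hemizygosity.
Planted variants are written in the defining genotype configuration of their
model, annotated nonsynonymous, each model in its own gene, all planted
genes included in the emitted gene list; compound genes get one rare
(MAF 0.0005) and one common (0.3) member to exercise the at-least-one-rare
rule, de novo sites get a missing MAF, recessive 0.005 and X-linked 0.004.

Observation layer, applied independently per genotype:

* **Error** (default ε = 0.005): with probability ε the genotype is redrawn
  uniformly from the legal genotype space *including the true genotype*
  (3 diploid genotypes, or 2 for male X). Realized discordance is therefore
  ε·(k−1)/k per call; `expected_discordance` computes the dataset-weighted
  effective value used by the calibration tests.
* **GQ** is a two-level caricature: 99 for untouched calls, 30 for
  error-perturbed ones — enough to exercise the GQ < 50 cutoff without a
  likelihood model.
* **Missingness** (default 0.01) blanks the genotype.
* **Depth** is Poisson with mean 46 (a typical targeted-exome mean
  coverage), floored at 0 by construction.

Sites are independent: no linkage disequilibrium, no recombination map, no
haplotype structure — trans configurations are planted, not emergent. The
generator also does not model allelic imbalance, indels, population
structure, or batch effects, so passing recovery tests demonstrates the
correctness of the decision logic under the stated statistical model, not
robustness to real-data artifacts.

Defaults (1000 background sites, one planted variant/gene per model, 5 % of
background on X) describe a small exome-scale screen; all are overridable
through `SimulationParams`. Everything derives from a single integer seed
through one `numpy` generator, making outputs byte-identical per seed.

## Worked-example fixture

`make_worked_example` writes a deterministic ten-site quad: five true
candidates (one de novo *BAG3* site with missing MAF; three *NRAP* sites —
paternal MAF 0.0004, maternal 0.25 and 0.27; one X-linked *FHL1* site,
MAF 0.0048) and five decoys, each constructed to fail exactly one stage
(proband GQ 40; a synonymous site; a site shared het with the sibling; a de
novo-configured site at MAF 0.05; a rare de novo site in a non-muscle gene).
The sibling's genotypes at the candidate sites are set hemizygous/homozygous
reference — the only configuration consistent with the family filter and his
unaffected status. The fixture's gene list holds the three candidate genes
plus seven well-known muscle genes and excludes the decoy gene *ALB*.

## Numerical and I/O choices

* The report TSV has a fixed, versioned column order; models are serialized
  as a sorted comma-joined list; runs are pure functions of their inputs
  (byte-identical reports, no timestamps outside the log stream).
* Stage counts satisfy conservation by construction (`entered = passed +
  Σ failures`), and each failure carries exactly one reason — the first
  failing check short-circuits.
* Filter-trace rows record every stage verdict per variant for audit.
* CLI exit codes: 0 success (an empty candidate set is a success), 2
  validation error, 3 I/O error.
* Symbolic alleles (`<DEL>`, breakends) are skipped with a warning; only
  SNVs and simple indels enter the cascade.

## Test problem sizes

The statistical suites use sizes at which three-sigma binomial bounds are
tight enough to be meaningful while keeping the default test run fast:
10,000 draws for transmission frequencies, 4,000–10,000 sites for
Hardy–Weinberg and discordance calibration, 20 seeds × 1,000 background
sites for error-free recovery. Exhaustive classifier checks enumerate the
complete genotype space (81 autosomal, 36 X configurations), so they are
proofs over the domain rather than samples.

## Known limitations

* Single-nucleotide-centric: no structural variants, no transcript-aware
  consequence re-annotation (the annotation table is trusted as given).
* HGVS strings are opaque text; they are reported, never validated.
* No penetrance, imprinting, mosaicism or X-inactivation modeling; the
  unaffected-relative assumptions are absolute.
* The muscle-gene restriction is exactly the user-supplied list — no
  bundled expression database and no expression threshold semantics.
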