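"""Model classifiers checked against independently written truth predicates
by exhaustive enumeration of quad genotype space."""

import itertools

import pytest

from conftest import call, make_variant
from quadprio import (
    RarityRule,
    apply_rarity,
    classify_dominant_de_novo,
    classify_recessive,
    classify_x_linked,
    family_genotype_filter,
    find_compound_het,
)

DIPLOID = [(0, 0), (0, 1), (1, 1)]
HAPLOID = [(0,), (1,)]


# Independent oracles: restated from the genetics, not from the classifier
# code.  De novo: the child carries one new allele absent from the family.
# Recessive: the affected child is the only hom-alt, both parents obligate
# carriers.  X-linked (female proband): carrier mother transmits to the
# affected daughter; father and unaffected brother are hemizygous reference.
def oracle_de_novo(p, m, f, s):
    return set(p) == {0, 1} and m == (0, 0) and f == (0, 0) and s == (0, 0)


def oracle_recessive(p, m, f, s):
    return p == (1, 1) and set(m) == {0, 1} and set(f) == {0, 1} and s != (1, 1)


def oracle_x_linked_female(p, m, f, s):
    return set(p) == {0, 1} and set(m) == {0, 1} and f == (0,) and s == (0,)


def test_autosomal_classifiers_match_oracle_exhaustively(quad):
    """All 81 autosomal quad genotype combinations agree with the oracles,
    and no combination is both de novo and recessive."""
    n_dn = n_ar = 0
    for p, m, f, s in itertools.product(DIPLOID, repeat=4):
        v = make_variant(p, m, f, s)
        dn = classify_dominant_de_novo(v, quad)
        ar = classify_recessive(v, quad)
        assert dn == oracle_de_novo(p, m, f, s), (p, m, f, s)
        assert ar == oracle_recessive(p, m, f, s), (p, m, f, s)
        assert not (dn and ar)
        n_dn += dn
        n_ar += ar
    assert n_dn == 1 and n_ar == 2  # sibling 0/0 or 0/1


def test_x_linked_classifier_matches_oracle_exhaustively(quad):
    """All 36 X configurations for a female proband with a male sibling."""
    for p, m in itertools.product(DIPLOID, repeat=2):
        for f, s in itertools.product(HAPLOID, repeat=2):
            v = make_variant(p, m, f, s, chrom="X")
            assert classify_x_linked(v, quad) == oracle_x_linked_female(p, m, f, s)


def test_x_linked_male_proband(quad):
    """A hemizygous-alternate son of a carrier mother fits the model."""
    male_quad = type(quad)(
        members=tuple(
            type(m)(m.sample_id, m.role, "male" if m.role == "proband" else m.sex, m.affected)
            for m in quad.members
        )
    )
    for p in HAPLOID:
        for m in DIPLOID:
            for f, s in itertools.product(HAPLOID, repeat=2):
                v = make_variant(p, m, f, s, chrom="X")
                expected = (
                    p == (1,) and set(m) == {0, 1} and f == (0,) and s == (0,)
                )
                assert classify_x_linked(v, male_quad) == expected


def test_autosomal_variant_rejected_by_x_classifier(quad):
    v = make_variant((0, 1), (0, 1), (0, 0), (0, 0), chrom="7")
    with pytest.raises(ValueError):
        classify_x_linked(v, quad)


def test_x_variant_rejected_by_autosomal_classifiers(quad):
    v = make_variant((0, 1), (0, 1), (0,), (0,), chrom="X")
    with pytest.raises(ValueError):
        classify_dominant_de_novo(v, quad)
    with pytest.raises(ValueError):
        classify_recessive(v, quad)


class TestCompoundHet:
    def nrap_like(self):
        v1 = make_variant((0, 1), (0, 0), (0, 1), (0, 0), pos=100, gene="NRAP", maf=0.0004)
        v2 = make_variant((0, 1), (0, 1), (0, 0), (0, 0), pos=200, gene="NRAP", maf=0.25)
        v3 = make_variant((0, 1), (0, 1), (0, 0), (0, 0), pos=300, gene="NRAP", maf=0.27)
        return v1, v2, v3

    def test_one_paternal_two_maternal_yields_three_candidates(self, quad):
        v1, v2, v3 = self.nrap_like()
        cands = {c.key: c for c in find_compound_het([v1, v2, v3], quad)}
        assert set(cands) == {v1.key, v2.key, v3.key}
        assert cands[v1.key].compound_partner_keys == {v2.key, v3.key}
        assert cands[v2.key].compound_partner_keys == {v1.key}
        assert cands[v3.key].compound_partner_keys == {v1.key}
        assert cands[v1.key].parental_origin == "paternal"
        assert cands[v2.key].parental_origin == "maternal"

    def test_same_origin_only_yields_nothing(self, quad):
        _, v2, v3 = self.nrap_like()
        assert find_compound_het([v2, v3], quad) == []

    def test_ambiguous_origin_cannot_anchor_a_pair(self, quad):
        v1 = make_variant((0, 1), (0, 1), (0, 1), (0, 0), pos=100, gene="G")
        v2 = make_variant((0, 1), (0, 1), (0, 0), (0, 0), pos=200, gene="G")
        assert find_compound_het([v1, v2], quad) == []

    def test_input_order_is_irrelevant(self, quad):
        vs = self.nrap_like()
        expected = find_compound_het(list(vs), quad)
        for perm in itertools.permutations(vs):
            assert find_compound_het(list(perm), quad) == expected

    def test_sibling_exclusion_brute_force(self, quad):
        """Enumerate all 9 brother genotype combinations at a paternal +
        maternal pair; candidates must appear exactly when the family filter
        keeps both variants and the brother does not carry the full trans
        pair (he would be affected too)."""
        for s1, s2 in itertools.product(DIPLOID, repeat=2):
            v1 = make_variant((0, 1), (0, 0), (0, 1), s1, pos=100, gene="G")
            v2 = make_variant((0, 1), (0, 1), (0, 0), s2, pos=200, gene="G")
            survivors = [
                v for v in (v1, v2) if family_genotype_filter(v, quad).passed
            ]
            cands = find_compound_het(survivors, quad)
            # independent statement of the rule
            both_survive = s1 != (0, 1) and s2 != (0, 1)
            sib_carries_pair = (1 in s1) and (1 in s2)
            expected = both_survive and not sib_carries_pair
            assert bool(cands) == expected, (s1, s2)
            if expected:
                assert {c.key for c in cands} == {v1.key, v2.key}


class TestRarity:
    def as_compound(self, quad, *variants):
        return find_compound_het(list(variants), quad)

    def test_one_rare_member_rescues_the_gene_set(self, quad):
        v1 = make_variant((0, 1), (0, 0), (0, 1), (0, 0), pos=100, gene="NRAP", maf=0.0004)
        v2 = make_variant((0, 1), (0, 1), (0, 0), (0, 0), pos=200, gene="NRAP", maf=0.25)
        v3 = make_variant((0, 1), (0, 1), (0, 0), (0, 0), pos=300, gene="NRAP", maf=0.27)
        kept = apply_rarity(self.as_compound(quad, v1, v2, v3), RarityRule())
        assert {c.key for c in kept} == {v1.key, v2.key, v3.key}

    def test_all_common_set_is_removed(self, quad):
        v1 = make_variant((0, 1), (0, 0), (0, 1), (0, 0), pos=100, gene="G", maf=0.25)
        v2 = make_variant((0, 1), (0, 1), (0, 0), (0, 0), pos=200, gene="G", maf=0.27)
        assert apply_rarity(self.as_compound(quad, v1, v2), RarityRule()) == []

    def test_missing_maf_counts_as_rare(self, quad):
        from quadprio import classify_all

        v = make_variant((0, 1), (0, 0), (0, 0), (0, 0), maf=None)
        (cand,) = classify_all([v], quad)
        assert apply_rarity([cand], RarityRule()) == [cand]

    def test_threshold_is_strict(self, quad):
        from quadprio import classify_all

        v = make_variant((0, 1), (0, 0), (0, 0), (0, 0), maf=0.01)
        (cand,) = classify_all([v], quad)
        assert apply_rarity([cand], RarityRule(max_maf=0.01)) == []

    @pytest.mark.parametrize("low, high", [(0.001, 0.01), (0.01, 0.05), (0.05, 0.5)])
    def test_monotone_in_max_maf(self, quad, low, high):
        """Raising the threshold never removes a candidate."""
        from quadprio import classify_all

        variants = [
            make_variant((0, 1), (0, 0), (0, 0), (0, 0), pos=100 + i, maf=maf, gene=f"G{i}")
            for i, maf in enumerate([None, 0.0004, 0.004, 0.02, 0.2])
        ]
        cands = classify_all(variants, quad)
        kept_low = {c.key for c in apply_rarity(cands, RarityRule(max_maf=low))}
        kept_high = {c.key for c in apply_rarity(cands, RarityRule(max_maf=high))}
        assert kept_low <= kept_high


def test_every_candidate_carries_an_alternate_allele(quad):
    """Across the exhaustive autosomal space, any variant classified under
    any model has >= 1 alternate allele in the proband."""
    from quadprio import classify_all

    for p, m, f, s in itertools.product(DIPLOID, repeat=4):
        v = make_variant(p, m, f, s)
        for cand in classify_all([v], quad):
            assert cand.variant.record.calls["proband"].carries_alt
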