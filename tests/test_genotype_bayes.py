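import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from snpanchor.genotype_bayes import (
    BaseCompositionModel,
    base_given_allele,
    base_given_genotype,
    call_genotype,
    genotype_posterior,
    genotype_prior,
)
from snpanchor.types import ALL_GENOTYPES, BASES, Genotype
from conftest import make_column

bases_st = st.sampled_from(BASES)
gc_st = st.floats(0.05, 0.95)
e_st = st.floats(0.0, 0.5)


def brute_posterior(col, prior, comp):
    """Independent direct-product posterior (no log space, no tables)."""
    weights = {}
    for g in ALL_GENOTYPES:
        p = prior[g]
        for b, e, _ in col.observations:
            p *= base_given_genotype(b, g, e, comp)
        weights[g] = p
    total = sum(weights.values())
    return {g: w / total for g, w in weights.items()}


class TestBaseGivenAllele:
    def test_two_sevenths_rule_at_gc40(self):
        # misreading into a G/C base when GC/AT = 2/3: weight 2 of total 7
        comp = BaseCompositionModel(0.40)
        for e in (0.001, 0.01, 0.2):
            assert base_given_allele("C", "A", e, comp) == pytest.approx((2 / 7) * e)
            assert base_given_allele("T", "A", e, comp) == pytest.approx((3 / 7) * e)

    def test_uniform_error_at_gc50(self, comp50):
        for b in "CGT":
            assert base_given_allele(b, "A", 0.09, comp50) == pytest.approx(0.09 / 3)

    def test_noiseless_limit(self, comp41):
        assert base_given_allele("A", "A", 0.0, comp41) == 1.0
        assert base_given_allele("C", "A", 0.0, comp41) == 0.0

    def test_value_at_gc41(self, comp41):
        # e * w_C / (1 - w_A) = 0.01 * 0.205 / 0.705
        expected = 0.01 * 0.205 / 0.705
        assert base_given_allele("C", "A", 0.01, comp41) == pytest.approx(expected)
        assert expected == pytest.approx(2.908e-3, rel=1e-3)

    @given(allele=bases_st, e=e_st, gc=gc_st)
    @settings(deadline=None)
    def test_four_probabilities_sum_to_one(self, allele, e, gc):
        comp = BaseCompositionModel(gc)
        total = sum(base_given_allele(b, allele, e, comp) for b in BASES)
        assert total == pytest.approx(1.0, abs=1e-12)


class TestBaseGivenGenotype:
    def test_homozygous_degenerates_to_allele(self, comp41):
        g = Genotype.of("G", "G")
        for b in BASES:
            assert base_given_genotype(b, g, 0.02, comp41) == base_given_allele(
                b, "G", 0.02, comp41
            )

    def test_het_is_even_mixture(self, comp50):
        g = Genotype.of("A", "T")
        e = 0.04
        assert base_given_genotype("A", g, e, comp50) == pytest.approx(
            0.5 * (1 - e) + 0.5 * (e / 3)
        )

    @given(
        g=st.sampled_from(ALL_GENOTYPES), e=e_st, gc=gc_st
    )
    @settings(deadline=None)
    def test_sums_to_one(self, g, e, gc):
        comp = BaseCompositionModel(gc)
        total = sum(base_given_genotype(b, g, e, comp) for b in BASES)
        assert total == pytest.approx(1.0, abs=1e-12)


class TestPrior:
    def test_uniform_composition(self, comp50):
        prior = genotype_prior(comp50)
        for g in ALL_GENOTYPES:
            assert prior[g] == pytest.approx(1 / 16 if g.is_hom else 1 / 8)

    def test_gc41_homozygote(self, comp41):
        prior = genotype_prior(comp41)
        assert prior[Genotype.of("A", "A")] == pytest.approx(0.295 ** 2)
        assert prior[Genotype.of("C", "G")] == pytest.approx(2 * 0.205 * 0.205)

    @given(gc=gc_st)
    @settings(deadline=None)
    def test_sums_to_one(self, gc):
        prior = genotype_prior(BaseCompositionModel(gc))
        assert sum(prior.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(p > 0 for p in prior.values())

    def test_invalid_gc_rejected(self):
        for gc in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                BaseCompositionModel(gc)


class TestPosterior:
    def test_empty_pileup_returns_prior(self, prior41, comp41):
        post = genotype_posterior(make_column(bases=""), prior41, comp41)
        for g in ALL_GENOTYPES:
            assert post[g] == pytest.approx(prior41[g])

    def test_hom_signal(self, prior41, comp41):
        col = make_column(ref="A", bases="A" * 10, e=0.001)
        post = genotype_posterior(col, prior41, comp41)
        assert max(post, key=post.get) == Genotype.of("A", "A")
        brute = brute_posterior(col, prior41, comp41)
        assert max(brute, key=brute.get) == Genotype.of("A", "A")

    def test_het_signal(self, prior41, comp41):
        col = make_column(ref="A", bases="AAATTT", e=0.001)
        post = genotype_posterior(col, prior41, comp41)
        assert max(post, key=post.get) == Genotype.of("A", "T")

    def test_normalization(self, rng, prior41, comp41):
        for _ in range(50):
            n = int(rng.integers(0, 40))
            bases = "".join(rng.choice(list(BASES), size=n))
            e = float(10 ** -rng.uniform(0.3, 4))
            post = genotype_posterior(make_column(bases=bases, e=e), prior41, comp41)
            assert abs(sum(post.values()) - 1.0) < 1e-12

    def test_log_space_matches_direct_product(self, rng, prior41, comp41):
        for _ in range(30):
            n = int(rng.integers(1, 21))
            bases = "".join(rng.choice(list(BASES), size=n))
            e = float(10 ** -rng.uniform(0.3, 3))
            col = make_column(bases=bases, e=e)
            post = genotype_posterior(col, prior41, comp41)
            brute = brute_posterior(col, prior41, comp41)
            for g in ALL_GENOTYPES:
                assert post[g] == pytest.approx(brute[g], abs=1e-9)

    def test_gc50_reduces_to_uniform_error_model(self, comp50):
        # closed form: likelihood with e/3 off-diagonal terms
        prior = genotype_prior(comp50)
        e = 0.01
        col = make_column(ref="A", bases="AAC", e=e)
        post = genotype_posterior(col, prior, comp50)

        def lik(g):
            out = 1.0
            for b in "AAC":
                terms = [(1 - e) if b == a else e / 3 for a in g.alleles]
                out *= 0.5 * terms[0] + 0.5 * terms[1]
            return out

        weights = {g: prior[g] * lik(g) for g in ALL_GENOTYPES}
        z = sum(weights.values())
        for g in ALL_GENOTYPES:
            assert post[g] == pytest.approx(weights[g] / z, abs=1e-12)

    @given(data=st.data())
    @settings(deadline=None, max_examples=40)
    def test_monotone_evidence(self, data, prior41, comp41):
        """An extra observation of b never disfavors {b,b} against
        genotypes not containing b."""
        b = data.draw(bases_st)
        n = data.draw(st.integers(0, 10))
        others = data.draw(st.lists(bases_st, min_size=0, max_size=6))
        e = data.draw(st.floats(1e-4, 0.3))
        col = make_column(bases="".join(others) + b * n, e=e)
        col2 = make_column(bases="".join(others) + b * (n + 1), e=e)
        post1 = genotype_posterior(col, prior41, comp41)
        post2 = genotype_posterior(col2, prior41, comp41)
        gb = Genotype.of(b, b)
        for g in ALL_GENOTYPES:
            if b in g:
                continue
            r1 = post1[gb] / post1[g] if post1[g] > 0 else math.inf
            r2 = post2[gb] / post2[g] if post2[g] > 0 else math.inf
            assert r2 >= r1 * (1 - 1e-9)


class TestCallGenotype:
    def test_shallow_pileup_uncertain(self, prior41, comp41):
        col = make_column(bases="GGGG", e=1e-4, ref="G")
        call = call_genotype(col, prior41, comp41)
        assert call.is_uncertain and call.depth == 4

    def test_exactly_five_reads_uncertain(self, prior41, comp41):
        # "more than 5 qualified reads" is strict: 5 is not enough
        col = make_column(bases="GGGGG", e=1e-4, ref="G")
        assert call_genotype(col, prior41, comp41).is_uncertain

    def test_deep_hom_called(self, prior41, comp41):
        col = make_column(bases="G" * 20, e=1e-4, ref="G")
        call = call_genotype(col, prior41, comp41)
        assert call.call == Genotype.of("G", "G")
        assert call.dominance_ratio >= 1000

    def test_ambiguous_six_reads_uncertain(self, prior41, comp41):
        call = call_genotype(make_column(bases="AAACCC", e=0.1), prior41, comp41)
        assert call.is_uncertain
        assert call.dominance_ratio < 1000

    def test_mapq_filter_drops_reads(self, prior41, comp41):
        obs = [("G", 1e-4, 10)] * 20 + [("G", 1e-4, 60)] * 4
        col = make_column(ref="G")
        col.observations = obs
        call = call_genotype(col, prior41, comp41, min_mapq=20)
        assert call.depth == 4 and call.is_uncertain

    def test_posterior_sums_to_one_on_call(self, prior41, comp41):
        call = call_genotype(make_column(bases="A" * 30, e=1e-3), prior41, comp41)
        assert sum(call.posterior.values()) == pytest.approx(1.0, abs=1e-12)
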