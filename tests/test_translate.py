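"""Diplotype enumeration, sample encoding, matching and phenotypes."""

import itertools

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from pgxtranslate import (
    GenotypeCall,
    GenotypeProfile,
    MissingPolicy,
    Phenotype,
    TranslationResult,
    assign_phenotype,
    curate,
    derive_annotation,
    encode_numeric,
    encode_sample,
    enumerate_diplotypes,
    match_diplotype,
    summarize_by_gene,
    summarize_by_sample,
    translate_variant,
)
from pgxtranslate.errors import ConsistencyError, PgxError, UnknownAlleleError
from pgxtranslate.simulate import generate_ambiguous_table, generate_table
from pgxtranslate.translate import SampleGeneVector

from helpers import oracle_match, oracle_pair_sums, oracle_tally


class TestEnumeration:
    def test_ugt1a5_six_diplotypes(self, ugt1a5_encoded):
        dips = enumerate_diplotypes(ugt1a5_encoded)
        names = [d.name for d in dips]
        assert names == ["*1/*1", "*1/*2", "*1/*3", "*2/*2", "*2/*3", "*3/*3"]

    def test_sum_vector_is_elementwise_sum(self, ugt1a5_encoded):
        dips = {d.name: d for d in enumerate_diplotypes(ugt1a5_encoded)}
        assert dips["*2/*3"].sum_vector == (1, 1, 0, 0)
        assert dips["*1/*1"].sum_vector == (0, 0, 0, 0)

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 8, 13, 21, 30])
    def test_count_is_n_choose_2_with_replacement(self, n):
        t = curate(generate_table("G", n_variants=10, n_haplotypes=n, max_minors=3, seed=n))
        assert len(enumerate_diplotypes(encode_numeric(t))) == n * (n + 1) // 2

    def test_single_haplotype_gene(self):
        t = curate(generate_table("G", n_variants=2, n_haplotypes=1, seed=0))
        dips = enumerate_diplotypes(encode_numeric(t))
        assert len(dips) == 1
        assert dips[0].sum_vector == (0, 0)

    def test_sums_match_oracle(self):
        for seed in range(5):
            t = curate(generate_table("G", 6, 5, max_minors=3, seed=seed))
            expected = oracle_pair_sums(t.alleles)
            for d in enumerate_diplotypes(encode_numeric(t)):
                assert d.sum_vector == expected[tuple(sorted(d.haplotype_pair))]


class TestEncodeSample:
    def test_worked_example_vector(self, sample_profile, ugt1a5_encoded, ugt1a5_annotation):
        v = encode_sample(sample_profile, ugt1a5_encoded, ugt1a5_annotation)
        assert v.sum_vector == (1, 1, 0, 0)
        assert v.missing_rsids == ()

    def test_all_homozygous_major_is_zero(self, ugt1a5_encoded, ugt1a5_annotation):
        profile = GenotypeProfile(
            "S",
            {
                rsid: GenotypeCall((ugt1a5_annotation[rsid].major_allele,) * 2)
                for rsid in ugt1a5_encoded.rsids
            },
        )
        v = encode_sample(profile, ugt1a5_encoded, ugt1a5_annotation)
        assert v.sum_vector == (0, 0, 0, 0)

    def test_assume_ref_equals_explicit_reference_oracle(
        self, ugt1a5_encoded, ugt1a5_annotation
    ):
        sparse = GenotypeProfile("S", {"rs12475068": GenotypeCall(("C", "G"))})
        explicit = GenotypeProfile(
            "S",
            {
                "rs12475068": GenotypeCall(("C", "G")),
                **{
                    rsid: GenotypeCall((ugt1a5_annotation[rsid].major_allele,) * 2)
                    for rsid in ugt1a5_encoded.rsids[1:]
                },
            },
        )
        got = encode_sample(sparse, ugt1a5_encoded, ugt1a5_annotation, MissingPolicy.ASSUME_REF)
        want = encode_sample(explicit, ugt1a5_encoded, ugt1a5_annotation)
        assert got.sum_vector == want.sum_vector
        assert set(got.missing_rsids) == set(ugt1a5_encoded.rsids[1:])
        assert got.usable

    def test_no_call_policy_flags_unusable(self, ugt1a5_encoded, ugt1a5_annotation):
        sparse = GenotypeProfile("S", {"rs12475068": GenotypeCall(("C", "G"))})
        v = encode_sample(sparse, ugt1a5_encoded, ugt1a5_annotation, MissingPolicy.NO_CALL)
        assert not v.usable
        r = match_diplotype(v, enumerate_diplotypes(ugt1a5_encoded))
        assert r.phenotype is Phenotype.NO_CALL and not r.matches

    def test_unknown_allele_names_rsid_and_allele(self, ugt1a5_encoded, ugt1a5_annotation):
        profile = GenotypeProfile("S", {"rs12475068": GenotypeCall(("C", "T"))})
        with pytest.raises(UnknownAlleleError, match="rs12475068.*'T'"):
            encode_sample(profile, ugt1a5_encoded, ugt1a5_annotation)


class TestMatching:
    def test_worked_example_matches_star2_star3(
        self, sample_profile, ugt1a5_encoded, ugt1a5_annotation
    ):
        v = encode_sample(sample_profile, ugt1a5_encoded, ugt1a5_annotation)
        r = match_diplotype(v, enumerate_diplotypes(ugt1a5_encoded))
        assert r.matches == (("*2", "*3"),)
        assert not r.ambiguous
        assert r.phenotype is Phenotype.VAR_VAR and r.phenotype.color == "red"

    def test_all_zero_vector_matches_reference_self_pair(self, ugt1a5_encoded):
        v = SampleGeneVector("S", "UGT1A5", (0, 0, 0, 0))
        r = match_diplotype(v, enumerate_diplotypes(ugt1a5_encoded))
        assert r.matches == (("*1", "*1"),)
        assert r.phenotype is Phenotype.WT_WT and r.phenotype.color == "green"

    def test_no_match_is_nocall_grey(self, ugt1a5_encoded):
        v = SampleGeneVector("S", "UGT1A5", (5, 5, 5, 5))
        r = match_diplotype(v, enumerate_diplotypes(ugt1a5_encoded))
        assert r.matches == ()
        assert r.phenotype is Phenotype.NO_CALL and r.phenotype.color == "grey"
        assert r.diplotype == ""

    def test_colliding_sums_return_all_matches(self):
        t = curate(generate_ambiguous_table(seed=3))
        e = encode_numeric(t)
        sums = oracle_pair_sums(t.alleles)
        target = sums[("*2", "*4")]  # codes 1 + 5
        expected = {p for p, s in sums.items() if s == target}
        assert len(expected) > 1  # the construction really collides (3 + 3)
        r = match_diplotype(
            SampleGeneVector("S", t.gene, target), enumerate_diplotypes(e)
        )
        assert {tuple(sorted(m)) for m in r.matches} == expected
        assert r.ambiguous

    def test_length_mismatch_is_internal_error(self, ugt1a5_encoded):
        v = SampleGeneVector("S", "UGT1A5", (0, 0))
        with pytest.raises(ConsistencyError):
            match_diplotype(v, enumerate_diplotypes(ugt1a5_encoded))

    @given(st.integers(0, 10_000), st.data())
    @settings(max_examples=60, deadline=None)
    def test_matching_equals_brute_force_oracle(self, seed, data):
        """Sum-vector matching returns exactly the pairs found by independent
        brute-force enumeration over the raw allele matrix."""
        rng = np.random.default_rng(seed)
        try:
            t = curate(
                generate_table(
                    "G",
                    n_variants=int(rng.integers(1, 11)),
                    n_haplotypes=int(rng.integers(1, 9)),
                    max_minors=3,
                    seed=seed,
                )
            )
        except PgxError:  # more haplotypes requested than combinations exist
            assume(False)
        e = encode_numeric(t)
        ann = derive_annotation([t])
        # draw a genotype consistent with a random haplotype pair
        names = list(t.haplotype_names)
        a = data.draw(st.sampled_from(names))
        b = data.draw(st.sampled_from(names))
        genotype = {
            rsid: (t.alleles.at[rsid, a], t.alleles.at[rsid, b])
            for rsid in t.variant_ids
        }
        profile = GenotypeProfile(
            "S", {rsid: GenotypeCall(pair) for rsid, pair in genotype.items()}
        )
        r = match_diplotype(
            encode_sample(profile, e, ann), enumerate_diplotypes(e)
        )
        assert {tuple(sorted(m)) for m in r.matches} == oracle_match(t.alleles, genotype)
        assert tuple(sorted((a, b))) in {tuple(sorted(m)) for m in r.matches}


class TestPhenotype:
    @pytest.mark.parametrize(
        "pair,expected,color",
        [
            (("*1", "*1"), Phenotype.WT_WT, "green"),
            (("*1", "*2"), Phenotype.WT_VAR, "yellow"),
            (("*2", "*3"), Phenotype.VAR_VAR, "red"),
        ],
    )
    def test_three_colour_scheme(self, pair, expected, color):
        r = TranslationResult("S", "G", (pair,), Phenotype.NO_CALL)
        assert assign_phenotype(r, "*1") is expected
        assert expected.color == color

    def test_ambiguous_matches_report_most_severe(self):
        r = TranslationResult("S", "G", (("*1", "*2"), ("*2", "*3")), Phenotype.NO_CALL)
        assert assign_phenotype(r, "*1") is Phenotype.VAR_VAR

    def test_empty_matches_are_nocall(self):
        r = TranslationResult("S", "G", (), Phenotype.NO_CALL)
        assert assign_phenotype(r, "*1") is Phenotype.NO_CALL


class TestVariantTranslation:
    def test_homozygous_minor_is_var_var(self, ugt1a5_annotation):
        # two minor alleles, same or different, classify as Var/Var
        assert (
            translate_variant(("G", "G"), "rs12475068", ugt1a5_annotation)
            is Phenotype.VAR_VAR
        )

    def test_both_major_wt_wt(self, ugt1a5_annotation):
        assert translate_variant(("C", "C"), "rs12475068", ugt1a5_annotation) is Phenotype.WT_WT

    def test_heterozygous_wt_var(self, ugt1a5_annotation):
        assert translate_variant(("C", "G"), "rs12475068", ugt1a5_annotation) is Phenotype.WT_VAR

    def test_missing_call_nocall(self, ugt1a5_annotation):
        assert translate_variant(None, "rs12475068", ugt1a5_annotation) is Phenotype.NO_CALL

    def test_severity_monotone_in_minor_allele_count(self, ugt1a5_annotation):
        """Adding a minor allele never makes the per-variant call less severe."""
        severities = [
            translate_variant(alleles, "rs12475068", ugt1a5_annotation).severity
            for alleles in [("C", "C"), ("C", "G"), ("G", "G")]
        ]
        assert severities == sorted(severities)


def _results(spec):
    """Build TranslationResults from (sample, gene, phenotype) triples."""
    out = []
    for sample, gene, pheno in spec:
        matches = () if pheno is Phenotype.NO_CALL else (("*1", "*1"),)
        out.append(TranslationResult(sample, gene, matches, pheno))
    return out


class TestSummaries:
    def test_gene_summary_simple_split(self):
        res = _results([("A", "G1", Phenotype.WT_WT), ("B", "G1", Phenotype.VAR_VAR)])
        table = summarize_by_gene(res)
        assert list(table.loc["G1"]) == [50.0, 0.0, 50.0, 0.0]

    def test_all_wt(self):
        res = _results([(s, "G1", Phenotype.WT_WT) for s in "ABC"])
        assert list(summarize_by_gene(res).loc["G1"]) == [100.0, 0.0, 0.0, 0.0]

    def test_sample_summary_thirds_sum_to_100(self):
        res = _results(
            [("A", "G1", Phenotype.WT_WT), ("A", "G2", Phenotype.WT_VAR), ("A", "G3", Phenotype.WT_VAR)]
        )
        row = summarize_by_sample(res).loc["A"]
        assert row["WT/Var"] == pytest.approx(66.7)
        assert sum(row) == pytest.approx(100.0)

    def test_all_nocall_sample(self):
        res = _results([("A", "G1", Phenotype.NO_CALL), ("A", "G2", Phenotype.NO_CALL)])
        assert list(summarize_by_sample(res).loc["A"]) == [0.0, 0.0, 0.0, 100.0]

    def test_random_cohort_matches_tally_oracle(self):
        rng = np.random.default_rng(11)
        phenos = [Phenotype.WT_WT, Phenotype.WT_VAR, Phenotype.VAR_VAR, Phenotype.NO_CALL]
        spec = [
            (f"S{i}", f"G{j}", phenos[rng.integers(4)])
            for i, j in itertools.product(range(7), range(5))
        ]
        res = _results(spec)
        for by, table in (("gene", summarize_by_gene(res)), ("sample", summarize_by_sample(res))):
            expected = oracle_tally(res, by)
            for key, pcts in expected.items():
                got = dict(table.loc[key])
                # the 1-dp rounding residual lands on the largest category
                assert sum(got.values()) == pytest.approx(100.0, abs=0.05)
                for cat in pcts:
                    assert got[cat] == pytest.approx(pcts[cat], abs=0.11)
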