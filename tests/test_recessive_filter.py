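import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhucscreen.recessive_filter import (
    FilterConfig,
    ZygosityClass,
    collect_biallelic,
    filter_by_maf,
    filter_consequence,
    filter_inhouse,
    run_cascade,
)
from rhucscreen.variant_model import (
    Consequence,
    Genotype,
    IndividualRecord,
    Sex,
    VariantAnnotation,
)

CONSEQUENCES = [c.value for c in Consequence]
SOURCES = ["gnomad", "exac", "kg1000p3", "dbsnp"]


def _var(i, chrom="11", gene="SLC22A12", csq="missense", freqs=None,
         inhouse=False, known=False):
    return VariantAnnotation(
        chrom=chrom, pos=1000 + i, ref="G", alt="A", gene=gene, consequence=csq,
        freq_sources=freqs or {}, inhouse_hom=inhouse, known_pathogenic=known,
    )


variant_strategy = st.builds(
    _var,
    i=st.integers(0, 500),
    chrom=st.sampled_from(["1", "11", "X"]),
    gene=st.sampled_from(["G1", "G2", "SLC22A12"]),
    csq=st.sampled_from(CONSEQUENCES),
    freqs=st.dictionaries(
        st.sampled_from(SOURCES), st.floats(0.0, 1.0), max_size=3
    ),
    inhouse=st.booleans(),
)


class TestMafFilter:
    def test_common_variant_removed(self):
        assert filter_by_maf([_var(1, freqs={"gnomad": 0.05})]) == []

    def test_rare_reference_variant_retained(self):
        # the rarest bundled allele frequency from the reference data
        v = _var(1, freqs={"gnomad": 0.000044})
        assert filter_by_maf([v]) == [v]

    def test_no_evidence_survives(self):
        v = _var(1, freqs={})
        assert filter_by_maf([v]) == [v]

    def test_threshold_is_strict_greater(self):
        v = _var(1, freqs={"gnomad": 0.01})
        assert filter_by_maf([v]) == [v]

    @given(variants=st.lists(variant_strategy, max_size=25))
    @settings(max_examples=60, deadline=None)
    def test_brute_force_source_oracle(self, variants):
        config = FilterConfig()
        result = filter_by_maf(variants, config)
        expected = [
            v for v in variants
            if not any(af > config.maf_threshold for af in v.freq_sources.values())
        ]
        assert result == expected
        # both aggregation policies agree: any-source-exceeds == max-exceeds
        alt = filter_by_maf(
            variants, FilterConfig(maf_policy="max_across_sources")
        )
        assert alt == expected

    @given(
        variants=st.lists(variant_strategy, max_size=25),
        thresholds=st.tuples(st.floats(0.001, 0.99), st.floats(0.001, 0.99)),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_threshold(self, variants, thresholds):
        lo, hi = sorted(thresholds)
        kept_lo = filter_by_maf(variants, FilterConfig(maf_threshold=lo))
        kept_hi = filter_by_maf(variants, FilterConfig(maf_threshold=hi))
        assert {v.key for v in kept_lo} <= {v.key for v in kept_hi}


class TestInhouseFilter:
    def test_inhouse_hom_removed(self):
        assert filter_inhouse([_var(1, inhouse=True)]) == []

    def test_het_only_in_controls_retained(self):
        # only hom/hemizygous presence in controls disqualifies
        v = _var(1, inhouse=False)
        assert filter_inhouse([v]) == [v]

    @given(variants=st.lists(variant_strategy, max_size=25))
    @settings(max_examples=40, deadline=None)
    def test_idempotent(self, variants):
        once = filter_inhouse(variants)
        assert filter_inhouse(once) == once


class TestConsequenceFilter:
    def test_stop_gained_retained(self):
        v = _var(1, csq="stop_gained")
        assert filter_consequence([v]) == [v]

    def test_synonymous_removed(self):
        assert filter_consequence([_var(1, csq="synonymous")]) == []

    def test_other_removed(self):
        assert filter_consequence([_var(1, csq="other")]) == []

    @given(variants=st.lists(variant_strategy, max_size=25))
    @settings(max_examples=60, deadline=None)
    def test_set_membership_oracle(self, variants):
        config = FilterConfig()
        assert filter_consequence(variants, config) == [
            v for v in variants if v.consequence in config.consequence_keep
        ]


class TestStepAlgebra:
    @given(variants=st.lists(variant_strategy, max_size=20))
    @settings(max_examples=40, deadline=None)
    def test_variant_steps_commute(self, variants):
        config = FilterConfig()
        orders = [
            filter_consequence(filter_inhouse(filter_by_maf(variants, config)), config),
            filter_by_maf(filter_consequence(filter_inhouse(variants), config), config),
            filter_inhouse(filter_by_maf(filter_consequence(variants, config), config)),
        ]
        keys = [{v.key for v in out} for out in orders]
        assert keys[0] == keys[1] == keys[2]

    @given(variants=st.lists(variant_strategy, max_size=20))
    @settings(max_examples=40, deadline=None)
    def test_survival_counts_non_increasing(self, variants):
        _, counts = run_cascade([], variants)
        assert (
            counts.n_variants_input
            >= counts.after_maf
            >= counts.after_inhouse
            >= counts.after_consequence
        )


class TestCollectBiallelic:
    def _individual(self, genotypes, sex=Sex.FEMALE):
        return IndividualRecord("S1", sex, 0.8, genotypes=genotypes)

    def test_homozygous(self):
        v = _var(1, csq="stop_gained", known=True)
        res = collect_biallelic(self._individual([Genotype(v.key, 2)]), [v])
        assert res.gene == "SLC22A12"
        assert res.zygosity_class is ZygosityClass.HOMOZYGOUS
        assert res.qualifying_alleles == [(v.key, 2)]

    def test_compound_het_unphased(self):
        v1, v2 = _var(1, known=True), _var(2, csq="stop_gained", known=True)
        res = collect_biallelic(
            self._individual([Genotype(v1.key, 1), Genotype(v2.key, 1)]), [v1, v2]
        )
        assert res.zygosity_class is ZygosityClass.COMPOUND_HET
        assert res.phase_resolved is False

    def test_single_het_excluded(self):
        v = _var(1)
        res = collect_biallelic(self._individual([Genotype(v.key, 1)]), [v])
        assert res.zygosity_class is ZygosityClass.NONE
        assert res.gene is None

    def test_two_hets_different_genes_excluded(self):
        v1, v2 = _var(1, gene="G1"), _var(2, gene="G2")
        res = collect_biallelic(
            self._individual([Genotype(v1.key, 1), Genotype(v2.key, 1)]), [v1, v2]
        )
        assert res.zygosity_class is ZygosityClass.NONE

    def test_hemizygous_male_x(self):
        v = _var(1, chrom="X", gene="GX")
        res = collect_biallelic(
            self._individual([Genotype(v.key, 1, hemizygous=True)], sex=Sex.MALE),
            [v],
        )
        assert res.zygosity_class is ZygosityClass.HEMIZYGOUS

    def test_female_single_x_het_excluded(self):
        v = _var(1, chrom="X", gene="GX")
        res = collect_biallelic(
            self._individual([Genotype(v.key, 1)], sex=Sex.FEMALE), [v]
        )
        assert res.zygosity_class is ZygosityClass.NONE

    def test_hom_dominates_extra_hets(self):
        v1, v2 = _var(1), _var(2)
        res = collect_biallelic(
            self._individual([Genotype(v1.key, 2), Genotype(v2.key, 1)]), [v1, v2]
        )
        assert res.zygosity_class is ZygosityClass.HOMOZYGOUS

    def test_multi_gene_reports_all(self):
        a1, a2 = _var(1, gene="AAA"), _var(2, gene="AAA")
        b1, b2 = _var(3, gene="BBB", known=True), _var(4, gene="BBB", known=True)
        res = collect_biallelic(
            self._individual(
                [Genotype(v.key, 1) for v in (a1, a2, b1, b2)]
            ),
            [a1, a2, b1, b2],
        )
        # known-pathogenic majority ranks BBB first despite lexicographic AAA
        assert res.gene == "BBB"
        assert set(res.gene_alleles) == {"AAA", "BBB"}

    def test_genotype_at_filtered_variant_ignored(self):
        v = _var(1, csq="synonymous")
        res = collect_biallelic(self._individual([Genotype(v.key, 2)]), [])
        assert res.zygosity_class is ZygosityClass.NONE


class TestRunCascade:
    def test_reference_discovery_yield(self, discovery_cohort):
        individuals, variants = discovery_cohort
        results, _ = run_cascade(individuals, variants)
        slc = [
            r for r in results
            if r.diagnosed and "SLC22A12" in r.gene_alleles
        ]
        assert len(slc) == 27

    def test_empty_variants_all_none(self, discovery_cohort):
        individuals, _ = discovery_cohort
        results, counts = run_cascade(individuals, [])
        assert all(r.zygosity_class is ZygosityClass.NONE for r in results)
        assert counts.n_diagnosed == 0

    def test_simulation_truth_oracle(self):
        from rhucscreen.synthetic_cohort import SimulationConfig, simulate_cohort

        cfg = SimulationConfig(
            n_individuals=2000, seed=31,
            panel_freqs={"trp258_stop": 0.05, "arg90_his": 0.04},
            other_pathogenic_freq=0.01, other_gene_fraction=0.003,
            transient_rate=0.0,
        )
        individuals, variants, truth = simulate_cohort(cfg)
        results, _ = run_cascade(individuals, variants)
        diagnosed = {r.individual_id for r in results if r.diagnosed}
        expected = set(truth.loc[truth["class"] == "biallelic_carrier", "id"])
        assert diagnosed == expected

    @given(
        gene_alleles=st.lists(
            st.tuples(st.sampled_from(["G1", "G2", "G3"]), st.just(1)),
            max_size=3,
            unique_by=lambda t: t[0],
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_at_most_one_allele_per_gene_never_diagnosed(self, gene_alleles):
        variants = [
            _var(i, gene=gene, known=True) for i, (gene, _) in enumerate(gene_alleles)
        ]
        ind = IndividualRecord(
            "S1", Sex.FEMALE, 0.5,
            genotypes=[Genotype(v.key, 1) for v in variants],
        )
        results, _ = run_cascade([ind], variants)
        assert results[0].zygosity_class is ZygosityClass.NONE
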