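"""The retention funnel and genotype-pattern flagging."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonevar import (
    CandidateGene,
    Consequence,
    FilterStage,
    Inheritance,
    PatternType,
    VariantRecord,
    Zygosity,
    consequence_filter,
    frequency_filter,
    genotype_patterns,
    qd_filter,
    run_funnel,
)

from .test_variant_model import make_variant


@pytest.fixture(scope="module")
def mini_panel():
    return [
        CandidateGene("COL1A2", Inheritance.DOMINANT, "7", 94023873, 94060544),
        CandidateGene("TCIRG1", Inheritance.RECESSIVE, "11", 67806077, 67818324),
        CandidateGene("PLS3", Inheritance.DOMINANT, "X", 114795465, 114885190, is_x_linked=True),
    ]


class TestQdFilter:
    @pytest.mark.parametrize(
        "qd,kept", [(5.0, False), (5.01, True), (0.0, False), (100.0, True)]
    )
    def test_boundary(self, qd, kept):
        retained, traces = qd_filter([make_variant(qd=qd)])
        assert (len(retained) == 1) is kept
        assert traces[0].retained is kept

    def test_absent_qd_retained_with_note(self):
        retained, traces = qd_filter([make_variant(qd=None)])
        assert len(retained) == 1
        assert "qd absent" in traces[0].note

    def test_empty_input(self):
        assert qd_filter([]) == ([], [])


class TestConsequenceFilter:
    @pytest.mark.parametrize(
        "consequence,kept",
        [
            (Consequence.STOPGAIN, True),
            (Consequence.NONSYNONYMOUS, True),
            (Consequence.SPLICING, True),
            (Consequence.STOPLOSS, True),
            (Consequence.UTR, True),
            (Consequence.FRAMESHIFT_INDEL, True),
            (Consequence.INFRAME_INDEL, True),
            (Consequence.SYNONYMOUS, False),
            (Consequence.OTHER, False),
        ],
    )
    def test_restriction(self, consequence, kept):
        ref, alt = ("AT", "A") if "indel" in consequence.value else ("A", "G")
        variant = make_variant(consequence=consequence, ref=ref, alt=alt)
        assert (consequence_filter([variant]) == [variant]) is kept


class TestFrequencyFilter:
    def test_dominant_cutoff_removes_common(self, mini_panel):
        v = make_variant(gene="COL1A2", af_db1=0.002)
        assert frequency_filter([v], mini_panel) == []

    def test_recessive_cutoff_keeps_intermediate(self, mini_panel):
        v = make_variant(gene="TCIRG1", af_db1=0.005)
        assert frequency_filter([v], mini_panel) == [v]

    def test_absent_frequency_always_rare(self, mini_panel):
        for gene in ("COL1A2", "TCIRG1"):
            v = make_variant(gene=gene, af_db1=None, af_db2=None)
            assert frequency_filter([v], mini_panel) == [v]

    def test_strict_inequality_at_cutoff(self, mini_panel):
        v = make_variant(gene="COL1A2", af_db1=0.001)
        assert frequency_filter([v], mini_panel) == []

    def test_max_over_databases(self, mini_panel):
        v = make_variant(gene="COL1A2", af_db1=0.0001, af_db2=0.005)
        assert frequency_filter([v], mini_panel) == []

    def test_non_panel_gene_dropped_with_warning(self, mini_panel):
        v = make_variant(gene="BRCA1")
        with pytest.warns(UserWarning, match="BRCA1"):
            assert frequency_filter([v], mini_panel) == []


@st.composite
def funnel_variants(draw):
    n = draw(st.integers(0, 12))
    out = []
    for i in range(n):
        out.append(
            VariantRecord(
                patient_id=f"P{draw(st.integers(1, 3))}",
                chrom="7",
                pos=94023873 + i,
                ref="A",
                alt="G",
                gene=draw(st.sampled_from(["COL1A2", "TCIRG1"])),
                consequence=draw(st.sampled_from(list(Consequence))),
                zygosity=draw(st.sampled_from([Zygosity.HET, Zygosity.HOM])),
                qd=draw(st.one_of(st.none(), st.floats(0, 40))),
                af_db1=draw(st.one_of(st.none(), st.floats(0, 0.05))),
            )
        )
    return out


class TestFunnel:
    @given(funnel_variants())
    @settings(deadline=None, max_examples=50)
    def test_count_conservation_and_idempotence(self, variants):
        panel = [
            CandidateGene("COL1A2", Inheritance.DOMINANT, "7", 94023873, 94060544),
            CandidateGene("TCIRG1", Inheritance.RECESSIVE, "11", 67806077, 67818324),
        ]
        retained, traces = run_funnel(variants, panel)
        assert len(traces) == len(variants)
        assert sum(t.retained for t in traces) == len(retained)
        assert sum(not t.retained for t in traces) == len(variants) - len(retained)
        for t in traces:
            assert t.retained == (t.stage_removed is FilterStage.NONE)
        # idempotence: the funnel is a no-op on its own output
        again, again_traces = run_funnel(retained, panel)
        assert again == retained
        assert all(t.retained for t in again_traces)


class TestGenotypePatterns:
    def test_single_het_in_recessive_gene_is_carrier(self, mini_panel):
        v = make_variant(gene="TCIRG1", chrom="11", consequence=Consequence.STOPGAIN)
        patterns = genotype_patterns([v], mini_panel)
        assert [p.pattern for p in patterns] == [PatternType.RECESSIVE_CARRIER]

    def test_two_distinct_hets_make_compound_het(self, mini_panel):
        v1 = make_variant(gene="TCIRG1", chrom="11", pos=67815000)
        v2 = make_variant(gene="TCIRG1", chrom="11", pos=67816000)
        patterns = genotype_patterns([v1, v2], mini_panel)
        assert [p.pattern for p in patterns] == [PatternType.RECESSIVE_COMPOUND_HET]
        assert patterns[0].note == "phase unknown"

    def test_same_site_twice_is_not_compound_het(self, mini_panel):
        v1 = make_variant(gene="TCIRG1", chrom="11", pos=67815000)
        patterns = genotype_patterns([v1, v1], mini_panel)
        assert [p.pattern for p in patterns] == [PatternType.RECESSIVE_CARRIER]

    def test_hom_in_recessive_gene(self, mini_panel):
        v = make_variant(gene="TCIRG1", chrom="11", zygosity=Zygosity.HOM)
        patterns = genotype_patterns([v], mini_panel)
        assert [p.pattern for p in patterns] == [PatternType.RECESSIVE_HOM]

    def test_dominant_het_and_hemizygous(self, mini_panel):
        het = make_variant(gene="COL1A2", chrom="7")
        hemi = make_variant(gene="PLS3", chrom="X", zygosity=Zygosity.HEMI, patient_id="P2")
        patterns = genotype_patterns([het, hemi], mini_panel)
        by_gene = {p.gene: p.pattern for p in patterns}
        assert by_gene == {
            "COL1A2": PatternType.DOMINANT_HET,
            "PLS3": PatternType.HEMIZYGOUS,
        }

    @given(st.data())
    @settings(deadline=None, max_examples=40)
    def test_agrees_with_bruteforce_enumeration(self, data):
        """Pattern flags equal an exhaustive check of each (patient, gene)
        zygosity multiset."""
        panel = [
            CandidateGene("COL1A2", Inheritance.DOMINANT, "7", 94023873, 94060544),
            CandidateGene("TCIRG1", Inheritance.RECESSIVE, "11", 67806077, 67818324),
        ]
        variants = []
        n = data.draw(st.integers(0, 8))
        for _ in range(n):
            gene = data.draw(st.sampled_from(["COL1A2", "TCIRG1"]))
            variants.append(
                make_variant(
                    patient_id=f"P{data.draw(st.integers(1, 2))}",
                    gene=gene,
                    chrom="7" if gene == "COL1A2" else "11",
                    pos=data.draw(st.sampled_from([94023880, 94023890, 67806100, 67806200])),
                    zygosity=data.draw(st.sampled_from([Zygosity.HET, Zygosity.HOM])),
                )
            )
        got = {
            (p.patient_id, p.gene): p.pattern for p in genotype_patterns(variants, panel)
        }
        # brute force: group observations and derive the expected flag directly
        expected = {}
        keys = {(v.patient_id, v.gene) for v in variants}
        for pid, gene in keys:
            vs = [v for v in variants if v.patient_id == pid and v.gene == gene]
            mode = next(g.inheritance for g in panel if g.symbol == gene)
            if mode is Inheritance.DOMINANT:
                expected[(pid, gene)] = PatternType.DOMINANT_HET
            elif any(v.zygosity is Zygosity.HOM for v in vs):
                expected[(pid, gene)] = PatternType.RECESSIVE_HOM
            else:
                sites = {v.site() for v in vs if v.zygosity is Zygosity.HET}
                expected[(pid, gene)] = (
                    PatternType.RECESSIVE_COMPOUND_HET
                    if len(sites) >= 2
                    else PatternType.RECESSIVE_CARRIER
                )
        assert got == expected
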