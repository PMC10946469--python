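"""ACMG evidence combination, automatic assignment and the proxy classifier."""

import itertools

import pytest

from bonevar import (
    ClinVarStatus,
    Consequence,
    EvidenceProfile,
    Verdict,
    auto_assign_evidence,
    classify_variant,
    combine_acmg,
    proxy_classify,
    vus_cadd_report,
)
from bonevar.classification import (
    KNOWN_CODES,
    default_strength,
    is_benign_code,
)

from .test_variant_model import make_variant


def oracle_combine(codes: frozenset) -> Verdict:
    """Independent re-statement of the published combining table as explicit
    conditions over default-strength counts (no shared code with the engine)."""
    vs = sum(1 for c in codes if c == "PVS1")
    s = sum(1 for c in codes if c.startswith("PS"))
    m = sum(1 for c in codes if c.startswith("PM"))
    p = sum(1 for c in codes if c.startswith("PP"))
    ba = sum(1 for c in codes if c == "BA1")
    bs = sum(1 for c in codes if c.startswith("BS"))
    bp = sum(1 for c in codes if c.startswith("BP"))
    path = (
        (vs >= 1 and s >= 1)
        or (vs >= 1 and m >= 2)
        or (vs >= 1 and m >= 1 and p >= 1)
        or (vs >= 1 and p >= 2)
        or s >= 2
        or (s >= 1 and m >= 3)
        or (s >= 1 and m >= 2 and p >= 2)
        or (s >= 1 and m >= 1 and p >= 4)
    )
    lp = (
        (vs >= 1 and m >= 1)
        or (s >= 1 and m >= 1)
        or (s >= 1 and p >= 2)
        or m >= 3
        or (m >= 2 and p >= 2)
        or (m >= 1 and p >= 4)
    )
    ben = ba >= 1 or bs >= 2
    lb = (bs >= 1 and bp >= 1) or bp >= 2
    path_arm = Verdict.PATHOGENIC if path else Verdict.LIKELY_PATHOGENIC if lp else None
    ben_arm = Verdict.BENIGN if ben else Verdict.LIKELY_BENIGN if lb else None
    if path_arm and ben_arm:
        return Verdict.UNCERTAIN_SIGNIFICANCE
    return path_arm or ben_arm or Verdict.UNCERTAIN_SIGNIFICANCE


class TestCombineAcmg:
    @pytest.mark.parametrize(
        "codes,expected",
        [
            (("PVS1", "PM2"), Verdict.LIKELY_PATHOGENIC),
            ((), Verdict.UNCERTAIN_SIGNIFICANCE),
            (("PVS1", "PS1", "PM2"), Verdict.PATHOGENIC),
            (("BA1",), Verdict.BENIGN),
            (("PS1", "PM1", "PM2"), Verdict.LIKELY_PATHOGENIC),
            (("PS1", "PS2"), Verdict.PATHOGENIC),
            (("PS1", "PM1", "PM2", "PM4"), Verdict.PATHOGENIC),
            (("PM1", "PM2", "PM4"), Verdict.LIKELY_PATHOGENIC),
            (("BS1", "BP4"), Verdict.LIKELY_BENIGN),
            (("BP4", "BP7"), Verdict.LIKELY_BENIGN),
            (("PVS1", "PM2", "BA1"), Verdict.UNCERTAIN_SIGNIFICANCE),  # conflict
            (("PP3",), Verdict.UNCERTAIN_SIGNIFICANCE),
        ],
    )
    def test_examples(self, codes, expected):
        assert combine_acmg(EvidenceProfile.from_codes(codes)).verdict is expected

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="PX9"):
            EvidenceProfile.from_codes(["PX9"])

    def test_exhaustive_against_oracle_up_to_size_3(self):
        """Engine verdicts equal the brute-force table lookup for every
        evidence set of at most three codes."""
        codes = sorted(KNOWN_CODES)
        for r in (0, 1, 2, 3):
            for combo in itertools.combinations(codes, r):
                got = combine_acmg(EvidenceProfile.from_codes(combo)).verdict
                assert got is oracle_combine(frozenset(combo)), combo

    def test_strength_override_changes_verdict(self):
        # PM2 downgraded to supporting: PVS1 + 1 supporting is not enough
        from bonevar import Strength

        profile = EvidenceProfile({"PVS1": None, "PM2": Strength.SUPPORTING})
        assert combine_acmg(profile).verdict is Verdict.UNCERTAIN_SIGNIFICANCE


class TestAutoAssign:
    def test_lof_rare_high_cadd(self):
        v = make_variant(
            consequence=Consequence.STOPGAIN, af_db1=1e-5, cadd=39.0
        )
        codes = set(auto_assign_evidence(v).codes)
        assert codes == {"PVS1", "PM2", "PP3"}

    def test_pp3_strictly_above_15(self):
        assert "PP3" not in auto_assign_evidence(make_variant(cadd=15.0)).codes
        assert "PP3" in auto_assign_evidence(make_variant(cadd=15.01)).codes

    def test_pm2_strictly_below_1e4(self):
        assert "PM2" not in auto_assign_evidence(make_variant(af_db1=1e-4)).codes
        assert "PM2" in auto_assign_evidence(make_variant(af_db1=9e-5)).codes

    def test_clinvar_mappings(self):
        assert "PS1" in auto_assign_evidence(
            make_variant(clinvar=ClinVarStatus.PATHOGENIC)
        ).codes
        assert "PP5" in auto_assign_evidence(
            make_variant(clinvar=ClinVarStatus.LIKELY_PATHOGENIC)
        ).codes
        benign = auto_assign_evidence(
            make_variant(clinvar=ClinVarStatus.BENIGN, af_db1=0.3)
        )
        assert set(benign.codes) == {"BP6"}

    def test_non_canonical_splice_is_not_pvs1(self):
        v = make_variant(consequence=Consequence.SPLICING, canonical_splice=False)
        assert "PVS1" not in auto_assign_evidence(v).codes


class TestProxyClassify:
    def test_lof_rare_asserted_is_likely_pathogenic(self):
        v = make_variant(
            consequence=Consequence.STOPGAIN,
            cadd=39.0,
            clinvar=ClinVarStatus.PATHOGENIC,
        )
        assert proxy_classify(v).verdict is Verdict.LIKELY_PATHOGENIC

    def test_low_cadd_fails_computational_arm(self):
        v = make_variant(af_db1=1e-5, cadd=12.0)
        assert proxy_classify(v).verdict is Verdict.UNCERTAIN_SIGNIFICANCE

    def test_clinvar_benign_bucket(self):
        assert (
            proxy_classify(make_variant(clinvar=ClinVarStatus.BENIGN)).verdict
            is Verdict.BENIGN
        )
        assert (
            proxy_classify(make_variant(clinvar=ClinVarStatus.LIKELY_BENIGN)).verdict
            is Verdict.LIKELY_BENIGN
        )

    def test_unscored_non_lof_indel_cannot_qualify(self):
        """An in-frame indel without a CADD score fails the computational
        arm even when ClinVar asserts it (likely) pathogenic."""
        v = make_variant(
            consequence=Consequence.INFRAME_INDEL,
            ref="AGAC",
            alt="A",
            cadd=None,
            clinvar=ClinVarStatus.LIKELY_PATHOGENIC,
        )
        assert proxy_classify(v).verdict is Verdict.UNCERTAIN_SIGNIFICANCE

    def test_unscored_frameshift_does_qualify(self):
        v = make_variant(
            consequence=Consequence.FRAMESHIFT_INDEL, ref="AG", alt="A", cadd=None
        )
        assert proxy_classify(v).verdict is Verdict.LIKELY_PATHOGENIC

    def test_never_more_permissive_than_engine_outside_assertion_arm(self):
        """Wherever the proxy calls (likely) pathogenic through the LOF or
        ClinVar-pathogenic route, the full engine on the auto-derived profile
        agrees at likely-pathogenic or stronger. The likely-pathogenic
        ClinVar assertion route is the documented exception: a supporting-
        level assertion plus rarity and computational support does not reach
        likely pathogenic under the combining table."""
        grid = itertools.product(
            [Consequence.STOPGAIN, Consequence.NONSYNONYMOUS, Consequence.SPLICING,
             Consequence.INFRAME_INDEL],
            [None, 10.0, 16.0, 30.0],
            [None, 5e-5, 5e-4],
            [ClinVarStatus.ABSENT, ClinVarStatus.PATHOGENIC,
             ClinVarStatus.LIKELY_PATHOGENIC, ClinVarStatus.UNCERTAIN],
        )
        strong = {Verdict.PATHOGENIC, Verdict.LIKELY_PATHOGENIC}
        for consequence, cadd, af, clinvar in grid:
            v = make_variant(
                consequence=consequence, cadd=cadd, af_db1=af, clinvar=clinvar
            )
            if proxy_classify(v).verdict not in strong:
                continue
            engine = combine_acmg(auto_assign_evidence(v)).verdict
            via_assertion_only = (
                not v.is_lof and clinvar is ClinVarStatus.LIKELY_PATHOGENIC
            )
            if via_assertion_only:
                continue
            assert engine in strong, (consequence, cadd, af, clinvar)


class TestVusReport:
    def _classified(self, variant):
        return variant, classify_variant(variant)

    def test_cadd_boundary(self):
        included = make_variant(cadd=20.0, af_db1=0.005)
        excluded = make_variant(cadd=19.9, af_db1=0.005)
        report = vus_cadd_report([self._classified(included), self._classified(excluded)])
        assert [v.cadd for v, _ in report] == [20.0]

    def test_unscored_indel_included(self):
        v = make_variant(
            consequence=Consequence.INFRAME_INDEL, ref="ATGT", alt="A",
            cadd=None, af_db1=0.005,
        )
        report = vus_cadd_report([self._classified(v)])
        assert len(report) == 1

    def test_only_vus_reported(self):
        pathogenic = make_variant(
            consequence=Consequence.STOPGAIN, cadd=40.0,
            curated_evidence=("PVS1", "PS1", "PM2"),
        )
        assert vus_cadd_report([self._classified(pathogenic)]) == []


class TestFixtureClassification:
    def test_engine_reproduces_published_verdicts(self, example_fixture):
        verdicts = {}
        for v in example_fixture.variants:
            if v.curated_evidence is not None:
                verdicts[(v.patient_id, v.gene)] = classify_variant(v).verdict
        assert verdicts[("S1", "PLS3")] is Verdict.PATHOGENIC
        assert verdicts[("S2", "PLS3")] is Verdict.PATHOGENIC
        assert verdicts[("S3", "ALPL")] is Verdict.PATHOGENIC
        assert verdicts[("S4", "COL1A2")] is Verdict.LIKELY_PATHOGENIC
        assert verdicts[("S5", "ALPL")] is Verdict.LIKELY_PATHOGENIC
        assert verdicts[("S6", "COL1A2")] is Verdict.LIKELY_PATHOGENIC
        assert verdicts[("S7", "COL1A2")] is Verdict.LIKELY_PATHOGENIC
        assert verdicts[("S15", "LRP5")] is Verdict.LIKELY_PATHOGENIC
        assert verdicts[("NS2", "TCIRG1")] is Verdict.LIKELY_PATHOGENIC

    def test_proxy_differs_from_engine_only_by_unscored_non_lof(self, example_fixture):
        """The proxy misses exactly the carriers whose qualifying variant has
        neither a CADD score nor LOF status (the in-frame deletion case)."""
        engine_carriers, proxy_carriers = set(), set()
        for v in example_fixture.variants:
            if classify_variant(v).verdict in (
                Verdict.PATHOGENIC, Verdict.LIKELY_PATHOGENIC
            ):
                engine_carriers.add(v.patient_id)
            if proxy_classify(v).verdict in (
                Verdict.PATHOGENIC, Verdict.LIKELY_PATHOGENIC
            ):
                proxy_carriers.add(v.patient_id)
        assert proxy_carriers < engine_carriers
        missed = engine_carriers - proxy_carriers
        assert missed == {"S5"}
        for v in example_fixture.variants:
            if v.patient_id in missed and v.curated_evidence is not None:
                assert v.cadd is None and not v.is_lof
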