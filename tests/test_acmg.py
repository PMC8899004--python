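from itertools import combinations

import pytest

import _oracles
from fibrovar.acmg import (
    ALL_CODES,
    Classification,
    EvidenceCode,
    EvidenceProfile,
    Strength,
    Tier,
    apply_vus_plus,
    auto_evidence,
    classify_callset,
    combine,
    merge_manual_evidence,
    read_manual_evidence,
    tier_summary,
)
from fibrovar.models import AnnotationRecord


def profile(*codes):
    p = EvidenceProfile(variant_id="x")
    for c in codes:
        p.add(EvidenceCode(c) if isinstance(c, str) else c)
    return p


class TestCombine:
    @pytest.mark.parametrize(
        "codes,tier",
        [
            (("PVS1", "PS1"), Tier.PATHOGENIC),
            (("PS1", "PM1", "PM2"), Tier.LIKELY_PATHOGENIC),
            (("PM2", "PP3"), Tier.VUS),
            (("BA1", "PS1"), Tier.VUS),  # contradictory evidence
            (("PVS1", "PM2"), Tier.LIKELY_PATHOGENIC),
            (("PVS1", "PM2", "PP3"), Tier.PATHOGENIC),
            (("PS1", "PS3"), Tier.PATHOGENIC),
            (("PM1", "PM2", "PM5"), Tier.LIKELY_PATHOGENIC),
            (("PM1", "PM2", "PP3", "PP5"), Tier.LIKELY_PATHOGENIC),
            (("BA1",), Tier.BENIGN),
            (("BS1", "BS2"), Tier.BENIGN),
            (("BS1", "BP4"), Tier.LIKELY_BENIGN),
            (("BP4", "BP6"), Tier.LIKELY_BENIGN),
            (("BS1",), Tier.VUS),
            ((), Tier.VUS),
        ],
    )
    def test_rule_table_cases(self, codes, tier):
        assert combine(profile(*codes)).tier is tier

    def test_strength_override_respected(self):
        # PS1 demoted to moderate no longer makes 1-strong+2-moderate
        demoted = profile(EvidenceCode("PS1", Strength.MODERATE), "PM1", "PM2")
        assert combine(demoted).tier is Tier.LIKELY_PATHOGENIC  # 3 moderates
        assert combine(profile(EvidenceCode("PS1", Strength.SUPPORTING), "PM2")).tier is Tier.VUS

    def test_exhaustive_agreement_with_clause_oracle(self):
        """combine matches the clause-enumeration oracle for every profile
        of up to four distinct codes at native strengths."""
        codes = sorted(ALL_CODES)
        checked = 0
        for size in range(5):
            for subset in combinations(codes, size):
                p = profile(*subset)
                assert combine(p).tier.value == _oracles.oracle_combine_label(p), subset
                checked += 1
        assert checked > 20_000

    def test_order_independence(self):
        a = profile("PM2", "PS1", "PP3")
        b = profile("PP3", "PM2", "PS1")
        assert combine(a) == combine(b)

    def test_monotonicity_on_small_profiles(self):
        """Adding pathogenic evidence never moves the call toward Benign and
        vice versa, over all 1-3 code profiles plus one added code."""
        order = {
            Tier.BENIGN: 0, Tier.LIKELY_BENIGN: 1, Tier.VUS: 2,
            Tier.LIKELY_PATHOGENIC: 3, Tier.PATHOGENIC: 4,
        }
        codes = sorted(ALL_CODES)
        for size in (1, 2, 3):
            for subset in combinations(codes, size):
                base = order[combine(profile(*subset)).tier]
                for extra in codes:
                    if extra in subset:
                        continue
                    new = order[combine(profile(*subset, extra)).tier]
                    if extra.startswith(("PVS", "PS", "PM", "PP")):
                        assert new >= base, (subset, extra)
                    else:
                        assert new <= base, (subset, extra)


class TestVusPlus:
    def test_borderline_profile_upgrades(self):
        p = profile("PM1", "PM2", "PP3")
        base = combine(p)
        assert base.tier is Tier.VUS
        result = apply_vus_plus(p, base)
        assert result.vus_plus and result.tier is Tier.VUS

    def test_insufficient_profile_stays_plain_vus(self):
        p = profile("PM2")
        result = apply_vus_plus(p, combine(p))
        assert result.tier is Tier.VUS and not result.vus_plus

    def test_non_vus_untouched(self):
        p = profile("PVS1", "PS1")
        base = combine(p)
        assert apply_vus_plus(p, base) == base

    def test_conflicting_profile_never_upgrades(self):
        # pathogenic-side boost cannot rescue evidence that also qualifies benign
        p = profile("PM1", "PM2", "PP3", "BA1")
        result = apply_vus_plus(p, combine(p))
        assert not result.vus_plus

    def test_vus_plus_invariant(self):
        with pytest.raises(ValueError):
            Classification(Tier.PATHOGENIC, vus_plus=True)


def make_annotation(**kwargs):
    base = dict(variant_id="1:1 G>A", gene_symbol="MYH7", consequence="missense_variant")
    base.update(kwargs)
    return AnnotationRecord(**base)


class TestAutoEvidence:
    def test_rare_clinvar_pathogenic_missense(self, panel):
        a = make_annotation(
            gnomad_af=1.28e-4, clinvar_assertion="path_or_lp",
            polyphen_call="probably_damaging", sift_call="deleterious",
            cadd_phred=26.0, fathmm_call="damaging",
        )
        codes = auto_evidence(a, panel=panel).code_names()
        assert codes == {"PM2", "PP5", "PP3"}

    def test_common_variant_gets_ba1(self, panel):
        a = make_annotation(gnomad_af=0.10)
        assert "BA1" in auto_evidence(a, panel=panel).code_names()

    def test_lof_in_lof_mechanism_gene(self, panel):
        a = make_annotation(gene_symbol="MYBPC3", consequence="stop_gained")
        codes = auto_evidence(a, panel=panel).code_names()
        assert {"PVS1", "PM2"} <= codes

    def test_lof_outside_lof_mechanism_gene_no_pvs1(self, panel):
        a = make_annotation(gene_symbol="MYH7", consequence="stop_gained")
        assert "PVS1" not in auto_evidence(a, panel=panel).code_names()

    def test_bs1_band(self, panel):
        a = make_annotation(gnomad_af=0.01)
        codes = auto_evidence(a, panel=panel).code_names()
        assert "BS1" in codes and "BA1" not in codes and "PM2" not in codes

    def test_benign_insilico_consensus_gives_bp4(self, panel):
        a = make_annotation(polyphen_call="benign", sift_call="tolerated", cadd_phred=2.0)
        assert "BP4" in auto_evidence(a, panel=panel).code_names()

    def test_conflicting_clinvar_contributes_nothing(self, panel):
        a = make_annotation(clinvar_assertion="conflicting")
        codes = auto_evidence(a, panel=panel).code_names()
        assert not codes & {"PP5", "BP6"}

    def test_clinvar_codes_can_be_disabled(self, panel):
        a = make_annotation(clinvar_assertion="pathogenic")
        assert "PP5" not in auto_evidence(a, panel=panel, use_clinvar_codes=False).code_names()

    def test_family_study_codes_never_assigned(self, panel):
        # PS2/BS4/PP1/PP4 need segregation or de-novo data absent from files
        a = make_annotation(
            gnomad_af=1e-6, clinvar_assertion="pathogenic",
            polyphen_call="probably_damaging", cadd_phred=30.0,
        )
        assert not auto_evidence(a, panel=panel).code_names() & {"PS2", "BS4", "PP1", "PP4"}


class TestCallsetAndManualEvidence:
    def test_table2_profiles_reproduce_published_tiers(self, table2):
        profiles = {vid: auto_evidence(a, panel=table2.panel) for vid, a in table2.annotations.items()}
        profiles = merge_manual_evidence(profiles, table2.manual_evidence)
        classifications = classify_callset(profiles)
        for vid, cls in classifications.items():
            assert cls.label == ("VUS+" if table2.expected_tier[vid] == "VUS+" else table2.expected_tier[vid])
        summary = tier_summary(classifications)
        assert summary["Pathogenic"] + summary["LikelyPathogenic"] == 6
        assert summary["VUS+"] == 3

    def test_empty_callset(self):
        assert classify_callset({}) == {}

    def test_manual_evidence_roundtrip(self, tmp_path):
        path = tmp_path / "manual.tsv"
        path.write_text("variant_id\tcodes\n1:1 G>A\tPS1, PM1@supporting\n")
        manual = read_manual_evidence(path)
        assert manual["1:1 G>A"] == [EvidenceCode("PS1"), EvidenceCode("PM1", Strength.SUPPORTING)]

    def test_manual_overrides_auto(self, panel):
        a = make_annotation(gnomad_af=1e-6)
        auto = {"1:1 G>A": auto_evidence(a, panel=panel)}
        merged = merge_manual_evidence(auto, {"1:1 G>A": [EvidenceCode("PM2", Strength.SUPPORTING)]})
        (pm2,) = [c for c in merged["1:1 G>A"].codes if c.code == "PM2"]
        assert pm2.strength is Strength.SUPPORTING
        assert merged["1:1 G>A"].provenance["PM2"] == "manual"
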