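import math
import warnings

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings, strategies as st

import _oracles
from fibrovar.stats import (
    PowerSpec,
    TwoByTwoTable,
    carrier_counts,
    compare_groups,
    enrichment,
    fisher_exact_two_sided,
    odds_ratio,
    power_simulation,
)


class TestFisher:
    def test_headline_table(self):
        p = fisher_exact_two_sided(TwoByTwoTable(5, 415, 1, 714))
        assert p == pytest.approx(0.0285, abs=5e-4)
        assert round(p, 2) == 0.03

    def test_balanced_table(self):
        assert fisher_exact_two_sided(TwoByTwoTable(1, 1, 1, 1)) == 1.0

    def test_degenerate_margins_warn_and_return_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact_two_sided(TwoByTwoTable(0, 10, 0, 20)) == 1.0

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 40, size=4)
            if (a + c) in (0, a + b + c + d) or (a + b) in (0, a + b + c + d):
                continue
            ours = fisher_exact_two_sided(TwoByTwoTable(int(a), int(b), int(c), int(d)))
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, abs=1e-9)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_symmetry_under_row_and_column_swaps(self, cells):
        a, b, c, d = cells
        t = TwoByTwoTable(a, b, c, d)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = fisher_exact_two_sided(t)
            assert fisher_exact_two_sided(TwoByTwoTable(c, d, a, b)) == pytest.approx(p, rel=1e-9)
            assert fisher_exact_two_sided(TwoByTwoTable(b, a, d, c)) == pytest.approx(p, rel=1e-9)

    def test_exhaustive_small_tables_vs_integer_oracle(self):
        """All tables with total <= 25 match exact integer enumeration."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for n in range(1, 26):
                for m in range(0, n + 1):
                    for k in range(0, n + 1):
                        lo, hi = max(0, m + k - n), min(m, k)
                        for a in range(lo, hi + 1):
                            t = TwoByTwoTable(a, m - a, k - a, n - k - m + a)
                            assert fisher_exact_two_sided(t) == pytest.approx(
                                _oracles.oracle_fisher_two_sided(t.a, t.b, t.c, t.d), abs=1e-10
                            )


class TestOddsRatio:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((5, 415, 1, 714), 8.6024),
            ((1, 1, 1, 1), 1.0),
            ((3, 7, 0, 10), math.inf),
        ],
    )
    def test_values(self, cells, expected):
        assert odds_ratio(TwoByTwoTable(*cells)) == pytest.approx(expected, abs=1e-3)

    def test_haldane_correction_finite(self):
        assert math.isfinite(odds_ratio(TwoByTwoTable(3, 7, 0, 10), haldane=True))

    def test_prevalences(self):
        t = TwoByTwoTable(7, 413, 2, 713)
        assert t.prevalence_case == pytest.approx(7 / 420 * 100)
        assert t.prevalence_control == pytest.approx(2 / 715 * 100)
        result = enrichment(t)
        assert result.p_two_sided == pytest.approx(0.0154, abs=5e-4)


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        result = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "x")
        assert result.p_value == 1.0

    def test_age_difference_at_study_sample_sizes(self):
        """Groups built to the published age summaries separate at p < 0.05."""
        a = 68.6 + 9.1 * sps.norm.ppf((np.arange(420) + 0.5) / 420)
        b = 67.0 + 8.4 * sps.norm.ppf((np.arange(715) + 0.5) / 715)
        result = compare_groups(a, b, "age")
        assert result.p_value < 0.05
        # Welch t from the summary statistics as an independent cross-check
        ref = sps.ttest_ind_from_stats(
            a.mean(), a.std(ddof=1), 420, b.mean(), b.std(ddof=1), 715, equal_var=False
        )
        assert result.p_value == pytest.approx(ref.pvalue, rel=1e-6)
        assert result.p_value == pytest.approx(0.003, abs=0.002)

    def test_sex_contingency(self):
        values_a = ["F"] * 265 + ["M"] * 155
        values_b = ["F"] * 277 + ["M"] * 438
        result = compare_groups(values_a, values_b, "sex", kind="categorical")
        assert result.kind == "categorical"
        assert result.p_value < 0.001

    def test_too_few_values_is_error(self):
        with pytest.raises(ValueError, match=">=2"):
            compare_groups([1.0], [1.0, 2.0], "x")


class TestCarrierCounts:
    def test_table2_carrier_tables(self, table2):
        from fibrovar import acmg
        from fibrovar.phenotype import apply_exclusions, assign_case_status

        profiles = {vid: acmg.auto_evidence(a, panel=table2.panel) for vid, a in table2.annotations.items()}
        profiles = acmg.merge_manual_evidence(profiles, table2.manual_evidence)
        classifications = acmg.classify_callset(profiles)
        included, _ = apply_exclusions(table2.participants)
        assignment = assign_case_status(included, table2.case_definition)
        tables = carrier_counts(
            table2.genotypes, classifications, dict(assignment.status), table2.panel, table2.annotations
        )
        assert (tables["plp"].a, tables["plp"].b, tables["plp"].c, tables["plp"].d) == (5, 415, 1, 714)
        t = tables["plp_vusplus"]
        assert (t.a, t.b, t.c, t.d) == (7, 413, 2, 713)

    def test_participant_with_two_variants_counted_once(self, panel):
        from fibrovar.acmg import Classification, Tier
        from fibrovar.models import AnnotationRecord, GenotypeMatrix

        ids = ["a", "b"]
        vids = ["1:1 G>A", "1:2 G>A"]
        gm = GenotypeMatrix(ids, vids, np.array([[1, 0], [1, 0]], dtype=np.int8))
        annotations = {
            vid: AnnotationRecord(variant_id=vid, gene_symbol="MYH7", consequence="missense_variant")
            for vid in vids
        }
        classifications = {vid: Classification(Tier.PATHOGENIC) for vid in vids}
        tables = carrier_counts(gm, classifications, {"a": "case", "b": "control"}, panel, annotations)
        assert tables["plp"].a == 1

    def test_ar_gene_requires_homozygous_carrier(self, panel):
        from fibrovar.acmg import Classification, Tier
        from fibrovar.models import AnnotationRecord, GenotypeMatrix

        ids = ["het", "hom"]
        vid = "17:78080000 G>A"
        gm = GenotypeMatrix(ids, [vid], np.array([[1, 2]], dtype=np.int8))
        annotations = {vid: AnnotationRecord(variant_id=vid, gene_symbol="GAA", consequence="missense_variant")}
        classifications = {vid: Classification(Tier.PATHOGENIC)}
        tables = carrier_counts(gm, classifications, {"het": "case", "hom": "case"}, panel, annotations)
        assert tables["plp"].a == 1  # only the homozygote counts for an AR gene

    def test_unknown_participant_is_error(self, panel):
        from fibrovar.models import GenotypeMatrix

        gm = GenotypeMatrix(["a"], [], np.empty((0, 1), dtype=np.int8))
        with pytest.raises(ValueError, match="not genotyped"):
            carrier_counts(gm, {}, {"ghost": "case"}, panel, {})


class TestPower:
    def test_study_design_exceeds_eighty_percent(self):
        est = power_simulation(PowerSpec(n_reps=20_000, seed=12))
        assert est.power_percent > 80.0

    def test_null_calibration_conservative(self):
        spec = PowerSpec(p_case=0.001, p_control=0.001, n_reps=5_000, seed=3)
        est = power_simulation(spec)
        assert est.power <= spec.alpha + 3 * max(est.se, math.sqrt(spec.alpha * (1 - spec.alpha) / spec.n_reps))

    def test_extreme_separation(self):
        est = power_simulation(PowerSpec(p_case=1.0, p_control=0.0, n_reps=500, seed=1))
        assert est.power == 1.0

    def test_monotone_in_effect_size_and_sample_size(self):
        base = power_simulation(PowerSpec(p_case=0.010, n_reps=4_000, seed=21))
        bigger_effect = power_simulation(PowerSpec(p_case=0.020, n_reps=4_000, seed=21))
        bigger_n = power_simulation(
            PowerSpec(p_case=0.010, n_cases=840, n_controls=1430, n_reps=4_000, seed=21)
        )
        slack = 3 * (base.se + bigger_effect.se)
        assert bigger_effect.power >= base.power - slack
        assert bigger_n.power >= base.power - 3 * (base.se + bigger_n.se)

    def test_reproducible_under_seed(self):
        a = power_simulation(PowerSpec(n_reps=2_000, seed=5))
        b = power_simulation(PowerSpec(n_reps=2_000, seed=5))
        assert a == b

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            PowerSpec(p_case=0.001, p_control=0.01)
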