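import dataclasses

import numpy as np
import pytest

import _oracles
from fibrovar.consequences import ConsequenceVocabulary, worst_consequence
from fibrovar.models import AnnotationRecord, GenotypeMatrix
from fibrovar.prioritize import (
    STAGES,
    is_monomorphic,
    passes_clinvar_screen,
    passes_frequency,
    passes_in_silico,
    run_cascade,
)

from conftest import random_callset

VOCAB = ConsequenceVocabulary()


class TestWorstConsequence:
    @pytest.mark.parametrize(
        "terms,expected",
        [
            (["synonymous_variant", "missense_variant"], "missense_variant"),
            (["missense_variant", "stop_gained"], "stop_gained"),
            (["start_lost"], "start_lost"),
            (["intron_variant", "splice_donor_variant", "missense_variant"], "splice_donor_variant"),
        ],
    )
    def test_severity_reduction(self, terms, expected):
        assert worst_consequence(terms, VOCAB) == expected

    def test_unknown_term_is_error(self):
        with pytest.raises(ValueError, match="unknown consequence"):
            worst_consequence(["made_up_variant"], VOCAB)

    def test_empty_list_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            worst_consequence([], VOCAB)


def _matrix(codes_row, ids):
    codes = np.asarray([codes_row], dtype=np.int8)
    return GenotypeMatrix(participant_ids=ids, variant_ids=["1:100 G>A"], codes=codes)


class TestMonomorphic:
    @pytest.mark.parametrize(
        "codes,expected",
        [
            ([0, 0, 0], True),
            ([0, 1, 0], False),
            ([0, -1, 0], True),  # missing calls are ignored
            ([1, 1, 1], True),  # uniform non-reference is still monomorphic
            ([-1, -1, -1], True),
        ],
    )
    def test_three_sample_cases(self, codes, expected):
        ids = ["a", "b", "c"]
        assert is_monomorphic("1:100 G>A", _matrix(codes, ids), ids) is expected

    def test_subsample_restriction(self):
        # polymorphic overall, monomorphic inside the phenotyped subsample
        gm = _matrix([0, 0, 1], ["a", "b", "c"])
        assert is_monomorphic("1:100 G>A", gm, ["a", "b"])
        assert not is_monomorphic("1:100 G>A", gm, ["a", "b", "c"])

    def test_unknown_variant_is_error(self):
        gm = _matrix([0, 1], ["a", "b"])
        with pytest.raises(KeyError, match="unknown variant"):
            is_monomorphic("9:9 G>A", gm, ["a"])


def ann(**kwargs):
    base = dict(variant_id="1:1 G>A", gene_symbol="MYH7", consequence="missense_variant")
    base.update(kwargs)
    return AnnotationRecord(**base)


class TestFrequencyFilter:
    @pytest.mark.parametrize(
        "gnomad,kg,expected",
        [
            (1.28e-4, None, True),
            (9.84e-4, None, True),
            (0.002, None, False),
            (None, None, True),  # unobserved in both databases passes
            (1e-5, 0.002, False),  # must be rare in both
            (0.001, None, False),  # strict inequality at the threshold
        ],
    )
    def test_threshold(self, gnomad, kg, expected):
        assert passes_frequency(ann(gnomad_af=gnomad, kg_af=kg), 0.001) is expected

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            passes_frequency(ann(), 0.0)


class TestInSilicoFilter:
    @pytest.mark.parametrize(
        "polyphen,cadd,sift,fathmm,expected",
        [
            ("probably_damaging", 25.0, "tolerated", "tolerated", True),  # branch 1
            ("benign", 10.0, "deleterious", "damaging", True),  # branch 2
            (None, None, None, None, True),  # no prediction anywhere passes
            ("benign", 10.0, "tolerated", "tolerated", False),
            ("possibly_damaging", 19.9, "tolerated", "damaging", False),  # CADD below cutoff kills branch 1
            (None, 25.0, "tolerated", None, True),  # missing PolyPhen is lenient
        ],
    )
    def test_truth_table(self, polyphen, cadd, sift, fathmm, expected):
        a = ann(polyphen_call=polyphen, cadd_phred=cadd, sift_call=sift, fathmm_call=fathmm)
        assert passes_in_silico(a, 20.0) is expected

    def test_missing_score_leniency(self):
        """Blanking any single score never removes a passing variant."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            a = ann(
                polyphen_call=rng.choice(["benign", "possibly_damaging", "probably_damaging", None]),
                cadd_phred=None if rng.random() < 0.3 else float(rng.uniform(0, 40)),
                sift_call=rng.choice(["tolerated", "deleterious", None]),
                fathmm_call=rng.choice(["tolerated", "damaging", None]),
            )
            if not passes_in_silico(a, 20.0):
                continue
            for field in ("polyphen_call", "cadd_phred", "sift_call", "fathmm_call"):
                blanked = dataclasses.replace(a, **{field: None})
                assert passes_in_silico(blanked, 20.0)


class TestClinvarScreen:
    @pytest.mark.parametrize(
        "assertion,expected",
        [
            ("conflicting", True),
            ("benign", False),
            ("likely_benign", False),
            ("not_found", True),  # absence from ClinVar is not benign evidence
            ("pathogenic", True),
            ("vus", True),
        ],
    )
    def test_screen(self, assertion, expected):
        assert passes_clinvar_screen(ann(clinvar_assertion=assertion)) is expected


class TestCascade:
    def test_table2_variants_survive_all_stages(self, table2):
        phenotyped = [p.id for p in table2.participants]
        trace = run_cascade(
            table2.variants, table2.annotations, table2.genotypes, table2.panel, phenotyped
        )
        assert trace.final_ids == {v.variant_id for v in table2.variants}
        assert all(n == 9 for n in trace.counts.values())

    def test_counts_non_increasing_and_subset_chain(self, panel):
        rng = np.random.default_rng(7)
        variants, annotations, genotypes, ids = random_callset(rng, 300, 40, panel)
        trace = run_cascade(variants, annotations, genotypes, panel, ids)
        previous = trace.input_ids
        for stage in STAGES:
            assert trace.surviving[stage] <= previous
            previous = trace.surviving[stage]

    def test_matches_intersection_of_predicates_oracle(self, panel):
        rng = np.random.default_rng(42)
        variants, annotations, genotypes, ids = random_callset(rng, 1000, 50, panel)
        trace = run_cascade(variants, annotations, genotypes, panel, ids)
        expected = _oracles.oracle_cascade_final(variants, annotations, genotypes, panel, ids, VOCAB)
        assert trace.final_ids == expected

    def test_funnel_example_counts(self, panel):
        """A hand-built ten-variant set loses the designed count at each stage."""
        import fibrovar.models as m

        rows, annotations = [], {}
        specs = [
            ("OFFPANEL_A", "missense_variant", 1e-5, "vus"),  # panel x3
            ("OFFPANEL_A", "missense_variant", 1e-5, "vus"),
            ("OFFPANEL_B", "missense_variant", 1e-5, "vus"),
            ("MYH7", "missense_variant", 0.01, "vus"),  # common x2
            ("MYH7", "missense_variant", 0.2, "vus"),
            ("MYH7", "synonymous_variant", 1e-5, "vus"),  # synonymous x1
            ("MYH7", "missense_variant", 1e-5, "benign"),  # ClinVar benign x1
            ("MYH7", "missense_variant", 1e-5, "vus"),  # survivors x3
            ("MYBPC3", "missense_variant", None, "conflicting"),
            ("SCN5A", "stop_gained", 1e-5, "pathogenic"),
        ]
        records = []
        for i, (gene, csq, af, clinvar) in enumerate(specs):
            rec = m.VariantRecord("1", 1000 + i, "G", "A")
            records.append(rec)
            annotations[rec.variant_id] = AnnotationRecord(
                variant_id=rec.variant_id, gene_symbol=gene, consequence=csq,
                gnomad_af=af, clinvar_assertion=clinvar,
            )
        ids = ["a", "b", "c"]
        codes = np.tile(np.array([0, 1, 0], dtype=np.int8), (10, 1))
        gm = m.GenotypeMatrix(participant_ids=ids, variant_ids=[r.variant_id for r in records], codes=codes)
        trace = run_cascade(records, annotations, gm, panel, ids)
        assert trace.counts == {
            "input": 10, "panel": 7, "non_monomorphic": 7, "coding_or_splice": 7,
            "rare": 5, "non_synonymous": 4, "in_silico": 4, "clinvar_non_benign": 3,
        }
        assert trace.final_ids == _oracles.oracle_cascade_final(records, annotations, gm, panel, ids, VOCAB)
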