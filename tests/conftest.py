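from __future__ import annotations

import numpy as np
import pytest

from fibrovar.cohort_io import default_panel
from fibrovar.models import AnnotationRecord, GenotypeMatrix, VariantRecord
from fibrovar.simulate import SyntheticCohortSpec, build_cohort, load_table2_fixture


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def table2():
    """The deterministic published-cohort fixture (nine variants, 1,164 participants)."""
    return load_table2_fixture()


@pytest.fixture(scope="session")
def table2_paths(table2, tmp_path_factory):
    """The same fixture materialized as on-disk pipeline inputs."""
    return table2.write(tmp_path_factory.mktemp("table2"))


@pytest.fixture(scope="session")
def synthetic_seed1():
    """Default synthetic cohort, seed 1, in memory."""
    return build_cohort(SyntheticCohortSpec(seed=1))


def random_annotation(rng: np.random.Generator, variant_id: str, gene: str) -> AnnotationRecord:
    """Annotation with independently randomized filter-relevant features."""
    consequences = [
        "missense_variant", "synonymous_variant", "intron_variant", "stop_gained",
        "splice_donor_variant", "start_lost", "5_prime_UTR_variant", "frameshift_variant",
    ]
    def maybe(p, value):
        return value if rng.random() < p else None
    return AnnotationRecord(
        variant_id=variant_id,
        gene_symbol=gene,
        consequence=consequences[int(rng.integers(len(consequences)))],
        gnomad_af=maybe(0.8, float(rng.choice([1e-5, 5e-4, 9.9e-4, 1e-3, 0.002, 0.01, 0.2]))),
        kg_af=maybe(0.5, float(rng.choice([1e-5, 5e-4, 0.002]))),
        polyphen_call=maybe(0.7, str(rng.choice(["benign", "possibly_damaging", "probably_damaging"]))),
        sift_call=maybe(0.7, str(rng.choice(["tolerated", "deleterious"]))),
        cadd_phred=maybe(0.7, float(rng.uniform(0, 40))),
        fathmm_call=maybe(0.7, str(rng.choice(["tolerated", "damaging"]))),
        clinvar_assertion=str(
            rng.choice(["pathogenic", "likely_pathogenic", "path_or_lp", "vus",
                        "conflicting", "likely_benign", "benign", "not_found"])
        ),
    )


def random_callset(rng: np.random.Generator, n_variants: int, n_samples: int, panel):
    """Random variants/annotations/genotypes over panel and off-panel genes."""
    genes = sorted(panel.gene_list)[:20] + ["OFFPANEL_A", "OFFPANEL_B"]
    sample_ids = [f"R{i:04d}" for i in range(n_samples)]
    variants, annotations = [], {}
    codes = np.zeros((n_variants, n_samples), dtype=np.int8)
    for i in range(n_variants):
        rec = VariantRecord("1", 1_000_000 + i, "G", "A")
        variants.append(rec)
        gene = genes[int(rng.integers(len(genes)))]
        annotations[rec.variant_id] = random_annotation(rng, rec.variant_id, gene)
        # random genotype pattern: some monomorphic, some polymorphic, some missing
        kind = rng.random()
        if kind < 0.2:
            pass  # all reference: monomorphic
        else:
            n_carriers = int(rng.integers(1, max(2, n_samples // 4)))
            carriers = rng.choice(n_samples, size=n_carriers, replace=False)
            codes[i, carriers] = rng.choice([1, 2], size=n_carriers)
        if rng.random() < 0.3:
            missing = rng.choice(n_samples, size=int(rng.integers(1, 4)), replace=False)
            codes[i, missing] = -1
    genotypes = GenotypeMatrix(
        participant_ids=sample_ids,
        variant_ids=[v.variant_id for v in variants],
        codes=codes,
    )
    return variants, annotations, genotypes, sample_ids
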