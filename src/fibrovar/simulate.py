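"""Synthetic cohorts and the packaged clinical-table fixture.

Two sources of test data, both producing exactly the file formats
:mod:`fibrovar.cohort_io` reads:

* :func:`load_table2_fixture` — a deterministic 1,164-participant cohort
  carrying the nine published case/control variants (six P/LP, three VUS+)
  with their verbatim allele frequencies and ClinVar assertions, and a
  phenotype table constructed so that the published thresholds
  (ECV > 28.8%, native T1 > 1,006 ms) yield 139 ECV-only, 139 T1-only and
  142 dual exceedances: 420 cases against 715 controls after the 29 MI/HF
  exclusions.  Evidence profiles are reverse-engineered to reproduce the
  published tier calls (the per-variant criteria the original curators
  invoked are not public) and are synthetic stand-ins, not curation output.

* :func:`generate_cohort` — a seeded random cohort with a latent
  two-component phenotype structure, planted carriers at specified
  prevalences, and per-stage decoy variants, plus a truth table recording
  every planted fact so pipeline recovery can be asserted exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats as sps

from .acmg import EvidenceCode
from .models import (
    AnnotationRecord,
    GenotypeMatrix,
    PanelConfig,
    Participant,
    VariantRecord,
    variant_key,
)
from .cohort_io import (
    default_panel,
    write_annotations,
    write_phenotypes,
    write_vcf,
)
from .phenotype import CaseDefinition, assign_case_status

# ---------------------------------------------------------------------------
# The nine-variant clinical fixture
# ---------------------------------------------------------------------------

#: published case-definition thresholds (ECV percent, native T1 ms)
PUBLISHED_ECV_THRESHOLD = 28.8
PUBLISHED_T1_THRESHOLD = 1006.0


@dataclass(frozen=True)
class FixtureVariant:
    row_id: str  # C1..C7, N1, N2
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: str
    protein_change: str
    clinvar: str
    gnomad_af: float
    expected_tier: str  # "Pathogenic" / "LikelyPathogenic" / "VUS+"
    group: str  # "case" / "control"
    phenotype_criteria: str  # "ecv_only" / "t1_only" / "both" / "control"
    manual_codes: tuple[str, ...]

    @property
    def variant_id(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


TABLE2_VARIANTS: tuple[FixtureVariant, ...] = (
    FixtureVariant("C1", "SCN5A", "3", 38613773, "G", "A", "missense_variant", "p.Arg225Trp",
                   "path_or_lp", 1.28e-4, "Pathogenic", "case", "ecv_only", ("PS3", "PM1", "PM5")),
    FixtureVariant("C2", "CRYAB", "11", 111908822, "G", "A", "missense_variant", "p.Arg157His",
                   "vus", 6.15e-5, "LikelyPathogenic", "case", "both", ("PM1", "PM5")),
    FixtureVariant("C3", "CRYAB", "11", 111911722, "G", "A", "start_lost", "p.Met1Ile",
                   "conflicting", 9.84e-4, "LikelyPathogenic", "case", "t1_only", ("PM1", "PM4")),
    FixtureVariant("C4", "MYH7", "14", 23424839, "G", "A", "missense_variant", "p.Arg870His",
                   "pathogenic", 1.55e-5, "LikelyPathogenic", "case", "both", ("PS1",)),
    FixtureVariant("C5", "MYH7", "14", 23429037, "C", "T", "missense_variant", "p.Arg442His",
                   "conflicting", 6.15e-5, "LikelyPathogenic", "case", "t1_only", ("PM1", "PM5")),
    FixtureVariant("C6", "MYBPC3", "11", 47337543, "G", "A", "missense_variant", "p.Arg817Gln",
                   "conflicting", 2.83e-5, "VUS+", "case", "ecv_only", ("PM1",)),
    FixtureVariant("C7", "MYBPC3", "11", 47337792, "G", "A", "missense_variant", "p.Val771Met",
                   "conflicting", 1.76e-5, "VUS+", "case", "both", ("PM1",)),
    FixtureVariant("N1", "MYL2", "12", 110914290, "C", "T", "missense_variant", "p.Gly57Glu",
                   "vus", 2.89e-5, "LikelyPathogenic", "control", "control", ("PM1", "PM5")),
    FixtureVariant("N2", "TNNT2", "1", 201365261, "G", "A", "missense_variant", "p.Ala114Val",
                   "conflicting", 1.76e-5, "VUS+", "control", "control", ("PM1",)),
)


def _fixture_annotation(v: FixtureVariant) -> AnnotationRecord:
    # PolyPhen does not score start-codon losses; the remaining three tools
    # still give >=2 concordant damaging calls.
    polyphen = None if v.consequence == "start_lost" else "probably_damaging"
    return AnnotationRecord(
        variant_id=v.variant_id,
        gene_symbol=v.gene,
        consequence=v.consequence,
        protein_change=v.protein_change,
        gnomad_af=v.gnomad_af,
        kg_af=None,
        polyphen_call=polyphen,
        sift_call="deleterious",
        cadd_phred=26.0,
        fathmm_call="damaging",
        clinvar_assertion=v.clinvar,
    )


@dataclass
class FixtureBundle:
    """In-memory pipeline inputs plus the planted ground truth."""

    variants: list[VariantRecord]
    genotypes: GenotypeMatrix
    annotations: dict[str, AnnotationRecord]
    participants: list[Participant]
    manual_evidence: dict[str, list[EvidenceCode]]
    panel: PanelConfig
    expected_tier: dict[str, str]
    carrier_of: dict[str, str]  # variant_id -> participant id
    case_definition: Optional[CaseDefinition] = None
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Materialize as the on-disk formats the readers consume."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": write_vcf(self.variants, self.genotypes, outdir / "cohort.vcf"),
            "annotations": write_annotations(self.annotations.values(), outdir / "annotations.tsv"),
            "phenotypes": write_phenotypes(self.participants, outdir / "phenotypes.csv"),
        }
        lines = ["variant_id\tcodes"]
        for vid in sorted(self.manual_evidence):
            tokens = ",".join(c.code for c in self.manual_evidence[vid])
            lines.append(f"{vid}\t{tokens}")
        manual = outdir / "manual_evidence.tsv"
        manual.write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths["manual_evidence"] = manual
        if self.truth:
            truth = outdir / "truth.json"
            truth.write_text(json.dumps(self.truth, indent=2, sort_keys=True), encoding="utf-8")
            paths["truth"] = truth
        return paths


def _norm_grid(n: int, mean: float, sd: float) -> np.ndarray:
    """Deterministic sample with approximately the given mean/SD: normal
    quantiles at evenly spaced probabilities."""
    return mean + sd * sps.norm.ppf((np.arange(n) + 0.5) / n)


def load_table2_fixture() -> FixtureBundle:
    """The deterministic published-cohort fixture (see module docstring)."""
    panel = default_panel()
    n_total, n_excluded = 1164, 29
    ids = [f"M{i:04d}" for i in range(1, n_total + 1)]

    # category layout among the 1,135 included participants (counts chosen to
    # reproduce the published 139/139/142 exceedance decomposition)
    layout = [("both", 142), ("ecv_only", 139), ("t1_only", 139), ("control", 715)]
    categories: list[str] = []
    for name, count in layout:
        categories.extend([name] * count)

    races = ("White", "AfricanAmerican", "ChineseAmerican", "Hispanic")
    participants: list[Participant] = []
    ecv_grid = {
        "both": _norm_grid(142, 31.5, 1.5).clip(28.9, 40.0),
        "ecv_only": _norm_grid(139, 31.0, 1.4).clip(28.9, 40.0),
        "t1_only": _norm_grid(139, 26.0, 1.5).clip(20.0, 28.8),
        "control": _norm_grid(715, 25.6, 1.8).clip(18.0, 28.8),
    }
    t1_grid = {
        "both": _norm_grid(142, 1030.0, 15.0).clip(1007.0, 1120.0),
        "ecv_only": _norm_grid(139, 985.0, 12.0).clip(900.0, 1006.0),
        "t1_only": _norm_grid(139, 1028.0, 14.0).clip(1007.0, 1120.0),
        "control": _norm_grid(715, 957.2, 30.7).clip(860.0, 1006.0),
    }
    counters = {name: 0 for name, _ in layout}
    # sex split mirroring the published baseline table (265 F cases, 277 F controls)
    case_index = control_index = 0
    for i, pid in enumerate(ids[:n_total - n_excluded]):
        cat = categories[i]
        j = counters[cat]
        counters[cat] += 1
        if cat == "control":
            sex = "F" if control_index < 277 else "M"
            control_index += 1
        else:
            sex = "F" if case_index < 265 else "M"
            case_index += 1
        participants.append(
            Participant(
                id=pid,
                age_at_cmr=float(45 + (i * 7) % 40),
                sex=sex,
                race=races[i % 4],
                mi_history=False,
                hf_history=False,
                hct=0.42,
                native_t1=round(float(t1_grid[cat][j]), 1),
                ecv=round(float(ecv_grid[cat][j]), 2),
                ef=62.0,
            )
        )
    # the 29 excluded participants (MI or HF history before CMR)
    for k, pid in enumerate(ids[n_total - n_excluded:]):
        participants.append(
            Participant(
                id=pid,
                age_at_cmr=float(50 + k),
                sex="M" if k % 2 else "F",
                race=races[k % 4],
                mi_history=k < 15,
                hf_history=k >= 15,
                hct=0.42,
                native_t1=980.0,
                ecv=27.0,
                ef=55.0,
            )
        )

    # one carrier per variant, drawn from the participant block matching the
    # published phenotype criteria (controls for the N rows); C7's carrier
    # additionally has missing LV features, as published
    category_members: dict[str, list[str]] = {name: [] for name, _ in layout}
    for i, pid in enumerate(ids[:n_total - n_excluded]):
        category_members[categories[i]].append(pid)
    used: dict[str, int] = {name: 0 for name, _ in layout}
    carrier_of: dict[str, str] = {}
    for v in TABLE2_VARIANTS:
        cat = v.phenotype_criteria
        carrier_of[v.variant_id] = category_members[cat][used[cat]]
        used[cat] += 1

    variant_records = [VariantRecord(v.chrom, v.pos, v.ref, v.alt) for v in TABLE2_VARIANTS]
    codes = np.zeros((len(variant_records), len(ids)), dtype=np.int8)
    col = {pid: j for j, pid in enumerate(ids)}
    for i, v in enumerate(TABLE2_VARIANTS):
        codes[i, col[carrier_of[v.variant_id]]] = 1
    genotypes = GenotypeMatrix(participant_ids=ids, variant_ids=[r.variant_id for r in variant_records], codes=codes)

    annotations = {v.variant_id: _fixture_annotation(v) for v in TABLE2_VARIANTS}
    manual = {v.variant_id: [EvidenceCode(c) for c in v.manual_codes] for v in TABLE2_VARIANTS}
    expected = {v.variant_id: v.expected_tier for v in TABLE2_VARIANTS}

    truth = {
        "n_total": n_total,
        "n_excluded": n_excluded,
        "n_cases": 420,
        "n_controls": 715,
        "decomposition": {"ecv_only": 139, "t1_only": 139, "both": 142},
        "tables": {"plp": [5, 415, 1, 714], "plp_vusplus": [7, 413, 2, 713]},
        "tier_counts": {"P/LP": 6, "VUS+": 3},
    }
    return FixtureBundle(
        variants=variant_records,
        genotypes=genotypes,
        annotations=annotations,
        participants=participants,
        manual_evidence=manual,
        panel=panel,
        expected_tier=expected,
        carrier_of=carrier_of,
        case_definition=CaseDefinition(PUBLISHED_ECV_THRESHOLD, PUBLISHED_T1_THRESHOLD),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Randomized cohort generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohortSpec:
    """Distribution and effect-size parameters for a generated cohort.

    Defaults emulate the study conditions: 1,164 genotyped-and-phenotyped
    participants of whom 29 carry MI/HF exclusion flags; a four-group race
    mix; case/control ECV and native-T1 means and SDs from the published
    baseline table with within-person correlation 0.5; and carrier
    prevalences of 1.2%/0.1% (P/LP, cases/controls) rising to 1.7%/0.3%
    once VUS+ variants are included.
    """

    n_total: int = 1164
    n_excluded_mi_hf: int = 29
    race_mix: tuple[float, float, float, float] = (0.38, 0.28, 0.23, 0.11)  # White/AA/Hispanic/Chinese
    case_fraction: float = 420 / 1135
    ecv_mean_case: float = 29.4
    ecv_sd_case: float = 2.5
    t1_mean_case: float = 1014.0
    t1_sd_case: float = 37.1
    ecv_mean_control: float = 25.6
    ecv_sd_control: float = 1.8
    t1_mean_control: float = 957.2
    t1_sd_control: float = 30.7
    ecv_t1_corr: float = 0.5
    p_plp_case: float = 0.012
    p_plp_control: float = 0.001
    p_vusplus_case: float = 0.005
    p_vusplus_control: float = 0.002
    n_vus_survivors: int = 2
    decoys_per_stage: int = 2
    n_genotyped_only: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.race_mix) - 1.0) > 1e-9:
            raise ValueError("race mix must sum to 1")
        for name in ("p_plp_case", "p_plp_control", "p_vusplus_case", "p_vusplus_control", "case_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name in ("ecv_sd_case", "t1_sd_case", "ecv_sd_control", "t1_sd_control"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_excluded_mi_hf >= self.n_total:
            raise ValueError("cannot exclude the whole cohort")


_RACE_ORDER = ("White", "AfricanAmerican", "Hispanic", "ChineseAmerican")

_DECOY_STAGES = (
    "panel",
    "non_monomorphic",
    "coding_or_splice",
    "rare",
    "non_synonymous",
    "in_silico",
    "clinvar_non_benign",
)


def _bivariate(rng: np.random.Generator, n: int, means, sds, corr: float) -> np.ndarray:
    cov = np.array(
        [
            [sds[0] ** 2, corr * sds[0] * sds[1]],
            [corr * sds[0] * sds[1], sds[1] ** 2],
        ]
    )
    return rng.multivariate_normal(np.asarray(means, dtype=float), cov, size=n)


class _VariantFactory:
    """Places synthetic variants inside per-gene panel windows with unique
    positions; gene choice restricted to AD genes so heterozygous planting
    counts as carriage."""

    def __init__(self, rng: np.random.Generator, panel: PanelConfig):
        self.rng = rng
        self.panel = panel
        self.ad_genes = sorted(
            g for g in panel.gene_list
            if panel.inheritance_mode(g) != "AR" and g in panel.windows
        )
        self.used_positions: set[tuple[str, int]] = set()

    def new(self, gene: Optional[str] = None) -> tuple[str, VariantRecord]:
        if gene is None:
            gene = self.ad_genes[int(self.rng.integers(len(self.ad_genes)))]
        if gene in self.panel.windows:
            chrom, start, end = self.panel.windows[gene]
        else:  # off-panel decoy gene: arbitrary coordinates
            chrom, start, end = "21", 10_000_000, 10_500_000
        while True:
            pos = int(self.rng.integers(start, end + 1))
            if (chrom, pos) not in self.used_positions:
                self.used_positions.add((chrom, pos))
                break
        ref, alt = ("G", "A") if self.rng.random() < 0.5 else ("C", "T")
        return gene, VariantRecord(chrom, pos, ref, alt)


def generate_cohort(
    spec: SyntheticCohortSpec,
    outdir: str | Path,
    panel: Optional[PanelConfig] = None,
) -> dict[str, Path]:
    """Generate a full synthetic cohort and write it under ``outdir``.

    Returns paths for the VCF, annotation TSV, phenotype CSV, manual-evidence
    TSV and the truth JSON.  Identical spec (including seed) produces
    byte-identical outputs.
    """
    bundle = build_cohort(spec, panel=panel)
    return bundle.write(outdir)


def build_cohort(spec: SyntheticCohortSpec, panel: Optional[PanelConfig] = None) -> FixtureBundle:
    """In-memory version of :func:`generate_cohort`."""
    if panel is None:
        panel = default_panel()
    rng = np.random.default_rng(spec.seed)

    n = spec.n_total
    ids = [f"S{i:05d}" for i in range(1, n + 1)]
    genotyped_only = [f"G{i:05d}" for i in range(1, spec.n_genotyped_only + 1)]

    excluded_idx = set(rng.choice(n, size=spec.n_excluded_mi_hf, replace=False).tolist())
    included_ids = [pid for i, pid in enumerate(ids) if i not in excluded_idx]

    latent_case = rng.random(n) < spec.case_fraction
    phen = np.empty((n, 2))
    case_rows = _bivariate(
        rng, n, (spec.ecv_mean_case, spec.t1_mean_case), (spec.ecv_sd_case, spec.t1_sd_case), spec.ecv_t1_corr
    )
    control_rows = _bivariate(
        rng,
        n,
        (spec.ecv_mean_control, spec.t1_mean_control),
        (spec.ecv_sd_control, spec.t1_sd_control),
        spec.ecv_t1_corr,
    )
    phen[latent_case] = case_rows[latent_case]
    phen[~latent_case] = control_rows[~latent_case]
    # keep within physiological bounds (the model invariant requires 0 < ECV < 100)
    phen[:, 0] = phen[:, 0].clip(5.0, 60.0)
    phen[:, 1] = phen[:, 1].clip(600.0, 1400.0)

    race_idx = rng.choice(4, size=n, p=list(spec.race_mix))
    sexes = rng.choice(["F", "M"], size=n)
    ages = rng.uniform(45, 85, size=n)
    mi_flags = rng.random(spec.n_excluded_mi_hf) < 0.5

    participants = []
    ex_counter = 0
    for i, pid in enumerate(ids):
        is_excluded = i in excluded_idx
        if is_excluded:
            mi = bool(mi_flags[ex_counter])
            ex_counter += 1
        else:
            mi = False
        participants.append(
            Participant(
                id=pid,
                age_at_cmr=round(float(ages[i]), 1),
                sex=str(sexes[i]),
                race=_RACE_ORDER[race_idx[i]],
                mi_history=mi if is_excluded else False,
                hf_history=(not mi) if is_excluded else False,
                hct=0.42,
                native_t1=round(float(phen[i, 1]), 2),
                ecv=round(float(phen[i, 0]), 3),
            )
        )

    # realized case status: the same top-quartile union rule the pipeline
    # applies downstream (thresholds from the post-exclusion population)
    included = [p for p in participants if not (p.mi_history or p.hf_history)]
    assignment = assign_case_status(included)
    case_ids = sorted(pid for pid, s in assignment.status.items() if s == "case")
    control_ids = sorted(pid for pid, s in assignment.status.items() if s == "control")

    factory = _VariantFactory(rng, panel)
    variants: list[VariantRecord] = []
    annotations: dict[str, AnnotationRecord] = {}
    manual: dict[str, list[EvidenceCode]] = {}
    carrier_of: dict[str, str] = {}
    expected_tier: dict[str, str] = {}
    roles: dict[str, str] = {}

    def rare_af() -> Optional[float]:
        return None if rng.random() < 0.3 else float(round(rng.uniform(1e-6, 5e-4), 8))

    def add_planted(group_ids: list[str], count: int, tier: str, taken: set[str]) -> None:
        free = [pid for pid in group_ids if pid not in taken]
        chosen = [free[int(k)] for k in rng.choice(len(free), size=count, replace=False)] if count else []
        for pid in chosen:
            taken.add(pid)
            gene, rec = factory.new()
            vid = rec.variant_id
            variants.append(rec)
            carrier_of[vid] = pid
            annotations[vid] = AnnotationRecord(
                variant_id=vid,
                gene_symbol=gene,
                consequence="missense_variant",
                protein_change="p.Xaa1Xaa",
                gnomad_af=rare_af(),
                kg_af=None,
                polyphen_call="probably_damaging",
                sift_call="deleterious",
                cadd_phred=float(round(rng.uniform(22, 34), 2)),
                fathmm_call="damaging",
                clinvar_assertion="conflicting" if rng.random() < 0.5 else "vus",
            )
            if tier == "Pathogenic":
                manual[vid] = [EvidenceCode("PS3"), EvidenceCode("PM1"), EvidenceCode("PM5")]
            elif tier == "LikelyPathogenic":
                manual[vid] = [EvidenceCode("PM1"), EvidenceCode("PM5")]
            elif tier == "VUS+":
                manual[vid] = [EvidenceCode("PM1")]
            # plain VUS: auto evidence only (PM2 + PP3 is not enough to call)
            expected_tier[vid] = tier
            roles[vid] = f"planted_{tier}"

    taken: set[str] = set()
    n_plp_case = int(rng.binomial(len(case_ids), spec.p_plp_case))
    n_plp_control = int(rng.binomial(len(control_ids), spec.p_plp_control))
    n_vp_case = int(rng.binomial(len(case_ids), spec.p_vusplus_case))
    n_vp_control = int(rng.binomial(len(control_ids), spec.p_vusplus_control))
    # alternate P and LP among the P/LP plants
    for k in range(n_plp_case):
        add_planted(case_ids, 1, "Pathogenic" if k % 2 == 0 else "LikelyPathogenic", taken)
    for k in range(n_plp_control):
        add_planted(control_ids, 1, "LikelyPathogenic" if k % 2 == 0 else "Pathogenic", taken)
    add_planted(case_ids, n_vp_case, "VUS+", taken)
    add_planted(control_ids, n_vp_control, "VUS+", taken)
    everyone = case_ids + control_ids
    add_planted(everyone, spec.n_vus_survivors, "VUS", taken)

    # decoys: each constructed to clear every earlier stage and fail exactly
    # one named stage of the cascade
    decoy_stage: dict[str, str] = {}

    def add_decoy(stage: str) -> None:
        damaging = dict(
            polyphen_call="probably_damaging", sift_call="deleterious",
            cadd_phred=28.0, fathmm_call="damaging",
        )
        fields = dict(
            consequence="missense_variant", protein_change="p.Xaa1Xaa",
            gnomad_af=rare_af(), kg_af=None, clinvar_assertion="vus", **damaging,
        )
        gene = None
        carrier_pool: list[str] = included_ids
        if stage == "panel":
            gene, rec = factory.new("NOTAPANELGENE")
        elif stage == "non_monomorphic":
            gene, rec = factory.new()
            carrier_pool = genotyped_only
        elif stage == "coding_or_splice":
            gene, rec = factory.new()
            fields["consequence"] = "intron_variant"
        elif stage == "rare":
            gene, rec = factory.new()
            fields["gnomad_af"] = float(round(rng.uniform(0.002, 0.05), 6))
        elif stage == "non_synonymous":
            gene, rec = factory.new()
            fields["consequence"] = "synonymous_variant"
        elif stage == "in_silico":
            gene, rec = factory.new()
            fields.update(polyphen_call="benign", sift_call="tolerated", cadd_phred=3.0, fathmm_call="tolerated")
        elif stage == "clinvar_non_benign":
            gene, rec = factory.new()
            fields["clinvar_assertion"] = "benign" if rng.random() < 0.5 else "likely_benign"
        else:  # pragma: no cover
            raise ValueError(stage)
        vid = rec.variant_id
        variants.append(rec)
        annotations[vid] = AnnotationRecord(variant_id=vid, gene_symbol=gene, **fields)
        if carrier_pool:
            carrier_of[vid] = carrier_pool[int(rng.integers(len(carrier_pool)))]
        decoy_stage[vid] = stage
        roles[vid] = f"decoy_{stage}"

    for stage in _DECOY_STAGES:
        for _ in range(spec.decoys_per_stage):
            add_decoy(stage)

    all_sample_ids = ids + genotyped_only
    variants_sorted = sorted(variants, key=lambda v: (v.chrom, v.pos))
    codes = np.zeros((len(variants_sorted), len(all_sample_ids)), dtype=np.int8)
    col = {pid: j for j, pid in enumerate(all_sample_ids)}
    for i, rec in enumerate(variants_sorted):
        pid = carrier_of.get(rec.variant_id)
        if pid is not None:
            codes[i, col[pid]] = 1
    genotypes = GenotypeMatrix(
        participant_ids=all_sample_ids,
        variant_ids=[v.variant_id for v in variants_sorted],
        codes=codes,
    )

    plp_case_carriers = {carrier_of[v] for v, t in expected_tier.items() if t in ("Pathogenic", "LikelyPathogenic") and carrier_of[v] in case_ids}
    plp_control_carriers = {carrier_of[v] for v, t in expected_tier.items() if t in ("Pathogenic", "LikelyPathogenic") and carrier_of[v] in control_ids}
    all_case_carriers = {carrier_of[v] for v, t in expected_tier.items() if t in ("Pathogenic", "LikelyPathogenic", "VUS+") and carrier_of[v] in case_ids}
    all_control_carriers = {carrier_of[v] for v, t in expected_tier.items() if t in ("Pathogenic", "LikelyPathogenic", "VUS+") and carrier_of[v] in control_ids}

    truth = {
        "seed": spec.seed,
        "n_total": spec.n_total,
        "n_excluded": spec.n_excluded_mi_hf,
        "n_cases": len(case_ids),
        "n_controls": len(control_ids),
        "case_definition": {
            "ecv_threshold": assignment.definition.ecv_threshold,
            "native_t1_threshold": assignment.definition.native_t1_threshold,
        },
        "latent_case_ids": [pid for i, pid in enumerate(ids) if latent_case[i]],
        "decomposition": assignment.decomposition(),
        "tables": {
            "plp": [
                len(plp_case_carriers),
                len(case_ids) - len(plp_case_carriers),
                len(plp_control_carriers),
                len(control_ids) - len(plp_control_carriers),
            ],
            "plp_vusplus": [
                len(all_case_carriers),
                len(case_ids) - len(all_case_carriers),
                len(all_control_carriers),
                len(control_ids) - len(all_control_carriers),
            ],
        },
        "expected_tier": expected_tier,
        "decoy_stage": decoy_stage,
        "roles": roles,
        "carrier_of": carrier_of,
    }

    return FixtureBundle(
        variants=variants_sorted,
        genotypes=genotypes,
        annotations=annotations,
        participants=participants,
        manual_evidence=manual,
        panel=panel,
        expected_tier=expected_tier,
        carrier_of=carrier_of,
        case_definition=None,  # thresholds are cohort-derived downstream
        truth=truth,
    )
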