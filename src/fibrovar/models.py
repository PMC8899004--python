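"""Shared data model for the variant/phenotype enrichment pipeline.

Coordinates are 1-based as in VCF.  A variant is keyed throughout by the
canonical string ``"chrom:pos ref>alt"`` (e.g. ``"3:38613773 G>A"``), the
rendering used in clinical variant tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np

_VALID_BASES = set("ACGT")

#: genotype code used for a missing call in :class:`GenotypeMatrix`
MISSING_GT = -1

POLYPHEN_CALLS = {"benign", "possibly_damaging", "probably_damaging"}
SIFT_CALLS = {"tolerated", "deleterious"}
FATHMM_CALLS = {"tolerated", "damaging"}
CLINVAR_ASSERTIONS = {
    "pathogenic",
    "likely_pathogenic",
    "path_or_lp",
    "vus",
    "conflicting",
    "likely_benign",
    "benign",
    "not_found",
}

# numeric in-silico scores, when supplied instead of categorical calls, are
# binned by the published cutoffs: PolyPhen-2 >= 0.446 is the damaging
# spectrum ("possibly damaging" and up), SIFT < 0.05 is deleterious.
POLYPHEN_DAMAGING_CUTOFF = 0.446
SIFT_DELETERIOUS_CUTOFF = 0.05


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical ``chrom:pos ref>alt`` identifier."""
    return f"{chrom}:{pos} {ref}>{alt}"


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic genomic variant (multi-allelic sites are decomposed)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(f"{name} allele {allele!r} is not an A/C/G/T string")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical ({self.ref})")

    @property
    def variant_id(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage per variant and participant.

    ``codes[i, j]`` is the number of alternate alleles (0/1/2) carried by
    participant ``participant_ids[j]`` at variant ``variant_ids[i]``, or
    :data:`MISSING_GT` for a missing call.
    """

    participant_ids: list[str]
    variant_ids: list[str]
    codes: np.ndarray  # (n_variants, n_participants) int8

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.variant_ids), len(self.participant_ids)):
            raise ValueError(
                f"genotype matrix shape {self.codes.shape} does not match "
                f"{len(self.variant_ids)} variants x {len(self.participant_ids)} participants"
            )
        if len(set(self.participant_ids)) != len(self.participant_ids):
            raise ValueError("participant ids are not unique")
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ValueError("variant ids are not unique")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING_GT))
        if bad.any():
            raise ValueError(f"genotype codes outside {{0,1,2,missing}}: {np.unique(self.codes[bad])}")
        self._variant_index = {v: i for i, v in enumerate(self.variant_ids)}
        self._participant_index = {p: j for j, p in enumerate(self.participant_ids)}

    def genotypes(self, variant_id: str, participant_ids: Optional[list[str]] = None) -> np.ndarray:
        """Dosage row for one variant, optionally restricted to a subsample."""
        try:
            row = self.codes[self._variant_index[variant_id]]
        except KeyError:
            raise KeyError(f"unknown variant_id {variant_id!r}") from None
        if participant_ids is None:
            return row
        try:
            cols = [self._participant_index[p] for p in participant_ids]
        except KeyError as exc:
            raise KeyError(f"participant {exc.args[0]!r} not in genotype matrix") from None
        return row[cols]


@dataclass(frozen=True)
class AnnotationRecord:
    """Functional annotation and population frequencies for one variant.

    ``consequence`` is the worst consequence across transcripts; categorical
    in-silico calls are ``None`` when the tool produced no prediction.
    """

    variant_id: str
    gene_symbol: str
    consequence: str
    protein_change: str = ""
    gnomad_af: Optional[float] = None
    kg_af: Optional[float] = None
    polyphen_call: Optional[str] = None
    sift_call: Optional[str] = None
    cadd_phred: Optional[float] = None
    fathmm_call: Optional[str] = None
    clinvar_assertion: str = "not_found"

    def __post_init__(self) -> None:
        for af, name in ((self.gnomad_af, "gnomad_af"), (self.kg_af, "kg_af")):
            if af is not None and not 0.0 <= af <= 1.0:
                raise ValueError(f"{name}={af} outside [0, 1] for {self.variant_id}")
        if self.cadd_phred is not None and self.cadd_phred < 0:
            raise ValueError(f"cadd_phred={self.cadd_phred} negative for {self.variant_id}")
        if self.polyphen_call is not None and self.polyphen_call not in POLYPHEN_CALLS:
            raise ValueError(f"unknown PolyPhen call {self.polyphen_call!r}")
        if self.sift_call is not None and self.sift_call not in SIFT_CALLS:
            raise ValueError(f"unknown SIFT call {self.sift_call!r}")
        if self.fathmm_call is not None and self.fathmm_call not in FATHMM_CALLS:
            raise ValueError(f"unknown FATHMM call {self.fathmm_call!r}")
        if self.clinvar_assertion not in CLINVAR_ASSERTIONS:
            raise ValueError(f"unknown ClinVar assertion {self.clinvar_assertion!r}")


RACES = ("White", "AfricanAmerican", "ChineseAmerican", "Hispanic")


@dataclass
class Participant:
    """One phenotyped participant: T1-mapping values, history, LV features."""

    id: str
    age_at_cmr: Optional[float] = None
    sex: Optional[str] = None  # "F" / "M"
    race: Optional[str] = None
    mi_history: Optional[bool] = None
    hf_history: Optional[bool] = None
    hct: Optional[float] = None
    t1_myo_pre: Optional[float] = None
    t1_myo_post: Optional[float] = None
    t1_blood_pre: Optional[float] = None
    t1_blood_post: Optional[float] = None
    native_t1: Optional[float] = None
    ecv: Optional[float] = None
    edm_index: Optional[float] = None
    edv_index: Optional[float] = None
    esv_index: Optional[float] = None
    ed_mvr: Optional[float] = None
    ef: Optional[float] = None
    gcs: Optional[float] = None
    gls: Optional[float] = None
    lge_scar: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in ("t1_myo_pre", "t1_myo_post", "t1_blood_pre", "t1_blood_post", "native_t1"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name}={value} must be positive (participant {self.id})")
        if self.ecv is not None and not 0.0 < self.ecv < 100.0:
            raise ValueError(f"ecv={self.ecv} outside (0, 100) (participant {self.id})")
        if self.ef is not None and not 0.0 < self.ef < 100.0:
            raise ValueError(f"ef={self.ef} outside (0, 100) (participant {self.id})")
        if self.hct is not None and not 0.0 < self.hct < 1.0:
            raise ValueError(f"hct={self.hct} outside (0, 1) (participant {self.id})")
        if self.sex is not None and self.sex not in ("F", "M"):
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        if self.race is not None and self.race not in RACES:
            raise ValueError(f"unknown race {self.race!r}")


PARTICIPANT_FIELDS = [f.name for f in fields(Participant)]


@dataclass
class PanelConfig:
    """Gene panel and filtering thresholds.

    ``inheritance`` maps gene symbol to ``"AD"``, ``"AR"`` or ``"both"``
    (genes absent from the map default to AD).  ``lof_genes`` flags genes for
    which loss of function is an established disease mechanism (gates PVS1).
    ``windows`` optionally maps gene symbol to ``(chrom, start, end)``; used
    by the synthetic-cohort generator to place variants, never for filtering.
    """

    gene_list: set[str]
    maf_threshold: float = 0.001
    cadd_threshold: float = 20.0
    inheritance: dict[str, str] = field(default_factory=dict)
    lof_genes: set[str] = field(default_factory=set)
    windows: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gene_list:
            raise ValueError("gene panel is empty")
        if not 0.0 < self.maf_threshold < 1.0:
            raise ValueError(f"maf_threshold={self.maf_threshold} outside (0, 1)")
        for gene, mode in self.inheritance.items():
            if mode not in ("AD", "AR", "both"):
                raise ValueError(f"inheritance for {gene} must be AD/AR/both, got {mode!r}")

    def inheritance_mode(self, gene: str) -> str:
        return self.inheritance.get(gene, "AD")

    def min_carrier_dosage(self, gene: str) -> int:
        """Alt-allele dosage needed to count as a carrier under the gene's
        inheritance mode: AR requires homozygous alternate, AD/both one allele."""
        return 2 if self.inheritance_mode(gene) == "AR" else 1
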