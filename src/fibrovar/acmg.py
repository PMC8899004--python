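"""ACMG/AMP evidence codes, combining rules, and the phenotype-supported
VUS upgrade ("VUS+").

The engine is deliberately split in two layers:

* :func:`auto_evidence` assigns only codes computable from the annotation
  files (population frequency, in-silico consensus, ClinVar assertions,
  loss-of-function consequence in an LOF-mechanism gene).  Codes that need
  family studies or functional data (PS2, BS4, PP1, PP4, PS3, PM1, ...)
  are never auto-assigned; they can be supplied through a manual-evidence
  table and merge into the same profiles.
* :func:`combine` implements the guideline's combining-rule table over
  evidence *strengths*, so per-code strength overrides are respected.

A "VUS+" is a variant whose evidence lands in VUS but would reach Likely
Pathogenic if one additional supporting-strength pathogenic criterion —
phenotype support for the disease in the carrier — were granted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .consequences import ConsequenceVocabulary
from .models import AnnotationRecord, PanelConfig


class Strength(Enum):
    STAND_ALONE = "stand_alone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


PATHOGENIC_CODES = {
    "PVS1": Strength.VERY_STRONG,
    **{f"PS{i}": Strength.STRONG for i in range(1, 5)},
    **{f"PM{i}": Strength.MODERATE for i in range(1, 7)},
    **{f"PP{i}": Strength.SUPPORTING for i in range(1, 6)},
}
BENIGN_CODES = {
    "BA1": Strength.STAND_ALONE,
    **{f"BS{i}": Strength.STRONG for i in range(1, 5)},
    **{f"BP{i}": Strength.SUPPORTING for i in range(1, 8)},
}
ALL_CODES = {**PATHOGENIC_CODES, **BENIGN_CODES}

#: codes that require family or de-novo data and are never auto-assigned
NON_AUTOMATABLE = {"PS2", "BS4", "PP1", "PP4"}


@dataclass(frozen=True)
class EvidenceCode:
    """One invoked criterion; ``strength`` defaults to the code's native
    strength and may be overridden (e.g. PVS1 applied at moderate)."""

    code: str
    strength: Optional[Strength] = None

    def __post_init__(self) -> None:
        if self.code not in ALL_CODES:
            raise ValueError(f"unknown ACMG code {self.code!r}")
        if self.strength is None:
            object.__setattr__(self, "strength", ALL_CODES[self.code])
        if self.strength is Strength.STAND_ALONE and self.code != "BA1":
            raise ValueError("stand_alone strength is reserved for BA1")

    @property
    def benign_side(self) -> bool:
        return self.code in BENIGN_CODES


@dataclass
class EvidenceProfile:
    """Evidence set for one variant with per-code provenance (auto/manual)."""

    variant_id: str
    codes: set[EvidenceCode] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [c.code for c in self.codes]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate evidence codes in profile for {self.variant_id}")

    def add(self, code: EvidenceCode, provenance: str = "manual") -> None:
        if any(c.code == code.code for c in self.codes):
            raise ValueError(f"duplicate evidence code {code.code} for {self.variant_id}")
        self.codes.add(code)
        self.provenance[code.code] = provenance

    def code_names(self) -> set[str]:
        return {c.code for c in self.codes}


class Tier(Enum):
    PATHOGENIC = "Pathogenic"
    LIKELY_PATHOGENIC = "LikelyPathogenic"
    VUS = "VUS"
    LIKELY_BENIGN = "LikelyBenign"
    BENIGN = "Benign"


@dataclass(frozen=True)
class Classification:
    tier: Tier
    vus_plus: bool = False

    def __post_init__(self) -> None:
        if self.vus_plus and self.tier is not Tier.VUS:
            raise ValueError("vus_plus is only meaningful for VUS")

    @property
    def is_plp(self) -> bool:
        return self.tier in (Tier.PATHOGENIC, Tier.LIKELY_PATHOGENIC)

    @property
    def label(self) -> str:
        if self.vus_plus:
            return "VUS+"
        return self.tier.value


# ---------------------------------------------------------------------------
# Automatic evidence assignment
# ---------------------------------------------------------------------------

_DAMAGING = {"possibly_damaging", "probably_damaging", "deleterious", "damaging"}
_BENIGN_CALL = {"benign", "tolerated"}


def _insilico_votes(a: AnnotationRecord, cadd_threshold: float) -> tuple[int, int]:
    """(damaging, benign) counts over the non-missing in-silico predictions."""
    damaging = benign = 0
    for call in (a.polyphen_call, a.sift_call, a.fathmm_call):
        if call is None:
            continue
        if call in _DAMAGING:
            damaging += 1
        elif call in _BENIGN_CALL:
            benign += 1
    if a.cadd_phred is not None:
        if a.cadd_phred >= cadd_threshold:
            damaging += 1
        else:
            benign += 1
    return damaging, benign


def auto_evidence(
    a: AnnotationRecord,
    vocab: Optional[ConsequenceVocabulary] = None,
    panel: Optional[PanelConfig] = None,
    bs1_threshold: float = 0.001,
    use_clinvar_codes: bool = True,
) -> EvidenceProfile:
    """Assign the file-computable evidence codes for one variant.

    Codes assigned: PVS1 (LOF consequence in an LOF-mechanism panel gene),
    PM2 (absent from or rare in both population databases), PP3 / BP4
    (in-silico consensus with at least two concordant non-missing calls),
    PP5 / BP6 (reputable-source ClinVar assertion; deprecated in later
    guidance, disable with ``use_clinvar_codes=False``), BA1 (gnomAD > 5%)
    and BS1 (gnomAD above the disease-incidence threshold ``bs1_threshold``).
    Conflicting ClinVar assertions contribute nothing.
    """
    if vocab is None:
        vocab = ConsequenceVocabulary()
    maf_threshold = panel.maf_threshold if panel is not None else 0.001
    cadd_threshold = panel.cadd_threshold if panel is not None else 20.0

    profile = EvidenceProfile(variant_id=a.variant_id)

    if panel is not None and a.gene_symbol in panel.lof_genes and vocab.is_lof(a.consequence):
        profile.add(EvidenceCode("PVS1"), "auto")

    gnomad_rare = a.gnomad_af is None or a.gnomad_af < maf_threshold
    kg_rare = a.kg_af is None or a.kg_af < maf_threshold
    if gnomad_rare and kg_rare:
        profile.add(EvidenceCode("PM2"), "auto")

    damaging, benign = _insilico_votes(a, cadd_threshold)
    if damaging >= 2 and benign == 0:
        profile.add(EvidenceCode("PP3"), "auto")
    elif benign >= 2 and damaging == 0:
        profile.add(EvidenceCode("BP4"), "auto")

    if use_clinvar_codes:
        if a.clinvar_assertion in ("pathogenic", "likely_pathogenic", "path_or_lp"):
            profile.add(EvidenceCode("PP5"), "auto")
        elif a.clinvar_assertion in ("benign", "likely_benign"):
            profile.add(EvidenceCode("BP6"), "auto")

    if a.gnomad_af is not None and a.gnomad_af > 0.05:
        profile.add(EvidenceCode("BA1"), "auto")
    elif a.gnomad_af is not None and a.gnomad_af > bs1_threshold:
        profile.add(EvidenceCode("BS1"), "auto")

    return profile


# ---------------------------------------------------------------------------
# Combining rules
# ---------------------------------------------------------------------------

def _strength_counts(codes: Iterable[EvidenceCode]) -> dict[str, int]:
    n = {"pvs": 0, "ps": 0, "pm": 0, "pp": 0, "ba": 0, "bs": 0, "bp": 0}
    for c in codes:
        if c.benign_side:
            if c.strength is Strength.STAND_ALONE:
                n["ba"] += 1
            elif c.strength in (Strength.STRONG, Strength.VERY_STRONG):
                n["bs"] += 1
            else:
                n["bp"] += 1
        else:
            if c.strength is Strength.VERY_STRONG:
                n["pvs"] += 1
            elif c.strength is Strength.STRONG:
                n["ps"] += 1
            elif c.strength is Strength.MODERATE:
                n["pm"] += 1
            else:
                n["pp"] += 1
    return n


def _pathogenic(n: dict[str, int]) -> bool:
    if n["pvs"] >= 2:
        return True
    if n["pvs"] >= 1 and (
        n["ps"] >= 1
        or n["pm"] >= 2
        or (n["pm"] >= 1 and n["pp"] >= 1)
        or n["pp"] >= 2
    ):
        return True
    if n["ps"] >= 2:
        return True
    if n["ps"] >= 1 and (
        n["pm"] >= 3
        or (n["pm"] >= 2 and n["pp"] >= 2)
        or (n["pm"] >= 1 and n["pp"] >= 4)
    ):
        return True
    return False


def _likely_pathogenic(n: dict[str, int]) -> bool:
    return (
        (n["pvs"] >= 1 and n["pm"] >= 1)
        or (n["ps"] >= 1 and 1 <= n["pm"] <= 2)
        or (n["ps"] >= 1 and n["pp"] >= 2)
        or n["pm"] >= 3
        or (n["pm"] >= 2 and n["pp"] >= 2)
        or (n["pm"] >= 1 and n["pp"] >= 4)
    )


def _benign(n: dict[str, int]) -> bool:
    return n["ba"] >= 1 or n["bs"] >= 2


def _likely_benign(n: dict[str, int]) -> bool:
    return (n["bs"] >= 1 and n["bp"] >= 1) or n["bp"] >= 2


def _conflicting(n: dict[str, int]) -> bool:
    """Contradictory evidence: both sides qualify for a call, or one side
    qualifies while the other holds strong-or-stronger evidence (e.g. BA1
    alongside PS1)."""
    pathogenic_side = _pathogenic(n) or _likely_pathogenic(n)
    benign_side = _benign(n) or _likely_benign(n)
    if pathogenic_side and benign_side:
        return True
    if benign_side and (n["ps"] >= 1 or n["pvs"] >= 1):
        return True
    if pathogenic_side and (n["ba"] >= 1 or n["bs"] >= 1):
        return True
    return False


def _resolve(n: dict[str, int]) -> Tier:
    if _conflicting(n):
        return Tier.VUS
    if _pathogenic(n):
        return Tier.PATHOGENIC
    if _likely_pathogenic(n):
        return Tier.LIKELY_PATHOGENIC
    if _benign(n):
        return Tier.BENIGN
    if _likely_benign(n):
        return Tier.LIKELY_BENIGN
    return Tier.VUS


def combine(profile: EvidenceProfile) -> Classification:
    """Fold an evidence profile through the combining-rule table.

    Contradictory evidence (see :func:`_conflicting`) yields VUS.
    """
    return Classification(_resolve(_strength_counts(profile.codes)))


def apply_vus_plus(
    profile: EvidenceProfile,
    base: Classification,
    support_strength: Strength = Strength.SUPPORTING,
) -> Classification:
    """Flag a VUS as VUS+ when one extra phenotype-support criterion (at
    ``support_strength``, default supporting) would lift it to LP or P.
    Non-VUS classifications pass through unchanged."""
    if base.tier is not Tier.VUS:
        return base
    n = _strength_counts(profile.codes)
    bucket = {
        Strength.VERY_STRONG: "pvs",
        Strength.STRONG: "ps",
        Strength.MODERATE: "pm",
        Strength.SUPPORTING: "pp",
    }[support_strength]
    n = dict(n)
    n[bucket] += 1
    if _resolve(n) in (Tier.PATHOGENIC, Tier.LIKELY_PATHOGENIC):
        return Classification(Tier.VUS, vus_plus=True)
    return base


def classify_callset(
    profiles: dict[str, EvidenceProfile],
    support_strength: Strength = Strength.SUPPORTING,
) -> dict[str, Classification]:
    """Classify every profile (combine, then the VUS+ upgrade check)."""
    out = {}
    for vid, profile in profiles.items():
        base = combine(profile)
        out[vid] = apply_vus_plus(profile, base, support_strength)
    return out


def tier_summary(classifications: dict[str, Classification]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for cls in classifications.values():
        counts[cls.label] = counts.get(cls.label, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Manual evidence table and serialization
# ---------------------------------------------------------------------------

def read_manual_evidence(path: str | Path) -> dict[str, list[EvidenceCode]]:
    """Read curator-supplied codes: TSV with columns variant_id, codes
    (comma-separated, each ``CODE`` or ``CODE@strength``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"variant_id", "codes"} <= set(df.columns):
        raise ValueError(f"{path}: manual evidence table needs variant_id and codes columns")
    out: dict[str, list[EvidenceCode]] = {}
    for _, row in df.iterrows():
        codes = []
        for token in str(row["codes"]).split(","):
            token = token.strip()
            if not token:
                continue
            if "@" in token:
                name, strength = token.split("@", 1)
                codes.append(EvidenceCode(name.strip(), Strength(strength.strip())))
            else:
                codes.append(EvidenceCode(token))
        out.setdefault(row["variant_id"].strip(), []).extend(codes)
    return out


def merge_manual_evidence(
    profiles: dict[str, EvidenceProfile],
    manual: dict[str, list[EvidenceCode]],
) -> dict[str, EvidenceProfile]:
    """Overlay manual codes on auto profiles.  A manual code replaces an auto
    code of the same name (curator wins, e.g. to override strength)."""
    merged = {}
    for vid, profile in profiles.items():
        codes = {c.code: (c, profile.provenance.get(c.code, "auto")) for c in profile.codes}
        for code in manual.get(vid, []):
            codes[code.code] = (code, "manual")
        new = EvidenceProfile(variant_id=vid)
        for code, prov in codes.values():
            new.add(code, prov)
        merged[vid] = new
    for vid, codes in manual.items():
        if vid not in merged:
            new = EvidenceProfile(variant_id=vid)
            for code in codes:
                new.add(code, "manual")
            merged[vid] = new
    return merged


def write_classifications(
    profiles: dict[str, EvidenceProfile],
    classifications: dict[str, Classification],
    path: str | Path,
) -> Path:
    path = Path(path)
    rows = []
    for vid in sorted(classifications):
        profile = profiles.get(vid, EvidenceProfile(variant_id=vid))
        codes = ",".join(sorted(c.code for c in profile.codes))
        cls = classifications[vid]
        rows.append(
            {
                "variant_id": vid,
                "codes": codes,
                "tier": cls.tier.value,
                "vus_plus": int(cls.vus_plus),
                "label": cls.label,
            }
        )
    pd.DataFrame(rows, columns=["variant_id", "codes", "tier", "vus_plus", "label"]).to_csv(
        path, sep="\t", index=False
    )
    return path
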