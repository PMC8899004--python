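"""T1-mapping phenotype derivation and quartile-based case assignment.

ECV is computed from the contrast-induced change in longitudinal relaxation
rate (R1 = 1/T1) of myocardium relative to blood, scaled by the plasma
fraction:

    lambda = (1/T1_myo_post - 1/T1_myo_pre) / (1/T1_blood_post - 1/T1_blood_pre)
    ECV%   = 100 * (1 - Hct) * lambda

Participants with a history of myocardial infarction or heart failure are
excluded (their fibrosis may be replacement scar rather than interstitial).
Cases are participants strictly above the 75th percentile of ECV *or* of
native T1 in the post-exclusion population; everyone else is a control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import Participant


@dataclass(frozen=True)
class EcvInputs:
    """Pre/post-contrast T1 (ms) of myocardium and blood, plus hematocrit."""

    t1_myo_pre: float
    t1_myo_post: float
    t1_blood_pre: float
    t1_blood_post: float
    hct: float

    def __post_init__(self) -> None:
        for name in ("t1_myo_pre", "t1_myo_post", "t1_blood_pre", "t1_blood_post"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.hct < 1.0:
            raise ValueError(f"hct={self.hct} outside (0, 1)")
        if self.t1_myo_post >= self.t1_myo_pre or self.t1_blood_post >= self.t1_blood_pre:
            raise ValueError("post-contrast T1 must be shorter than pre-contrast T1")


def partition_coefficient(x: EcvInputs) -> float:
    """Gadolinium partition coefficient lambda = ΔR1_myo / ΔR1_blood."""
    d_r1_myo = 1.0 / x.t1_myo_post - 1.0 / x.t1_myo_pre
    d_r1_blood = 1.0 / x.t1_blood_post - 1.0 / x.t1_blood_pre
    if d_r1_blood <= 0:
        raise ValueError("non-positive blood ΔR1: invalid contrast dynamics")
    return d_r1_myo / d_r1_blood


def ecv_percent(x: EcvInputs) -> float:
    """Extracellular volume fraction in percent: 100·(1−Hct)·λ."""
    return 100.0 * (1.0 - x.hct) * partition_coefficient(x)


def derive_ecv(p: Participant) -> Optional[float]:
    """Participant's ECV: the supplied value if present, otherwise derived
    from T1 values and hematocrit when all five inputs are available."""
    if p.ecv is not None:
        return p.ecv
    needed = (p.t1_myo_pre, p.t1_myo_post, p.t1_blood_pre, p.t1_blood_post, p.hct)
    if any(v is None for v in needed):
        return None
    return ecv_percent(EcvInputs(*needed))


def apply_exclusions(participants: Sequence[Participant]) -> tuple[list[Participant], list[Participant]]:
    """Split into (included, excluded) by MI/HF history; order-preserving."""
    missing = [p.id for p in participants if p.mi_history is None or p.hf_history is None]
    if missing:
        raise ValueError(f"participants lacking MI/HF history flags: {missing}")
    included = [p for p in participants if not (p.mi_history or p.hf_history)]
    excluded = [p for p in participants if p.mi_history or p.hf_history]
    return included, excluded


def quartile_threshold(values: Iterable[float], q: float = 0.75) -> float:
    """q-quantile by linear interpolation between order statistics (missing
    values dropped); the common default convention in scientific software."""
    if not 0.0 < q < 1.0:
        raise ValueError(f"q={q} outside (0, 1)")
    arr = np.asarray([v for v in values if v is not None and not np.isnan(v)], dtype=float)
    if arr.size < 4:
        raise ValueError(f"need at least 4 non-missing values, got {arr.size}")
    return float(np.quantile(arr, q, method="linear"))


@dataclass(frozen=True)
class CaseDefinition:
    """Case iff ECV > ecv_threshold OR native T1 > t1_threshold (strict)."""

    ecv_threshold: float
    native_t1_threshold: float
    q: float = 0.75

    def is_case(self, ecv: float, native_t1: float) -> bool:
        return ecv > self.ecv_threshold or native_t1 > self.native_t1_threshold

    def category(self, ecv: float, native_t1: float) -> str:
        high_ecv = ecv > self.ecv_threshold
        high_t1 = native_t1 > self.native_t1_threshold
        if high_ecv and high_t1:
            return "both"
        if high_ecv:
            return "ecv_only"
        if high_t1:
            return "t1_only"
        return "control"


@dataclass
class CaseAssignment:
    definition: CaseDefinition
    status: dict[str, str]  # id -> "case" / "control"
    category: dict[str, str]  # id -> "ecv_only" / "t1_only" / "both" / "control"

    @property
    def n_cases(self) -> int:
        return sum(1 for s in self.status.values() if s == "case")

    @property
    def n_controls(self) -> int:
        return sum(1 for s in self.status.values() if s == "control")

    def decomposition(self) -> dict[str, int]:
        out = {"ecv_only": 0, "t1_only": 0, "both": 0}
        for cat in self.category.values():
            if cat in out:
                out[cat] += 1
        return out


def assign_case_status(
    participants: Sequence[Participant],
    definition: Optional[CaseDefinition] = None,
    q: float = 0.75,
) -> CaseAssignment:
    """Assign case/control labels by the top-quartile union rule.

    Thresholds are computed from the supplied (post-exclusion) population
    unless an explicit :class:`CaseDefinition` is given — e.g. to reuse
    thresholds published for another cohort.  Every participant must have
    ECV (supplied or derivable) and native T1.
    """
    ecv = {p.id: derive_ecv(p) for p in participants}
    t1 = {p.id: p.native_t1 for p in participants}
    missing = [pid for pid in ecv if ecv[pid] is None or t1[pid] is None]
    if missing:
        raise ValueError(f"participants lacking ECV or native T1: {missing[:10]}")

    if definition is None:
        definition = CaseDefinition(
            ecv_threshold=quartile_threshold(ecv.values(), q),
            native_t1_threshold=quartile_threshold(t1.values(), q),
            q=q,
        )

    status, category = {}, {}
    for p in participants:
        cat = definition.category(ecv[p.id], t1[p.id])
        category[p.id] = cat
        status[p.id] = "control" if cat == "control" else "case"
    return CaseAssignment(definition=definition, status=status, category=category)


def case_assignment_frame(participants: Sequence[Participant], assignment: CaseAssignment) -> pd.DataFrame:
    """Per-participant export (id, ecv, native_t1, status, category)."""
    rows = [
        {
            "id": p.id,
            "ecv": derive_ecv(p),
            "native_t1": p.native_t1,
            "status": assignment.status[p.id],
            "category": assignment.category[p.id],
        }
        for p in participants
    ]
    return pd.DataFrame(rows, columns=["id", "ecv", "native_t1", "status", "category"])
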