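"""Carrier enrichment statistics: exact two-sided test, odds ratio,
group comparisons, and Monte-Carlo power for the case/control design.

The two-sided exact test uses the minimum-likelihood convention: the p-value
sums the hypergeometric probabilities of every table with the observed
margins whose point probability does not exceed that of the observed table
(within a small relative tolerance to absorb floating-point ties).  Point
probabilities are evaluated from log-factorials for numerical stability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .acmg import Classification
from .models import AnnotationRecord, GenotypeMatrix, PanelConfig

#: relative tolerance when comparing point probabilities to the observed one
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class TwoByTwoTable:
    """Carrier counts: a/b = case carriers/non-carriers, c/d = controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def prevalence_case(self) -> float:
        """Case carrier prevalence in percent."""
        return 100.0 * self.a / self.n_cases if self.n_cases else float("nan")

    @property
    def prevalence_control(self) -> float:
        return 100.0 * self.c / self.n_controls if self.n_controls else float("nan")


def _log_factorials(n: int) -> np.ndarray:
    return np.array([math.lgamma(i + 1) for i in range(n + 1)])


def fisher_exact_two_sided(t: TwoByTwoTable) -> float:
    """Two-sided exact p by minimum-likelihood summation over the
    hypergeometric support of the observed margins.

    Degenerate margins (an empty row or an all-carrier/no-carrier column)
    admit only one table, so p = 1 with a warning.
    """
    n = t.a + t.b + t.c + t.d
    k = t.a + t.c  # total carriers
    m = t.n_cases
    if n == 0 or k == 0 or k == n or m == 0 or m == n:
        warnings.warn("degenerate 2x2 margins: exact test is uninformative (p = 1)")
        return 1.0

    lf = _log_factorials(n)
    lo = max(0, m + k - n)
    hi = min(m, k)
    support = np.arange(lo, hi + 1)
    # log P(X = x) for hypergeometric(n, k, m), via log-factorials
    log_pmf = (
        lf[k] - lf[support] - lf[k - support]
        + lf[n - k] - lf[m - support] - lf[n - k - m + support]
        - (lf[n] - lf[m] - lf[n - m])
    )
    log_obs = log_pmf[t.a - lo]
    included = log_pmf <= log_obs + math.log1p(_TIE_RTOL)
    if included.all():
        return 1.0  # whole support included: exactly 1 regardless of roundoff
    p = float(np.exp(log_pmf[included]).sum())
    return min(p, 1.0)


def odds_ratio(t: TwoByTwoTable, haldane: bool = False) -> float:
    """(a·d)/(b·c); infinity for a zero denominator with a positive
    numerator; optional Haldane–Anscombe 0.5 continuity correction."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    num, den = a * d, b * c
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return num / den


@dataclass(frozen=True)
class EnrichmentResult:
    table: TwoByTwoTable
    prevalence_case: float
    prevalence_control: float
    odds_ratio: float
    p_two_sided: float
    method: str = "fisher_min_likelihood"

    def as_dict(self) -> dict:
        return {
            "table": [self.table.a, self.table.b, self.table.c, self.table.d],
            "prevalence_case_percent": self.prevalence_case,
            "prevalence_control_percent": self.prevalence_control,
            "odds_ratio": self.odds_ratio,
            "p_two_sided": self.p_two_sided,
            "method": self.method,
        }


def enrichment(t: TwoByTwoTable) -> EnrichmentResult:
    return EnrichmentResult(
        table=t,
        prevalence_case=t.prevalence_case,
        prevalence_control=t.prevalence_control,
        odds_ratio=odds_ratio(t),
        p_two_sided=fisher_exact_two_sided(t),
    )


# ---------------------------------------------------------------------------
# Carrier counting
# ---------------------------------------------------------------------------

#: classification labels making up the two reported tier-sets
TIER_SETS = {
    "plp": ("Pathogenic", "LikelyPathogenic"),
    "plp_vusplus": ("Pathogenic", "LikelyPathogenic", "VUS+"),
}


def carriers_of(
    genotypes: GenotypeMatrix,
    variant_ids: Sequence[str],
    annotations: dict[str, AnnotationRecord],
    panel: PanelConfig,
    participant_ids: Sequence[str],
) -> set[str]:
    """Participants carrying >=1 of the given variants under each variant
    gene's inheritance rule (AR genes require homozygous alternate)."""
    carriers: set[str] = set()
    ids = list(participant_ids)
    for vid in variant_ids:
        gene = annotations[vid].gene_symbol
        min_dosage = panel.min_carrier_dosage(gene)
        codes = genotypes.genotypes(vid, ids)
        for pid, code in zip(ids, codes):
            if code >= min_dosage:
                carriers.add(pid)
    return carriers


def carrier_counts(
    genotypes: GenotypeMatrix,
    classifications: dict[str, Classification],
    case_map: dict[str, str],
    panel: PanelConfig,
    annotations: dict[str, AnnotationRecord],
) -> dict[str, TwoByTwoTable]:
    """Person-level 2x2 carrier tables for each reported tier-set.

    A participant counts once regardless of how many qualifying variants
    they carry.  ``case_map`` maps participant id to "case"/"control" and
    defines the analysis population; every id must be genotyped.
    """
    unknown = [pid for pid in case_map if pid not in genotypes.participant_ids]
    if unknown:
        raise ValueError(f"participants in case map but not genotyped: {unknown[:10]}")
    cases = [pid for pid, s in case_map.items() if s == "case"]
    controls = [pid for pid, s in case_map.items() if s == "control"]

    tables = {}
    for name, labels in TIER_SETS.items():
        qualifying = [vid for vid, cls in classifications.items() if cls.label in labels]
        case_carriers = carriers_of(genotypes, qualifying, annotations, panel, cases)
        control_carriers = carriers_of(genotypes, qualifying, annotations, panel, controls)
        tables[name] = TwoByTwoTable(
            a=len(case_carriers),
            b=len(cases) - len(case_carriers),
            c=len(control_carriers),
            d=len(controls) - len(control_carriers),
        )
    return tables


# ---------------------------------------------------------------------------
# Group comparisons (baseline-table style)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    variable: str
    kind: str  # "continuous" / "categorical"
    statistic: float
    p_value: float
    summary: dict[str, str] = field(default_factory=dict)


def compare_groups(
    values_a: Sequence,
    values_b: Sequence,
    variable: str = "",
    kind: str = "continuous",
) -> GroupComparison:
    """Two-group comparison as in a baseline characteristics table.

    Continuous variables: unequal-variance (Welch) t test, missing dropped,
    summaries as "mean (SD)".  Categorical variables: chi-square on the
    level-by-group contingency table, summaries as "n (%)" per level.
    """
    if kind == "continuous":
        a = np.asarray([v for v in values_a if v is not None and not np.isnan(v)], dtype=float)
        b = np.asarray([v for v in values_b if v is not None and not np.isnan(v)], dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"{variable}: need >=2 non-missing values per group")
        if np.array_equal(a, b):
            # identical samples: zero difference by construction
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_ind(a, b, equal_var=False)
        summary = {
            "group_a": f"{a.mean():.1f} ({a.std(ddof=1):.1f})",
            "group_b": f"{b.mean():.1f} ({b.std(ddof=1):.1f})",
        }
        return GroupComparison(variable, kind, float(stat), float(p), summary)
    if kind == "categorical":
        a = [v for v in values_a if v is not None]
        b = [v for v in values_b if v is not None]
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"{variable}: need >=2 non-missing values per group")
        levels = sorted(set(a) | set(b), key=str)
        table = np.array([[a.count(l) for l in levels], [b.count(l) for l in levels]])
        stat, p, _, _ = sps.chi2_contingency(table)
        summary = {}
        for i, group in enumerate(("group_a", "group_b")):
            total = table[i].sum()
            summary[group] = "; ".join(
                f"{l}: {table[i, j]} ({100 * table[i, j] / total:.1f}%)" for j, l in enumerate(levels)
            )
        return GroupComparison(variable, kind, float(stat), float(p), summary)
    raise ValueError(f"unknown comparison kind {kind!r}")


# ---------------------------------------------------------------------------
# Monte-Carlo power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for the two-group rare-carrier power simulation."""

    n_cases: int = 420
    n_controls: int = 715
    p_case: float = 0.016
    p_control: float = 0.001
    alpha: float = 0.05
    n_reps: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_control <= self.p_case <= 1.0:
            raise ValueError("need 0 <= p_control <= p_case <= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    se: float
    n_reps: int

    @property
    def power_percent(self) -> float:
        return 100.0 * self.power


def power_simulation(spec: PowerSpec) -> PowerEstimate:
    """Estimate power of the two-sided exact test by simulating binomial
    carrier counts; returns the rejection fraction and its binomial SE.

    Identical simulated tables share one exact-test evaluation, so runtime is
    governed by the number of distinct (case, control) carrier-count pairs,
    not by ``n_reps``.
    """
    rng = np.random.default_rng(spec.seed)
    a = rng.binomial(spec.n_cases, spec.p_case, size=spec.n_reps)
    c = rng.binomial(spec.n_controls, spec.p_control, size=spec.n_reps)
    pairs, counts = np.unique(np.stack([a, c], axis=1), axis=0, return_counts=True)
    rejected = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate all-zero draws give p = 1
        for (ai, ci), count in zip(pairs, counts):
            table = TwoByTwoTable(int(ai), spec.n_cases - int(ai), int(ci), spec.n_controls - int(ci))
            if fisher_exact_two_sided(table) < spec.alpha:
                rejected += int(count)
    power = rejected / spec.n_reps
    se = math.sqrt(power * (1.0 - power) / spec.n_reps)
    return PowerEstimate(power=power, se=se, n_reps=spec.n_reps)
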