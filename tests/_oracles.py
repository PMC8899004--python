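"""Independent reference implementations used only for cross-checking.

Each oracle is a direct, brute-force transcription of the published rule it
checks, structured differently from the library code: the classification
oracle enumerates the guideline's disjunctive clauses as minimum-count
patterns, and the exact-test oracle sums hypergeometric weights in exact
integer arithmetic.
"""

from __future__ import annotations

from collections import Counter
from math import comb

from fibrovar.acmg import EvidenceProfile, Strength

# --- ACMG combining-rule oracle -------------------------------------------

_PATHOGENIC_CLAUSES = [
    {"pvs": 2},
    {"pvs": 1, "ps": 1},
    {"pvs": 1, "pm": 2},
    {"pvs": 1, "pm": 1, "pp": 1},
    {"pvs": 1, "pp": 2},
    {"ps": 2},
    {"ps": 1, "pm": 3},
    {"ps": 1, "pm": 2, "pp": 2},
    {"ps": 1, "pm": 1, "pp": 4},
]
_LIKELY_PATHOGENIC_CLAUSES = [
    {"pvs": 1, "pm": 1},
    {"ps": 1, "pm": 1},
    {"ps": 1, "pp": 2},
    {"pm": 3},
    {"pm": 2, "pp": 2},
    {"pm": 1, "pp": 4},
]
_BENIGN_CLAUSES = [{"ba": 1}, {"bs": 2}]
_LIKELY_BENIGN_CLAUSES = [{"bs": 1, "bp": 1}, {"bp": 2}]


def _bucket(code) -> str:
    if code.benign_side:
        return {
            Strength.STAND_ALONE: "ba",
            Strength.VERY_STRONG: "bs",
            Strength.STRONG: "bs",
            Strength.MODERATE: "bp",
            Strength.SUPPORTING: "bp",
        }[code.strength]
    return {
        Strength.VERY_STRONG: "pvs",
        Strength.STRONG: "ps",
        Strength.MODERATE: "pm",
        Strength.SUPPORTING: "pp",
    }[code.strength]


def _meets(counts: Counter, clause: dict) -> bool:
    return all(counts[key] >= minimum for key, minimum in clause.items())


def oracle_combine_label(profile: EvidenceProfile) -> str:
    """5-tier call by clause enumeration; contradictions collapse to VUS.

    A contradiction is either both sides qualifying for a call, or one side
    qualifying while the other carries strong-or-stronger evidence (BA1/BS
    against PS/PVS), e.g. {BA1, PS1}.
    """
    counts = Counter(_bucket(c) for c in profile.codes)
    pathogenic = any(_meets(counts, cl) for cl in _PATHOGENIC_CLAUSES)
    likely_pathogenic = any(_meets(counts, cl) for cl in _LIKELY_PATHOGENIC_CLAUSES)
    benign = any(_meets(counts, cl) for cl in _BENIGN_CLAUSES)
    likely_benign = any(_meets(counts, cl) for cl in _LIKELY_BENIGN_CLAUSES)
    path_call = pathogenic or likely_pathogenic
    benign_call = benign or likely_benign
    strong_pathogenic = counts["ps"] + counts["pvs"] >= 1
    strong_benign = counts["ba"] + counts["bs"] >= 1
    if (path_call and benign_call) or (benign_call and strong_pathogenic) or (path_call and strong_benign):
        return "VUS"
    if pathogenic:
        return "Pathogenic"
    if likely_pathogenic:
        return "LikelyPathogenic"
    if benign:
        return "Benign"
    if likely_benign:
        return "LikelyBenign"
    return "VUS"


# --- exact-test oracle -----------------------------------------------------

def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Minimum-likelihood two-sided p by exact integer enumeration of the
    hypergeometric support (ties decided in integer arithmetic)."""
    n = a + b + c + d
    k = a + c
    m = a + b
    if n == 0 or k in (0, n) or m in (0, n):
        return 1.0
    lo, hi = max(0, m + k - n), min(m, k)
    weights = {x: comb(k, x) * comb(n - k, m - x) for x in range(lo, hi + 1)}
    observed = weights[a]
    return sum(w for w in weights.values() if w <= observed) / sum(weights.values())


# --- filter-cascade oracle -------------------------------------------------

def oracle_cascade_final(variants, annotations, genotypes, panel, subsample_ids, vocab) -> set[str]:
    """Final surviving set as a plain conjunction of per-variant predicates,
    evaluated independently of any staging."""
    from fibrovar.models import MISSING_GT

    survivors = set()
    for v in variants:
        a = annotations.get(v.variant_id)
        if a is None or a.gene_symbol not in panel.gene_list:
            continue
        codes = [int(x) for x in genotypes.genotypes(v.variant_id, subsample_ids) if x != MISSING_GT]
        if len(set(codes)) <= 1:
            continue
        if not (a.consequence in vocab.coding or a.consequence in vocab.canonical_splice):
            continue
        if a.gnomad_af is not None and a.gnomad_af >= panel.maf_threshold:
            continue
        if a.kg_af is not None and a.kg_af >= panel.maf_threshold:
            continue
        if a.consequence in vocab.synonymous:
            continue
        branch1 = (a.polyphen_call in (None, "possibly_damaging", "probably_damaging")) and (
            a.cadd_phred is None or a.cadd_phred >= panel.cadd_threshold
        )
        branch2 = (a.sift_call in (None, "deleterious")) and (a.fathmm_call in (None, "damaging"))
        if not (branch1 or branch2):
            continue
        if a.clinvar_assertion in ("benign", "likely_benign"):
            continue
        survivors.add(v.variant_id)
    return survivors
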