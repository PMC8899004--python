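"""Five-criterion rare-variant filter cascade for a cardiomyopathy gene panel.

Starting from every call in the panel genes, variants are kept only if they
are (after restriction to the panel and to sites polymorphic in the
phenotyped subsample): located in coding sequence or canonical splice
donor/acceptor sites; rarer than the MAF threshold in both gnomAD and
1000 Genomes; non-synonymous; predicted damaging — or unscored — by
(PolyPhen and CADD) or by (SIFT and FATHMM); and free of benign ClinVar
assertions.  Each predicate is exposed on its own so the cascade can be
cross-checked against an independent per-variant evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from .consequences import ConsequenceVocabulary, worst_consequence  # re-export
from .models import MISSING_GT, AnnotationRecord, GenotypeMatrix, PanelConfig, VariantRecord

__all__ = [
    "STAGES",
    "FilterTrace",
    "worst_consequence",
    "is_monomorphic",
    "passes_frequency",
    "passes_in_silico",
    "passes_clinvar_screen",
    "run_cascade",
]

#: fixed stage order of the cascade
STAGES = (
    "panel",
    "non_monomorphic",
    "coding_or_splice",
    "rare",
    "non_synonymous",
    "in_silico",
    "clinvar_non_benign",
)


@dataclass
class FilterTrace:
    """Per-stage surviving variant sets and counts (the selection funnel)."""

    input_ids: set[str]
    surviving: dict[str, set[str]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        out = {"input": len(self.input_ids)}
        out.update({stage: len(self.surviving[stage]) for stage in STAGES})
        return out

    @property
    def final_ids(self) -> set[str]:
        return self.surviving[STAGES[-1]]

    def validate(self) -> None:
        previous = self.input_ids
        for stage in STAGES:
            current = self.surviving[stage]
            if not current <= previous:
                raise AssertionError(f"stage {stage} is not a subset of its predecessor")
            previous = current

    def to_json(self) -> str:
        payload = {
            "counts": self.counts,
            "surviving": {stage: sorted(ids) for stage, ids in self.surviving.items()},
        }
        return json.dumps(payload, indent=2)

    def funnel_table(self) -> str:
        """Human-readable funnel: stage, surviving n, removed at stage."""
        lines = [f"{'stage':<20} {'n':>6} {'removed':>8}"]
        lines.append(f"{'input':<20} {len(self.input_ids):>6} {'-':>8}")
        previous = len(self.input_ids)
        for stage in STAGES:
            n = len(self.surviving[stage])
            lines.append(f"{stage:<20} {n:>6} {previous - n:>8}")
            previous = n
        return "\n".join(lines)


def is_monomorphic(
    variant_id: str,
    genotypes: GenotypeMatrix,
    subsample_ids: list[str],
) -> bool:
    """True iff all non-missing genotype codes in the subsample are equal.

    A variant with no non-missing calls in the subsample is monomorphic
    (vacuously: it shows no variation there).
    """
    codes = genotypes.genotypes(variant_id, subsample_ids)
    observed = {int(c) for c in codes if c != MISSING_GT}
    return len(observed) <= 1


def passes_frequency(a: AnnotationRecord, threshold: float) -> bool:
    """Strictly below ``threshold`` in both gnomAD and 1000 Genomes; an
    absent frequency (variant unobserved in the reference database) passes."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    gnomad_ok = a.gnomad_af is None or a.gnomad_af < threshold
    kg_ok = a.kg_af is None or a.kg_af < threshold
    return gnomad_ok and kg_ok


def passes_in_silico(a: AnnotationRecord, cadd_threshold: float = 20.0) -> bool:
    """Deleterious — or unscored — by (PolyPhen AND CADD), or damaging — or
    unscored — by (SIFT AND FATHMM).

    Missing predictions count in favour of keeping the variant, so a variant
    with no scores at all passes; this matches the leniency of treating
    "no prediction" as non-exculpatory.
    """
    polyphen_ok = a.polyphen_call is None or a.polyphen_call in ("possibly_damaging", "probably_damaging")
    cadd_ok = a.cadd_phred is None or a.cadd_phred >= cadd_threshold
    sift_ok = a.sift_call is None or a.sift_call == "deleterious"
    fathmm_ok = a.fathmm_call is None or a.fathmm_call == "damaging"
    return (polyphen_ok and cadd_ok) or (sift_ok and fathmm_ok)


def passes_clinvar_screen(a: AnnotationRecord) -> bool:
    """Non-benign ClinVar evidence: only benign/likely-benign assertions fail.
    Absence from ClinVar is not benign evidence, so ``not_found`` passes."""
    return a.clinvar_assertion not in ("benign", "likely_benign")


def _passes_non_synonymous(a: AnnotationRecord, vocab: ConsequenceVocabulary) -> bool:
    # start/stop losses and splice-site terms alter the protein and count as
    # non-synonymous; synonymous and stop-retained changes do not.
    return not vocab.is_synonymous(a.consequence)


def run_cascade(
    variants: list[VariantRecord],
    annotations: dict[str, AnnotationRecord],
    genotypes: GenotypeMatrix,
    panel: PanelConfig,
    subsample_ids: list[str],
    vocab: Optional[ConsequenceVocabulary] = None,
) -> FilterTrace:
    """Apply the filter cascade in its fixed stage order and return the trace.

    ``annotations`` must cover every variant that survives the panel stage;
    a surviving variant without annotation raises with its variant_id.
    """
    if vocab is None:
        vocab = ConsequenceVocabulary()

    input_ids = {v.variant_id for v in variants}
    trace = FilterTrace(input_ids=input_ids)

    def annotation(vid: str) -> AnnotationRecord:
        try:
            return annotations[vid]
        except KeyError:
            raise ValueError(f"missing annotation for variant {vid}") from None

    current = {vid for vid in input_ids if vid in annotations and annotations[vid].gene_symbol in panel.gene_list}
    trace.surviving["panel"] = current

    current = {vid for vid in current if not is_monomorphic(vid, genotypes, subsample_ids)}
    trace.surviving["non_monomorphic"] = current

    current = {vid for vid in current if vocab.is_coding_or_splice(annotation(vid).consequence)}
    trace.surviving["coding_or_splice"] = current

    current = {vid for vid in current if passes_frequency(annotation(vid), panel.maf_threshold)}
    trace.surviving["rare"] = current

    current = {vid for vid in current if _passes_non_synonymous(annotation(vid), vocab)}
    trace.surviving["non_synonymous"] = current

    current = {vid for vid in current if passes_in_silico(annotation(vid), panel.cadd_threshold)}
    trace.surviving["in_silico"] = current

    current = {vid for vid in current if passes_clinvar_screen(annotation(vid))}
    trace.surviving["clinvar_non_benign"] = current

    trace.validate()
    return trace
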