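"""Sequence-ontology consequence vocabulary with a total severity order.

The default vocabulary covers the VEP consequence terms this pipeline
consumes, ordered from least to most severe.  The ordering only needs to be
total and to rank truncating/splice-disrupting terms above missense and
missense above synonymous; ties in published severity rankings are broken
arbitrarily but deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: least → most severe
DEFAULT_SEVERITY_ORDER = [
    "intergenic_variant",
    "downstream_gene_variant",
    "upstream_gene_variant",
    "non_coding_transcript_exon_variant",
    "intron_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "synonymous_variant",
    "stop_retained_variant",
    "splice_region_variant",
    "protein_altering_variant",
    "missense_variant",
    "inframe_deletion",
    "inframe_insertion",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "start_lost",
    "stop_lost",
    "frameshift_variant",
    "stop_gained",
]

DEFAULT_CODING = {
    "synonymous_variant",
    "stop_retained_variant",
    "protein_altering_variant",
    "missense_variant",
    "inframe_deletion",
    "inframe_insertion",
    "start_lost",
    "stop_lost",
    "frameshift_variant",
    "stop_gained",
}

DEFAULT_CANONICAL_SPLICE = {"splice_acceptor_variant", "splice_donor_variant"}

DEFAULT_SYNONYMOUS = {"synonymous_variant", "stop_retained_variant"}

DEFAULT_LOF = {
    "stop_gained",
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "start_lost",
}


@dataclass
class ConsequenceVocabulary:
    """Ordered consequence terms plus the subsets the filter cascade needs."""

    severity_order: list[str] = field(default_factory=lambda: list(DEFAULT_SEVERITY_ORDER))
    coding: set[str] = field(default_factory=lambda: set(DEFAULT_CODING))
    canonical_splice: set[str] = field(default_factory=lambda: set(DEFAULT_CANONICAL_SPLICE))
    synonymous: set[str] = field(default_factory=lambda: set(DEFAULT_SYNONYMOUS))
    lof: set[str] = field(default_factory=lambda: set(DEFAULT_LOF))

    def __post_init__(self) -> None:
        if len(set(self.severity_order)) != len(self.severity_order):
            raise ValueError("severity order contains duplicate terms")
        known = set(self.severity_order)
        for name, subset in (
            ("coding", self.coding),
            ("canonical_splice", self.canonical_splice),
            ("synonymous", self.synonymous),
            ("lof", self.lof),
        ):
            unknown = subset - known
            if unknown:
                raise ValueError(f"{name} terms not in severity order: {sorted(unknown)}")
        if not self.lof <= (self.coding | self.canonical_splice):
            raise ValueError("lof terms must be coding or canonical-splice terms")
        self._rank = {term: i for i, term in enumerate(self.severity_order)}

    def rank(self, term: str) -> int:
        try:
            return self._rank[term]
        except KeyError:
            raise ValueError(f"unknown consequence term {term!r}") from None

    def is_coding_or_splice(self, term: str) -> bool:
        self.rank(term)
        return term in self.coding or term in self.canonical_splice

    def is_synonymous(self, term: str) -> bool:
        self.rank(term)
        return term in self.synonymous

    def is_lof(self, term: str) -> bool:
        self.rank(term)
        return term in self.lof


def worst_consequence(terms: list[str], vocab: ConsequenceVocabulary | None = None) -> str:
    """Most severe consequence across transcripts.

    This is the per-variant reduction applied upstream annotation tables are
    expected to carry already; it is exposed for callers holding raw
    per-transcript terms.
    """
    if vocab is None:
        vocab = ConsequenceVocabulary()
    if not terms:
        raise ValueError("empty consequence list")
    return max(terms, key=vocab.rank)
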