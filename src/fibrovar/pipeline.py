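"""End-to-end orchestration: inputs → exclusions/case status → filter
cascade → classification → carrier enrichment → reports.

Machine-readable outputs (JSON/TSV/CSV) are written under the configured
output directory; progress and per-stage counts are logged to stderr so the
selection funnel can be inspected without parsing the reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import acmg, cohort_io, prioritize, stats
from .phenotype import (
    CaseAssignment,
    CaseDefinition,
    apply_exclusions,
    assign_case_status,
    case_assignment_frame,
)

log = logging.getLogger("fibrovar")


@dataclass
class RunConfig:
    vcf: Path
    annotations: Path
    phenotypes: Path
    outdir: Path
    panel: Optional[Path] = None
    manual_evidence: Optional[Path] = None
    q: float = 0.75
    alpha: float = 0.05
    ecv_threshold: Optional[float] = None  # explicit case thresholds override
    native_t1_threshold: Optional[float] = None  # the cohort quantiles
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"q={self.q} outside (0, 1)")
        for name in ("vcf", "annotations", "phenotypes", "outdir"):
            setattr(self, name, Path(getattr(self, name)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: run config must be a mapping")
        return cls(**doc)


@dataclass
class RunReport:
    trace: prioritize.FilterTrace
    assignment: CaseAssignment
    classifications: dict[str, acmg.Classification]
    enrichment: dict[str, Optional[stats.EnrichmentResult]]
    n_excluded: int
    outputs: dict[str, Path] = field(default_factory=dict)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    return wrap


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute every stage and write the full report set under ``cfg.outdir``."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # --- input stage -------------------------------------------------------
    panel = _stage("panel_config")(cohort_io.read_panel_config, cfg.panel) if cfg.panel else cohort_io.default_panel()
    variants, genotypes = _stage("read_vcf")(cohort_io.read_vcf, cfg.vcf, panel)
    annotation_list = _stage("read_annotations")(cohort_io.read_annotations, cfg.annotations)
    annotations = {a.variant_id: a for a in annotation_list}
    participants = _stage("read_phenotypes")(cohort_io.read_phenotypes, cfg.phenotypes)
    log.info("inputs: %d variants, %d genotyped samples, %d phenotyped participants",
             len(variants), len(genotypes.participant_ids), len(participants))

    # --- phenotyping -------------------------------------------------------
    included, excluded = _stage("exclusions")(apply_exclusions, participants)
    log.info("exclusions: %d included, %d excluded (MI/HF history)", len(included), len(excluded))
    definition = None
    if cfg.ecv_threshold is not None and cfg.native_t1_threshold is not None:
        definition = CaseDefinition(cfg.ecv_threshold, cfg.native_t1_threshold, q=cfg.q)
    assignment = _stage("case_assignment")(assign_case_status, included, definition, cfg.q)
    decomposition = assignment.decomposition()
    log.info(
        "case assignment: %d cases (%d ECV-only, %d T1-only, %d both), %d controls; "
        "thresholds ECV > %.4g, native T1 > %.5g",
        assignment.n_cases, decomposition["ecv_only"], decomposition["t1_only"],
        decomposition["both"], assignment.n_controls,
        assignment.definition.ecv_threshold, assignment.definition.native_t1_threshold,
    )

    # --- variant prioritization -------------------------------------------
    phenotyped_ids = [p.id for p in participants if p.id in set(genotypes.participant_ids)]
    trace = _stage("filter_cascade")(
        prioritize.run_cascade, variants, annotations, genotypes, panel, phenotyped_ids
    )
    for line in trace.funnel_table().splitlines():
        log.info("funnel: %s", line)

    # --- classification ----------------------------------------------------
    profiles = {
        vid: acmg.auto_evidence(annotations[vid], panel=panel)
        for vid in sorted(trace.final_ids)
    }
    if cfg.manual_evidence:
        manual = _stage("manual_evidence")(acmg.read_manual_evidence, cfg.manual_evidence)
        profiles = acmg.merge_manual_evidence(profiles, manual)
        profiles = {vid: p for vid, p in profiles.items() if vid in trace.final_ids}
    classifications = _stage("classification")(acmg.classify_callset, profiles)
    log.info("classification: %s", acmg.tier_summary(classifications) or "no variants")

    # --- enrichment --------------------------------------------------------
    case_map = dict(assignment.status)
    enrichment_results: dict[str, Optional[stats.EnrichmentResult]] = {}
    tables = _stage("carrier_counts")(
        stats.carrier_counts, genotypes, classifications, case_map, panel, annotations
    )
    for name, table in tables.items():
        if table.a + table.c == 0:
            log.warning("enrichment[%s]: no qualifying carriers; exact test skipped", name)
            enrichment_results[name] = None
        else:
            result = stats.enrichment(table)
            enrichment_results[name] = result
            log.info(
                "enrichment[%s]: %d/%d cases (%.1f%%) vs %d/%d controls (%.1f%%), OR=%.3g, p=%.4g",
                name, table.a, table.n_cases, table.prevalence_case,
                table.c, table.n_controls, table.prevalence_control,
                result.odds_ratio, result.p_two_sided,
            )

    # --- reports -----------------------------------------------------------
    outputs["filter_trace"] = cfg.outdir / "filter_trace.json"
    outputs["filter_trace"].write_text(trace.to_json(), encoding="utf-8")

    outputs["cases"] = cfg.outdir / "cases.csv"
    case_assignment_frame(included, assignment).to_csv(outputs["cases"], index=False)

    outputs["case_definition"] = cfg.outdir / "case_definition.json"
    outputs["case_definition"].write_text(
        json.dumps(
            {
                "ecv_threshold": assignment.definition.ecv_threshold,
                "native_t1_threshold": assignment.definition.native_t1_threshold,
                "q": assignment.definition.q,
                "n_cases": assignment.n_cases,
                "n_controls": assignment.n_controls,
                "decomposition": decomposition,
                "n_excluded": len(excluded),
            },
            indent=2,
        ),
        encoding="utf-8",
    )

    outputs["classifications"] = cfg.outdir / "classifications.tsv"
    acmg.write_classifications(profiles, classifications, outputs["classifications"])

    outputs["enrichment"] = cfg.outdir / "enrichment.json"
    outputs["enrichment"].write_text(
        json.dumps(
            {name: (r.as_dict() if r else None) for name, r in enrichment_results.items()},
            indent=2,
        ),
        encoding="utf-8",
    )

    outputs["report"] = cfg.outdir / "report.md"
    outputs["report"].write_text(
        _markdown_report(trace, assignment, len(excluded), profiles, classifications, enrichment_results),
        encoding="utf-8",
    )

    return RunReport(
        trace=trace,
        assignment=assignment,
        classifications=classifications,
        enrichment=enrichment_results,
        n_excluded=len(excluded),
        outputs=outputs,
    )


def _markdown_report(
    trace: prioritize.FilterTrace,
    assignment: CaseAssignment,
    n_excluded: int,
    profiles: dict[str, acmg.EvidenceProfile],
    classifications: dict[str, acmg.Classification],
    enrichment_results: dict[str, Optional[stats.EnrichmentResult]],
) -> str:
    decomposition = assignment.decomposition()
    lines = ["# Rare-variant fibrosis enrichment report", ""]

    lines += ["## Population and case definition", ""]
    lines.append(f"- Excluded for MI/HF history: {n_excluded}")
    lines.append(f"- Analyzable participants: {assignment.n_cases + assignment.n_controls}")
    lines.append(
        f"- Cases: {assignment.n_cases} "
        f"(ECV-only {decomposition['ecv_only']}, T1-only {decomposition['t1_only']}, both {decomposition['both']}); "
        f"controls: {assignment.n_controls}"
    )
    lines.append(
        f"- Thresholds: ECV > {assignment.definition.ecv_threshold:.4g}%, "
        f"native T1 > {assignment.definition.native_t1_threshold:.6g} ms"
    )

    lines += ["", "## Variant selection funnel", "", "```", trace.funnel_table(), "```", ""]

    lines += ["## Classified variants", ""]
    if classifications:
        lines.append("| variant | evidence | interpretation |")
        lines.append("|---|---|---|")
        for vid in sorted(classifications):
            codes = ",".join(sorted(c.code for c in profiles[vid].codes)) if vid in profiles else ""
            lines.append(f"| {vid} | {codes} | {classifications[vid].label} |")
        summary = acmg.tier_summary(classifications)
        lines.append("")
        lines.append("Tier counts: " + ", ".join(f"{k}: {v}" for k, v in sorted(summary.items())))
    else:
        lines.append("No variants survived the cascade.")

    lines += ["", "## Carrier enrichment", ""]
    labels = {"plp": "P/LP", "plp_vusplus": "P/LP + VUS+"}
    for name, result in enrichment_results.items():
        title = labels.get(name, name)
        if result is None:
            lines.append(f"- {title}: no qualifying carriers; exact test skipped.")
            continue
        t = result.table
        lines.append(
            f"- {title}: {t.a}/{t.n_cases} cases ({t.prevalence_case:.1f}%) vs "
            f"{t.c}/{t.n_controls} controls ({t.prevalence_control:.1f}%); "
            f"OR {result.odds_ratio:.3g}; two-sided exact p = {result.p_two_sided:.3g}"
        )
    lines.append("")
    return "\n".join(lines)
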