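"""Readers and writers for the three input tables and the panel config.

Formats: genotypes as VCF v4.x (only CHROM/POS/REF/ALT and the GT subfield
are consumed; QUAL/FILTER are ignored because quality recalibration happens
upstream of this pipeline), variant annotations as TSV, participant
phenotypes as CSV, gene panel and thresholds as YAML.  All files are UTF-8
with '.' decimal points.  See ``data/annotation_columns.md`` for the
annotation column dictionary.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .models import (
    MISSING_GT,
    AnnotationRecord,
    GenotypeMatrix,
    PanelConfig,
    Participant,
    PARTICIPANT_FIELDS,
    POLYPHEN_DAMAGING_CUTOFF,
    SIFT_DELETERIOUS_CUTOFF,
    VariantRecord,
)


class VcfParseError(ValueError):
    """Malformed VCF content; carries the offending line number when known."""


# ---------------------------------------------------------------------------
# VCF genotypes
# ---------------------------------------------------------------------------

def _prevalidate_vcf(path: Path) -> None:
    """Light structural scan so parse errors can name a line number."""
    saw_header = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                if len(line.split("\t")) < 10:
                    raise VcfParseError(
                        f"{path}:{lineno}: VCF has no sample/genotype columns"
                    )
                continue
            if not saw_header:
                raise VcfParseError(f"{path}:{lineno}: data line before #CHROM header")
            fields = line.split("\t")
            if len(fields) < 10:
                raise VcfParseError(
                    f"{path}:{lineno}: expected >=10 tab-separated fields, got {len(fields)}"
                )
            if not fields[1].isdigit():
                raise VcfParseError(f"{path}:{lineno}: POS {fields[1]!r} is not an integer")
            if "GT" not in fields[8].split(":"):
                raise VcfParseError(f"{path}:{lineno}: FORMAT lacks the GT field")
    if not saw_header:
        raise VcfParseError(f"{path}: missing #CHROM header line")


def read_vcf(path: str | Path, panel: Optional[PanelConfig] = None) -> tuple[list[VariantRecord], GenotypeMatrix]:
    """Read genotype calls into variant records and an alt-dosage matrix.

    Multi-allelic sites are decomposed into one biallelic record per alternate
    allele; each participant's code for a decomposed record is their count of
    that specific allele.  A genotype with any missing allele is recorded as
    missing.  No region or gene filtering happens here (``panel`` is accepted
    for interface symmetry; gene filtering is annotation-driven downstream).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_vcf(path)

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - htslib-level failure
        raise VcfParseError(f"{path}: {exc}") from exc
    samples = list(vcf.samples)

    variants: list[VariantRecord] = []
    rows: list[np.ndarray] = []
    seen: set[str] = set()
    for v in vcf:
        alts = v.ALT or []
        # genotype allele indices per sample; -1 encodes '.'
        allele_arrays = [np.asarray(g[:-1], dtype=int) for g in v.genotypes]
        for alt_index, alt in enumerate(alts, start=1):
            rec = VariantRecord(chrom=str(v.CHROM), pos=int(v.POS), ref=str(v.REF), alt=str(alt))
            if rec.variant_id in seen:
                raise VcfParseError(f"{path}: duplicate variant {rec.variant_id}")
            seen.add(rec.variant_id)
            row = np.empty(len(samples), dtype=np.int8)
            for j, alleles in enumerate(allele_arrays):
                if alleles.size == 0 or (alleles < 0).any():
                    row[j] = MISSING_GT
                else:
                    row[j] = int((alleles == alt_index).sum())
            variants.append(rec)
            rows.append(row)

    codes = np.vstack(rows) if rows else np.empty((0, len(samples)), dtype=np.int8)
    matrix = GenotypeMatrix(
        participant_ids=samples,
        variant_ids=[v.variant_id for v in variants],
        codes=codes,
    )
    return variants, matrix


def write_vcf(
    variants: list[VariantRecord],
    genotypes: GenotypeMatrix,
    path: str | Path,
) -> Path:
    """Write biallelic records with GT-only genotypes (VCF v4.2 subset)."""
    path = Path(path)
    lines = ["##fileformat=VCFv4.2", '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    seen_contigs: list[str] = []
    for rec in variants:
        if rec.chrom not in seen_contigs:
            seen_contigs.append(rec.chrom)
    lines.extend(f"##contig=<ID={chrom}>" for chrom in seen_contigs)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(genotypes.participant_ids))
    gt_string = {0: "0/0", 1: "0/1", 2: "1/1", MISSING_GT: "./."}
    for rec in variants:
        row = genotypes.genotypes(rec.variant_id)
        gts = "\t".join(gt_string[int(code)] for code in row)
        lines.append(f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\tPASS\t.\tGT\t{gts}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Annotation TSV
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = [
    "variant_id",
    "gene_symbol",
    "consequence",
    "protein_change",
    "gnomad_af",
    "kg_af",
    "polyphen",
    "sift",
    "cadd_phred",
    "fathmm",
    "clinvar",
]

_CLINVAR_ALIASES = {
    "pathogenic": "pathogenic",
    "likely pathogenic": "likely_pathogenic",
    "likely_pathogenic": "likely_pathogenic",
    "pathogenic/likely pathogenic": "path_or_lp",
    "pathogenic/likely_pathogenic": "path_or_lp",
    "path_or_lp": "path_or_lp",
    "p/lp": "path_or_lp",
    "vus": "vus",
    "uncertain significance": "vus",
    "uncertain_significance": "vus",
    "conflicting": "conflicting",
    "conflicting interpretations of pathogenicity": "conflicting",
    "likely benign": "likely_benign",
    "likely_benign": "likely_benign",
    "benign": "benign",
    "not_found": "not_found",
    "": "not_found",
}


def _parse_float(cell: str, column: str, variant_id: str) -> Optional[float]:
    if cell == "":
        return None
    try:
        value = float(cell)
    except ValueError:
        raise ValueError(f"{column} for {variant_id}: cannot parse {cell!r} as a number") from None
    if math.isnan(value):
        return None
    return value


def _parse_call(cell: str, categories: dict[str, str], numeric_bin=None) -> Optional[str]:
    if cell == "":
        return None
    token = cell.strip().lower()
    if token in categories:
        return categories[token]
    if numeric_bin is not None:
        try:
            return numeric_bin(float(cell))
        except ValueError:
            pass
    raise ValueError(f"unrecognized in-silico call {cell!r}")


_POLYPHEN_TOKENS = {
    "benign": "benign",
    "possibly_damaging": "possibly_damaging",
    "possibly damaging": "possibly_damaging",
    "probably_damaging": "probably_damaging",
    "probably damaging": "probably_damaging",
}
_SIFT_TOKENS = {"tolerated": "tolerated", "deleterious": "deleterious"}
_FATHMM_TOKENS = {"tolerated": "tolerated", "damaging": "damaging"}


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read the per-variant annotation table (one row per variant_id).

    Numeric PolyPhen/SIFT scores, if supplied in place of categorical calls,
    are binned at the published cutoffs (PolyPhen >= 0.446 damaging-spectrum,
    SIFT < 0.05 deleterious).  Unknown columns are ignored.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"variant_id", "gene_symbol", "consequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation table lacks columns {sorted(missing)}")
    dup = df["variant_id"][df["variant_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate variant_id {dup.iloc[0]!r}")

    def cell(row, col) -> str:
        return str(row[col]).strip() if col in df.columns else ""

    records = []
    for _, row in df.iterrows():
        vid = row["variant_id"].strip()
        clinvar_raw = cell(row, "clinvar").lower()
        if clinvar_raw not in _CLINVAR_ALIASES:
            raise ValueError(f"{path}: unknown ClinVar assertion {cell(row, 'clinvar')!r} for {vid}")
        records.append(
            AnnotationRecord(
                variant_id=vid,
                gene_symbol=row["gene_symbol"].strip(),
                consequence=row["consequence"].strip(),
                protein_change=cell(row, "protein_change"),
                gnomad_af=_parse_float(cell(row, "gnomad_af"), "gnomad_af", vid),
                kg_af=_parse_float(cell(row, "kg_af"), "kg_af", vid),
                polyphen_call=_parse_call(
                    cell(row, "polyphen"),
                    _POLYPHEN_TOKENS,
                    lambda x: "possibly_damaging" if x >= POLYPHEN_DAMAGING_CUTOFF else "benign",
                ),
                sift_call=_parse_call(
                    cell(row, "sift"),
                    _SIFT_TOKENS,
                    lambda x: "deleterious" if x < SIFT_DELETERIOUS_CUTOFF else "tolerated",
                ),
                cadd_phred=_parse_float(cell(row, "cadd_phred"), "cadd_phred", vid),
                fathmm_call=_parse_call(cell(row, "fathmm"), _FATHMM_TOKENS),
                clinvar_assertion=_CLINVAR_ALIASES[clinvar_raw],
            )
        )
    return records


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for r in records:
        rows.append(
            {
                "variant_id": r.variant_id,
                "gene_symbol": r.gene_symbol,
                "consequence": r.consequence,
                "protein_change": r.protein_change,
                "gnomad_af": "" if r.gnomad_af is None else repr(r.gnomad_af),
                "kg_af": "" if r.kg_af is None else repr(r.kg_af),
                "polyphen": r.polyphen_call or "",
                "sift": r.sift_call or "",
                "cadd_phred": "" if r.cadd_phred is None else repr(r.cadd_phred),
                "fathmm": r.fathmm_call or "",
                "clinvar": r.clinvar_assertion,
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# Phenotype CSV
# ---------------------------------------------------------------------------

_BOOL_TOKENS = {"0": False, "1": True, "false": False, "true": True}
_BOOL_FIELDS = {"mi_history", "hf_history", "lge_scar"}
_STR_FIELDS = {"id", "sex", "race"}


def read_phenotypes(path: str | Path) -> list[Participant]:
    """Read the participant phenotype table (one row per unique id)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "id" not in df.columns:
        raise ValueError(f"{path}: phenotype table lacks an 'id' column")
    dup = df["id"][df["id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate participant id {dup.iloc[0]!r}")

    participants = []
    for _, row in df.iterrows():
        kwargs: dict = {}
        for name in PARTICIPANT_FIELDS:
            if name not in df.columns:
                continue
            cell = str(row[name]).strip()
            if cell == "":
                continue
            if name in _STR_FIELDS:
                kwargs[name] = cell
            elif name in _BOOL_FIELDS:
                token = cell.lower()
                if token not in _BOOL_TOKENS:
                    raise ValueError(f"{path}: cannot parse boolean {cell!r} in column {name}")
                kwargs[name] = _BOOL_TOKENS[token]
            else:
                kwargs[name] = float(cell)
        participants.append(Participant(**kwargs))
    return participants


def write_phenotypes(participants: Iterable[Participant], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for p in participants:
        row = {}
        for name in PARTICIPANT_FIELDS:
            value = getattr(p, name)
            if value is None:
                row[name] = ""
            elif name in _BOOL_FIELDS:
                row[name] = "1" if value else "0"
            elif name in _STR_FIELDS:
                row[name] = value
            else:
                row[name] = repr(float(value))
        rows.append(row)
    pd.DataFrame(rows, columns=PARTICIPANT_FIELDS).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# Panel configuration
# ---------------------------------------------------------------------------

def _panel_from_mapping(doc: dict) -> PanelConfig:
    genes = doc.get("genes") or doc.get("gene_list")
    if genes is None:
        raise ValueError("panel config lacks a 'genes' section")
    inheritance: dict[str, str] = {}
    lof_genes: set[str] = set()
    windows: dict[str, tuple[str, int, int]] = {}
    if isinstance(genes, dict):
        gene_list = set(genes)
        for symbol, info in genes.items():
            info = info or {}
            if "inheritance" in info:
                inheritance[symbol] = info["inheritance"]
            if info.get("lof_mechanism"):
                lof_genes.add(symbol)
            if "chrom" in info and "window" in info:
                start, end = info["window"]
                windows[symbol] = (str(info["chrom"]), int(start), int(end))
    else:
        gene_list = set(genes)
    inheritance.update(doc.get("inheritance", {}))
    return PanelConfig(
        gene_list=gene_list,
        maf_threshold=float(doc.get("maf_threshold", 0.001)),
        cadd_threshold=float(doc.get("cadd_threshold", 20.0)),
        inheritance=inheritance,
        lof_genes=lof_genes,
        windows=windows,
    )


def read_panel_config(path: str | Path) -> PanelConfig:
    """Load a YAML/JSON panel config (gene list, thresholds, inheritance)."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: panel config must be a mapping")
    return _panel_from_mapping(doc)


def default_panel() -> PanelConfig:
    """The packaged 82-gene cardiomyopathy panel.

    The shipped list is a documented, user-replaceable compilation of genes
    with established cardiomyopathy associations; swap in your own panel file
    via :func:`read_panel_config` to change it.
    """
    ref = resources.files("fibrovar.data").joinpath("cm_panel_82.yaml")
    with resources.as_file(ref) as path:
        return read_panel_config(path)
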