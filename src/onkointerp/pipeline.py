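"""End-to-end annotation pipeline: parse -> annotate -> classify -> prioritize
-> match therapies -> export.

The pipeline mirrors the interpretation steps of a molecular tumor board:
variants are parsed from a file, joined with per-variant annotation tables
(population allele frequency, predictor scores, clinical assertions),
classified into the five ACMG categories, sorted pathogenic-first, matched
against the harmonized clinical-evidence knowledge base at the five
specificity levels, merged across sources, and exported as CSV tables plus
per-variant JSON traces.  One structured log line per stage reports record
and skip counts; on failure, partial outputs are removed and the failing
stage is named.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .acmg import AcmgConfig, AnnotationBundle, evaluate_criteria, prioritize
from .errors import OnkoError
from .harmonize import (CancerTypeTable, DrugClassTable, load_evidence_source,
                        load_level_mapping)
from .matching import TREATMENT_COLUMNS, build_treatment_table
from .variants import (Level, ParsedVariant, TranscriptAnnotation, parse_query,
                       read_variant_file, write_variant_table)

logger = logging.getLogger(__name__)

VARIANT_CSV_FIELDS = ["query", "gene", "chrom", "pos", "ref", "alt",
                      "variant_type", "acmg_label", "clinical_assertion",
                      "population_af", "revel_like", "am_like"]


class PipelineError(OnkoError):
    """A stage failed; ``stage`` names it for the exit message."""

    def __init__(self, stage: str, message: str):
        super().__init__(message)
        self.stage = stage


def load_annotation_table(path: str | Path
                          ) -> dict[str, tuple[AnnotationBundle, dict]]:
    """Read a per-variant annotation TSV into bundles keyed by variant key.

    Returns ``key -> (AnnotationBundle, extra)`` where ``extra`` holds the
    optional protein-resolution columns (gene, hgvsp).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, tuple[AnnotationBundle, dict]] = {}
    for _, row in df.iterrows():
        scores = {}
        for name in ("revel_like", "am_like", "primateai_like"):
            if row.get(name, ""):
                scores[name] = float(row[name])
        bundle = AnnotationBundle(
            population_af=float(row["population_af"])
            if row.get("population_af", "") else None,
            predictor_scores=scores,
            clinical_assertion=row.get("clinical_assertion", "none") or "none",
            known_pathogenic_same_change=row.get(
                "known_pathogenic_same_change", "0") == "1",
            known_pathogenic_same_residue=row.get(
                "known_pathogenic_same_residue", "0") == "1",
            in_hotspot_or_functional_domain=row.get(
                "in_hotspot_or_functional_domain", "0") == "1",
            null_variant_in_lof_gene=row.get(
                "null_variant_in_lof_gene", "0") == "1",
        )
        extra = {"gene": row.get("gene", ""), "hgvsp": row.get("hgvsp", "")}
        out[row["key"]] = (bundle, extra)
    return out


def _resolve_protein(v: ParsedVariant, extra: dict) -> None:
    """Populate protein fields from annotation columns (gene, HGVS.p)."""
    if v.gene is None and extra.get("gene"):
        v.gene = extra["gene"]
    if v.ref_aa is None and extra.get("gene") and extra.get("hgvsp"):
        try:
            p = parse_query(f"{extra['gene']}:{extra['hgvsp']}")
            v.ref_aa, v.aa_pos, v.alt_aa = p.ref_aa, p.aa_pos, p.alt_aa
        except OnkoError:
            logger.warning("unusable hgvsp annotation %r", extra.get("hgvsp"))


def load_kb_dir(kb_dir: str | Path,
                cancer_table: CancerTypeTable | None = None,
                drug_table: DrugClassTable | None = None,
                level_mapping_path: str | Path | None = None,
                fuzzy_threshold: float = 0.85) -> list:
    """Load every recognized dialect file from a knowledge-base directory."""
    kb_dir = Path(kb_dir)
    if not kb_dir.is_dir():
        raise PipelineError("therapy_match",
                            f"knowledge-base directory not found: {kb_dir}")
    mapping = load_level_mapping(level_mapping_path)
    records = []
    for dialect in ("civic_like", "oncokb_like", "metakb_like"):
        path = kb_dir / f"{dialect}.tsv"
        if path.exists():
            records.extend(load_evidence_source(
                path, dialect, cancer_table, drug_table, mapping,
                fuzzy_threshold))
    if not records:
        raise PipelineError("therapy_match",
                            f"no evidence tables found in {kb_dir}")
    return records


def run_annotate(
    input_path: str | Path,
    input_format: str,
    kb_dir: str | Path,
    out_dir: str | Path,
    annotations_path: str | Path | None = None,
    cancer_table_path: str | Path | None = None,
    drug_table_path: str | Path | None = None,
    acmg_config_path: str | Path | None = None,
    level_mapping_path: str | Path | None = None,
    transcript_annotation: TranscriptAnnotation | None = None,
    sort_key: str = "acmg",
    variant_fields: list[str] | None = None,
) -> dict:
    """Run the full interpretation pipeline and export results.

    Writes ``variants.csv`` (default sort: highest estimated pathogenicity
    first), ``treatments.csv`` (biomarker, match type, drugs, drug class,
    evidence level, response, citation ID), and ``traces.json`` (per-variant
    ACMG derivation traces) into ``out_dir``.  Returns a summary dict with
    per-stage counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = [out_dir / "variants.csv", out_dir / "treatments.csv",
               out_dir / "traces.json"]
    try:
        summary = _run(Path(input_path), input_format, kb_dir, out_dir,
                       annotations_path, cancer_table_path, drug_table_path,
                       acmg_config_path, level_mapping_path,
                       transcript_annotation, sort_key, variant_fields)
    except Exception:
        for p in outputs:
            p.unlink(missing_ok=True)
        raise
    return summary


def _run(input_path, input_format, kb_dir, out_dir, annotations_path,
         cancer_table_path, drug_table_path, acmg_config_path,
         level_mapping_path, transcript_annotation, sort_key,
         variant_fields) -> dict:
    # stage 1: parse
    try:
        collection = read_variant_file(input_path, input_format)
    except OnkoError as exc:
        raise PipelineError("variant_model", str(exc)) from exc
    logger.info("stage=parse records=%d skipped=%d",
                len(collection), collection.skipped)

    # stage 2: annotate
    annotations: dict = {}
    if annotations_path is not None:
        try:
            annotations = load_annotation_table(annotations_path)
        except (OSError, ValueError, KeyError) as exc:
            raise PipelineError("annotation", str(exc)) from exc
    items = []
    n_annotated = 0
    for v in collection:
        bundle, extra = annotations.get(v.key(), (AnnotationBundle(), {}))
        n_annotated += v.key() in annotations
        _resolve_protein(v, extra)
        items.append({"variant": v, "bundle": bundle})
    logger.info("stage=annotate records=%d annotated=%d",
                len(items), n_annotated)

    # stage 3: ACMG classification
    try:
        config = AcmgConfig.from_file(acmg_config_path)
        for it in items:
            it["acmg"] = evaluate_criteria(it["bundle"], config)
    except OnkoError as exc:
        raise PipelineError("acmg_classifier", str(exc)) from exc
    logger.info("stage=classify records=%d", len(items))

    # stage 4: prioritize (default: highest estimated pathogenicity first)
    try:
        items = prioritize(items, sort_key)
    except OnkoError as exc:
        raise PipelineError("acmg_classifier", str(exc)) from exc

    # stage 5: therapy matching
    cancer_table = (CancerTypeTable.from_tsv(cancer_table_path)
                    if cancer_table_path else None)
    drug_table = (DrugClassTable.from_tsv(drug_table_path)
                  if drug_table_path else None)
    kb = load_kb_dir(kb_dir, cancer_table, drug_table, level_mapping_path)
    matchable = [it["variant"] for it in items if it["variant"].gene]
    treatments = build_treatment_table(matchable, kb, transcript_annotation)
    logger.info("stage=therapy_match kb_records=%d variants=%d treatments=%d",
                len(kb), len(matchable), len(treatments))

    # stage 6: export
    variants = [it["variant"] for it in items]
    ann_rows = []
    for it in items:
        b = it["bundle"]
        ann_rows.append({
            "acmg_label": it["acmg"].label,
            "acmg_criteria": "+".join(sorted(it["acmg"].triggered)),
            "clinical_assertion": b.clinical_assertion,
            "population_af": "" if b.population_af is None else b.population_af,
            "revel_like": "", "am_like": "",
            **{k: v for k, v in b.predictor_scores.items()},
        })
    fields = variant_fields or VARIANT_CSV_FIELDS
    write_variant_table(variants, ann_rows, fields, out_dir / "variants.csv")
    treatments[TREATMENT_COLUMNS].to_csv(out_dir / "treatments.csv", index=False)
    traces = {
        it["variant"].key(): {
            "label": it["acmg"].label,
            "triggered": sorted(it["acmg"].triggered),
            "trace": [list(t) for t in it["acmg"].trace],
        }
        for it in items
    }
    (out_dir / "traces.json").write_text(json.dumps(traces, indent=1))
    logger.info("stage=export variant_rows=%d treatment_rows=%d",
                len(variants), len(treatments))
    return {
        "parsed": len(collection),
        "skipped": collection.skipped,
        "classified": len(items),
        "variant_rows": len(variants),
        "treatment_rows": int(len(treatments)),
        "kb_records": len(kb),
    }
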