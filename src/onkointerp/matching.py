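"""Match clinical evidence to variants at five specificity levels.

A knowledge-base biomarker can match a patient variant as:

1. ``exact``             — the same amino-acid exchange ("KRAS G12A")
2. ``same_pos_other_aa`` — a different exchange at the same residue ("KRAS G12C")
3. ``same_pos_any``      — an arbitrary exchange at the residue ("KRAS G12")
4. ``same_exon``         — a variant within the same exon ("KRAS exon 2";
   requires a transcript annotation to place the patient residue)
5. ``gene_level``        — any mutation in the gene ("KRAS mutation")

All levels are searched and reported together: a broader hit is never
suppressed by a narrower one.  Each evidence record appears at most once,
labeled with the most specific match type it satisfies.  Records identical
on the five normalized key fields (drug label, cancer entity, evidence
level, response type, citation ID) are merged across sources.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .errors import ValidationError
from .harmonize import EvidenceRecord
from .variants import ParsedVariant, TranscriptAnnotation

logger = logging.getLogger(__name__)

MATCH_TYPES = ("exact", "same_pos_other_aa", "same_pos_any", "same_exon",
               "gene_level")

HIERARCHY_LAYERS = ("biomarker", "match_type", "drug_class", "drug",
                    "cancer_type", "evidence_level", "response", "citation")

_EXCHANGE_RE = re.compile(r"^([A-Z*])(\d+)([A-Z*])$")
_POSITIONAL_RE = re.compile(r"^([A-Z])(\d+)$")
_EXON_RE = re.compile(r"^exon\s+(\d+)$", re.IGNORECASE)
_GENE_LEVEL_RE = re.compile(r"^(any\s+)?mutation$", re.IGNORECASE)


@dataclass(frozen=True)
class BiomarkerSpec:
    """Parsed form of a knowledge-base biomarker variant string."""

    kind: str  # exchange | positional | exon | gene | other
    ref_aa: str | None = None
    pos: int | None = None
    alt_aa: str | None = None
    exon: int | None = None

    @classmethod
    def parse(cls, spec: str) -> "BiomarkerSpec":
        spec = spec.strip()
        if m := _EXCHANGE_RE.match(spec):
            return cls("exchange", ref_aa=m[1], pos=int(m[2]), alt_aa=m[3])
        if m := _POSITIONAL_RE.match(spec):
            return cls("positional", ref_aa=m[1], pos=int(m[2]))
        if m := _EXON_RE.match(spec):
            return cls("exon", exon=int(m[1]))
        if _GENE_LEVEL_RE.match(spec):
            return cls("gene")
        return cls("other")


@dataclass
class MatchedTreatment:
    """An evidence record attached to a patient variant with a match type."""

    variant: str  # biomarker string of the patient variant, e.g. "KRAS G12A"
    match_type: str
    record: EvidenceRecord
    sources: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.match_type not in MATCH_TYPES:
            raise ValidationError(f"unknown match type {self.match_type!r}")
        if not self.sources:
            self.sources = frozenset({self.record.source})

    def merge_key(self) -> tuple:
        r = self.record
        return (tuple(sorted(r.drugs)), r.cancer_type_main, r.amp_tier or "",
                r.response, r.citation_id)


def _variant_biomarker(v: ParsedVariant) -> str:
    if v.ref_aa is not None and v.aa_pos is not None:
        return f"{v.gene} {v.ref_aa}{v.aa_pos}{v.alt_aa}"
    return str(v.gene)


def match_record(
    v: ParsedVariant,
    record: EvidenceRecord,
    annotation: TranscriptAnnotation | None = None,
) -> str | None:
    """Most specific match type of one evidence record for one variant, or None."""
    if record.biomarker_gene != (v.gene or "").upper():
        return None
    spec = BiomarkerSpec.parse(record.biomarker_spec)
    has_exchange = v.ref_aa is not None and v.aa_pos is not None and v.alt_aa
    if spec.kind == "exchange" and has_exchange and spec.pos == v.aa_pos:
        if spec.alt_aa == v.alt_aa and spec.ref_aa == v.ref_aa:
            return "exact"
        return "same_pos_other_aa"
    if spec.kind == "positional" and has_exchange and spec.pos == v.aa_pos:
        return "same_pos_any"
    if spec.kind == "exon" and has_exchange and annotation is not None:
        exon = annotation.exon_of_residue(v.aa_pos)
        if exon is not None and exon == spec.exon:
            return "same_exon"
    if spec.kind == "gene":
        return "gene_level"
    return None


def match_evidence(
    v: ParsedVariant,
    kb: Iterable[EvidenceRecord],
    annotation: TranscriptAnnotation | None = None,
) -> list[MatchedTreatment]:
    """Search all five match types for one variant against a knowledge base.

    Requires a protein-level variant (or one with protein fields resolved).
    Exon-level biomarkers are only matched when a transcript annotation is
    supplied; otherwise that level is skipped with a warning.
    """
    if v.gene is None:
        raise ValidationError("therapy matching requires a resolved gene symbol")
    matches: list[MatchedTreatment] = []
    warned_exon = False
    for record in kb:
        if (annotation is None and not warned_exon
                and BiomarkerSpec.parse(record.biomarker_spec).kind == "exon"
                and record.biomarker_gene == v.gene.upper()):
            logger.warning("no transcript annotation supplied; "
                           "same-exon matching skipped for %s", v.gene)
            warned_exon = True
        mt = match_record(v, record, annotation)
        if mt is not None:
            matches.append(MatchedTreatment(
                variant=_variant_biomarker(v), match_type=mt, record=record))
    return matches


def merge_duplicates(matches: Sequence[MatchedTreatment]) -> list[MatchedTreatment]:
    """Collapse treatments identical on the five normalized key fields.

    The key is (drug label, cancer entity, evidence level, response type,
    citation ID); contributing sources are unioned and the most specific
    match type among the merged records is kept.  Output order is
    deterministic (sorted by key).
    """
    groups: dict[tuple, MatchedTreatment] = {}
    for m in matches:
        key = (m.variant,) + m.merge_key()
        if key not in groups:
            groups[key] = MatchedTreatment(
                variant=m.variant, match_type=m.match_type, record=m.record,
                sources=frozenset(m.sources))
        else:
            g = groups[key]
            best = min(MATCH_TYPES.index(g.match_type),
                       MATCH_TYPES.index(m.match_type))
            groups[key] = MatchedTreatment(
                variant=g.variant, match_type=MATCH_TYPES[best],
                record=g.record, sources=g.sources | m.sources)
    return [groups[k] for k in sorted(groups)]


TREATMENT_COLUMNS = ["biomarker", "match_type", "drugs", "drug_class",
                     "evidence_level", "response", "citation_id"]

_TIER_ORDER = {"A": 0, "B": 1, "C": 2, "D": 3, "": 4}
_RESPONSE_ORDER = {"sensitive": 0, "resistant": 1, "unknown": 2}


def build_treatment_table(
    variants: Sequence[ParsedVariant],
    kb: Iterable[EvidenceRecord],
    annotation: TranscriptAnnotation | None = None,
    sort_by: str | None = None,
) -> pd.DataFrame:
    """Patient-level treatment table: matched + merged evidence per variant.

    One row per merged treatment, tagged with its originating biomarker;
    optionally sorted by ``tier``, ``response``, or ``match_type``.
    """
    kb = list(kb)
    rows = []
    for v in variants:
        for m in merge_duplicates(match_evidence(v, kb, annotation)):
            r = m.record
            rows.append({
                "biomarker": m.variant,
                "match_type": m.match_type,
                "drugs": ",".join(r.drugs),
                "drug_class": ",".join(r.drug_classes),
                "evidence_level": r.amp_tier or "",
                "response": r.response,
                "citation_id": r.citation_id,
                "cancer_type": r.cancer_type_main,
                "sources": ",".join(sorted(m.sources)),
            })
    df = pd.DataFrame(rows, columns=TREATMENT_COLUMNS + ["cancer_type", "sources"])
    if sort_by and len(df):
        if sort_by == "tier":
            df = df.sort_values("evidence_level", key=lambda s: s.map(_TIER_ORDER),
                                kind="stable")
        elif sort_by == "response":
            df = df.sort_values("response", key=lambda s: s.map(_RESPONSE_ORDER),
                                kind="stable")
        elif sort_by == "match_type":
            df = df.sort_values("match_type",
                                key=lambda s: s.map(MATCH_TYPES.index),
                                kind="stable")
        else:
            raise ValidationError(
                f"unknown sort key {sort_by!r}; valid: tier, response, match_type")
        df = df.reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# sunburst hierarchy


def _layer_value(m: MatchedTreatment, layer: str) -> str:
    r = m.record
    if layer == "biomarker":
        return m.variant
    if layer == "match_type":
        return m.match_type
    if layer == "drug_class":
        return ",".join(r.drug_classes) or "Unclassified"
    if layer == "drug":
        return ",".join(r.drugs)
    if layer == "cancer_type":
        return r.cancer_type_main
    if layer == "evidence_level":
        return r.amp_tier or "unset"
    if layer == "response":
        return r.response
    if layer == "citation":
        return r.citation_id or "uncited"
    raise ValidationError(
        f"unknown layer {layer!r}; valid layers: {', '.join(HIERARCHY_LAYERS)}")


@dataclass
class TreatmentHierarchy:
    """Nested sunburst-style aggregation of matched treatments."""

    layers: list[str]
    root: dict

    def to_json(self, **kw) -> str:
        return json.dumps({"layers": self.layers, "root": self.root}, **kw)

    def leaf_count(self) -> int:
        def walk(node: dict) -> int:
            if not node["children"]:
                return node["count"]
            return sum(walk(c) for c in node["children"])
        return walk(self.root)


def build_hierarchy(
    treatments: Sequence[MatchedTreatment],
    layer_order: Sequence[str],
) -> TreatmentHierarchy:
    """Group treatments into a nested hierarchy over the given layer order.

    The leaf layer is always ``citation`` (appended if absent); node counts
    equal the number of underlying treatments, so the root count is
    conserved under any layer permutation.
    """
    layers = list(layer_order)
    for layer in layers:
        if layer not in HIERARCHY_LAYERS:
            raise ValidationError(
                f"unknown layer {layer!r}; valid layers: "
                f"{', '.join(HIERARCHY_LAYERS)}")
    if not layers or layers[-1] != "citation":
        layers.append("citation")

    def group(items: list[MatchedTreatment], remaining: list[str]) -> list[dict]:
        if not remaining:
            return []
        layer, rest = remaining[0], remaining[1:]
        buckets: dict[str, list[MatchedTreatment]] = {}
        for m in items:
            buckets.setdefault(_layer_value(m, layer), []).append(m)
        return [
            {"label": label, "layer": layer, "count": len(sub),
             "children": group(sub, rest)}
            for label, sub in sorted(buckets.items())
        ]

    root = {"label": "all", "layer": "root", "count": len(treatments),
            "children": group(list(treatments), layers)}
    return TreatmentHierarchy(layers=layers, root=root)
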