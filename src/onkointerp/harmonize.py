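"""Harmonize clinical-evidence tables from heterogeneous knowledge-base dialects.

Three tab-separated source dialects are supported — ``civic_like``,
``oncokb_like``, and ``metakb_like`` — each with its own column names,
evidence-level codes, and response-type vocabulary.  Loading a source applies,
in order: response-type mapping, evidence-level mapping to AMP/ASCO/CAP tier
letters (A–D), splitting of "substitutes" therapy interactions into separate
single-drug options, cancer-type normalization against an OncoTree-style
main-type table (exact then fuzzy matching), and drug classification.

The evidence-level mapping ships as an editable flat configuration file
(``data/evidence_level_mapping.cfg``) following the cross-source
harmonization proposed by Wagner et al.; unmapped codes leave the tier unset
with a warning, never an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib.resources import files
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError, FormatError

logger = logging.getLogger(__name__)

SOURCES = ("civic_like", "oncokb_like", "metakb_like")
RESPONSES = ("sensitive", "resistant", "unknown")
TIERS = ("A", "B", "C", "D")

DEFAULT_FUZZY_THRESHOLD = 0.85


@dataclass(frozen=True)
class EvidenceRecord:
    """One normalized clinical-evidence assertion."""

    source: str
    biomarker_gene: str
    biomarker_spec: str  # "G12A", "G12", "exon 2", or "mutation"
    cancer_type_raw: str
    cancer_type_main: str = "Unmatched"
    drugs: tuple[str, ...] = ()
    drug_classes: tuple[str, ...] = ()
    interaction: str = "none"  # none | substitutes | combination
    response: str = "unknown"
    response_raw: str = ""
    evidence_level_raw: str = ""
    amp_tier: str | None = None
    statement: str = ""
    citation_id: str = ""


@dataclass
class CancerTypeTable:
    """OncoTree-style cancer-type rows: (label, main type, synonyms)."""

    rows: list[tuple[str, str, tuple[str, ...]]]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CancerTypeTable":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        for col in ("label", "main_type"):
            if col not in df.columns:
                raise FormatError(f"cancer-type table is missing column {col!r}")
        rows = []
        for _, r in df.iterrows():
            syn = tuple(s.strip() for s in str(r.get("synonyms", "")).split("|")
                        if s.strip())
            rows.append((r["label"], r["main_type"], syn))
        return cls(rows)

    def all_labels(self) -> list[tuple[str, str]]:
        """(label-or-synonym, main type) pairs, main types included as labels."""
        out = []
        seen_main = set()
        for label, main, syns in self.rows:
            out.append((label, main))
            for s in syns:
                out.append((s, main))
            if main not in seen_main:
                out.append((main, main))
                seen_main.add(main)
        return out


@dataclass
class DrugClassTable:
    """Drug label -> class label; first occurrence wins on conflict."""

    mapping: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugClassTable":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        for col in ("drug", "drug_class"):
            if col not in df.columns:
                raise FormatError(f"drug-class table is missing column {col!r}")
        mapping: dict[str, str] = {}
        for _, r in df.iterrows():
            key = normalize_drug_label(r["drug"])
            if key in mapping and mapping[key] != r["drug_class"]:
                logger.warning("conflicting class for drug %r; keeping first", key)
                continue
            mapping.setdefault(key, r["drug_class"])
        return cls(mapping)


def normalize_drug_label(label: str) -> str:
    """Trim, case-fold, and collapse internal whitespace (dedup key)."""
    return " ".join(label.strip().casefold().split())


# ---------------------------------------------------------------------------
# response-type mapping

_ONCOKB_RESISTANT = {"R1", "R2"}
_ONCOKB_SENSITIVE = {"1", "2", "3A", "3B"}


def map_response_type(source: str, raw_value: str) -> str:
    """Map a source-specific response/significance value to the common vocabulary.

    civic_like values containing "Sensitivity" or "Resistance" map
    accordingly; oncokb_like codes R1/R2 map to resistant and 1/2/3A/3B to
    sensitive; metakb_like descriptive association values are mapped by
    keyword.  Anything else is ``unknown``.
    """
    raw = (raw_value or "").strip()
    if source == "civic_like":
        if "sensitivity" in raw.casefold():
            return "sensitive"
        if "resistance" in raw.casefold():
            return "resistant"
        return "unknown"
    if source == "oncokb_like":
        code = raw.upper()
        if code in _ONCOKB_RESISTANT:
            return "resistant"
        if code in _ONCOKB_SENSITIVE:
            return "sensitive"
        return "unknown"
    if source == "metakb_like":
        low = raw.casefold()
        if "resist" in low:
            return "resistant"
        if "sensitiv" in low or "respon" in low:
            return "sensitive"
        return "unknown"
    return "unknown"


# ---------------------------------------------------------------------------
# evidence-level mapping


def load_level_mapping(path: str | Path | None = None) -> dict[tuple[str, str], str]:
    """Load the (source, raw code) -> AMP tier mapping configuration."""
    if path is None:
        text = files("onkointerp.data").joinpath(
            "evidence_level_mapping.cfg").read_text()
    else:
        text = Path(path).read_text()
    mapping: dict[tuple[str, str], str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ConfigError(f"level-mapping line {lineno} is not "
                              f"'<source> <code> <tier>': {line!r}")
        source, code, tier = parts
        if tier not in TIERS:
            raise ConfigError(f"tier must be one of {TIERS}, got {tier!r}")
        mapping[(source, code.upper())] = tier
    return mapping


def map_evidence_level(
    source: str, code: str,
    mapping: dict[tuple[str, str], str] | None = None,
) -> str | None:
    """Return the configured AMP/ASCO/CAP tier letter, or None with a warning."""
    if mapping is None:
        mapping = load_level_mapping()
    tier = mapping.get((source, (code or "").strip().upper()))
    if tier is None:
        logger.warning("unmapped evidence code %r for source %s", code, source)
    return tier


# ---------------------------------------------------------------------------
# substitutes splitting


def split_substitutes(r: EvidenceRecord) -> list[EvidenceRecord]:
    """Expand a substitutes-interaction record into single-drug options.

    A record listing k interchangeable drugs becomes k otherwise-identical
    records of one drug each; all other records pass through unchanged.
    """
    if r.interaction != "substitutes" or len(r.drugs) <= 1:
        if r.interaction == "substitutes":
            r = replace(r, interaction="none")
        return [r]
    return [replace(r, drugs=(d,), interaction="none") for d in r.drugs]


# ---------------------------------------------------------------------------
# cancer-type normalization


def _levenshtein(a: str, b: str) -> int:
    try:
        import edlib
        return edlib.align(a, b, task="distance")["editDistance"]
    except ImportError:  # pragma: no cover - edlib is installed in practice
        prev = list(range(len(b) + 1))
        for i, ca in enumerate(a, 1):
            cur = [i]
            for j, cb in enumerate(b, 1):
                cur.append(min(prev[j] + 1, cur[-1] + 1,
                               prev[j - 1] + (ca != cb)))
            prev = cur
        return prev[-1]


def similarity(a: str, b: str) -> float:
    """Normalized edit similarity: 1 - distance / max length, in [0, 1]."""
    a, b = a.casefold(), b.casefold()
    if not a and not b:
        return 1.0
    return 1.0 - _levenshtein(a, b) / max(len(a), len(b))


def normalize_cancer_type(
    raw: str, table: CancerTypeTable,
    threshold: float = DEFAULT_FUZZY_THRESHOLD,
) -> str:
    """Map a free-text cancer type to an OncoTree-style main type.

    Exact case-insensitive matching on labels, synonyms, and main-type names
    always wins; otherwise the highest-similarity label at or above
    ``threshold`` decides, with ties broken by lexicographically smallest
    main type.  Below threshold the result is ``"Unmatched"``.
    """
    if not (0 < threshold <= 1):
        raise ConfigError(f"threshold must be in (0, 1], got {threshold}")
    if not table.rows:
        raise ConfigError("cancer-type table is empty")
    raw_cf = (raw or "").strip().casefold()
    if not raw_cf:
        return "Unmatched"
    pairs = table.all_labels()
    for label, main in pairs:
        if label.casefold() == raw_cf:
            return main
    best_sim, best_main = -1.0, "Unmatched"
    for label, main in pairs:
        sim = similarity(raw, label)
        if sim > best_sim or (sim == best_sim and main < best_main):
            best_sim, best_main = sim, main
    return best_main if best_sim >= threshold else "Unmatched"


def classify_drug(label: str, table: DrugClassTable) -> str:
    """Case-insensitive exact drug-class lookup; unknown -> 'Unclassified'."""
    return table.mapping.get(normalize_drug_label(label), "Unclassified")


# ---------------------------------------------------------------------------
# dialect loading

_DIALECT_COLUMNS = {
    "civic_like": {
        "gene": "gene", "variant": "variant", "disease": "disease",
        "drugs": "drugs", "interaction": "drug_interaction_type",
        "level": "evidence_level", "response": "significance",
        "statement": "evidence_statement", "citation": "citation_id",
    },
    "oncokb_like": {
        "gene": "hugo_symbol", "variant": "alteration",
        "disease": "cancer_type", "drugs": "drugs", "interaction": None,
        "level": "level", "response": "level",  # OncoKB levels encode response
        "statement": "description", "citation": "pmid",
    },
    "metakb_like": {
        "gene": "gene", "variant": "variant", "disease": "disease",
        "drugs": "therapies", "interaction": None,
        "level": "evidence_level", "response": "association",
        "statement": "statement", "citation": "citation",
    },
}


def load_evidence_source(
    path: str | Path,
    dialect: str,
    cancer_table: CancerTypeTable | None = None,
    drug_table: DrugClassTable | None = None,
    level_mapping: dict[tuple[str, str], str] | None = None,
    fuzzy_threshold: float = DEFAULT_FUZZY_THRESHOLD,
) -> list[EvidenceRecord]:
    """Load one evidence table in a source dialect and normalize it fully.

    Normalization order: response type -> evidence level -> substitutes
    splitting -> cancer type -> drug class.  Therapy rows with an empty drug
    field are rejected and counted in the skip log.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise FormatError(f"unknown dialect {dialect!r}; expected one of {SOURCES}")
    cols = _DIALECT_COLUMNS[dialect]
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {v for v in cols.values() if v}
    missing = sorted(required - set(df.columns))
    if missing:
        raise FormatError(
            f"{dialect} table is missing column(s): {', '.join(missing)}")
    raw_records: list[EvidenceRecord] = []
    skipped = 0
    for _, row in df.iterrows():
        drugs = tuple(normalize_drug_label(d) for d in
                      str(row[cols["drugs"]]).split(",") if d.strip())
        if not drugs:
            skipped += 1
            logger.warning("skipping therapy row without drugs: %s/%s",
                           row[cols["gene"]], row[cols["variant"]])
            continue
        interaction = "none"
        if cols["interaction"]:
            raw_int = str(row[cols["interaction"]]).strip().casefold()
            if raw_int in ("substitutes", "combination"):
                interaction = raw_int
        raw_records.append(EvidenceRecord(
            source=dialect,
            biomarker_gene=str(row[cols["gene"]]).strip().upper(),
            biomarker_spec=str(row[cols["variant"]]).strip(),
            cancer_type_raw=str(row[cols["disease"]]).strip(),
            drugs=drugs,
            interaction=interaction,
            response_raw=str(row[cols["response"]]).strip(),
            evidence_level_raw=str(row[cols["level"]]).strip(),
            statement=str(row[cols["statement"]]).strip(),
            citation_id=str(row[cols["citation"]]).strip(),
        ))
    if skipped:
        logger.warning("skipped %d evidence row(s) in %s", skipped, path)
    return normalize_records(raw_records, cancer_table, drug_table,
                             level_mapping, fuzzy_threshold)


def normalize_records(
    records: Iterable[EvidenceRecord],
    cancer_table: CancerTypeTable | None = None,
    drug_table: DrugClassTable | None = None,
    level_mapping: dict[tuple[str, str], str] | None = None,
    fuzzy_threshold: float = DEFAULT_FUZZY_THRESHOLD,
) -> list[EvidenceRecord]:
    """Apply the normalization pipeline to in-memory evidence records.

    Normalized fields are always recomputed from the retained raw fields,
    so applying the pipeline twice equals applying it once.
    """
    if level_mapping is None:
        level_mapping = load_level_mapping()
    out: list[EvidenceRecord] = []
    for rec in records:
        rec = replace(
            rec,
            response=map_response_type(rec.source, rec.response_raw),
            amp_tier=map_evidence_level(rec.source, rec.evidence_level_raw,
                                        level_mapping),
        )
        for split in split_substitutes(rec):
            if cancer_table is not None:
                split = replace(split, cancer_type_main=normalize_cancer_type(
                    split.cancer_type_raw, cancer_table, fuzzy_threshold))
            if drug_table is not None:
                split = replace(split, drug_classes=tuple(
                    classify_drug(d, drug_table) for d in split.drugs))
            out.append(split)
    return out
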