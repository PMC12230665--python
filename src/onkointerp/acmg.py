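"""Five-class pathogenicity classification from retrieved variant annotations.

A deterministic subset of the ACMG/AMP evidence criteria (Richards et al.
2015) is evaluated from an annotation bundle — population allele frequency,
in-silico predictor scores, a ClinVar-style clinical assertion, and
hotspot/known-variant flags — and combined into one of five labels:
pathogenic, likely pathogenic, VUS, likely benign, benign.  Only criteria
computable from these inputs are implemented; segregation, de novo, and
functional-assay criteria have no input here and are out of scope.

Implemented criteria and strengths:

===========  ============  =====================================================
criterion    strength      trigger
===========  ============  =====================================================
PVS1         very strong   null variant in a loss-of-function gene
PS1          strong        same amino-acid change previously established pathogenic
PM1          moderate      mutational hotspot / critical functional domain
PM2          moderate      absent from population data or below the rare cutoff
PM5          moderate      different pathogenic missense at the same residue
PP3          supporting    predictor consensus deleterious
PP5          supporting    reputable-source (ClinVar-like) pathogenic assertion
BA1          stand-alone   allele frequency above the common cutoff
BS1          strong        frequency greater than expected for the disorder
BP4          supporting    predictor consensus benign
BP6          supporting    reputable-source benign assertion
===========  ============  =====================================================

All numeric cutoffs live in an editable configuration file
(``data/acmg.cfg``); nothing is hard-coded.  Conflicting pathogenic- and
benign-side evidence yields VUS, following the guideline's treatment of
contradictory evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib.resources import files
from pathlib import Path
from typing import Sequence

from .errors import ConfigError, ValidationError

LABELS = ("pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign")

# rank on the pathogenicity axis; higher = more pathogenic
LABEL_RANK = {"benign": 0, "likely_benign": 1, "vus": 2,
              "likely_pathogenic": 3, "pathogenic": 4}

PATHOGENIC_STRENGTH = {
    "PVS1": "very_strong",
    "PS1": "strong",
    "PM1": "moderate", "PM2": "moderate", "PM5": "moderate",
    "PP3": "supporting", "PP5": "supporting",
}
BENIGN_STRENGTH = {
    "BA1": "stand_alone",
    "BS1": "strong",
    "BP4": "supporting", "BP6": "supporting",
}
ALL_CRITERIA = tuple(PATHOGENIC_STRENGTH) + tuple(BENIGN_STRENGTH)


@dataclass
class AnnotationBundle:
    """Retrieved annotations of one variant feeding the classifier."""

    population_af: float | None = None
    predictor_scores: dict[str, float] = field(default_factory=dict)
    clinical_assertion: str = "none"  # pathogenic|likely_pathogenic|benign|likely_benign|vus|none
    known_pathogenic_same_change: bool = False
    known_pathogenic_same_residue: bool = False
    in_hotspot_or_functional_domain: bool = False
    null_variant_in_lof_gene: bool = False

    def __post_init__(self) -> None:
        if self.population_af is not None and not 0 <= self.population_af <= 1:
            raise ValidationError(
                f"population_af must be in [0,1], got {self.population_af}")
        for name, score in self.predictor_scores.items():
            if not 0 <= score <= 1:
                raise ValidationError(
                    f"predictor score {name} must be in [0,1], got {score}")


@dataclass
class AcmgConfig:
    """Thresholds for the frequency and predictor-consensus criteria."""

    pm2_af: float = 1e-4
    bs1_af: float = 0.01
    ba1_af: float = 0.05
    consensus_fraction: float = 0.75
    predictor_cutoffs: dict[str, tuple[float, float]] = field(
        default_factory=dict)  # name -> (deleterious >=, benign <=)

    def __post_init__(self) -> None:
        for name, val in (("pm2_af", self.pm2_af), ("bs1_af", self.bs1_af),
                          ("ba1_af", self.ba1_af),
                          ("consensus_fraction", self.consensus_fraction)):
            if not 0 <= val <= 1:
                raise ConfigError(f"{name} must be in [0,1], got {val}")
        if not self.pm2_af < self.bs1_af < self.ba1_af:
            raise ConfigError(
                "frequency cutoffs must satisfy pm2_af < bs1_af < ba1_af "
                f"(rare below common), got {self.pm2_af}, {self.bs1_af}, "
                f"{self.ba1_af}")
        for name, (dele, ben) in self.predictor_cutoffs.items():
            if not (0 <= ben <= 1 and 0 <= dele <= 1):
                raise ConfigError(f"predictor cutoffs for {name} out of [0,1]")

    @classmethod
    def from_file(cls, path: str | Path | None = None) -> "AcmgConfig":
        """Load from a flat key-value file; ``None`` loads the packaged default."""
        if path is None:
            text = files("onkointerp.data").joinpath("acmg.cfg").read_text()
        else:
            text = Path(path).read_text()
        kv: dict[str, float] = {}
        for lineno, line in enumerate(text.splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ConfigError(f"config line {lineno} is not '<key> <value>'")
            try:
                kv[parts[0]] = float(parts[1])
            except ValueError as exc:
                raise ConfigError(f"non-numeric value on line {lineno}") from exc
        cutoffs: dict[str, tuple[float, float]] = {}
        for key in list(kv):
            if key.endswith("_deleterious"):
                name = key.removesuffix("_deleterious")
                cutoffs[name] = (kv.pop(key), kv.pop(f"{name}_benign", 0.0))
        return cls(
            pm2_af=kv.get("pm2_af", 1e-4),
            bs1_af=kv.get("bs1_af", 0.01),
            ba1_af=kv.get("ba1_af", 0.05),
            consensus_fraction=kv.get("consensus_fraction", 0.75),
            predictor_cutoffs=cutoffs,
        )


@dataclass
class AcmgResult:
    """Triggered criteria, combined label, and the derivation trace."""

    triggered: frozenset[str]
    label: str
    trace: list[tuple[str, str, str]]  # (criterion, annotation, value)


def evaluate_criteria(
    a: AnnotationBundle, config: AcmgConfig | None = None
) -> AcmgResult:
    """Map an annotation bundle to the triggered criterion set (with trace)."""
    cfg = config or AcmgConfig.from_file()
    triggered: set[str] = set()
    trace: list[tuple[str, str, str]] = []

    def hit(code: str, annotation: str, value) -> None:
        triggered.add(code)
        trace.append((code, annotation, str(value)))

    if a.null_variant_in_lof_gene:
        hit("PVS1", "null_variant_in_lof_gene", True)
    if a.known_pathogenic_same_change:
        hit("PS1", "known_pathogenic_same_change", True)
    if a.known_pathogenic_same_residue:
        hit("PM5", "known_pathogenic_same_residue", True)
    if a.in_hotspot_or_functional_domain:
        hit("PM1", "in_hotspot_or_functional_domain", True)

    af = a.population_af
    if af is None or af < cfg.pm2_af:
        hit("PM2", "population_af", "absent" if af is None else af)
    if af is not None and af > cfg.ba1_af:
        hit("BA1", "population_af", af)
    if af is not None and af > cfg.bs1_af:
        hit("BS1", "population_af", af)

    scored = {n: s for n, s in a.predictor_scores.items()
              if n in cfg.predictor_cutoffs}
    if scored:
        n_del = sum(s >= cfg.predictor_cutoffs[n][0] for n, s in scored.items())
        n_ben = sum(s <= cfg.predictor_cutoffs[n][1] for n, s in scored.items())
        if n_del / len(scored) >= cfg.consensus_fraction:
            hit("PP3", "predictor_consensus",
                f"{n_del}/{len(scored)} deleterious")
        if n_ben / len(scored) >= cfg.consensus_fraction:
            hit("BP4", "predictor_consensus", f"{n_ben}/{len(scored)} benign")

    if a.clinical_assertion in ("pathogenic", "likely_pathogenic"):
        hit("PP5", "clinical_assertion", a.clinical_assertion)
    elif a.clinical_assertion in ("benign", "likely_benign"):
        hit("BP6", "clinical_assertion", a.clinical_assertion)

    return AcmgResult(triggered=frozenset(triggered),
                      label=combine_criteria(triggered), trace=trace)


def combine_criteria(triggered: set[str] | frozenset[str]) -> str:
    """Combine triggered criteria into a five-class label (Richards rules).

    The label depends only on the multiset of strengths.  Contradictory
    pathogenic- and benign-side evidence, or evidence insufficient for any
    rule, yields ``vus``.
    """
    unknown = set(triggered) - set(ALL_CRITERIA)
    if unknown:
        raise ValidationError(f"unknown criterion code(s): {sorted(unknown)}")
    pvs = sum(PATHOGENIC_STRENGTH.get(c) == "very_strong" for c in triggered)
    ps = sum(PATHOGENIC_STRENGTH.get(c) == "strong" for c in triggered)
    pm = sum(PATHOGENIC_STRENGTH.get(c) == "moderate" for c in triggered)
    pp = sum(PATHOGENIC_STRENGTH.get(c) == "supporting" for c in triggered)
    ba = sum(BENIGN_STRENGTH.get(c) == "stand_alone" for c in triggered)
    bs = sum(BENIGN_STRENGTH.get(c) == "strong" for c in triggered)
    bp = sum(BENIGN_STRENGTH.get(c) == "supporting" for c in triggered)

    if (pvs + ps + pm + pp) and (ba + bs + bp):
        return "vus"

    # pathogenic
    if pvs >= 1 and (ps >= 1 or pm >= 2 or (pm >= 1 and pp >= 1) or pp >= 2):
        return "pathogenic"
    if ps >= 2:
        return "pathogenic"
    if ps >= 1 and (pm >= 3 or (pm >= 2 and pp >= 2) or (pm >= 1 and pp >= 4)):
        return "pathogenic"
    # likely pathogenic
    if pvs >= 1 and pm >= 1:
        return "likely_pathogenic"
    if ps >= 1 and pm >= 1:
        return "likely_pathogenic"
    if ps >= 1 and pp >= 2:
        return "likely_pathogenic"
    if pm >= 3:
        return "likely_pathogenic"
    if pm >= 2 and pp >= 2:
        return "likely_pathogenic"
    if pm >= 1 and pp >= 4:
        return "likely_pathogenic"
    # benign
    if ba >= 1 or bs >= 2:
        return "benign"
    if bs >= 1 and bp >= 1:
        return "likely_benign"
    if bp >= 2:
        return "likely_benign"
    return "vus"


# ---------------------------------------------------------------------------
# prioritization


_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24,
                                                    "M": 25, "MT": 25}

_ASSERTION_RANK = {"pathogenic": 0, "likely_pathogenic": 1, "vus": 2,
                   "none": 3, "likely_benign": 4, "benign": 5}


def _genomic_key(item: dict) -> tuple:
    v = item.get("variant")
    chrom = getattr(v, "chrom", None) or ""
    pos = getattr(v, "pos", None) or 0
    return (_CHROM_ORDER.get(str(chrom), 99), pos)


def prioritize(items: Sequence[dict], sort_key: str = "acmg") -> list[dict]:
    """Stable descending-pathogenicity sort of annotated variants.

    Each item is a dict with keys ``variant`` (ParsedVariant), ``acmg``
    (AcmgResult), ``bundle`` (AnnotationBundle).  ``sort_key`` is ``acmg``
    (default), ``clinical_assertion``, or a named predictor score; predictor
    sorts place absent scores last.  Ties are broken by (chrom, pos).
    """
    items = list(items)
    if sort_key == "acmg":
        return sorted(items, key=lambda it: (
            4 - LABEL_RANK[it["acmg"].label], _genomic_key(it)))
    if sort_key == "clinical_assertion":
        return sorted(items, key=lambda it: (
            _ASSERTION_RANK.get(it["bundle"].clinical_assertion, 3),
            _genomic_key(it)))
    predictor_names = {n for it in items
                       for n in it["bundle"].predictor_scores}
    if sort_key in predictor_names:
        def score_key(it: dict) -> tuple:
            s = it["bundle"].predictor_scores.get(sort_key)
            return (0, -s, _genomic_key(it)) if s is not None \
                else (1, 0.0, _genomic_key(it))
        return sorted(items, key=score_key)
    raise ValidationError(
        f"unknown sort key {sort_key!r}; valid: acmg, clinical_assertion, "
        f"or a predictor name ({', '.join(sorted(predictor_names)) or 'none loaded'})")
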