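"""Aligned per-residue feature tracks for a mutated protein site.

Combines the individual computations — ASA/RSA, Calpha distances to the
mutated residue, secondary structure, domain membership (from an input
interval table), known variants, and optional precomputed binding-site
probabilities — into one table, exportable as TSV or JSON, plus a
rule-based one-line context summary for the mutated site (domain membership
+ burial + predictor score lean the site pathogenic; exposed loop outside
any domain with a low score leans it benign).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ..errors import FormatError
from .geometry import calpha_distances, compute_asa, compute_rsa, load_maxasa
from .secondary import assign_secondary_structure
from .structure import StructureModel


@dataclass
class ResidueFeatures:
    """Structural context of one residue relative to the mutated site."""

    index: int
    aa: str
    asa: float  # A^2
    rsa: float  # fraction of MaxASA, clamped to [0, 1]
    calpha_dist: float | None  # A; 0 iff this is the mutated residue
    ss_state: str  # H | E | C
    domain: str | None
    binding_prob: float | None
    known_variants_here: list[str]
    confidence: float = 0.0


def read_domain_table(path: str | Path) -> list[tuple[int, int, str]]:
    """Domain intervals from TSV (start, end, label), 1-based inclusive."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("start"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"domain table line is not start/end/label: {line!r}")
        rows.append((int(parts[0]), int(parts[1]), parts[2]))
    return rows


def read_known_variants(path: str | Path) -> list[tuple[int, str]]:
    """Known variants from TSV (aa_pos, label)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("aa_pos"):
            continue
        parts = line.split("\t")
        rows.append((int(parts[0]), parts[1]))
    return rows


def read_binding_table(path: str | Path) -> dict[int, float]:
    """Precomputed per-residue binding-site probabilities (aa_pos, prob)."""
    out: dict[int, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("aa_pos"):
            continue
        pos, prob = line.split("\t")
        out[int(pos)] = float(prob)
    return out


def _domain_of(index: int, domains: Sequence[tuple[int, int, str]]) -> str | None:
    for start, end, label in domains:
        if start <= index <= end:
            return label
    return None


def build_feature_tracks(
    s: StructureModel,
    mutated_index: int,
    domain_table: Sequence[tuple[int, int, str]] = (),
    known_variants: Sequence[tuple[int, str]] = (),
    binding_table: dict[int, float] | None = None,
    predictor_score: float | None = None,
    maxasa_table: dict[str, float] | None = None,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> tuple[list[ResidueFeatures], str]:
    """Aligned per-residue feature table plus a context summary line.

    Raises a track-naming error when an input table refers to residues
    outside the structure.
    """
    indices = {r.index for r in s.residues}
    for start, end, label in domain_table:
        if start > end:
            raise FormatError(f"domain track: interval {label!r} has start > end")
    if binding_table:
        bad = sorted(set(binding_table) - indices)
        if bad:
            raise FormatError(
                f"binding-probability track refers to residues {bad} "
                "absent from the structure")

    maxasa = maxasa_table or load_maxasa()
    asa = compute_asa(s, probe_radius=probe_radius, n_points=n_points)
    dists = calpha_distances(s, mutated_index)
    ss = assign_secondary_structure(s)
    known_by_pos: dict[int, list[str]] = {}
    for pos, label in known_variants:
        known_by_pos.setdefault(pos, []).append(label)

    rows = []
    for r in s.residues:
        rows.append(ResidueFeatures(
            index=r.index,
            aa=r.aa,
            asa=round(asa[r.index], 2),
            rsa=round(compute_rsa(asa[r.index], r.aa, maxasa), 4)
            if r.aa in maxasa else 0.0,
            calpha_dist=None if dists[r.index] is None
            else round(dists[r.index], 3),
            ss_state=ss[r.index],
            domain=_domain_of(r.index, domain_table),
            binding_prob=(binding_table or {}).get(r.index),
            known_variants_here=known_by_pos.get(r.index, []),
            confidence=round(r.confidence, 2),
        ))
    summary = summarize_context(rows, mutated_index, predictor_score)
    return rows, summary


def summarize_context(
    rows: Sequence[ResidueFeatures],
    mutated_index: int,
    predictor_score: float | None = None,
    score_high: float = 0.6,
    score_low: float = 0.4,
) -> str:
    """Rule-based one-line interpretation of the mutated site's context.

    Domain membership, below-average RSA (burial), and a high predictor
    score lean the site pathogenic; an exposed loop outside any domain with
    a low score leans it benign; anything else is indeterminate.
    """
    site = next((r for r in rows if r.index == mutated_index), None)
    if site is None:
        raise FormatError(f"mutated residue {mutated_index} not in feature rows")
    mean_rsa = float(np.mean([r.rsa for r in rows]))
    buried = site.rsa < mean_rsa
    in_domain = site.domain is not None
    high_score = predictor_score is not None and predictor_score >= score_high
    low_score = predictor_score is not None and predictor_score <= score_low
    where = (f"residue {site.index} ({site.aa}): ss={site.ss_state}, "
             f"rsa={site.rsa:.2f} (protein mean {mean_rsa:.2f}), "
             f"domain={site.domain or 'none'}")
    if in_domain and buried and high_score:
        return f"{where} -> pathogenic-leaning context"
    if (not in_domain) and site.ss_state == "C" and (not buried) and low_score:
        return f"{where} -> benign-leaning context"
    return f"{where} -> indeterminate context"


def features_to_tsv(rows: Sequence[ResidueFeatures], path: str | Path) -> None:
    """Export the feature table as TSV (index, aa, asa, rsa, calpha_dist, ss,
    domain, binding_prob)."""
    df = pd.DataFrame([{
        "index": r.index, "aa": r.aa, "asa": r.asa, "rsa": r.rsa,
        "calpha_dist": "" if r.calpha_dist is None else r.calpha_dist,
        "ss": r.ss_state, "domain": r.domain or "",
        "binding_prob": "" if r.binding_prob is None else r.binding_prob,
        "known_variants": ";".join(r.known_variants_here),
    } for r in rows])
    df.to_csv(path, sep="\t", index=False)


def features_to_json(rows: Sequence[ResidueFeatures], summary: str = "") -> str:
    return json.dumps({"summary": summary,
                       "residues": [asdict(r) for r in rows]}, indent=1)
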