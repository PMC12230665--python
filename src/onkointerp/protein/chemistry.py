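"""Physicochemical profile of an amino-acid substitution.

Deltas are computed from a packaged property table (molecular weight,
side-chain charge at pH 7, polarity, aromaticity, helix breakers,
Chou-Fasman beta-sheet propensity, Kyte-Doolittle hydropathy, isoelectric
point); conservation is scored with the canonical NCBI BLOSUM62 matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib.resources import files
from pathlib import Path

from ..errors import ValidationError

_CHARGE_NAMES = {-1: "negative", 0: "neutral", 1: "positive"}
_HELIX_BREAKERS = {"P", "G"}


@lru_cache(maxsize=4)
def load_aa_properties(path: str | None = None) -> dict[str, dict]:
    """Amino acid -> property dict from the packaged (or given) TSV table."""
    if path is None:
        text = files("onkointerp.data").joinpath("aa_properties.tsv").read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    table: dict[str, dict] = {}
    for line in lines[1:]:
        vals = line.split("\t")
        row = dict(zip(header, vals))
        table[row["aa"]] = {
            "mw": float(row["mw"]),
            "charge": int(row["charge"]),
            "polar": bool(int(row["polar"])),
            "aromatic": bool(int(row["aromatic"])),
            "helix_breaker": bool(int(row["helix_breaker"])),
            "beta_propensity": float(row["beta_propensity"]),
            "hydropathy": float(row["hydropathy"]),
            "pi": float(row["pi"]),
        }
    return table


@lru_cache(maxsize=1)
def _blosum62():
    from Bio.Align import substitution_matrices

    return substitution_matrices.load("BLOSUM62")


def blosum62_score(ref_aa: str, alt_aa: str) -> int:
    """Canonical BLOSUM62 substitution score (diagonal = conservation)."""
    return int(_blosum62()[ref_aa, alt_aa])


@dataclass(frozen=True)
class SubstitutionProfile:
    """Chemical consequences of replacing ``ref_aa`` with ``alt_aa``."""

    ref_aa: str
    alt_aa: str
    delta_weight: float  # Da
    charge_change: tuple[str, str]  # (from, to) at pH 7
    polarity_change: bool
    aromaticity_change: bool
    helix_breaker_introduced: bool
    delta_beta_propensity: float
    delta_hydropathy: float
    delta_pi: float
    blosum62: int
    new_cys: bool
    charge_pair_potential: bool


def substitution_features(ref_aa: str, alt_aa: str) -> SubstitutionProfile:
    """Profile the substitution of two canonical amino acids.

    All deltas are zero and the BLOSUM62 score equals the diagonal entry
    when ``ref_aa == alt_aa``.
    """
    props = load_aa_properties()
    for aa in (ref_aa, alt_aa):
        if aa not in props:
            raise ValidationError(f"not a canonical amino acid: {aa!r}")
    ref, alt = props[ref_aa], props[alt_aa]
    return SubstitutionProfile(
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        delta_weight=round(alt["mw"] - ref["mw"], 2),
        charge_change=(_CHARGE_NAMES[ref["charge"]], _CHARGE_NAMES[alt["charge"]]),
        polarity_change=ref["polar"] != alt["polar"],
        aromaticity_change=ref["aromatic"] != alt["aromatic"],
        helix_breaker_introduced=(alt_aa in _HELIX_BREAKERS
                                  and ref_aa not in _HELIX_BREAKERS),
        delta_beta_propensity=round(alt["beta_propensity"]
                                    - ref["beta_propensity"], 3),
        delta_hydropathy=round(alt["hydropathy"] - ref["hydropathy"], 2),
        delta_pi=round(alt["pi"] - ref["pi"], 2),
        blosum62=blosum62_score(ref_aa, alt_aa),
        new_cys=alt_aa == "C" and ref_aa != "C",
        charge_pair_potential=alt["charge"] != 0,
    )
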