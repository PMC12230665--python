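"""Solvent accessibility, distance geometry, bridges, and spatial neighbors.

ASA is computed by the Shrake-Rupley rolling-probe quadrature: quasi-uniform
points are placed on each atom's solvent-expanded sphere and a point counts
as accessible iff it lies outside every other atom's expanded sphere.  The
relative accessibility RSA = ASA / MaxASA uses the Tien et al. (2013)
theoretical maxima and is clamped to [0, 1].

Alpha-carbon distances to the mutated residue are plain Euclidean distances
between Calpha coordinates, d_i = sqrt((x_i-x_m)^2 + (y_i-y_m)^2 + (z_i-z_m)^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from ..errors import ConfigError, ValidationError
from .structure import StructureModel

DEFAULT_PROBE_RADIUS = 1.4  # water probe, Angstrom
DEFAULT_N_POINTS = 960

# side-chain charge carriers at pH 7 and their terminal atoms
_POSITIVE_TERMINALS = {"K": ("NZ",), "R": ("NH1", "NH2", "NE"),
                       "H": ("ND1", "NE2")}
_NEGATIVE_TERMINALS = {"D": ("OD1", "OD2"), "E": ("OE1", "OE2")}

DEFAULT_DISULFIDE_CUTOFF = 2.5  # Sgamma-Sgamma, Angstrom
DEFAULT_SALT_BRIDGE_CUTOFF = 4.0  # charged terminal atoms, Angstrom


def load_maxasa(path: str | Path | None = None) -> dict[str, float]:
    """Residue type -> theoretical maximum ASA (A^2); packaged default table."""
    if path is None:
        text = files("onkointerp.data").joinpath("maxasa_tien2013.tsv").read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("aa"):
            continue
        aa, val = line.split("\t")
        if float(val) <= 0:
            raise ConfigError(f"MaxASA for {aa} must be positive")
        table[aa] = float(val)
    return table


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([np.sin(phi) * np.cos(theta),
                            np.sin(phi) * np.sin(theta),
                            np.cos(phi)])


def compute_asa(
    s: StructureModel,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> dict[int, float]:
    """Per-residue accessible surface area (A^2) by Shrake-Rupley.

    Atom ASA = accessible point fraction x 4 pi (r + probe)^2; residue ASA
    is the sum over its atoms.
    """
    if probe_radius <= 0:
        raise ConfigError(f"probe_radius must be positive, got {probe_radius}")
    if n_points < 92:
        raise ConfigError(f"n_points must be >= 92, got {n_points}")
    coords, radii, owner = s.atom_table()
    n_atoms = len(coords)
    unit = fibonacci_sphere(n_points)
    expanded = radii + probe_radius
    tree = cKDTree(coords)
    max_reach = 2 * expanded.max()
    asa = {r.index: 0.0 for r in s.residues}
    for i in range(n_atoms):
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach)
                     if j != i]
        pts = coords[i] + expanded[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
            if not accessible.any():
                break
        frac = accessible.mean()
        asa[owner[i]] += frac * 4.0 * np.pi * expanded[i] ** 2
    return asa


def compute_rsa(asa: float, residue_type: str,
                maxasa_table: dict[str, float] | None = None) -> float:
    """RSA = ASA / MaxASA, clamped to [0, 1]."""
    table = maxasa_table or load_maxasa()
    if residue_type not in table:
        raise ValidationError(
            f"residue type {residue_type!r} absent from the MaxASA table")
    return min(max(asa / table[residue_type], 0.0), 1.0)


def calpha_distances(s: StructureModel, mutated_index: int
                     ) -> dict[int, float | None]:
    """Euclidean Calpha distance of every residue to the mutated residue.

    Residues lacking a Calpha atom are reported as None.  The mutated
    residue itself has distance 0.
    """
    mut = s.residue(mutated_index).calpha
    if mut is None:
        raise ValidationError(
            f"mutated residue {mutated_index} lacks a Calpha atom")
    out: dict[int, float | None] = {}
    for r in s.residues:
        ca = r.calpha
        out[r.index] = None if ca is None else float(
            np.linalg.norm(ca.coord - mut.coord))
    return out


@dataclass(frozen=True)
class BridgeCandidate:
    kind: str  # "disulfide" | "salt_bridge"
    change: str  # "gained" | "lost"
    partner_index: int
    distance: float


def _proxy_atom(residue, names: Sequence[str]):
    """First available atom from ``names``, falling back to CB then CA."""
    for n in list(names) + ["CB", "CA"]:
        if n in residue.atoms:
            return residue.atoms[n]
    return None


def detect_bridges(
    s: StructureModel,
    mutated_index: int,
    ref_aa: str,
    alt_aa: str,
    disulfide_cutoff: float = DEFAULT_DISULFIDE_CUTOFF,
    salt_bridge_cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
) -> list[BridgeCandidate]:
    """Disulfide-bond and salt-bridge candidates gained or lost by a substitution.

    A disulfide candidate arises when the alternate residue is cysteine and
    another cysteine's Sgamma (or Cbeta proxy) lies within the disulfide
    cutoff; a salt-bridge candidate when the alternate residue is charged
    and an oppositely charged side-chain terminal atom lies within the
    salt-bridge cutoff.  Bridges supported by the reference residue
    (cysteine or charged) are reported as lost.
    """
    if disulfide_cutoff <= 0 or salt_bridge_cutoff <= 0:
        raise ConfigError("bridge cutoffs must be positive")
    mutated = s.residue(mutated_index)
    candidates: list[BridgeCandidate] = []

    def charge(aa: str) -> int:
        if aa in _POSITIVE_TERMINALS:
            return 1
        if aa in _NEGATIVE_TERMINALS:
            return -1
        return 0

    def site_atom(for_aa: str):
        """Anchor atom at the mutated site: the residue's own terminal when
        it matches ``for_aa``, otherwise the Cbeta (or Calpha) proxy."""
        names: list[str] = []
        if for_aa == "C":
            names = ["SG"]
        elif for_aa in _POSITIVE_TERMINALS:
            names = list(_POSITIVE_TERMINALS[for_aa]) if mutated.aa == for_aa \
                else []
        elif for_aa in _NEGATIVE_TERMINALS:
            names = list(_NEGATIVE_TERMINALS[for_aa]) if mutated.aa == for_aa \
                else []
        return _proxy_atom(mutated, names)

    def scan(kind: str, change: str, want_aa: str | int, site) -> None:
        if site is None:
            return
        for r in s.residues:
            if r.index == mutated_index:
                continue
            if kind == "disulfide":
                if r.aa != "C":
                    continue
                partner = _proxy_atom(r, ["SG"])
                cutoff = disulfide_cutoff
            else:
                if charge(r.aa) != want_aa:
                    continue
                terminals = (_POSITIVE_TERMINALS | _NEGATIVE_TERMINALS)[r.aa]
                partner = _proxy_atom(r, terminals)
                cutoff = salt_bridge_cutoff
            if partner is None:
                continue
            d = float(np.linalg.norm(partner.coord - site.coord))
            if d <= cutoff:
                candidates.append(BridgeCandidate(kind, change, r.index, d))

    if alt_aa == "C":
        scan("disulfide", "gained", "C", site_atom("C"))
    if charge(alt_aa):
        scan("salt_bridge", "gained", -charge(alt_aa), site_atom(alt_aa))
    if ref_aa == "C":
        scan("disulfide", "lost", "C", site_atom("C"))
    if charge(ref_aa):
        scan("salt_bridge", "lost", -charge(ref_aa), site_atom(ref_aa))
    return sorted(candidates, key=lambda c: (c.kind, c.change, c.distance))


def spatial_neighbors(
    s: StructureModel,
    mutated_index: int,
    known_variants: Sequence[tuple[int, str]],
    radius: float,
) -> list[dict]:
    """Known variants whose Calpha lies within ``radius`` of the mutated site.

    Sorted ascending by 3D distance; each entry also reports the sequence
    separation, making 3D-close but sequence-far neighbors visible.
    """
    if radius <= 0:
        raise ConfigError(f"radius must be positive, got {radius}")
    dists = calpha_distances(s, mutated_index)
    out = []
    for aa_pos, label in known_variants:
        d = dists.get(aa_pos)
        if d is None or aa_pos == mutated_index or d > radius:
            continue
        out.append({"aa_pos": aa_pos, "label": label,
                    "calpha_dist": d,
                    "seq_separation": abs(aa_pos - mutated_index)})
    return sorted(out, key=lambda e: e["calpha_dist"])
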