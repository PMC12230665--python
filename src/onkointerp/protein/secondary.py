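"""Three-state secondary-structure assignment (H / E / C).

A simplified Kabsch-Sander scheme: backbone hydrogen bonds are detected
with the electrostatic energy model

    E = 0.084 * 332 * (1/d_ON + 1/d_CH - 1/d_OH - 1/d_CN)  [kcal/mol]

with a bond declared when E < -0.5 kcal/mol.  The amide hydrogen, absent
from most structure files, is placed on the backbone nitrogen along the
bisector of the N->C(prev) and N->O(prev) directions at 1.01 A (prolines
have no amide H and cannot donate).

Alpha helix (H) is assigned on runs of at least two consecutive i -> i+4
hydrogen bonds; extended strand (E) on ladder-forming inter-strand bond
patterns (parallel or antiparallel bridges); everything else is coil (C).
Residues with missing backbone atoms are assigned C with a warning.
"""

from __future__ import annotations

import logging

import numpy as np

from .structure import StructureModel

logger = logging.getLogger(__name__)

HB_ENERGY_CUTOFF = -0.5  # kcal/mol
_Q1Q2F = 0.084 * 332.0
_PEPTIDE_BOND_MAX = 2.0  # C(prev)-N distance sanity bound, Angstrom
_H_BOND_LENGTH = 1.01  # N-H, Angstrom


def _backbone(model: StructureModel):
    """Per-residue backbone coordinate dict (or None if incomplete)."""
    out = []
    for r in model.residues:
        atoms = {}
        ok = True
        for name in ("N", "CA", "C", "O"):
            a = r.atoms.get(name)
            if a is None:
                ok = False
                break
            atoms[name] = a.coord
        if not ok:
            logger.warning("residue %d lacks backbone atoms; assigned coil",
                           r.index)
        out.append(atoms if ok else None)
    return out


def _place_hydrogens(model: StructureModel, backbone) -> list[np.ndarray | None]:
    """Amide-H position per residue (None at chain starts, breaks, prolines)."""
    hs: list[np.ndarray | None] = []
    for li, r in enumerate(model.residues):
        bb = backbone[li]
        prev_bb = backbone[li - 1] if li > 0 else None
        prev_idx = model.residues[li - 1].index if li > 0 else None
        if (bb is None or prev_bb is None or r.aa == "P"
                or prev_idx != r.index - 1):
            hs.append(None)
            continue
        if np.linalg.norm(bb["N"] - prev_bb["C"]) > _PEPTIDE_BOND_MAX:
            hs.append(None)  # chain break despite consecutive numbering
            continue
        d1 = bb["N"] - prev_bb["C"]
        d2 = bb["N"] - prev_bb["O"]
        direction = d1 / np.linalg.norm(d1) + d2 / np.linalg.norm(d2)
        direction /= np.linalg.norm(direction)
        hs.append(bb["N"] + _H_BOND_LENGTH * direction)
    return hs


def hydrogen_bonds(model: StructureModel,
                   energy_cutoff: float = HB_ENERGY_CUTOFF) -> set[tuple[int, int]]:
    """Set of (donor, acceptor) list positions: NH of donor -> CO of acceptor."""
    backbone = _backbone(model)
    hs = _place_hydrogens(model, backbone)
    n = len(model.residues)
    bonds: set[tuple[int, int]] = set()
    for i in range(n):  # donor
        if hs[i] is None or backbone[i] is None:
            continue
        for j in range(n):  # acceptor
            if abs(i - j) < 2 or backbone[j] is None:
                continue
            d_on = np.linalg.norm(backbone[j]["O"] - backbone[i]["N"])
            if d_on > 5.2:  # beyond plausible H-bond range; skip the energy
                continue
            d_ch = np.linalg.norm(backbone[j]["C"] - hs[i])
            d_oh = np.linalg.norm(backbone[j]["O"] - hs[i])
            d_cn = np.linalg.norm(backbone[j]["C"] - backbone[i]["N"])
            energy = _Q1Q2F * (1 / d_on + 1 / d_ch - 1 / d_oh - 1 / d_cn)
            if energy < energy_cutoff:
                bonds.add((i, j))
    return bonds


def assign_secondary_structure(
    model: StructureModel,
    energy_cutoff: float = HB_ENERGY_CUTOFF,
) -> dict[int, str]:
    """Per-residue state in {H, E, C}, keyed by residue index."""
    residues = model.residues
    n = len(residues)
    bonds = hydrogen_bonds(model, energy_cutoff)

    def contiguous(a: int, b: int) -> bool:
        """List positions a..b span consecutively numbered residues."""
        if a < 0 or b >= n:
            return False
        return residues[b].index - residues[a].index == b - a

    def hb(acceptor: int, donor: int) -> bool:
        """Kabsch-Sander Hbond(i, j): CO of ``acceptor`` accepts NH of ``donor``."""
        return (donor, acceptor) in bonds

    states = ["C"] * n

    # alpha helix: two consecutive i -> i+4 bonds mark residues i+1 .. i+4
    turn4 = [i for i in range(n - 4)
             if contiguous(i, i + 4) and hb(i, i + 4)]
    for i in turn4:
        if i + 1 in turn4:
            for k in range(i + 1, i + 5):
                states[k] = "H"

    # beta bridges (parallel and antiparallel ladder patterns)
    for i in range(n):
        for j in range(i + 3, n):
            if residues[j].index - residues[i].index <= 4 and contiguous(i, j):
                continue  # helix/turn territory, not an inter-strand contact
            parallel = (
                (contiguous(i - 1, i + 1) and hb(i - 1, j) and hb(j, i + 1))
                or (contiguous(j - 1, j + 1) and hb(j - 1, i) and hb(i, j + 1))
            )
            antiparallel = (
                (hb(i, j) and hb(j, i))
                or (contiguous(i - 1, i + 1) and contiguous(j - 1, j + 1)
                    and hb(i - 1, j + 1) and hb(j - 1, i + 1))
            )
            if parallel or antiparallel:
                for k in (i, j):
                    if states[k] != "H":
                        states[k] = "E"

    return {r.index: s for r, s in zip(residues, states)}
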