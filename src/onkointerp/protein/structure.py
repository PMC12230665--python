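"""PDB structure ingestion into a per-residue model.

Structures are read from PDB ATOM records (AlphaFold-style single chain,
per-atom confidence in the B-factor column).  Atoms carry element-typed van
der Waals radii from a packaged table; residue indices follow the 1-based
``aa_pos`` convention of protein-level variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib.resources import files
from pathlib import Path

import numpy as np

from ..errors import FormatError

AA_3TO1_UPPER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA_1TO3 = {v: k for k, v in AA_3TO1_UPPER.items()}

_DEFAULT_RADIUS = 1.70  # carbon fallback for unlisted elements


def load_vdw_radii(path: str | Path | None = None) -> dict[str, float]:
    """Element -> van der Waals radius (A) from the packaged (or given) table."""
    if path is None:
        text = files("onkointerp.data").joinpath("vdw_radii.tsv").read_text()
    else:
        text = Path(path).read_text()
    radii: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("element"):
            continue
        element, radius = line.split("\t")
        radii[element.upper()] = float(radius)
    return radii


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) in Angstrom
    radius: float
    confidence: float = 0.0  # B-factor column (per-residue pLDDT for AlphaFold)


@dataclass
class Residue:
    index: int  # 1-based residue index (aa_pos convention)
    aa: str  # one-letter code, "X" for unknown
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def calpha(self) -> Atom | None:
        return self.atoms.get("CA")

    @property
    def confidence(self) -> float:
        """Mean per-atom confidence (the AlphaFold pLDDT convention)."""
        if not self.atoms:
            return 0.0
        return float(np.mean([a.confidence for a in self.atoms.values()]))


@dataclass
class StructureModel:
    """Single-chain protein structure, residues ordered by residue index."""

    residues: list[Residue]
    chain_id: str = "A"

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise FormatError("residue indices must be strictly increasing")
        for r in self.residues:
            for a in r.atoms.values():
                if not np.all(np.isfinite(a.coord)):
                    raise FormatError(
                        f"non-finite coordinate in residue {r.index}")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, index: int) -> Residue:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(f"no residue with index {index}")

    def atom_table(self) -> tuple[np.ndarray, np.ndarray, list[int]]:
        """(coords (n,3), radii (n,), residue index per atom)."""
        coords, radii, owner = [], [], []
        for r in self.residues:
            for a in r.atoms.values():
                coords.append(a.coord)
                radii.append(a.radius)
                owner.append(r.index)
        return np.asarray(coords, float), np.asarray(radii, float), owner

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "StructureModel":
        """Apply a rigid motion; returns a new model (used for invariance checks)."""
        new_residues = []
        for r in self.residues:
            atoms = {
                n: Atom(a.name, a.element, rotation @ a.coord + translation,
                        a.radius, a.confidence)
                for n, a in r.atoms.items()
            }
            new_residues.append(Residue(r.index, r.aa, atoms))
        return StructureModel(new_residues, self.chain_id)


def read_structure(path: str | Path, chain: str | None = None,
                   vdw_table: dict[str, float] | None = None) -> StructureModel:
    """Read a PDB file into a StructureModel.

    Only ATOM records are used; HETATM-only files are rejected.  Files with
    several chains require an explicit ``chain`` selection.  The B-factor
    column is kept as per-atom confidence (AlphaFold writes pLDDT there).
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        arr = pdb_file.get_structure(model=1, extra_fields=["b_factor"])
    except Exception as exc:
        raise FormatError(f"not a readable PDB file: {path} ({exc})") from exc
    arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise FormatError(f"no ATOM records in {path}")
    chains = sorted(set(arr.chain_id))
    if chain is None:
        if len(chains) > 1:
            raise FormatError(
                f"{path} contains chains {', '.join(chains)}; select one "
                "with the chain argument (--chain on the command line)")
        chain = chains[0]
    elif chain not in chains:
        raise FormatError(f"chain {chain!r} not in {path} (has {chains})")
    arr = arr[arr.chain_id == chain]

    radii = vdw_table or load_vdw_radii()
    residues: dict[int, Residue] = {}
    for i in range(arr.array_length()):
        idx = int(arr.res_id[i])
        if idx not in residues:
            residues[idx] = Residue(
                index=idx, aa=AA_3TO1_UPPER.get(arr.res_name[i], "X"))
        element = str(arr.element[i]).upper()
        residues[idx].atoms[str(arr.atom_name[i])] = Atom(
            name=str(arr.atom_name[i]),
            element=element,
            coord=np.array(arr.coord[i], dtype=float),
            radius=radii.get(element, _DEFAULT_RADIUS),
            confidence=float(arr.b_factor[i]),
        )
    ordered = [residues[i] for i in sorted(residues)]
    return StructureModel(ordered, chain_id=chain)
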