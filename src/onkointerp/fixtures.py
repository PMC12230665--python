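"""Deterministic synthetic fixtures: toy knowledge bases, annotation tables,
variant files, transcript layouts, and synthetic protein structures.

Everything here is generated programmatically so the toolkit is fully
testable without downloads.  All generators are deterministic under their
``seed`` argument.  The structures are idealized poly-glycine backbones
built from canonical internal coordinates (helix phi = -57, psi = -47;
strand phi = -139, psi = +135; consecutive Calpha-Calpha distance ~3.8 A).
"""

from __future__ import annotations

import random
from pathlib import Path

import numpy as np

from .variants import TranscriptAnnotation

# canonical backbone internal coordinates (Angstrom / degrees)
_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANG_C_N_CA = 121.7
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_CA_C_O = 120.8

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)
# two-residue type II' turn closing a beta hairpin
TURN_PHI_PSI = ((60.0, -120.0), (-80.0, 0.0))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension-of-reference-frame placement of atom D.

    D is placed at distance ``bond`` from C, with angle B-C-D ``angle`` and
    torsion A-B-C-D ``torsion`` (degrees).
    """
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.sin(ang) * np.cos(tor),
                        bond * np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi_psi: list[tuple[float, float]]) -> list[dict]:
    """Backbone N/CA/C/O coordinates for a chain with the given dihedrals.

    ``phi_psi[i]`` supplies (phi_i, psi_i); phi of the first residue is
    unused (no preceding carbonyl), omega is held at 180.
    """
    n_res = len(phi_psi)
    res: list[dict] = []
    # first residue laid out in the xy-plane
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _ANG_N_CA_C)
    c0 = ca0 + _BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = res[-1]
        psi_prev = phi_psi[i - 1][1]
        phi_i = phi_psi[i][0]
        n_i = place_atom(prev["N"], prev["CA"], prev["C"],
                         _BOND_C_N, _ANG_CA_C_N, psi_prev)
        ca_i = place_atom(prev["CA"], prev["C"], n_i,
                          _BOND_N_CA, _ANG_C_N_CA, 180.0)  # omega
        c_i = place_atom(prev["C"], n_i, ca_i,
                         _BOND_CA_C, _ANG_N_CA_C, phi_i)
        res.append({"N": n_i, "CA": ca_i, "C": c_i})
    # carbonyl oxygens: anti to the next amide nitrogen (torsion psi + 180)
    for i in range(n_res):
        psi = phi_psi[i][1]
        res[i]["O"] = place_atom(res[i]["N"], res[i]["CA"], res[i]["C"],
                                 _BOND_C_O, _ANG_CA_C_O, psi + 180.0)
    return res


def _to_pdb(residue_coords: list[dict], res_ids: list[int],
            confidence: float = 90.0) -> str:
    """Poly-glycine PDB text from backbone coordinate dicts."""
    lines = []
    serial = 1
    for coords, rid in zip(residue_coords, res_ids):
        for name in ("N", "CA", "C", "O"):
            if name not in coords:
                continue
            x, y, z = coords[name]
            element = name[0]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{'GLY':>4s} A{rid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{confidence:6.2f}"
                f"          {element:>2s}")
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def _rigid(coords: list[dict], rotation: np.ndarray,
           translation: np.ndarray) -> list[dict]:
    return [{k: rotation @ v + translation for k, v in c.items()}
            for c in coords]


def _principal_align(coords: list[dict]) -> list[dict]:
    """Center the chain and align its Calpha principal axis with x."""
    cas = np.array([c["CA"] for c in coords])
    center = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - center)
    axis = vt[0]
    if axis @ (cas[-1] - cas[0]) < 0:
        axis = -axis
    z = np.cross(axis, vt[1])
    z /= np.linalg.norm(z)
    y = np.cross(z, axis)
    rot = np.vstack([axis, y, z])  # rows -> new basis
    return _rigid(coords, rot, -rot @ center)


def _strand_pair_coords(per_strand: int) -> tuple[list[dict], list[dict]]:
    """Two antiparallel strands registered by rigid-body optimization.

    The partner strand starts as a two-fold (C2-about-z) copy of the first
    and is rigidly moved to satisfy the canonical antiparallel hydrogen-bond
    registry (N_i..O_j and O_i..N_j at 2.9 A for directly paired residues),
    with a soft clash penalty.  Deterministic.
    """
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    a = _principal_align(build_backbone([STRAND_PHI_PSI] * per_strand))

    def arrs(coords: list[dict]) -> dict[str, np.ndarray]:
        return {k: np.array([r[k] for r in coords]) for k in ("N", "CA", "C", "O")}

    A = arrs(a)
    B0 = arrs(_rigid(a, np.diag([-1.0, -1.0, 1.0]), np.zeros(3)))
    pairs = [(i, per_strand - 1 - i) for i in range(0, per_strand, 2)]

    def transform(x: np.ndarray) -> dict[str, np.ndarray]:
        rot = Rotation.from_rotvec(x[:3]).as_matrix()
        return {k: v @ rot.T + x[3:] for k, v in B0.items()}

    def objective(x: np.ndarray) -> float:
        B = transform(x)
        s = 0.0
        for i, j in pairs:
            s += (np.linalg.norm(A["N"][i] - B["O"][j]) - 2.9) ** 2
            s += (np.linalg.norm(A["O"][i] - B["N"][j]) - 2.9) ** 2
        d = np.linalg.norm(A["CA"][:, None] - B["CA"][None], axis=2)
        s += float(np.sum(np.clip(4.0 - d, 0.0, None) ** 2))
        return s

    best = None
    for ty in (4.0, 4.5, 5.0, 5.5):
        r = minimize(objective, np.array([0, 0, 0, 0, ty, 0.0]),
                     method="Nelder-Mead",
                     options={"maxiter": 4000, "fatol": 1e-10, "xatol": 1e-8})
        if best is None or r.fun < best.fun:
            best = r
    B = transform(best.x)
    b = [{k: B[k][i] for k in B} for i in range(per_strand)]
    return a, b


def generate_synthetic_structure(
    kind: str, length: int, seed: int = 0,
    path: str | Path | None = None,
) -> str:
    """Synthetic poly-glycine PDB of the requested backbone geometry.

    Kinds: ``helix`` (canonical alpha helix), ``strand_pair`` (two
    antiparallel strands in one chain with a residue-numbering gap),
    ``hairpin`` (two strands joined by a tight two-residue turn), and
    ``cluster`` (a compact pseudo-random arrangement growing outward from
    residue 1, deterministic and prefix-stable under the seed).

    Returns the PDB text; writes it to ``path`` when given.
    """
    if length < 4:
        raise ValueError(f"length must be >= 4, got {length}")
    rng = random.Random(seed)
    if kind == "helix":
        coords = build_backbone([HELIX_PHI_PSI] * length)
        res_ids = list(range(1, length + 1))
    elif kind == "strand_pair":
        per = max(4, length // 2)
        a, b = _strand_pair_coords(per)
        coords = a + b
        res_ids = list(range(1, per + 1)) + \
            list(range(per + 12, per + 12 + per))
    elif kind == "hairpin":
        per = max(4, (length - 2) // 2)
        dihedrals = ([STRAND_PHI_PSI] * per + list(TURN_PHI_PSI)
                     + [STRAND_PHI_PSI] * per)
        coords = build_backbone(dihedrals)
        res_ids = list(range(1, len(dihedrals) + 1))
    elif kind == "cluster":
        from .protein.geometry import fibonacci_sphere
        # fixed direction set + coprime stride, so shorter clusters are
        # prefixes of longer ones and every prefix spreads over the sphere
        dirs = fibonacci_sphere(97)[[(i * 37) % 97 for i in range(97)]]
        coords = []
        local = build_backbone([HELIX_PHI_PSI])[0]  # one-residue template
        local = {k: v - local["CA"] for k, v in local.items()}
        for i in range(length):
            if i == 0:
                center = np.zeros(3)
            else:
                radius = 4.0 + 0.15 * i
                center = dirs[i] * radius + np.array(
                    [rng.uniform(-0.4, 0.4) for _ in range(3)])
            # random orientation of the residue template
            q = np.array([rng.gauss(0, 1) for _ in range(4)])
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ])
            coords.append({k: rot @ v + center for k, v in local.items()})
        res_ids = list(range(1, length + 1))
    else:
        raise ValueError(f"unknown structure kind {kind!r}")
    text = _to_pdb(coords, res_ids)
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# toy knowledge base


CANCER_TYPE_ROWS = [
    ("Lung Adenocarcinoma", "Lung", "LUAD"),
    ("Non-Small Cell Lung Cancer", "Lung", "NSCLC"),
    ("Thyroid Cancer", "Thyroid", ""),
    ("Medullary Thyroid Cancer", "Thyroid", "MTC"),
    ("Melanoma", "Skin", ""),
    ("Colorectal Adenocarcinoma", "Colorectal", "CRC"),
    ("Breast Carcinoma", "Breast", ""),
    ("Glioblastoma", "Brain", "GBM"),
]

DRUG_CLASS_ROWS = [
    ("selpercatinib", "RET tyrosine kinase inhibitor"),
    ("pralsetinib", "RET tyrosine kinase inhibitor"),
    ("vandetanib", "VEGFR inhibitor"),
    ("cabozantinib", "VEGFR inhibitor"),
    ("dabrafenib", "BRAF inhibitor"),
    ("vemurafenib", "BRAF inhibitor"),
    ("trametinib", "MEK inhibitor"),
    ("sotorasib", "KRAS G12C inhibitor"),
    ("adagrasib", "KRAS G12C inhibitor"),
    ("osimertinib", "EGFR tyrosine kinase inhibitor"),
    ("cetuximab", "EGFR antibody"),
]


def write_cancer_type_table(path: str | Path) -> None:
    lines = ["label\tmain_type\tsynonyms"]
    lines += [f"{l}\t{m}\t{s}" for l, m, s in CANCER_TYPE_ROWS]
    Path(path).write_text("\n".join(lines) + "\n")


def write_drug_class_table(path: str | Path) -> None:
    lines = ["drug\tdrug_class"]
    lines += [f"{d}\t{c}" for d, c in DRUG_CLASS_ROWS]
    Path(path).write_text("\n".join(lines) + "\n")


_CIVIC_HEADER = ("gene\tvariant\tdisease\tdrugs\tdrug_interaction_type\t"
                 "evidence_level\tsignificance\tevidence_statement\tcitation_id")
_ONCOKB_HEADER = "hugo_symbol\talteration\tcancer_type\tdrugs\tlevel\tdescription\tpmid"
_METAKB_HEADER = ("gene\tvariant\tdisease\ttherapies\tevidence_level\t"
                  "association\tstatement\tcitation")

_GENES = ["KRAS", "BRAF", "EGFR", "RET", "TP53"]
_DISEASES = ["Lung Adenocarcinoma", "Melanoma", "Thyroid Cancer",
             "Colorectal Adenocarcinoma", "Glioblastoma", "NSCLC",
             "Thyroid Cancr"]  # last one exercises fuzzy matching
_DRUGS = [d for d, _ in DRUG_CLASS_ROWS]
_VARIANT_SPECS = ["G12A", "G12C", "G12D", "V600E", "V600R", "M918T",
                  "G12", "V600", "exon 2", "exon 15", "mutation"]


def generate_toy_kb(seed: int, n_per_source: int,
                    outdir: str | Path) -> dict[str, Path]:
    """Write three evidence tables (one per dialect) with guaranteed cases.

    Guaranteed content: one cross-source duplicate (civic + metakb), one
    substitutes record, all five biomarker-spec kinds for KRAS, a tier-A
    sensitive gene-level RET record carrying selpercatinib, and one
    unmapped evidence code.  Deterministic under ``seed``.
    """
    if n_per_source < 1:
        raise ValueError("n_per_source must be >= 1")
    rng = random.Random(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    civic = [
        # exact-spec kind + half of the cross-source duplicate
        "KRAS\tG12A\tLung Adenocarcinoma\tsotorasib\t\tB\t"
        "Sensitivity/Response\tObjective responses in KRAS G12A tumors.\tCIT100",
        # substitutes record
        "BRAF\tV600E\tMelanoma\tdabrafenib,vemurafenib\tsubstitutes\tA\t"
        "Sensitivity/Response\tApproved BRAF-inhibitor options.\tCIT101",
        # differing exchange at the same position
        "KRAS\tG12C\tLung Adenocarcinoma\tadagrasib\t\tB\t"
        "Sensitivity/Response\tG12C-selective inhibition.\tCIT102",
        # unmapped evidence code
        "EGFR\tmutation\tNSCLC\tosimertinib\t\tZ9\tSensitivity/Response\t"
        "Code not in the harmonization table.\tCIT103",
    ]
    oncokb = [
        # positional spec kind
        "KRAS\tG12\tLung Adenocarcinoma\tsotorasib\t3A\t"
        "Position-level evidence.\tCIT104",
        # gene-level RET record: tier A, sensitive, selpercatinib
        "RET\tmutation\tThyroid Cancer\tselpercatinib\t1\t"
        "Any RET mutation responds.\tCIT105",
        # gene-level KRAS (five-kinds guarantee) and a resistance example
        "KRAS\tmutation\tColorectal Adenocarcinoma\tcetuximab\tR1\t"
        "KRAS mutations confer resistance.\tCIT106",
    ]
    metakb = [
        # other half of the cross-source duplicate (same 5-field key)
        "KRAS\tG12A\tLung Adenocarcinoma\tsotorasib\tB\t"
        "predicts sensitivity\tSame assertion as the civic row.\tCIT100",
        # exon spec kind
        "KRAS\texon 2\tLung Adenocarcinoma\tadagrasib\tC\t"
        "responsive\tExon-level evidence.\tCIT107",
    ]

    civic_sig = ["Sensitivity/Response", "Resistance", "N/A"]
    oncokb_levels = ["1", "2", "3A", "3B", "4", "R1", "R2"]
    metakb_assoc = ["predicts sensitivity", "resistance", "responsive", "unclear"]
    civic_levels = ["A", "B", "C", "D", "E"]
    metakb_levels = ["A", "B", "C", "D"]

    for k in range(n_per_source):
        g = rng.choice(_GENES)
        v = rng.choice(_VARIANT_SPECS)
        d = rng.choice(_DISEASES)
        drug = rng.choice(_DRUGS)
        cit = f"CIT{200 + k}"
        civic.append(f"{g}\t{v}\t{d}\t{drug}\t\t{rng.choice(civic_levels)}\t"
                     f"{rng.choice(civic_sig)}\tRandomized toy statement.\t{cit}")
        oncokb.append(f"{g}\t{v}\t{d}\t{drug}\t{rng.choice(oncokb_levels)}\t"
                      f"Randomized toy statement.\tCIT{300 + k}")
        metakb.append(f"{g}\t{v}\t{d}\t{drug}\t{rng.choice(metakb_levels)}\t"
                      f"{rng.choice(metakb_assoc)}\tRandomized toy statement.\t"
                      f"CIT{400 + k}")

    paths = {}
    for name, header, rows in (("civic_like", _CIVIC_HEADER, civic),
                               ("oncokb_like", _ONCOKB_HEADER, oncokb),
                               ("metakb_like", _METAKB_HEADER, metakb)):
        p = outdir / f"{name}.tsv"
        p.write_text("\n".join([header] + rows) + "\n")
        paths[name] = p
    return paths


# ---------------------------------------------------------------------------
# toy transcripts, variant files, annotation tables


def toy_transcript_annotation(gene: str = "KRAS") -> TranscriptAnnotation:
    """Small two-exon transcript layouts used across tests and examples.

    The KRAS-like toy places residue 12's codon in exon 2, mirroring the
    exon-level biomarker of the toy knowledge base.  TOYB is minus-strand.
    """
    if gene == "KRAS":
        return TranscriptAnnotation("TOY_KRAS.1", "KRAS", "+",
                                    [(100, 130), (200, 400)], 110, 390)
    if gene == "TOYA":
        return TranscriptAnnotation("TOY_A.1", "TOYA", "+",
                                    [(100, 260), (340, 560)], 121, 540)
    if gene == "TOYB":
        return TranscriptAnnotation("TOY_B.1", "TOYB", "-",
                                    [(1000, 1100), (1200, 1320)], 1050, 1260)
    raise KeyError(f"no toy transcript for gene {gene!r}")


TOY_VCF_RECORDS = [
    # chrom, pos, id, ref, alt  (KRAS G12D-like, BRAF V600E-like, RET M918T-like)
    ("chr12", 25245350, "var1", "C", "T"),
    ("chr7", 140753336, "var2", "A", "T"),
    ("chr10", 43121968, "var3", "T", "C"),
]


def write_toy_vcf(path: str | Path,
                  records: list[tuple] | None = None) -> None:
    records = records if records is not None else TOY_VCF_RECORDS
    contigs = sorted({c.removeprefix("chr") for c, *_ in records},
                     key=lambda c: (len(c), c))
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID=chr{c}>" for c in contigs]
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for chrom, pos, vid, ref, alt in records:
        lines.append(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.")
    Path(path).write_text("\n".join(lines) + "\n")


def write_toy_maf(path: str | Path) -> None:
    lines = ["Hugo_Symbol\tChromosome\tStart_Position\tReference_Allele\t"
             "Tumor_Seq_Allele2\tHGVSp_Short",
             "KRAS\tchr12\t25245350\tC\tT\tp.G12D",
             "BRAF\tchr7\t140753336\tA\tT\tp.V600E",
             "RET\tchr10\t43121968\tT\tC\tp.M918T"]
    Path(path).write_text("\n".join(lines) + "\n")


ANNOTATION_COLUMNS = ["key", "gene", "hgvsp", "population_af", "revel_like",
                      "am_like", "clinical_assertion",
                      "known_pathogenic_same_change",
                      "known_pathogenic_same_residue",
                      "in_hotspot_or_functional_domain",
                      "null_variant_in_lof_gene"]

# protein-level resolution of the toy VCF records (emulating the conversion
# an external genomic-to-protein mapping service would provide)
TOY_VCF_PROTEINS = {
    "12:25245350:C:T": ("KRAS", "p.G12D"),
    "7:140753336:A:T": ("BRAF", "p.V600E"),
    "10:43121968:T:C": ("RET", "p.M918T"),
}


def write_toy_annotations(path: str | Path, keys: list[str], seed: int = 0,
                          proteins: dict[str, tuple[str, str]] | None = None,
                          ) -> None:
    """Per-variant annotation table emulating dbNSFP/ClinVar record shapes.

    The first key gets a clearly pathogenic bundle, the second a benign
    one, the rest are randomized; deterministic under ``seed``.
    ``proteins`` optionally resolves keys to (gene, HGVS.p) columns.
    """
    rng = random.Random(seed)
    proteins = TOY_VCF_PROTEINS if proteins is None else proteins
    assertions = ["pathogenic", "likely_pathogenic", "vus",
                  "likely_benign", "benign", "none"]
    lines = ["\t".join(ANNOTATION_COLUMNS)]
    for i, key in enumerate(keys):
        gene, hgvsp = proteins.get(key, ("", ""))
        if i == 0:
            row = [key, gene, hgvsp, "", "0.95", "0.91",
                   "pathogenic", "1", "1", "1", "0"]
        elif i == 1:
            row = [key, gene, hgvsp, "0.12", "0.05", "0.08",
                   "benign", "0", "0", "0", "0"]
        else:
            af = rng.choice(["", f"{rng.uniform(0, 0.2):.5f}"])
            row = [key, gene, hgvsp, af,
                   f"{rng.random():.3f}", f"{rng.random():.3f}",
                   rng.choice(assertions),
                   str(rng.randint(0, 1)), str(rng.randint(0, 1)),
                   str(rng.randint(0, 1)), "0"]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
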