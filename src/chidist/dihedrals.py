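"""Side-chain chi dihedral angles.

Each of the 18 chi-bearing residue types (all but Ala/Gly) has 1-4 chi
angles defined by standard IUPAC heavy-atom quadruples (chi1 = N-CA-CB-G,
chi2 = CA-CB-G-D, ...).  Angles live on the circle [-180, 180), except the
last chi of Phe, Tyr, Asp and Glu, which is folded into [0, 180): the
terminal aromatic ring or carboxylate is two-fold symmetric, so chi and
chi + 180 name the same conformation.

A residue missing any chi-defining atom yields a missing-marker (``None``)
rather than a partial vector — the distribution functions downstream are
n-dimensional and a partial vector has no grid cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Residue, ResidueKey

__all__ = [
    "ChiDefinition", "DihedralVector", "CHI_ATOMS", "CHI_COUNT",
    "FOLDED_LAST_CHI", "chi_definitions", "torsion", "fold_symmetric",
    "residue_chi_vector", "chi_ranges",
]

# IUPAC chi quadruples; Arg limited to chi1-chi4.
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
}

CHI_COUNT: dict[str, int] = {rt: len(q) for rt, q in CHI_ATOMS.items()}

#: residue types whose LAST chi is folded into [0, 180) by terminal-group symmetry
FOLDED_LAST_CHI = frozenset({"PHE", "TYR", "ASP", "GLU"})


@dataclass
class ChiDefinition:
    res_type: str
    chi_index: int  # 1-based
    atoms: tuple[str, str, str, str]


@dataclass
class DihedralVector:
    residue_key: ResidueKey
    res_type: str
    angles: tuple[float, ...]


def chi_definitions(res_type: str) -> list[ChiDefinition]:
    """Ordered chi definitions for a residue type; empty for Ala/Gly/unknown."""
    quads = CHI_ATOMS.get(res_type, [])
    return [ChiDefinition(res_type, i + 1, q) for i, q in enumerate(quads)]


def chi_ranges(res_type: str) -> list[tuple[float, float]]:
    """Per-chi (start, width) of the angle range: (-180, 360) or (0, 180)."""
    n = CHI_COUNT.get(res_type)
    if n is None:
        raise KeyError(f"residue type {res_type!r} has no chi angles")
    ranges = [(-180.0, 360.0)] * n
    if res_type in FOLDED_LAST_CHI:
        ranges[-1] = (0.0, 180.0)
    return ranges


def torsion(p1, p2, p3, p4) -> float:
    """Signed dihedral angle of four points, degrees in [-180, 180).

    Uses the atan2 formulation: with bond vectors b1 = p2-p1, b2 = p3-p2,
    b3 = p4-p3, the angle is atan2((b1 x b2) x (b2 x b3) . b2/|b2|,
    (b1 x b2).(b2 x b3)).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 < 1e-12 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("undefined dihedral: collinear or coincident points")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    angle = float(np.degrees(np.arctan2(y, x)))
    if angle >= 180.0:  # keep the half-open convention: +180 -> -180
        angle -= 360.0
    return angle


def fold_symmetric(angle: float, res_type: str, chi_index: int) -> float:
    """Map the last chi of Phe/Tyr/Asp/Glu into [0, 180); otherwise identity."""
    if res_type in FOLDED_LAST_CHI and chi_index == CHI_COUNT[res_type]:
        return float(np.mod(angle, 180.0))
    return angle


def residue_chi_vector(r: Residue) -> DihedralVector | None:
    """All chi angles of a residue, folded where symmetric.

    Returns ``None`` (missing-marker) when the residue type has no chi
    angles or any chi-defining atom is absent.
    """
    quads = CHI_ATOMS.get(r.res_type)
    if not quads:
        return None
    angles = []
    for i, quad in enumerate(quads):
        atoms = [r.atom(name) for name in quad]
        if any(a is None for a in atoms):
            return None
        angle = torsion(*(a.coords for a in atoms))
        angles.append(fold_symmetric(angle, r.res_type, i + 1))
    return DihedralVector(r.key, r.res_type, tuple(angles))
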