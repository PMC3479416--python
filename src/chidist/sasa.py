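"""Solvent-accessible surface area and interface classification.

Per-atom SASA is computed with the Shrake-Rupley algorithm: a deterministic
golden-spiral point set on each atom's probe-expanded sphere, a point being
accessible when it lies outside every other atom's expanded sphere.  Residue
SASA is the sum over its atoms; relative SASA divides by a residue-type
reference maximum.

Classification follows the standard bound/unbound interface convention:

* *surface* residue: relative SASA >= 25% in the bound monomer and (when an
  unbound counterpart exists) in the unbound structure;
* *interface* residue: a surface residue losing > 1 A^2 of SASA when its
  monomer is placed in the complex; other surface residues are
  *non-interface*; everything else is *excluded*.

Radii and reference maxima ship as plain-text data files (see
``data/radii.json`` and ``data/rel_sasa_max.tsv``).
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass
from enum import Enum
from importlib import resources

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .structure_io import ResidueKey, Structure

__all__ = [
    "SurfaceClass", "SasaRecord", "atom_radius", "sphere_points",
    "shrake_rupley", "residue_sasa", "relative_sasa", "delta_sasa",
    "classify_surface", "DEFAULT_PROBE", "DEFAULT_N_POINTS",
]

DEFAULT_PROBE = 1.4     # water probe radius, angstrom
DEFAULT_N_POINTS = 960  # quadrature points per atom
DELTA_CLAMP = 1e-6      # quadrature-noise tolerance on negative dSASA

REL_SASA_SURFACE = 0.25    # surface-residue threshold (fraction)
DSASA_INTERFACE = 1.0      # interface threshold (angstrom^2)


def _load_radii() -> dict:
    with resources.files("chidist.data").joinpath("radii.json").open() as fh:
        return json.load(fh)


def _load_reference_max() -> dict[str, float]:
    table = {}
    path = resources.files("chidist.data").joinpath("rel_sasa_max.tsv")
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("res_type"):
                continue
            res_type, value = line.split("\t")
            table[res_type] = float(value)
    return table


_RADII = _load_radii()
_REF_MAX = _load_reference_max()


class SurfaceClass(str, Enum):
    INTERFACE = "interface"
    NON_INTERFACE = "non_interface_surface"
    EXCLUDED = "excluded"


@dataclass
class SasaRecord:
    residue_key: ResidueKey
    res_type: str
    abs_sasa: float
    rel_sasa: float | None = None


def atom_radius(name: str, element: str, res_type: str) -> float:
    """Van der Waals radius for a heavy atom, from the shipped radii table.

    Lookup order: backbone names, residue-specific sp2 carbons, element
    default.  Unknown atoms fall back to the element default with a warning.
    """
    name = name.strip().upper()
    element = element.strip().upper()
    backbone = _RADII["backbone"]
    if name in backbone:
        return backbone[name]
    if element == "C":
        if name in _RADII["sp2_carbons"].get(res_type, ()):
            return _RADII["sp2_carbon_radius"]
        return _RADII["element_default"]["C"]
    default = _RADII["element_default"].get(element)
    if default is not None:
        return default
    warnings.warn(f"unknown element {element!r} for atom {name!r}; "
                  f"using fallback radius {_RADII['fallback']} A")
    return _RADII["fallback"]


def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (golden spiral).

    Deterministic: the same ``n`` always yields the same point set.
    """
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k          # golden angle increments
    z = 1.0 - 2.0 * (k + 0.5) / n                   # uniform in z
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _structure_arrays(s: Structure) -> tuple[np.ndarray, np.ndarray, list]:
    coords, radii, owners = [], [], []
    for res in s.residues:
        for a in res.atoms:
            coords.append(a.coords)
            radii.append(atom_radius(a.name, a.element, res.res_type))
            owners.append(res.key)
    return np.asarray(coords, dtype=float), np.asarray(radii, dtype=float), owners


def _atom_orientation(coords: np.ndarray) -> np.ndarray:
    """Deterministic rotation matrix keyed on an atom's coordinates.

    Each atom gets its own orientation of the quadrature point set so that
    per-atom quadrature errors decorrelate and cancel in totals, instead of
    adding up coherently as they would with one shared orientation.  Keying
    on the coordinates (not the atom index) makes the point set of an atom
    identical in a complex and in its extracted monomer, which keeps
    SASA-loss-upon-binding exactly non-negative.
    """
    seed = zlib.crc32(np.ascontiguousarray(coords, dtype=np.float64).tobytes())
    q = np.random.default_rng(seed).normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def shrake_rupley(s: Structure, probe: float = DEFAULT_PROBE,
                  n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-atom SASA (A^2) in structure atom order.

    SASA of atom *i* = (accessible points / n_points) * 4 pi (r_i + probe)^2.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    coords, radii, _ = _structure_arrays(s)
    if coords.size == 0:
        raise ValueError("structure has no atoms")
    expanded = radii + probe
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    out = np.empty(len(coords))
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * (unit @ _atom_orientation(coords[i]).T)
        # any occluder's center lies within r_i + probe + max(r_j + probe)
        neighbors = tree.query_ball_point(coords[i], expanded[i] + expanded.max())
        neighbors = [j for j in neighbors if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > expanded[j] ** 2
            if not accessible.any():
                break
        out[i] = accessible.sum() / n_points * 4.0 * np.pi * expanded[i] ** 2
    return out


def residue_sasa(per_atom: np.ndarray, s: Structure) -> list[SasaRecord]:
    """Aggregate per-atom SASA to per-residue records (absolute only)."""
    _, _, owners = _structure_arrays(s)
    if len(per_atom) != len(owners):
        raise ValueError("per-atom SASA length does not match structure")
    totals: dict[ResidueKey, float] = {}
    types: dict[ResidueKey, str] = {}
    for res in s.residues:
        totals[res.key] = 0.0
        types[res.key] = res.res_type
    for value, key in zip(per_atom, owners):
        totals[key] += float(value)
    return [SasaRecord(k, types[k], v) for k, v in totals.items()]


def relative_sasa(abs_sasa: float, res_type: str,
                  reference: dict[str, float] | None = None) -> float:
    """Absolute residue SASA divided by the residue-type reference maximum.

    May exceed 1 for extended conformations.
    """
    table = reference if reference is not None else _REF_MAX
    if res_type not in table:
        raise KeyError(f"no reference maximum SASA for residue type {res_type!r}")
    return abs_sasa / table[res_type]


def delta_sasa(monomer_abs: float, complex_abs: float) -> float:
    """SASA lost upon binding; tiny negatives (quadrature noise) clamp to 0."""
    d = monomer_abs - complex_abs
    if -DELTA_CLAMP < d < 0.0:
        return 0.0
    return d


def classify_surface(rel_bound: float, rel_unbound: float | None,
                     dsasa: float,
                     surface_threshold: float = REL_SASA_SURFACE,
                     interface_threshold: float = DSASA_INTERFACE) -> SurfaceClass:
    """Classify one residue as interface / non-interface surface / excluded.

    ``rel_unbound`` is ``None`` when the protein has no unbound counterpart;
    the surface criterion then uses the bound state only.
    """
    surface = rel_bound >= surface_threshold and (
        rel_unbound is None or rel_unbound >= surface_threshold)
    if not surface:
        return SurfaceClass.EXCLUDED
    return (SurfaceClass.INTERFACE if dsasa > interface_threshold
            else SurfaceClass.NON_INTERFACE)
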