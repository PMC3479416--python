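"""Minimal PDB-format structure model.

Reads fixed-column ATOM records into a ``Structure`` of chains, residues
and heavy atoms — the carrier for all downstream solvent-accessibility and
torsion computation.  Deliberately small: no mmCIF, no symmetry expansion,
first MODEL only.

Parse rules (deterministic):

* only ``ATOM`` records; ``HETATM``, waters and hydrogens are dropped;
* alternate locations resolved per atom name to the highest-occupancy
  conformer, ties broken by file order;
* only the first ``MODEL`` block of multi-model files is read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "read_structure",
    "write_structure",
    "extract_monomer",
    "residue_sequence",
    "THREE_TO_ONE",
    "STANDARD_RESIDUES",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

STANDARD_RESIDUES = frozenset(THREE_TO_ONE)

#: residue key: (chain_id, seq_num, icode)
ResidueKey = tuple[str, int, str]


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # shape (3,), angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    res_type: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.seq_num, self.icode)

    @property
    def is_standard(self) -> bool:
        return self.res_type in STANDARD_RESIDUES

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    @property
    def residues(self) -> list[Residue]:
        return [r for chain in self.chains.values() for r in chain]

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def residue(self, key: ResidueKey) -> Residue | None:
        for r in self.chains.get(key[0], []):
            if r.key == key:
                return r
        return None


def _guess_element(name: str) -> str:
    # PDB v3 columns 77-78 carry the element; old files need the name heuristic
    stripped = name.strip()
    if stripped[:2] in ("CL", "BR", "FE", "ZN", "MG", "NA", "SE"):
        return stripped[:2]
    for ch in stripped:
        if ch.isalpha():
            return ch
    return stripped[:1]


def read_structure(pdb_text: str, chains: set[str] | None = None,
                   structure_id: str = "structure") -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Parameters
    ----------
    pdb_text : str
        PDB-format text with fixed-column ATOM records.
    chains : set of str, optional
        Chain identifiers to keep.  ``None`` keeps all chains.

    Raises
    ------
    ValueError
        If a requested chain is absent or the selection is empty.
    """
    wanted = set(chains) if chains is not None else None
    # (chain, seqnum, icode) -> Residue; per residue: atom name -> best Atom
    structure = Structure(id=structure_id)
    residues: dict[ResidueKey, Residue] = {}
    seen_chains: set[str] = set()
    in_first_model = True
    model_count = 0

    for line in pdb_text.splitlines():
        record = line[:6]
        if record == "MODEL ":
            model_count += 1
            in_first_model = model_count == 1
            continue
        if record == "ENDMDL":
            in_first_model = False
            continue
        if record != "ATOM  " or not in_first_model:
            continue
        name = line[12:16].strip()
        altloc = line[16].strip()
        res_type = line[17:20].strip()
        chain_id = line[21]
        seen_chains.add(chain_id)
        if wanted is not None and chain_id not in wanted:
            continue
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(name)
        element = element.upper()
        if element in ("H", "D"):
            continue
        seq_num = int(line[22:26])
        icode = line[26].strip()
        coords = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0

        key: ResidueKey = (chain_id, seq_num, icode)
        res = residues.get(key)
        if res is None:
            res = Residue(chain_id, seq_num, icode, res_type)
            residues[key] = res
        atom = Atom(name, element, np.array(coords), occupancy, altloc)
        existing = res.atom(name)
        if existing is None:
            res.atoms.append(atom)
        elif atom.occupancy > existing.occupancy:  # tie keeps first in file
            res.atoms[res.atoms.index(existing)] = atom

    if wanted is not None:
        missing = wanted - seen_chains
        if missing:
            raise ValueError(
                f"chain(s) {sorted(missing)} not found in PDB input "
                f"(available: {sorted(seen_chains)})")
    if not residues:
        raise ValueError("no amino-acid ATOM records selected")

    for key in residues:  # file order is preserved by dict insertion order
        structure.chains.setdefault(key[0], []).append(residues[key])
    return structure


def write_structure(s: Structure) -> str:
    """Serialize to PDB-format text (ATOM records only)."""
    lines = []
    serial = 1
    for chain_id, chain in s.chains.items():
        for res in chain:
            for a in res.atoms:
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name}{'':1s}{res.res_type:>3s} "
                    f"{chain_id}{res.seq_num:4d}{res.icode or ' '}   "
                    f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                    f"{a.occupancy:6.2f}{0.0:6.2f}          "
                    f"{a.element:>2s}")
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def extract_monomer(complex_structure: Structure, chains: set[str]) -> Structure:
    """Return a new Structure with exactly the given chains, coordinates unchanged."""
    if not chains:
        raise ValueError("empty chain set")
    missing = set(chains) - set(complex_structure.chains)
    if missing:
        raise ValueError(f"chain(s) {sorted(missing)} not in structure "
                         f"{complex_structure.id!r}")
    out = Structure(id=f"{complex_structure.id}:{''.join(sorted(chains))}")
    for cid, reslist in complex_structure.chains.items():
        if cid in chains:
            out.chains[cid] = reslist
    return out


def residue_sequence(s: Structure, chain: str) -> tuple[str, list[ResidueKey]]:
    """One-letter sequence of a chain plus the position -> residue-key map.

    Non-standard residue types are emitted as ``"X"``.
    """
    if chain not in s.chains:
        raise ValueError(f"chain {chain!r} not in structure {s.id!r}")
    seq = []
    index: list[ResidueKey] = []
    for res in s.chains[chain]:
        seq.append(THREE_TO_ONE.get(res.res_type, "X"))
        index.append(res.key)
    return "".join(seq), index
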