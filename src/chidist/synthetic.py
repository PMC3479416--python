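"""Synthetic inputs with the statistical structure of real side chains.

Real chi angles cluster into rotamers roughly 120 degrees apart, with a
tight intra-rotamer spread and, between a protein's bound and unbound
states, mostly small local readjustments plus rare rotamer-to-rotamer
flips.  This module emulates exactly that structure:

* :func:`sample_pool` draws chi vectors from a per-dimension three-rotamer
  mixture (wrapped-normal jitter around the rotamer centers; von Mises
  optional via ``kappa``);
* :func:`perturb_paired` derives a paired pool by re-drawing each sample's
  rotamer with probability ``flip_prob`` and always adding wrapped-normal
  jitter — the two perturbation modes of binding/crystal contacts;
* :func:`build_toy_residue` constructs single-residue coordinate models
  with prescribed chi angles by sequential internal-coordinate (NeRF)
  placement, for exercising the torsion and SASA machinery on files;
* :func:`synthetic_benchmark` writes bound/unbound angle tables for
  interface-like and non-interface-like pools so the whole comparison
  pipeline runs without any external structure download.

Nothing here aims at physically realistic rotamer frequencies or
backbone dependence; only the clustered-with-tails shape matters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .dihedrals import CHI_COUNT, chi_ranges
from .structure_io import Atom, Residue, Structure

__all__ = [
    "RotamerMixtureSpec", "PairedPoolSpec", "Pool", "sample_pool",
    "perturb_paired", "build_toy_residue", "build_toy_structure",
    "synthetic_benchmark", "FULL_RANGE_CENTERS", "FOLDED_CENTERS",
]

#: default rotamer centers: gauche-, gauche+, trans for full-range dims
FULL_RANGE_CENTERS = (-60.0, 60.0, 180.0)
#: range-interior centers for the folded [0, 180) dims
FOLDED_CENTERS = (30.0, 90.0, 150.0)


def _load_geometry() -> dict:
    path = resources.files("chidist.data").joinpath("ideal_geometry.json")
    with path.open() as fh:
        return json.load(fh)


_GEOM = _load_geometry()


def _wrap(angles: np.ndarray, start: float, width: float) -> np.ndarray:
    """Reduce angles into [start, start + width) on a circle of that width."""
    return start + np.mod(angles - start, width)


@dataclass
class RotamerMixtureSpec:
    """Three-rotamer von Mises / wrapped-normal mixture for one residue type.

    ``jitter_sd`` is the wrapped-normal standard deviation in degrees;
    setting ``kappa`` instead draws intra-rotamer deviations from a von
    Mises distribution with that concentration.
    """
    res_type: str
    centers: tuple[tuple[float, ...], ...] = ()  # per chi; default by range
    weights: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    jitter_sd: float = 10.0
    kappa: float | None = None

    def __post_init__(self) -> None:
        ranges = chi_ranges(self.res_type)
        if not self.centers:
            self.centers = tuple(
                FOLDED_CENTERS if (start, width) == (0.0, 180.0)
                else FULL_RANGE_CENTERS
                for start, width in ranges)
        if len(self.centers) != len(ranges):
            raise ValueError("one center tuple per chi dimension required")
        # normalize centers onto each dimension's circle (e.g. trans 180 -> -180)
        self.centers = tuple(
            tuple(float(start + np.mod(c - start, width)) for c in centers)
            for (start, width), centers in zip(ranges, self.centers))
        if not np.isclose(sum(self.weights), 1.0):
            raise ValueError("rotamer weights must sum to 1")


@dataclass
class PairedPoolSpec:
    """How a paired ("bound") pool is derived from a base ("unbound") pool."""
    base: RotamerMixtureSpec
    flip_prob: float = 0.0
    jitter_sd: float = 0.0
    n: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in [0, 1]")
        if self.n <= 0:
            raise ValueError("pool size n must be positive")


@dataclass
class Pool:
    """A pool of chi vectors plus the rotamer index each sample came from."""
    res_type: str
    angles: np.ndarray    # (n, dims), degrees, within the per-dim ranges
    rotamers: np.ndarray  # (n, dims), int index into the center tuples
    spec: RotamerMixtureSpec = field(repr=False, default=None)


def _jitter(shape, sd: float, kappa: float | None,
            rng: np.random.Generator) -> np.ndarray:
    if kappa is not None:
        return np.degrees(rng.vonmises(0.0, kappa, size=shape))
    return rng.normal(0.0, sd, size=shape)


def sample_pool(spec: RotamerMixtureSpec, n: int,
                rng: np.random.Generator) -> Pool:
    """Draw ``n`` chi vectors from the rotamer mixture."""
    if n <= 0:
        raise ValueError("n must be positive")
    ranges = chi_ranges(spec.res_type)
    dims = len(ranges)
    angles = np.empty((n, dims))
    rotamers = np.empty((n, dims), dtype=np.int64)
    for d, (start, width) in enumerate(ranges):
        centers = np.asarray(spec.centers[d])
        idx = rng.choice(len(centers), size=n, p=np.asarray(spec.weights))
        raw = centers[idx] + _jitter(n, spec.jitter_sd, spec.kappa, rng)
        angles[:, d] = _wrap(raw, start, width)
        rotamers[:, d] = idx
    return Pool(spec.res_type, angles, rotamers, spec)


def perturb_paired(pool: Pool, spec: PairedPoolSpec,
                   rng: np.random.Generator) -> Pool:
    """Derive the paired pool: rare rotamer flips plus always-on jitter.

    Per sample and chi dimension: with probability ``spec.flip_prob`` the
    rotamer index is re-drawn uniformly among the *other* rotamers and the
    angle resampled around the new center; wrapped-normal jitter of
    ``spec.jitter_sd`` degrees is then added to every angle.
    """
    base = pool.spec if pool.spec is not None else spec.base
    ranges = chi_ranges(pool.res_type)
    angles = pool.angles.copy()
    rotamers = pool.rotamers.copy()
    n, dims = angles.shape
    for d, (start, width) in enumerate(ranges):
        centers = np.asarray(base.centers[d])
        k = len(centers)
        flip = rng.random(n) < spec.flip_prob
        if flip.any() and k > 1:
            shift = rng.integers(1, k, size=int(flip.sum()))
            new_idx = (rotamers[flip, d] + shift) % k
            rotamers[flip, d] = new_idx
            angles[flip, d] = centers[new_idx] + _jitter(
                int(flip.sum()), base.jitter_sd, base.kappa, rng)
        if spec.jitter_sd > 0:
            angles[:, d] = angles[:, d] + rng.normal(0.0, spec.jitter_sd, n)
        angles[:, d] = _wrap(angles[:, d], start, width)
    return Pool(pool.res_type, angles, rotamers, base)


# ---------------------------------------------------------------------------
# toy coordinate models


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle: float, tors: float) -> np.ndarray:
    """Place atom d bonded to c with given internal coordinates.

    |cd| = bond, angle(b, c, d) = ``angle`` degrees, and the signed dihedral
    (a, b, c, d) equals ``tors`` degrees under this package's torsion sign
    convention.
    """
    ang = np.radians(angle)
    tor = np.radians(tors)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * np.cos(ang),
                        bond * np.sin(ang) * np.cos(tor),
                        bond * np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_toy_residue(res_type: str, chi_targets, chain_id: str = "A",
                      seq_num: int = 1,
                      origin=(0.0, 0.0, 0.0)) -> Structure:
    """Single-residue Structure with backbone and the chi-chain side atoms.

    Atoms are placed by sequential internal-coordinate construction with
    ideal bond lengths/angles and torsions set to ``chi_targets``, so
    :func:`chidist.dihedrals.residue_chi_vector` recovers the targets (the
    folded last chi of Phe/Tyr/Asp/Glu is recovered modulo 180).
    """
    if res_type not in CHI_COUNT:
        raise ValueError(f"unsupported residue type {res_type!r}")
    chi_targets = [float(c) for c in chi_targets]
    if len(chi_targets) != CHI_COUNT[res_type]:
        raise ValueError(f"{res_type} needs {CHI_COUNT[res_type]} chi targets")

    g = _GEOM["backbone"]
    origin = np.asarray(origin, dtype=float)
    n_pos = origin + np.zeros(3)
    ca = n_pos + np.array([g["N_CA"], 0.0, 0.0])
    # CB in the xy-plane at the ideal N-CA-CB angle
    theta = np.radians(g["N_CA_CB"])
    cb = ca + g["CA_CB"] * np.array([-np.cos(theta), np.sin(theta), 0.0])
    # carbonyl C on the other side of the N-CA axis; O off the C
    c = _nerf(cb, n_pos, ca, g["CA_C"], g["N_CA_C"], -122.0)
    o = _nerf(n_pos, ca, c, g["C_O"], g["CA_C_O"], 0.0)

    res = Residue(chain_id, seq_num, "", res_type)
    for name, pos in (("N", n_pos), ("CA", ca), ("C", c), ("O", o), ("CB", cb)):
        res.atoms.append(Atom(name, name[0], pos))

    chain = [n_pos, ca, cb]
    for (name, bond, angle), chi in zip(_GEOM["side_chains"][res_type],
                                        chi_targets):
        pos = _nerf(chain[-3], chain[-2], chain[-1], bond, angle, chi)
        res.atoms.append(Atom(name, name[0], pos))
        chain.append(pos)

    s = Structure(id=f"toy_{res_type}")
    s.chains[chain_id] = [res]
    return s


def build_toy_structure(entries) -> Structure:
    """Assemble several toy residues into one multi-chain Structure.

    ``entries``: iterable of ``(chain_id, seq_num, res_type, chi_targets,
    origin)``.  Residues are rigid copies placed at their origins; they are
    not covalently linked — sufficient for SASA and torsion exercises.
    """
    s = Structure(id="toy_structure")
    for chain_id, seq_num, res_type, chis, origin in entries:
        single = build_toy_residue(res_type, chis, chain_id, seq_num, origin)
        s.chains.setdefault(chain_id, []).extend(single.chains[chain_id])
    return s


# ---------------------------------------------------------------------------
# synthetic four-category benchmark


def synthetic_benchmark(config: dict, out_dir=None, rng=None):
    """Generate four-category angle pools emulating a bound/unbound study.

    ``config`` maps ``res_types`` to per-category paired-pool parameters::

        {"seed": 7,
         "res_types": {"MET": {
             "interface":     {"n": 2000, "flip_prob": 0.2,  "jitter_sd": 10.0},
             "non_interface": {"n": 2000, "flip_prob": 0.02, "jitter_sd": 10.0}}}}

    The "unbound" pool of each category is drawn from the rotamer mixture;
    the "bound" pool is its paired perturbation.  Returns the list of
    :class:`chidist.pipeline.ResidueRecord`; when ``out_dir`` is given, an
    angle table TSV and a small manifest are written there as well.
    """
    from .pipeline import ResidueRecord, write_angle_table

    seed = config.get("seed", 0)
    if rng is None:
        rng = np.random.default_rng(seed)
    records: list = []
    for res_type, categories in config["res_types"].items():
        for category, params in categories.items():
            n = int(params.get("n", 0))
            if n <= 0:
                raise ValueError(
                    f"synthetic pool size must be positive for "
                    f"{res_type}/{category}")
            base = RotamerMixtureSpec(
                res_type, jitter_sd=float(params.get("base_jitter_sd", 10.0)))
            paired = PairedPoolSpec(
                base=base, flip_prob=float(params.get("flip_prob", 0.0)),
                jitter_sd=float(params.get("jitter_sd", 0.0)), n=n)
            unbound = sample_pool(base, n, rng)
            bound = perturb_paired(unbound, paired, rng)
            surface_class = ("interface" if category == "interface"
                             else "non_interface_surface")
            for state, pool in (("unbound", unbound), ("bound", bound)):
                for i in range(n):
                    records.append(ResidueRecord(
                        case_id="synthetic", side="receptor", state=state,
                        chain_id="A", seq_num=i + 1, icode="",
                        res_type=res_type, surface_class=surface_class,
                        angles=tuple(float(a) for a in pool.angles[i])))
    if out_dir is not None:
        import pathlib

        import yaml
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_angle_table(records, out / "angles.tsv")
        manifest = {"kind": "synthetic_benchmark", "seed": seed,
                    "config": config, "angle_table": "angles.tsv"}
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
    return records
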