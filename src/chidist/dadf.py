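"""Dihedral-angle distribution functions (DADFs) on cubic grids.

A DADF is the discrete probability distribution of a residue type's chi
vector over an n-dimensional cubic grid laid on chi space.  The grid has a
single spacing for every dimension and a per-dimension *offset* (the split
origin): shifting the origin changes which samples share a cell, which is
why comparisons downstream average over many random origins.

Angles are periodic, so the grid wraps: a full-range dimension is a 360
degree circle, and the folded last chi of Phe/Tyr/Asp/Glu a 180 degree
circle.  When the spacing does not divide the range width (e.g. 70 into
360) the cell count is ceil(width / spacing) and the final, wrap-adjacent
cell is narrower — every sample is binned and the cell count stays
well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dihedrals import CHI_COUNT, DihedralVector, chi_ranges

__all__ = ["GridSpec", "DADF", "make_grid", "random_offsets", "cell_index",
           "build_dadf", "samples_to_array"]


@dataclass(frozen=True)
class GridSpec:
    spacing: float
    ranges: tuple[tuple[float, float], ...]  # per-dim (start, width)
    offsets: tuple[float, ...]               # per-dim, in [0, spacing)
    counts: tuple[int, ...]                  # per-dim cell count

    @property
    def dims(self) -> int:
        return len(self.ranges)

    @property
    def m(self) -> int:
        """Total number of grid cells."""
        return int(np.prod(self.counts))


def make_grid(spacing: float, res_type: str,
              offsets: tuple[float, ...] | None = None) -> GridSpec:
    """Grid over a residue type's chi space.

    Per-dimension cell count is ceil(range width / spacing); offsets default
    to zero.
    """
    if not 0.0 < spacing <= 360.0:
        raise ValueError(f"spacing must be in (0, 360], got {spacing}")
    ranges = tuple(chi_ranges(res_type))
    if offsets is None:
        offsets = (0.0,) * len(ranges)
    offsets = tuple(float(o) for o in offsets)
    if len(offsets) != len(ranges):
        raise ValueError("one offset per chi dimension required")
    if any(not 0.0 <= o < spacing for o in offsets):
        raise ValueError("offsets must lie in [0, spacing)")
    counts = tuple(int(np.ceil(width / spacing)) for _, width in ranges)
    return GridSpec(float(spacing), ranges, offsets, counts)


def random_offsets(spacing: float, dims: int, rng: np.random.Generator
                   ) -> tuple[float, ...]:
    """Independent uniform offsets on [0, spacing), one per dimension."""
    return tuple(float(x) for x in rng.uniform(0.0, spacing, size=dims))


def _dim_indices(angles: np.ndarray, g: GridSpec) -> np.ndarray:
    """Per-dimension cell indices, shape (n_samples, dims)."""
    idx = np.empty(angles.shape, dtype=np.int64)
    for d, ((start, width), offset, count) in enumerate(
            zip(g.ranges, g.offsets, g.counts)):
        rel = np.mod(angles[:, d] - start - offset, width)
        idx[:, d] = np.minimum((rel / g.spacing).astype(np.int64), count - 1)
    return idx


def _flatten(idx: np.ndarray, g: GridSpec) -> np.ndarray:
    """Row-major flattening, chi1 the slowest axis."""
    flat = np.zeros(idx.shape[0], dtype=np.int64)
    for d, count in enumerate(g.counts):
        flat = flat * count + idx[:, d]
    return flat


def cell_index(v: DihedralVector, g: GridSpec) -> int:
    """Flat grid-cell index of one chi vector; every angle maps to one cell."""
    if len(v.angles) != g.dims:
        raise ValueError(
            f"{v.res_type} vector has {len(v.angles)} angles, grid has "
            f"{g.dims} dimensions")
    angles = np.asarray(v.angles, dtype=float)[None, :]
    return int(_flatten(_dim_indices(angles, g), g)[0])


@dataclass
class DADF:
    """Probability vector over the grid cells, plus the sample count."""
    grid: GridSpec
    probs: np.ndarray
    n_samples: int

    def to_frame(self):
        """Tabular export: per cell, the multi-index, lower boundaries and
        probability."""
        import pandas as pd
        multi = np.array(np.unravel_index(np.arange(self.grid.m),
                                          self.grid.counts)).T
        data = {}
        for d in range(self.grid.dims):
            start, width = self.grid.ranges[d]
            lower = start + self.grid.offsets[d] + multi[:, d] * self.grid.spacing
            data[f"chi{d + 1}_cell"] = multi[:, d]
            # boundaries reduced into the range (wrap cell boundaries exceed it)
            data[f"chi{d + 1}_lower"] = start + np.mod(lower - start, width)
        data["prob"] = self.probs
        return pd.DataFrame(data)


def samples_to_array(samples) -> np.ndarray:
    """Accept a list of DihedralVector or an (n, dims) array of angles."""
    if isinstance(samples, np.ndarray):
        return np.atleast_2d(np.asarray(samples, dtype=float))
    arr = np.asarray([v.angles for v in samples], dtype=float)
    return np.atleast_2d(arr)


def build_dadf(samples, g: GridSpec) -> DADF:
    """Bin chi-vector samples on a grid and normalize to probabilities.

    Empty cells are retained at probability zero: similarity statistics sum
    over all m cells.
    """
    angles = samples_to_array(samples)
    if angles.size == 0:
        raise ValueError("cannot build a DADF from an empty sample list")
    if angles.shape[1] != g.dims:
        raise ValueError(f"samples have {angles.shape[1]} dimensions, "
                         f"grid has {g.dims}")
    flat = _flatten(_dim_indices(angles, g), g)
    counts = np.bincount(flat, minlength=g.m)
    n = angles.shape[0]
    return DADF(grid=g, probs=counts / n, n_samples=n)
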