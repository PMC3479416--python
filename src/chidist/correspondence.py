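"""Residue correspondence between bound and unbound chains.

A bound monomer and its separately crystallized unbound counterpart share
(nearly) the same sequence but not necessarily the same author numbering,
so interface/non-interface status assigned on the complex must be carried
to the unbound residues through a global sequence alignment.

The aligner is a plain Needleman-Wunsch with linear gap cost (match +1,
mismatch -1, gap -2) and deterministic traceback (diagonal preferred over
up over left).  At the >97% identity typical of bound/unbound pairs any
sensible scheme yields the same mapping; this one is the simplest that is
reproducible bit-for-bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structure_io import ResidueKey, Structure, residue_sequence

__all__ = ["ResidueCorrespondence", "align_global", "map_residues",
           "LowIdentityWarning"]

MATCH, MISMATCH, GAP = 1, -1, -2
IDENTITY_WARN = 0.97


class LowIdentityWarning(UserWarning):
    """Bound/unbound sequence identity below the expected 97%."""


@dataclass
class ResidueCorrespondence:
    pairs: list[tuple[ResidueKey, ResidueKey]]
    identity: float


def align_global(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global alignment of two sequences; returns the gapped string pair.

    Scoring: match +1, mismatch -1, gap -2 (linear).  Ties in the dynamic
    program are broken diagonal > up > left, making the traceback unique.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    na, nb = len(seq_a), len(seq_b)
    score = np.zeros((na + 1, nb + 1), dtype=np.int64)
    score[:, 0] = GAP * np.arange(na + 1)
    score[0, :] = GAP * np.arange(nb + 1)
    # 0 = diagonal, 1 = up (gap in b), 2 = left (gap in a)
    move = np.zeros((na + 1, nb + 1), dtype=np.int8)
    move[1:, 0] = 1
    move[0, 1:] = 2
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            diag = score[i - 1, j - 1] + (MATCH if seq_a[i - 1] == seq_b[j - 1]
                                          else MISMATCH)
            up = score[i - 1, j] + GAP
            left = score[i, j - 1] + GAP
            best = max(diag, up, left)
            score[i, j] = best
            move[i, j] = 0 if diag == best else (1 if up == best else 2)

    out_a, out_b = [], []
    i, j = na, nb
    while i > 0 or j > 0:
        m = move[i, j]
        if m == 0:
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i -= 1
            j -= 1
        elif m == 1:
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def alignment_score(aln_a: str, aln_b: str) -> int:
    """Score of an alignment under the module's scheme (test/oracle helper)."""
    s = 0
    for ca, cb in zip(aln_a, aln_b):
        if ca == "-" or cb == "-":
            s += GAP
        else:
            s += MATCH if ca == cb else MISMATCH
    return s


def map_residues(aln: tuple[str, str],
                 bound: Structure, bound_chain: str,
                 unbound: Structure, unbound_chain: str) -> ResidueCorrespondence:
    """Pair bound and unbound residues at aligned identical positions.

    Mismatched aligned positions are left unpaired: a substituted residue's
    side-chain dihedrals are not comparable between the two states.  Emits
    :class:`LowIdentityWarning` when identity over aligned (non-gap)
    positions drops below 0.97.
    """
    aln_a, aln_b = aln
    _, idx_a = residue_sequence(bound, bound_chain)
    _, idx_b = residue_sequence(unbound, unbound_chain)
    pairs: list[tuple[ResidueKey, ResidueKey]] = []
    i = j = 0
    n_aligned = n_identical = 0
    for ca, cb in zip(aln_a, aln_b):
        if ca != "-" and cb != "-":
            n_aligned += 1
            if ca == cb:
                n_identical += 1
                pairs.append((idx_a[i], idx_b[j]))
        if ca != "-":
            i += 1
        if cb != "-":
            j += 1
    identity = n_identical / n_aligned if n_aligned else 0.0
    if identity < IDENTITY_WARN:
        warnings.warn(
            f"bound/unbound sequence identity {identity:.3f} < {IDENTITY_WARN}"
            f" for chains {bound_chain}/{unbound_chain}",
            LowIdentityWarning, stacklevel=2)
    return ResidueCorrespondence(pairs=pairs, identity=identity)
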