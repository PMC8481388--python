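"""Helical secondary-structure assignment by the Kabsch–Sander method.

Backbone hydrogen bonds are scored with the standard electrostatic model

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)  kcal/mol
      = 27.888 * (...)

and a bond is recorded when E < -0.5 kcal/mol.  An n-turn (n in 3, 4, 5)
exists at residue i when the amide of residue i+n donates to the carbonyl of
residue i; two consecutive turns make residues i..i+n-1 helical.  Overlaps
resolve with priority alpha > 3/10 > pi, and the minimal segment lengths are
4 / 3 / 5 residues respectively.

Deposited structures mostly lack amide hydrogens, so
:func:`place_amide_hydrogens` builds them at 1.00 A from N along the
direction of the preceding residue's C=O bond (the common DSSP convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .structure import Atom, Residue, Structure

__all__ = [
    "HelixType",
    "HBond",
    "HelixSegment",
    "place_amide_hydrogens",
    "hbond_energy",
    "assign_helices",
    "HBOND_CUTOFF",
    "Q_CONSTANT",
]

Q_CONSTANT = 27.888      # kcal*A/mol, q1*q2*332 of the Kabsch-Sander model
HBOND_CUTOFF = -0.5      # kcal/mol
CHAIN_BREAK_DISTANCE = 2.5  # A between C(i) and N(i+1)
MIN_FITTABLE_LENGTH = 5  # residues needed for axis fitting downstream


class HelixType(Enum):
    ALPHA = 4      # value = n of the defining n-turn
    THREE_TEN = 3
    PI = 5

    @property
    def min_length(self) -> int:
        return {HelixType.ALPHA: 4, HelixType.THREE_TEN: 3, HelixType.PI: 5}[self]


@dataclass(frozen=True)
class HBond:
    donor_index: int      # residue index within the Structure (backbone N-H)
    acceptor_index: int   # residue index (backbone C=O)
    energy: float


@dataclass
class HelixSegment:
    chain_id: str
    start_index: int   # inclusive residue indices into Structure.residues
    end_index: int
    helix_type: HelixType
    calpha_coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __len__(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def fittable(self) -> bool:
        return len(self) >= MIN_FITTABLE_LENGTH


def _chain_runs(structure: Structure) -> list[list[int]]:
    """Indices of consecutive bonded residues (chain id + peptide-bond check)."""
    runs: list[list[int]] = []
    current: list[int] = []
    prev: Residue | None = None
    for i, res in enumerate(structure.residues):
        broken = True
        if prev is not None and prev.chain_id == res.chain_id:
            c, n = prev.get("C"), res.get("N")
            if c is not None and n is not None:
                broken = float(np.linalg.norm(c.coords - n.coords)) > CHAIN_BREAK_DISTANCE
        if broken and current:
            runs.append(current)
            current = []
        current.append(i)
        prev = res
    if current:
        runs.append(current)
    return runs


def place_amide_hydrogens(structure: Structure) -> Structure:
    """Return a copy with an amide H built on every backbone N that lacks one.

    H is placed 1.00 A from N along the unit vector C_prev - O_prev, i.e.
    anti-parallel to the preceding carbonyl.  Chain N-termini, prolines and
    residues with incomplete backbones are left untouched.
    """
    out = structure.copy()
    runs = _chain_runs(out)
    for run in runs:
        for prev_i, i in zip(run[:-1], run[1:]):
            res = out.residues[i]
            if res.aa_code == "PRO":
                continue
            if res.get("H") is not None:
                continue
            n = res.get("N")
            prev = out.residues[prev_i]
            c, o = prev.get("C"), prev.get("O")
            if n is None or c is None or o is None:
                continue
            direction = c.coords - o.coords
            norm = float(np.linalg.norm(direction))
            if norm == 0.0:
                continue
            h_pos = n.coords + direction / norm
            res.atoms.append(Atom(name="H", element="H", coords=h_pos))
    return out


def hbond_energy(donor: Residue, acceptor: Residue) -> float | None:
    """Kabsch-Sander electrostatic H-bond energy (kcal/mol).

    Donor contributes N-H, acceptor contributes C=O.  Returns None when any
    of the four atoms is missing (the pair is then excluded from bonding).
    """
    n, h = donor.get("N"), donor.get("H")
    c, o = acceptor.get("C"), acceptor.get("O")
    if n is None or h is None or c is None or o is None:
        return None
    r_on = float(np.linalg.norm(o.coords - n.coords))
    r_ch = float(np.linalg.norm(c.coords - h.coords))
    r_oh = float(np.linalg.norm(o.coords - h.coords))
    r_cn = float(np.linalg.norm(c.coords - n.coords))
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9  # atoms essentially on top of each other: clamp like DSSP
    e = Q_CONSTANT * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return max(e, -9.9)


def backbone_hbonds(structure: Structure,
                    hbond_cutoff: float = HBOND_CUTOFF) -> list[HBond]:
    """All recorded i+n -> i backbone H-bonds for n in 3, 4, 5 (within runs)."""
    bonds: list[HBond] = []
    for run in _chain_runs(structure):
        for pos, i in enumerate(run):
            for n_turn in (3, 4, 5):
                if pos + n_turn >= len(run):
                    continue
                j = run[pos + n_turn]
                e = hbond_energy(structure.residues[j], structure.residues[i])
                if e is not None and e < hbond_cutoff:
                    bonds.append(HBond(donor_index=j, acceptor_index=i, energy=e))
    return bonds


def assign_helices(structure: Structure,
                   hbond_cutoff: float = HBOND_CUTOFF,
                   include_types: tuple[HelixType, ...] = (
                       HelixType.ALPHA, HelixType.THREE_TEN, HelixType.PI),
                   ) -> list[HelixSegment]:
    """Assign helical segments with the Kabsch-Sander turn bookkeeping.

    Requires amide hydrogens (see :func:`place_amide_hydrogens`); residues
    without an H simply form no bonds.  Chain breaks terminate segments.
    """
    n_res = len(structure.residues)
    bonds = backbone_hbonds(structure, hbond_cutoff)
    turn: dict[int, set[int]] = {3: set(), 4: set(), 5: set()}
    for b in bonds:
        n_turn = b.donor_index - b.acceptor_index
        if n_turn in turn:
            turn[n_turn].add(b.acceptor_index)

    # per-residue state with priority alpha(4) > 3/10(3) > pi(5)
    state = [None] * n_res
    for n_turn in (4, 3, 5):
        htype = {4: HelixType.ALPHA, 3: HelixType.THREE_TEN, 5: HelixType.PI}[n_turn]
        for i in turn[n_turn]:
            if i - 1 in turn[n_turn]:  # two consecutive n-turns at i-1 and i
                for k in range(i, i + n_turn):
                    if state[k] is None:
                        state[k] = htype

    segments: list[HelixSegment] = []
    for run in _chain_runs(structure):
        start = None
        current: HelixType | None = None
        for pos, i in enumerate(run + [None]):  # sentinel flushes last segment
            s = state[i] if i is not None else None
            if s is not current or i is None:
                if current is not None and current in include_types:
                    seg_start, seg_end = start, run[pos - 1]
                    length = seg_end - seg_start + 1
                    if length >= current.min_length:
                        ca = np.array([structure.residues[k]["CA"].coords
                                       for k in range(seg_start, seg_end + 1)])
                        segments.append(HelixSegment(
                            chain_id=structure.residues[seg_start].chain_id,
                            start_index=seg_start, end_index=seg_end,
                            helix_type=current, calpha_coords=ca))
                start, current = i, s
    segments.sort(key=lambda s: s.start_index)
    return segments
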