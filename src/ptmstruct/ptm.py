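"""In-silico mounting of PTM moieties onto protein structures.

Supported moieties and their monoisotopic mass shifts:

    acetyl-lysine (acK)        +42.0106 Da  (C2H2O on NZ, planar sp2 amide)
    phospho-Ser/Thr/Tyr        +79.9663 Da  (HPO3 on OG/OG1/OH, tetrahedral)
    Gly-Gly remnant on lysine +114.0429 Da  (C4H6N2O2, the tryptic stub of
                                             ubiquitination, condensed on NZ)

Moieties are built heavy-atoms-only from idealised internal coordinates; the
rotatable dihedral anchoring the moiety to the side chain is chosen by a
30-degree grid scan that maximises the minimum distance to all non-target
heavy atoms (a purely steric criterion — no force field, no relaxation of
the surrounding structure).  Mounting never moves an existing atom and is
deterministic for a given input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from ._zmatrix import place_atom
from .structure import Atom, Residue, Structure

__all__ = [
    "PTMKind",
    "PTMSpec",
    "MountResult",
    "mount_ptm",
    "clash_report",
    "moiety_formula_mass",
]

# monoisotopic atomic masses (Da)
_MASS = {"H": 1.0078250319, "C": 12.0, "N": 14.0030740052,
         "O": 15.9949146221, "P": 30.97376151}

CLASH_FLOOR = 1.5  # A: hard lower bound on moiety/structure heavy contacts
GRID_STEP = 30.0   # degrees


class PTMKind(Enum):
    ACETYL_K = "acetyl-K"
    PHOSPHO_S = "phospho-S"
    PHOSPHO_T = "phospho-T"
    PHOSPHO_Y = "phospho-Y"
    GG_K = "gg-K"


# kind -> (target aa, anchor atom, anchor neighbour, dihedral reference,
#          formula {element: count}, nominal mass shift)
_DEFS = {
    PTMKind.ACETYL_K: ("LYS", "NZ", "CE", "CD",
                       {"C": 2, "H": 2, "O": 1}, 42.0106),
    PTMKind.PHOSPHO_S: ("SER", "OG", "CB", "CA",
                        {"H": 1, "P": 1, "O": 3}, 79.9663),
    PTMKind.PHOSPHO_T: ("THR", "OG1", "CB", "CA",
                        {"H": 1, "P": 1, "O": 3}, 79.9663),
    PTMKind.PHOSPHO_Y: ("TYR", "OH", "CZ", "CE1",
                        {"H": 1, "P": 1, "O": 3}, 79.9663),
    PTMKind.GG_K: ("LYS", "NZ", "CE", "CD",
                   {"C": 4, "H": 6, "N": 2, "O": 2}, 114.0429),
}


def moiety_formula_mass(kind: PTMKind) -> float:
    """Monoisotopic mass of the moiety formula (built atoms + implicit H)."""
    formula = _DEFS[kind][4]
    return sum(_MASS[el] * n for el, n in formula.items())


@dataclass
class PTMSpec:
    kind: PTMKind
    target: tuple[str, int, str] | tuple[str, int]  # (chain, seq_id[, icode])

    def __post_init__(self) -> None:
        if len(self.target) == 2:
            self.target = (self.target[0], self.target[1], "")

    @property
    def mass_shift(self) -> float:
        return _DEFS[self.kind][5]


@dataclass
class MountResult:
    structure: Structure
    added_atoms: list[Atom]
    chosen_dihedral: float
    min_clash_distance: float
    spec: PTMSpec | None = field(default=None, repr=False)


def _build_moiety(kind: PTMKind, ref: np.ndarray, nbr: np.ndarray,
                  anchor: np.ndarray, tau: float) -> list[tuple[str, str, np.ndarray]]:
    """(name, element, coords) of the moiety heavy atoms at scan dihedral tau."""
    out: list[tuple[str, str, np.ndarray]] = []
    if kind is PTMKind.ACETYL_K:
        c1 = place_atom(ref, nbr, anchor, 1.33, 120.0, tau)
        o1 = place_atom(nbr, anchor, c1, 1.23, 121.0, 0.0)
        ch3 = place_atom(nbr, anchor, c1, 1.50, 116.0, 180.0)
        out = [("CX", "C", c1), ("OX", "O", o1), ("CME", "C", ch3)]
    elif kind in (PTMKind.PHOSPHO_S, PTMKind.PHOSPHO_T, PTMKind.PHOSPHO_Y):
        p = place_atom(ref, nbr, anchor, 1.61, 119.0, tau)
        oxy = [place_atom(nbr, anchor, p, 1.52, 109.47, t)
               for t in (60.0, 180.0, -60.0)]
        out = [("P", "P", p)] + [(f"O{i}P", "O", o) for i, o in enumerate(oxy, 1)]
    elif kind is PTMKind.GG_K:
        # proximal glycine (amide-bonded to NZ), then distal glycine
        c1 = place_atom(ref, nbr, anchor, 1.33, 120.0, tau)
        o1 = place_atom(nbr, anchor, c1, 1.23, 121.0, 180.0)
        ca1 = place_atom(nbr, anchor, c1, 1.52, 116.0, 0.0)
        n1 = place_atom(anchor, c1, ca1, 1.46, 110.0, 180.0)
        c2 = place_atom(c1, ca1, n1, 1.33, 121.0, 180.0)
        o2 = place_atom(ca1, n1, c2, 1.23, 123.0, 0.0)
        ca2 = place_atom(ca1, n1, c2, 1.52, 116.0, 180.0)
        n2 = place_atom(n1, c2, ca2, 1.46, 110.0, 180.0)
        out = [("CQ1", "C", c1), ("OQ1", "O", o1), ("CQA", "C", ca1),
               ("NQ1", "N", n1), ("CQ2", "C", c2), ("OQ2", "O", o2),
               ("CQB", "C", ca2), ("NQ2", "N", n2)]
    else:  # pragma: no cover
        raise ValueError(f"unsupported PTM kind {kind}")
    return out


def _min_distance(moiety: list[tuple[str, str, np.ndarray]],
                  other_coords: np.ndarray) -> float:
    if len(other_coords) == 0:
        return math.inf
    pts = np.array([c for _, _, c in moiety])
    diff = pts[:, None, :] - other_coords[None, :, :]
    return float(np.sqrt(np.einsum("ijk,ijk->ij", diff, diff).min()))


def mount_ptm(structure: Structure, spec: PTMSpec) -> MountResult:
    """Mount the moiety of *spec* on its target residue (pure function).

    Raises on a missing anchor atom, an incompatible residue type, or when
    every scanned rotamer clashes below the 1.5 A hard floor.
    """
    target_aa, anchor_name, nbr_name, ref_name, _, _ = _DEFS[spec.kind]
    res = structure.find(*spec.target)
    if res.aa_code != target_aa:
        raise ValueError(f"{spec.kind.value} requires {target_aa}, "
                         f"target {res.chain_id}:{res.seq_id} is {res.aa_code}")
    try:
        anchor = res[anchor_name].coords
        nbr = res[nbr_name].coords
        ref = res[ref_name].coords
    except KeyError as exc:
        raise ValueError(f"target residue lacks anchor atom: {exc}") from exc

    other = np.array([a.coords for r, a in structure.iter_atoms()
                      if a.is_heavy and r.key != res.key])

    best_tau, best_min, best_moiety = None, -math.inf, None
    for tau in np.arange(0.0, 360.0, GRID_STEP):
        moiety = _build_moiety(spec.kind, ref, nbr, anchor, float(tau))
        dmin = _min_distance(moiety, other)
        if dmin > best_min:  # strict: ties keep the first (lowest tau)
            best_tau, best_min, best_moiety = float(tau), dmin, moiety
    assert best_moiety is not None
    if best_min < CLASH_FLOOR:
        raise ValueError(
            f"all rotamers clash: best minimum heavy-atom distance "
            f"{best_min:.2f} A at dihedral {best_tau:.0f} deg is below the "
            f"{CLASH_FLOOR} A floor")

    out = structure.copy()
    out_res = out.find(*res.key)
    added = [Atom(name=n, element=el, coords=c, het=True)
             for n, el, c in best_moiety]
    out_res.atoms.extend(added)
    return MountResult(structure=out, added_atoms=added,
                       chosen_dihedral=best_tau, min_clash_distance=best_min,
                       spec=spec)


def clash_report(result: MountResult, structure: Structure
                 ) -> tuple[float, tuple[str, str] | None]:
    """Minimum heavy-atom distance between the moiety and non-target atoms.

    Returns ``(math.inf, None)`` when the structure has no non-target atoms.
    """
    spec = result.spec
    target_key = result.structure.find(*spec.target).key if spec else None
    others = [(f"{r.chain_id}:{r.seq_id}:{a.name}", a.coords)
              for r, a in structure.iter_atoms()
              if a.is_heavy and (target_key is None or r.key != target_key)]
    if not others:
        return math.inf, None
    best = (math.inf, None)
    other_coords = np.array([c for _, c in others])
    for m in result.added_atoms:
        d = np.linalg.norm(other_coords - m.coords, axis=1)
        j = int(np.argmin(d))
        if d[j] < best[0]:
            best = (float(d[j]), (m.name, others[j][0]))
    return best
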