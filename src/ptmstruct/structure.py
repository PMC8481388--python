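"""Protein structures and multi-frame coordinate sets in PDB format.

The data model is deliberately small: atoms with coordinates and element,
residues keyed by author numbering, structures as ordered residue lists, and
trajectories as lists of structures sharing one topology.  All coordinates
are in Angstroms; author residue numbering is preserved verbatim.

Parsing goes through :mod:`gemmi`; writing is a fixed-column PDB formatter so
that multi-MODEL trajectories and moiety HETATM records round-trip exactly.
Waters and non-polypeptide heteroatoms are discarded on read — the geometric
and surface-area analyses downstream operate on the polypeptide only.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Trajectory",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "STANDARD_AA",
]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_WATER = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    het: bool = False  # written as HETATM (mounted moiety atoms)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    aa_code: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.insertion_code)

    def get(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __getitem__(self, name: str) -> Atom:
        a = self.get(name)
        if a is None:
            raise KeyError(f"no atom {name!r} in {self.chain_id}{self.seq_id}{self.aa_code}")
        return a

    @property
    def has_backbone(self) -> bool:
        return all(self.get(n) is not None for n in ("N", "CA", "C", "O"))

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for a in self.atoms if a.is_heavy]
        return np.array(pts) if pts else np.empty((0, 3))


@dataclass
class Structure:
    residues: list[Residue] = field(default_factory=list)
    model_id: int = 1
    source_path: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, int, str]] = set()
        for r in self.residues:
            if r.key in seen:
                raise ValueError(f"duplicate residue {r.key}")
            seen.add(r.key)

    def __len__(self) -> int:
        return len(self.residues)

    def iter_atoms(self):
        for r in self.residues:
            for a in r.atoms:
                yield r, a

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def chains(self) -> dict[str, list[Residue]]:
        out: dict[str, list[Residue]] = {}
        for r in self.residues:
            out.setdefault(r.chain_id, []).append(r)
        return out

    def find(self, chain_id: str, seq_id: int, insertion_code: str = "") -> Residue:
        for r in self.residues:
            if r.key == (chain_id, seq_id, insertion_code):
                return r
        raise KeyError(f"residue {chain_id}:{seq_id}{insertion_code} not found")

    def index_of(self, residue: Residue) -> int:
        for i, r in enumerate(self.residues):
            if r.key == residue.key:
                return i
        raise KeyError(f"residue {residue.key} not in structure")

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for _, a in self.iter_atoms() if a.is_heavy]
        return np.array(pts) if pts else np.empty((0, 3))

    def copy(self) -> "Structure":
        return copy.deepcopy(self)

    def atom_identity(self) -> list[tuple[str, int, str, str]]:
        """(chain, seq_id, icode+aa, atom name) for every atom, in order."""
        return [(r.chain_id, r.seq_id, r.insertion_code + r.aa_code, a.name)
                for r, a in self.iter_atoms()]


@dataclass
class Trajectory:
    frames: list[Structure]
    frame_interval: float = 0.005  # ns

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        ref = self.frames[0].atom_identity()
        for i, f in enumerate(self.frames[1:], start=2):
            if f.atom_identity() != ref:
                raise ValueError(f"frame {i} does not share atom identity with frame 1")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        return (len(self.frames) - 1) * self.frame_interval


def _convert_model(model: gemmi.Model, model_id: int, source: str,
                   altloc_policy: str) -> Structure:
    if altloc_policy not in ("highest_occupancy", "first"):
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    residues: list[Residue] = []
    for chain in model:
        for res in chain:
            rname = res.name.strip()
            if rname in _WATER:
                continue
            if rname not in STANDARD_AA:
                # non-polypeptide heteroatoms (ligands, ions) are out of scope
                continue
            atoms: list[Atom] = []
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = by_name.get(at.name)
                if prev is None:
                    by_name[at.name] = at
                elif altloc_policy == "highest_occupancy" and at.occ > prev.occ:
                    by_name[at.name] = at  # ties keep the first listed
            for at in by_name.values():
                atoms.append(Atom(
                    name=at.name,
                    element=at.element.name if at.element.name else at.name[0],
                    coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    occupancy=at.occ,
                    het=res.het_flag == "H",
                ))
            seqid = res.seqid
            residues.append(Residue(
                chain_id=chain.name,
                seq_id=seqid.num,
                insertion_code=(seqid.icode or " ").strip(),
                aa_code=rname,
                atoms=atoms,
            ))
    return Structure(residues=residues, model_id=model_id, source_path=source)


def _read_gemmi(path: str | Path) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"malformed PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no ATOM records / models found")
    return st


def read_structure(path: str | Path, model_index: int = 0,
                   altloc_policy: str = "highest_occupancy") -> Structure:
    """Read one MODEL of a PDB file.

    Alt-locs are resolved per *altloc_policy* (default: highest occupancy,
    ties keep the first listed); waters and non-polypeptide HETATM are
    discarded; hydrogens are retained if present.
    """
    st = _read_gemmi(path)
    if not 0 <= model_index < len(st):
        raise IndexError(f"model_index {model_index} out of range (file has {len(st)} models)")
    structure = _convert_model(st[model_index], model_index + 1, str(path), altloc_policy)
    if len(structure) == 0:
        raise ValueError(f"{path}: model {model_index} contains no polypeptide residues")
    return structure


def read_trajectory(path: str | Path, frame_interval: float = 0.005) -> Trajectory:
    """Read a multi-MODEL PDB file as a trajectory (one Structure per MODEL)."""
    st = _read_gemmi(path)
    frames = [_convert_model(st[i], i + 1, str(path), "highest_occupancy")
              for i in range(len(st))]
    ref = frames[0].atom_identity()
    for i, f in enumerate(frames[1:], start=2):
        if f.atom_identity() != ref:
            raise ValueError(f"{path}: frame {i} atom set inconsistent with frame 1 "
                             "(corrupt trajectory)")
    return Trajectory(frames=frames, frame_interval=frame_interval)


def _format_atom_line(serial: int, atom: Atom, res: Residue) -> str:
    record = "HETATM" if atom.het else "ATOM"
    name = atom.name
    # PDB convention: 1-char element names start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    x, y, z = atom.coords
    return (f"{record:<6}{serial:>5} {name:<4} {res.aa_code:<3}{res.chain_id:>2}"
            f"{res.seq_id:>4}{res.insertion_code or ' ':1}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2}")


def _model_lines(structure: Structure, serial_start: int = 1) -> list[str]:
    lines = []
    serial = serial_start
    chains = structure.chains()
    for chain_id, residues in chains.items():
        for res in residues:
            for atom in res.atoms:
                lines.append(_format_atom_line(serial, atom, res))
                serial = min(serial + 1, 99999)
        last = residues[-1]
        lines.append(f"TER   {serial:>5}      {last.aa_code:<3}{chain_id:>2}{last.seq_id:>4}")
        serial = min(serial + 1, 99999)
    return lines


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write standard fixed-column PDB ATOM/HETATM records (single model)."""
    if len(structure) == 0:
        raise ValueError("refusing to write an empty structure")
    lines = _model_lines(structure)
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-MODEL PDB file."""
    lines: list[str] = []
    for i, frame in enumerate(trajectory.frames, start=1):
        lines.append(f"MODEL     {i:>4}")
        lines.extend(_model_lines(frame))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
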