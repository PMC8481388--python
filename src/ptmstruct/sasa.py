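"""Solvent-accessible surface area (Shrake–Rupley) and active-environment deltas.

Per-atom accessible area is estimated by rolling a probe sphere (default
1.4 A) over the van der Waals surface: each heavy atom is covered with a
deterministic golden-spiral lattice of test points on its expanded sphere of
radius r_vdw + probe, and the accessible fraction is the share of points not
buried inside any neighbouring expanded sphere.  Hydrogens are ignored.

The "active environment" of a modified residue is the set of residues with
any heavy atom within a cutoff (default 6 A) of the residue's heavy atoms,
frozen on the intact structure so that intact/modified sums compare identical
residue sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure import Residue, Structure

__all__ = [
    "VDW_RADII",
    "SasaResult",
    "ActiveEnvironment",
    "SASAReport",
    "sphere_points",
    "compute_sasa",
    "active_environment",
    "sasa_delta_report",
    "environment_decrease_count",
]

VDW_RADII = {"C": 1.76, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.90}
DEFAULT_RADIUS = 1.70
DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960

ResKey = tuple[str, int, str]


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of *n* points on the unit sphere."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = phi * k
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SasaResult:
    per_atom_area: dict[tuple[ResKey, str], float]
    probe_radius: float
    n_points: int
    radii_table_id: str = "ptmstruct-default"

    def residue_area(self, key: ResKey) -> float:
        return sum(a for (rk, _), a in self.per_atom_area.items() if rk == key)

    @property
    def total(self) -> float:
        return sum(self.per_atom_area.values())


@dataclass
class ActiveEnvironment:
    center: ResKey
    members: set[ResKey]
    cutoff: float

    def __post_init__(self) -> None:
        self.members.discard(self.center)


@dataclass
class SASAReport:
    residue_intact: float
    residue_modified: float
    environment_intact: float   # includes the centre residue's own area
    environment_modified: float
    environment: ActiveEnvironment | None = None
    parameters: dict = field(default_factory=dict)

    @property
    def residue_delta(self) -> float:
        return self.residue_modified - self.residue_intact

    @property
    def environment_delta(self) -> float:
        return self.environment_modified - self.environment_intact

    def to_dict(self) -> dict:
        return {
            "residue": None if self.environment is None else list(self.environment.center),
            "areas": {
                "residue_intact": self.residue_intact,
                "residue_modified": self.residue_modified,
                "environment_intact": self.environment_intact,
                "environment_modified": self.environment_modified,
            },
            "deltas": {
                "residue": self.residue_delta,
                "environment": self.environment_delta,
            },
            "environment_members": (
                sorted(list(k) for k in self.environment.members)
                if self.environment is not None else []),
            "parameters": self.parameters,
        }


def _heavy_atoms(structure: Structure):
    keys, names, coords, radii = [], [], [], []
    for res, atom in structure.iter_atoms():
        if not atom.is_heavy:
            continue
        el = atom.element.upper()
        r = VDW_RADII.get(el)
        if r is None:
            warnings.warn(f"unknown element {el!r}; using default vdW radius "
                          f"{DEFAULT_RADIUS} A", stacklevel=3)
            r = DEFAULT_RADIUS
        keys.append(res.key)
        names.append(atom.name)
        coords.append(atom.coords)
        radii.append(r)
    return keys, names, np.asarray(coords, dtype=float), np.asarray(radii, dtype=float)


def compute_sasa(structure: Structure, probe_radius: float = DEFAULT_PROBE,
                 n_points: int = DEFAULT_N_POINTS) -> SasaResult:
    """Shrake-Rupley accessible area per heavy atom (A^2), deterministic."""
    keys, names, coords, radii = _heavy_atoms(structure)
    if len(coords) == 0:
        raise ValueError("structure has no heavy atoms")
    expanded = radii + probe_radius
    unit = sphere_points(n_points)
    tree = cKDTree(coords)
    max_r = expanded.max()
    per_atom: dict[tuple[ResKey, str], float] = {}
    for i in range(len(coords)):
        pts = coords[i] + expanded[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], expanded[i] + max_r):
            if j == i:
                continue
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 >= expanded[j] ** 2
        area = 4.0 * np.pi * expanded[i] ** 2 * accessible.sum() / n_points
        per_atom[(keys[i], names[i])] = float(area)
    return SasaResult(per_atom_area=per_atom, probe_radius=probe_radius,
                      n_points=n_points)


def active_environment(structure: Structure, residue: Residue | ResKey,
                       cutoff: float = 6.0) -> ActiveEnvironment:
    """Residues with any heavy atom within *cutoff* of the centre's heavy atoms."""
    if isinstance(residue, tuple):
        residue = structure.find(*residue)
    else:
        residue = structure.find(*residue.key)  # validate membership
    center_pts = residue.heavy_coords()
    members: set[ResKey] = set()
    if cutoff > 0 and len(center_pts):
        tree = cKDTree(center_pts)
        for other in structure.residues:
            if other.key == residue.key:
                continue
            pts = other.heavy_coords()
            if len(pts) and np.any(tree.query(pts, k=1)[0] <= cutoff):
                members.add(other.key)
    return ActiveEnvironment(center=residue.key, members=members, cutoff=cutoff)


def _verify_moiety_diff(intact: Structure, modified: Structure,
                        center: ResKey) -> None:
    a = intact.atom_identity()
    b = modified.atom_identity()
    extra = [t for t in b if t not in set(a)]
    missing = [t for t in a if t not in set(b)]
    if missing:
        raise ValueError(f"modified structure lost atoms present in intact: {missing[:5]}")
    off_target = [t for t in extra if (t[0], t[1]) != (center[0], center[1])]
    if off_target:
        raise ValueError("structures differ beyond the mounted moiety "
                         f"(extra atoms off target: {off_target[:5]})")


def sasa_delta_report(intact: Structure, modified: Structure,
                      residue: Residue | ResKey,
                      env: ActiveEnvironment | None = None,
                      probe_radius: float = DEFAULT_PROBE,
                      n_points: int = DEFAULT_N_POINTS,
                      cutoff: float = 6.0) -> SASAReport:
    """Compare residue and active-environment SASA before and after mounting.

    The environment member set is determined on the intact structure (or
    passed in) and reused for the modified one; environment sums include the
    centre residue, and moiety atoms are attributed to the modified residue.
    """
    key = residue if isinstance(residue, tuple) else residue.key
    intact.find(*key)
    _verify_moiety_diff(intact, modified, key)
    if env is None:
        env = active_environment(intact, key, cutoff)
    sasa_i = compute_sasa(intact, probe_radius, n_points)
    sasa_m = compute_sasa(modified, probe_radius, n_points)
    env_keys = env.members | {key}
    return SASAReport(
        residue_intact=sasa_i.residue_area(key),
        residue_modified=sasa_m.residue_area(key),
        environment_intact=sum(sasa_i.residue_area(k) for k in env_keys),
        environment_modified=sum(sasa_m.residue_area(k) for k in env_keys),
        environment=env,
        parameters={"probe_radius": probe_radius, "n_points": n_points,
                    "cutoff": env.cutoff},
    )


def environment_decrease_count(table: pd.DataFrame) -> int:
    """Distinct peptides whose active-environment SASA decreases on modification.

    Expects the packaged per-peptide SASA table with columns ``peptide``,
    ``env_intact`` and ``env_ptm``.
    """
    delta = table["env_ptm"] - table["env_intact"]
    return int(table.loc[delta < 0, "peptide"].nunique())
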