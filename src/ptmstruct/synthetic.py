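"""Generators for every input the pipeline consumes, plus packaged fixtures.

The generators emulate the study conditions end to end: ideal and perturbed
alpha-helices with exactly known axes, helical pairs built to a prescribed
pair geometry (plane distance, torsion, crossing point), jittered and
drifting multi-frame trajectories, and cohort identification tables with
planted group-specific PTMs and rule-violating decoys.  Every generator is
deterministic under its seed, and each returns the ground truth it was built
from so that analysis results can be checked for parameter recovery.

Packaged fixtures transcribe a reference study's tables (peptide lists
and per-peptide solvent-accessibility quadruples) and ship two reference
structures written by these same generators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from ._zmatrix import place_atom
from .geometry import HelixAxis, PairGeometry, _segment_distance, projection_intersection
from .structure import Atom, Residue, Structure, Trajectory

__all__ = [
    "HelixParams",
    "PairParams",
    "PairResult",
    "PlantedPTM",
    "CohortDesign",
    "make_ideal_helix",
    "make_helix_pair",
    "make_trajectory",
    "make_identification_table",
    "make_intensity_table",
    "default_cohort_design",
    "reference_cohort_design",
    "load_fixture",
]

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


@dataclass
class HelixParams:
    n_res: int = 20
    radius: float = 2.3        # C-alpha cylinder radius, A (CA_ONLY mode)
    rise: float = 1.5          # A per residue (CA_ONLY mode)
    twist: float = 100.0       # degrees per residue (CA_ONLY mode)
    phase: float = 0.0         # degrees
    backbone: str = "CA_ONLY"  # or "FULL_BACKBONE"
    sequence: str | None = None  # one-letter codes; default poly-Ala
    axis_anchor: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    chain_id: str = "A"
    start_seq_id: int = 1

    def __post_init__(self) -> None:
        if self.n_res < 4:
            raise ValueError("n_res must be >= 4")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.sequence is not None and len(self.sequence) != self.n_res:
            raise ValueError("sequence length must equal n_res")


def _rigid_to_axis(coords: np.ndarray, local_dir: np.ndarray,
                   local_origin: np.ndarray, params: HelixParams) -> np.ndarray:
    target_dir = np.asarray(params.axis_direction, float)
    target_dir = target_dir / np.linalg.norm(target_dir)
    rot, _ = Rotation.align_vectors([target_dir], [local_dir])
    return rot.apply(coords - local_origin) + np.asarray(params.axis_anchor, float)


def _backbone_nerf(n_res: int, phi: float = -57.0, psi: float = -47.0,
                   omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Ideal-internal-coordinate backbone chain (N, CA, C, O per residue)."""
    res: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([1.46, 0.0, 0.0])
    c = place_atom(np.array([0.0, 1.0, 0.0]), n, ca, 1.52, 111.0, 0.0)
    res.append({"N": n, "CA": ca, "C": c})
    for _ in range(1, n_res):
        n_next = place_atom(res[-1]["N"], res[-1]["CA"], res[-1]["C"],
                            1.33, 116.2, psi)
        res[-1]["O"] = place_atom(n_next, res[-1]["CA"], res[-1]["C"],
                                  1.23, 120.8, 180.0)
        ca_next = place_atom(res[-1]["CA"], res[-1]["C"], n_next, 1.46, 121.7, omega)
        c_next = place_atom(res[-1]["C"], n_next, ca_next, 1.52, 111.0, phi)
        res.append({"N": n_next, "CA": ca_next, "C": c_next})
    res[-1]["O"] = place_atom(res[-1]["N"], res[-1]["CA"], res[-1]["C"],
                              1.23, 120.8, psi + 180.0)
    return res


_SIDE_CHAINS: dict[str, list[tuple[str, str, tuple[str, str, str], float, float, float]]] = {
    # residue -> (atom, element, (ref_a, ref_b, ref_c), bond, angle, torsion)
    "ALA": [],
    "LYS": [("CG", "C", ("N", "CA", "CB"), 1.52, 111.0, 180.0),
            ("CD", "C", ("CA", "CB", "CG"), 1.52, 111.0, 180.0),
            ("CE", "C", ("CB", "CG", "CD"), 1.52, 111.0, 180.0),
            ("NZ", "N", ("CG", "CD", "CE"), 1.47, 111.0, 180.0)],
    "SER": [("OG", "O", ("N", "CA", "CB"), 1.41, 110.5, 180.0)],
    "THR": [("OG1", "O", ("N", "CA", "CB"), 1.41, 109.5, 180.0),
            ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, -60.0)],
    "TYR": [("CG", "C", ("N", "CA", "CB"), 1.51, 113.9, 180.0),
            ("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.8, 90.0),
            ("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.8, -90.0),
            ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 121.0, 180.0),
            ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 121.0, 180.0),
            ("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, 0.0),
            ("OH", "O", ("CD1", "CE1", "CZ"), 1.38, 120.0, 180.0)],
}


def _add_side_chain(atoms: dict[str, np.ndarray], aa3: str) -> dict[str, str]:
    """Extend backbone dict with CB and side-chain heavy atoms; return elements."""
    elements: dict[str, str] = {}
    if aa3 == "GLY":
        return elements
    atoms["CB"] = place_atom(atoms["C"], atoms["N"], atoms["CA"],
                             1.53, 110.5, 122.6)
    elements["CB"] = "C"
    for name, el, refs, bond, angle, torsion in _SIDE_CHAINS.get(aa3, []):
        atoms[name] = place_atom(atoms[refs[0]], atoms[refs[1]], atoms[refs[2]],
                                 bond, angle, torsion)
        elements[name] = el
    return elements


def _screw_axis(res: list[dict[str, np.ndarray]]) -> tuple[np.ndarray, np.ndarray]:
    """Exact screw axis (point, unit direction) of a repeating backbone chain."""
    names = ("N", "CA", "C")
    a = np.array([res[1][x] for x in names])
    b = np.array([res[2][x] for x in names])
    ca_a, ca_b = a.mean(axis=0), b.mean(axis=0)
    rot, _ = Rotation.align_vectors(b - ca_b, a - ca_a)
    rmat = rot.as_matrix()
    t = ca_b - rmat @ ca_a
    axis = rot.as_rotvec()
    axis = axis / np.linalg.norm(axis)
    rise = float(t @ axis)
    t_perp = t - rise * axis
    point, *_ = np.linalg.lstsq(np.eye(3) - rmat, t_perp, rcond=None)
    point = point - (point @ axis) * axis + (res[0]["CA"] @ axis) * axis
    if rise < 0:
        axis = -axis
    return point, axis


def make_ideal_helix(params: HelixParams) -> tuple[Structure, HelixAxis]:
    """Build an ideal helix and return it with the exact axis it was built on.

    ``CA_ONLY`` places C-alphas exactly on the requested cylinder
    (radius/rise/twist).  ``FULL_BACKBONE`` builds the chain from ideal
    internal coordinates (phi/psi = -57/-47), whose own exact screw axis is
    computed and returned; the cylinder parameters then follow from the
    internal coordinates rather than from the requested radius/rise/twist.
    """
    n = params.n_res
    seq = params.sequence or "A" * n
    if params.backbone == "CA_ONLY":
        k = np.arange(n)
        ang = np.radians(params.phase + k * params.twist)
        local = np.column_stack([params.radius * np.cos(ang),
                                 params.radius * np.sin(ang),
                                 k * params.rise])
        coords = _rigid_to_axis(local, np.array([0.0, 0.0, 1.0]),
                                np.array([0.0, 0.0, 0.0]), params)
        per_res = [{"CA": coords[i]} for i in range(n)]
        elements = [{"CA": "C"} for _ in range(n)]
        seg_end = (n - 1) * params.rise
        radius, rmsd = params.radius, 0.0
    elif params.backbone == "FULL_BACKBONE":
        chain = _backbone_nerf(n)
        elements = []
        for i, r in enumerate(chain):
            els = {"N": "N", "CA": "C", "C": "C", "O": "O"}
            els.update(_add_side_chain(r, _ONE_TO_THREE[seq[i]]))
            elements.append(els)
        point, axis = _screw_axis(chain)
        ca = np.array([r["CA"] for r in chain])
        axial = (ca - point) @ axis
        origin = point + axial[0] * axis
        all_names = [list(r.keys()) for r in chain]
        flat = np.array([r[nm] for r, names in zip(chain, all_names) for nm in names])
        flat = _rigid_to_axis(flat, axis, origin, params)
        per_res = []
        pos = 0
        for names in all_names:
            per_res.append({nm: flat[pos + j] for j, nm in enumerate(names)})
            pos += len(names)
        radial = np.linalg.norm((ca - origin) - np.outer(axial - axial[0], axis), axis=1)
        radius = float(radial.mean())
        rmsd = float(radial.std())
        seg_end = float(axial[-1] - axial[0])
    else:
        raise ValueError(f"unknown backbone mode {params.backbone!r}")

    residues = []
    order = ["N", "CA", "C", "O", "CB", "CG", "CD", "CD1", "CD2", "CE", "CE1",
             "CE2", "CZ", "NZ", "OG", "OG1", "CG2", "OH"]
    for i in range(n):
        atom_map = per_res[i]
        names = [nm for nm in order if nm in atom_map]
        names += [nm for nm in atom_map if nm not in names]
        atoms = [Atom(name=nm, element=elements[i].get(nm, nm[0]),
                      coords=atom_map[nm]) for nm in names]
        residues.append(Residue(chain_id=params.chain_id,
                                seq_id=params.start_seq_id + i,
                                aa_code=_ONE_TO_THREE[seq[i]], atoms=atoms))
    structure = Structure(residues=residues, source_path="<synthetic>")
    direction = np.asarray(params.axis_direction, float)
    direction = direction / np.linalg.norm(direction)
    axis = HelixAxis(anchor=np.asarray(params.axis_anchor, float),
                     direction=direction, seg_start=0.0,
                     seg_end=seg_end, radius=radius, fit_rmsd=rmsd)
    return structure, axis


@dataclass
class PairParams:
    plane_distance: float = 11.7    # d*, A
    theta: float = -57.0            # signed torsion, degrees
    crossing_offset: float = 0.5    # fractional crossing position; outside
                                    # [0, 1] the projections do not cross
    lengths: tuple[int, int] = (14, 14)   # residues per helix
    connection_length: int = 4
    backbone: str = "FULL_BACKBONE"
    sequence_a: str | None = None
    sequence_b: str | None = None

    def __post_init__(self) -> None:
        if self.plane_distance < 0:
            raise ValueError("plane distance must be >= 0")
        if not -180.0 < self.theta <= 180.0:
            raise ValueError("theta must lie in (-180, 180]")


@dataclass
class PairResult:
    structure: Structure
    geometry: PairGeometry           # analytic ground truth
    axis_a: HelixAxis
    axis_b: HelixAxis
    span_a: tuple[int, int]          # residue index ranges in the structure
    span_b: tuple[int, int]


def make_helix_pair(params: PairParams) -> PairResult:
    """Two helices posed at a prescribed plane distance and torsion angle.

    Helix A runs along x in the z = 0 plane; helix B lies in the plane
    z = d* with in-plane direction rotated by theta about +z.  Both are
    positioned so their projections cross at ``crossing_offset`` along each
    segment (offsets outside [0, 1] produce a non-crossing pair).  The
    analytic geometry of the constructed axes is returned as ground truth.
    """
    n_a, n_b = params.lengths
    seq_a = params.sequence_a or "A" * n_a
    seq_b = params.sequence_b or "A" * n_b

    helix_a, axis_a = make_ideal_helix(HelixParams(
        n_res=n_a, backbone=params.backbone, sequence=seq_a,
        axis_anchor=(0.0, 0.0, 0.0), axis_direction=(1.0, 0.0, 0.0)))
    len_a = axis_a.length

    theta_r = math.radians(params.theta)
    dir_b = np.array([math.cos(theta_r), math.sin(theta_r), 0.0])
    # axial length of helix B from its own construction
    _, axis_b_tmp = make_ideal_helix(HelixParams(
        n_res=n_b, backbone=params.backbone, sequence=seq_b))
    len_b = axis_b_tmp.length

    f = params.crossing_offset
    cross_pt = np.array([f * len_a, 0.0, params.plane_distance])
    start_b = cross_pt - f * len_b * dir_b

    helix_b, axis_b = make_ideal_helix(HelixParams(
        n_res=n_b, backbone=params.backbone, sequence=seq_b,
        axis_anchor=tuple(start_b), axis_direction=tuple(dir_b),
        start_seq_id=n_a + params.connection_length + 1))

    # connecting linker: C-alpha pseudo-atoms interpolated between the ends
    end_a = helix_a.residues[-1]["CA"].coords
    beg_b = helix_b.residues[0]["CA"].coords
    linker: list[Residue] = []
    for k in range(params.connection_length):
        t = (k + 1) / (params.connection_length + 1)
        pos = end_a * (1 - t) + beg_b * t
        linker.append(Residue(chain_id="A", seq_id=n_a + k + 1, aa_code="GLY",
                              atoms=[Atom(name="CA", element="C", coords=pos)]))

    residues = helix_a.residues + linker + helix_b.residues
    structure = Structure(residues=residues, source_path="<synthetic-pair>")

    crossing = 0.0 < f < 1.0
    alpha = abs(params.theta)
    alpha = min(alpha, 180.0 - alpha)
    if crossing:
        r = params.plane_distance
    else:
        r = _segment_distance(axis_a.p0, axis_a.p1, axis_b.p0, axis_b.p1)
    S, P, poly = projection_intersection(axis_a, axis_b)
    truth = PairGeometry(d=params.plane_distance, r=float(r), alpha=float(alpha),
                         theta=params.theta if abs(params.theta) != 180.0 else 180.0,
                         S=S, P=P, crossing=crossing, polygon=poly)
    span_a = (0, n_a - 1)
    span_b = (n_a + params.connection_length,
              n_a + params.connection_length + n_b - 1)
    return PairResult(structure=structure, geometry=truth, axis_a=axis_a,
                      axis_b=axis_b, span_a=span_a, span_b=span_b)


def make_trajectory(structure: Structure, n_frames: int, jitter_sd: float,
                    seed: int, drift: np.ndarray | None = None,
                    drift_span: tuple[int, int] | None = None,
                    frame_interval: float = 0.005) -> Trajectory:
    """Jittered (and optionally drifting) copies of one structure.

    Frame k adds i.i.d. Gaussian noise (sigma = ``jitter_sd``) to every atom
    and, when given, k * ``drift`` to the residues in ``drift_span``
    (inclusive index range).  Reproducible under ``seed``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for k in range(n_frames):
        frame = structure.copy()
        frame.model_id = k + 1
        for idx, res in enumerate(frame.residues):
            shift = np.zeros(3)
            if drift is not None and drift_span is not None \
                    and drift_span[0] <= idx <= drift_span[1]:
                shift = k * np.asarray(drift, float)
            for atom in res.atoms:
                atom.coords = atom.coords + shift + \
                    rng.normal(0.0, jitter_sd, size=3)
        frames.append(frame)
    return Trajectory(frames=frames, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# cohort identification tables


@dataclass
class PlantedPTM:
    peptide: str
    protein: str
    ptm_kind: str
    site: int
    groups: tuple[str, ...]          # target cancer groups, e.g. ("OC",)
    carrier_fraction: float = 0.6    # fraction of each target group's samples

    def __post_init__(self) -> None:
        if not 0.0 < self.carrier_fraction <= 1.0:
            raise ValueError("carrier_fraction must be in (0, 1]")


@dataclass
class CohortDesign:
    n_oc: int = 53
    n_bc: int = 24
    n_cnt: int = 30
    planted_ptms: list[PlantedPTM] = field(default_factory=list)
    with_decoys: bool = True
    intensity_mu_log: float = 16.0   # natural-log intensity location
    intensity_sigma_log: float = 1.0
    seed: int = 0


def default_cohort_design(seed: int = 0) -> CohortDesign:
    """Cohort mirroring the study demography (53 OC / 24 BC / 30 controls)."""
    planted = [
        PlantedPTM("KQINDYVEK", "A1AT", "acetyl-K", 1, ("OC",), 0.6),
        PlantedPTM("EQLKAVMDDFAAFVEK", "ALBU", "acetyl-K", 4, ("OC", "BC"), 0.7),
        PlantedPTM("RHPYFYAPELLFFAK", "ALBU", "phospho-Y", 6, ("OC",), 0.6),
        PlantedPTM("ETTCSKESNEELTESCETK", "KNG1", "phospho-T", 2, ("OC",), 0.6),
        PlantedPTM("KVPQVSTPTLVEVSR", "ALBU", "acetyl-K", 1, ("BC",), 0.8),
        PlantedPTM("KSASDLTWDNLK", "TRFE", "acetyl-K", 1, ("BC",), 0.8),
    ]
    return CohortDesign(planted_ptms=planted, seed=seed)


def reference_cohort_design(seed: int = 0) -> CohortDesign:
    """Cohort whose planted PTMs mirror the reference peptide list fixture.

    12 OC-specific modified peptides over 8 proteins and 6 BC-specific
    peptides over 3 proteins, with the albumin and serotransferrin peptides
    shared between the two cancer groups exactly as in the fixture table.
    """
    table = load_fixture("TABLE1")
    by_key: dict[tuple[str, str, int], PlantedPTM] = {}
    for _, row in table.iterrows():
        key = (row["peptide"], row["ptm_kind"], int(row["site"]))
        if key in by_key:
            groups = tuple(sorted(set(by_key[key].groups) | {row["group"]}))
            by_key[key].groups = groups
        else:
            frac = 0.6 if row["group"] == "OC" else 0.8
            by_key[key] = PlantedPTM(row["peptide"], row["gene"],
                                     row["ptm_kind"], int(row["site"]),
                                     (row["group"],), frac)
    for p in by_key.values():
        if "BC" in p.groups:
            p.carrier_fraction = 0.8
    return CohortDesign(planted_ptms=list(by_key.values()), seed=seed)


_DECOY_RULES = ("low_confidence", "low_coverage", "low_dscore", "missing_by",
                "in_control", "low_prevalence", "low_carrier_fraction")


def make_identification_table(design: CohortDesign
                              ) -> tuple[pd.DataFrame, dict]:
    """Identification records for a synthetic cohort, with ground truth.

    Planted PTMs appear in their target groups at the designed carrier
    fractions with comfortably passing quality metrics; each decoy violates
    exactly one curation rule with a wide margin.  Returns the record table
    and ``{"sets": per-group truth, "protein_map": peptide -> protein,
    "decoys": decoy peptide names}``.
    """
    rng = np.random.default_rng(design.seed)
    samples = {"OC": [f"OC{i + 1:02d}" for i in range(design.n_oc)],
               "BC": [f"BC{i + 1:02d}" for i in range(design.n_bc)],
               "CNT": [f"CNT{i + 1:02d}" for i in range(design.n_cnt)]}
    group_of = {s: g for g, ss in samples.items() for s in ss}

    good = {"confidence": 99.5, "coverage_pct": 92.0, "d_score": 22.0,
            "by_pairs_ok": True}
    rows: list[dict] = []
    protein_map: dict[str, str] = {}

    def emit(sample: str, peptide: str, protein: str, kind: str, site: int,
             **overrides) -> None:
        metrics = dict(good)
        metrics.update(overrides)
        rows.append({
            "sample_id": sample, "group": group_of[sample],
            "protein": protein, "peptide": peptide,
            "ptm_kind": kind, "site": site,
            "psm_count": int(rng.integers(5, 40)),
            "intensity": float(rng.lognormal(design.intensity_mu_log,
                                             design.intensity_sigma_log)),
            **metrics,
        })
        protein_map[peptide] = protein

    truth_sets: dict[str, set] = {"OC": set(), "BC": set()}
    for p in design.planted_ptms:
        if any(math.ceil(p.carrier_fraction * len(samples[g])) < 1
               for g in p.groups):
            raise ValueError(f"infeasible design for {p.peptide}: "
                             "carrier fraction x group size < 1")
        for g in p.groups:
            n_carry = math.ceil(p.carrier_fraction * len(samples[g]))
            chosen = rng.choice(samples[g], size=n_carry, replace=False)
            for s in sorted(chosen):
                emit(s, p.peptide, p.protein, p.ptm_kind, p.site)
            truth_sets[g].add((p.peptide, p.ptm_kind, p.site))

    decoys: dict[str, str] = {}
    if design.with_decoys:
        n_oc_60 = math.ceil(0.6 * design.n_oc)
        specs = {
            "low_confidence": ("DECOYAAAK", "DC01", dict(confidence=88.0), "OC", n_oc_60, 0),
            "low_coverage": ("DECOYCCCK", "DC02", dict(coverage_pct=55.0), "OC", n_oc_60, 0),
            "low_dscore": ("DECOYDDDK", "DC03", dict(d_score=3.0), "OC", n_oc_60, 0),
            "missing_by": ("DECOYEEEK", "DC04", dict(by_pairs_ok=False), "OC", n_oc_60, 0),
            "in_control": ("DECOYFFFK", "DC05", {}, "OC", n_oc_60, 2),
            "low_prevalence": ("DECOYGGGK", "DC06", {}, "OC",
                               max(1, math.floor(0.25 * design.n_oc)), 0),
            "low_carrier_fraction": ("DECOYHHHK", "DC07", {}, "BC",
                                     math.ceil(0.55 * design.n_bc), 0),
        }
        for rule, (pep, prot, overrides, grp, n_in_group, n_cnt) in specs.items():
            decoys[pep] = rule
            chosen = rng.choice(samples[grp], size=n_in_group, replace=False)
            for s in sorted(chosen):
                emit(s, pep, prot, "acetyl-K", 1, **overrides)
            if n_cnt:
                for s in samples["CNT"][:n_cnt]:
                    emit(s, pep, prot, "acetyl-K", 1, **overrides)

    df = pd.DataFrame(rows)
    truth = {"sets": truth_sets, "protein_map": protein_map, "decoys": decoys,
             "samples": samples}
    return df, truth


def make_intensity_table(n_case: int = 10, n_control: int = 10,
                         n_proteins: int = 20, planted_protein: str = "P01",
                         fold_change: float = 4.0, sigma_log2: float = 0.5,
                         base_log2: float = 23.0, seed: int = 0
                         ) -> tuple[pd.DataFrame, dict[str, str]]:
    """Sample x protein intensity matrix with one planted fold change.

    Intensities are log-normal (sigma given on the log2 scale); the planted
    protein is shifted up by ``fold_change`` in the case group.  Returns the
    wide table and the sample -> group map.
    """
    rng = np.random.default_rng(seed)
    case = [f"CASE{i + 1:02d}" for i in range(n_case)]
    ctrl = [f"CTRL{i + 1:02d}" for i in range(n_control)]
    proteins = [f"P{i + 1:02d}" for i in range(n_proteins)]
    data = {}
    for p in proteins:
        shift = math.log2(fold_change) if p == planted_protein else 0.0
        vals_case = 2.0 ** (base_log2 + shift + rng.normal(0, sigma_log2, n_case))
        vals_ctrl = 2.0 ** (base_log2 + rng.normal(0, sigma_log2, n_control))
        data[p] = np.concatenate([vals_case, vals_ctrl])
    table = pd.DataFrame(data, index=case + ctrl)
    groups = {s: "CASE" for s in case} | {s: "CNT" for s in ctrl}
    return table, groups


# ---------------------------------------------------------------------------
# packaged fixtures

_FIXTURES = {"TABLE1": "table1.tsv", "TABLE2": "table2.tsv",
             "IDEAL_HELIX_20": "ideal_helix_20.pdb",
             "PAIR_CORNER": "pair_corner.pdb"}


def fixture_path(name: str):
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}")
    return resources.files("ptmstruct.data") / _FIXTURES[name]


def load_fixture(name: str):
    """Load a packaged fixture: a transcribed table or a reference structure."""
    path = fixture_path(name)
    if name in ("TABLE1", "TABLE2"):
        return pd.read_csv(path, sep="\t", comment="#")
    from .structure import read_structure
    with resources.as_file(path) as p:
        return read_structure(p)
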