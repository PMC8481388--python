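"""Helix axes and helical-pair geometry.

A helix is modelled as a cylinder: the axis line is the least-squares
solution minimising the spread of point-to-line radial distances of the
C-alpha trace, with the cylinder radius taken as the mean radial distance of
a chosen atom set (all heavy atoms by default, which for an alpha-helix with
side chains is the effective packing radius of ~5 A rather than the ~2.3 A
C-alpha radius).

A pair of fitted axes is summarised by six descriptors:

    d      distance between the two parallel planes each containing one axis
    r      minimal distance between the two finite axis segments
    alpha  unsigned angle between the (undirected) axis directions, in [0, 90]
    theta  signed dihedral from axis 1 to axis 2 about the inter-plane
           normal (right-hand rule, N->C orientation), in (-180, 180]
    S, P   area and perimeter of the intersection of the two cylinder
           silhouette rectangles projected onto the mid-plane

For contacting (axially crossing) pairs r = d; non-crossing pairs have
r > d.  Motifs classify as alpha-alpha corners or hairpins when the
projections cross (split on |theta|), and as L- or V-structures otherwise
(split on connection length).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import least_squares
from shapely.geometry import Polygon

from .secondary import HelixSegment
from .structure import Structure

__all__ = [
    "HelixAxis",
    "PairGeometry",
    "MotifClass",
    "MotifPair",
    "MotifConfig",
    "fit_helix_axis",
    "fit_segment_axis",
    "pair_planes",
    "pair_geometry",
    "projection_intersection",
    "classify_motif",
    "select_motifs",
]


@dataclass
class HelixAxis:
    anchor: np.ndarray       # a point on the axis line
    direction: np.ndarray    # unit vector, oriented N->C
    seg_start: float         # axial coordinate of the first C-alpha (A)
    seg_end: float           # axial coordinate of the last C-alpha (A)
    radius: float            # mean radial distance of the fitted atom set (A)
    fit_rmsd: float          # SD of radial distances about the mean (A)

    def __post_init__(self) -> None:
        self.anchor = np.asarray(self.anchor, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if not np.isclose(n, 1.0, atol=1e-8):
            self.direction = self.direction / n
        if self.seg_end <= self.seg_start:
            raise ValueError("seg_end must lie strictly beyond seg_start")

    @property
    def p0(self) -> np.ndarray:
        return self.anchor + self.seg_start * self.direction

    @property
    def p1(self) -> np.ndarray:
        return self.anchor + self.seg_end * self.direction

    @property
    def length(self) -> float:
        return self.seg_end - self.seg_start


@dataclass
class PairGeometry:
    d: float
    r: float
    alpha: float
    theta: float
    S: float
    P: float
    crossing: bool
    polygon: np.ndarray | None = None  # 2-D vertices of the intersection

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.d, self.r, self.alpha, self.theta, self.S, self.P)


class MotifClass(Enum):
    AA_CORNER = "alpha-alpha-corner"
    AA_HAIRPIN = "alpha-alpha-hairpin"
    L_STRUCTURE = "L-structure"
    V_STRUCTURE = "V-structure"
    OTHER = "other"


@dataclass
class MotifPair:
    helix_a: HelixSegment
    helix_b: HelixSegment
    axis_a: HelixAxis
    axis_b: HelixAxis
    geometry: PairGeometry
    connection_length: int
    motif_class: MotifClass


@dataclass
class MotifConfig:
    contact_limit: float = 16.0      # r = d <= 16 A selection rule
    eps_contact: float = 0.5         # |r - d| tolerance for "tight contact"
    rmsd_max: float = 1.0            # axis-fit quality gate (A)
    ptm_window: int = 2              # residues beyond helix ends still "close"
    hairpin_theta: float = 120.0     # |theta| >= this => hairpin
    v_max_conn: int = 5              # connection length <= this => V


def _radial_distances(points: np.ndarray, anchor: np.ndarray,
                      direction: np.ndarray) -> np.ndarray:
    rel = points - anchor
    axial = rel @ direction
    perp = rel - np.outer(axial, direction)
    return np.linalg.norm(perp, axis=1)


def _direction_from_angles(theta: float, phi: float) -> np.ndarray:
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def fit_helix_axis(calpha_coords: np.ndarray,
                   all_heavy_coords: np.ndarray | None = None) -> HelixAxis:
    """Least-squares cylinder axis through an ordered C-alpha trace.

    Minimises the standard deviation of point-to-axis radial distances,
    initialised from the principal direction of the centred point cloud and
    refined with nonlinear least squares.  The axis direction is oriented
    from the first towards the last residue (N->C); *radius* is the mean
    radial distance of ``all_heavy_coords`` when given, else of the C-alphas.
    """
    pts = np.asarray(calpha_coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 5:
        raise ValueError("need at least 5 C-alpha points to fit a helix axis")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[0] < 1e-9 or np.all(_radial_distances(pts, centroid, vt[0]) < 1e-9):
        raise ValueError("collinear points: degenerate cylinder")
    d0 = vt[0]
    theta0 = float(np.arccos(np.clip(d0[2], -1.0, 1.0)))
    phi0 = float(np.arctan2(d0[1], d0[0]))

    def residuals(params: np.ndarray) -> np.ndarray:
        theta, phi, u, v = params
        direction = _direction_from_angles(theta, phi)
        # anchor offset expressed in the plane perpendicular to the direction
        e1 = np.array([np.cos(theta) * np.cos(phi), np.cos(theta) * np.sin(phi),
                       -np.sin(theta)])
        e2 = np.cross(direction, e1)
        anchor = centroid + u * e1 + v * e2
        radial = _radial_distances(pts, anchor, direction)
        return radial - radial.mean()

    sol = least_squares(residuals, x0=[theta0, phi0, 0.0, 0.0], method="lm",
                        xtol=1e-12, ftol=1e-12)
    theta, phi, u, v = sol.x
    direction = _direction_from_angles(theta, phi)
    e1 = np.array([np.cos(theta) * np.cos(phi), np.cos(theta) * np.sin(phi),
                   -np.sin(theta)])
    e2 = np.cross(direction, e1)
    anchor = centroid + u * e1 + v * e2
    if (pts[-1] - pts[0]) @ direction < 0:
        direction = -direction

    radial_ca = _radial_distances(pts, anchor, direction)
    fit_rmsd = float(radial_ca.std())
    radius_set = pts if all_heavy_coords is None else np.asarray(all_heavy_coords, float)
    radius = float(_radial_distances(radius_set, anchor, direction).mean())
    axial = (pts - anchor) @ direction
    # re-anchor at the axial midpoint for a well-conditioned reference point
    mid = 0.5 * (axial[0] + axial[-1])
    anchor = anchor + mid * direction
    return HelixAxis(anchor=anchor, direction=direction,
                     seg_start=float(axial[0] - mid), seg_end=float(axial[-1] - mid),
                     radius=radius, fit_rmsd=fit_rmsd)


def fit_segment_axis(structure: Structure, segment: HelixSegment,
                     use_heavy_radius: bool = True) -> HelixAxis:
    """Fit the axis of a helix segment from a structure's coordinates."""
    residues = structure.residues[segment.start_index:segment.end_index + 1]
    ca = np.array([r["CA"].coords for r in residues])
    heavy = None
    if use_heavy_radius:
        heavy = np.concatenate([r.heavy_coords() for r in residues])
    return fit_helix_axis(ca, heavy)


_PARALLEL_TOL = 1e-8


def pair_planes(axis_a: HelixAxis, axis_b: HelixAxis) -> tuple[np.ndarray, float]:
    """Normal and separation of the two parallel planes containing the axes.

    The normal is the unit cross product of the directions, signed to point
    from the plane of axis A towards the plane of axis B.  Parallel axes fall
    back to the perpendicular component of the anchor offset.
    """
    cross = np.cross(axis_a.direction, axis_b.direction)
    offset = axis_b.anchor - axis_a.anchor
    nc = np.linalg.norm(cross)
    if nc < _PARALLEL_TOL:
        perp = offset - (offset @ axis_a.direction) * axis_a.direction
        d = float(np.linalg.norm(perp))
        if d < _PARALLEL_TOL:  # coincident lines: any perpendicular works
            helper = np.array([1.0, 0.0, 0.0])
            if abs(axis_a.direction @ helper) > 0.9:
                helper = np.array([0.0, 1.0, 0.0])
            perp = np.cross(axis_a.direction, helper)
            return perp / np.linalg.norm(perp), 0.0
        return perp / d, d
    normal = cross / nc
    signed = float(offset @ normal)
    if signed < 0:
        normal, signed = -normal, -signed
    return normal, signed


def _segment_distance(p0: np.ndarray, p1: np.ndarray,
                      q0: np.ndarray, q1: np.ndarray) -> float:
    """Minimal Euclidean distance between two finite 3-D segments."""
    u, v, w = p1 - p0, q1 - q0, p0 - q0
    a, b, c = u @ u, u @ v, v @ v
    d_, e_ = u @ w, v @ w

    def dist(s: float, t: float) -> float:
        return float(np.linalg.norm(w + s * u - t * v))

    candidates: list[float] = []
    denom = a * c - b * b
    if denom > 1e-12:  # unconstrained minimiser, valid only inside the square
        s0 = (b * e_ - c * d_) / denom
        t0 = (a * e_ - b * d_) / denom
        if 0.0 <= s0 <= 1.0 and 0.0 <= t0 <= 1.0:
            candidates.append(dist(s0, t0))
    # the constrained minimum otherwise lies on an edge of the (s, t) square
    for s_fix in (0.0, 1.0):
        t_opt = np.clip((b * s_fix + e_) / c, 0.0, 1.0) if c > 1e-12 else 0.0
        candidates.append(dist(s_fix, float(t_opt)))
    for t_fix in (0.0, 1.0):
        s_opt = np.clip((b * t_fix - d_) / a, 0.0, 1.0) if a > 1e-12 else 0.0
        candidates.append(dist(float(s_opt), t_fix))
    return min(candidates)


def _plane_basis(normal: np.ndarray, axis_a: HelixAxis) -> tuple[np.ndarray, np.ndarray]:
    e1 = axis_a.direction - (axis_a.direction @ normal) * normal
    n = np.linalg.norm(e1)
    if n < _PARALLEL_TOL:
        helper = np.array([1.0, 0.0, 0.0])
        if abs(normal @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e1 = helper - (helper @ normal) * normal
        n = np.linalg.norm(e1)
    e1 = e1 / n
    return e1, np.cross(normal, e1)


def _project_segment(axis: HelixAxis, e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    return np.array([[axis.p0 @ e1, axis.p0 @ e2], [axis.p1 @ e1, axis.p1 @ e2]])


def _silhouette_rectangle(seg2d: np.ndarray, radius: float) -> Polygon:
    p0, p1 = seg2d
    axis = p1 - p0
    n = np.linalg.norm(axis)
    if n < _PARALLEL_TOL:
        raise ValueError("degenerate (zero-length) axis segment")
    perp = np.array([-axis[1], axis[0]]) / n * radius
    return Polygon([p0 + perp, p1 + perp, p1 - perp, p0 - perp])


def _segments_cross_2d(a: np.ndarray, b: np.ndarray) -> bool:
    """Do 2-D segments a and b intersect (inclusive of touching)?"""
    def orient(p, q, r):
        v = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    def on_seg(p, q, r):
        return (min(p[0], q[0]) - 1e-12 <= r[0] <= max(p[0], q[0]) + 1e-12 and
                min(p[1], q[1]) - 1e-12 <= r[1] <= max(p[1], q[1]) + 1e-12)

    p1, p2 = a
    q1, q2 = b
    o1, o2 = orient(p1, p2, q1), orient(p1, p2, q2)
    o3, o4 = orient(q1, q2, p1), orient(q1, q2, p2)
    if o1 != o2 and o3 != o4:
        return True
    for (p, q, r) in ((p1, p2, q1), (p1, p2, q2), (q1, q2, p1), (q1, q2, p2)):
        if orient(p, q, r) == 0 and on_seg(p, q, r):
            return True
    return False


def projection_intersection(axis_a: HelixAxis, axis_b: HelixAxis
                            ) -> tuple[float, float, np.ndarray | None]:
    """Area and perimeter of the intersection of the projected silhouettes.

    Each cylinder projects onto the mid-plane as a rectangle (length = axial
    segment length, width = 2 * radius); S and P are taken from the convex
    intersection polygon of the two rectangles.
    """
    normal, _ = pair_planes(axis_a, axis_b)
    e1, e2 = _plane_basis(normal, axis_a)
    rect_a = _silhouette_rectangle(_project_segment(axis_a, e1, e2), axis_a.radius)
    rect_b = _silhouette_rectangle(_project_segment(axis_b, e1, e2), axis_b.radius)
    inter = rect_a.intersection(rect_b)
    if inter.is_empty or inter.area <= 0.0:
        return 0.0, 0.0, None
    poly = np.array(inter.exterior.coords)
    return float(inter.area), float(inter.length), poly


def pair_geometry(axis_a: HelixAxis, axis_b: HelixAxis) -> PairGeometry:
    """The six descriptors (d, r, alpha, theta, S, P) of a helical pair."""
    if axis_a.length < _PARALLEL_TOL or axis_b.length < _PARALLEL_TOL:
        raise ValueError("degenerate (zero-length) axis segment")
    normal, d = pair_planes(axis_a, axis_b)
    r = _segment_distance(axis_a.p0, axis_a.p1, axis_b.p0, axis_b.p1)

    cosang = float(np.clip(axis_a.direction @ axis_b.direction, -1.0, 1.0))
    angle = np.degrees(np.arccos(cosang))
    alpha = min(angle, 180.0 - angle)

    sin_t = float(np.cross(axis_a.direction, axis_b.direction) @ normal)
    theta = float(np.degrees(np.arctan2(sin_t, cosang)))
    if theta <= -180.0:
        theta += 360.0

    S, P, poly = projection_intersection(axis_a, axis_b)

    e1, e2 = _plane_basis(normal, axis_a)
    crossing = _segments_cross_2d(_project_segment(axis_a, e1, e2),
                                  _project_segment(axis_b, e1, e2))
    return PairGeometry(d=d, r=r, alpha=float(alpha), theta=theta, S=S, P=P,
                        crossing=crossing, polygon=poly)


def classify_motif(geometry: PairGeometry, connection_length: int,
                   hairpin_theta: float = 120.0, v_max_conn: int = 5) -> MotifClass:
    """Split helical pairs into corner / hairpin / L / V topology classes."""
    if geometry.crossing:
        if abs(geometry.theta) >= hairpin_theta:
            return MotifClass.AA_HAIRPIN
        return MotifClass.AA_CORNER
    if connection_length <= v_max_conn:
        return MotifClass.V_STRUCTURE
    return MotifClass.L_STRUCTURE


def select_motifs(structure: Structure, helices: list[HelixSegment],
                  modified_residue, config: MotifConfig | None = None,
                  axes: list[HelixAxis] | None = None) -> list[MotifPair]:
    """All helix pairs in tight contact that host the modified residue.

    A pair (any number of intervening helices) is retained when: the modified
    residue lies on either helix or on the chain between them (within
    ``ptm_window`` residues of the helix ends); both axis fits satisfy the
    RMSD gate; the pair is in tight contact (|r - d| <= eps_contact and
    r <= contact_limit); and the projection overlap is non-null (S, P > 0).
    """
    config = config or MotifConfig()
    if isinstance(modified_residue, tuple):
        modified_residue = structure.find(*modified_residue)
    mod_index = structure.index_of(modified_residue)

    fittable = [h for h in helices if h.fittable]
    if axes is None:
        axes = [fit_segment_axis(structure, h) for h in fittable]
    elif len(axes) != len(fittable):
        raise ValueError("axes list must align with the fittable helices")

    pairs: list[MotifPair] = []
    for i in range(len(fittable)):
        for j in range(i + 1, len(fittable)):
            ha, hb = fittable[i], fittable[j]
            if ha.chain_id != hb.chain_id:
                continue
            if modified_residue.chain_id != ha.chain_id:
                continue
            if not (ha.start_index - config.ptm_window <= mod_index
                    <= hb.end_index + config.ptm_window):
                continue
            if axes[i].fit_rmsd > config.rmsd_max or axes[j].fit_rmsd > config.rmsd_max:
                continue
            geom = pair_geometry(axes[i], axes[j])
            if abs(geom.r - geom.d) > config.eps_contact:
                continue
            if geom.r > config.contact_limit:
                continue
            if geom.S <= 0.0 or geom.P <= 0.0:
                continue
            conn = max(0, hb.start_index - ha.end_index - 1)
            pairs.append(MotifPair(
                helix_a=ha, helix_b=hb, axis_a=axes[i], axis_b=axes[j],
                geometry=geom, connection_length=conn,
                motif_class=classify_motif(geom, conn, config.hairpin_theta,
                                           config.v_max_conn)))
    return pairs
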