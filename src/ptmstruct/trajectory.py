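"""Tracking helical-pair geometry across trajectory frames.

Each recorded frame gets both axes re-fitted from that frame's coordinates
and the six pair descriptors (d, r, alpha, theta, S, P) recomputed; means
and population standard deviations over the usable frames summarise a run.
The stability verdict compares a modified run against its intact twin: a
motif is STABLE when the helices stay in tight contact (r = d) with a
non-null projection overlap in at least 90% of frames, RUPTURED when contact
is lost in most frames or the mean contact gap opens beyond a threshold,
and FLUCTUATING in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .geometry import PairGeometry, fit_helix_axis, pair_geometry
from .structure import Structure, Trajectory

__all__ = [
    "GeometrySeries",
    "TrajectoryStats",
    "Verdict",
    "StabilityReport",
    "StabilityConfig",
    "track_geometry",
    "summarize_geometry",
    "stability_verdict",
]

FEATURES = ("d", "r", "alpha", "theta", "S", "P")


@dataclass
class GeometrySeries:
    frames: list[PairGeometry | None]   # None marks a failed axis fit
    frame_interval: float
    span_a: tuple[int, int]
    span_b: tuple[int, int]

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_flagged(self) -> int:
        return sum(f is None for f in self.frames)

    def values(self, feature: str) -> np.ndarray:
        return np.array([getattr(f, feature) for f in self.frames if f is not None])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.frames):
            row = {"frame": i}
            if f is None:
                row.update({k: np.nan for k in FEATURES})
            else:
                row.update({k: getattr(f, k) for k in FEATURES})
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class TrajectoryStats:
    means: dict[str, float]   # keyed by feature name
    sds: dict[str, float]     # population standard deviations
    n_frames: int
    n_flagged: int

    def __getitem__(self, feature: str) -> tuple[float, float]:
        return self.means[feature], self.sds[feature]


class Verdict(Enum):
    STABLE = "stable"
    FLUCTUATING = "fluctuating"
    RUPTURED = "ruptured"


@dataclass
class StabilityConfig:
    eps_contact: float = 0.5       # A: |r - d| tolerance for "in contact"
    stable_fraction: float = 0.9   # contact + non-null fractions for STABLE
    rupture_fraction: float = 0.5  # contact fraction below this => RUPTURED
    rupture_gap: float = 2.0       # A: mean r - mean d above this => RUPTURED
    flag_k: float = 2.0            # flag features shifted > k * intact SD


@dataclass
class StabilityReport:
    verdict: Verdict
    contact_fraction: float
    nonnull_projection_fraction: float
    comparison: dict[str, float]        # |modified mean - intact mean|
    flagged_features: list[str] = field(default_factory=list)
    config: StabilityConfig = field(default_factory=StabilityConfig)

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict.value,
            "contact_fraction": self.contact_fraction,
            "nonnull_projection_fraction": self.nonnull_projection_fraction,
            "comparison": self.comparison,
            "flagged_features": self.flagged_features,
            "thresholds": vars(self.config),
        }


def _fit_span(frame: Structure, span: tuple[int, int]):
    residues = frame.residues[span[0]:span[1] + 1]
    ca = np.array([r["CA"].coords for r in residues])
    heavy = np.concatenate([r.heavy_coords() for r in residues])
    return fit_helix_axis(ca, heavy)


def track_geometry(trajectory: Trajectory, span_a: tuple[int, int],
                   span_b: tuple[int, int]) -> GeometrySeries:
    """Re-fit both helix axes and recompute pair geometry for every frame.

    ``span_a`` and ``span_b`` are inclusive residue-index ranges of the two
    helices in the trajectory's topology (the caller supplies re-indexed
    spans when intact and modified numbering differ).  Frames where an axis
    fit fails are flagged (None), never dropped silently.
    """
    n_res = len(trajectory.frames[0].residues)
    for span in (span_a, span_b):
        if not (0 <= span[0] <= span[1] < n_res):
            raise IndexError(f"helix span {span} outside trajectory topology")
    series: list[PairGeometry | None] = []
    for frame in trajectory.frames:
        try:
            axis_a = _fit_span(frame, span_a)
            axis_b = _fit_span(frame, span_b)
            series.append(pair_geometry(axis_a, axis_b))
        except (ValueError, KeyError):
            series.append(None)
    return GeometrySeries(frames=series, frame_interval=trajectory.frame_interval,
                          span_a=span_a, span_b=span_b)


def summarize_geometry(series: GeometrySeries) -> TrajectoryStats:
    """Arithmetic means and population SDs over the unflagged frames."""
    usable = [f for f in series.frames if f is not None]
    if len(usable) < 2:
        raise ValueError(f"need >= 2 usable frames, have {len(usable)}")
    means, sds = {}, {}
    for feat in FEATURES:
        vals = np.array([getattr(f, feat) for f in usable])
        means[feat] = float(vals.mean())
        sd = float(vals.std())  # population SD
        # a constant series must report exactly zero spread; the pairwise
        # summation in the mean can leave an ulp-level residue otherwise
        if sd < 1e-12 * max(1.0, abs(means[feat])):
            sd = 0.0
        sds[feat] = sd
    return TrajectoryStats(means=means, sds=sds, n_frames=len(series),
                           n_flagged=series.n_flagged)


def stability_verdict(modified_stats: TrajectoryStats,
                      intact_stats: TrajectoryStats,
                      series_mod: GeometrySeries,
                      config: StabilityConfig | None = None) -> StabilityReport:
    """Judge whether the modified run keeps the motif geometry intact."""
    config = config or StabilityConfig()
    usable = [f for f in series_mod.frames if f is not None]
    if not usable:
        raise ValueError("modified series has no usable frames")
    contact = np.mean([abs(f.r - f.d) <= config.eps_contact for f in usable])
    nonnull = np.mean([f.S > 0.0 for f in usable])
    gap = modified_stats.means["r"] - modified_stats.means["d"]

    if contact < config.rupture_fraction or gap > config.rupture_gap:
        verdict = Verdict.RUPTURED
    elif contact >= config.stable_fraction and nonnull >= config.stable_fraction:
        verdict = Verdict.STABLE
    else:
        verdict = Verdict.FLUCTUATING

    comparison, flagged = {}, []
    for feat in FEATURES:
        delta = abs(modified_stats.means[feat] - intact_stats.means[feat])
        comparison[feat] = float(delta)
        sd = intact_stats.sds[feat]
        if delta > max(config.flag_k * sd, 1e-9):
            flagged.append(feat)
    return StabilityReport(verdict=verdict, contact_fraction=float(contact),
                           nonnull_projection_fraction=float(nonnull),
                           comparison=comparison, flagged_features=flagged,
                           config=config)
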