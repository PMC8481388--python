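"""End-to-end orchestration: structure -> helices -> motifs -> mount -> SASA
-> trajectory verdicts, and identification tables -> curation -> abundance.

Reports are plain dictionaries (JSON-serialisable) that embed the full
configuration, so every threshold applied in a run is auditable from its
output alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .curation import (FilterThresholds, count_summary, differential_abundance,
                       filter_identifications, phenotype_specific_ptms)
from .geometry import MotifConfig, select_motifs
from .ptm import PTMKind, PTMSpec, mount_ptm
from .sasa import active_environment, sasa_delta_report
from .secondary import assign_helices, place_amide_hydrogens
from .structure import Structure, read_structure, read_trajectory
from .trajectory import (StabilityConfig, stability_verdict, summarize_geometry,
                         track_geometry)

__all__ = ["PipelineConfig", "run_structural_pipeline", "run_curation_pipeline"]

log = logging.getLogger("ptmstruct")


@dataclass
class PipelineConfig:
    motif: MotifConfig = field(default_factory=MotifConfig)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    filters: FilterThresholds = field(default_factory=FilterThresholds)
    probe_radius: float = 1.4
    sasa_points: int = 960
    env_cutoff: float = 6.0
    min_phenotype_frac: float = 0.5
    min_carrier_frac: float = 0.2
    carrier_denominator: str = "cohort"
    abundance_floor: float = 1e5
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _parse_site(site: str) -> tuple[str, int, str]:
    parts = site.split(":")
    if len(parts) < 2:
        raise ValueError(f"site must be CHAIN:SEQID[:ICODE], got {site!r}")
    return parts[0], int(parts[1]), parts[2] if len(parts) > 2 else ""


def run_structural_pipeline(pdb, site, ptm_kind: str | PTMKind,
                            trajectory_intact=None, trajectory_modified=None,
                            modified_spans=None,
                            config: PipelineConfig | None = None) -> dict:
    """Helices -> axes -> motif selection -> moiety mounting -> SASA deltas,
    optionally followed by trajectory stats and a stability verdict.

    *pdb* is a path or Structure; *site* a "CHAIN:SEQID" string or key tuple.
    ``modified_spans`` optionally re-indexes the motif's helix spans in the
    modified trajectory's topology.
    """
    config = config or PipelineConfig()
    structure = pdb if isinstance(pdb, Structure) else read_structure(pdb)
    key = _parse_site(site) if isinstance(site, str) else tuple(site)
    if len(key) == 2:
        key = (key[0], key[1], "")
    kind = PTMKind(ptm_kind) if isinstance(ptm_kind, str) else ptm_kind

    log.info("assigning helices (Kabsch-Sander, cutoff -0.5 kcal/mol)")
    with_h = place_amide_hydrogens(structure)
    helices = assign_helices(with_h)
    log.info("found %d helical segments", len(helices))

    motifs = select_motifs(structure, helices, key, config.motif)
    log.info("motif selection (|r-d| <= %.2f A, r <= %.1f A): %d pair(s)",
             config.motif.eps_contact, config.motif.contact_limit, len(motifs))

    report: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "site": list(key),
        "ptm": kind.value,
        "n_helices": len(helices),
        "helices": [{"chain": h.chain_id, "start": h.start_index,
                     "end": h.end_index, "type": h.helix_type.name}
                    for h in helices],
        "motifs": [],
    }
    for m in motifs:
        report["motifs"].append({
            "helix_a": [m.helix_a.start_index, m.helix_a.end_index],
            "helix_b": [m.helix_b.start_index, m.helix_b.end_index],
            "geometry": {k: getattr(m.geometry, k)
                         for k in ("d", "r", "alpha", "theta", "S", "P",
                                   "crossing")},
            "fit_rmsd": [m.axis_a.fit_rmsd, m.axis_b.fit_rmsd],
            "connection_length": m.connection_length,
            "class": m.motif_class.value,
        })
    if not motifs:
        report["outcome"] = "no motif under criteria"

    mount = mount_ptm(structure, PTMSpec(kind=kind, target=key))
    env = active_environment(structure, key, config.env_cutoff)
    sasa = sasa_delta_report(structure, mount.structure, key, env,
                             config.probe_radius, config.sasa_points)
    report["mount"] = {"chosen_dihedral": mount.chosen_dihedral,
                       "min_clash_distance": mount.min_clash_distance,
                       "n_added_atoms": len(mount.added_atoms)}
    report["sasa"] = sasa.to_dict()

    if trajectory_intact is not None and trajectory_modified is not None and motifs:
        motif = motifs[0]
        span_i = ((motif.helix_a.start_index, motif.helix_a.end_index),
                  (motif.helix_b.start_index, motif.helix_b.end_index))
        span_m = modified_spans or span_i
        traj_i = trajectory_intact if not isinstance(trajectory_intact, (str, Path)) \
            else read_trajectory(trajectory_intact)
        traj_m = trajectory_modified if not isinstance(trajectory_modified, (str, Path)) \
            else read_trajectory(trajectory_modified)
        series_i = track_geometry(traj_i, *span_i)
        series_m = track_geometry(traj_m, *span_m)
        stats_i = summarize_geometry(series_i)
        stats_m = summarize_geometry(series_m)
        verdict = stability_verdict(stats_m, stats_i, series_m, config.stability)
        report["trajectory"] = {
            "span_mapping": {"intact": [list(s) for s in span_i],
                             "modified": [list(s) for s in span_m]},
            "intact": {"means": stats_i.means, "sds": stats_i.sds},
            "modified": {"means": stats_m.means, "sds": stats_m.sds},
            "stability": verdict.to_dict(),
        }
    return report


def run_curation_pipeline(ids, cohort: dict[str, str] | None = None,
                          intensities: pd.DataFrame | None = None,
                          config: PipelineConfig | None = None) -> dict:
    """Quality filters -> phenotype-specific PTM sets -> count summary,
    with optional differential abundance when an intensity matrix is given.

    *ids* is an identification table (path or DataFrame).  Without a cohort
    map (group-level tables such as the packaged peptide list), per-sample
    prevalence rules cannot apply and the per-group distinct counts are
    computed directly from the listed group assignments.
    """
    config = config or PipelineConfig()
    df = ids if isinstance(ids, pd.DataFrame) else pd.read_csv(
        ids, sep="\t", comment="#")
    report: dict = {"version": __version__, "config": config.to_dict()}

    if cohort is None:
        needed = {"group", "gene", "peptide", "ptm_kind", "site"}
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"group-level table lacks column(s): {sorted(missing)}")
        sets = {g: set(zip(sub["peptide"], sub["ptm_kind"], sub["site"].astype(int)))
                for g, sub in df.groupby("group")}
        protein_map = dict(zip(df["peptide"], df["gene"]))
        result = count_summary(sets, protein_map)
    else:
        passed, filter_log = filter_identifications(df, config.filters)
        sets = phenotype_specific_ptms(passed, cohort,
                                       config.min_phenotype_frac,
                                       config.min_carrier_frac,
                                       config.carrier_denominator)
        protein_map = dict(zip(df["peptide"], df["protein"]))
        result = count_summary(sets, protein_map, filter_log)
        report["filter_log"] = filter_log
    report["curation"] = result.to_dict()

    if intensities is not None and cohort is not None:
        abundance = {}
        for case in ("OC", "BC"):
            n_case = sum(1 for s in intensities.index if cohort.get(s) == case)
            if n_case >= 3:
                stats = differential_abundance(intensities, cohort, case,
                                               floor=config.abundance_floor)
                abundance[case] = [
                    {"protein": a.protein, "log2_fc": a.log2_fc,
                     "p_value": a.p_value, "frequency": a.frequency,
                     "significant": a.significant} for a in stats]
        report["abundance"] = abundance
    return report


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
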