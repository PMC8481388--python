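"""Curation of PTM identification tables and differential abundance.

Record-level quality filters (applied in order, each logged):

    (a) peptide identification confidence >= 98%
    (b) fragment-spectrum sequence coverage >= 80%
    (c) site-localization D-score >= 10
    (d) a proper flanking b/y fragment-ion pair present

Cohort-level phenotype specificity: a modified peptide belongs to a cancer
group's PTM set when it is identified in at least 50% of that group's
samples, in no control sample at all, and in at least 20% of PTM-carrying
subjects.  Peptides may be shared between the two cancer groups but never
with the control group.

Differential abundance: missing/zero intensities are floored at the
instrument threshold (1e5 counts), per-protein fold change is the median
ratio versus the control group on the log2 scale, significance is a
two-sided Wilcoxon rank-sum test (exact for small untied samples), and a
protein is called significant when |log2 FC| > 1, p < 0.05 and its
detection frequency in the case group exceeds 0.8.  No multiple-testing
correction is applied at this stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterThresholds",
    "CurationResult",
    "AbundanceStats",
    "REQUIRED_COLUMNS",
    "filter_identifications",
    "phenotype_specific_ptms",
    "count_summary",
    "differential_abundance",
]

REQUIRED_COLUMNS = ("sample_id", "group", "protein", "peptide", "ptm_kind",
                    "site", "confidence", "coverage_pct", "d_score",
                    "by_pairs_ok")

PeptideKey = tuple[str, str, int]  # (sequence, ptm kind, site)

CONTROL_GROUP = "CNT"
CANCER_GROUPS = ("OC", "BC")


@dataclass
class FilterThresholds:
    min_confidence: float = 98.0
    min_coverage: float = 80.0
    min_d_score: float = 10.0
    require_by_pairs: bool = True


@dataclass
class CurationResult:
    per_group: dict[str, dict]
    filter_log: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"per_group": {g: {**v, "ptm_list": sorted(map(list, v["ptm_list"]))}
                              for g, v in self.per_group.items()},
                "filter_log": self.filter_log}


@dataclass
class AbundanceStats:
    protein: str
    median_case: float
    median_control: float
    log2_fc: float
    p_value: float
    frequency: float

    @property
    def significant(self) -> bool:
        return abs(self.log2_fc) > 1.0 and self.p_value < 0.05 \
            and self.frequency > 0.8


def _check_columns(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"identification table lacks required column(s): {missing}")


def filter_identifications(records: pd.DataFrame,
                           thresholds: FilterThresholds | None = None
                           ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Record-level quality filters; returns (passed records, removal log).

    The log counts removals per rule in application order; the surviving set
    is a pure conjunction, so it is independent of that order.
    """
    thresholds = thresholds or FilterThresholds()
    _check_columns(records)
    log: dict[str, int] = {}
    current = records
    # evaluate sequentially so each rule's count reflects what earlier rules left
    masks = {
        "confidence": lambda df: df["confidence"] >= thresholds.min_confidence,
        "coverage": lambda df: df["coverage_pct"] >= thresholds.min_coverage,
        "d_score": lambda df: df["d_score"] >= thresholds.min_d_score,
        "by_pairs": lambda df: (df["by_pairs_ok"].astype(bool)
                                if thresholds.require_by_pairs
                                else pd.Series(True, index=df.index)),
    }
    for rule, fn in masks.items():
        if len(current) == 0:
            log[rule] = 0
            continue
        keep = fn(current)
        log[rule] = int((~keep).sum())
        current = current[keep]
    return current.copy(), log


def _peptide_keys(records: pd.DataFrame) -> pd.Series:
    return pd.Series(list(zip(records["peptide"], records["ptm_kind"],
                              records["site"].astype(int))),
                     index=records.index)


def phenotype_specific_ptms(records: pd.DataFrame,
                            cohort: dict[str, str],
                            min_phenotype_frac: float = 0.5,
                            min_carrier_frac: float = 0.2,
                            carrier_denominator: str = "cohort",
                            ) -> dict[str, set[PeptideKey]]:
    """Per-cancer-group sets of phenotype-specific modified peptides.

    *cohort* maps every sample id to its group (so samples without passed
    records still count in the denominators).  ``carrier_denominator``
    selects whether the >= 20% carrier rule divides by PTM-carrying subjects
    across the whole cohort (default) or within the candidate group.
    """
    _check_columns(records)
    unknown = set(records["sample_id"]) - set(cohort)
    if unknown:
        raise ValueError(f"records contain samples absent from the cohort map: "
                         f"{sorted(unknown)[:5]}")
    if carrier_denominator not in ("cohort", "group"):
        raise ValueError("carrier_denominator must be 'cohort' or 'group'")

    group_sizes: dict[str, int] = {}
    for g in list(CANCER_GROUPS) + [CONTROL_GROUP]:
        group_sizes[g] = sum(1 for v in cohort.values() if v == g)

    modified = records[records["ptm_kind"].notna()
                       & (records["ptm_kind"] != "NONE")]
    carriers_all = set(modified["sample_id"])
    keys = _peptide_keys(modified)

    out: dict[str, set[PeptideKey]] = {g: set() for g in CANCER_GROUPS}
    for key in sorted(set(keys)):
        samples = set(modified.loc[keys == key, "sample_id"])
        if any(cohort[s] == CONTROL_GROUP for s in samples):
            continue  # detectable in the control group: never specific
        for g in CANCER_GROUPS:
            size = group_sizes[g]
            if size == 0:
                continue
            in_group = {s for s in samples if cohort[s] == g}
            if len(in_group) < min_phenotype_frac * size:
                continue
            if carrier_denominator == "cohort":
                denom_set = carriers_all
                numer = samples
            else:
                denom_set = {s for s in carriers_all if cohort[s] == g}
                numer = in_group
            if denom_set and len(numer) < min_carrier_frac * len(denom_set):
                continue
            out[g].add(key)
    return out


def count_summary(sets: dict[str, set[PeptideKey]],
                  protein_map: dict[str, str],
                  filter_log: dict[str, int] | None = None) -> CurationResult:
    """Distinct modified-peptide and protein counts per cancer group."""
    per_group = {}
    for g, keys in sets.items():
        missing = [k[0] for k in keys if k[0] not in protein_map]
        if missing:
            raise ValueError(f"peptide(s) without protein mapping: {missing[:5]}")
        proteins = {protein_map[k[0]] for k in keys}
        per_group[g] = {"peptides": len(keys), "proteins": len(proteins),
                        "ptm_list": set(keys)}
    return CurationResult(per_group=per_group, filter_log=filter_log or {})


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(np.concatenate([x, y])) == 0.0:
        return 1.0  # all-constant: the test is undefined, report no evidence
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 12 and len(y) <= 12 and not has_ties) \
        else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method).pvalue)


def differential_abundance(intensity_table: pd.DataFrame,
                           groups: dict[str, str],
                           case_group: str,
                           control_group: str = CONTROL_GROUP,
                           floor: float = 1e5) -> list[AbundanceStats]:
    """Per-protein abundance comparison of one case group against control.

    *intensity_table* is samples x proteins; zeros and missing values are
    replaced by the instrument floor before any statistic is computed.
    """
    case_samples = [s for s in intensity_table.index if groups.get(s) == case_group]
    ctrl_samples = [s for s in intensity_table.index if groups.get(s) == control_group]
    if len(case_samples) < 3 or len(ctrl_samples) < 3:
        raise ValueError("need at least 3 samples per group for the rank-sum test")
    table = intensity_table.fillna(0.0).clip(lower=floor)
    out: list[AbundanceStats] = []
    for protein in table.columns:
        x = table.loc[case_samples, protein].to_numpy(dtype=float)
        y = table.loc[ctrl_samples, protein].to_numpy(dtype=float)
        med_case, med_ctrl = float(np.median(x)), float(np.median(y))
        log2_fc = float(np.log2(med_case / med_ctrl))
        p = _ranksum_p(x, y)
        freq = float(np.mean(x > floor))
        out.append(AbundanceStats(protein=protein, median_case=med_case,
                                  median_control=med_ctrl, log2_fc=log2_fc,
                                  p_value=p, frequency=freq))
    return out
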