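"""Identification-table filters, phenotype specificity and abundance stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ptmstruct import (FilterThresholds, count_summary, default_cohort_design,
                       differential_abundance, filter_identifications,
                       load_fixture, make_identification_table,
                       make_intensity_table, phenotype_specific_ptms)


def _record(**overrides):
    base = dict(sample_id="OC01", group="OC", protein="ALBU",
                peptide="EQLKAVMDDFAAFVEK", ptm_kind="acetyl-K", site=4,
                confidence=99.0, coverage_pct=85.0, d_score=12.0,
                by_pairs_ok=True, psm_count=10, intensity=1e7)
    base.update(overrides)
    return base


def test_filter_boundaries():
    records = pd.DataFrame([
        _record(),                                  # passes all
        _record(coverage_pct=79.0),                 # fails (b) at the boundary
        _record(coverage_pct=80.0),                 # exactly at threshold: kept
        _record(confidence=97.9),                   # fails (a)
        _record(d_score=9.9),                       # fails (c)
        _record(by_pairs_ok=False),                 # fails b/y curation
    ])
    passed, log = filter_identifications(records)
    assert len(passed) == 2
    assert log == {"confidence": 1, "coverage": 1, "d_score": 1, "by_pairs": 1}
    # conservation: input = passed + removals
    assert len(records) == len(passed) + sum(log.values())


def test_empty_input():
    cols = ["sample_id", "group", "protein", "peptide", "ptm_kind", "site",
            "confidence", "coverage_pct", "d_score", "by_pairs_ok"]
    passed, log = filter_identifications(pd.DataFrame(columns=cols))
    assert len(passed) == 0 and sum(log.values()) == 0


def test_missing_column_reported():
    with pytest.raises(ValueError, match="d_score"):
        filter_identifications(pd.DataFrame([{"sample_id": "x"}]))


def test_filters_idempotent_and_order_independent():
    df, _ = make_identification_table(default_cohort_design(seed=2))
    passed, _ = filter_identifications(df)
    again, log2 = filter_identifications(passed)
    assert len(again) == len(passed) and sum(log2.values()) == 0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(d_conf=st.floats(0, 5), d_cov=st.floats(0, 20), d_ds=st.floats(0, 8))
def test_relaxing_thresholds_is_monotone(d_conf, d_cov, d_ds):
    df, _ = make_identification_table(default_cohort_design(seed=4))
    strict, _ = filter_identifications(df)
    relaxed, _ = filter_identifications(df, FilterThresholds(
        min_confidence=98.0 - d_conf, min_coverage=80.0 - d_cov,
        min_d_score=10.0 - d_ds))
    assert len(relaxed) >= len(strict)


def _toy_cohort(n_oc=10, n_cnt=6):
    samples = {f"OC{i:02d}": "OC" for i in range(n_oc)}
    samples |= {f"CNT{i:02d}": "CNT" for i in range(n_cnt)}
    return samples


def _records_for(samples, peptide="PEPTIDEK", protein="P1"):
    return [
        _record(sample_id=s, group="OC" if s.startswith("OC") else "CNT",
                peptide=peptide, protein=protein, site=1)
        for s in samples]


def test_phenotype_specific_basic_rules():
    cohort = _toy_cohort()
    # 60% of OC, no control, sole peptide (=> 100% of carriers)
    records = pd.DataFrame(_records_for([f"OC{i:02d}" for i in range(6)]))
    sets = phenotype_specific_ptms(records, cohort)
    assert ("PEPTIDEK", "acetyl-K", 1) in sets["OC"]
    # one control appearance disqualifies
    records2 = pd.DataFrame(_records_for(
        [f"OC{i:02d}" for i in range(6)] + ["CNT00"]))
    sets2 = phenotype_specific_ptms(records2, cohort)
    assert sets2["OC"] == set()
    # below 50% prevalence disqualifies
    records3 = pd.DataFrame(_records_for([f"OC{i:02d}" for i in range(4)]))
    assert phenotype_specific_ptms(records3, cohort)["OC"] == set()


def test_unknown_sample_rejected():
    records = pd.DataFrame(_records_for(["OC99"]))
    with pytest.raises(ValueError, match="absent from the cohort"):
        phenotype_specific_ptms(records, _toy_cohort())


def test_planted_cohort_exact_recovery():
    design = default_cohort_design(seed=11)
    df, truth = make_identification_table(design)
    cohort = {s: g for g, ss in truth["samples"].items() for s in ss}
    passed, log = filter_identifications(df)
    # conservation through the filter stage
    assert len(df) == len(passed) + sum(log.values())
    sets = phenotype_specific_ptms(passed, cohort)
    assert sets["OC"] == truth["sets"]["OC"]
    assert sets["BC"] == truth["sets"]["BC"]
    planted = {k[0] for s in truth["sets"].values() for k in s}
    recovered = {k[0] for s in sets.values() for k in s}
    assert recovered.isdisjoint(truth["decoys"])  # zero false positives
    assert planted == recovered                   # sensitivity 1.0


def test_count_summary_on_reference_peptide_list():
    table = load_fixture("TABLE1")
    sets = {g: set(zip(sub["peptide"], sub["ptm_kind"], sub["site"]))
            for g, sub in table.groupby("group")}
    protein_map = dict(zip(table["peptide"], table["gene"]))
    result = count_summary(sets, protein_map)
    assert result.per_group["OC"]["peptides"] == 12
    assert result.per_group["OC"]["proteins"] == 8
    assert result.per_group["BC"]["peptides"] == 6
    assert result.per_group["BC"]["proteins"] == 3


def test_count_summary_edge_cases():
    assert count_summary({"OC": set()}, {}).per_group["OC"]["peptides"] == 0
    with pytest.raises(ValueError, match="without protein mapping"):
        count_summary({"OC": {("XX", "acetyl-K", 1)}}, {})


def test_identical_groups_nothing_significant():
    rng = np.random.default_rng(0)
    vals = rng.lognormal(16, 1, size=8)
    table = pd.DataFrame({"P1": np.concatenate([vals, vals])},
                         index=[f"CASE{i}" for i in range(8)] +
                               [f"CTRL{i}" for i in range(8)])
    groups = {f"CASE{i}": "CASE" for i in range(8)} | \
        {f"CTRL{i}": "CNT" for i in range(8)}
    (stats,) = differential_abundance(table, groups, "CASE")
    assert stats.log2_fc == 0.0
    assert not stats.significant


def test_floor_rule_arithmetic():
    # protein absent in all cases (floored) vs present in controls
    case = {f"CASE{i}": 0.0 for i in range(5)}
    ctrl = {f"CTRL{i}": 1e7 for i in range(5)}
    table = pd.DataFrame({"P1": pd.Series(case | ctrl)})
    groups = {s: ("CASE" if s.startswith("CASE") else "CNT")
              for s in table.index}
    (stats,) = differential_abundance(table, groups, "CASE")
    assert stats.median_case == 1e5
    assert stats.log2_fc == pytest.approx(np.log2(1e5 / 1e7))
    assert stats.log2_fc < -1
    assert stats.frequency == 0.0


def test_planted_fold_change_detected():
    hits = 0
    for rep in range(40):
        table, groups = make_intensity_table(fold_change=4.0, sigma_log2=0.5,
                                             seed=500 + rep)
        stats = differential_abundance(table, groups, "CASE")
        planted = next(a for a in stats if a.protein == "P01")
        hits += planted.significant
    assert hits >= 38  # >= 95% detection


def test_all_constant_protein_p_is_one():
    table = pd.DataFrame({"P1": [5e5] * 8},
                         index=[f"CASE{i}" for i in range(4)] +
                               [f"CTRL{i}" for i in range(4)])
    groups = {f"CASE{i}": "CASE" for i in range(4)} | \
        {f"CTRL{i}": "CNT" for i in range(4)}
    (stats,) = differential_abundance(table, groups, "CASE")
    assert stats.p_value == 1.0
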