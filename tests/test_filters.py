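"""Filter cascade rules, boundary semantics and partition invariants."""

import numpy as np
import pandas as pd
import pytest

from nitroprof import FilterConfig, apply_filter_cascade
from nitroprof.tables_io import UNLABELLED


def make_enrichment(rows):
    """rows: (condition, tracer, metabolite, total_labelling)."""
    return pd.DataFrame(
        [{"condition": c, "tracer": t, "metabolite": m, "k": 0,
          "fe_mean": 1.0 - tl, "fe_sem": 0.0, "total_labelling": tl,
          "n": 1, "is_control": t == UNLABELLED}
         for c, t, m, tl in rows]
    )


def make_pools(rows):
    """rows: (sample, metabolite, pool)."""
    return pd.DataFrame(
        [{"sample": s, "condition": "A", "tracer": "t1", "metabolite": m, "pool": p}
         for s, m, p in rows]
    )


def _clean_inputs(metabolite="m", tl=0.40, pool=1e7, n_samples=3):
    enrich = make_enrichment([("A", "t1", metabolite, tl)])
    pools = make_pools([(f"s{i}", metabolite, pool) for i in range(n_samples)])
    return enrich, pools


def test_clean_metabolite_kept():
    enrich, pools = _clean_inputs()
    report = apply_filter_cascade(enrich, pools, FilterConfig())
    assert report.kept == {"m"}
    assert report.removed == {}


def test_low_quant_single_sample_removed():
    enrich, pools = _clean_inputs(n_samples=1)
    report = apply_filter_cascade(enrich, pools, FilterConfig())
    assert "LOW_QUANT" in report.removed["m"]


def test_low_pool_removed():
    enrich, pools = _clean_inputs(pool=1e5)
    report = apply_filter_cascade(enrich, pools, FilterConfig(pool_size_threshold=2e6))
    assert "LOW_POOL" in report.removed["m"]


def test_low_label_summed_below_one_percent_removed():
    enrich, pools = _clean_inputs(tl=0.004)
    report = apply_filter_cascade(enrich, pools, FilterConfig())
    assert "LOW_LABEL" in report.removed["m"]


def test_summed_labelling_accumulates_across_tracer_conditions():
    """0.4% in each of three tracer conditions sums to 1.2% and survives
    the 1% rule under the sum aggregate."""
    enrich = make_enrichment([("A", t, "m", 0.004) for t in ("t1", "t2", "t3")])
    pools = make_pools([(f"s{i}", "m", 1e7) for i in range(3)])
    report = apply_filter_cascade(enrich, pools, FilterConfig())
    assert "m" in report.kept
    cfg_max = FilterConfig(labelling_aggregate="max")
    report_max = apply_filter_cascade(enrich, pools, cfg_max)
    assert "LOW_LABEL" in report_max.removed["m"]


def test_control_contamination_removed():
    enrich = make_enrichment([("A", "t1", "m", 0.40), ("A", UNLABELLED, "m", 0.04)])
    pools = make_pools([(f"s{i}", "m", 1e7) for i in range(3)])
    report = apply_filter_cascade(enrich, pools, FilterConfig())
    assert "CONTROL_CONTAM" in report.removed["m"]


def test_control_rule_skipped_without_controls(caplog):
    enrich, pools = _clean_inputs()
    with caplog.at_level("WARNING"):
        report = apply_filter_cascade(enrich, pools, FilterConfig())
    assert "m" in report.kept


def test_over_label_removed():
    enrich = make_enrichment([("A", f"t{i}", "m", 0.75) for i in range(8)])  # 600%
    pools = make_pools([(f"s{i}", "m", 1e7) for i in range(3)])
    report = apply_filter_cascade(enrich, pools, FilterConfig())
    assert "OVER_LABEL" in report.removed["m"]


def test_reasons_accumulate():
    enrich = make_enrichment([("A", "t1", "m", 0.004), ("A", UNLABELLED, "m", 0.05)])
    pools = make_pools([("s1", "m", 10.0)])
    report = apply_filter_cascade(enrich, pools, FilterConfig())
    assert set(report.removed["m"]) == {
        "LOW_QUANT", "LOW_POOL", "LOW_LABEL", "CONTROL_CONTAM"}


@pytest.mark.parametrize(
    "tl_pct,kept", [(0.9, False), (1.0, True), (1.1, True)]
)
def test_low_label_boundary_is_strict(tl_pct, kept):
    """'less than 1%' removes strictly below; exactly 1% keeps."""
    enrich, pools = _clean_inputs(tl=tl_pct / 100.0)
    report = apply_filter_cascade(enrich, pools, FilterConfig())
    assert ("m" in report.kept) == kept


@pytest.mark.parametrize("ctl_pct,kept", [(2.9, True), (3.0, True), (3.1, False)])
def test_control_boundary_is_strict(ctl_pct, kept):
    """'>3% in any unlabelled sample' removes strictly above; 3% keeps."""
    enrich = make_enrichment(
        [("A", "t1", "m", 0.40), ("A", UNLABELLED, "m", ctl_pct / 100.0)])
    pools = make_pools([(f"s{i}", "m", 1e7) for i in range(3)])
    report = apply_filter_cascade(enrich, pools, FilterConfig())
    assert ("m" in report.kept) == kept


@pytest.mark.parametrize("sum_pct,kept", [(499.0, True), (500.0, True), (501.0, False)])
def test_over_label_boundary_is_strict(sum_pct, kept):
    """'greater than 500%' removes strictly above; 500% keeps."""
    enrich = make_enrichment([("A", f"t{i}", "m", sum_pct / 700.0) for i in range(7)])
    pools = make_pools([(f"s{i}", "m", 1e7) for i in range(3)])
    report = apply_filter_cascade(enrich, pools, FilterConfig())
    assert ("m" in report.kept) == kept


def test_partition_invariant(rng):
    """kept and removed always partition the metabolite set exactly."""
    mets = [f"m{i}" for i in range(30)]
    enrich = make_enrichment(
        [("A", "t1", m, float(tl)) for m, tl in zip(mets, rng.uniform(0, 0.9, 30))])
    pools = make_pools(
        [(f"s{j}", m, float(p)) for m in mets
         for j, p in enumerate(rng.lognormal(15, 2, 3))])
    report = apply_filter_cascade(enrich, pools, FilterConfig())
    assert report.kept | set(report.removed) == set(mets)
    assert report.kept.isdisjoint(report.removed)
    assert all(report.removed.values())


def test_raising_min_label_threshold_is_monotone(rng):
    """Raising min_summed_labelling never moves a metabolite from removed
    to kept."""
    mets = [f"m{i}" for i in range(20)]
    enrich = make_enrichment(
        [("A", "t1", m, float(tl)) for m, tl in zip(mets, rng.uniform(0, 0.05, 20))])
    pools = make_pools([(f"s{j}", m, 1e7) for m in mets for j in range(3)])
    kept_sets = [
        apply_filter_cascade(enrich, pools, FilterConfig(min_summed_labelling=th)).kept
        for th in (0.5, 1.0, 2.0, 4.0)
    ]
    for lo, hi in zip(kept_sets, kept_sets[1:]):
        assert hi <= lo
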