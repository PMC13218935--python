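"""Metabolite filter cascade applied before scoring and visualisation.

Five independent rules partition metabolites into kept and removed, with
reasons accumulated per metabolite:

``LOW_QUANT``      quantified (intensity > 0) in fewer than
                   ``min_samples_quantified`` samples (default 2 — i.e. the
                   metabolite must be seen in more than one sample);
``LOW_POOL``       mean total pool size, over samples that quantified the
                   metabolite, below an experiment-defined threshold
                   (presets 2e6 and 1e5 for the two supported assay scales);
``LOW_LABEL``      summed total labelling across all tracer conditions
                   below 1% (strictly — exactly 1% keeps);
``CONTROL_CONTAM`` total labelling above 3% (strictly) in any tracer-free
                   control sample;
``OVER_LABEL``     summed total labelling across all tracer conditions
                   above 500% (strictly).

"Summed labelling across all conditions" is the sum over every
(condition, tracer) pair of that pair's total labelling, expressed in
percent; a single pair cannot exceed 100%, which is what makes the paired
1% / 500% bounds coherent. A ``max`` aggregate is available in the config
for the alternative reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .tables_io import RunConfig, UNLABELLED

__all__ = ["FilterConfig", "FilterReport", "apply_filter_cascade"]

logger = logging.getLogger(__name__)

REASONS = ("LOW_QUANT", "LOW_POOL", "LOW_LABEL", "CONTROL_CONTAM", "OVER_LABEL")

# FilterConfig is the filtering slice of the run configuration.
FilterConfig = RunConfig


@dataclass
class FilterReport:
    """Kept/removed partition with per-rule reasons and the measured
    quantities each rule inspected."""

    kept: set
    removed: dict  # metabolite -> list of reason codes
    metrics: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for met in sorted(self.kept | set(self.removed)):
            rows.append({
                "metabolite": met,
                "status": "kept" if met in self.kept else "removed",
                "reasons": ";".join(self.removed.get(met, [])),
            })
        df = pd.DataFrame(rows, columns=["metabolite", "status", "reasons"])
        if not self.metrics.empty:
            df = df.merge(self.metrics, on="metabolite", how="left")
        return df


def apply_filter_cascade(
    enrichment: pd.DataFrame,
    pools: pd.DataFrame,
    config: FilterConfig | None = None,
    per_sample: pd.DataFrame | None = None,
) -> FilterReport:
    """Evaluate all five filter rules independently and partition the
    metabolite set.

    ``enrichment`` is the replicate-mean enrichment table
    (:func:`nitroprof.enrichment.build_enrichment_table`); ``pools`` the
    per-sample pool-size table. ``per_sample`` (per-sample enrichments)
    supplies sample-resolution control labelling for CONTROL_CONTAM; when
    absent, the control rows of the mean table are used. If no control data
    exist at all the rule is skipped with a warning.
    """
    config = config or FilterConfig()
    metabolites = set(pools["metabolite"]) | set(enrichment["metabolite"])
    removed: dict[str, list[str]] = {m: [] for m in metabolites}

    # Per-(condition, tracer, metabolite) total labelling, tracer rows only.
    key_cols = ["condition", "tracer", "metabolite"]
    per_key = enrichment.drop_duplicates(subset=key_cols)[key_cols + ["total_labelling"]]
    tracer_rows = per_key[per_key["tracer"] != UNLABELLED]
    agg = "sum" if config.labelling_aggregate == "sum" else "max"
    summed_pct = tracer_rows.groupby("metabolite")["total_labelling"].agg(agg) * 100.0

    # LOW_QUANT: per-sample, over all samples (controls included).
    quantified = pools[pools["pool"] > 0]
    n_quant = quantified.groupby("metabolite")["sample"].nunique()
    # LOW_POOL: mean over samples in which the metabolite was quantified.
    mean_pool = quantified.groupby("metabolite")["pool"].mean()

    # CONTROL_CONTAM source: per-sample enrichments if available.
    if per_sample is not None and not per_sample.empty:
        ctrl = per_sample[per_sample["tracer"] == UNLABELLED]
    else:
        ctrl = enrichment[enrichment["tracer"] == UNLABELLED]
    have_controls = not ctrl.empty
    if have_controls:
        ctrl_keys = [c for c in ("sample", "condition", "tracer", "metabolite") if c in ctrl.columns]
        ctrl_pct = (
            ctrl.drop_duplicates(subset=ctrl_keys)
            .groupby("metabolite")["total_labelling"].max() * 100.0
        )
    else:
        logger.warning("no tracer-free control samples; CONTROL_CONTAM rule skipped")
        ctrl_pct = pd.Series(dtype=float)

    for met in metabolites:
        if n_quant.get(met, 0) < config.min_samples_quantified:
            removed[met].append("LOW_QUANT")
        if mean_pool.get(met, 0.0) < config.pool_size_threshold:
            removed[met].append("LOW_POOL")
        if summed_pct.get(met, 0.0) < config.min_summed_labelling:
            removed[met].append("LOW_LABEL")
        if have_controls and ctrl_pct.get(met, 0.0) > config.max_unlabelled_labelling:
            removed[met].append("CONTROL_CONTAM")
        if summed_pct.get(met, 0.0) > config.max_summed_labelling:
            removed[met].append("OVER_LABEL")

    kept = {m for m in metabolites if not removed[m]}
    removed = {m: r for m, r in removed.items() if r}
    metrics = pd.DataFrame({
        "metabolite": sorted(metabolites),
    })
    metrics["n_samples_quantified"] = metrics["metabolite"].map(n_quant).fillna(0).astype(int)
    metrics["mean_pool"] = metrics["metabolite"].map(mean_pool).fillna(0.0)
    metrics["summed_labelling_pct"] = metrics["metabolite"].map(summed_pct).fillna(0.0)
    metrics["max_control_labelling_pct"] = metrics["metabolite"].map(ctrl_pct).fillna(0.0)
    return FilterReport(kept=kept, removed=removed, metrics=metrics)
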