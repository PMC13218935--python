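"""End-to-end orchestration: peak table -> enrichment -> filters -> scores
and Sankey flow sets, producing the deterministic output file set."""

from __future__ import annotations

import pandas as pd

from .enrichment import build_enrichment_table, sample_enrichment
from .filters import apply_filter_cascade
from .preprocess import pool_sizes
from .scoring_flows import build_sankey_flows, sankey_to_json, score_table
from .tables_io import RunConfig, UNLABELLED

__all__ = ["run_pipeline"]


def run_pipeline(records: pd.DataFrame, catalog: pd.DataFrame,
                 registry: pd.DataFrame | None, config: RunConfig) -> dict:
    """Run correction, enrichment, filtering, scoring and Sankey
    construction; returns the results dict consumed by
    :func:`nitroprof.tables_io.write_outputs`."""
    log = []
    per_sample = sample_enrichment(records, catalog, mode=config.correction_mode)
    enrich = build_enrichment_table(records, catalog, registry,
                                    mode=config.correction_mode,
                                    per_sample=per_sample)
    log.append(("INFO", "enrich", f"{len(enrich)} enrichment rows"))
    pools = pool_sizes(records)
    report = apply_filter_cascade(enrich, pools, config, per_sample=per_sample)
    log.append(("INFO", "filter",
                f"{len(report.kept)} kept, {len(report.removed)} removed"))

    conds = [c for c in records["condition"].unique()]
    c1 = config.condition1 or (conds[0] if conds else None)
    c2 = config.condition2 or (conds[1] if len(conds) > 1 else None)
    scores = None
    if c1 is not None and c2 is not None:
        try:
            scores = score_table(enrich, c1, c2, kept=report.kept)
            log.append(("INFO", "score", f"{len(scores)} pairs scored"))
        except ValueError as exc:
            log.append(("WARNING", "score", str(exc)))
    else:
        log.append(("WARNING", "score", "fewer than two conditions; scoring skipped"))

    sankey = {"nodes": [], "links": []}
    edges = None
    if c1 is not None:
        edges = build_sankey_flows(enrich, catalog, c1,
                                   threshold=config.sankey_threshold,
                                   kept=report.kept)
        sankey = sankey_to_json(edges)
        log.append(("INFO", "sankey", f"{len(edges)} edges for condition {c1}"))

    return {
        "enrichment": enrich,
        "per_sample": per_sample,
        "pools": pools,
        "filter_report": report.to_frame(),
        "filter_kept": report.kept,
        "scores": scores,
        "sankey": sankey,
        "sankey_edges": edges,
        "log": log,
    }
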