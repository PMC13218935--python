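"""Differential labelling scores, waterfall ranking and Sankey flow sets.

The differential labelling score (DLS) ranks tracer-metabolite pairs by the
difference in labelling between two conditions:

    DLS = |ln(FE1 / FE2)| x (FE1 - FE2)

where FE1, FE2 are the pair's total labelling in condition 1 and 2. The
log-ratio term amplifies relative changes, the difference term carries the
sign and absolute effect size; the score is antisymmetric under swapping
conditions and zero at equality. Log arguments are clamped below at
``eps = 1e-6`` so zero enrichments are scoreable; the difference term uses
the unclamped values.

Sankey flow sets connect each tracer to the pathway-representative
metabolites it labels; edge weight is the representative's total labelling
fraction, and metabolites below the visualisation threshold (default 5%
total labelling, strictly below excludes) are omitted.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .tables_io import UNLABELLED

__all__ = [
    "DLS_EPS",
    "differential_labelling_score",
    "score_table",
    "rank_waterfall",
    "build_sankey_flows",
    "sankey_to_json",
]

DLS_EPS = 1e-6


def differential_labelling_score(fe1: float, fe2: float, eps: float = DLS_EPS) -> float:
    """Signed differential labelling score |ln(fe1/fe2)| x (fe1 - fe2)."""
    f1, f2 = float(fe1), float(fe2)
    if not (0.0 <= f1 <= 1.0 and 0.0 <= f2 <= 1.0):
        raise ValueError(f"enrichments must lie in [0, 1], got {f1}, {f2}")
    return abs(math.log(max(f1, eps) / max(f2, eps))) * (f1 - f2)


def score_table(
    enrichment: pd.DataFrame,
    condition1: str,
    condition2: str,
    kept: set | None = None,
    value: str = "total_labelling",
    k: int | None = None,
) -> pd.DataFrame:
    """Score every (tracer, metabolite) pair present in both conditions.

    ``enrichment`` is the replicate-mean table; control rows are excluded.
    ``kept`` optionally restricts to the metabolites surviving the filter
    cascade. By default the score operates on total labelling; pass ``k``
    to score a specific isotopologue's FE instead. Pairs present in only
    one condition are omitted.
    """
    df = enrichment[enrichment["tracer"] != UNLABELLED]
    if kept is not None:
        df = df[df["metabolite"].isin(kept)]
    conds = {condition1, condition2}
    present = set(df["condition"].unique())
    if not conds <= present:
        raise ValueError(f"conditions {sorted(conds - present)} absent from table")
    if k is not None:
        df = df[df["k"] == k]
        col = "fe_mean"
    else:
        df = df.drop_duplicates(subset=["condition", "tracer", "metabolite"])
        col = "total_labelling"
    wide = df.pivot_table(index=["tracer", "metabolite"], columns="condition",
                          values=col, aggfunc="first")
    if condition1 not in wide.columns or condition2 not in wide.columns:
        raise ValueError("no pairs present in both conditions")
    wide = wide.dropna(subset=[condition1, condition2])
    if wide.empty:
        raise ValueError("no pairs present in both conditions")
    out = wide.reset_index()[["tracer", "metabolite"]]
    out["fe1"] = wide[condition1].to_numpy()
    out["fe2"] = wide[condition2].to_numpy()
    f1 = np.clip(out["fe1"].to_numpy(), 0.0, 1.0)
    f2 = np.clip(out["fe2"].to_numpy(), 0.0, 1.0)
    out["score"] = np.abs(np.log(np.maximum(f1, DLS_EPS) / np.maximum(f2, DLS_EPS))) * (
        out["fe1"].to_numpy() - out["fe2"].to_numpy()
    )
    return rank_waterfall(out)


def rank_waterfall(records: pd.DataFrame) -> pd.DataFrame:
    """Order score records descending by score, ties broken lexicographically
    by (tracer, metabolite) for determinism, and assign ranks 1..N."""
    if records.empty:
        raise ValueError("no records to rank")
    out = records.sort_values(
        by=["score", "tracer", "metabolite"], ascending=[False, True, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def build_sankey_flows(
    enrichment: pd.DataFrame,
    pathway_map: pd.DataFrame,
    condition: str,
    threshold: float = 5.0,
    kept: set | None = None,
) -> pd.DataFrame:
    """Tracer -> pathway-representative edges for one condition.

    ``pathway_map`` is the metabolite catalog (metabolite, pathway,
    representative). Edge weight is the representative metabolite's total
    labelling fraction; edges strictly below ``threshold`` percent total
    labelling are excluded. Returns columns source (tracer), target
    (metabolite), pathway, value.
    """
    reps = pathway_map[pathway_map["representative"]]
    missing = set(reps["pathway"]) - set(pathway_map["pathway"])
    if missing:
        raise ValueError(f"representatives reference unknown pathway classes: {missing}")
    df = enrichment[(enrichment["condition"] == condition)
                    & (enrichment["tracer"] != UNLABELLED)]
    if kept is not None:
        df = df[df["metabolite"].isin(kept)]
    df = df.drop_duplicates(subset=["tracer", "metabolite"])
    df = df.merge(reps[["metabolite", "pathway"]], on="metabolite", how="inner")
    df = df[df["total_labelling"] * 100.0 >= threshold]
    edges = df.rename(columns={"tracer": "source", "metabolite": "target",
                               "total_labelling": "value"})
    edges = edges[["source", "target", "pathway", "value"]]
    # Stable rendering: order by total outgoing / incoming weight.
    src_w = edges.groupby("source")["value"].sum()
    tgt_w = edges.groupby("target")["value"].sum()
    edges = edges.assign(
        _sw=edges["source"].map(src_w), _tw=edges["target"].map(tgt_w)
    ).sort_values(by=["_sw", "source", "_tw", "target"],
                  ascending=[False, True, False, True]).drop(columns=["_sw", "_tw"])
    return edges.reset_index(drop=True)


def sankey_to_json(edges: pd.DataFrame) -> dict:
    """Convert an edge table to a nodes[]/links[] document consumable by
    standard Sankey renderers (source/target as node indices)."""
    sources = list(dict.fromkeys(edges["source"]))
    targets = list(dict.fromkeys(edges["target"]))
    nodes = [{"name": s, "side": "tracer"} for s in sources] + [
        {"name": t, "side": "metabolite"} for t in targets
    ]
    index = {(n["name"], n["side"]): i for i, n in enumerate(nodes)}
    links = [
        {
            "source": index[(row.source, "tracer")],
            "target": index[(row.target, "metabolite")],
            "value": float(row.value),
        }
        for row in edges.itertuples()
    ]
    return {"nodes": nodes, "links": links}


def render_sankey(edges: pd.DataFrame, path=None):
    """Minimal static ribbon rendering of a Sankey flow set with
    matplotlib; returns the figure (saved to ``path`` when given)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import PathPatch
    from matplotlib.path import Path as MplPath

    sources = list(dict.fromkeys(edges["source"]))
    targets = list(dict.fromkeys(edges["target"]))
    fig, ax = plt.subplots(figsize=(8, max(3, 0.3 * max(len(sources), len(targets)))))
    sy = {s: i for i, s in enumerate(sources)}
    ty = {t: i for i, t in enumerate(targets)}
    for row in edges.itertuples():
        y0, y1 = sy[row.source], ty[row.target]
        verts = [(0, y0), (0.5, y0), (0.5, y1), (1, y1)]
        codes = [MplPath.MOVETO, MplPath.CURVE4, MplPath.CURVE4, MplPath.CURVE4]
        ax.add_patch(PathPatch(MplPath(verts, codes), fill=False,
                               lw=1 + 10 * row.value, alpha=0.5))
    for s, y in sy.items():
        ax.text(-0.02, y, s, ha="right", va="center", fontsize=7)
    for t, y in ty.items():
        ax.text(1.02, y, t, ha="left", va="center", fontsize=7)
    ax.set_xlim(-0.4, 1.4)
    ax.set_ylim(-1, max(len(sources), len(targets)))
    ax.axis("off")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
    return fig
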