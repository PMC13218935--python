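"""Condition x tracer x metabolite enrichment tables and derived
normalisations.

``sample_enrichment`` corrects every (sample, metabolite) isotopologue
vector for natural abundance and converts it to fractional enrichments;
``build_enrichment_table`` averages those per-sample enrichments across
replicates (mean and s.e.m. of per-sample FEs, not FE of summed
intensities, so error bars reflect replicate variation). Total labelling is
1 - FE(M+0): the fraction of the pool carrying at least one tracer-derived
heavy atom, the primary readout for multi-atom tracers.
"""

from __future__ import annotations

import logging
from functools import lru_cache

import numpy as np
import pandas as pd

from .isotope_chem import IsotopeAbundanceTable, correction_matrix, parse_formula
from .na_correction import correct_many
from .tables_io import UNLABELLED

__all__ = [
    "sample_enrichment",
    "build_enrichment_table",
    "normalize_to_precursor",
    "rowmax_normalize",
    "timecourse_auc",
]

logger = logging.getLogger(__name__)


@lru_cache(maxsize=512)
def _matrix_for(formula: str, mode: str, tracer_element: str) -> np.ndarray:
    table = IsotopeAbundanceTable.default(tracer_element=tracer_element)
    return correction_matrix(parse_formula(formula), table, mode=mode)


def sample_enrichment(
    records: pd.DataFrame,
    catalog: pd.DataFrame,
    mode: str = "resolved",
    tracer_element: str = "N",
    correct: bool = True,
) -> pd.DataFrame:
    """Per-sample corrected fractional enrichments, long format.

    Returns columns sample, condition, tracer, metabolite, k, fe,
    total_labelling, is_control. Samples in which a metabolite has all-zero
    intensities are dropped for that metabolite (the replicate does not
    contribute). Metabolites without the tracer element carry a single
    M+0 row with total labelling 0.
    """
    formulas = dict(zip(catalog["metabolite"], catalog["formula"]))
    unknown = set(records["metabolite"]) - set(formulas)
    if unknown:
        raise ValueError(f"metabolites missing from catalog: {sorted(unknown)[:5]}")
    meta_cols = ["sample", "condition", "tracer"]
    sample_meta = records[meta_cols].drop_duplicates().set_index("sample")
    out_frames = []
    for met, grp in records.groupby("metabolite", sort=True):
        n_atoms = parse_formula(formulas[met]).count(tracer_element)
        width = n_atoms + 1
        pivot = (
            grp.pivot_table(index="sample", columns="k", values="intensity",
                            aggfunc="sum", fill_value=0.0)
            .reindex(columns=range(width), fill_value=0.0)
        )
        obs = pivot.to_numpy(dtype=float)
        if n_atoms == 0 or not correct:
            totals = obs.sum(axis=1)
            with np.errstate(invalid="ignore"):
                fracs = np.where(totals[:, None] > 0, obs / np.where(totals[:, None] > 0, totals[:, None], 1.0), np.nan)
        else:
            fracs, _ = correct_many(obs, _matrix_for(formulas[met], mode, tracer_element))
        keep = ~np.isnan(fracs[:, 0])
        if not keep.any():
            continue
        samples = pivot.index.to_numpy()[keep]
        fr = fracs[keep]
        n_rows, n_k = fr.shape
        frame = pd.DataFrame({
            "sample": np.repeat(samples, n_k),
            "metabolite": met,
            "k": np.tile(np.arange(n_k), n_rows),
            "fe": fr.ravel(),
            "total_labelling": np.repeat(1.0 - fr[:, 0], n_k),
        })
        out_frames.append(frame)
    if not out_frames:
        return pd.DataFrame(columns=["sample", "condition", "tracer", "metabolite",
                                     "k", "fe", "total_labelling", "is_control"])
    out = pd.concat(out_frames, ignore_index=True)
    out = out.join(sample_meta, on="sample")
    out["is_control"] = out["tracer"] == UNLABELLED
    return out[["sample", "condition", "tracer", "metabolite", "k", "fe",
                "total_labelling", "is_control"]]


def build_enrichment_table(
    records: pd.DataFrame,
    catalog: pd.DataFrame,
    registry: pd.DataFrame | None = None,
    mode: str = "resolved",
    tracer_element: str = "N",
    per_sample: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Replicate-averaged enrichment table.

    One row per (condition, tracer, metabolite, k) with fe_mean, fe_sem,
    total_labelling (mean across replicates), n (replicate count) and the
    is_control flag. Pass precomputed ``per_sample`` enrichments to avoid
    re-correcting.
    """
    if per_sample is None:
        per_sample = sample_enrichment(records, catalog, mode=mode,
                                       tracer_element=tracer_element)
    if per_sample.empty:
        return pd.DataFrame(columns=["condition", "tracer", "metabolite", "k",
                                     "fe_mean", "fe_sem", "total_labelling",
                                     "n", "is_control"])
    g = per_sample.groupby(["condition", "tracer", "metabolite", "k"], sort=True)
    agg = g.agg(
        fe_mean=("fe", "mean"),
        fe_sem=("fe", "sem"),
        total_labelling=("total_labelling", "mean"),
        n=("fe", "size"),
        is_control=("is_control", "first"),
    ).reset_index()
    agg["fe_sem"] = agg["fe_sem"].fillna(0.0)
    return agg


def normalize_to_precursor(product_value: float, precursor_fe: float) -> float:
    """Express a product's labelling relative to its precursor's cognate
    isotopologue FE (e.g. UMP M+1 over glutamine M+1). Values above 1 are
    reported as-is (logged), not clamped."""
    if precursor_fe <= 0:
        raise ValueError(f"precursor FE must be positive, got {precursor_fe}")
    ratio = product_value / precursor_fe
    if ratio > 1:
        logger.warning("precursor-normalized value %.3f exceeds 1", ratio)
    return ratio


def rowmax_normalize(values) -> np.ndarray:
    """Scale a set of per-condition values so the maximum becomes exactly 1."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.all(v <= 0):
        raise ValueError("rowmax_normalize needs at least one positive value")
    if np.any(v < 0):
        raise ValueError("negative enrichment value")
    return v / v.max()


def timecourse_auc(times, values) -> float:
    """Trapezoidal area under a labelling time course (FE x hours)."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("AUC needs at least 2 time points")
    if t.size != v.size:
        raise ValueError("times and values differ in length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(v, t))
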