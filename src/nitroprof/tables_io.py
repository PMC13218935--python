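"""Readers, writers and validation for peak tables, catalogs, tracer
registries and run configuration.

All tables are tidy (long-format) CSV/TSV with the delimiter inferred from
the file extension. The peak table has one row per
(sample, metabolite, isotopologue index) with columns::

    sample, condition, tracer, metabolite, k, intensity

``tracer`` is the tracer id of the medium the sample was cultured in; the
reserved id ``"unlabelled"`` marks tracer-free control samples. Undetected
isotopologues are simply absent (treated as zero downstream).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .isotope_chem import parse_formula

__all__ = [
    "UNLABELLED",
    "PEAK_COLUMNS",
    "ValidationError",
    "RunConfig",
    "read_peak_table",
    "read_catalog",
    "read_tracer_registry",
    "write_outputs",
]

UNLABELLED = "unlabelled"
PEAK_COLUMNS = ["sample", "condition", "tracer", "metabolite", "k", "intensity"]
CATALOG_COLUMNS = ["metabolite", "formula", "pathway", "representative"]
REGISTRY_COLUMNS = ["tracer", "nutrient", "n_labelled", "element"]


class ValidationError(ValueError):
    """Input table failed validation; the message names the offending row."""


def _read_delim(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def read_peak_table(path, catalog: pd.DataFrame | None = None,
                    registry: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate a long-format peak table.

    Checks: required columns present, intensities non-negative, isotopologue
    indices non-negative integers, (sample, metabolite, k) keys unique, and
    — when a catalog / registry is given — metabolite and tracer ids known
    and k within the metabolite's tracer-atom range.
    """
    df = _read_delim(path)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"peak table missing columns: {missing}")
    df = df[PEAK_COLUMNS].copy()
    df["k"] = df["k"].astype(int)
    df["intensity"] = df["intensity"].astype(float)
    bad = df[(df["intensity"] < 0) | (df["k"] < 0)]
    if not bad.empty:
        row = bad.iloc[0]
        raise ValidationError(
            f"negative intensity or isotopologue index in row "
            f"(sample={row['sample']!r}, metabolite={row['metabolite']!r}, k={row['k']})"
        )
    dup = df.duplicated(subset=["sample", "metabolite", "k"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate key (sample={row['sample']!r}, "
            f"metabolite={row['metabolite']!r}, k={row['k']})"
        )
    if catalog is not None:
        known = set(catalog["metabolite"])
        unknown = set(df["metabolite"]) - known
        if unknown:
            raise ValidationError(f"unknown metabolites: {sorted(unknown)[:5]}")
        n_atoms = {
            m: parse_formula(f).count("N")
            for m, f in zip(catalog["metabolite"], catalog["formula"])
        }
        over = df[df["k"] > df["metabolite"].map(n_atoms)]
        if not over.empty:
            row = over.iloc[0]
            raise ValidationError(
                f"isotopologue index k={row['k']} exceeds tracer-atom count "
                f"of metabolite {row['metabolite']!r}"
            )
    if registry is not None:
        known_tracers = set(registry["tracer"]) | {UNLABELLED}
        unknown = set(df["tracer"]) - known_tracers
        if unknown:
            raise ValidationError(f"unknown tracers: {sorted(unknown)[:5]}")
    return df


def read_catalog(path) -> pd.DataFrame:
    """Read a metabolite catalog (metabolite, formula, pathway,
    representative flag); every formula must parse and every pathway class
    must have at least one representative."""
    df = _read_delim(path)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"catalog missing columns: {missing}")
    df = df[CATALOG_COLUMNS].copy()
    df["representative"] = df["representative"].astype(bool)
    for _, row in df.iterrows():
        try:
            parse_formula(row["formula"])
        except ValueError as exc:
            raise ValidationError(
                f"metabolite {row['metabolite']!r}: unparseable formula "
                f"{row['formula']!r} ({exc})"
            ) from exc
    if df["metabolite"].duplicated().any():
        dup = df[df["metabolite"].duplicated()].iloc[0]["metabolite"]
        raise ValidationError(f"duplicate metabolite id {dup!r}")
    without_rep = set(df["pathway"]) - set(df.loc[df["representative"], "pathway"])
    if without_rep:
        raise ValidationError(
            f"pathway classes without a representative: {sorted(without_rep)}"
        )
    return df


def read_tracer_registry(path, catalog: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a tracer registry (tracer, nutrient, n_labelled, element);
    cross-checked against the catalog when given."""
    df = _read_delim(path)
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"registry missing columns: {missing}")
    df = df[REGISTRY_COLUMNS].copy()
    df["n_labelled"] = df["n_labelled"].astype(int)
    if (df["n_labelled"] < 1).any():
        bad = df[df["n_labelled"] < 1].iloc[0]
        raise ValidationError(f"tracer {bad['tracer']!r}: n_labelled must be >= 1")
    if df["tracer"].duplicated().any():
        dup = df[df["tracer"].duplicated()].iloc[0]["tracer"]
        raise ValidationError(f"duplicate tracer id {dup!r}")
    if catalog is not None:
        formulas = dict(zip(catalog["metabolite"], catalog["formula"]))
        for _, row in df.iterrows():
            if row["nutrient"] not in formulas:
                raise ValidationError(
                    f"tracer {row['tracer']!r}: nutrient {row['nutrient']!r} "
                    f"not in catalog"
                )
            avail = parse_formula(formulas[row["nutrient"]]).count(row["element"])
            if row["n_labelled"] > avail:
                raise ValidationError(
                    f"tracer {row['tracer']!r}: {row['n_labelled']} labelled "
                    f"{row['element']} atoms exceed the {avail} in "
                    f"{formulas[row['nutrient']]}"
                )
    return df


@dataclass
class RunConfig:
    """Pipeline run configuration (filter thresholds, correction mode,
    Sankey threshold, seed, output directory)."""

    min_samples_quantified: int = 2
    pool_size_threshold: float = 2e6
    min_summed_labelling: float = 1.0     # percent
    max_unlabelled_labelling: float = 3.0  # percent
    max_summed_labelling: float = 500.0    # percent
    labelling_aggregate: str = "sum"       # "sum" or "max" across conditions
    correction_mode: str = "resolved"
    sankey_threshold: float = 5.0          # percent total labelling
    condition1: str | None = None
    condition2: str | None = None
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("pool_size_threshold", "min_summed_labelling",
                     "max_unlabelled_labelling", "max_summed_labelling",
                     "sankey_threshold"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.min_summed_labelling >= self.max_summed_labelling:
            raise ValidationError("min_summed_labelling must be < max_summed_labelling")
        self.seed = int(self.seed)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yml", ".yaml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**(data or {}))

    def to_dict(self) -> dict:
        return asdict(self)


def write_outputs(results: dict, directory) -> list[Path]:
    """Write the deterministic output file set for one pipeline run.

    ``results`` may contain ``enrichment``, ``filter_report``, ``scores``
    (DataFrames), ``sankey`` (dict with ``nodes`` and ``links``) and ``log``
    (list of (level, stage, message) tuples). Missing pieces yield
    headers-only files so the file set is stable. Identical inputs give
    byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_df(key: str, filename: str, columns: list[str]) -> None:
        df = results.get(key)
        if df is None:
            df = pd.DataFrame(columns=columns)
        p = directory / filename
        df.to_csv(p, index=False, float_format="%.10g")
        written.append(p)

    _write_df("enrichment", "enrichment.csv",
              ["condition", "tracer", "metabolite", "k", "fe_mean", "fe_sem",
               "total_labelling", "n"])
    _write_df("filter_report", "filter_report.csv",
              ["metabolite", "status", "reasons"])
    _write_df("scores", "scores.csv",
              ["tracer", "metabolite", "fe1", "fe2", "score", "rank"])
    sankey = results.get("sankey") or {"nodes": [], "links": []}
    edges = pd.DataFrame(sankey["links"], columns=["source", "target", "value"])
    p = directory / "sankey_edges.csv"
    edges.to_csv(p, index=False, float_format="%.10g")
    written.append(p)
    p = directory / "sankey.json"
    p.write_text(json.dumps(sankey, indent=1, sort_keys=True) + "\n")
    written.append(p)
    log = results.get("log", [])
    (directory / "run.log").write_text(
        "".join(f"{level}\t{stage}\t{message}\n" for level, stage, message in log)
    )
    return written
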