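"""Synthetic tracer-experiment generator with known ground truth.

Emulates a parallelised 15N tracing panel: a library of 30 media stocks,
each replacing one nitrogenous nutrient with its heavy-isotope
counterpart, traced into a catalog of >100 nitrogen-containing
metabolites across two paired culture conditions, plus tracer-free control
samples. The generative model per (condition, tracer, metabolite) is

    true fractions -> forward natural-abundance convolution
                   -> pool-size scaling -> multiplicative lognormal noise,

so the correction/enrichment pipeline can be tested against planted
transfer fractions exactly. Transfer has two channels mirroring real
nitrogen exchange: ``single`` places the planted fraction at M+1
(transamination-like single-nitrogen transfer) and ``intact`` at M+m for an
m-atom tracer (salvage-like intact-moiety incorporation, e.g.
15N2-uridine -> UMP M+2). Every tracer labels its own metabolite pool in
every tracer condition (cognate transfer), and controls are generated with
zero transfer everywhere.

The packaged tracer registry and metabolite catalog are synthetic
stand-ins assembled from the standard coverage of nitrogen metabolism
(amino acids and derivatives, nucleotides, urea cycle, polyamines, redox,
NAD, creatine, amino sugars); identities beyond the enumerated tracer
classes are illustrative, not a published list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .isotope_chem import IsotopeAbundanceTable, correction_matrix, parse_formula
from .tables_io import UNLABELLED, read_catalog, read_tracer_registry

__all__ = [
    "GroundTruthModel",
    "default_tracer_registry",
    "default_catalog",
    "default_model",
    "plant_differential_flow",
    "simulate_peak_table",
    "simulate_pixel_grid",
    "simulate_timecourse",
]


def _data_path(name: str):
    return resources.files("nitroprof.data").joinpath(name)


def default_tracer_registry() -> pd.DataFrame:
    """The 30-stock tracer library: all 20 proteinogenic amino acids,
    taurine, ornithine, citrulline, hypoxanthine, uridine, nitrate,
    ammonium, urea, urate, and the amide-15N glutamine positional variant."""
    with resources.as_file(_data_path("tracer_registry.csv")) as p:
        reg = read_tracer_registry(p, catalog=default_catalog())
        raw = pd.read_csv(p)
    reg = reg.merge(raw[["tracer", "proteinogenic"]], on="tracer")
    reg["proteinogenic"] = reg["proteinogenic"].astype(bool)
    return reg


def default_catalog() -> pd.DataFrame:
    """Packaged catalog of >100 nitrogenous metabolites with formulas,
    pathway classes and pathway representatives."""
    with resources.as_file(_data_path("metabolite_catalog.csv")) as p:
        return read_catalog(p)


@dataclass
class GroundTruthModel:
    """Planted ground truth for a two-condition tracer panel.

    ``transfers`` maps (tracer, metabolite, condition) to a
    (fraction, channel) pair: the planted total-labelling fraction and the
    transfer channel (``"single"`` -> M+1, ``"intact"`` -> M+m). Pool sizes
    are per-metabolite mean total intensities; noise is multiplicative
    lognormal with the given CV on every isotopologue intensity.
    """

    registry: pd.DataFrame
    catalog: pd.DataFrame
    conditions: tuple = ("A", "B")
    transfers: dict = field(default_factory=dict)
    pool_mean: float = 1e7
    noise_cv: float = 0.10
    seed: int = 0
    correction_mode: str = "resolved"
    tracer_element: str = "N"

    def __post_init__(self) -> None:
        for (tracer, met, cond), (frac, channel) in self.transfers.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"transfer fraction {frac} outside [0, 1]")
            if channel not in ("single", "intact"):
                raise ValueError(f"unknown transfer channel {channel!r}")


def default_model(conditions=("A", "B"), cognate_fraction: float = 0.7,
                  noise_cv: float = 0.10, seed: int = 0) -> GroundTruthModel:
    """Model with cognate transfers only: each tracer labels its own
    nutrient pool (intact channel) in every condition."""
    registry = default_tracer_registry()
    catalog = default_catalog()
    transfers = {}
    for row in registry.itertuples():
        for cond in conditions:
            transfers[(row.tracer, row.nutrient, cond)] = (cognate_fraction, "intact")
    return GroundTruthModel(registry=registry, catalog=catalog,
                            conditions=tuple(conditions), transfers=transfers,
                            noise_cv=noise_cv, seed=seed)


def plant_differential_flow(model: GroundTruthModel, tracer: str, metabolite: str,
                            fe_condition1: float, fe_condition2: float,
                            channel: str = "single") -> GroundTruthModel:
    """Plant a condition-specific labelling difference for one
    tracer-metabolite pair; the ground-truth differential labelling score
    follows analytically from the planted fractions."""
    if tracer not in set(model.registry["tracer"]):
        raise ValueError(f"unknown tracer {tracer!r}")
    if metabolite not in set(model.catalog["metabolite"]):
        raise ValueError(f"unknown metabolite {metabolite!r}")
    for fe in (fe_condition1, fe_condition2):
        if not 0.0 <= fe <= 1.0:
            raise ValueError(f"planted fraction {fe} outside [0, 1]")
    c1, c2 = model.conditions[:2]
    model.transfers[(tracer, metabolite, c1)] = (fe_condition1, channel)
    model.transfers[(tracer, metabolite, c2)] = (fe_condition2, channel)
    return model


def _true_fractions(n_atoms: int, frac: float, channel: str, m_labelled: int) -> np.ndarray:
    x = np.zeros(n_atoms + 1)
    shift = 1 if channel == "single" else min(m_labelled, n_atoms)
    x[shift] = frac
    x[0] = 1.0 - frac
    return x


def simulate_peak_table(model: GroundTruthModel, n_replicates: int = 1,
                        include_unlabelled_control: bool = True) -> pd.DataFrame:
    """Generate a long-format peak table for the full panel.

    One sample per (condition, tracer, replicate), plus tracer-free
    controls per condition when requested. Pure function of
    (model, model.seed): identical models give identical tables.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(model.seed)
    table = IsotopeAbundanceTable.default(tracer_element=model.tracer_element)
    sigma = float(np.sqrt(np.log(1.0 + model.noise_cv ** 2)))

    mets, n_atoms, offsets, nat = [], {}, {}, []
    matrices = {}
    off = 0
    for row in model.catalog.itertuples():
        n = parse_formula(row.formula).count(model.tracer_element)
        if n == 0:
            continue
        C = correction_matrix(parse_formula(row.formula), table,
                              mode=model.correction_mode)
        matrices[row.metabolite] = C
        mets.append(row.metabolite)
        n_atoms[row.metabolite] = n
        offsets[row.metabolite] = off
        nat.append(C[:, 0])
        off += n + 1
    base_spec = np.concatenate(nat)
    met_col = np.concatenate([[m] * (n_atoms[m] + 1) for m in mets])
    k_col = np.concatenate([np.arange(n_atoms[m] + 1) for m in mets])

    m_labelled = dict(zip(model.registry["tracer"], model.registry["n_labelled"]))
    tracers = list(model.registry["tracer"])
    samples = []
    for cond in model.conditions:
        for tracer in tracers:
            for rep in range(1, n_replicates + 1):
                samples.append((f"{cond}_{tracer}_r{rep}", cond, tracer))
        if include_unlabelled_control:
            for rep in range(1, n_replicates + 1):
                samples.append((f"{cond}_{UNLABELLED}_r{rep}", cond, UNLABELLED))

    frames = []
    for sample_id, cond, tracer in samples:
        spec = base_spec.copy()
        if tracer != UNLABELLED:
            for met in mets:
                t = model.transfers.get((tracer, met, cond))
                if t is None or t[0] == 0.0:
                    continue
                frac, channel = t
                x = _true_fractions(n_atoms[met], frac, channel, m_labelled[tracer])
                o = offsets[met]
                spec[o:o + n_atoms[met] + 1] = matrices[met] @ x
        noise = (np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=spec.size))
                 if model.noise_cv > 0 else 1.0)
        frames.append(pd.DataFrame({
            "sample": sample_id,
            "condition": cond,
            "tracer": tracer,
            "metabolite": met_col,
            "k": k_col,
            "intensity": model.pool_mean * spec * noise,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out[out["intensity"] > 0].reset_index(drop=True)


def simulate_pixel_grid(formula: str, width: int, height: int,
                        regions: list, pool: float = 1e5,
                        noise_cv: float = 0.05, seed: int = 0,
                        shift: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Two-dimensional imaging phantom with region-specific planted FEs.

    ``regions`` is a list of (mask, fe) pairs whose boolean masks of shape
    (height, width) must partition the grid (no overlap, full cover). The
    planted fraction ``fe`` is placed at isotopologue M+``shift``. Returns
    (grid, truth): the noisy observed grid of shape (height, width, n+1)
    and the per-pixel planted FE image.
    """
    rng = np.random.default_rng(seed)
    f = parse_formula(formula)
    C = correction_matrix(f)
    n = C.shape[0] - 1
    if not 1 <= shift <= n:
        raise ValueError(f"shift {shift} outside 1..{n}")
    cover = np.zeros((height, width), dtype=int)
    for mask, _ in regions:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (height, width):
            raise ValueError("region mask shape does not match the grid")
        cover += mask
    if np.any(cover > 1):
        raise ValueError("region masks overlap")
    if np.any(cover == 0):
        raise ValueError("region masks do not cover the grid")
    truth = np.zeros((height, width))
    grid = np.zeros((height, width, n + 1))
    sigma = float(np.sqrt(np.log(1.0 + noise_cv ** 2))) if noise_cv > 0 else 0.0
    for mask, fe in regions:
        mask = np.asarray(mask, dtype=bool)
        if not 0.0 <= fe <= 1.0:
            raise ValueError(f"planted FE {fe} outside [0, 1]")
        x = np.zeros(n + 1)
        x[shift] = fe
        x[0] = 1.0 - fe
        truth[mask] = fe
        grid[mask] = pool * (C @ x)
    if sigma > 0:
        grid *= np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=grid.shape))
    return grid, truth


def simulate_timecourse(times, saturating_fe: float, rate: float,
                        noise_cv: float = 0.0, seed: int = 0) -> np.ndarray:
    """Saturating exponential labelling time course
    FE(t) = saturating_fe * (1 - exp(-rate * t)), with optional
    multiplicative lognormal noise."""
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if not 0.0 <= saturating_fe <= 1.0:
        raise ValueError("saturating FE outside [0, 1]")
    fe = saturating_fe * (1.0 - np.exp(-rate * t))
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log(1.0 + noise_cv ** 2)))
        rng = np.random.default_rng(seed)
        fe = fe * np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=fe.shape))
    return fe
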