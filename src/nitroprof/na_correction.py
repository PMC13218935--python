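"""Natural-abundance correction of observed isotopologue intensities.

The observed isotopologue spectrum ``m`` of a metabolite is modelled as the
convolution of the true labelling state with natural isotope abundance:
``m = C x`` where column ``j`` of the correction matrix ``C`` is the
theoretical spectrum of a molecule carrying exactly ``j`` tracer atoms
(:func:`nitroprof.isotope_chem.correction_matrix`) and ``x`` holds the true
fractions of each labelling state. Correction recovers ``x`` by solving the
linear system with a non-negativity constraint,

    minimise ||C x - m||_2  subject to  x >= 0,

then renormalising ``x`` to sum to 1. The forward direction
(:func:`forward_convolve`) is the generative model used by the synthetic-data
generator and serves as the round-trip oracle for the inverse.

For speed on whole sample tables and pixel grids the resolved-mode system is
first solved exactly by triangular back-substitution (``C`` is lower
triangular with positive diagonal); only spectra that noise drives to a
meaningfully negative solution are re-solved with NNLS, so the constrained
solve is used exactly where the constraint binds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import nnls

__all__ = [
    "EnrichmentVector",
    "forward_convolve",
    "correct_vector",
    "correct_many",
    "fractional_enrichment",
    "correct_pixel_grid",
    "NaturalAbundanceCorrector",
]

_NEG_TOL = 1e-10


@dataclass
class EnrichmentVector:
    """Fractional enrichments over M+0..M+n plus derived total labelling.

    ``fractions`` sum to 1; ``total_labelling = 1 - fractions[0]`` is the
    fraction of the pool carrying at least one tracer-derived heavy atom.
    ``residual`` is the correction residual norm (QC; 0 for uncorrected
    data).
    """

    fractions: np.ndarray
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)

    @property
    def total_labelling(self) -> float:
        return float(1.0 - self.fractions[0])


def forward_convolve(true_fractions: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Predict the observed isotopologue spectrum from true labelling
    fractions: ``matrix @ true_fractions`` (unit total in resolved mode)."""
    x = np.asarray(true_fractions, dtype=float)
    if np.any(x < 0):
        raise ValueError("fractions must be non-negative")
    if abs(x.sum() - 1.0) > 1e-6:
        raise ValueError(f"fractions sum to {x.sum()}, expected 1")
    if matrix.shape[1] != x.size:
        raise ValueError(
            f"dimension mismatch: matrix has {matrix.shape[1]} columns, "
            f"fractions length {x.size}"
        )
    return matrix @ x


def _solve_one(matrix: np.ndarray, observed: np.ndarray) -> tuple[np.ndarray, float]:
    x, res = nnls(matrix, observed)
    return x, float(res)


def correct_vector(observed: np.ndarray, matrix: np.ndarray) -> EnrichmentVector:
    """Invert natural abundance for one observed isotopologue vector.

    Solves the non-negatively constrained linear system and renormalises
    the solution to sum to 1. Raises on an all-zero input or a dimension
    mismatch.
    """
    m = np.asarray(observed, dtype=float)
    if m.ndim != 1 or m.size != matrix.shape[0]:
        raise ValueError(
            f"dimension mismatch: observed length {m.size}, "
            f"matrix {matrix.shape}"
        )
    if not np.any(m > 0):
        raise ValueError("all-zero observed vector cannot be corrected")
    x, res = _solve_one(matrix, m)
    total = x.sum()
    if total <= 0:
        raise ValueError("degenerate correction: solution sums to zero")
    return EnrichmentVector(x / total, residual=res)


def correct_many(observed: np.ndarray, matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Correct many spectra sharing one matrix (rows of ``observed``).

    Returns ``(fractions, residuals)``; rows that are all zero come back as
    NaN rather than raising, so callers can mark them missing. Uses a
    vectorised triangular solve with per-row NNLS fallback when the
    unconstrained solution has a negative component.
    """
    obs = np.atleast_2d(np.asarray(observed, dtype=float))
    n_rows = obs.shape[0]
    fractions = np.full((n_rows, matrix.shape[1]), np.nan)
    residuals = np.zeros(n_rows)
    nonzero = np.any(obs > 0, axis=1)
    if not np.any(nonzero):
        return fractions, residuals
    square_lower = (
        matrix.shape[0] == matrix.shape[1]
        and np.allclose(matrix, np.tril(matrix))
        and np.all(np.diag(matrix) > 0)
    )
    idx = np.flatnonzero(nonzero)
    if square_lower:
        x = solve_triangular(matrix, obs[idx].T, lower=True).T
        bad = np.any(x < -_NEG_TOL * np.maximum(obs[idx].sum(axis=1, keepdims=True), 1.0), axis=1)
        x = np.clip(x, 0.0, None)
        for i in np.flatnonzero(bad):
            x[i], residuals[idx[i]] = _solve_one(matrix, obs[idx[i]])
    else:
        x = np.empty((idx.size, matrix.shape[1]))
        for i, r in enumerate(idx):
            x[i], residuals[r] = _solve_one(matrix, obs[r])
    totals = x.sum(axis=1)
    ok = totals > 0
    fractions[idx[ok]] = x[ok] / totals[ok, None]
    return fractions, residuals


def fractional_enrichment(intensities: np.ndarray) -> EnrichmentVector:
    """Fractions of total intensity per isotopologue (no correction):
    ``fraction_k = intensity_k / sum(intensities)``."""
    v = np.asarray(intensities, dtype=float)
    if v.size == 0 or not np.any(v > 0):
        raise ValueError("cannot compute enrichment of an empty or all-zero vector")
    if np.any(v < 0):
        raise ValueError("negative intensity")
    return EnrichmentVector(v / v.sum())


def correct_pixel_grid(grid: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Per-pixel natural-abundance correction of an imaging grid.

    ``grid`` has shape (height, width, n_isotopologues); the result has the
    same leading dimensions and holds fractional enrichments. Pixels with
    all-zero spectra become NaN (missing) rather than raising.
    """
    g = np.asarray(grid, dtype=float)
    if g.ndim != 3:
        raise ValueError("pixel grid must have shape (height, width, n_iso)")
    if g.shape[2] != matrix.shape[0]:
        raise ValueError(
            f"dimension mismatch: pixels have {g.shape[2]} isotopologues, "
            f"matrix {matrix.shape}"
        )
    h, w, k = g.shape
    flat = g.reshape(h * w, k)
    frac_nonzero = np.mean(np.any(flat > 0, axis=1))
    if frac_nonzero < 0.01:
        import logging

        logging.getLogger(__name__).warning(
            "pixel grid is %.1f%% nonzero; correction proceeds", 100 * frac_nonzero
        )
    fractions, _ = correct_many(flat, matrix)
    return fractions.reshape(h, w, matrix.shape[1])


class NaturalAbundanceCorrector:
    """sklearn-style transformer wrapping :func:`correct_many`.

    Parameters
    ----------
    formula : str
        Molecular formula of the metabolite (determines the matrix).
    mode : {"resolved", "unresolved"}
        Spectral resolution regime.
    tracer_element : str
        Traced element symbol, default ``"N"``.

    After :meth:`fit`, ``matrix_`` holds the correction matrix and
    ``n_isotopologues_`` its dimension. :meth:`transform` maps an array of
    observed spectra (rows) to corrected fraction rows.
    """

    def __init__(self, formula: str, mode: str = "resolved", tracer_element: str = "N"):
        self.formula = formula
        self.mode = mode
        self.tracer_element = tracer_element

    def get_params(self, deep: bool = True) -> dict:
        return {
            "formula": self.formula,
            "mode": self.mode,
            "tracer_element": self.tracer_element,
        }

    def set_params(self, **params) -> "NaturalAbundanceCorrector":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X=None, y=None) -> "NaturalAbundanceCorrector":
        from .isotope_chem import IsotopeAbundanceTable, correction_matrix, parse_formula

        table = IsotopeAbundanceTable.default(tracer_element=self.tracer_element)
        self.matrix_ = correction_matrix(parse_formula(self.formula), table, mode=self.mode)
        self.n_isotopologues_ = self.matrix_.shape[0]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "matrix_"):
            raise RuntimeError("NaturalAbundanceCorrector is not fitted")
        fractions, _ = correct_many(np.asarray(X, dtype=float), self.matrix_)
        return fractions

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).transform(X)
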