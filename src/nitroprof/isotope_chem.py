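"""Molecular formulas, natural isotope abundances and theoretical isotopologue
distributions.

A metabolite traced with a heavy-isotope nutrient (here ``15N``) produces a
mass spectrum whose isotopologue peaks M+0 ... M+n mix two signals: atoms
derived from the tracer, and naturally occurring heavy isotopes. This module
computes the *theoretical* isotopologue distribution of a molecule carrying
exactly ``j`` tracer-derived heavy atoms, and assembles those distributions
into the correction matrix whose inversion removes the natural-abundance
contribution (see :mod:`nitroprof.na_correction`).

Two resolution regimes are supported:

``resolved``
    The mass analyser separates the tracer isotopologue from isobaric
    natural-isotope interference of other elements (e.g. 15N from 13C at
    60,000+ FWHM). Only unlabelled tracer-element positions contribute:
    the distribution is the (n - j)-fold convolution of the tracer element's
    single-atom natural distribution, shifted by j — a binomial for a
    two-isotope element such as nitrogen.

``unresolved``
    Nominal-mass regime: the natural heavy-isotope distributions of all
    non-tracer elements are convolved in as well, truncated at a configured
    maximum shift.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Mapping

import numpy as np

__all__ = [
    "SUPPORTED_ELEMENTS",
    "MolecularFormula",
    "IsotopeAbundanceTable",
    "parse_formula",
    "labelled_distribution",
    "correction_matrix",
]

SUPPORTED_ELEMENTS = ("C", "H", "N", "O", "P", "S")

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or unsupported molecular formula strings."""


@dataclass(frozen=True)
class MolecularFormula:
    """Element -> atom-count map for a neutral molecule.

    Counts are non-negative integers; at least one element must be present.
    """

    elements: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.elements:
            raise FormulaError("formula contains no elements")
        for el, count in self.elements.items():
            if el not in SUPPORTED_ELEMENTS:
                raise FormulaError(f"unsupported element {el!r}")
            if not isinstance(count, (int, np.integer)) or count < 0:
                raise FormulaError(f"invalid count {count!r} for element {el!r}")

    def count(self, element: str) -> int:
        return int(self.elements.get(element, 0))

    def __str__(self) -> str:
        return "".join(
            f"{el}{self.elements[el] if self.elements[el] != 1 else ''}"
            for el in sorted(self.elements, key=lambda e: (e != "C", e != "H", e))
            if self.elements[el] > 0
        )


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation-like formula string, e.g. ``"C9H13N2O9P"``.

    Raises :class:`FormulaError` on empty input, malformed tokens or
    elements outside the supported set (C, H, N, O, P, S).
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    pos = 0
    counts: Dict[str, int] = {}
    for m in _TOKEN.finditer(text):
        if m.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in SUPPORTED_ELEMENTS:
            raise FormulaError(f"unsupported element {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text) or not counts:
        raise FormulaError(f"malformed formula {text!r}")
    return MolecularFormula(counts)


@dataclass
class IsotopeAbundanceTable:
    """Natural isotope abundances per element, indexed by nominal mass shift.

    ``distributions[el][k]`` is the abundance of the isotope of element
    ``el`` that is ``k`` nominal mass units above the lightest isotope.
    Each element's abundances must sum to 1 (within 1e-9) and include a
    shift-0 entry. ``tracer_element`` names the traced element (default N).
    """

    distributions: Dict[str, np.ndarray]
    tracer_element: str = "N"

    def __post_init__(self) -> None:
        for el, dist in self.distributions.items():
            dist = np.asarray(dist, dtype=float)
            self.distributions[el] = dist
            if dist.ndim != 1 or dist.size == 0 or dist[0] <= 0:
                raise ValueError(f"element {el}: shift-0 abundance missing")
            if np.any(dist < 0):
                raise ValueError(f"element {el}: negative abundance")
            if abs(dist.sum() - 1.0) > 1e-9:
                raise ValueError(f"element {el}: abundances sum to {dist.sum()}, not 1")
        if self.tracer_element not in self.distributions:
            raise ValueError(f"tracer element {self.tracer_element!r} not in table")

    @classmethod
    def from_csv(cls, path, tracer_element: str = "N") -> "IsotopeAbundanceTable":
        import pandas as pd

        df = pd.read_csv(path)
        dists: Dict[str, np.ndarray] = {}
        for el, grp in df.groupby("element"):
            arr = np.zeros(int(grp["shift"].max()) + 1)
            arr[grp["shift"].to_numpy(dtype=int)] = grp["abundance"].to_numpy(dtype=float)
            dists[str(el)] = arr
        return cls(dists, tracer_element=tracer_element)

    @classmethod
    def default(cls, tracer_element: str = "N") -> "IsotopeAbundanceTable":
        """Packaged IUPAC natural abundances for C, H, N, O, P, S."""
        ref = resources.files("nitroprof.data").joinpath("isotope_abundances.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path, tracer_element=tracer_element)


def _convolve_power(single: np.ndarray, count: int, max_len: int) -> np.ndarray:
    """``count``-fold self-convolution of a single-atom distribution,
    truncated to ``max_len`` entries (exponentiation by squaring)."""
    result = np.zeros(max_len)
    result[0] = 1.0
    base = single[:max_len].copy()
    k = count
    while k:
        if k & 1:
            result = np.convolve(result, base)[:max_len]
        k >>= 1
        if k:
            base = np.convolve(base, base)[:max_len]
    return result


def labelled_distribution(
    formula: MolecularFormula,
    j: int,
    table: IsotopeAbundanceTable | None = None,
    mode: str = "resolved",
    max_shift: int | None = None,
) -> np.ndarray:
    """Theoretical isotopologue distribution of a molecule carrying exactly
    ``j`` tracer-derived heavy atoms.

    Returns a probability vector over mass shifts 0..K where
    K = tracer-atom count (resolved mode) or ``max_shift`` (unresolved).
    Resolved-mode vectors sum to 1; unresolved-mode vectors may sum to
    less than 1 because of truncation.
    """
    table = table or IsotopeAbundanceTable.default()
    tracer = table.tracer_element
    n = formula.count(tracer)
    if n == 0:
        raise ValueError(f"formula {formula} lacks tracer element {tracer!r}")
    if not 0 <= j <= n:
        raise ValueError(f"labelled-atom count j={j} outside 0..{n}")
    if mode not in ("resolved", "unresolved"):
        raise ValueError(f"unknown mode {mode!r}")
    K = n if max_shift is None else int(max_shift)
    out_len = K + 1
    # Unlabelled tracer positions contribute natural heavy isotopes.
    dist = _convolve_power(table.distributions[tracer], n - j, out_len)
    if mode == "unresolved":
        for el, atom_count in formula.elements.items():
            if el == tracer or atom_count == 0:
                continue
            dist = np.convolve(dist, _convolve_power(table.distributions[el], atom_count, out_len))[:out_len]
    # Shift by j labelled positions.
    shifted = np.zeros(out_len)
    shifted[j:] = dist[: out_len - j]
    return shifted


def correction_matrix(
    formula: MolecularFormula,
    table: IsotopeAbundanceTable | None = None,
    mode: str = "resolved",
    max_shift: int | None = None,
) -> np.ndarray:
    """(n+1) x (n+1) matrix whose column ``j`` is the theoretical
    isotopologue distribution for ``j`` labelled tracer atoms.

    Resolved mode yields a lower-triangular matrix with unit column sums
    and strictly positive diagonal (hence invertible). Unresolved mode is
    truncated at shift n, keeping the matrix square.
    """
    table = table or IsotopeAbundanceTable.default()
    n = formula.count(table.tracer_element)
    if n == 0:
        raise ValueError(
            f"formula {formula} lacks tracer element {table.tracer_element!r}"
        )
    K = n if max_shift is None else int(max_shift)
    cols = [
        labelled_distribution(formula, j, table, mode=mode, max_shift=K)
        for j in range(n + 1)
    ]
    return np.column_stack(cols)
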