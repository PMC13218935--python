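"""Intensity normalisation and steady-state pool-size analysis.

Probabilistic quotient normalisation (PQN) rescales each sample by the
median ratio of its metabolite intensities to a reference spectrum (the
per-metabolite median across samples), correcting dilution-type variation
without distorting relative composition. Pool sizes (summed isotopologue
intensity per sample and metabolite) feed the pool-size filter and the
steady-state volcano contrast, which uses an unpaired t-test that switches
to Welch's form when an F test rejects equal variances at P < 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["pqn_normalize", "PQNNormalizer", "pool_sizes", "pool_contrast"]

logger = logging.getLogger(__name__)


def pqn_normalize(
    matrix: pd.DataFrame | np.ndarray, max_missing_frac: float = 0.5
) -> tuple[pd.DataFrame | np.ndarray, np.ndarray]:
    """Probabilistic quotient normalisation of a samples x metabolites matrix.

    Reference spectrum = per-metabolite median across samples; per-sample
    factor = median over metabolites of (sample value / reference);
    normalised value = value / factor. Metabolites missing (zero or NaN) in
    more than ``max_missing_frac`` of samples are excluded from quotient
    computation (they are still rescaled). Returns the normalised matrix
    and the per-sample factors.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PQN requires at least 2 samples")
    present = np.isfinite(X) & (X > 0)
    if np.any(~present.any(axis=1)):
        raise ValueError("all-zero sample cannot be normalised")
    usable = present.mean(axis=0) >= (1.0 - max_missing_frac)
    if not usable.all():
        logger.info("PQN: excluding %d metabolites missing in >%.0f%% of samples",
                    int((~usable).sum()), 100 * max_missing_frac)
    if not usable.any():
        raise ValueError("no metabolite is quantified in enough samples for PQN")
    with np.errstate(invalid="ignore", divide="ignore"):
        ref = np.nanmedian(np.where(present, X, np.nan), axis=0)
        quot = X[:, usable] / ref[usable]
        quot[~present[:, usable]] = np.nan
        factors = np.nanmedian(quot, axis=1)
    if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
        raise ValueError("degenerate PQN factors; check the reference spectrum")
    normalized = X / factors[:, None]
    if is_df:
        normalized = pd.DataFrame(normalized, index=matrix.index, columns=matrix.columns)
    return normalized, factors


class PQNNormalizer:
    """sklearn-style transformer for probabilistic quotient normalisation.

    ``fit`` learns the reference spectrum (per-metabolite median of the
    training samples, stored as ``reference_``); ``transform`` rescales new
    samples by their median quotient against that reference, so factors for
    unseen samples are comparable with the training run.
    """

    def __init__(self, max_missing_frac: float = 0.5):
        self.max_missing_frac = max_missing_frac

    def get_params(self, deep: bool = True) -> dict:
        return {"max_missing_frac": self.max_missing_frac}

    def set_params(self, **params) -> "PQNNormalizer":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "PQNNormalizer":
        A = np.asarray(X, dtype=float)
        if A.ndim != 2 or A.shape[0] < 2:
            raise ValueError("PQN requires at least 2 samples")
        present = np.isfinite(A) & (A > 0)
        self.usable_ = present.mean(axis=0) >= (1.0 - self.max_missing_frac)
        if not self.usable_.any():
            raise ValueError("no metabolite quantified in enough samples")
        self.reference_ = np.nanmedian(np.where(present, A, np.nan), axis=0)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "reference_"):
            raise RuntimeError("PQNNormalizer is not fitted")
        A = np.asarray(X, dtype=float)
        present = np.isfinite(A) & (A > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            quot = A[:, self.usable_] / self.reference_[self.usable_]
            quot[~present[:, self.usable_]] = np.nan
            factors = np.nanmedian(quot, axis=1)
        self.factors_ = factors
        return A / factors[:, None]

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)


def pool_sizes(records: pd.DataFrame) -> pd.DataFrame:
    """Total (summed-isotopologue) intensity per (sample, metabolite), with
    condition and tracer labels carried through.

    A metabolite absent from a sample simply has no row; per-metabolite
    means downstream are over the samples that quantified it.
    """
    if records.empty:
        return pd.DataFrame(columns=["sample", "condition", "tracer", "metabolite", "pool"])
    out = (
        records.groupby(["sample", "condition", "tracer", "metabolite"], sort=True)["intensity"]
        .sum()
        .reset_index()
        .rename(columns={"intensity": "pool"})
    )
    return out


def pool_contrast(pools_a: pd.DataFrame, pools_b: pd.DataFrame) -> pd.DataFrame:
    """Per-metabolite steady-state contrast between two conditions.

    For each metabolite quantified with n >= 2 in both groups: log2 fold
    change of means (A over B), t statistic and two-tailed p-value from an
    unpaired t-test — Student's form by default, Welch's form when an F test
    of variance equality gives P < 0.05. Returns columns
    metabolite, log2fc, t, p, test_form, n_a, n_b.
    """
    rows = []
    a_groups = pools_a.groupby("metabolite")["pool"]
    b_groups = dict(iter(pools_b.groupby("metabolite")["pool"]))
    for met, a_vals in a_groups:
        if met not in b_groups:
            continue
        a = a_vals.to_numpy(dtype=float)
        b = b_groups[met].to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"metabolite {met!r}: need >= 2 samples per group")
        mean_a, mean_b = a.mean(), b.mean()
        if mean_a <= 0 or mean_b <= 0:
            raise ValueError(f"metabolite {met!r}: non-positive group mean")
        var_a, var_b = a.var(ddof=1), b.var(ddof=1)
        welch = False
        if var_a > 0 and var_b > 0:
            f = var_a / var_b
            dfn, dfd = len(a) - 1, len(b) - 1
            p_f = 2 * min(stats.f.sf(f, dfn, dfd), stats.f.cdf(f, dfn, dfd))
            welch = p_f < 0.05
        if var_a == 0 and var_b == 0:
            # Degenerate: no within-group variation.
            t = 0.0 if mean_a == mean_b else np.sign(mean_a - mean_b) * np.inf
            p = 1.0 if mean_a == mean_b else 0.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append({
            "metabolite": met,
            "log2fc": float(np.log2(mean_a / mean_b)),
            "t": float(t),
            "p": float(p),
            "test_form": "welch" if welch else "student",
            "n_a": len(a),
            "n_b": len(b),
        })
    return pd.DataFrame(rows, columns=["metabolite", "log2fc", "t", "p", "test_form", "n_a", "n_b"])
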