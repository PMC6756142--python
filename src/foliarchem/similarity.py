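"""Sample-pair chemical similarity: CSCS and Bray-Curtis.

Chemical structural-compositional similarity (CSCS) weights the structural
similarity ``css_ij`` of every compound pair in the molecular network by the
compounds' relative ion intensities in two samples:

    CSCS(A, B) = sum_ij css_ij a_i b_j / max(sum_ij css_ij a_i a_j,
                                             sum_ij css_ij b_i b_j)

so distinct but structurally related compounds contribute even when the
samples share no compound.  Bray-Curtis similarity,
``2 * sum_i min(a_i, b_i) / sum_i (a_i + b_i)``, ignores structure and
responds only to shared compounds.  Both are computed on relative
intensities (rows normalised to sum to 1) so they are scale-free.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "normalize_relative",
    "cscs_pair",
    "bray_curtis_pair",
    "pairwise_matrix",
    "total_ion_intensity",
]

log = logging.getLogger(__name__)

Metric = Literal["CSCS", "BC"]


def _validate_table(table: pd.DataFrame) -> None:
    if table.index.has_duplicates:
        raise InputError("duplicate sample ids in feature table")
    if table.columns.has_duplicates:
        raise InputError("duplicate compound ids in feature table")
    if (table.to_numpy() < 0).any():
        raise InputError("negative intensities in feature table")


def normalize_relative(table: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample row to relative intensities summing to 1.

    Idempotent; preserves the zero pattern.  An all-zero row is an error
    naming the sample.
    """
    _validate_table(table)
    sums = table.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise InputError(f"all-zero sample row(s): {list(zero.index)}")
    return table.div(sums, axis=0)


def cscs_pair(a: np.ndarray, b: np.ndarray, css: pd.DataFrame | np.ndarray) -> float:
    """CSCS between two relative-intensity vectors on a shared compound index.

    The raw quotient can exceed 1 marginally when the css matrix is not
    positive semidefinite; values above 1 by more than 1e-9 are clamped with
    a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m = css.to_numpy() if isinstance(css, pd.DataFrame) else np.asarray(css, float)
    if a.shape != b.shape or m.shape != (a.size, a.size):
        raise InputError("compound index mismatch between vectors and css matrix")
    num = float(a @ m @ b)
    den = max(float(a @ m @ a), float(b @ m @ b))
    if den == 0.0:
        raise InputError("zero denominator: both samples empty under css")
    val = num / den
    if val > 1.0 + 1e-9:
        log.warning("raw CSCS %.12f exceeds 1; clamped", val)
    return float(min(max(val, 0.0), 1.0))


def bray_curtis_pair(a: np.ndarray, b: np.ndarray) -> float:
    """Bray-Curtis similarity ``2 sum min / sum (a+b)`` of two nonnegative vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError("vector length mismatch")
    if np.any(a < 0) or np.any(b < 0):
        raise InputError("negative intensities")
    tot = float(a.sum() + b.sum())
    if tot == 0.0:
        raise InputError("both vectors are all-zero")
    return 2.0 * float(np.minimum(a, b).sum()) / tot


def pairwise_matrix(table: pd.DataFrame, metric: Metric,
                    css: pd.DataFrame | None = None,
                    normalize: bool = True) -> pd.DataFrame:
    """Similarity matrix over all unordered sample pairs of a feature table.

    ``metric`` is "CSCS" (requires ``css``, aligned to the table's compound
    columns) or "BC".  Rows are normalised to relative intensities first
    unless ``normalize=False``.  For n samples the result holds n(n-1)/2
    distinct pair values; the matrix is symmetric with unit diagonal.
    """
    if metric not in ("CSCS", "BC"):
        raise ConfigurationError(f"unknown metric {metric!r}")
    if metric == "CSCS" and css is None:
        raise ConfigurationError("metric CSCS requires a css matrix")
    rel = normalize_relative(table) if normalize else table
    x = rel.to_numpy(dtype=float)
    n = x.shape[0]
    if metric == "CSCS":
        m = css.loc[table.columns, table.columns].to_numpy() \
            if isinstance(css, pd.DataFrame) else np.asarray(css, float)
        g = x @ m @ x.T                       # g[p, q] = sum_ij css_ij x_pi x_qj
        self_terms = np.diag(g)
        den = np.maximum(self_terms[:, None], self_terms[None, :])
        if np.any(self_terms <= 0):
            raise InputError("sample with zero self-similarity under css")
        sim = np.clip(g / den, 0.0, 1.0)
    else:
        tot = x.sum(axis=1)
        shared = np.empty((n, n))
        for p in range(n):
            shared[p] = np.minimum(x[p], x).sum(axis=1)
        sim = 2.0 * shared / (tot[:, None] + tot[None, :])
    sim = (sim + sim.T) / 2.0
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=table.index, columns=table.index)


def total_ion_intensity(table: pd.DataFrame) -> pd.Series:
    """Per-sample summed ion intensity of a raw (un-normalised) table."""
    _validate_table(table)
    return table.sum(axis=1)
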