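"""Factor effects on chemical similarity via constrained permutation.

For a factor (treatment, leaf age, species) the test statistic is
``delta = mean(within-factor pair similarity) - mean(between-factor pair
similarity)``, computed over sample pairs concordant for an optional control
factor.  Significance comes from randomising the factor labels across the
samples (control labels held fixed) and, after each shuffle, rejecting any
pair discordant for the control — the observed delta is compared against the
permuted deltas one-sidedly (within > between).  Species-level p-values are
combined across groups with the weighted-Z (Stouffer/Liptak) method, and
total-ion-intensity contrasts use a one-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InferenceError, InputError

__all__ = [
    "DeltaResult",
    "CombinedResult",
    "delta_statistic",
    "constrained_permutation_test",
    "weighted_z_combine",
    "wilcoxon_one_sided",
    "classical_mds",
]

log = logging.getLogger(__name__)

PMode = Literal["paper", "corrected"]


@dataclass
class DeltaResult:
    """Within-vs-between similarity contrast for one factor.

    ``delta = within_mean - between_mean``; positive values mean the factor
    structures the metabolome.  ``p_value`` follows ``p_mode``: "paper" is
    the strict proportion of permuted deltas larger than observed (can be 0),
    "corrected" is (count + 1) / (n_perm + 1).  Both are retained.
    """

    factor: str
    control: str | None
    within_mean: float
    between_mean: float
    n_within_pairs: int
    n_between_pairs: int
    delta: float = field(init=False)
    p_value: float | None = None
    p_paper: float | None = None
    p_corrected: float | None = None
    n_perm: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_within_pairs < 1 or self.n_between_pairs < 1:
            raise InferenceError(
                f"factor {self.factor!r}: empty within or between pair set")
        self.delta = self.within_mean - self.between_mean


def _align(sim: pd.DataFrame, meta: pd.DataFrame,
           subset: Sequence[str] | pd.Series | None) -> tuple[pd.DataFrame, pd.DataFrame]:
    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    if subset is not None:
        ids = [s for s in (subset.index[subset] if isinstance(subset, pd.Series) else subset)]
    else:
        ids = [s for s in sim.index if s in m.index]
    missing = [s for s in ids if s not in sim.index or s not in m.index]
    if missing:
        raise InputError(f"samples missing from similarity matrix or metadata: {missing}")
    return sim.loc[ids, ids], m.loc[ids]


def _pair_masks(labels: np.ndarray, keep: np.ndarray, iu: tuple[np.ndarray, np.ndarray],
                focal_level: str | None) -> tuple[np.ndarray, np.ndarray]:
    li, lj = labels[iu[0]], labels[iu[1]]
    same = li == lj
    if focal_level is None:
        return same & keep, ~same & keep
    fi, fj = li == focal_level, lj == focal_level
    return same & fi & keep, (fi ^ fj) & keep


def _delta_from_masks(vals: np.ndarray, within: np.ndarray,
                      between: np.ndarray) -> tuple[float, float, int, int] | None:
    nw, nb = int(within.sum()), int(between.sum())
    if nw == 0 or nb == 0:
        return None
    return float(vals[within].mean()), float(vals[between].mean()), nw, nb


def _setup(sim, meta, factor, control, subset, focal_level):
    s, m = _align(sim, meta, subset)
    labels = m[factor].to_numpy()
    if len(pd.unique(labels)) < 2:
        raise InferenceError(f"factor {factor!r} has fewer than 2 levels in subset")
    n = len(labels)
    iu = np.triu_indices(n, 1)
    if control is not None:
        c = m[control].to_numpy()
        keep = c[iu[0]] == c[iu[1]]
    else:
        keep = np.ones(iu[0].size, dtype=bool)
    vals = s.to_numpy()[iu]
    return labels, keep, iu, vals


def delta_statistic(sim: pd.DataFrame, meta: pd.DataFrame, factor: str,
                    control: str | None = None,
                    subset: Sequence[str] | pd.Series | None = None,
                    focal_level: str | None = None) -> DeltaResult:
    """Observed within-minus-between similarity contrast (no p-value).

    Within pairs are concordant for ``factor`` (and for ``control`` when
    given); between pairs are discordant for ``factor`` but concordant for
    ``control``.  With ``focal_level`` set, the contrast follows the
    focal-vs-congener design: within pairs are both at ``focal_level`` and
    between pairs join exactly one ``focal_level`` sample with one other —
    pairs of two distinct non-focal species are not compared.
    """
    labels, keep, iu, vals = _setup(sim, meta, factor, control, subset, focal_level)
    within, between = _pair_masks(labels, keep, iu, focal_level)
    res = _delta_from_masks(vals, within, between)
    if res is None:
        raise InferenceError(
            f"factor {factor!r}: empty within or between pair set after control filtering")
    wm, bm, nw, nb = res
    return DeltaResult(factor=factor, control=control, within_mean=wm,
                       between_mean=bm, n_within_pairs=nw, n_between_pairs=nb)


def constrained_permutation_test(sim: pd.DataFrame, meta: pd.DataFrame, factor: str,
                                 control: str | None = None,
                                 subset: Sequence[str] | pd.Series | None = None,
                                 focal_level: str | None = None,
                                 n_perm: int = 999, seed: int | None = None,
                                 p_mode: PMode = "corrected") -> DeltaResult:
    """Permutation test of the delta statistic with control-pair rejection.

    Factor labels are shuffled across the subset's samples (control labels
    fixed); after each shuffle, pairs discordant for the control are
    rejected exactly as in the observed statistic.  One-sided for
    within > between.  Permutations yielding an empty pair set are redrawn,
    capped at 100 x ``n_perm`` draws.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    labels, keep, iu, vals = _setup(sim, meta, factor, control, subset, focal_level)
    within, between = _pair_masks(labels, keep, iu, focal_level)
    obs = _delta_from_masks(vals, within, between)
    if obs is None:
        raise InferenceError(
            f"factor {factor!r}: empty within or between pair set after control filtering")
    wm, bm, nw, nb = obs
    observed_delta = wm - bm

    rng = np.random.default_rng(seed)
    larger = 0
    ties = 0
    draws = 0
    done = 0
    cap = 100 * n_perm
    while done < n_perm:
        if draws >= cap:
            raise InferenceError(
                f"factor {factor!r}: exceeded {cap} permutation draws with valid pair sets")
        perm = rng.permutation(labels)
        draws += 1
        res = _delta_from_masks(vals, *_pair_masks(perm, keep, iu, focal_level))
        if res is None:
            continue
        pw, pb, _, _ = res
        if pw - pb > observed_delta:
            larger += 1
        elif pw - pb == observed_delta:
            ties += 1
        done += 1

    # paper convention: strict "larger than" proportion (ties excluded).
    # corrected mode: ties belong in the tail (a permutation reproducing the
    # observed partition must not shrink p), plus the observed replicate.
    p_paper = larger / n_perm
    p_corrected = (larger + ties + 1) / (n_perm + 1)
    out = DeltaResult(factor=factor, control=control, within_mean=wm,
                      between_mean=bm, n_within_pairs=nw, n_between_pairs=nb)
    out.p_paper = p_paper
    out.p_corrected = p_corrected
    out.p_value = p_paper if p_mode == "paper" else p_corrected
    out.n_perm = n_perm
    out.seed = seed
    return out


@dataclass
class CombinedResult:
    """Weighted-Z combination of one-sided p-values across groups."""

    p_values: np.ndarray
    weights: np.ndarray
    z_scores: np.ndarray
    z_w: float
    p_combined: float


def weighted_z_combine(p_values: Sequence[float],
                       weights: Sequence[float] | None = None) -> CombinedResult:
    """Combine one-sided p-values: ``Z_w = sum(w_i Z_i) / sqrt(sum(w_i^2))``
    with ``Z_i = Phi^{-1}(1 - p_i)``; combined p is the upper normal tail."""
    p = np.asarray(p_values, dtype=float)
    w = np.ones_like(p) if weights is None else np.asarray(weights, dtype=float)
    if p.size == 0 or p.size != w.size:
        raise InputError("p_values and weights must be non-empty and equal length")
    if np.any((p <= 0) | (p >= 1)):
        raise InputError(
            "p-values must lie strictly in (0, 1); use the corrected permutation "
            "p-value mode ((count + 1) / (n_perm + 1)) to avoid exact 0 or 1")
    if np.any(w <= 0):
        raise InputError("weights must be positive")
    z = stats.norm.isf(p)
    z_w = float(w @ z / np.sqrt(w @ w))
    return CombinedResult(p_values=p, weights=w, z_scores=z, z_w=z_w,
                          p_combined=float(stats.norm.sf(z_w)))


def wilcoxon_one_sided(x: Sequence[float], y: Sequence[float]) -> float:
    """One-sided Wilcoxon rank-sum p-value for H1: x tends to be greater.

    Exact tail probability by enumerating all rank assignments when
    ``len(x) + len(y) <= 12`` and there are no ties; otherwise the normal
    approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    n, m = x.size, y.size
    no_ties = np.unique(pooled).size == pooled.size
    if n + m <= 12 and no_ties:
        ranks = stats.rankdata(pooled)
        w_obs = ranks[:n].sum()
        total = 0
        hits = 0
        for idx in combinations(range(n + m), n):
            total += 1
            if ranks[list(idx)].sum() >= w_obs - 1e-9:
                hits += 1
        return hits / total
    res = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic",
                             use_continuity=True)
    return float(res.pvalue)


def classical_mds(sim: pd.DataFrame, k: int = 2,
                  transform: Literal["one_minus", "sqrt"] = "one_minus") -> pd.DataFrame:
    """Classical (metric) MDS of a similarity matrix.

    Dissimilarity is ``1 - s`` (or ``sqrt(1 - s)``); the squared-distance
    matrix is double-centered and eigendecomposed, and coordinates come from
    the top-k positive eigenvalues.  Negative eigenvalues are dropped with a
    logged count; if fewer than k positive eigenvalues exist, fewer columns
    are returned with a warning.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    s = sim.to_numpy(dtype=float)
    d = 1.0 - s
    if transform == "sqrt":
        d = np.sqrt(np.clip(d, 0.0, None))
    n = d.shape[0]
    d2 = d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-9 * abs(evals[0])) if n else 0.0
    pos = evals > tol
    n_neg = int((evals < -tol).sum())
    if n_neg:
        log.info("classical_mds dropped %d negative eigenvalue(s)", n_neg)
    n_pos = int(pos.sum())
    if n_pos < k:
        log.warning("only %d positive eigenvalue(s); returning %d column(s)", n_pos, n_pos)
    kk = min(k, n_pos)
    coords = evecs[:, :kk] * np.sqrt(evals[:kk])
    return pd.DataFrame(coords, index=sim.index,
                        columns=[f"MDS{i+1}" for i in range(kk)])
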