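"""Shared statistical kernels.

Every stage of the pipeline funnels its inference through the small set of
primitives defined here: Benjamini-Hochberg FDR adjustment, (partial)
Spearman correlation, the hypergeometric over-representation tail, and a
two-group rank-sum test.  All operations are pure and deterministic; rank
ties use average ranks and ordering ties downstream are broken
lexicographically by feature identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankedGeneList",
    "bh_adjust",
    "partial_spearman",
    "hypergeometric_tail",
    "two_group_test",
]


@dataclass(frozen=True)
class RankedGeneList:
    """Gene identifiers ordered by descending score.

    The ordering is strict: score ties are broken by ascending gene id, so a
    given score vector always yields one canonical list.  Duplicated ids are
    rejected.
    """

    ids: tuple[str, ...]
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.scores):
            raise ValueError("ids and scores must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate gene ids in ranked list")
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))

    @classmethod
    def from_scores(cls, scores: pd.Series | dict) -> "RankedGeneList":
        """Build a canonical ranked list from a gene -> score mapping."""
        s = pd.Series(scores, dtype=float)
        order = sorted(s.index, key=lambda g: (-s[g], str(g)))
        return cls(ids=tuple(str(g) for g in order), scores=s.loc[order].to_numpy())

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": list(self.ids), "score": self.scores})


def bh_adjust(p, ids=None):
    """Benjamini-Hochberg step-up adjusted p-values (FDR q-values).

    Parameters
    ----------
    p : array-like of p-values in [0, 1].
    ids : optional sequence of identifiers; when given, a pandas Series
        indexed by ``ids`` is returned, otherwise a numpy array.  Input
        order is preserved either way.
    """
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if arr.size == 0:
        out = arr.copy()
    else:
        if np.any(np.isnan(arr)) or np.any((arr < 0) | (arr > 1)):
            raise ValueError("p-values must lie in [0, 1]")
        out = multipletests(arr, method="fdr_bh")[1]
    if ids is not None:
        return pd.Series(out, index=list(ids))
    return out


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero variance input to Spearman correlation")
    return float(np.clip(np.corrcoef(rx, ry)[0, 1], -1.0, 1.0))


def partial_spearman(x, y, z=None) -> float:
    """Partial Spearman correlation of ``x`` and ``y`` controlling for ``z``.

    Ranks all three vectors (average ranks on ties) and applies the
    first-order partial-correlation identity

        r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).

    Conventions: a constant ``z`` (or ``z=None``) falls back to the plain
    Spearman correlation of x and y; a constant x or y raises, because the
    correlation is undefined.  When z explains x or y exactly on the rank
    scale (denominator 0) the partial correlation is returned as 0.0 — the
    controlled-for covariate leaves no rankable signal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if z is None:
        return _spearman(x, y)
    z = np.asarray(z, dtype=float)
    if z.shape != x.shape:
        raise ValueError("z must match x and y in length")
    if np.all(z == z[0]):
        return _spearman(x, y)
    rx, ry, rz = sps.rankdata(x), sps.rankdata(y), sps.rankdata(z)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero variance input to partial Spearman correlation")
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xz = np.corrcoef(rx, rz)[0, 1]
    r_yz = np.corrcoef(ry, rz)[0, 1]
    denom_sq = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom_sq <= 0:
        return 0.0
    return float(np.clip((r_xy - r_xz * r_yz) / np.sqrt(denom_sq), -1.0, 1.0))


def partial_spearman_pvalue(r: float, n: int, n_controls: int = 1) -> float:
    """Two-sided p-value for a (partial) Spearman coefficient.

    Uses the t approximation with ``n - 2 - n_controls`` degrees of freedom.
    """
    df = n - 2 - n_controls
    if df <= 0:
        raise ValueError("not enough observations for a p-value")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df))


def hypergeometric_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for drawing ``n`` from ``N`` with ``K`` annotated.

    ``k`` successes among ``n`` draws without replacement from a universe of
    ``N`` objects of which ``K`` carry the annotation.
    """
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer")
    k, n, K, N = int(k), int(n), int(K), int(N)
    if not (k <= min(n, K) <= N and n <= N and K <= N):
        raise ValueError("inconsistent hypergeometric counts")
    if k == 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def two_group_test(a, b) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of two independent groups.

    Returns ``(statistic, p)`` where ``statistic = U_a - n_a n_b / 2`` is
    positive when values in ``a`` tend to exceed those in ``b``, and ``p``
    is two-sided.  Small tie-free samples use the exact null distribution
    (scipy's ``method='auto'``); larger samples use the normal approximation
    with continuity correction.  If every value is tied across both groups
    the test is uninformative and ``(0.0, 1.0)`` is returned by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("groups must be one-dimensional")
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs at least 3 observations")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    stat = float(res.statistic) - len(a) * len(b) / 2.0
    return stat, float(min(res.pvalue, 1.0))


def ranksum_rows(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise rank-sum test for feature matrices (features x samples).

    Vectorized counterpart of :func:`two_group_test` used by the
    differential stage; rows where every value is tied return (0, 1).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("matrices must share the feature axis")
    if a.shape[1] < 3 or b.shape[1] < 3:
        raise ValueError("each group needs at least 3 samples")
    pooled = np.concatenate([a, b], axis=1)
    flat = pooled == pooled[:, :1]
    all_tied = flat.all(axis=1)
    res = sps.mannwhitneyu(a, b, axis=1, alternative="two-sided", method="auto")
    stat = np.asarray(res.statistic, dtype=float) - a.shape[1] * b.shape[1] / 2.0
    p = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    stat[all_tied] = 0.0
    p[all_tied] = 1.0
    return stat, p
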