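"""Weighted Kolmogorov-Smirnov gene-set enrichment and the lncAut score.

Implements the three-step candidate screen for autophagy-related lncRNAs:

1. ``rs_rank_genes`` — rank all genes by the RS score of a candidate
   lncRNA, i.e. the tumor-purity-adjusted partial Spearman correlation
   between the lncRNA's expression and each gene's expression across tumor
   samples.
2. ``enrichment_score`` / ``gsea_significance`` — the classic weighted
   running-sum enrichment statistic of the gene set of differential
   autophagy genes in that ranked list, with a gene-label permutation null
   giving the nominal p, NES and a pooled-NES FDR across candidates.
3. ``lncaut_select`` — convert the nominal p to a lncAut score
   (lncAut = 1 - p) and select lncRNAs with lncAut > 0.9 and FDR < 0.05.

The permutation null reassigns set membership uniformly at random with the
set size preserved (gene-label permutation); the ranking itself is a
correlation profile per lncRNA, not a two-class phenotype, so phenotype
permutation does not apply.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import RankedGeneList, bh_adjust

__all__ = [
    "GseaResult",
    "enrichment_score",
    "gsea_significance",
    "nes_pooled_fdr",
    "rs_rank_genes",
    "lncaut_select",
]


@dataclass
class GseaResult:
    """Enrichment of one gene set in one ranked list."""

    es: float
    nes: float
    nominal_p: float
    n_perm: int
    seed: int | None = None
    fdr_q: float = np.nan
    null_es: np.ndarray = field(default=None, repr=False)

    @property
    def valid_nes(self) -> bool:
        return np.isfinite(self.nes)


def _running_sums(scores: np.ndarray, member: np.ndarray, weight: float) -> np.ndarray:
    """Running P_hit - P_miss for one or many membership vectors.

    ``member`` is boolean, shape (..., N) aligned to ``scores`` (already in
    ranked order).  Hit increments are |score|^weight normalized over the
    in-set total; miss increments are 1/(N - N_H).  A set whose in-set
    weight totals zero (all member scores zero) falls back to uniform hit
    increments 1/N_H.
    """
    member = np.atleast_2d(member).astype(bool)
    n = scores.shape[0]
    n_hit = member.sum(axis=1)
    if np.any(n_hit == 0):
        raise ValueError("gene set does not intersect the ranked list")
    if np.any(n_hit == n):
        raise ValueError("gene set covers the entire ranked list; P_miss undefined")
    w = np.abs(scores) ** weight
    hit_w = member * w
    tot = hit_w.sum(axis=1, keepdims=True)
    hit = np.divide(hit_w, tot, out=np.zeros_like(hit_w), where=tot > 0)
    uniform = (tot[:, 0] == 0)
    if np.any(uniform):
        hit[uniform] = member[uniform] / n_hit[uniform, None]
    miss = (~member) / (n - n_hit)[:, None]
    return np.cumsum(hit - miss, axis=1)


def _es_from_running(running: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(running), axis=1)
    return np.take_along_axis(running, idx[:, None], axis=1)[:, 0]


def enrichment_score(
    ranked: RankedGeneList, gene_set: Iterable[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Signed maximum deviation of the weighted running sum.

    Returns ``(ES, running_sum)``; ES is the running-sum value of largest
    magnitude (first occurrence on exact magnitude ties, hence
    deterministic).  Requires the set to intersect the list and to be a
    proper subset of it.
    """
    gene_set = set(gene_set)
    member = np.fromiter((g in gene_set for g in ranked.ids), dtype=bool, count=len(ranked))
    running = _running_sums(ranked.scores, member, weight)[0]
    return float(_es_from_running(running[None, :])[0]), running


def _permutation_null(
    scores: np.ndarray,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    weight: float,
    exhaustive: bool,
) -> np.ndarray:
    n = scores.shape[0]
    if exhaustive:
        combos = list(itertools.combinations(range(n), set_size))
        member = np.zeros((len(combos), n), dtype=bool)
        for i, c in enumerate(combos):
            member[i, list(c)] = True
    else:
        keys = rng.random((n_perm, n))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        member = np.zeros((n_perm, n), dtype=bool)
        np.put_along_axis(member, idx, True, axis=1)
    return _es_from_running(_running_sums(scores, member, weight))


def gsea_significance(
    ranked: RankedGeneList,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    weight: float = 1.0,
    exhaustive: bool = False,
) -> GseaResult:
    """Permutation significance of the enrichment score.

    The null reassigns set membership uniformly at random (set size
    preserved).  With ``exhaustive=True`` every possible membership is
    enumerated instead of sampled (feasible only for tiny lists; used by
    oracle tests).

    The nominal p uses the add-one estimator restricted to same-sign nulls:

        p = (1 + #{null ES of the same sign with |null| >= |ES|})
            / (1 + #{null ES of the same sign})

    NES is ES divided by the mean magnitude of same-sign null ES values.
    When no same-sign null exists, p = 1/(n_perm + 1) and NES is NaN
    (signalled via :attr:`GseaResult.valid_nes`).
    """
    if not exhaustive and n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    gene_set = set(gene_set)
    es, _ = enrichment_score(ranked, gene_set, weight=weight)
    set_size = sum(g in gene_set for g in ranked.ids)
    if rng is None:
        rng = np.random.default_rng(seed)
    null_es = _permutation_null(ranked.scores, set_size, n_perm, rng, weight, exhaustive)
    n_null = len(null_es)
    if es == 0:
        return GseaResult(es=0.0, nes=0.0, nominal_p=1.0, n_perm=n_null, seed=seed, null_es=null_es)
    same = null_es[np.sign(null_es) == np.sign(es)]
    if len(same) == 0:
        return GseaResult(
            es=es, nes=np.nan, nominal_p=1.0 / (n_null + 1), n_perm=n_null, seed=seed, null_es=null_es
        )
    p = (1 + int(np.sum(np.abs(same) >= abs(es)))) / (1 + len(same))
    nes = es / np.mean(np.abs(same))
    return GseaResult(es=es, nes=float(nes), nominal_p=float(p), n_perm=n_null, seed=seed, null_es=null_es)


def nes_pooled_fdr(results: list[GseaResult]) -> np.ndarray:
    """FDR q-values by the standard pooled-NES positive/negative procedure.

    Null ES values from every result's permutations are normalized by the
    same-sign null mean of their own result and pooled; for an observed
    NES* > 0,

        q = [#(pooled null NES >= NES*) / #(pooled null NES >= 0)]
            / [#(observed NES >= NES*) / #(observed NES >= 0)]

    and symmetrically for NES* < 0.  q is clipped to [0, 1] and made
    monotone non-decreasing as |NES| shrinks, separately per sign.
    Results with undefined NES receive q = 1.
    """
    obs = np.array([r.nes for r in results], dtype=float)
    pool = []
    for r in results:
        null = np.asarray(r.null_es, dtype=float)
        pos = null[null > 0]
        neg = null[null < 0]
        if len(pos):
            pool.append(pos / pos.mean())
        if len(neg):
            pool.append(neg / np.abs(neg).mean())
        if np.any(null == 0):
            pool.append(null[null == 0])
    pool = np.concatenate(pool) if pool else np.array([])
    q = np.ones_like(obs)
    finite = np.isfinite(obs)
    pool_pos = np.sum(pool >= 0)
    pool_neg = np.sum(pool <= 0)
    obs_pos = np.sum(obs[finite] >= 0)
    obs_neg = np.sum(obs[finite] <= 0)
    for i in np.flatnonzero(finite):
        v = obs[i]
        if v >= 0:
            num = np.sum(pool >= v) / pool_pos if pool_pos else 0.0
            den = np.sum(obs[finite] >= v) / obs_pos
        else:
            num = np.sum(pool <= v) / pool_neg if pool_neg else 0.0
            den = np.sum(obs[finite] <= v) / obs_neg
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    # monotone cleanup: a more extreme NES never has a larger q
    for sign in (1, -1):
        idx = np.flatnonzero(finite & (np.sign(obs) == sign))
        if len(idx) == 0:
            continue
        order = idx[np.argsort(-np.abs(obs[idx]))]
        q[order] = np.maximum.accumulate(q[order])
    for r, qi in zip(results, q):
        r.fdr_q = float(qi)
    return q


def rs_rank_genes(
    lnc_expr: pd.Series,
    gene_expr: pd.DataFrame,
    purity: pd.Series | None = None,
) -> RankedGeneList:
    """Rank genes by RS score for one candidate lncRNA.

    RS(g) is the partial Spearman correlation between the lncRNA's
    expression and gene g's expression across tumor samples, controlling
    for tumor purity.  A constant (or absent) purity vector reduces RS to
    the plain Spearman correlation.  Genes with constant expression, or
    whose ranks coincide exactly with purity, carry no adjustable signal
    and receive RS = 0.  Output is sorted by descending RS with ties broken
    by gene id.
    """
    samples = [s for s in gene_expr.columns if s in lnc_expr.index]
    if purity is not None:
        samples = [s for s in samples if s in purity.index]
    if len(samples) < 10:
        raise ValueError("need at least 10 shared tumor samples for RS ranking")
    x = lnc_expr.loc[samples].to_numpy(dtype=float)
    if np.all(x == x[0]):
        raise ValueError("constant lncRNA expression: no ranking possible")
    mat = gene_expr.loc[:, samples].to_numpy(dtype=float)
    n = len(samples)

    def _std_ranks(v: np.ndarray) -> np.ndarray:
        r = sps.rankdata(v, axis=-1)
        r = r - r.mean(axis=-1, keepdims=True)
        s = r.std(axis=-1, keepdims=True)
        return np.divide(r, s, out=np.zeros_like(r), where=s > 0)

    rl = _std_ranks(x)
    rg = _std_ranks(mat)
    r_lg = rg @ rl / n
    const_gene = np.all(mat == mat[:, :1], axis=1)
    if purity is None or np.all(purity.loc[samples].to_numpy() == purity.loc[samples].to_numpy()[0]):
        rs = r_lg
    else:
        rp = _std_ranks(purity.loc[samples].to_numpy(dtype=float))
        r_lp = float(rl @ rp / n)
        r_gp = rg @ rp / n
        denom_sq = (1.0 - r_lp**2) * (1.0 - r_gp**2)
        rs = np.where(denom_sq > 0, (r_lg - r_lp * r_gp) / np.sqrt(np.where(denom_sq > 0, denom_sq, 1.0)), 0.0)
    rs = np.clip(rs, -1.0, 1.0)
    rs[const_gene] = 0.0
    return RankedGeneList.from_scores(pd.Series(rs, index=gene_expr.index))


def lncaut_select(
    results: Mapping[str, GseaResult],
    threshold: float = 0.9,
    fdr_threshold: float = 0.05,
    fdr_method: str = "nes_pooled",
) -> pd.DataFrame:
    """Convert GSEA p-values to lncAut scores and select candidates.

    lncAut = 1 - nominal p; a lncRNA is selected iff lncAut > ``threshold``
    (strict) and its FDR q < ``fdr_threshold``.  FDR is the pooled-NES
    procedure by default; ``fdr_method='bh'`` applies Benjamini-Hochberg to
    the nominal p-values instead.
    """
    ids = sorted(results)
    res = [results[i] for i in ids]
    if fdr_method == "nes_pooled":
        q = nes_pooled_fdr(res)
    elif fdr_method == "bh":
        q = bh_adjust([r.nominal_p for r in res])
        for r, qi in zip(res, q):
            r.fdr_q = float(qi)
    else:
        raise ValueError(f"unknown fdr_method: {fdr_method!r}")
    out = pd.DataFrame(
        {
            "lncrna_id": ids,
            "es": [r.es for r in res],
            "nes": [r.nes for r in res],
            "nominal_p": [r.nominal_p for r in res],
            "fdr_q": np.asarray(q, dtype=float),
            "lncaut": [1.0 - r.nominal_p for r in res],
        }
    )
    out["selected"] = (out["lncaut"] > threshold) & (out["fdr_q"] < fdr_threshold)
    return out
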