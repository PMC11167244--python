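"""Stages 4-5: signed lncRNA-autophagy regulatory network and drug screen.

The network links each selected autophagy-related lncRNA to autophagy genes
through purity-adjusted Spearman correlation; an edge requires both a
minimum correlation magnitude and BH FDR < 0.05 across all tested pairs,
and carries the correlation's sign (positive = red / activating edge,
negative = blue / repressing edge).  One-sample Wilcoxon signed-rank tests
on a lncRNA's edge correlations over autophagy-promoting (AT+) versus
autophagy-inhibiting (AT-) genes classify it as autophagy-promoting or
-inhibiting.  Each lncRNA's edge partners form its target gene set, which
is then screened against per-drug perturbation signatures with the same
GSEA kernel used for lncAut scoring: a positive NES at FDR < 0.01 means the
drug induces the lncRNA's targets, a negative NES that it represses them.
A generic hypergeometric over-representation test rounds out the module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gsea import GseaResult, gsea_significance, nes_pooled_fdr, rs_rank_genes
from .stats import RankedGeneList, bh_adjust, hypergeometric_tail, partial_spearman_pvalue

__all__ = [
    "DrugSignature",
    "build_regulatory_network",
    "activator_inhibitor_test",
    "target_gene_set",
    "drug_lncrna_screen",
    "ora_enrichment",
    "to_graphml",
]


@dataclass(frozen=True)
class DrugSignature:
    """One drug's perturbation signature: genes ranked by differential
    expression under treatment, most up-regulated first."""

    drug_id: str
    ranking: RankedGeneList


def build_regulatory_network(
    selected_lncrnas: list[str],
    autophagy_genes: list[str],
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    purity: pd.Series | None = None,
    rho_threshold: float = 0.3,
    fdr_threshold: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signed co-expression edges between lncRNAs and autophagy genes.

    Returns ``(edges, tested)``: ``tested`` holds every (lncRNA, gene) pair
    with its purity-adjusted Spearman rho, p and BH fdr; ``edges`` is the
    subset with |rho| >= ``rho_threshold`` and fdr < ``fdr_threshold``,
    plus a ``sign`` column.  An empty lncRNA set yields an empty network
    with a warning.
    """
    selected_lncrnas = sorted(set(selected_lncrnas) & set(lnc_expr.index))
    genes = sorted(set(autophagy_genes) & set(gene_expr.index))
    cols = ["lncrna_id", "gene_id", "rho", "p", "fdr", "sign"]
    if not selected_lncrnas or not genes:
        warnings.warn("empty lncRNA or gene set: empty network")
        empty = pd.DataFrame(columns=cols)
        return empty, empty.copy()
    rows = []
    n_controls = 0 if purity is None else 1
    for lnc in selected_lncrnas:
        ranked = rs_rank_genes(lnc_expr.loc[lnc], gene_expr.loc[genes], purity)
        n = len([s for s in gene_expr.columns if s in lnc_expr.columns
                 and (purity is None or s in purity.index)])
        for g, rho in zip(ranked.ids, ranked.scores):
            rows.append((lnc, g, float(rho), partial_spearman_pvalue(rho, n, n_controls)))
    tested = pd.DataFrame(rows, columns=["lncrna_id", "gene_id", "rho", "p"])
    tested = tested.sort_values(["lncrna_id", "gene_id"], kind="mergesort").reset_index(drop=True)
    tested["fdr"] = bh_adjust(tested["p"].to_numpy())
    tested["sign"] = np.where(tested["rho"] > 0, "positive", "negative")
    keep = (tested["rho"].abs() >= rho_threshold) & (tested["fdr"] < fdr_threshold)
    edges = tested[keep].reset_index(drop=True)
    return edges, tested


def activator_inhibitor_test(
    lncrna_id: str,
    edges: pd.DataFrame,
    annotation: pd.DataFrame,
    alpha: float = 0.05,
    min_genes: int = 3,
) -> tuple[float, float, str]:
    """Infer a lncRNA's autophagy role from its edge correlations.

    ``annotation`` maps ``gene_id`` to ``group`` in {AT+, AT-, both,
    unknown}.  One-sample Wilcoxon signed-rank tests ask whether the
    lncRNA's rho values over AT+ genes are shifted above zero and those
    over AT- genes below zero (autophagy-promoting), or the mirror image
    (autophagy-inhibiting).  Returns ``(p_plus, p_minus, role)`` where the
    reported p-values are the promoting-orientation tests (AT+ > 0,
    AT- < 0).  Fewer than ``min_genes`` annotated correlations on either
    side leaves the lncRNA unclassified.
    """
    ann = annotation.set_index("gene_id")["group"]
    mine = edges[edges["lncrna_id"] == lncrna_id]
    rho_plus = mine[mine["gene_id"].map(ann) == "AT+"]["rho"].to_numpy(dtype=float)
    rho_minus = mine[mine["gene_id"].map(ann) == "AT-"]["rho"].to_numpy(dtype=float)
    if len(rho_plus) < min_genes or len(rho_minus) < min_genes:
        return np.nan, np.nan, "unclassified"

    def _wilcoxon(v: np.ndarray, alternative: str) -> float:
        if np.all(v == 0):
            return 1.0
        return float(sps.wilcoxon(v, alternative=alternative).pvalue)

    p_plus = _wilcoxon(rho_plus, "greater")
    p_minus = _wilcoxon(rho_minus, "less")
    if p_plus < alpha and p_minus < alpha:
        return p_plus, p_minus, "autophagy-promoting"
    if _wilcoxon(rho_plus, "less") < alpha and _wilcoxon(rho_minus, "greater") < alpha:
        return p_plus, p_minus, "autophagy-inhibiting"
    return p_plus, p_minus, "unclassified"


def target_gene_set(lncrna_id: str, edges: pd.DataFrame) -> set[str]:
    """The lncRNA's network partners (either edge sign) as a gene set."""
    targets = set(edges.loc[edges["lncrna_id"] == lncrna_id, "gene_id"])
    if not targets:
        warnings.warn(f"{lncrna_id}: no network edges; empty target set")
    return targets


def drug_lncrna_screen(
    target_sets: dict[str, set[str]],
    signatures: list[DrugSignature],
    n_perm: int = 1000,
    seed: int | None = None,
    fdr_threshold: float = 0.01,
    min_coverage: float = 0.5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """GSEA of each lncRNA's target set against every drug signature.

    Each (drug, lncRNA) pair is scored with the shared enrichment kernel
    using a gene-label permutation null; FDR q-values are pooled across all
    pairs.  Targets absent from a signature are dropped (warning when
    coverage falls below ``min_coverage``); lncRNAs with empty target sets
    are skipped with a warning.  A pair is ``reported`` iff its
    fdr_q < ``fdr_threshold``; ``direction`` is ``induces`` for NES > 0 and
    ``represses`` for NES < 0.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    results: list[GseaResult] = []
    for sig in sorted(signatures, key=lambda s: s.drug_id):
        universe = set(sig.ranking.ids)
        for lnc in sorted(target_sets):
            targets = set(target_sets[lnc])
            if not targets:
                warnings.warn(f"{lnc}: empty target set; skipped in drug screen")
                continue
            covered = targets & universe
            if not covered:
                warnings.warn(f"{sig.drug_id}/{lnc}: no target genes in signature; skipped")
                continue
            if len(covered) / len(targets) < min_coverage:
                warnings.warn(
                    f"{sig.drug_id}/{lnc}: only {len(covered)}/{len(targets)} targets covered"
                )
            pairs.append((sig.drug_id, lnc))
            results.append(gsea_significance(sig.ranking, covered, n_perm=n_perm, rng=rng))
    if not results:
        return pd.DataFrame(
            columns=["drug_id", "lncrna_id", "es", "nes", "nominal_p", "fdr_q", "direction", "reported"]
        )
    q = nes_pooled_fdr(results)
    out = pd.DataFrame(
        {
            "drug_id": [d for d, _ in pairs],
            "lncrna_id": [l for _, l in pairs],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "nominal_p": [r.nominal_p for r in results],
            "fdr_q": q,
        }
    )
    out["direction"] = np.where(out["nes"] > 0, "induces", "represses")
    out["reported"] = out["fdr_q"] < fdr_threshold
    return out.sort_values(["drug_id", "lncrna_id"], kind="mergesort").reset_index(drop=True)


def ora_enrichment(
    genes: set[str],
    function_sets: dict[str, list[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``genes`` in each function set.

    Returns one row per set with the overlap k, query size n, set size K,
    universe size N, upper-tail p and BH fdr.  Sets disjoint from the
    universe are skipped with a warning; an empty universe is an error.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    genes = set(genes) & universe
    rows = []
    for name in sorted(function_sets):
        members = set(function_sets[name]) & universe
        if not members:
            warnings.warn(f"{name}: no members in universe; skipped")
            continue
        k = len(genes & members)
        rows.append(
            {"set": name, "k": k, "n": len(genes), "K": len(members), "N": len(universe),
             "p": hypergeometric_tail(k, len(genes), len(members), len(universe))}
        )
    out = pd.DataFrame(rows, columns=["set", "k", "n", "K", "N", "p"])
    out["fdr"] = bh_adjust(out["p"].to_numpy()) if len(out) else pd.Series(dtype=float)
    return out


def to_graphml(edges: pd.DataFrame, path) -> None:
    """Optional GraphML export of the regulatory network for viewers."""
    import networkx as nx

    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_node(row.lncrna_id, kind="lncrna")
        g.add_node(row.gene_id, kind="gene")
        g.add_edge(row.lncrna_id, row.gene_id, rho=float(row.rho), sign=row.sign)
    nx.write_graphml(g, path)
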