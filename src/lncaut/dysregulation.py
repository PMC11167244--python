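"""Stage 2: calling DNA-methylation-dysregulated lncRNAs.

A lncRNA is methylation-dysregulated when (i) it is differentially
expressed, (ii) at least one differentially methylated CpG site lies in its
promoter or enhancer, (iii) the site's methylation change opposes the
expression change (hyper+down or hypo+up), and (iv) the site's beta values
correlate negatively with the lncRNA's expression across tumor samples at
BH FDR < 0.05 (BH taken across all tested site-lncRNA pairs).  Regions with
several differential sites are summarized by the most significant site.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .stats import bh_adjust, partial_spearman, partial_spearman_pvalue

__all__ = ["map_sites_to_regions", "call_dysregulated_lncrnas"]

ROLES = ("promoter", "enhancer")


def map_sites_to_regions(sites: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Assign CpG sites to lncRNA promoter/enhancer regions.

    ``sites`` needs columns ``site_id, chrom, pos`` (0-based positions);
    ``regions`` needs ``chrom, start, end, lncrna_id, role`` with 0-based
    half-open intervals.  A site maps to a region iff
    ``start <= pos < end`` on the same chromosome; one site may map to
    several regions.  Returns a tidy frame with one row per (site, region)
    hit: columns ``site_id, lncrna_id, role``.

    Strand is deliberately ignored: array-summarized CpG methylation is
    strand-symmetric.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for row in regions.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if start >= end:
            raise ValueError(f"malformed region for {row.lncrna_id}: start {start} >= end {end}")
        trees[str(row.chrom)].addi(start, end, (str(row.lncrna_id), str(row.role)))
    hits: list[tuple[str, str, str]] = []
    for row in sites.itertuples(index=False):
        tree = trees.get(str(row.chrom))
        if tree is None:
            continue
        for iv in tree.at(int(row.pos)):
            hits.append((str(row.site_id), iv.data[0], iv.data[1]))
    out = pd.DataFrame(hits, columns=["site_id", "lncrna_id", "role"])
    return out.sort_values(["lncrna_id", "role", "site_id"], kind="mergesort").reset_index(drop=True)


def call_dysregulated_lncrnas(
    de_lnc: pd.DataFrame,
    dm_sites: pd.DataFrame,
    mapping: pd.DataFrame,
    beta: pd.DataFrame,
    lnc_expr: pd.DataFrame,
    tumor_samples: list[str] | None = None,
    dm_fdr: float = 0.05,
    corr_fdr: float = 0.05,
    require_direction: bool = True,
    require_correlation: bool = True,
) -> pd.DataFrame:
    """Apply the four-clause dysregulation rule, one row per lncRNA x role.

    ``de_lnc`` / ``dm_sites`` are differential tables (columns ``id,
    effect, p, fdr, direction``); ``mapping`` links sites to regions.  The
    methylation-expression Spearman correlation is computed across the
    tumor samples shared by ``beta`` and ``lnc_expr``.  The two rule
    clauses beyond DE + mapped-DM-site — direction opposition and negative
    correlation at FDR < ``corr_fdr`` — can each be relaxed via the
    ``require_*`` flags.
    """
    if tumor_samples is None:
        tumor_samples = [s for s in beta.columns if s in set(lnc_expr.columns)]
    else:
        tumor_samples = [s for s in tumor_samples if s in set(beta.columns) & set(lnc_expr.columns)]
    if len(tumor_samples) < 4:
        raise ValueError("no (or too few) shared tumor samples between beta and expression")

    de = de_lnc.set_index("id")
    dm = dm_sites.set_index("id")
    de_called = de[de["direction"].isin(["up", "down"])]
    dm_called = dm[dm["direction"].isin(["up", "down"])]

    rows = []
    for (lnc, role), grp in mapping.groupby(["lncrna_id", "role"], sort=True):
        if lnc not in de_called.index or lnc not in lnc_expr.index:
            continue
        cand = [s for s in grp["site_id"] if s in dm_called.index and s in beta.index]
        if not cand:
            continue
        # summarize the region by its most significant site (min DM fdr,
        # ties broken by site id)
        best = min(cand, key=lambda s: (dm_called.loc[s, "fdr"], s))
        meth_dir = "hyper" if dm_called.loc[best, "effect"] > 0 else "hypo"
        expr_dir = de_called.loc[lnc, "direction"]
        x = beta.loc[best, tumor_samples].to_numpy(dtype=float)
        y = lnc_expr.loc[lnc, tumor_samples].to_numpy(dtype=float)
        try:
            r = partial_spearman(x, y)
            p = partial_spearman_pvalue(r, len(tumor_samples), n_controls=0)
        except ValueError:  # constant methylation or expression: no evidence
            r, p = np.nan, 1.0
        rows.append(
            {
                "lncrna_id": lnc,
                "role": role,
                "site_id": best,
                "n_sites": len(cand),
                "meth_direction": meth_dir,
                "expr_direction": expr_dir,
                "corr_r": r,
                "corr_p": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["lncrna_id", "role", "site_id", "n_sites", "meth_direction",
                 "expr_direction", "corr_r", "corr_p"],
    )
    if len(out) == 0:
        out["corr_fdr"] = pd.Series(dtype=float)
        out["dysregulated"] = pd.Series(dtype=bool)
        return out
    out["corr_fdr"] = bh_adjust(out["corr_p"].to_numpy())
    opposite = (
        ((out["meth_direction"] == "hyper") & (out["expr_direction"] == "down"))
        | ((out["meth_direction"] == "hypo") & (out["expr_direction"] == "up"))
    )
    ok = pd.Series(True, index=out.index)
    if require_direction:
        ok &= opposite
    if require_correlation:
        ok &= (out["corr_r"] < 0) & (out["corr_fdr"] < corr_fdr)
    out["dysregulated"] = ok
    return out.sort_values(["lncrna_id", "role"], kind="mergesort").reset_index(drop=True)
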