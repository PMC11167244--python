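"""Stage 1: tumor-vs-normal differential expression and methylation.

Both operations test each feature with the Wilcoxon rank-sum statistic and
control the FDR across features by Benjamini-Hochberg.  Expression effects
are reported as log2 fold change (difference of group means on the log2
scale); methylation is tested on M-values, M = log2((beta+eps)/(1-beta+eps))
with eps = 0.01, while the effect is reported as the mean difference on the
beta scale to keep the hyper-/hypomethylation language directly readable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import bh_adjust, ranksum_rows

__all__ = ["differential_expression", "differential_methylation", "split_groups"]

M_EPS = 0.01


def split_groups(matrix: pd.DataFrame, labels: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a features x samples matrix into (tumor, normal) blocks."""
    labels = labels.astype(str)
    tumor = [s for s in matrix.columns if labels.get(s) == "tumor"]
    normal = [s for s in matrix.columns if labels.get(s) == "normal"]
    if len(tumor) < 3 or len(normal) < 3:
        raise ValueError("need at least 3 tumor and 3 normal samples")
    return matrix.loc[:, tumor], matrix.loc[:, normal]


def _diff_table(ids, effect, stat, p, fdr, called_up, called_down) -> pd.DataFrame:
    direction = np.where(called_up, "up", np.where(called_down, "down", "ns"))
    return pd.DataFrame(
        {"id": list(ids), "effect": effect, "statistic": stat, "p": p,
         "fdr": fdr, "direction": direction}
    )


def differential_expression(
    expr: pd.DataFrame,
    labels: pd.Series,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Per-feature rank-sum DE with BH correction.

    ``expr`` holds log2 expression, features in rows.  A feature is called
    ``up``/``down`` iff fdr < ``fdr_threshold`` and |log2FC| >=
    ``lfc_threshold`` (tumor minus normal); otherwise ``ns``.
    """
    t, n = split_groups(expr, labels)
    stat, p = ranksum_rows(t.to_numpy(dtype=float), n.to_numpy(dtype=float))
    lfc = t.mean(axis=1).to_numpy() - n.mean(axis=1).to_numpy()
    fdr = bh_adjust(p)
    sig = fdr < fdr_threshold
    up = sig & (lfc >= lfc_threshold)
    down = sig & (lfc <= -lfc_threshold)
    return _diff_table(expr.index, lfc, stat, p, fdr, up, down)


def differential_methylation(
    beta: pd.DataFrame,
    labels: pd.Series,
    fdr_threshold: float = 0.05,
    min_delta: float = 0.0,
    eps: float = M_EPS,
) -> pd.DataFrame:
    """Per-site differential methylation on M-values.

    The rank-sum test is applied to M = log2((beta+eps)/(1-beta+eps)); the
    eps offset keeps beta values of exactly 0 or 1 finite.  ``effect`` is
    the tumor-minus-normal mean difference on the beta scale.  A site is
    differentially methylated iff fdr < ``fdr_threshold`` (and
    |delta_beta| >= ``min_delta`` when a minimum effect is configured;
    default none), with direction ``up`` (hyper) or ``down`` (hypo).
    """
    vals = beta.to_numpy(dtype=float)
    if np.any(np.isnan(vals)) or vals.min() < 0 or vals.max() > 1:
        raise ValueError("beta values must lie in [0, 1]")
    t, n = split_groups(beta, labels)
    mt = np.log2((t.to_numpy(dtype=float) + eps) / (1 - t.to_numpy(dtype=float) + eps))
    mn = np.log2((n.to_numpy(dtype=float) + eps) / (1 - n.to_numpy(dtype=float) + eps))
    stat, p = ranksum_rows(mt, mn)
    delta = t.mean(axis=1).to_numpy() - n.mean(axis=1).to_numpy()
    fdr = bh_adjust(p)
    sig = (fdr < fdr_threshold) & (np.abs(delta) >= min_delta)
    return _diff_table(beta.index, delta, stat, p, fdr, sig & (delta > 0), sig & (delta < 0))
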