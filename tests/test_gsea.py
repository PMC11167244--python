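"""Tests for the GSEA kernel, RS ranking and lncAut selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncaut.gsea import (
    enrichment_score,
    gsea_significance,
    lncaut_select,
    nes_pooled_fdr,
    rs_rank_genes,
)
from lncaut.stats import RankedGeneList


def brute_force_es(scores, member, weight=1.0):
    """Independent running-sum oracle: explicit loop, no vectorization."""
    n = len(scores)
    n_hit = sum(member)
    w = [abs(s) ** weight for s in scores]
    tot = sum(wi for wi, m in zip(w, member) if m)
    running = []
    acc = 0.0
    for i in range(n):
        if member[i]:
            acc += (w[i] / tot) if tot > 0 else 1.0 / n_hit
        else:
            acc -= 1.0 / (n - n_hit)
        running.append(acc)
    best = max(running, key=lambda v: (abs(v), -running.index(v)))
    # first index achieving the maximum magnitude
    idx = min(i for i, v in enumerate(running) if abs(v) == abs(best))
    return running[idx]


def ranked_list(scores):
    ids = [f"g{i+1}" for i in range(len(scores))]
    return RankedGeneList(ids=tuple(ids), scores=np.asarray(scores, dtype=float))


class TestEnrichmentScore:
    def test_top_placement_hand_case(self):
        es, running = enrichment_score(ranked_list([4, 3, 2, 1]), {"g1"})
        assert es == pytest.approx(1.0)
        np.testing.assert_allclose(running, [1.0, 2 / 3, 1 / 3, 0.0], atol=1e-12)

    def test_bottom_placement_hand_case(self):
        es, running = enrichment_score(ranked_list([4, 3, 2, 1]), {"g4"})
        assert es == pytest.approx(-1.0)
        np.testing.assert_allclose(running, [-1 / 3, -2 / 3, -1.0, 0.0], atol=1e-12)

    def test_full_or_disjoint_set_rejected(self):
        r = ranked_list([3, 2, 1])
        with pytest.raises(ValueError):
            enrichment_score(r, {"g1", "g2", "g3"})
        with pytest.raises(ValueError):
            enrichment_score(r, {"nope"})

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=200)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 13))
        scores = np.sort(rng.normal(size=n))[::-1]
        k = int(rng.integers(1, n))
        member = np.zeros(n, dtype=bool)
        member[rng.choice(n, size=k, replace=False)] = True
        r = ranked_list(scores)
        gene_set = {r.ids[i] for i in range(n) if member[i]}
        es, _ = enrichment_score(r, gene_set)
        assert es == pytest.approx(brute_force_es(scores, member), abs=1e-12)


class TestGseaSignificance:
    def test_exhaustive_null_hand_case(self):
        # list of 4, set size 1, observed at the top: same-sign (positive)
        # nulls are ES(g1)=1 and ES(g2)=2/3, so p = (1+1)/(1+2)
        res = gsea_significance(ranked_list([4, 3, 2, 1]), {"g1"}, exhaustive=True)
        assert res.es == pytest.approx(1.0)
        assert res.nominal_p == pytest.approx(2 / 3)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_exhaustive_p_matches_enumeration_estimator(self, seed):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=4))[::-1]
        r = ranked_list(scores)
        pick = int(rng.integers(0, 4))
        res = gsea_significance(r, {r.ids[pick]}, exhaustive=True)
        null = [brute_force_es(scores, [i == j for i in range(4)]) for j in range(4)]
        same = [v for v in null if np.sign(v) == np.sign(res.es)]
        expected = (1 + sum(abs(v) >= abs(res.es) - 1e-12 for v in same)) / (1 + len(same))
        assert res.nominal_p == pytest.approx(expected)

    def test_seeded_reproducibility(self):
        r = ranked_list(np.linspace(3, -3, 40))
        a = gsea_significance(r, {f"g{i}" for i in (1, 2, 3, 7)}, n_perm=200, seed=9)
        b = gsea_significance(r, {f"g{i}" for i in (1, 2, 3, 7)}, n_perm=200, seed=9)
        assert a.nominal_p == b.nominal_p and a.nes == b.nes
        assert np.array_equal(a.null_es, b.null_es)

    def test_minimum_p_respects_permutation_count(self):
        rng = np.random.default_rng(3)
        scores = np.sort(rng.normal(size=60))[::-1] + np.linspace(4, 0, 60)
        r = ranked_list(scores)
        res = gsea_significance(r, set(list(r.ids)[:6]), n_perm=200, seed=0)
        assert res.nominal_p >= 1 / (res.n_perm + 1)

    def test_pooled_fdr_in_range(self):
        rng = np.random.default_rng(4)
        results = []
        for _ in range(6):
            scores = np.sort(rng.normal(size=50))[::-1]
            r = ranked_list(scores)
            results.append(gsea_significance(r, set(list(r.ids)[::7]), n_perm=150, rng=rng))
        q = nes_pooled_fdr(results)
        assert np.all((q >= 0) & (q <= 1))


class TestRsRankGenes:
    def _cohort_frames(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        samples = [f"S{i}" for i in range(n)]
        lnc = pd.Series(rng.normal(size=n), index=samples)
        genes = pd.DataFrame(rng.normal(size=(30, n)),
                             index=[f"G{i:02d}" for i in range(30)], columns=samples)
        purity = pd.Series(rng.uniform(0.4, 1, n), index=samples)
        return lnc, genes, purity

    def test_constant_purity_equals_plain_spearman_order(self):
        lnc, genes, _ = self._cohort_frames()
        flat = pd.Series(0.7, index=lnc.index)
        a = rs_rank_genes(lnc, genes, flat)
        b = rs_rank_genes(lnc, genes, None)
        assert a.ids == b.ids
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-12)

    def test_planted_target_ranks_near_top(self, cohort):
        truth = cohort.truth
        lnc = sorted(truth.autophagy_lnc_ids)[0]
        tumor = cohort.tumor_samples
        ranked = rs_rank_genes(cohort.lnc_expr.loc[lnc, tumor],
                               cohort.gene_expr[tumor], cohort.purity)
        positives = [g for g, s in truth.targets[lnc].items() if s > 0]
        cutoff = int(0.05 * len(ranked))
        top = set(list(ranked.ids)[:cutoff])
        assert all(g in top for g in positives)

    def test_pure_confounder_gene_has_no_rs(self):
        lnc, genes, purity = self._cohort_frames(seed=5)
        # lncRNA dominated by purity; one gene IS the confounder
        lnc = 0.2 * lnc + 3.0 * purity.to_numpy()
        genes.loc["G00"] = purity.to_numpy()
        marginal = rs_rank_genes(lnc, genes, None)
        adjusted = rs_rank_genes(lnc, genes, purity)
        m = dict(zip(marginal.ids, marginal.scores))
        a = dict(zip(adjusted.ids, adjusted.scores))
        assert m["G00"] > 0.8
        assert abs(a["G00"]) < 1e-9

    def test_constant_lncrna_rejected(self):
        _, genes, purity = self._cohort_frames()
        flat = pd.Series(1.0, index=genes.columns)
        with pytest.raises(ValueError):
            rs_rank_genes(flat, genes, purity)


class TestLncautSelect:
    def _result(self, p, nes=1.5):
        from lncaut.gsea import GseaResult

        return GseaResult(es=0.5 * np.sign(nes), nes=nes, nominal_p=p, n_perm=1000,
                          null_es=np.concatenate([np.full(50, 0.3), np.full(50, -0.3)]))

    def test_score_is_one_minus_p_with_strict_boundary(self):
        tab = lncaut_select(
            {"a": self._result(0.05), "b": self._result(0.10), "c": self._result(1.0)},
            fdr_method="bh",
        )
        tab = tab.set_index("lncrna_id")
        assert tab.loc["a", "lncaut"] == pytest.approx(0.95)
        assert tab.loc["b", "lncaut"] == pytest.approx(0.90)
        assert not tab.loc["b", "selected"]  # lncAut must exceed 0.9 strictly
        assert tab.loc["c", "lncaut"] == pytest.approx(0.0)
        assert not tab.loc["c", "selected"]

    def test_selection_requires_both_gates(self):
        tab = lncaut_select({"a": self._result(0.01)}, fdr_method="bh").set_index("lncrna_id")
        assert bool(tab.loc["a", "selected"]) == (tab.loc["a", "fdr_q"] < 0.05)
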