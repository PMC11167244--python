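"""Tests for the regulatory network, role inference, drug screen and ORA."""

import numpy as np
import pandas as pd
import pytest

from lncaut import generate_drug_signatures
from lncaut.gsea import enrichment_score
from lncaut.network import (
    DrugSignature,
    activator_inhibitor_test,
    build_regulatory_network,
    drug_lncrna_screen,
    ora_enrichment,
    target_gene_set,
)
from lncaut.stats import RankedGeneList, bh_adjust, hypergeometric_tail


@pytest.fixture(scope="module")
def network(cohort):
    selected = sorted(cohort.truth.autophagy_lnc_ids)
    tumor = cohort.tumor_samples
    edges, tested = build_regulatory_network(
        selected, cohort.autophagy_genes,
        cohort.lnc_expr[tumor], cohort.gene_expr[tumor], cohort.purity,
    )
    return cohort, edges, tested


class TestBuildNetwork:
    def test_planted_edges_present_with_correct_sign(self, network):
        cohort, edges, _ = network
        idx = edges.set_index(["lncrna_id", "gene_id"])
        found = missing = 0
        for lnc, block in cohort.truth.targets.items():
            for gene, sign in block.items():
                if (lnc, gene) in idx.index:
                    found += 1
                    expected = "positive" if sign > 0 else "negative"
                    assert idx.loc[(lnc, gene), "sign"] == expected
                else:
                    missing += 1
        assert found >= 0.8 * (found + missing)

    def test_extreme_threshold_gives_no_edges(self, cohort):
        tumor = cohort.tumor_samples
        edges, _ = build_regulatory_network(
            sorted(cohort.truth.autophagy_lnc_ids)[:2], cohort.autophagy_genes,
            cohort.lnc_expr[tumor], cohort.gene_expr[tumor], cohort.purity,
            rho_threshold=1.0,
        )
        assert len(edges) == 0

    def test_empty_lncrna_set_warns_and_returns_empty(self, cohort):
        tumor = cohort.tumor_samples
        with pytest.warns(UserWarning):
            edges, tested = build_regulatory_network(
                [], cohort.autophagy_genes,
                cohort.lnc_expr[tumor], cohort.gene_expr[tumor], cohort.purity,
            )
        assert len(edges) == 0 and len(tested) == 0

    def test_edge_criterion_holds_for_every_edge(self, network):
        _, edges, _ = network
        assert (edges["rho"].abs() >= 0.3).all()
        assert (edges["fdr"] < 0.05).all()
        assert ((edges["rho"] > 0) == (edges["sign"] == "positive")).all()


class TestActivatorInhibitor:
    def _edges(self, rhos_plus, rhos_minus):
        rows = [("L1", f"P{i}", r, 0.001, 0.01, "positive" if r > 0 else "negative")
                for i, r in enumerate(rhos_plus)]
        rows += [("L1", f"M{i}", r, 0.001, 0.01, "positive" if r > 0 else "negative")
                 for i, r in enumerate(rhos_minus)]
        return pd.DataFrame(rows, columns=["lncrna_id", "gene_id", "rho", "p", "fdr", "sign"])

    def _annotation(self, n_plus, n_minus):
        return pd.DataFrame({
            "gene_id": [f"P{i}" for i in range(n_plus)] + [f"M{i}" for i in range(n_minus)],
            "group": ["AT+"] * n_plus + ["AT-"] * n_minus,
        })

    def test_clean_separation_infers_promoting(self):
        edges = self._edges([0.5, 0.55, 0.6, 0.52, 0.58, 0.51, 0.54, 0.56, 0.53, 0.57],
                            [-0.5, -0.55, -0.6, -0.52, -0.58, -0.51, -0.54, -0.56, -0.53, -0.57])
        p_plus, p_minus, role = activator_inhibitor_test("L1", edges, self._annotation(10, 10))
        assert role == "autophagy-promoting"
        assert p_plus < 0.05 and p_minus < 0.05

    def test_mirrored_correlations_infer_inhibiting(self):
        edges = self._edges([-0.5] * 8 + [-0.6] * 2, [0.5] * 8 + [0.6] * 2)
        _, _, role = activator_inhibitor_test("L1", edges, self._annotation(10, 10))
        assert role == "autophagy-inhibiting"

    def test_symmetric_correlations_unclassified(self):
        edges = self._edges([0.4, -0.4, 0.3, -0.3, 0.2, -0.2, 0.35, -0.35],
                            [0.4, -0.4, 0.3, -0.3, 0.2, -0.2, 0.45, -0.45])
        _, _, role = activator_inhibitor_test("L1", edges, self._annotation(8, 8))
        assert role == "unclassified"

    def test_insufficient_annotation_unclassified(self):
        edges = self._edges([0.5, 0.6], [-0.5])
        p_plus, p_minus, role = activator_inhibitor_test("L1", edges, self._annotation(2, 1))
        assert role == "unclassified"
        assert np.isnan(p_plus) and np.isnan(p_minus)

    def test_planted_lncrnas_inferred_promoting(self, network):
        cohort, edges, _ = network
        roles = [
            activator_inhibitor_test(lnc, edges, cohort.gene_annotation)[2]
            for lnc in sorted(cohort.truth.autophagy_lnc_ids)
        ]
        assert roles.count("autophagy-promoting") >= 0.8 * len(roles)


class TestTargetGeneSet:
    def test_identity_on_hand_built_network(self):
        edges = pd.DataFrame({
            "lncrna_id": ["L1", "L1", "L2"],
            "gene_id": ["G1", "G2", "G3"],
            "rho": [0.5, -0.4, 0.6],
            "p": [0.01] * 3, "fdr": [0.02] * 3,
            "sign": ["positive", "negative", "positive"],
        })
        assert target_gene_set("L1", edges) == {"G1", "G2"}
        assert target_gene_set("L2", edges) == {"G3"}

    def test_isolated_lncrna_warns_empty(self):
        edges = pd.DataFrame(columns=["lncrna_id", "gene_id", "rho", "p", "fdr", "sign"])
        with pytest.warns(UserWarning):
            assert target_gene_set("L9", edges) == set()


class TestDrugScreen:
    def test_planted_pairs_recovered_with_expected_sign(self, default_config, cohort):
        sigs = generate_drug_signatures(default_config, cohort.truth)
        target_sets = {lnc: set(block) for lnc, block in cohort.truth.targets.items()}
        out = drug_lncrna_screen(target_sets, sigs, n_perm=300, seed=0)
        rep = out[out["reported"]].set_index(["drug_id", "lncrna_id"])
        for drug, lnc, sign in cohort.truth.drug_pairs:
            assert (drug, lnc) in rep.index
            nes = rep.loc[(drug, lnc), "nes"]
            assert np.sign(nes) == sign
            assert rep.loc[(drug, lnc), "direction"] == ("induces" if sign > 0 else "represses")

    def test_reversed_signature_flips_enrichment_sign(self):
        rng = np.random.default_rng(5)
        ids = [f"G{i:03d}" for i in range(100)]
        scores = pd.Series(rng.normal(size=100), index=ids)
        targets = set(ids[:8])
        scores[list(targets)] += 3.0
        fwd = RankedGeneList.from_scores(scores)
        rev = RankedGeneList.from_scores(-scores)
        es_f, _ = enrichment_score(fwd, targets)
        es_r, _ = enrichment_score(rev, targets)
        assert es_f > 0.5 and es_r < -0.5

    def test_screen_uses_the_shared_enrichment_kernel(self, default_config, cohort):
        sigs = generate_drug_signatures(default_config, cohort.truth)
        drug, lnc, _ = sorted(cohort.truth.drug_pairs)[0]
        sig = next(s for s in sigs if s.drug_id == drug)
        targets = set(cohort.truth.targets[lnc])
        out = drug_lncrna_screen({lnc: targets}, [sig], n_perm=150, seed=1)
        es_direct, _ = enrichment_score(sig.ranking, targets & set(sig.ranking.ids))
        assert out.loc[0, "es"] == pytest.approx(es_direct)

    def test_uncovered_targets_warn(self):
        rng = np.random.default_rng(6)
        ids = [f"G{i}" for i in range(50)]
        sig = DrugSignature("D1", RankedGeneList.from_scores(
            pd.Series(rng.normal(size=50), index=ids)))
        with pytest.warns(UserWarning, match="covered"):
            drug_lncrna_screen({"L1": {"G1", "G2", "X1", "X2", "X3"}}, [sig],
                               n_perm=150, seed=2)


class TestOra:
    def test_composes_hypergeometric_and_bh(self):
        universe = {f"G{i}" for i in range(20)}
        genes = {"G0", "G1", "G2", "G3"}
        sets = {"A": ["G0", "G1", "G2", "G4", "G5"], "B": ["G10", "G11", "G12"]}
        out = ora_enrichment(genes, sets, universe).set_index("set")
        expected_a = hypergeometric_tail(3, 4, 5, 20)
        expected_b = hypergeometric_tail(0, 4, 3, 20)
        assert out.loc["A", "p"] == pytest.approx(expected_a)
        assert out.loc["B", "p"] == pytest.approx(expected_b)
        np.testing.assert_allclose(
            out["fdr"].to_numpy(), bh_adjust([expected_a, expected_b]), atol=1e-12
        )

    def test_empty_query_gives_p_one(self):
        universe = {f"G{i}" for i in range(10)}
        out = ora_enrichment(set(), {"A": ["G0", "G1"]}, universe)
        assert (out["p"] == 1.0).all()

    def test_disjoint_set_skipped_with_warning(self):
        universe = {"G0", "G1"}
        with pytest.warns(UserWarning):
            out = ora_enrichment({"G0"}, {"A": ["X1", "X2"]}, universe)
        assert len(out) == 0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_enrichment({"G0"}, {"A": ["G0"]}, set())
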