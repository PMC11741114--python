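"""Enrichment statistics: BH step-up, Mann-Whitney module test branches,
chi-square overrepresentation identities, link report assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import mixlink as ml
from mixlink.enrichment import _mannwhitney_greater


def _partition(mapping: dict[str, int]) -> ml.ModulePartition:
    return ml.ModulePartition(assignment=pd.Series(mapping), min_module_size=1)


class TestBenjaminiHochberg:
    def test_step_up_formula_hand_applied(self):
        np.testing.assert_allclose(ml.benjamini_hochberg([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged_and_boundary(self):
        assert ml.benjamini_hochberg([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(ml.benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ml.benjamini_hochberg([0.5, 1.2])

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=30))
    def test_adjustment_is_order_preserving_and_bounded(self, ps):
        adj = ml.benjamini_hochberg(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestModuleEnrichment:
    def test_worked_example_exact_p_by_enumeration(self):
        # module {a,b} beats all out-group genes: U = 6, p = 1/C(5,2) = 0.1
        u, p = _mannwhitney_greater(np.array([0.4, 0.3]), np.array([0.1, 0.1, 0.1]))
        assert u == 6.0
        assert p == pytest.approx(0.1)

    def test_all_identical_sw_is_null(self):
        sw = pd.Series(0.2, index=[f"g{i}" for i in range(12)])
        part = _partition({f"g{i}": (1 if i < 5 else 0) for i in range(12)})
        table = ml.module_enrichment(sw, part)
        row = table.iloc[0]
        assert row["U"] == pytest.approx(5 * 7 / 2)
        assert row["p_value"] > 0.4
        assert not row["significant"]

    def test_exact_and_asymptotic_branches_agree_at_boundary(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            x, y = rng.uniform(size=8), rng.uniform(size=8)
            _, p_exact = _mannwhitney_greater(x, y)
            p_asym = stats.mannwhitneyu(x, y, alternative="greater",
                                        method="asymptotic").pvalue
            assert abs(p_exact - p_asym) < 0.02

    def test_module_equal_to_universe_rejected(self):
        sw = pd.Series([0.5, 0.5], index=["a", "b"])
        part = _partition({"a": 1, "b": 1})
        with pytest.raises(ValueError, match="out-group"):
            ml.module_enrichment(sw, part)

    def test_strong_module_detected_across_components(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(60)]
        part = _partition({g: (1 if i < 20 else (2 if i < 40 else 0))
                           for i, g in enumerate(genes)})
        sw = pd.DataFrame({"LDR1": np.r_[rng.uniform(0.5, 1, 20), rng.uniform(0, 0.1, 40)],
                           "LDR2": rng.uniform(0, 1, 60)}, index=genes)
        table = ml.module_enrichment(sw, part)
        hit = table[(table["module"] == 1) & (table["component"] == "LDR1")].iloc[0]
        assert hit["significant"]
        assert len(table) == 4  # 2 modules x 2 components, every pair present
        assert (table["adj_p_value"] >= table["p_value"] - 1e-15).all()


class TestPathwayOverrepresentation:
    @staticmethod
    def _annotation(sets):
        return ml.PathwayAnnotation(sets={k: set(v) for k, v in sets.items()})

    def test_proportional_pathway_is_independent(self):
        universe = {f"g{i}" for i in range(100)}
        module = {f"g{i}" for i in range(20)}
        pathway = {f"g{i}" for i in range(4)} | {f"g{i}" for i in range(20, 36)}  # 4/20 = 16/80
        table = ml.pathway_overrepresentation(module, universe,
                                              self._annotation({"pw": pathway}))
        row = table.iloc[0]
        assert row["chi2"] == pytest.approx(0.0, abs=1e-10)
        assert row["p_value"] == pytest.approx(1.0)
        assert not row["enriched"]

    def test_chi_square_equals_hand_evaluated_formula(self):
        # 2x2 table (10, 40, 10, 940)
        universe = {f"g{i}" for i in range(1000)}
        module = {f"g{i}" for i in range(50)}
        pathway = {f"g{i}" for i in range(10)} | {f"g{i}" for i in range(50, 60)}
        table = ml.pathway_overrepresentation(module, universe,
                                              self._annotation({"pw": pathway}))
        obs = np.array([[10, 40], [10, 940]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        chi2_hand = float(((obs - exp) ** 2 / exp).sum())
        assert table.iloc[0]["chi2"] == pytest.approx(chi2_hand, abs=1e-10)

    def test_chi_square_equals_squared_two_proportion_z(self):
        universe = {f"g{i}" for i in range(500)}
        module = {f"g{i}" for i in range(60)}
        pathway = {f"g{i}" for i in range(25)} | {f"g{i}" for i in range(60, 90)}
        table = ml.pathway_overrepresentation(module, universe,
                                              self._annotation({"pw": pathway}))
        a, c = 25, 30
        n1, n2 = 60, 440
        p1, p2 = a / n1, c / n2
        pool = (a + c) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
        assert table.iloc[0]["chi2"] == pytest.approx(z ** 2, abs=1e-10)

    def test_nested_pathway_has_maximal_chi_square(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(50)]
        module = set(universe[:5])
        sets = {"nested": module}
        for k in range(40):
            sets[f"rand{k}"] = set(rng.choice(universe, size=5, replace=False))
        table = ml.pathway_overrepresentation(module, set(universe),
                                              self._annotation(sets), min_overlap=1)
        chi = table.set_index("pathway")["chi2"]
        assert chi.idxmax() == "nested"

    def test_small_overlap_skipped_and_flagged(self):
        universe = {f"g{i}" for i in range(100)}
        module = {f"g{i}" for i in range(10)}
        table = ml.pathway_overrepresentation(
            module, universe, self._annotation({"tiny": {"g0", "g50"}}), min_overlap=3)
        assert bool(table.iloc[0]["skipped"])
        assert np.isnan(table.iloc[0]["p_value"])

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ml.pathway_overrepresentation(set(), set(), self._annotation({"p": {"g"}}))


class TestGmtAndLinkReport:
    def test_gmt_round_trip(self, tmp_path):
        gmt = tmp_path / "sets.gmt"
        gmt.write_text("pw1\tfirst pathway\tg1\tg2\tg3\npw2\tsecond\tg2\tg4\n")
        ann = ml.PathwayAnnotation.from_gmt(gmt)
        assert ann.sets == {"pw1": {"g1", "g2", "g3"}, "pw2": {"g2", "g4"}}
        assert ann.descriptions["pw2"] == "second"
        restricted = ann.restricted_to({"g1", "g2"})
        assert restricted.sets == {"pw1": {"g1", "g2"}, "pw2": {"g2"}}

    def test_malformed_gmt_rejected(self, tmp_path):
        bad = tmp_path / "bad.gmt"
        bad.write_text("only_id\tdescription\n")
        with pytest.raises(ValueError, match="GMT"):
            ml.PathwayAnnotation.from_gmt(bad)

    @staticmethod
    def _null_fit():
        rng = np.random.default_rng(11)
        X = rng.standard_normal((20, 6))
        Y = rng.standard_normal((20, 30))
        return ml.fit_sgcca([X, Y], ml.SgccaConfig(n_components=1,
                                                   sparsity_per_block=(1.0, 1.0)))

    def test_contributor_list_matches_direct_threshold(self):
        fit = self._null_fit()
        genes = list(fit.weights[1].index)
        part = _partition({g: (1 if i < 15 else 0) for i, g in enumerate(genes)})
        enr = ml.module_enrichment(fit.squared_weights[1]["LDR1"], part)
        rep = ml.link_report(fit, enr, sw_cutoff=0.01, partition=part)
        sw = fit.squared_weights[0]["LDR1"]
        assert set(rep.contributors["LDR1"].index) == set(sw.index[sw > 0.01])

    def test_all_sw_below_cutoff_gives_empty_contributors(self):
        fit = self._null_fit()
        genes = list(fit.weights[1].index)
        part = _partition({g: (1 if i < 15 else 0) for i, g in enumerate(genes)})
        enr = ml.module_enrichment(fit.squared_weights[1]["LDR1"], part)
        rep = ml.link_report(fit, enr, sw_cutoff=1.1, partition=part)
        assert len(rep.contributors["LDR1"]) == 0
        assert "no enriched pathways" in rep.to_text()

    def test_gene_universe_mismatch_rejected(self):
        fit = self._null_fit()
        part = _partition({"not_a_gene": 1, "also_not": 0})
        enr = pd.DataFrame({"module": [1], "component": ["LDR1"], "significant": [False]})
        with pytest.raises(ValueError, match="universe"):
            ml.link_report(fit, enr, partition=part)
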