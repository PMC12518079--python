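import numpy as np
import pandas as pd
import pytest

from tumorhet import (
    DataModelError,
    ExpressionMatrix,
    RiskModel,
    consistent_direction,
    cox_screen,
    default_risk_model,
    filter_degs,
    generate_funnel_scenario,
    intersect_low_ith,
    risk_score,
    score_all_genes,
    select_signature_genes,
    simple_de,
    stratify,
    stratify_median,
)


def _expr(values, genes, samples):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestFilterDegs:
    def test_joint_thresholds(self):
        tbl = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "log2fc": [0.1, 0.2, -0.5],
                "fdr": [0.01, 0.01, 0.2],
            }
        )
        assert filter_degs(tbl) == ["b"]

    def test_zero_fc_cut_keeps_all_significant(self):
        tbl = pd.DataFrame(
            {"gene_id": ["a", "b"], "log2fc": [0.01, -0.02], "fdr": [0.04, 0.06]}
        )
        assert filter_degs(tbl, fc_cut=0.0) == ["a"]

    def test_boundary_is_strict(self):
        tbl = pd.DataFrame(
            {"gene_id": ["a"], "log2fc": [0.137], "fdr": [0.01]}
        )
        assert filter_degs(tbl) == []


class TestSimpleDe:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(8, 1, size=(30, 10))
        a = _expr(vals[:, :5], [f"g{i}" for i in range(30)], [f"a{i}" for i in range(5)])
        b = _expr(vals[:, 5:], [f"g{i}" for i in range(30)], [f"b{i}" for i in range(5)])
        de = simple_de(a, b)
        assert de["fdr"].min() > 0.05 or abs(de["log2fc"]).max() < 0.137 * 5

    def test_planted_shift_detected(self):
        """One gene shifted by +1 among nulls survives the DEG filter."""
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            genes = [f"g{i}" for i in range(300)]
            base = rng.normal(8, 0.5, size=(300, 40))
            shifted = base.copy()
            shifted[0, :20] += 1.0
            a = _expr(shifted[:, :20], genes, [f"a{i}" for i in range(20)])
            b = _expr(base[:, 20:], genes, [f"b{i}" for i in range(20)])
            hits += "g0" in filter_degs(simple_de(a, b))
        assert hits >= 9

    def test_group_too_small_rejected(self):
        a = _expr([[1.0]], ["g"], ["s1"])
        b = _expr([[1.0, 2.0]], ["g"], ["s2", "s3"])
        with pytest.raises(DataModelError):
            simple_de(a, b)


class TestConsistentDirection:
    def _screen(self, hrs, sig=True, ph=True):
        hrs = np.asarray(hrs, dtype=float)
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(hrs))],
                "hr": hrs,
                "significant": [sig] * len(hrs),
                "ph_ok": [ph] * len(hrs),
            }
        )

    def test_same_direction_kept(self):
        out = consistent_direction(self._screen([1.5]), self._screen([1.2]))
        assert out == ["g0"]

    def test_opposite_direction_dropped(self):
        assert consistent_direction(self._screen([1.5]), self._screen([0.8])) == []

    def test_hr_exactly_one_has_no_direction(self):
        assert consistent_direction(self._screen([1.0]), self._screen([1.3])) == []

    def test_ph_requirement(self):
        a, b = self._screen([1.5]), self._screen([1.4], ph=False)
        assert consistent_direction(a, b) == []
        assert consistent_direction(a, b, require_ph=False) == ["g0"]

    def test_disjoint_screens_rejected(self):
        a = self._screen([1.5])
        b = self._screen([1.5])
        b["gene_id"] = ["other"]
        with pytest.raises(DataModelError):
            consistent_direction(a, b)


class TestIntersectLowIth:
    def _het(self, low, high):
        return pd.DataFrame(
            {
                "gene_id": low + high,
                "ith_class": ["low"] * len(low) + ["high"] * len(high),
            }
        )

    def test_basic_intersection(self):
        het = self._het(["B", "C", "D"], ["A"])
        assert intersect_low_ith(["A", "B", "C"], het) == ["B", "C"]

    def test_disjoint_gives_empty(self):
        het = self._het(["X"], [])
        assert intersect_low_ith(["A"], het) == []

    def test_duplicates_deduplicated(self):
        het = self._het(["A"], [])
        assert intersect_low_ith(["A", "A"], het) == ["A"]


class TestRiskScore:
    def test_published_weights_contract(self):
        model = default_risk_model()
        em = _expr([[0.0, 10.0], [0.0, 10.0]], ["CYP4B1", "GBP1"], ["s1", "s2"])
        scores = risk_score(em, model)
        assert scores["s1"] == pytest.approx(0.0)
        assert scores["s2"] == pytest.approx(0.024 * 10 + 0.02 * 10)  # 0.44

    def test_linearity_and_order_invariance(self):
        model = default_risk_model()
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 10, size=(2, 6))
        em = _expr(vals, ["CYP4B1", "GBP1"], [f"s{i}" for i in range(6)])
        doubled = _expr(2 * vals, ["CYP4B1", "GBP1"], [f"s{i}" for i in range(6)])
        np.testing.assert_allclose(
            risk_score(doubled, model), 2 * risk_score(em, model), atol=1e-12
        )
        perm = ["s3", "s1", "s5", "s0", "s2", "s4"]
        np.testing.assert_allclose(
            risk_score(em.subset_samples(perm), model),
            risk_score(em, model)[perm],
            atol=1e-12,
        )

    def test_missing_model_gene_rejected(self):
        em = _expr([[1.0, 2.0]], ["CYP4B1"], ["s1", "s2"])
        with pytest.raises(DataModelError, match="GBP1"):
            risk_score(em, default_risk_model())

    def test_model_validation(self):
        with pytest.raises(DataModelError):
            RiskModel(genes=("a",), weights=(1.0, 2.0))
        with pytest.raises(DataModelError):
            RiskModel(genes=("a",), weights=(float("inf"),))


class TestStratify:
    def test_median_split_even(self):
        labels = stratify_median(pd.Series([1, 2, 3, 4], index=list("abcd")))
        assert labels.tolist() == ["low", "low", "high", "high"]

    def test_tie_convention(self):
        labels = stratify_median(pd.Series([1, 2, 2, 4], index=list("abcd")))
        assert labels.tolist() == ["low", "low", "low", "high"]

    def test_all_identical_rejected(self):
        with pytest.raises(DataModelError, match="identical"):
            stratify_median(pd.Series([2.0, 2.0, 2.0]))

    def test_single_sample_rejected(self):
        with pytest.raises(DataModelError):
            stratify_median(pd.Series([5.0]))

    def test_tertile_and_fixed_rules(self):
        s = pd.Series(np.arange(9, dtype=float))
        assert (stratify(s, rule="tertile") == "high").sum() == 3
        assert (stratify(s, rule="fixed", value=7.5) == "high").sum() == 1
        with pytest.raises(DataModelError):
            stratify(s, rule="fixed")


class TestFunnelEndToEnd:
    def test_planted_genes_selected_no_false_positives(self):
        """On one seeded synthetic study the funnel output is a subset of
        the planted genes (the PH diagnostic may drop a planted gene)."""
        sc = generate_funnel_scenario(1)
        het = score_all_genes(sc["expr"], sc["smap"])
        de = simple_de(sc["tumor"], sc["normal"])
        (ea, sa), (eb, sb) = sc["cohorts"]
        selected = select_signature_genes(
            de, cox_screen(ea, sa), cox_screen(eb, sb), het
        )
        assert set(selected) <= set(sc["planted"])
        assert len(selected) >= 1
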