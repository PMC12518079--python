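import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tumorhet import (
    DataModelError,
    ExpressionMatrix,
    SampleMap,
    ccs,
    classify_ith,
    ihs,
    pgor_curve,
    score_all_genes,
)
from tumorhet.consistency import PgorCurve
from .conftest import pgor_by_enumeration


def _curve(pgor, gene="g"):
    pgor = np.asarray(pgor, dtype=float)
    return PgorCurve(
        gene_id=gene,
        k_values=np.arange(1, pgor.size + 1),
        pgor_values=pgor,
        n_evaluable_patients=2,
    )


class TestPgorCurve:
    @pytest.mark.parametrize("rule", ["ward", "average", "complete"])
    def test_hand_traced_two_patient_toy(self, rule):
        # P1:{0,0.1}, P2:{10,10.2}: both pairs merge first, so the cuts give
        # PGOR = [1, 1, 0.5, 0] and AUPC = 1 + 0.75 + 0.25 = 2.0
        curve = pgor_curve(
            np.array([0.0, 0.1, 10.0, 10.2]),
            np.array(["P1", "P1", "P2", "P2"], dtype=object),
            linkage_rule=rule,
        )
        np.testing.assert_allclose(curve.pgor_values, [1.0, 1.0, 0.5, 0.0])
        assert curve.aupc == pytest.approx(2.0)
        assert ccs(curve) == pytest.approx(1 / 3)

    def test_forced_endpoints(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=9)
        patients = np.repeat(["P1", "P2", "P3"], 3).astype(object)
        curve = pgor_curve(values, patients)
        assert curve.pgor_values[0] == 1.0  # k=1: one cluster holds everyone
        assert curve.pgor_values[-1] == 0.0  # k=N: singletons split all

    def test_no_multiregion_patient_error(self):
        with pytest.raises(DataModelError, match="undefined"):
            pgor_curve(
                np.array([1.0, 2.0]), np.array(["P1", "P2"], dtype=object)
            )

    @pytest.mark.parametrize("rule", ["ward", "average", "complete", "single"])
    def test_matches_bruteforce_enumeration_small_n(self, rule):
        """For N <= 6, every cut level must agree with naive agglomeration."""
        rng = np.random.default_rng(42)
        for trial in range(30):
            n = int(rng.integers(3, 7))
            values = rng.normal(size=n)
            # random patient assignment with at least one multi-region patient
            patients = rng.integers(0, max(2, n // 2), size=n)
            patients[: 2] = 0
            patients = np.array([f"P{p}" for p in patients], dtype=object)
            expected = pgor_by_enumeration(values, patients, rule)
            got = pgor_curve(values, patients, linkage_rule=rule).pgor_values
            np.testing.assert_allclose(got, expected, err_msg=f"{rule} trial {trial}")


class TestCcs:
    def test_from_hand_traced_curve(self):
        assert ccs(_curve([1, 1, 0.5, 0])) == pytest.approx(1 / 3)

    def test_maximal_consistency_gives_zero(self):
        assert ccs(_curve([1, 1, 1, 1, 1])) == pytest.approx(0.0)

    def test_immediate_breakup(self):
        n = 5
        value = ccs(_curve([1, 0, 0, 0, 0]))
        assert value == pytest.approx(1 - 0.5 / (n - 1))

    def test_needs_two_samples(self):
        with pytest.raises(DataModelError):
            ccs(_curve([1.0]))


class TestIhs:
    @pytest.mark.parametrize(
        "a,b,expected", [(0.25, 0.25, 0.25), (1, 0, 0.0), (0.9, 0.4, 0.6)]
    )
    def test_geometric_mean(self, a, b, expected):
        assert ihs(a, b) == pytest.approx(expected)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for a, b in rng.uniform(0, 1, size=(20, 2)):
            assert ihs(a, b) == pytest.approx(ihs(b, a))

    def test_nan_propagates(self):
        assert np.isnan(ihs(float("nan"), 0.5))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ihs(1.2, 0.5)


class TestClassify:
    def test_boundary_is_inclusive_low(self):
        labels = classify_ith(pd.Series([0.2, 0.5, 0.7]))
        assert labels.tolist() == ["low", "low", "high"]

    def test_zero_threshold(self):
        labels = classify_ith(pd.Series([0.0, 0.1]), threshold=0.0)
        assert labels.tolist() == ["low", "high"]

    def test_all_undefined_classifies_nothing(self):
        labels = classify_ith(pd.Series([np.nan, np.nan]))
        assert labels.tolist() == ["", ""]

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            classify_ith(pd.Series([0.5]), threshold=1.5)


class TestScoreAllGenes:
    def test_single_gene_table(self, two_patient_expr):
        em, sm = two_patient_expr
        table = score_all_genes(em, sm)
        assert len(table) == 1
        assert set(table.columns) >= {"gene_id", "ITVS", "CCS", "AUPC", "IHS", "ith_class"}

    def test_sample_permutation_invariance(self, small_cohort):
        em, sm = small_cohort
        base = score_all_genes(em, sm)
        rng = np.random.default_rng(9)
        perm = list(rng.permutation(em.sample_ids))
        shuffled = score_all_genes(em.subset_samples(perm), sm)
        for col in ("ITVS", "CCS", "IHS"):
            np.testing.assert_allclose(base[col], shuffled[col], atol=1e-12)

    def test_min_mean_expression_filter(self, small_cohort):
        em, sm = small_cohort
        hi = em.values.mean(axis=1).max()
        table = score_all_genes(em, sm, min_mean_expression=hi - 1e-9)
        assert len(table) == 1


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_ccs_always_in_unit_interval(seed):
    rng = np.random.default_rng(seed)
    n_pat = int(rng.integers(2, 5))
    regions = rng.integers(1, 4, size=n_pat)
    regions[0] = max(regions[0], 2)
    values = rng.normal(size=int(regions.sum()))
    patients = np.repeat([f"P{i}" for i in range(n_pat)], regions).astype(object)
    curve = pgor_curve(values, patients)
    assert 0.0 <= ccs(curve) <= 1.0
    assert curve.aupc <= values.size - 1 + 1e-12
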