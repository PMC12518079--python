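import numpy as np
import pandas as pd
import pytest

from tumorhet import (
    DataModelError,
    ExpressionMatrix,
    concordance,
    cox_screen,
    km_logrank,
    time_dependent_auc,
)
from .conftest import make_survival, two_group_logrank_chi2


def _screen_inputs(n=150, n_genes=6, effect=0.8, seed=0, ties=False):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_genes, n))
    hazard = 0.05 * np.exp(effect * X[0])
    t_event = rng.exponential(1 / hazard)
    censor = rng.uniform(0, np.quantile(t_event, 0.9), n)
    time = np.minimum(t_event, censor)
    if ties:
        time = np.round(time, 0) + 0.5
    event = (t_event <= censor).astype(int)
    em = ExpressionMatrix(
        pd.DataFrame(
            X, index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n)],
        )
    )
    return em, make_survival(time, event)


class TestCoxScreen:
    @pytest.mark.parametrize("ties", [False, True])
    def test_agrees_with_lifelines(self, ties):
        """Coefficients, p-values and the PH diagnostic must match the
        reference mixed implementation (Efron ties) closely."""
        from lifelines import CoxPHFitter
        from lifelines.statistics import proportional_hazard_test

        em, sf = _screen_inputs(ties=ties)
        screen = cox_screen(em, sf)
        for i, gene in enumerate(em.gene_ids):
            df = pd.DataFrame({"T": sf.time, "E": sf.event, "x": em.values[i]})
            cph = CoxPHFitter().fit(df, "T", "E")
            ref_ph = proportional_hazard_test(cph, df, time_transform="km")
            # lifelines stops at a looser score tolerance than our Newton
            # solver, so agreement is to ~1e-4, not machine precision
            row = screen.iloc[i]
            assert row["coef"] == pytest.approx(cph.params_["x"], abs=1e-4)
            assert row["p_value"] == pytest.approx(cph.summary["p"]["x"], abs=1e-3)
            # our diagnostic uses full-risk-set (Breslow-form) residuals, so
            # with tied deaths it deviates slightly more from lifelines
            assert row["ph_p"] == pytest.approx(
                float(np.asarray(ref_ph.p_value).ravel()[0]),
                abs=0.05 if ties else 0.02,
            )

    def test_detects_planted_effect(self):
        em, sf = _screen_inputs(effect=1.0, n=200)
        screen = cox_screen(em, sf)
        assert screen["significant"].iloc[0]
        assert screen["hr"].iloc[0] > 1

    def test_constant_covariate_flagged(self):
        em, sf = _screen_inputs(n_genes=2)
        const = ExpressionMatrix(
            pd.DataFrame(
                np.vstack([em.values[0], np.full(em.shape[1], 3.0)]),
                index=["g0", "const"],
                columns=em.sample_ids,
            )
        )
        screen = cox_screen(const, sf)
        assert bool(screen.set_index("gene_id").loc["const", "flagged"])
        assert not bool(screen.set_index("gene_id").loc["const", "significant"])

    def test_no_events_rejected(self):
        em, _ = _screen_inputs(n=20)
        sf = make_survival(np.arange(1, 21, dtype=float), np.zeros(20, dtype=int))
        with pytest.raises(DataModelError, match="no events"):
            cox_screen(em, sf)


class TestKmLogrank:
    def test_identical_groups_give_null_statistic(self):
        time = np.r_[np.arange(1.0, 11.0), np.arange(1.0, 11.0)]
        event = np.ones(20, dtype=int)
        sf = make_survival(time, event)
        res = km_logrank(sf, ["a"] * 10 + ["b"] * 10)
        assert res["chi2"] == pytest.approx(0.0, abs=1e-10)
        assert res["p_value"] == pytest.approx(1.0)

    def test_matches_hand_computed_risk_table(self):
        # 6 + 6 subjects, fixed times, some censoring
        time = np.array([1, 3, 4, 6, 8, 9, 2, 3, 5, 7, 7, 10], dtype=float)
        event = np.array([1, 1, 0, 1, 1, 1, 1, 1, 1, 1, 0, 1])
        group = ["a"] * 6 + ["b"] * 6
        sf = make_survival(time, event)
        expected = two_group_logrank_chi2(time, event, group)
        res = km_logrank(sf, group)
        assert res["chi2"] == pytest.approx(expected, abs=1e-6)

    def test_single_group_rejected(self):
        sf = make_survival(np.arange(1.0, 5.0), np.ones(4, dtype=int))
        with pytest.raises(DataModelError, match="2 groups"):
            km_logrank(sf, ["a"] * 4)

    def test_curves_are_proper_survival_functions(self):
        rng = np.random.default_rng(3)
        sf = make_survival(rng.exponential(10, 40) + 0.01, rng.integers(0, 2, 40))
        res = km_logrank(sf, ["a"] * 20 + ["b"] * 20)
        for curve in res["curves"].values():
            s = curve["survival"].to_numpy()
            assert (np.diff(s) <= 1e-12).all()
            assert s[0] <= 1.0 and s[-1] >= 0.0


class TestDiscrimination:
    def test_perfect_score_no_censoring(self):
        rng = np.random.default_rng(4)
        time = rng.exponential(10, 80) + 0.01
        sf = make_survival(time, np.ones(80, dtype=int))
        scores = -time  # exact risk ordering
        cidx = concordance(scores, sf)
        assert cidx == pytest.approx(1.0)
        auc = time_dependent_auc(scores, sf, np.quantile(time, [0.3, 0.6]))
        np.testing.assert_allclose(auc["auc"], 1.0)

    def test_all_equal_scores_c_half(self):
        sf = make_survival(np.arange(1.0, 21.0), np.ones(20, dtype=int))
        assert concordance(np.zeros(20), sf) == pytest.approx(0.5)

    def test_horizon_outside_follow_up_rejected(self):
        sf = make_survival(np.arange(1.0, 11.0), np.ones(10, dtype=int))
        with pytest.raises(DataModelError, match="horizon"):
            time_dependent_auc(np.zeros(10), sf, [50.0])

    def test_true_score_beats_random_score(self):
        """Paired comparison: the generating log-hazard outranks noise."""
        from tumorhet import SyntheticConfig, generate_survival

        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            score = rng.normal(0, 1, 150)
            cfg = SyntheticConfig(censoring_rate=0.2, seed=500 + seed)
            sf = generate_survival(score, cfg)
            c_true = concordance(score, sf)
            c_rand = concordance(rng.permutation(score), sf)
            wins += c_true > c_rand
        assert wins == n_rep
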