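import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import idmauc as m
from idmauc.cox import CoxFit, breslow_partial_loglik, _event_table

P = m.SIMULATION_TRUTH


class TestCountingProcess:
    def test_diagnosed_subject_splits_at_diagnosis(self, small_panel):
        rows = m.build_counting_process(small_panel)
        s1 = rows[rows.id == "s1"].reset_index(drop=True)
        assert list(s1.itertuples(index=False, name=None)) == [
            ("s1", 0.0, 6.0, 0, 0),
            ("s1", 6.0, 14.0, 1, 1),
        ]

    def test_undiagnosed_single_row(self, small_panel):
        rows = m.build_counting_process(small_panel)
        s2 = rows[rows.id == "s2"].iloc[0]
        assert (s2.tstart, s2.tstop, s2.x, s2.event) == (0.0, 7.2, 0, 0)

    def test_diagnosis_at_death_visit_convention(self):
        panel = m.PanelDataset(
            [m.SubjectRecord("d", [0.0, 6.0], [0, 1], 6.0, 1)]
        )
        rows = m.build_counting_process(panel, diseased_at_death=True)
        # no zero-length exposure interval with x=1, but the death carries x=1
        assert (rows.event == 1).sum() == 1
        assert rows[rows.event == 1].x.item() == 1
        rows0 = m.build_counting_process(panel, diseased_at_death=False)
        assert rows0[rows0.event == 1].x.item() == 0


class TestPartialLikelihood:
    def test_three_subject_brute_force_oracle(self):
        # A dies at 2 (never diseased); B diagnosed at 1, dies at 3;
        # C censored at 4.  Two-term Breslow partial likelihood.
        rows = pd.DataFrame(
            [
                ("A", 0.0, 2.0, 0, 1),
                ("B", 0.0, 1.0, 0, 0),
                ("B", 1.0, 3.0, 1, 1),
                ("C", 0.0, 4.0, 0, 0),
            ],
            columns=["id", "tstart", "tstop", "x", "event"],
        )
        _, d, d1, n0, n1 = _event_table(rows)
        oracle = minimize_scalar(
            lambda b: -breslow_partial_loglik(b, d, d1, n0, n1),
            bounds=(-10, 10),
            method="bounded",
            options={"xatol": 1e-10},
        )
        fit = m.fit_cox_td(rows)
        assert fit.beta == pytest.approx(oracle.x, abs=1e-6)
        # explicit two-term likelihood: -log(2+e^b) + b - log(1+e^b)
        direct = lambda b: -np.log(2 + np.exp(b)) + b - np.log(1 + np.exp(b))
        grid = np.linspace(-5, 5, 200001)
        assert fit.beta == pytest.approx(grid[np.argmax(direct(grid))], abs=1e-4)

    def test_null_marker_gives_zero_coefficient(self):
        # marker switch times independent of death: beta -> 0
        rng = np.random.default_rng(1)
        n = 800
        death = rng.exponential(50, n)
        switch = rng.uniform(0, 100, n)
        rows = []
        for i in range(n):
            t, r = death[i], switch[i]
            if r < t:
                rows += [(f"s{i}", 0.0, r, 0, 0), (f"s{i}", r, t, 1, 1)]
            else:
                rows += [(f"s{i}", 0.0, t, 0, 1)]
        fit = m.fit_cox_td(pd.DataFrame(rows, columns=["id", "tstart", "tstop", "x", "event"]))
        assert abs(fit.beta) < 3 * fit.se_beta

    def test_against_lifelines_on_tie_free_data(self):
        # continuous death times -> no ties -> Efron == Breslow
        lifelines = pytest.importorskip("lifelines")
        data = m.simulate_scenario(m.scenario("M", seed=77))
        rows = m.build_counting_process(data)
        fit = m.fit_cox_td(rows)
        ctv = lifelines.CoxTimeVaryingFitter()
        df = rows.rename(columns={"tstart": "start", "tstop": "stop"})
        df = df[df.start < df.stop]
        ctv.fit(df, id_col="id", start_col="start", stop_col="stop", event_col="event")
        assert fit.beta == pytest.approx(ctv.params_["x"], abs=1e-5)

    def test_separation_flagged(self):
        rows = pd.DataFrame(
            [("a", 0.0, 1.0, 0, 0), ("a", 1.0, 2.0, 1, 1), ("b", 0.0, 3.0, 0, 0)],
            columns=["id", "tstart", "tstop", "x", "event"],
        )
        fit = m.fit_cox_td(rows)
        assert fit.separated
        with pytest.raises(ValueError):
            m.CoxIDM(fit)


class TestAalenJohansen:
    def _tiny_fit(self):
        panel = m.PanelDataset(
            [
                m.SubjectRecord("s1", [0.0, 1.0], [0, 1], 2.0, 1),
                m.SubjectRecord("s2", [0.0], [0], 2.0, 1),
                m.SubjectRecord("s3", [0.0], [0], 3.0, 0),
                m.SubjectRecord("s4", [0.0, 1.0], [0, 1], 3.0, 0),
            ]
        )
        return m.fit_cox_td(m.build_counting_process(panel))

    def test_hand_computed_product(self):
        # two deaths at t=2 split evenly between marker levels in a
        # balanced risk set -> beta-hat = 0; dL01(1) = 2/4, Breslow
        # dL02(2) = 2/4: the two AJ factors multiply out by hand
        fit = self._tiny_fit()
        assert fit.beta == pytest.approx(0.0, abs=1e-8)
        model = m.CoxIDM(fit)
        np.testing.assert_allclose(
            model.transprob(0.0, 2.5)[0], [1 / 4, 1 / 4, 1 / 2], atol=1e-10
        )
        np.testing.assert_allclose(
            model.transprob_left(0.0, 2.0)[0], [1 / 2, 1 / 2, 0.0], atol=1e-10
        )

    def test_identity_at_equal_times(self):
        model = m.CoxIDM(self._tiny_fit())
        np.testing.assert_array_equal(model.transprob(5.0, 5.0), np.eye(3))

    def test_reduces_to_kaplan_meier_without_diagnoses(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        n = 300
        t = rng.exponential(30, n)
        c = rng.uniform(10, 60, n)
        tstar, delta = np.minimum(t, c), (t <= c).astype(int)
        panel = m.PanelDataset(
            [m.SubjectRecord(f"s{i}", [0.0], [0], tstar[i], delta[i]) for i in range(n)]
        )
        fit = m.fit_cox_td(m.build_counting_process(panel))
        model = m.CoxIDM(fit)
        km = lifelines.KaplanMeierFitter().fit(tstar, delta)
        for u in (5.0, 20.0, 40.0):
            assert model.transprob(0, u)[0, 0] == pytest.approx(
                km.predict(u), abs=1e-10
            )
        assert model.transprob(0, 40.0)[0, 1] == 0.0


class TestRisksetAUC:
    def test_uniform_weights_give_half(self):
        rows = pd.DataFrame(
            [("a", 0.0, 1.0, 0, 0), ("a", 1.0, 2.0, 1, 1), ("b", 0.0, 3.0, 0, 1)],
            columns=["id", "tstart", "tstop", "x", "event"],
        )
        fit = m.fit_cox_td(rows)
        flat = CoxFit(0.0, fit.se_beta, fit.loglik, False, fit.event_times,
                      fit.breslow_dL, fit.diag_times, fit.dL01)
        curve = m.riskset_auc_id(flat, rows)
        np.testing.assert_allclose(curve.values, 0.5, atol=1e-12)

    def test_all_diseased_risk_set_gives_half(self):
        rows = pd.DataFrame(
            [("a", 0.0, 0.5, 0, 0), ("a", 0.5, 2.0, 1, 1),
             ("b", 0.0, 0.5, 0, 0), ("b", 0.5, 3.0, 1, 0)],
            columns=["id", "tstart", "tstop", "x", "event"],
        )
        fit = m.fit_cox_td(rows)
        curve = m.riskset_auc_id(fit, rows)
        np.testing.assert_allclose(curve.values, 0.5, atol=1e-12)

    def test_agrees_with_transition_probability_curve(self, scenario_a_data):
        rows = m.build_counting_process(scenario_a_data)
        fit = m.fit_cox_td(rows)
        curve = m.riskset_auc_id(fit, rows)
        model = m.CoxIDM(fit)
        sel = (curve.times >= 6) & (curve.times <= 90)
        probs = np.array([m.auc_id_estimate(model, t).value for t in curve.times[sel]])
        assert np.mean(np.abs(curve.values[sel] - probs)) < 0.02

    def test_half_before_first_observed_diagnosis(self, scenario_a_data):
        model = m.CoxIDM(m.fit_cox_td(m.build_counting_process(scenario_a_data)))
        assert m.auc_id_estimate(model, 1.0).value == 0.5
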