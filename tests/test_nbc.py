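"""Naive-Bayes engine: discretization, fitting, posterior, VOI, NL."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import oracle_nl, oracle_posterior, oracle_voi
from conftest import make_binary_model
from nephrisk.errors import EvidenceError, InvalidInputError, TrainingError
from nephrisk.nbc import (
    fit_discretization,
    fit_nbc,
    load_model,
    normalized_likelihood,
    outcome_entropy,
    posterior_risk,
    predict,
    save_model,
    score_frame,
    value_of_information,
)
from nephrisk.variables import VariableSpec, specs_for_horizon


class TestDiscretization:
    def test_equal_frequency_edges_match_quantiles(self):
        values = np.arange(1, 101, dtype=float)
        spec = fit_discretization(values, VariableSpec("x", "continuous"), n_bins=5)
        assert spec.usable
        assert len(spec.bin_edges) == 4
        assert np.allclose(spec.bin_edges, [20.5, 40.5, 60.5, 80.5], atol=0.5)

    def test_constant_variable_flagged_unusable(self):
        spec = fit_discretization([3.0] * 50, VariableSpec("x", "continuous"))
        assert not spec.usable

    def test_all_missing_flagged_unusable(self):
        spec = fit_discretization([np.nan] * 20, VariableSpec("x", "continuous"))
        assert not spec.usable

    def test_two_bins_split_at_median(self):
        spec = fit_discretization([1, 2, 3, 4], VariableSpec("x", "continuous"), n_bins=2)
        assert spec.bin_edges == (2.5,)


class TestFitting:
    def test_laplace_smoothing_arithmetic(self):
        # 8 of 10 events have X=1, 2 levels, alpha=1 -> P(X=1|Y=1) = 9/12
        df = pd.DataFrame(
            {"x": [1] * 8 + [0] * 2 + [1] * 3 + [0] * 7, "y": [1] * 10 + [0] * 10}
        )
        model = fit_nbc(df, "y", (VariableSpec("x", "boolean"),), 24)
        assert model.cpts["x"][1, 1] == pytest.approx(9 / 12)
        assert model.cpts["x"][0, 1] == pytest.approx(4 / 12)
        assert model.prior == pytest.approx(0.5)

    def test_zero_count_cell_gets_smoothing_floor(self):
        df = pd.DataFrame({"x": [1] * 10 + [0] * 10, "y": [1] * 10 + [0] * 10})
        model = fit_nbc(df, "y", (VariableSpec("x", "boolean"),), 24)
        assert model.cpts["x"][1, 0] == pytest.approx(1 / 12)
        assert np.all(model.cpts["x"] > 0)

    def test_alpha_zero_gives_maximum_likelihood(self):
        df = pd.DataFrame(
            {"x": [1, 1, 1, 0, 1, 0, 0, 0], "y": [1, 1, 1, 1, 0, 0, 0, 0]}
        )
        model = fit_nbc(df, "y", (VariableSpec("x", "boolean"),), 24, smoothing_alpha=0)
        assert model.cpts["x"][1, 1] == pytest.approx(3 / 4)
        assert model.cpts["x"][0, 1] == pytest.approx(1 / 4)

    def test_missing_values_use_available_cases(self):
        df = pd.DataFrame(
            {
                "x": [1, 1, np.nan, np.nan, 0, np.nan, 0, 0],
                "y": [1, 1, 1, 1, 0, 0, 0, 0],
            }
        )
        model = fit_nbc(df, "y", (VariableSpec("x", "boolean"),), 24)
        # events: 2 observed, both x=1 -> (2+1)/(2+2)
        assert model.cpts["x"][1, 1] == pytest.approx(3 / 4)

    def test_single_class_cohort_rejected(self):
        df = pd.DataFrame({"x": [0, 1, 0], "y": [1, 1, 1]})
        with pytest.raises(TrainingError):
            fit_nbc(df, "y", (VariableSpec("x", "boolean"),), 24)

    def test_cpt_parameter_recovery_from_known_model(self):
        """Fitting draws from a known model drives CPT error below 0.02."""
        rng = np.random.default_rng(2024)
        true = make_binary_model(
            0.25, {"A": (0.3, 0.8), "B": (0.5, 0.7), "C": (0.9, 0.4)}
        )
        n = 10_000
        y = (rng.uniform(size=n) < true.prior).astype(int)
        df = pd.DataFrame({"y": y})
        for name in ("A", "B", "C"):
            p1 = true.cpts[name][1, 1]
            p0 = true.cpts[name][0, 1]
            df[name] = (rng.uniform(size=n) < np.where(y == 1, p1, p0)).astype(int)
        fitted = fit_nbc(df, "y", true.specs, 24)
        err = max(
            np.abs(fitted.cpts[name] - true.cpts[name]).max() for name in ("A", "B", "C")
        )
        assert err <= 0.02
        assert fitted.prior == pytest.approx(true.prior, abs=0.02)


class TestPosterior:
    def test_empty_evidence_returns_prior(self, micro_model):
        assert posterior_risk(micro_model, {}) == pytest.approx(0.2)

    def test_direct_bayes_arithmetic(self, micro_model):
        # 0.2*0.8 / (0.2*0.8 + 0.8*0.3) = 0.4
        assert posterior_risk(micro_model, {"A": 1}) == pytest.approx(0.4)

    def test_missing_variable_marginalizes(self, two_var_model, micro_model):
        assert posterior_risk(two_var_model, {"A": 1}) == pytest.approx(
            posterior_risk(micro_model, {"A": 1})
        )

    def test_unknown_variable_or_level_rejected(self, micro_model):
        with pytest.raises(EvidenceError):
            posterior_risk(micro_model, {"Z": 1})
        with pytest.raises(EvidenceError):
            posterior_risk(micro_model, {"A": 5})

    @given(
        prior=st.floats(0.01, 0.99),
        pa0=st.floats(0.01, 0.99),
        pa1=st.floats(0.01, 0.99),
        pb0=st.floats(0.01, 0.99),
        pb1=st.floats(0.01, 0.99),
        ev_a=st.sampled_from([None, 0, 1]),
        ev_b=st.sampled_from([None, 0, 1]),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_joint_enumeration_oracle(self, prior, pa0, pa1, pb0, pb1, ev_a, ev_b):
        model = make_binary_model(prior, {"A": (pa0, pa1), "B": (pb0, pb1)})
        evidence = {}
        if ev_a is not None:
            evidence["A"] = ev_a
        if ev_b is not None:
            evidence["B"] = ev_b
        cpts = {k: np.asarray(v) for k, v in model.cpts.items()}
        expected = oracle_posterior(prior, cpts, evidence)
        assert posterior_risk(model, evidence) == pytest.approx(expected, abs=1e-12)


class TestEntropy:
    @pytest.mark.parametrize(
        "p,h", [(0.5, 1.0), (0.0, 0.0), (1.0, 0.0), (0.25, 0.8112781244591328)]
    )
    def test_closed_form(self, p, h):
        assert outcome_entropy(p) == pytest.approx(h, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            outcome_entropy(1.2)


class TestVoi:
    def test_uninformative_variable_has_zero_voi(self):
        model = make_binary_model(0.2, {"A": (0.6, 0.6)})
        assert value_of_information(model, {}, "A") == pytest.approx(0.0, abs=1e-12)

    def test_micro_model_hand_computation(self, micro_model):
        # P(A=1) = 0.4; posteriors 0.4 (A=1) and 2/30 (A=0)
        def h(p):
            return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))

        expected = h(0.2) - (0.4 * h(0.4) + 0.6 * h(2 / 30))
        assert value_of_information(micro_model, {}, "A") == pytest.approx(
            expected, abs=1e-12
        )

    def test_observed_variable_rejected(self, micro_model):
        with pytest.raises(EvidenceError):
            value_of_information(micro_model, {"A": 1}, "A")

    @given(
        prior=st.floats(0.05, 0.95),
        pa0=st.floats(0.05, 0.95),
        pa1=st.floats(0.05, 0.95),
        pb0=st.floats(0.05, 0.95),
        pb1=st.floats(0.05, 0.95),
        ev_b=st.sampled_from([None, 0, 1]),
    )
    @settings(max_examples=100, deadline=None)
    def test_bounded_and_matches_oracle(self, prior, pa0, pa1, pb0, pb1, ev_b):
        model = make_binary_model(prior, {"A": (pa0, pa1), "B": (pb0, pb1)})
        evidence = {} if ev_b is None else {"B": ev_b}
        voi = value_of_information(model, evidence, "A")
        h = outcome_entropy(posterior_risk(model, evidence))
        assert 0.0 <= voi <= h + 1e-12
        cpts = {k: np.asarray(v) for k, v in model.cpts.items()}
        assert voi == pytest.approx(oracle_voi(prior, cpts, evidence, "A"), abs=1e-12)


class TestNormalizedLikelihood:
    def test_micro_model_lift(self, micro_model):
        assert normalized_likelihood(micro_model, {"A": 1}, "A") == pytest.approx(2.0)

    def test_uninformative_variable_is_one(self):
        model = make_binary_model(0.3, {"A": (0.4, 0.4)})
        assert normalized_likelihood(model, {"A": 1}, "A") == pytest.approx(1.0)

    def test_total_probability_identity(self, micro_model):
        # sum_x P(x) NL(x) = 1
        total = 0.0
        for level in (0, 1):
            cpt = micro_model.cpts["A"]
            p_x = 0.2 * cpt[1, level] + 0.8 * cpt[0, level]
            total += p_x * normalized_likelihood(micro_model, {"A": level}, "A")
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_equals_single_variable_posterior_lift(self, two_var_model):
        for level in (0, 1):
            nl = normalized_likelihood(two_var_model, {"A": level}, "A")
            lift = posterior_risk(two_var_model, {"A": level}) / two_var_model.prior
            assert nl == pytest.approx(lift, abs=1e-12)

    def test_missing_variable_rejected(self, micro_model):
        with pytest.raises(EvidenceError):
            normalized_likelihood(micro_model, {}, "A")

    def test_oracle_agreement(self, two_var_model):
        cpts = {k: np.asarray(v) for k, v in two_var_model.cpts.items()}
        for level in (0, 1):
            assert normalized_likelihood(
                two_var_model, {"A": level}, "A"
            ) == pytest.approx(oracle_nl(0.2, cpts, "A", level), abs=1e-12)


class TestPredictBundle:
    def test_fully_missing_record(self, two_var_model):
        pred = predict(two_var_model, {})
        assert pred.risk == pytest.approx(0.2)
        assert pred.impacts == ()
        assert {n for n, _ in pred.voi} == {"A", "B"}

    def test_fully_observed_record(self, two_var_model):
        pred = predict(two_var_model, {"A": 1, "B": 0})
        assert pred.voi == ()
        assert {n for n, _ in pred.impacts} == {"A", "B"}

    def test_partial_record_matches_components(self, two_var_model, micro_model):
        pred = predict(two_var_model, {"A": 1})
        assert pred.risk == pytest.approx(0.4)
        assert dict(pred.impacts)["A"] == pytest.approx(2.0)
        assert dict(pred.voi)["B"] == pytest.approx(
            value_of_information(two_var_model, {"A": 1}, "B")
        )

    def test_voi_ranking_descending_with_name_tiebreak(self):
        model = make_binary_model(
            0.2, {"A": (0.3, 0.8), "B": (0.3, 0.8), "C": (0.45, 0.55)}
        )
        pred = predict(model, {})
        names = [n for n, _ in pred.voi]
        values = [v for _, v in pred.voi]
        assert values == sorted(values, reverse=True)
        assert names[:2] == ["A", "B"]  # equal VOI: lexicographic

    def test_removing_noninformative_evidence_keeps_risk(self):
        model = make_binary_model(0.2, {"A": (0.3, 0.8), "N": (0.5, 0.5)})
        assert posterior_risk(model, {"A": 1, "N": 1}) == pytest.approx(
            posterior_risk(model, {"A": 1})
        )


class TestCalibrationInTheSmall:
    def test_mean_risk_matches_event_fraction_on_own_samples(self):
        """Scoring data sampled from the scoring model is calibrated."""
        rng = np.random.default_rng(7)
        model = make_binary_model(
            0.2, {"A": (0.3, 0.8), "B": (0.5, 0.7), "C": (0.8, 0.35)}
        )
        n = 20_000
        y = (rng.uniform(size=n) < model.prior).astype(int)
        df = pd.DataFrame()
        for name in ("A", "B", "C"):
            p1, p0 = model.cpts[name][1, 1], model.cpts[name][0, 1]
            df[name] = (rng.uniform(size=n) < np.where(y == 1, p1, p0)).astype(int)
        risks = score_frame(model, df)
        mc_se = y.std() / math.sqrt(n)
        assert abs(risks.mean() - y.mean()) < 4 * mc_se


class TestSerialization:
    def test_model_document_round_trips_exactly(self, tmp_path, registry_cohorts):
        train, _ = registry_cohorts
        train = train[train["event_24m"].notna()]
        model = fit_nbc(train, "event_24m", specs_for_horizon(24), 24)
        path = tmp_path / "model.yaml"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.prior == model.prior
        assert loaded.horizon_months == model.horizon_months
        assert loaded.variable_names == model.variable_names
        for name in model.variable_names:
            assert np.array_equal(loaded.cpts[name], model.cpts[name])
            assert loaded.spec(name).bin_edges == model.spec(name).bin_edges
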