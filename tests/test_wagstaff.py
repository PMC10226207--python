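"""Logit fit, marginal effects, and the concentration-index decomposition."""
import numpy as np
import pytest

import ineqdecomp as iq
from ineqdecomp.survey import DataError, DesignMatrix
from ineqdecomp.wagstaff import average_marginal_effects, decompose, fit_logit


def _design(columns: dict) -> DesignMatrix:
    names = list(columns)
    values = np.column_stack([np.asarray(v, dtype=float) for v in columns.values()])
    return DesignMatrix(column_names=names, values=values, reference_map={},
                        groups={n: n for n in names})


class TestFitLogit:
    def test_intercept_only_closed_form(self):
        n = 400
        y = np.zeros(n)
        y[:100] = 1  # prevalence 0.25
        design = _design({"z": np.r_[np.zeros(n // 2), np.ones(n // 2)]})
        # permute so z is independent of y
        rng = np.random.default_rng(0)
        perm = rng.permutation(n)
        fit = fit_logit(_design({"z": design.values[perm, 0]}), y)
        # with an uninformative regressor the intercept stays near logit(1/4)
        assert fit.intercept == pytest.approx(np.log(1 / 3), abs=0.25)

    def test_two_by_two_closed_form(self):
        # x=1: 30 ill / 70 not ; x=0: 10 ill / 90 not
        x = np.r_[np.ones(100), np.zeros(100)]
        y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        fit = fit_logit(_design({"x": x}), y)
        expected = np.log((30 / 70) / (10 / 90))
        assert float(fit.params["x"]) == pytest.approx(expected, abs=1e-6)
        assert float(fit.odds_ratios["x"]) == pytest.approx(3.857, abs=1e-3)
        assert fit.converged

    def test_collinear_design_raises_naming_columns(self):
        x = np.r_[np.ones(50), np.zeros(50)]
        y = np.r_[np.ones(30), np.zeros(40), np.ones(30)]
        with pytest.raises(DataError, match="rank deficient"):
            fit_logit(_design({"a": x, "b": 1 - x}), y)

    def test_single_class_outcome_raises(self):
        with pytest.raises(DataError, match="single class"):
            fit_logit(_design({"x": np.arange(10.0)}), np.ones(10))

    def test_separation_raises(self):
        x = np.r_[np.ones(30), np.zeros(30)]
        with pytest.raises(DataError, match="separation"):
            fit_logit(_design({"x": x}), x.copy())

    def test_parameter_recovery_on_synthetic_wave(self, schema):
        ds = iq.generate_wave(iq.default_baseline_spec(n=20000, seed=99))
        design = iq.encode_covariates(ds, schema)
        fit = fit_logit(design, ds.outcome, ds.weight)
        truth = iq.default_baseline_spec().outcome_coefficients
        for key, beta in truth.items():
            est = float(fit.params[key])
            se = float(fit.bse[key])
            assert abs(est - beta) < 3 * se, f"{key}: {est} vs {beta} (se {se})"


class TestMarginalEffects:
    def test_zero_coefficient_zero_ame(self):
        x = np.r_[np.ones(200), np.zeros(200)]
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=400).astype(float)
        design = _design({"x": x})
        fit = fit_logit(design, y)
        fit.params["x"] = 0.0
        ames = average_marginal_effects(fit, design)
        assert ames["x"] == 0.0

    def test_scale_factor_at_half_prevalence(self):
        # p == 0.5 everywhere -> sum w p(1-p) == 0.25, so AME == beta/4
        x = np.r_[np.ones(100), np.zeros(100)]
        y = np.r_[np.ones(50), np.zeros(50), np.ones(50), np.zeros(50)]
        design = _design({"x": x})
        fit = fit_logit(design, y)
        fit.params["x"] = 1.0
        fit.fitted = np.full(200, 0.5)
        ames = average_marginal_effects(fit, design)
        assert ames["x"] == pytest.approx(0.25)

    def test_ame_sign_matches_coefficient(self, small_wave, schema):
        design = iq.encode_covariates(small_wave, schema)
        fit = fit_logit(design, small_wave.outcome, small_wave.weight)
        ames = average_marginal_effects(fit, design, small_wave.weight)
        for name in design.column_names:
            assert np.sign(ames[name]) == np.sign(float(fit.params[name]))

    def test_discrete_ame_close_to_derivative_for_dummies(self, small_wave, schema):
        design = iq.encode_covariates(small_wave, schema)
        fit = fit_logit(design, small_wave.outcome, small_wave.weight)
        der = average_marginal_effects(fit, design, small_wave.weight)
        dis = average_marginal_effects(fit, design, small_wave.weight,
                                       kind="discrete")
        for name in design.column_names:
            if name == "children":
                continue
            assert np.sign(der[name]) == np.sign(dis[name])
            assert abs(der[name] - dis[name]) < 0.05


class TestDecomposition:
    def test_adding_up_identity_exact(self, small_results):
        dec = small_results.decomposition
        assert dec.explained + dec.residual == dec.total_ci
        assert dec.percent_explained + dec.percent_residual \
            == pytest.approx(100.0, abs=1e-9)
        for row in dec.rows:
            assert row.contribution == pytest.approx(
                row.elasticity * row.ci_k, abs=1e-15)

    def test_covariate_ci_uses_shared_ranks(self, small_wave, schema):
        """C_k must come from the outcome's rank vector, not a re-ranking
        of the covariate itself."""
        res = iq.WagstaffModel(small_wave, schema).fit()
        ranked = small_wave.ranked()
        richest = small_wave.covariates["wealth"].to_numpy() == "richest"
        expected = iq.concentration_index(
            richest.astype(float), ranks=ranked.ranks,
            weight=small_wave.weight).value
        row = {r.label: r for r in res.decomposition.rows}["wealth[richest]"]
        assert row.ci_k == pytest.approx(expected, abs=1e-12)
        assert row.ci_k > 0.5  # richest membership is concentrated among rich

    def test_dummy_elasticity_identity(self, small_results):
        """Elasticity of a dummy equals AME x level share / prevalence."""
        dec = small_results.decomposition
        mean_h = dec.mean_h
        for row in dec.rows:
            if row.label == "children":
                continue
            assert row.elasticity == pytest.approx(
                row.ame * row.mean_x / mean_h, abs=1e-12)

    def test_residual_share_small_and_stabilizes_with_n(self, schema):
        """On data drawn from the fitted model family the residual share
        is small at every n and settles near its population value (which
        is nonzero: the decomposition linearizes a logit mean) as n
        grows."""
        shares = []
        for n in (2000, 20000, 50000):
            ds = iq.generate_wave(iq.default_baseline_spec(n=n, seed=321))
            res = iq.WagstaffModel(ds, schema).fit()
            shares.append(res.decomposition.residual
                          / res.decomposition.total_ci)
        assert all(abs(s) < 0.06 for s in shares)
        assert abs(shares[2] - shares[1]) < 0.02

    def test_functional_surface_matches_model(self, small_wave, schema):
        design = iq.encode_covariates(small_wave, schema)
        ranked = small_wave.ranked()
        fit = fit_logit(design, small_wave.outcome, small_wave.weight)
        table = decompose(fit, design, ranked, small_wave.weight)
        model_table = iq.WagstaffModel(small_wave, schema).fit().decomposition
        assert table.total_ci == pytest.approx(model_table.total_ci, abs=1e-12)
        assert table.explained == pytest.approx(model_table.explained, abs=1e-12)

    def test_json_round_trip_full_precision(self, small_results):
        dec = small_results.decomposition
        clone = iq.DecompositionTable.from_json(dec.to_json())
        assert clone.total_ci == dec.total_ci
        assert [r.contribution for r in clone.rows] \
            == [r.contribution for r in dec.rows]


class TestOddsRatioTable:
    def test_reference_rows_render_dashes(self, small_results):
        table = small_results.odds_ratio_table()
        ref_rows = table[table["OR"] == "-"]
        # one dash row per categorical covariate
        assert set(ref_rows["covariate"]) == {
            "wealth", "education", "residence", "employment", "distance"}
        assert (ref_rows["level"].tolist()
                == ["poorest", "none", "urban", "not_working", "not_a_problem"])

    def test_aic_footer_present(self, small_results):
        table = small_results.odds_ratio_table()
        assert table.iloc[-1]["covariate"] == "AIC"
        assert float(table.iloc[-1]["OR"]) == pytest.approx(
            small_results.logit.aic)

    def test_zero_coefficient_gives_unit_or(self):
        x = np.r_[np.ones(100), np.zeros(100)]
        rng = np.random.default_rng(8)
        y = rng.integers(0, 2, 200).astype(float)
        design = _design({"x": x})
        fit = fit_logit(design, y)
        fit.params["x"] = 0.0
        table = iq.odds_ratio_table(fit, design)
        assert float(table.loc[table["level"] == "", "OR"].iloc[0]) == 1.0
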