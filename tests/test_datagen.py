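import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

import diagmiss as dm
from diagmiss.datagen import _phi_of_latent, _round_half_away
from diagmiss.errors import ConfigurationError, InfeasibleCorrelationError


class TestDiseasedMean:
    @pytest.mark.parametrize(
        "sens,spec,expected",
        [
            (0.5, 0.5, 0.0),
            (0.8, 0.8, 1.68324),  # 2 * Phi^-1(0.8)
            (0.9, 0.7, 1.80595),  # Phi^-1(0.7) + Phi^-1(0.9)
        ],
    )
    def test_values(self, sens, spec, expected):
        assert dm.diseased_mean(sens, spec) == pytest.approx(expected, abs=1e-4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            dm.diseased_mean(0.0, 0.8)
        with pytest.raises(ConfigurationError):
            dm.diseased_mean(0.8, 1.0)


class TestSolveLatentCorrelation:
    def test_zero_target_is_exact(self):
        assert dm.solve_latent_correlation(0.0, 0.3, -1.2) == 0.0

    def test_double_median_split_closed_form(self):
        # for two median splits: phi = (2/pi) * arcsin(rho)
        rho = dm.solve_latent_correlation(0.4, 0.0, 0.0)
        assert rho == pytest.approx(math.sin(0.4 * math.pi / 2), abs=1e-4)

    @pytest.mark.parametrize("phi,cut_a,cut_b", [(0.3, 0.5, -0.3), (0.45, 0.0, 0.8)])
    def test_round_trip(self, phi, cut_a, cut_b):
        rho = dm.solve_latent_correlation(phi, cut_a, cut_b)
        assert _phi_of_latent(rho, cut_a, cut_b) == pytest.approx(phi, abs=1e-6)

    def test_infeasible_target_names_bounds(self):
        # margins 0.9 / 0.5 bound the phi coefficient at sqrt(1/9) ~ 0.333
        with pytest.raises(InfeasibleCorrelationError) as err:
            dm.solve_latent_correlation(0.4, norm.ppf(0.1), 0.0)
        lo, hi = err.value.bounds
        assert hi == pytest.approx(1.0 / 3.0, abs=1e-3)
        assert lo < 0 < hi

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        phi=st.tuples(
            st.floats(0.05, 0.45), st.floats(0.05, 0.45)
        ).filter(lambda t: abs(t[0] - t[1]) > 0.02)
    )
    def test_strictly_increasing_in_target(self, phi):
        a, b = sorted(phi)
        assert dm.solve_latent_correlation(a, 0.2, -0.1) < dm.solve_latent_correlation(
            b, 0.2, -0.1
        )


class TestScenarioSpec:
    def test_rounding_rule_half_away_from_zero(self):
        assert _round_half_away(40.5) == 41
        assert _round_half_away(39.4) == 39
        sc = dm.ScenarioSpec(0.8, 0.8, "MCAR", 0.1, 0.1, 405)
        assert sc.n_diseased == 41  # 40.5 rounds away from zero

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ConfigurationError):
            dm.ScenarioSpec(0.8, 0.8, "MACR", 0.1, 0.1, 400)
        with pytest.raises(ConfigurationError):
            dm.ScenarioSpec(0.8, 0.8, "MCAR", 0.1, 0.0001, 400)  # n_D = 0
        with pytest.raises(ConfigurationError):
            dm.ScenarioSpec(1.2, 0.8, "MCAR", 0.1, 0.2, 400)


class TestBuildLatentModel:
    def test_cutoffs_and_means(self):
        sc = dm.ScenarioSpec(0.8, 0.8, "MCAR", 0.1, 0.2, 400)
        model = dm.build_latent_model(sc)
        assert model.cutoffs[0] == pytest.approx(norm.ppf(0.8), abs=1e-4)
        np.testing.assert_allclose(model.cutoffs[1:], (0.0, 5.0, 35.0))
        np.testing.assert_allclose(model.mean_nondiseased, (0.0, 0.0, 5.0, 35.0))
        assert model.mean_diseased[0] == pytest.approx(dm.diseased_mean(0.8, 0.8))

    def test_balanced_scenario_centred(self):
        sc = dm.ScenarioSpec(0.5, 0.5, "MCAR", 0.1, 0.2, 400)
        model = dm.build_latent_model(sc)
        assert model.mean_diseased[0] == 0.0
        assert model.cutoffs[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("sens,spec", [(0.7, 0.7), (0.8, 0.9), (0.9, 0.9)])
    def test_correlation_matrices_psd(self, sens, spec):
        sc = dm.ScenarioSpec(sens, spec, "MCAR", 0.1, 0.2, 400)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = dm.build_latent_model(sc)
        for corr in (model.corr_nondiseased, model.corr_diseased):
            assert np.linalg.eigvalsh(corr).min() >= -1e-10

    def test_extreme_margin_falls_back_with_warning(self):
        sc = dm.ScenarioSpec(0.9, 0.9, "MCAR", 0.1, 0.2, 400)
        with pytest.warns(UserWarning, match="unattainable"):
            dm.build_latent_model(sc)


class TestGenerateComplete:
    def test_group_sizes_deterministic(self):
        sc = dm.ScenarioSpec(0.8, 0.8, "MCAR", 0.1, 0.1, 400)
        table = dm.generate_complete(sc, dm.build_latent_model(sc), 3)
        assert len(table) == 400
        assert int(table["D"].sum()) == 40
        assert not table.isna().any().any()

    def test_seed_reproducibility(self):
        sc = dm.ScenarioSpec(0.7, 0.9, "MCAR", 0.1, 0.2, 400)
        model = dm.build_latent_model(sc)
        a = dm.generate_complete(sc, model, 123)
        b = dm.generate_complete(sc, model, 123)
        c = dm.generate_complete(sc, model, 124)
        assert a.equals(b)
        assert not a.equals(c)

    def test_covariates_median_split(self):
        sc = dm.ScenarioSpec(0.8, 0.8, "MCAR", 0.1, 0.2, 2000)
        table = dm.generate_complete(sc, dm.build_latent_model(sc), 9)
        for col in ("X1", "X2", "X3"):
            # binomial(2000, 0.5): 3 SE ~ 0.034
            assert table[col].mean() == pytest.approx(0.5, abs=0.04)

    def test_calibration_of_sens_spec(self):
        # mean complete-data estimates match truth within 3 Monte Carlo SEs
        sc = dm.ScenarioSpec(0.9, 0.9, "MCAR", 0.1, 0.4, 1600)
        model = dm.build_latent_model(sc)
        reps = 400
        sens = np.empty(reps)
        spec = np.empty(reps)
        for r in range(reps):
            c = dm.confusion_counts(dm.generate_complete(sc, model, r))
            sens[r] = c.tp / (c.tp + c.fn)
            spec[r] = c.tn / (c.tn + c.fp)
        se_sens = math.sqrt(0.9 * 0.1 / (sc.n_diseased * reps))
        se_spec = math.sqrt(0.9 * 0.1 / (sc.n_nondiseased * reps))
        assert abs(sens.mean() - 0.9) < 3 * se_sens
        assert abs(spec.mean() - 0.9) < 3 * se_spec

    def test_pooled_phi_coefficient_near_target(self):
        # symmetric scenario: both groups share margins, pooled phi = target
        sc = dm.ScenarioSpec(0.5, 0.5, "MCAR", 0.1, 0.2, 200000)
        table = dm.generate_complete(sc, dm.build_latent_model(sc), 17)
        for col in ("X1", "X2", "X3"):
            phi = np.corrcoef(table["Y"], table[col])[0, 1]
            assert phi == pytest.approx(0.4, abs=0.01)
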