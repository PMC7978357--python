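"""Rate laws, global fits, mechanism discrimination, 4PL dose-response."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from auxintor import synthetic_data as sd
from auxintor.inhibition_kinetics import (
    KineticParams,
    bootstrap_ci,
    fit_ic50,
    fit_model,
    four_pl,
    relative_activity,
    select_mechanism,
    velocity,
)

INHIBITED = ("competitive", "noncompetitive", "uncompetitive")

positive = st.floats(min_value=0.1, max_value=1e4)


def _params(mechanism, vmax=100.0, km=50.5, ki=2.4, alpha=2.0):
    if mechanism == "MM":
        return KineticParams("MM", vmax, km)
    if mechanism == "mixed":
        return KineticParams("mixed", vmax, km, ki, alpha)
    return KineticParams(mechanism, vmax, km, ki)


class TestVelocity:
    @pytest.mark.parametrize("mechanism", ("MM",) + INHIBITED + ("mixed",))
    def test_half_saturation_at_km_without_inhibitor(self, mechanism):
        p = _params(mechanism)
        assert velocity(p, 50.5, 0.0) == pytest.approx(50.0, abs=1e-12)

    @given(vmax=positive, km=positive, ki=positive, alpha=positive,
           s=st.floats(min_value=0.01, max_value=1e5))
    def test_all_mechanisms_reduce_to_mm_at_zero_inhibitor(self, vmax, km, ki, alpha, s):
        mm = velocity(KineticParams("MM", vmax, km), s, 0.0)
        for mech in INHIBITED:
            assert velocity(_params(mech, vmax, km, ki), s, 0.0) == pytest.approx(mm, rel=1e-12)
        assert velocity(_params("mixed", vmax, km, ki, alpha), s, 0.0) == pytest.approx(
            mm, rel=1e-12)

    def test_hand_evaluated_competitive_rate(self):
        # 100*300 / (50.5*(1 + 20/2.4) + 300) = 30000/771.333 = 38.894
        assert velocity(_params("competitive"), 300.0, 20.0) == pytest.approx(38.894, abs=0.001)

    def test_competitive_inhibition_is_surmountable_by_substrate(self):
        p = _params("competitive")
        assert velocity(p, 1e6 * p.km, 40.0) == pytest.approx(p.vmax, rel=1e-3)

    def test_noncompetitive_inhibition_is_not_surmountable(self):
        p = _params("noncompetitive", ki=10.0)
        assert velocity(p, 1e6 * p.km, 10.0) == pytest.approx(p.vmax / 2, rel=1e-3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            velocity(_params("competitive"), -1.0, 0.0)
        with pytest.raises(ValueError):
            velocity(_params("competitive"), 10.0, -5.0)


GRID = np.geomspace(10, 1000, 8)


class TestFitModel:
    @pytest.mark.parametrize("mechanism", INHIBITED + ("mixed",))
    def test_noiseless_data_recovered_to_high_precision(self, mechanism):
        truth = _params(mechanism)
        data, _ = sd.simulate_kinetics(truth, GRID, [0, 20, 40], cv=0.0, replicates=1, seed=0)
        fit = fit_model(data, mechanism)
        assert fit.converged
        assert fit.sse == pytest.approx(0.0, abs=1e-10)
        assert fit.params.vmax == pytest.approx(truth.vmax, rel=1e-4)
        assert fit.params.km == pytest.approx(truth.km, rel=1e-4)
        assert fit.params.ki == pytest.approx(truth.ki, rel=1e-4)

    def test_noiseless_mm_recovers_km(self):
        truth = _params("MM")
        data, _ = sd.simulate_kinetics(truth, GRID, [0.0], cv=0.0, replicates=1, seed=0)
        fit = fit_model(data, "MM")
        assert fit.params.km == pytest.approx(truth.km, rel=1e-6)

    def test_noisy_recovery_within_15_percent(self):
        truth = _params("competitive")
        data, _ = sd.simulate_kinetics(truth, GRID, [0, 20, 40], cv=0.05, replicates=3, seed=1)
        fit = fit_model(data, "competitive")
        assert fit.params.km == pytest.approx(truth.km, rel=0.15)
        assert fit.params.ki == pytest.approx(truth.ki, rel=0.15)

    def test_noisy_fit_beats_coarse_grid_search_oracle(self):
        """The optimizer's SSE must not exceed an exhaustive coarse grid search."""
        truth = _params("competitive")
        data, _ = sd.simulate_kinetics(truth, GRID, [0, 20, 40], cv=0.05, replicates=3, seed=2)
        S = data["substrate_uM"].to_numpy()
        I = data["inhibitor_uM"].to_numpy()
        v = data["velocity"].to_numpy()
        best_grid = np.inf
        for vmax in np.linspace(80, 120, 9):
            for km in np.geomspace(20, 120, 12):
                for ki in np.geomspace(0.5, 10, 12):
                    pred = vmax * S / (km * (1 + I / ki) + S)
                    best_grid = min(best_grid, float(np.sum((pred - v) ** 2)))
        fit = fit_model(data, "competitive")
        assert fit.sse <= best_grid + 1e-9

    def test_too_few_observations_rejected(self):
        data = pd.DataFrame({"substrate_uM": [10, 100], "inhibitor_uM": [0, 0],
                             "velocity": [5, 50], "replicate": [1, 1]})
        with pytest.raises(ValueError):
            fit_model(data, "competitive")

    def test_single_substrate_level_rejected(self):
        data = pd.DataFrame({"substrate_uM": [100] * 8, "inhibitor_uM": [0, 0, 20, 20] * 2,
                             "velocity": np.linspace(10, 60, 8), "replicate": 1})
        with pytest.raises(ValueError):
            fit_model(data, "competitive")

    def test_apparent_km_rises_linearly_with_inhibitor_under_competition(self):
        """Per-level MM fits on noiseless competitive data: Km_app = Km(1+I/Ki),
        Vmax invariant."""
        truth = _params("competitive")
        data, _ = sd.simulate_kinetics(truth, GRID, [0, 20, 40], cv=0.0, replicates=1, seed=0)
        km_app, vmax_app = [], []
        for level in (0, 20, 40):
            sub = data[data["inhibitor_uM"] == level].assign(inhibitor_uM=0.0)
            fit = fit_model(sub, "MM")
            km_app.append(fit.params.km)
            vmax_app.append(fit.params.vmax)
        expected = [truth.km * (1 + lev / truth.ki) for lev in (0, 20, 40)]
        assert np.allclose(km_app, expected, rtol=1e-4)
        assert np.allclose(vmax_app, truth.vmax, rtol=1e-4)

    def test_apparent_vmax_falls_under_noncompetitive_inhibition(self):
        truth = _params("noncompetitive", ki=10.0)
        data, _ = sd.simulate_kinetics(truth, GRID, [0, 20, 40], cv=0.0, replicates=1, seed=0)
        for level in (0, 20, 40):
            sub = data[data["inhibitor_uM"] == level].assign(inhibitor_uM=0.0)
            fit = fit_model(sub, "MM")
            assert fit.params.vmax == pytest.approx(truth.vmax / (1 + level / truth.ki),
                                                    rel=1e-4)
            assert fit.params.km == pytest.approx(truth.km, rel=1e-4)


class TestSelectMechanism:
    @pytest.mark.parametrize("true_mech", INHIBITED)
    def test_true_mechanism_ranked_first_on_seeded_data(self, true_mech):
        truth = _params(true_mech, ki=5.0)
        data, _ = sd.simulate_kinetics(truth, GRID, [0, 20, 40], cv=0.05, replicates=3, seed=3)
        fits = select_mechanism(data, candidates=INHIBITED)
        assert fits[0].params.mechanism == true_mech

    def test_parsimony_prefers_mm_on_uninhibited_data(self):
        data, _ = sd.simulate_kinetics(_params("MM"), GRID, [0.0], cv=0.0, replicates=2, seed=0)
        fits = select_mechanism(data, candidates=("MM", "competitive", "noncompetitive"))
        assert fits[0].params.mechanism == "MM"

    @pytest.mark.parametrize("true_mech", INHIBITED)
    def test_selection_accuracy_at_least_90_percent(self, true_mech):
        """AICc picks the generating mechanism in >= 90 of 100 seeded runs (5% CV)."""
        truth = _params(true_mech, ki=5.0)
        wins = 0
        for seed in range(100):
            data, _ = sd.simulate_kinetics(truth, GRID, [0, 20, 40], cv=0.05,
                                           replicates=3, seed=seed)
            fits = select_mechanism(data, candidates=("MM",) + INHIBITED)
            wins += fits[0].params.mechanism == true_mech
        assert wins >= 90


class TestBootstrap:
    DATA_ARGS = dict(substrate_grid=GRID, inhibitor_levels=[0, 20, 40], replicates=2)

    def test_zero_noise_gives_zero_width_intervals(self):
        data, _ = sd.simulate_kinetics(_params("competitive"), cv=0.0, seed=0,
                                       **self.DATA_ARGS)
        fit = bootstrap_ci(data, "competitive", n_boot=100, seed=0)
        for lo, hi in fit.ci.values():
            assert hi - lo == pytest.approx(0.0, abs=1e-6 * max(abs(hi), 1.0))

    def test_same_seed_reproduces_identical_intervals(self):
        data, _ = sd.simulate_kinetics(_params("competitive"), cv=0.05, seed=1,
                                       **self.DATA_ARGS)
        a = bootstrap_ci(data, "competitive", n_boot=100, seed=5)
        b = bootstrap_ci(data, "competitive", n_boot=100, seed=5)
        assert a.ci == b.ci

    def test_intervals_contain_point_estimate(self):
        data, _ = sd.simulate_kinetics(_params("competitive"), cv=0.05, seed=2,
                                       **self.DATA_ARGS)
        fit = bootstrap_ci(data, "competitive", n_boot=100, seed=3)
        assert fit.ci["km"][0] <= fit.params.km <= fit.ci["km"][1]
        assert fit.ci["ki"][0] <= fit.params.ki <= fit.ci["ki"][1]

    def test_coverage_of_true_km_across_simulations(self):
        """95% percentile intervals cover the true Km in >= 88% of 200 datasets."""
        truth = _params("competitive")
        covered = 0
        for seed in range(200):
            data, _ = sd.simulate_kinetics(truth, GRID, [0, 20, 40], cv=0.05,
                                           replicates=1, seed=seed)
            fit = bootstrap_ci(data, "competitive", n_boot=100, seed=seed)
            lo, hi = fit.ci["km"]
            covered += lo <= truth.km <= hi
        assert covered >= 0.88 * 200


class TestFitIC50:
    DOSES = [0.0] + list(np.geomspace(0.05, 5, 8))

    def test_exact_4pl_data_recovered(self):
        data, _ = sd.simulate_dose_response(0.6, hill=1.0, doses=self.DOSES, cv=0.0, seed=0)
        fit = fit_ic50(data["dose"], data["response"])
        assert fit.converged
        assert fit.ic50 == pytest.approx(0.6, rel=1e-6)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)

    def test_flat_curve_is_a_fit_failure(self):
        doses = np.array([0, 0.1, 0.5, 1, 5], dtype=float)
        fit = fit_ic50(doses, np.full_like(doses, 50.0))
        assert not fit.converged

    @pytest.mark.parametrize("ic50,seed", [(0.6, 1), (2.35, 2)])
    def test_noisy_recovery_within_15_percent(self, ic50, seed):
        doses = [0.0] + list(np.geomspace(ic50 / 12, ic50 * 8, 8))
        data, _ = sd.simulate_dose_response(ic50, hill=1.0, doses=doses, cv=0.05,
                                            replicates=3, seed=seed)
        fit = fit_ic50(data["dose"], data["response"])
        assert fit.ic50 == pytest.approx(ic50, rel=0.15)

    def test_bottom_constrained_non_negative(self):
        data, _ = sd.simulate_dose_response(0.6, hill=1.5, top=100, bottom=0,
                                            doses=self.DOSES, cv=0.05, replicates=3, seed=4)
        fit = fit_ic50(data["dose"], data["response"])
        assert fit.bottom >= 0

    def test_too_few_dose_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_ic50([0, 1, 2, 3], [100, 60, 30, 10])

    def test_missing_zero_dose_rejected(self):
        with pytest.raises(ValueError):
            fit_ic50([0.1, 0.5, 1, 2, 5], [100, 80, 50, 30, 10])


class TestRelativeActivity:
    def test_equal_target_and_loading_gives_100_percent(self):
        table = pd.DataFrame({"condition": ["ref", "a", "b"],
                              "target_signal": [3.0, 5.0, 7.0],
                              "loading_signal": [3.0, 5.0, 7.0]})
        out = relative_activity(table, reference_condition="ref")
        assert np.allclose(out["activity_pct"], 100.0)

    def test_halved_target_gives_50_percent(self):
        table = pd.DataFrame({"condition": ["ref", "half"],
                              "target_signal": [4.0, 2.0],
                              "loading_signal": [4.0, 4.0]})
        out = relative_activity(table, reference_condition="ref").set_index("condition")
        assert out.loc["half", "activity_pct"] == pytest.approx(50.0)

    def test_matches_hand_normalization_on_random_table(self, rng):
        table = pd.DataFrame({
            "condition": [f"c{i}" for i in range(8)],
            "target_signal": rng.uniform(1, 10, 8),
            "loading_signal": rng.uniform(1, 10, 8),
        })
        out = relative_activity(table, reference_condition="c0")
        ratios = table["target_signal"] / table["loading_signal"]
        expected = 100 * ratios / ratios.iloc[0]
        assert np.allclose(out["activity_pct"], expected)

    def test_zero_loading_signal_rejected(self):
        table = pd.DataFrame({"condition": ["ref"], "target_signal": [1.0],
                              "loading_signal": [0.0]})
        with pytest.raises(ValueError):
            relative_activity(table)
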