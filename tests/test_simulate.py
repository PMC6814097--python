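"""Synthetic-cohort generator: calibration, determinism, observation
schemes and full-loop recovery."""

import numpy as np
import pytest

import ltcmsm as L
from ltcmsm.data import OBS_EXACT_DEATH, OBS_EXACT_TRANSITION, OBS_SNAPSHOT


class TestDefaultTrueModel:
    def test_calibration_targets(self):
        tm = L.default_true_model()
        assert round(L.transition_rate_ratio(tm.params, (1, 2), (1, 3)).value, 2) == 11.08
        assert round(L.mean_sojourn_time(tm.params, 3), 2) == 2.51
        assert round(L.mean_sojourn_time(tm.params, 1), 2) == 7.95

    def test_rates_positive_and_structure_progressive(self):
        tm = L.default_true_model()
        Q = L.build_generator(tm.params)
        assert all(
            Q[i, j] > 0 for i, j in tm.structure.transitions
        )
        assert tm.structure.is_acyclic()

    def test_effect_presets_keep_mean_linear_predictor(self):
        # baseline shift compensates beta' E[z], so the rate at the average
        # covariate profile equals the calibrated rate
        tm = L.default_true_model(effects="table")
        means = {g.name: g.mean() for g in tm.covariate_generators}
        Q = L.build_generator(tm.params, means)
        for (i, j), rate in L.CALIBRATED_RATES.items():
            assert Q[i - 1, j - 1] == pytest.approx(rate, rel=1e-9)

    def test_single_preset_has_published_style_effect(self):
        tm = L.default_true_model(effects="single")
        k = tm.structure.transition_index(0, 1)
        assert np.exp(tm.params.coefficients[k]["high_need"]) == pytest.approx(1.5)


class TestSimulateSubject:
    def test_vanishing_rates_leave_subject_censored_in_state_one(self, structure):
        params = L.IntensityParameters.from_rates(
            structure, {k: 1e-12 for k in L.CALIBRATED_RATES}
        )
        traj = L.simulate_subject(
            params, {}, 10.0, np.random.default_rng(0)
        )
        assert traj == [(0.0, 0)]

    def test_same_seed_reproduces_trajectory(self, calibrated_params):
        t1 = L.simulate_subject(
            calibrated_params, {}, 10.0, np.random.default_rng(42)
        )
        t2 = L.simulate_subject(
            calibrated_params, {}, 10.0, np.random.default_rng(42)
        )
        assert t1 == t2

    def test_cohort_is_order_independent_and_seeded(self):
        tm1 = L.default_true_model(n=50, seed=9)
        tm2 = L.default_true_model(n=50, seed=9)
        tr1, cov1 = L.simulate_cohort(tm1)
        tr2, cov2 = L.simulate_cohort(tm2)
        assert tr1 == tr2
        assert cov1.equals(cov2)
        tr3, _ = L.simulate_cohort(L.default_true_model(n=50, seed=10))
        assert tr1 != tr3

    def test_trajectories_are_progressive_and_censored(self, small_cohort):
        _, trajectories, _ = small_cohort
        for traj in trajectories:
            states = [s for _, s in traj]
            times = [t for t, _ in traj]
            assert states[0] == 0 and times[0] == 0.0
            assert all(b > a for a, b in zip(states, states[1:]))
            assert all(t < 10.0 for t in times)


@pytest.fixture(scope="module")
def big_cohort():
    tm = L.default_true_model(n=20000, seed=2)
    trajectories, cov = L.simulate_cohort(tm)
    return tm, trajectories, cov


class TestEmpiricalCalibration:
    def test_state1_ten_year_occupancy(self, big_cohort):
        tm, trajectories, _ = big_cohort
        p = np.exp(-10.0 * 0.12579)
        frac = np.mean([len(t) == 1 for t in trajectories])
        mc3 = 3 * np.sqrt(p * (1 - p) / len(trajectories))
        assert abs(frac - p) < mc3

    def test_first_destination_distribution(self, big_cohort):
        _, trajectories, _ = big_cohort
        firsts = [t[1][1] for t in trajectories if len(t) > 1]
        n = len(firsts)
        expect = {1: 0.81982, 2: 0.07400, 3: 0.10618}
        for state, p in expect.items():
            frac = np.mean([f == state for f in firsts])
            assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_covariate_marginals_match_published_prevalences(self, big_cohort):
        _, _, cov = big_cohort
        n = len(cov)
        for name, p in L.COVARIATE_PREVALENCES.items():
            assert abs(cov[name].mean() - p) < 3 * np.sqrt(p * (1 - p) / n)
        assert 77.5 < cov["age"].median() < 79.5

    def test_censoring_corrected_mean_exit_time(self, big_cohort):
        # for an exponential exit censored at T, E[min(X, T)] =
        # (1 - exp(-qT))/q; invert the empirical mean to recover 1/q = 7.95
        _, trajectories, _ = big_cohort
        waits = [t[1][0] if len(t) > 1 else 10.0 for t in trajectories]
        mean_obs = np.mean(waits)
        from scipy.optimize import brentq

        q = brentq(lambda q: (1 - np.exp(-q * 10.0)) / q - mean_obs, 1e-3, 2.0)
        se = np.std(waits, ddof=1) / np.sqrt(len(waits))
        # propagate the MC error of the mean through the inversion slope
        slope = abs(
            (1 - np.exp(-10 * q)) / q**2 - 10 * np.exp(-10 * q) / q
        )
        assert abs(1 / q - 7.95) < 3 * se / (slope * q**2) + 0.02


class TestObserveCohort:
    def test_censored_trajectory_on_three_year_grid(self, structure):
        scheme = L.ObservationScheme.from_name("panel-3yr", 10.0)
        cov = _frame(["w1"])
        data = L.observe_cohort([[(0.0, 0)]], cov, scheme, structure, 10.0)
        obs = data.subjects[0].observations
        assert [(o.time, o.state, o.obs_type) for o in obs] == [
            (0.0, 0, OBS_SNAPSHOT),
            (3.0, 0, OBS_SNAPSHOT),
            (6.0, 0, OBS_SNAPSHOT),
            (9.0, 0, OBS_SNAPSHOT),
        ]
        assert not data.fully_observed

    def test_exact_scheme_maps_events_directly(self, structure):
        scheme = L.ObservationScheme.from_name("exact", 10.0)
        traj = [(0.0, 0), (2.4, 1), (7.1, 3)]
        data = L.observe_cohort([traj], _frame(["w1"]), scheme, structure, 10.0)
        obs = data.subjects[0].observations
        assert [(o.time, o.state, o.obs_type) for o in obs] == [
            (0.0, 0, OBS_SNAPSHOT),
            (2.4, 1, OBS_EXACT_TRANSITION),
            (7.1, 3, OBS_EXACT_DEATH),
        ]
        assert data.fully_observed

    def test_frequency_table_round_trip(self, small_cohort):
        """The table from exact-scheme observations equals the table
        computed directly from the trajectories."""
        tm, trajectories, data = small_cohort
        from ltcmsm.data import PanelObservation, Subject

        direct_subjects = [
            Subject(str(k), [PanelObservation(t, s) for t, s in traj])
            for k, traj in enumerate(trajectories)
        ]
        direct = L.multistate_frequency_table(
            L.PanelDataset(tm.structure, direct_subjects)
        )
        observed = L.multistate_frequency_table(data)
        assert observed.equals(direct)

    def test_observed_data_satisfy_all_invariants(self, small_cohort):
        _, _, data = small_cohort
        data.validate()


class TestFullLoopRecovery:
    def test_published_effect_sizes_are_recovered(self):
        """Simulate with the published hazard ratios as truth, fit the same
        model, and recover the coefficients on well-observed transitions.

        With ~50 coefficients compared at the 3-SE level, one excursion is
        within expectation; more than one, or any beyond 4.5 SE, fails.
        """
        tm = L.default_true_model(effects="table", n=4000, seed=0)
        trajectories, cov = L.simulate_cohort(tm)
        data = L.observe_cohort(
            trajectories, cov, tm.scheme, tm.structure, tm.horizon
        )
        names = list(L.TABLE_HAZARD_RATIOS)
        fitted = L.fit(data, names)
        tab = L.multistate_frequency_table(data).values
        se = fitted.se_theta()
        z_scores = []
        for k, (i, j) in enumerate(tm.structure.transitions):
            if tab[i, j] < 200:
                continue
            for name in names:
                pos = fitted._beta_position((i + 1, j + 1), name)
                truth = tm.params.coefficients[k][name]
                z_scores.append(abs(fitted.theta[pos] - truth) / se[pos])
        z_scores = np.asarray(z_scores)
        assert len(z_scores) >= 18  # at least two transitions well observed
        assert (z_scores > 3.0).sum() <= 1
        assert z_scores.max() < 4.5


def _frame(ids):
    import pandas as pd

    return pd.DataFrame({"age": [78.0] * len(ids)}, index=ids)
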