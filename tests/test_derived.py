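"""Reported summaries: rate ratios, next-state probabilities, sojourns,
lengths of stay, survival, frequency tables and prevalence."""

import numpy as np
import pytest

import ltcmsm as L
from ltcmsm.data import (
    OBS_EXACT_DEATH,
    OBS_EXACT_TRANSITION,
    PanelObservation,
    Subject,
)


class TestTransitionRateRatio:
    def test_identical_transitions_give_one(self, calibrated_params):
        est = L.transition_rate_ratio(calibrated_params, (1, 2), (1, 2))
        assert est.value == 1.0

    def test_calibrated_defaults_reproduce_printed_trr(self, calibrated_params):
        est = L.transition_rate_ratio(calibrated_params, (1, 2), (1, 3))
        assert round(est.value, 2) == 11.08

    def test_ratio_algebra_consistency(self, structure):
        rng = np.random.default_rng(8)
        rates = {
            (i + 1, j + 1): rng.uniform(0.05, 1.0) for i, j in structure.transitions
        }
        params = L.IntensityParameters.from_rates(structure, rates)
        a = L.transition_rate_ratio(params, (1, 2), (1, 3)).value
        b = L.transition_rate_ratio(params, (1, 2), (1, 4)).value
        c = L.transition_rate_ratio(params, (1, 3), (1, 4)).value
        assert a == pytest.approx(b / c, abs=1e-12)


class TestNextStateProbabilities:
    def test_two_equal_exits_split_evenly(self):
        st = L.TransitionStructure(("A", "B", "C"), [(0, 1), (0, 2)], {1, 2})
        params = L.IntensityParameters.from_rates(st, {(1, 2): 0.4, (1, 3): 0.4})
        probs = L.next_state_probabilities(params, "A")
        assert probs == {"B": 0.5, "C": 0.5}

    def test_printed_state1_ratios_round_to_published_values(self, structure):
        # intensities in proportion 1 : 1/11.08 : 1/7.72 (printed TRRs)
        params = L.IntensityParameters.from_rates(
            structure,
            {
                (1, 2): 1.0,
                (1, 3): 1 / 11.08,
                (1, 4): 1 / 7.72,
                (2, 3): 1.69,
                (2, 4): 1.0,
                (3, 4): 1.0,
            },
        )
        p1 = L.next_state_probabilities(params, 1)
        assert [round(p1[s], 2) for s in ("HACC", "RAC", "Death")] == [
            0.82,
            0.07,
            0.11,
        ]
        p2 = L.next_state_probabilities(params, "HACC")
        assert [round(p2[s], 2) for s in ("RAC", "Death")] == [0.63, 0.37]

    def test_distribution_sums_to_one(self, calibrated_params):
        for state in (1, 2, 3):
            probs = L.next_state_probabilities(calibrated_params, state)
            assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_absorbing_state_rejected(self, calibrated_params):
        with pytest.raises(L.AbsorbingStateError):
            L.next_state_probabilities(calibrated_params, "Death")


class TestMeanSojournTime:
    def test_calibrated_state1_matches_printed_stay(self, calibrated_params):
        assert round(L.mean_sojourn_time(calibrated_params, 1), 2) == 7.95

    def test_doubling_rates_halves_sojourns(self, structure, calibrated_params):
        doubled = L.IntensityParameters.from_rates(
            structure, {k: 2 * v for k, v in L.CALIBRATED_RATES.items()}
        )
        for s in (1, 2, 3):
            assert L.mean_sojourn_time(doubled, s) == pytest.approx(
                L.mean_sojourn_time(calibrated_params, s) / 2, rel=1e-12
            )

    def test_simple_reciprocal(self):
        st = L.TransitionStructure(("A", "B"), [(0, 1)], {1})
        params = L.IntensityParameters.from_rates(st, {(1, 2): 0.5})
        assert L.mean_sojourn_time(params, "A") == pytest.approx(2.0)

    def test_absorbing_state_rejected(self, calibrated_params):
        with pytest.raises(L.AbsorbingStateError):
            L.mean_sojourn_time(calibrated_params, 4)


@pytest.fixture(scope="module")
def two_state():
    st = L.TransitionStructure(("A", "B"), [(0, 1)], {1})
    return L.IntensityParameters.from_rates(st, {(1, 2): 1 / 3.0})


class TestTotalLengthOfStay:
    def test_infinite_horizon_equals_exponential_mean(self, two_state):
        assert L.total_length_of_stay(two_state, 1, 1, None) == pytest.approx(3.0)

    def test_finite_horizon_closed_form(self, two_state):
        lam, T = 1 / 3.0, 10.0
        expected = (1 - np.exp(-lam * T)) / lam
        assert L.total_length_of_stay(two_state, 1, 1, T) == pytest.approx(
            expected, rel=1e-9
        )

    def test_matches_trapezoid_oracle(self, calibrated_params, calibrated_Q):
        value = L.total_length_of_stay(calibrated_params, 1, 2, 10.0)
        grid = np.arange(0.0, 10.0 + 1e-12, 1e-3)
        curve = [
            L.transition_probability_matrix(calibrated_Q, t)[0, 1] for t in grid
        ]
        assert value == pytest.approx(np.trapezoid(curve, grid), abs=1e-5)

    def test_absorbing_target_diverges(self, calibrated_params):
        with pytest.raises(L.AbsorbingStateError):
            L.total_length_of_stay(calibrated_params, 1, "Death", None)


class TestSurvivalProbability:
    def test_certain_survival_at_time_zero(self, calibrated_params):
        assert L.survival_probability(calibrated_params, 1, 0.0) == 1.0

    def test_death_state_never_survives(self, calibrated_params):
        assert L.survival_probability(calibrated_params, "Death", 5.0) == 0.0

    def test_single_exit_state_closed_form(self, calibrated_params, calibrated_Q):
        q34 = L.CALIBRATED_RATES[(3, 4)]
        s = L.survival_probability(calibrated_params, "RAC", 10.0)
        assert s == pytest.approx(np.exp(-10 * q34), abs=1e-10)
        assert s == pytest.approx(
            1 - L.transition_probability_matrix(calibrated_Q, 10.0)[2, 3],
            abs=1e-10,
        )


class TestMultistateFrequencyTable:
    def test_hand_enumerated_toy_cohort(self, structure):
        subjects = [
            Subject(
                "a",
                [
                    PanelObservation(0.0, 0),
                    PanelObservation(1.0, 1, OBS_EXACT_TRANSITION),
                    PanelObservation(2.0, 3, OBS_EXACT_DEATH),
                ],
            ),
            Subject("b", [PanelObservation(0.0, 0), PanelObservation(10.0, 0)]),
            Subject(
                "c",
                [
                    PanelObservation(0.0, 0),
                    PanelObservation(4.0, 2, OBS_EXACT_TRANSITION),
                    PanelObservation(10.0, 2),
                ],
            ),
        ]
        tab = L.multistate_frequency_table(L.PanelDataset(structure, subjects))
        assert tab.values.tolist() == [
            [1, 1, 1, 0],
            [0, 0, 0, 1],
            [0, 0, 1, 0],
            [0, 0, 0, 1],
        ]

    def test_all_censored_cohort(self, structure):
        subjects = [
            Subject(f"s{k}", [PanelObservation(0.0, 0), PanelObservation(10.0, 0)])
            for k in range(7)
        ]
        tab = L.multistate_frequency_table(L.PanelDataset(structure, subjects))
        assert np.diag(tab.values).tolist() == [7, 0, 0, 0]
        assert tab.values.sum() == 7

    def test_conservation_on_simulated_cohort(self, small_cohort):
        _, _, data = small_cohort
        tab = L.multistate_frequency_table(data).values
        # everyone starts in state 1
        assert tab[0].sum() == data.n_subjects
        # subjects ever in state j = inflow from elsewhere (column) for j > 1
        for j in (1, 2):
            assert tab[j].sum() == tab[:j, j].sum()


class TestPrevalenceGof:
    def test_time_zero_mass_in_state_one(self, small_cohort):
        tm, _, data = small_cohort
        series = L.prevalence_gof(tm.params, data, [0.0])
        n = data.n_subjects
        assert series.observed[0].tolist() == [n, 0, 0, 0]
        assert series.expected[0] == pytest.approx([n, 0, 0, 0], abs=1e-9)

    def test_expected_counts_conserve_cohort_size(self, small_cohort):
        tm, _, data = small_cohort
        series = L.prevalence_gof(tm.params, data, np.arange(0.0, 10.5, 0.5))
        assert np.abs(series.expected.sum(axis=1) - data.n_subjects).max() < 1e-6
        assert (series.observed.sum(axis=1) == data.n_subjects).all()

    def test_negative_grid_rejected(self, small_cohort):
        tm, _, data = small_cohort
        with pytest.raises(ValueError):
            L.prevalence_gof(tm.params, data, [-1.0, 2.0])
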