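"""Conditional logit: utilities, probabilities, likelihood, estimation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from centrasim import choice_model, choice_sets, validation
from centrasim.choice_model import (
    ChoiceParams,
    PatientProfile,
    choice_probabilities,
    compose_travel_or,
    utility,
)
from conftest import make_centers, make_matrix, make_patients


def cs_from(minutes, ids=None):
    m = make_matrix([minutes], center_ids=ids)
    return choice_sets.build_choice_set(0, m, max_minutes=np.inf)


class TestUtility:
    def test_zero_minutes_base_profile_plain_center_is_zero(self, table_params):
        center = {"media": False, "teaching": False, "robotic": False}
        assert utility(PatientProfile(), center, 0.0, table_params) == 0.0

    def test_zero_minutes_robotic_center_is_delta_robotic(self, table_params):
        center = {"media": False, "teaching": False, "robotic": True}
        assert utility(PatientProfile(), center, 0.0, table_params) == pytest.approx(
            math.log(1.756))

    def test_slope_composes_interaction_odds_ratios(self, table_params):
        profile = PatientProfile(age65=True, comorbidity=True, london=True)
        slope = choice_model.travel_slope(profile, table_params)
        assert slope == pytest.approx(
            math.log(0.920) + math.log(0.991) + math.log(0.987) + math.log(0.846))

    def test_negative_minutes_rejected(self, table_params):
        with pytest.raises(ValueError):
            utility(PatientProfile(), {"media": 0, "teaching": 0, "robotic": 0},
                    -1.0, table_params)

    def test_london_and_rural_mutually_exclusive(self):
        with pytest.raises(ValueError):
            PatientProfile(london=True, rural=True)


class TestProbabilities:
    def test_single_alternative_has_probability_one(self, table_params):
        centers = make_centers([(False, False, False, True)])
        p = choice_probabilities(PatientProfile(), cs_from([40.0]), centers,
                                 table_params)
        assert p.iloc[0] == pytest.approx(1.0)

    def test_identical_equidistant_centers_split_evenly(self, table_params):
        centers = make_centers([(True, True, False, True)] * 2)
        p = choice_probabilities(PatientProfile(), cs_from([25.0, 25.0]),
                                 centers, table_params)
        assert np.allclose(p, 0.5)

    def test_two_identical_centers_ten_vs_twenty_minutes(self, table_params):
        """Nearer of two identical centers taken with prob 1/(1+0.92^10)."""
        centers = make_centers([(False, False, False, True)] * 2)
        p = choice_probabilities(PatientProfile(), cs_from([10.0, 20.0]),
                                 centers, table_params)
        assert p.iloc[0] == pytest.approx(1.0 / (1.0 + 0.920 ** 10), rel=1e-6)

    def test_empty_choice_set_rejected(self, table_params):
        empty = choice_sets.build_choice_set(0, make_matrix([[500.0]]))
        with pytest.raises(ValueError):
            choice_probabilities(PatientProfile(), empty,
                                 make_centers([(0, 0, 0, 1)]), table_params)

    @given(
        minutes=st.lists(st.floats(0.0, 180.0), min_size=1, max_size=8),
        flags=st.integers(0, 7),
        age=st.booleans(), ses=st.booleans(), com=st.booleans(),
        res=st.sampled_from(["london", "rural", "other_urban"]),
    )
    def test_probabilities_sum_to_one(self, table_params, minutes, flags,
                                      age, ses, com, res):
        centers = make_centers([(bool(flags & 1), bool(flags & 2),
                                 bool(flags & 4), True)] * len(minutes))
        profile = PatientProfile(age65=age, low_ses=ses, comorbidity=com,
                                 london=res == "london", rural=res == "rural")
        p = choice_probabilities(profile, cs_from(minutes), centers, table_params)
        assert abs(p.sum() - 1.0) < 1e-10

    @given(data=st.data())
    def test_iia_subset_probabilities_are_renormalized_full_set(self, table_params,
                                                                data):
        """Probabilities on a subset equal full-set probabilities renormalized."""
        k = data.draw(st.integers(2, 8))
        minutes = data.draw(st.lists(st.floats(1.0, 180.0), min_size=k,
                                     max_size=k))
        flag_bits = data.draw(st.lists(st.integers(0, 7), min_size=k, max_size=k))
        keep = data.draw(st.lists(st.booleans(), min_size=k, max_size=k))
        if not any(keep):
            keep[0] = True
        centers = make_centers([(bool(b & 1), bool(b & 2), bool(b & 4), True)
                                for b in flag_bits])
        full = choice_probabilities(PatientProfile(), cs_from(minutes), centers,
                                    table_params)
        sub_ids = [i for i, k_ in enumerate(keep) if k_]
        sub_minutes = [minutes[i] for i in sub_ids]
        sub = choice_probabilities(
            PatientProfile(),
            cs_from(sub_minutes, ids=sub_ids),
            centers, table_params)
        renorm = full.loc[sub_ids] / full.loc[sub_ids].sum()
        assert np.allclose(sub.sort_index().to_numpy(),
                           renorm.sort_index().to_numpy(), atol=1e-10)

    def test_shared_attribute_shift_leaves_probabilities_unchanged(self,
                                                                   table_params):
        """Adding the same utility constant to every alternative is a no-op."""
        plain = make_centers([(False, False, False, True)] * 3)
        shifted = make_centers([(True, True, True, True)] * 3)
        cs = cs_from([10.0, 40.0, 90.0])
        p0 = choice_probabilities(PatientProfile(), cs, plain, table_params)
        p1 = choice_probabilities(PatientProfile(), cs, shifted, table_params)
        assert np.allclose(p0, p1, atol=1e-12)


@pytest.fixture
def toy_fit_data(table_params):
    """60 patients, 3 distinguishable centers, choices simulated from truth."""
    from centrasim import synthetic

    n = 60
    rng = np.random.default_rng(21)
    patients = make_patients([
        (bool(rng.random() < 0.4), bool(rng.random() < 0.1),
         bool(rng.random() < 0.5),
         ["london", "other_urban", "rural"][rng.integers(3)], 0)
        for _ in range(n)
    ])
    centers = make_centers([(True, False, False, True),
                            (False, False, True, True),
                            (False, True, False, False)])
    minutes = rng.uniform(5.0, 120.0, size=(n, 3))
    matrix = make_matrix(minutes)
    patients = synthetic.simulate_choices(patients, centers, matrix,
                                          table_params, seed=22)
    sets = choice_sets.build_all_choice_sets(matrix)
    return patients, sets, centers, matrix


class TestLikelihood:
    def test_zero_params_give_uniform_model_loglik(self, toy_fit_data):
        patients, sets, centers, _ = toy_fit_data
        ll = choice_model.log_likelihood(ChoiceParams(0.0), patients, sets, centers)
        expected = -sum(math.log(sets[i].n_alternatives) for i in patients["id"])
        assert ll == pytest.approx(expected)

    def test_singleton_sets_give_zero_loglik_and_zero_gradient(self):
        patients = make_patients([(False, False, False, "other_urban", 0),
                                  (True, False, True, "rural", 0)])
        sets = choice_sets.build_all_choice_sets(make_matrix([[30.0, 400.0],
                                                              [20.0, 400.0]]))
        centers = make_centers([(True, False, True, True),
                                (False, True, False, False)])
        params = ChoiceParams(-0.05, media=0.3)
        assert choice_model.log_likelihood(params, patients, sets, centers) == 0.0
        assert np.allclose(choice_model.gradient(params, patients, sets, centers),
                           0.0)

    def test_loglik_matches_hand_summed_probabilities(self, table_params):
        """Three patients with tiny sets: sum of hand-computed log softmaxes."""
        patients = make_patients([
            (False, False, False, "other_urban", 0),
            (True, False, False, "london", 1),
            (False, False, True, "rural", 2),   # low_ses, rural
        ])
        minutes = np.array([[10.0, 30.0, 500.0],
                            [20.0, 25.0, 500.0],
                            [15.0, 40.0, 60.0]])
        centers = make_centers([(True, False, False, True),
                                (False, False, True, True),
                                (False, True, False, True)])
        sets = choice_sets.build_all_choice_sets(make_matrix(minutes))
        ll = choice_model.log_likelihood(table_params, patients, sets, centers)

        def hand(profile, mins, attr_idx, chosen_pos):
            slopes = choice_model.travel_slope(profile, table_params)
            deltas = [table_params.robotic, table_params.media,
                      table_params.teaching]
            u = [slopes * m + deltas[j] for j, m in zip(attr_idx, mins)]
            w = np.exp(u)
            return math.log(w[chosen_pos] / w.sum())

        expected = (
            hand(PatientProfile(), [10.0, 30.0], [0, 1], 0)
            + hand(PatientProfile(age65=True, london=True), [20.0, 25.0], [0, 1], 1)
            + hand(PatientProfile(low_ses=True, rural=True),
                   [15.0, 40.0, 60.0], [0, 1, 2], 2)
        )
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_loglik_is_nonpositive(self, toy_fit_data, table_params):
        patients, sets, centers, _ = toy_fit_data
        assert choice_model.log_likelihood(table_params, patients, sets,
                                           centers) <= 0.0

    def test_loglik_invariant_to_choice_set_ordering(self, toy_fit_data,
                                                     table_params):
        patients, sets, centers, matrix = toy_fit_data
        shuffled = {
            pid: choice_sets.ChoiceSet(pid, cs.center_ids[::-1],
                                       cs.minutes[::-1])
            for pid, cs in sets.items()
        }
        a = choice_model.log_likelihood(table_params, patients, sets, centers)
        b = choice_model.log_likelihood(table_params, patients, shuffled, centers)
        assert a == pytest.approx(b, rel=1e-12)


class TestGradient:
    def test_analytic_score_matches_central_differences(self, toy_fit_data):
        patients, sets, centers, _ = toy_fit_data
        rng = np.random.default_rng(31)
        h = 1e-6
        for _ in range(10):
            beta = rng.normal(0.0, 0.05, size=9)
            beta[:6] *= 0.2  # keep minute-scale terms moderate
            g = choice_model.gradient(ChoiceParams.from_array(beta), patients,
                                      sets, centers)
            fd = np.empty(9)
            for j in range(9):
                e = np.zeros(9)
                e[j] = h
                lp = choice_model.log_likelihood(
                    ChoiceParams.from_array(beta + e), patients, sets, centers)
                lm = choice_model.log_likelihood(
                    ChoiceParams.from_array(beta - e), patients, sets, centers)
                fd[j] = (lp - lm) / (2 * h)
            assert np.allclose(g, fd, rtol=1e-6, atol=1e-6 * np.abs(fd).max())


class TestFit:
    def test_two_alternative_closed_form_mle(self):
        """Binary logit on a shared 10-minute gap: beta = logit(share)/10."""
        n, k = 400, 120  # k patients take the farther center
        patients = make_patients(
            [(False, False, False, "other_urban", 1)] * k
            + [(False, False, False, "other_urban", 0)] * (n - k))
        patients["id"] = np.arange(n)
        centers = make_centers([(False, False, False, True)] * 2)
        sets = choice_sets.build_all_choice_sets(
            make_matrix(np.tile([10.0, 20.0], (n, 1))))
        res = choice_model.fit(patients, sets, centers, terms=["travel_time"])
        share = k / n
        expected = math.log(share / (1 - share)) / 10.0
        assert res.converged
        assert res.params.travel_time == pytest.approx(expected, abs=1e-8)

    def test_fitted_loglik_dominates_truth(self, small_world, table_params):
        f = small_world["fit"]
        ll_truth = choice_model.log_likelihood(
            table_params, small_world["cohort"], small_world["choice_sets"],
            small_world["centers"])
        assert f.log_likelihood >= ll_truth

    def test_score_small_at_optimum(self, small_world):
        f = small_world["fit"]
        g = choice_model.gradient(f.params, small_world["cohort"],
                                  small_world["choice_sets"],
                                  small_world["centers"])
        assert np.max(np.abs(g)) < 1e-4

    def test_fit_reports_consistent_dimensions(self, small_world):
        f = small_world["fit"]
        sizes = sum(small_world["choice_sets"][pid].n_alternatives
                    for pid in small_world["cohort"]["id"])
        assert f.n_observations == sizes
        assert f.n_patients == len(small_world["cohort"])
        assert np.allclose(f.covariance, f.covariance.T)
        assert (np.linalg.eigvalsh(f.covariance) > 0).all()
        assert ((f.table["ci_low"] <= f.table["or"])
                & (f.table["or"] <= f.table["ci_high"])).all()

    def test_matches_statsmodels_conditional_logit(self, toy_fit_data):
        """Independent optimizer agreement on the same stacked data."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        # teaching is omitted: with one flag per toy center the three
        # dummies sum to a within-set constant, which a logit cannot identify
        patients, sets, centers, _ = toy_fit_data
        mine = choice_model.fit(patients, sets, centers,
                                terms=["travel_time", "media", "robotic"])
        d = choice_model.build_design(patients, sets, centers)
        y = np.zeros(d.n_observations)
        y[d.chosen] = 1.0
        cols = [choice_model.PARAM_NAMES.index(t)
                for t in ("travel_time", "media", "robotic")]
        sm_fit = ConditionalLogit(y, d.X[:, cols], groups=d.groups).fit(disp=0)
        # table rows follow the `terms` order, which matches `cols`;
        # tolerance reflects statsmodels' default BFGS stopping rule
        assert np.allclose(mine.table["coef"].to_numpy(), sm_fit.params,
                           atol=1e-4)
        assert np.allclose(mine.table["se"].to_numpy(), sm_fit.bse, rtol=1e-3)

    def test_wald_interval_coverage_over_replicates(self):
        """95% CI for the base travel-time coefficient covers ~95% of truths."""
        hits = 0
        nrep = 100
        for i in range(nrep):
            res = validation.run_choice_recovery(seed=5000 + i, n_patients=2000,
                                                 n_centers=50)
            hits += bool(res.loc["travel_time", "covered"])
        assert 0.88 <= hits / nrep <= 0.99


class TestComposeOR:
    def test_base_profile_returns_base_or(self, table_params):
        assert compose_travel_or(table_params, PatientProfile()) == pytest.approx(
            0.920)

    def test_elderly_comorbid_london_composition(self, table_params):
        got = compose_travel_or(
            table_params,
            PatientProfile(age65=True, comorbidity=True, london=True))
        assert got == pytest.approx(0.920 * 0.991 * 0.987 * 0.846, rel=1e-12)

    def test_unit_interaction_ors_leave_base_unchanged(self):
        params = ChoiceParams(travel_time=math.log(0.9))
        got = compose_travel_or(
            params, PatientProfile(age65=True, low_ses=True, rural=True))
        assert got == pytest.approx(0.9)
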