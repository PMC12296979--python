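import numpy as np
import pytest

from ersppc.gpcm import GpcmParameters, ResponseMatrix, thresholds_to_intercepts
from ersppc.posterior import PosteriorDraws, replicate_datasets
from ersppc.ppc import (
    PpcConfig,
    classify_flags,
    expected_extreme_count,
    extreme_proportion,
    group_ppp_d,
    group_ppp_er,
    person_ppp_d,
    person_ppp_er,
    run_ppc,
)


class TestExtremeProportion:
    def test_half_extreme(self):
        assert extreme_proportion(np.array([1, 4, 2, 3]), c=4) == 0.5

    def test_no_extremes(self):
        assert extreme_proportion(np.array([2, 3, 3, 2]), c=4) == 0.0

    def test_missing_excluded_from_denominator(self):
        resp = np.array([1, 4, 0, 4])
        mask = np.array([False, False, True, False])
        assert extreme_proportion(resp, c=4, missing_mask=mask) == 1.0

    def test_all_missing_person_rejected(self):
        with pytest.raises(ValueError, match="no observed"):
            extreme_proportion(np.array([0, 0]), c=4, missing_mask=np.array([True, True]))


class TestPersonPppEr:
    def test_all_replicates_greater(self):
        assert person_ppp_er(1, np.array([2, 3, 4])) == 1.0

    def test_all_ties_give_half(self):
        assert person_ppp_er(2, np.array([2, 2, 2, 2])) == 0.5

    def test_four_draw_worked_example(self):
        # observed proportion .5 of 4 items (count 2); replicated
        # proportions (.25, .5, .5, .75) -> (1 + .5 + .5 + 0) / 4
        assert person_ppp_er(2, np.array([1, 2, 2, 3])) == 0.5

    def test_role_swap_tie_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            obs = rng.integers(0, 7)
            rep = rng.integers(0, 7, size=rng.integers(1, 30))
            forward = person_ppp_er(obs, rep)
            swapped = np.mean((obs > rep) + 0.5 * (obs == rep))
            assert forward == pytest.approx(1.0 - swapped, abs=1e-15)


class TestExpectedExtremeCount:
    def make_params(self, slopes, taus):
        ints = np.stack(
            [thresholds_to_intercepts(t, s) for t, s in zip(taus, slopes)]
        )
        return GpcmParameters(slopes=np.asarray(slopes, dtype=float), intercepts=ints)

    def test_zero_slopes_give_half_per_item(self):
        params = self.make_params([0.0] * 12, [[0, 0, 0]] * 12)
        assert expected_extreme_count(np.array([0.3]), params) == pytest.approx(6.0)

    def test_bounded_by_observed_items(self):
        params = self.make_params([1.5, 0.7], [[-1, 0, 1], [-0.5, 0, 0.5]])
        e = expected_extreme_count(np.array([2.0]), params)
        assert 0.0 <= e <= 2.0

    def test_two_item_oracle(self):
        from ersppc.gpcm import category_probabilities

        slopes = [1.1, 0.9]
        taus = [[-1.0, 0.0, 1.0], [-0.3, 0.2, 0.9]]
        params = self.make_params(slopes, taus)
        theta = 0.4
        expected = sum(
            category_probabilities(theta, s, np.array(t))[[0, 3]].sum()
            for s, t in zip(slopes, taus)
        )
        got = expected_extreme_count(np.array([theta]), params)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_missing_items_excluded(self):
        params = self.make_params([0.0] * 4, [[0, 0, 0]] * 4)
        obs = np.array([True, True, False, True])
        assert expected_extreme_count(
            np.array([0.0]), params, observed_items=obs
        ) == pytest.approx(1.5)


class TestPersonPppD:
    def test_all_ties_give_one(self):
        assert person_ppp_d(3, np.array([3, 3, 3]), np.array([1.0, 1.0, 1.0])) == 1.0

    def test_four_draw_worked_example(self):
        # D_obs = 4 every draw, D_rep = (1, 4, 9, 16) -> 3/4
        ppp = person_ppp_d(
            2.0, np.array([1.0, 2.0, 3.0, 4.0]), np.zeros(4)
        )
        assert ppp == 0.75

    def test_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            v = person_ppp_d(
                rng.integers(0, 5),
                rng.integers(0, 5, 10),
                rng.uniform(0, 5, 10),
            )
            assert 0.0 <= v <= 1.0


class TestGroupPpp:
    def test_single_person_reduces_to_person_check(self):
        ne_obs, expected = 3.0, np.array([1.0, 2.5, 4.0])
        ne_rep = np.array([2.0, 3.0, 5.0])
        person = person_ppp_d(ne_obs, ne_rep, expected)
        group = group_ppp_d(
            ((ne_obs - expected) ** 2)[:, None], ((ne_rep - expected) ** 2)[:, None]
        )
        assert group == person

    def test_identical_replicates_give_one(self):
        d = np.abs(np.random.default_rng(2).normal(0, 1, (5, 4)))
        assert group_ppp_d(d, d.copy()) == 1.0

    def test_three_person_two_draw_enumeration_oracle(self):
        d_obs = np.array([[1.0, 0.5, 2.0], [0.8, 1.5, 0.2]])
        d_rep = np.array([[2.0, 1.0, 1.5], [0.1, 0.3, 0.4]])
        manual = np.mean(
            [d_rep[t].sum() >= d_obs[t].sum() for t in range(2)]
        )
        assert group_ppp_d(d_obs, d_rep) == manual == 0.5

    def test_er_variance_permutation_invariance(self):
        er_obs = np.array([0.1, 0.5, 0.9, 0.3])
        rng = np.random.default_rng(3)
        er_rep = np.stack([rng.permutation(er_obs) for _ in range(10)])
        assert group_ppp_er(er_obs, er_rep) == 1.0

    def test_three_draw_variance_worked_example(self):
        # sample variances: rep (0.01, 0.02, 0.03) vs obs 0.02 -> 2/3
        def pair(v):
            d = np.sqrt(2.0 * v)
            return np.array([0.0, d])

        ppp = group_ppp_er(
            pair(0.02), np.stack([pair(0.01), pair(0.02), pair(0.03)])
        )
        assert ppp == pytest.approx(2.0 / 3.0)

    def test_monotone_in_observed_spread(self):
        rng = np.random.default_rng(4)
        er_rep = rng.uniform(0, 1, (200, 6))
        er_obs = np.array([0.2, 0.3, 0.4, 0.6, 0.7, 0.8])
        inflated = er_obs.mean() + 2.0 * (er_obs - er_obs.mean())
        assert group_ppp_er(inflated, er_rep) <= group_ppp_er(er_obs, er_rep)


class TestClassifyFlags:
    def test_high_ppp_er_is_low_ers(self):
        fe, fd, _ = classify_flags(
            np.array([0.97]), np.array([0.5]), np.array([2]), np.array([3.0])
        )
        assert fe[0] == "L-ERS" and fd[0] == "none"

    def test_middle_values_unflagged(self):
        fe, fd, _ = classify_flags(
            np.array([0.5]), np.array([0.9]), np.array([2]), np.array([3.0])
        )
        assert fe[0] == "none" and fd[0] == "none"

    def test_d_flag_direction_from_expected_count(self):
        fe, fd, _ = classify_flags(
            np.array([0.5]), np.array([0.05]), np.array([7]), np.array([2.1])
        )
        assert fd[0] == "H-ERS"

    def test_exact_tie_direction_indeterminate(self):
        with pytest.warns(UserWarning, match="indeterminate"):
            _, fd, _ = classify_flags(
                np.array([0.5]), np.array([0.05]), np.array([3]), np.array([3.0])
            )
        assert fd[0] == "indeterminate"


class TestRunPpc:
    def test_streaming_equals_naive_materialized_oracle(self, toy_data, toy_draws):
        cfg = PpcConfig(seed=123)
        person, group = run_ppc(toy_data, toy_draws, cfg)
        # naive path: materialize every replicate, use the scalar operations
        obs = toy_data.observed
        ne_obs = toy_data.is_extreme().sum(axis=1)
        n_obs = obs.sum(axis=1)
        T, n = toy_draws.n_draws, toy_data.n_persons
        ne_rep = np.zeros((T, n), dtype=int)
        expected = np.zeros((T, n))
        for t, rep in enumerate(replicate_datasets(toy_draws, toy_data, seed=123)):
            ne_rep[t] = rep.is_extreme().sum(axis=1)
            for p in range(n):
                expected[t, p] = expected_extreme_count(
                    toy_draws.theta[t, p], toy_draws.params_at(t), obs[p]
                )
        for p in range(n):
            assert person.ppp_er[p] == person_ppp_er(ne_obs[p], ne_rep[:, p])
            assert person.ppp_d[p] == person_ppp_d(
                ne_obs[p], ne_rep[:, p], expected[:, p]
            )
            assert person.mean_expected_ne[p] == pytest.approx(
                expected[:, p].mean(), abs=1e-10
            )
        d_obs = (ne_obs[None, :] - expected) ** 2
        d_rep = (ne_rep - expected) ** 2
        assert group.ppp_d == group_ppp_d(d_obs, d_rep)
        er_rep = ne_rep / n_obs[None, :]
        assert group.ppp_er == group_ppp_er(ne_obs / n_obs, er_rep)

    def test_all_ppp_values_bounded(self, toy_data, toy_draws):
        person, group = run_ppc(toy_data, toy_draws, PpcConfig(seed=5))
        for v in (person.ppp_er, person.ppp_d):
            assert np.all((v >= 0) & (v <= 1))
        assert 0 <= group.ppp_er <= 1 and 0 <= group.ppp_d <= 1

    def test_single_person_group_consistent_with_person(self, toy_draws):
        one = PosteriorDraws(
            theta=toy_draws.theta[:, :1, :],
            slopes=toy_draws.slopes,
            intercepts=toy_draws.intercepts,
            correlation=toy_draws.correlation,
            chain_id=toy_draws.chain_id,
            dim_of_item=toy_draws.dim_of_item,
        )
        data = ResponseMatrix(responses=np.array([[1, 4, 2, 3, 4, 1]]), c=4)
        person, group = run_ppc(data, one, PpcConfig(seed=9))
        assert group.ppp_d == person.ppp_d[0]

    def test_all_missing_person_excluded_with_warning(self, toy_draws):
        resp = np.ones((5, 6), dtype=int)
        mask = np.zeros((5, 6), dtype=bool)
        mask[2, :] = True
        data = ResponseMatrix(responses=resp, c=4, missing_mask=mask)
        with pytest.warns(UserWarning, match="excluding 1 person"):
            person, _ = run_ppc(data, toy_draws, PpcConfig(seed=1))
        assert len(person.person_ids) == 4

    def test_deterministic_given_seed(self, toy_data, toy_draws):
        p1, g1 = run_ppc(toy_data, toy_draws, PpcConfig(seed=77))
        p2, g2 = run_ppc(toy_data, toy_draws, PpcConfig(seed=77))
        np.testing.assert_array_equal(p1.ppp_er, p2.ppp_er)
        np.testing.assert_array_equal(p1.ppp_d, p2.ppp_d)
        assert g1.ppp_er == g2.ppp_er

    def test_well_fitting_model_concentrates_near_half(
        self, recovery_truth, recovery_fit
    ):
        # data generated from a GPCM and checked against its own fit:
        # group PPPs should sit far from the rejection region and person
        # flag rates stay below the nominal cutoffs (conservativeness)
        _, _, data = recovery_truth
        draws, _ = recovery_fit
        person, group = run_ppc(data, draws, PpcConfig(seed=31))
        assert 0.1 < group.ppp_er
        assert 0.1 < group.ppp_d
        # one dataset of 500 persons: nominal rate plus two binomial sds
        slack = 0.05 + 2 * np.sqrt(0.05 * 0.95 / 500)
        assert (person.flag_er != "none").mean() <= slack
        assert (person.flag_d != "none").mean() <= slack
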