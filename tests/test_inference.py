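"""ABC-SMC machinery: distance, sampler, selection, posterior comparison."""

import numpy as np
import pandas as pd
import pytest

from proteokin.inference import (Prior, PriorSet, Posterior, abc_distance,
                                 abc_smc, abc_smc_model_select,
                                 default_priors, posterior_compare)
from proteokin.synthetic import TimeCourseDataset


def _dataset(values: dict) -> TimeCourseDataset:
    rows = [("X", c, t, 1, v) for (c, t), v in values.items()]
    return TimeCourseDataset(pd.DataFrame(
        rows, columns=list(TimeCourseDataset.REQUIRED)))


class TestDistance:
    def test_identical_datasets_give_zero(self):
        ds = _dataset({(10, 15): 10.0, (10, 30): 20.0,
                       (20, 15): 5.0, (20, 30): 40.0})
        assert abc_distance(ds, ds) == 0.0

    def test_all_zero_datasets_give_zero(self):
        ds = _dataset({(10, 15): 0.0, (20, 15): 0.0})
        assert abc_distance(ds, ds) == 0.0

    def test_two_by_two_matches_hand_computed_rms(self):
        # per-series max normalisation: row 10 -> 20, row 20 -> 40;
        # normalised diffs 0.1, -0.1, 0.025, -0.1 -> RMS = 0.0875
        obs = _dataset({(10, 15): 10.0, (10, 30): 20.0,
                        (20, 15): 5.0, (20, 30): 40.0})
        sim = _dataset({(10, 15): 12.0, (10, 30): 18.0,
                        (20, 15): 6.0, (20, 30): 36.0})
        assert abc_distance(sim, obs) == pytest.approx(0.0875, rel=1e-12)

    def test_design_mismatch_lists_missing_cells(self):
        obs = _dataset({(10, 15): 1.0, (20, 15): 2.0})
        sim = _dataset({(10, 15): 1.0})
        with pytest.raises(ValueError, match="20"):
            abc_distance(sim, obs)


class TestPriors:
    def test_loguniform_sampling_and_pdf(self):
        pr = Prior("loguniform", 1e-2, 1e2)
        rng = np.random.default_rng(0)
        draws = np.array([pr.sample(rng) for _ in range(500)])
        assert draws.min() >= 1e-2 and draws.max() <= 1e2
        # log10 draws roughly uniform over [-2, 2]
        assert abs(np.log10(draws).mean()) < 0.3
        assert pr.pdf(1e3) == 0.0 and pr.pdf(1.0) > 0.0

    def test_invalid_specifications_rejected(self):
        with pytest.raises(ValueError):
            Prior("loguniform", -1.0, 1.0)
        with pytest.raises(ValueError):
            Prior("uniform", 2.0, 1.0)
        with pytest.raises(ValueError):
            Prior("weird", 0.0, 1.0)

    def test_default_priors_use_capacity_bounds(self, llvy):
        ps = default_priors(["vin", "C"], llvy)
        assert ps["C"].family == "uniform" and ps["C"].a == 10.0
        assert ps["vin"].family == "loguniform"


def _toy_problem():
    priors = PriorSet(mu=Prior("uniform", -5.0, 5.0))

    def simulate(theta, rng):
        return theta["mu"] + rng.normal(0, 0.1)

    return priors, simulate


class TestAbcSmc:
    def test_bit_identical_under_same_seed(self):
        priors, simulate = _toy_problem()
        kw = dict(n_particles=60, seed=123, max_populations=4)
        a = abc_smc(priors, simulate, lambda s, o: abs(s - o), 1.0, **kw)
        b = abc_smc(priors, simulate, lambda s, o: abs(s - o), 1.0, **kw)
        assert a.particles.equals(b.particles)
        assert np.array_equal(a.weights, b.weights)
        assert a.epsilons == b.epsilons

    def test_epsilon_schedule_strictly_decreases(self):
        priors, simulate = _toy_problem()
        post = abc_smc(priors, simulate, lambda s, o: abs(s - o), 1.0,
                       n_particles=80, seed=5, max_populations=5)
        eps = post.epsilons[1:]
        assert all(b < a for a, b in zip(eps, eps[1:]))
        assert all(0 < r <= 1 for r in post.acceptance_rates)

    def test_final_distances_below_final_epsilon(self):
        priors, simulate = _toy_problem()
        post = abc_smc(priors, simulate, lambda s, o: abs(s - o), 1.0,
                       n_particles=80, seed=5, max_populations=5)
        assert np.all(post.distances <= post.epsilons[-1])
        assert post.weights.sum() == pytest.approx(1.0)

    def test_posterior_concentrates_on_truth(self):
        priors, simulate = _toy_problem()
        post = abc_smc(priors, simulate, lambda s, o: abs(s - o), 1.5,
                       n_particles=100, seed=2, max_populations=6)
        assert post.median("mu") == pytest.approx(1.5, abs=0.2)

    def test_too_few_particles_rejected(self):
        priors, simulate = _toy_problem()
        with pytest.raises(ValueError):
            abc_smc(priors, simulate, lambda s, o: abs(s - o), 0.0,
                    n_particles=1)


class TestModelSelection:
    def test_model_against_itself_stays_near_half(self):
        priors, simulate = _toy_problem()
        problems = {"A": (priors, simulate),
                    "B": (PriorSet(mu=Prior("uniform", -5.0, 5.0)), simulate)}
        res = abc_smc_model_select(problems, 0.5,
                                   lambda s, o: abs(s - o),
                                   n_particles=100, seed=9,
                                   max_populations=4)
        pA = res.final_probabilities["A"]
        assert 0.2 < pA < 0.8

    def test_probabilities_sum_to_one_each_population(self):
        priors, simulate = _toy_problem()
        problems = {"A": (priors, simulate),
                    "B": (PriorSet(mu=Prior("uniform", -5.0, 5.0)), simulate)}
        res = abc_smc_model_select(problems, 0.5, lambda s, o: abs(s - o),
                                   n_particles=60, seed=3, max_populations=3)
        assert np.allclose(res.probabilities.sum(axis=1), 1.0)

    def test_needs_two_models(self):
        priors, simulate = _toy_problem()
        with pytest.raises(ValueError):
            abc_smc_model_select({"A": (priors, simulate)}, 0.0,
                                 lambda s, o: abs(s - o))


class TestIterativeScheme:
    def test_ladder_structure_and_m1_recovery(self):
        """Stage 1 joint comparison, then a pairwise ascent through the
        compartmental models; Michaelis-Menten data keep M1 on top."""
        from proteokin.inference import (_distance_matrices,
                                         _make_model_simulator,
                                         iterative_selection_scheme)
        from proteokin.models import build_model
        from proteokin.params import ParameterSet
        from proteokin.studies import (_SELECTION_CONCS, _SELECTION_TIMES,
                                       _SOLVER, make_selection_problems)
        from proteokin.synthetic import fixture_parameters

        rng = np.random.default_rng(0)
        truth = ParameterSet(vmax=0.02, KM=150.0)
        sim = _make_model_simulator(build_model("M1"), truth,
                                    _SELECTION_CONCS, _SELECTION_TIMES,
                                    solver_opts=_SOLVER)
        obs = sim({}, rng) * np.exp(0.05 * rng.standard_normal((3, 6)))
        problems = make_selection_problems(
            obs, fixture_parameters("LLVY"), [f"M{i}" for i in range(1, 10)])
        winner, hist = iterative_selection_scheme(
            lambda mid: problems[mid], obs,
            lambda s, o: _distance_matrices(s, o), seed=0, n_particles=50,
            max_populations=2, final_retest=False)
        labels = [h[0] for h in hist]
        assert labels[0] == "stage1:M1-M4"
        assert len(labels) == 6  # one joint + five pairwise rungs
        assert winner == "M1"


def _synthetic_posterior(rng, medians: dict, spread: float = 0.1) -> Posterior:
    n = 400
    cols = {nm: med * np.exp(spread * rng.standard_normal(n))
            for nm, med in medians.items()}
    return Posterior(pd.DataFrame(cols), np.full(n, 1.0 / n), np.zeros(n),
                     [np.inf], [1.0], 0)


class TestPosteriorCompare:
    def test_identical_posteriors_fully_overlap(self):
        rng = np.random.default_rng(0)
        post = _synthetic_posterior(rng, {"vin": 50.0, "kp": 100.0})
        tab = posterior_compare(post, post)
        assert np.allclose(tab["overlap"], 1.0)
        assert not tab["flagged"].any()

    def test_disjoint_marginals_flagged(self):
        rng = np.random.default_rng(1)
        a = _synthetic_posterior(rng, {"kp": 1.0})
        b = _synthetic_posterior(rng, {"kp": 100.0})
        tab = posterior_compare(a, b)
        assert tab["overlap"].iloc[0] == 0.0
        assert tab["flagged"].iloc[0]

    def test_mismatched_parameterisations_rejected(self):
        rng = np.random.default_rng(2)
        a = _synthetic_posterior(rng, {"kp": 1.0})
        b = _synthetic_posterior(rng, {"vin": 1.0})
        with pytest.raises(ValueError):
            posterior_compare(a, b)
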