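"""ABC machinery: distance, rejection order statistics, MCMC behaviour."""

import numpy as np
import pytest
from scipy.stats import kstest

import woundabc as w


def _dataset(values_by_key, n_rep=1):
    """Tiny hand-built SummaryDataset: {(stat, t): vector or matrix}."""
    data = {}
    names, times = [], []
    for (name, t), vals in values_by_key.items():
        arr = np.atleast_2d(np.asarray(vals, dtype=float))
        if arr.shape[0] == 1 and n_rep > 1:
            arr = np.repeat(arr, n_rep, axis=0)
        data[(name, t)] = arr
        names.append(name)
        times.append(t)
    return w.SummaryDataset(tuple(dict.fromkeys(names)), tuple(dict.fromkeys(times)), data)


TOY_DESIGN = w.unrealistic_design(20, 3, n_replicates=1, times=(5.0,))
TOY_SPEC = w.DistanceSpec(statistics=("pcf",), times=(5.0,))


class TestDistance:
    def test_identical_datasets_zero(self):
        a = _dataset({("pcf", 240.0): [1.0, 2.0]})
        assert w.distance(a, a, w.DistanceSpec(times=(240.0,))) == 0.0

    def test_l1_sum(self):
        a = _dataset({("pcf", 240.0): [1.0, 2.0]})
        b = _dataset({("pcf", 240.0): [0.0, 4.0]})
        assert w.distance(a, b, w.DistanceSpec(times=(240.0,))) == 3.0

    def test_additive_over_times(self):
        a = _dataset({("pcf", 240.0): [1.0, 2.0], ("pcf", 480.0): [1.0, 2.0]})
        b = _dataset({("pcf", 240.0): [0.0, 4.0], ("pcf", 480.0): [0.0, 4.0]})
        assert w.distance(a, b, w.DistanceSpec(times=(240.0, 480.0))) == 6.0

    def test_shape_mismatch_names_offender(self):
        a = _dataset({("pcf", 240.0): [1.0, 2.0]})
        b = _dataset({("pcf", 240.0): [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match=r"pcf, t=240"):
            w.distance(a, b, w.DistanceSpec(times=(240.0,)))

    def test_missing_time_errors(self):
        a = _dataset({("pcf", 240.0): [1.0]})
        with pytest.raises(ValueError, match="missing"):
            w.distance(a, a, w.DistanceSpec(times=(999.0,)))


class TestPriorBox:
    def test_defaults_follow_model(self):
        assert w.PriorBox(model="A").alpha_bounds == (-0.2, 0.25)
        assert w.PriorBox(model="B").alpha_bounds == (-0.2, 1.0)

    def test_bounds_must_respect_admissibility(self):
        with pytest.raises(ValueError, match="admissible"):
            w.PriorBox(alpha_bounds=(-0.2, 0.5), model="A")

    def test_sampling_stays_in_box(self):
        box = w.PriorBox(model="B")
        s = box.sample(np.random.default_rng(0), 500)
        assert all(box.contains(t) for t in s)


@pytest.fixture(scope="module")
def small_run():
    observed = w.generate_synthetic_data(TOY_DESIGN, w.ModelParams(0.5, 0.1, "A"), seed=3)
    return w.abc_rejection(TOY_DESIGN, w.PriorBox(model="A"), observed, TOY_SPEC,
                           n_sims=60, n_accept=20, seed=5)


class TestRejection:
    def test_accepted_are_smallest_distances(self, small_run):
        accepted = np.sort(small_run.distances)
        everything = np.sort(small_run.all_distances)
        assert accepted == pytest.approx(everything[:20])
        assert accepted.max() <= np.sort(small_run.all_distances)[20:].min()

    def test_accept_all_returns_prior_sample(self):
        observed = w.generate_synthetic_data(TOY_DESIGN, w.ModelParams(0.5, 0.1, "A"), seed=3)
        res = w.abc_rejection(TOY_DESIGN, w.PriorBox(model="A"), observed, TOY_SPEC,
                              n_sims=15, n_accept=15, seed=5)
        assert sorted(map(tuple, res.samples)) == sorted(map(tuple, res.all_samples))

    def test_n_accept_validated(self):
        observed = w.generate_synthetic_data(TOY_DESIGN, w.ModelParams(0.5, 0.1, "A"), seed=3)
        with pytest.raises(ValueError, match="exceeds"):
            w.abc_rejection(TOY_DESIGN, w.PriorBox(model="A"), observed, TOY_SPEC,
                            n_sims=5, n_accept=6, seed=0)

    def test_reproducible(self, small_run):
        observed = w.generate_synthetic_data(TOY_DESIGN, w.ModelParams(0.5, 0.1, "A"), seed=3)
        again = w.abc_rejection(TOY_DESIGN, w.PriorBox(model="A"), observed, TOY_SPEC,
                                n_sims=60, n_accept=20, seed=5)
        assert np.array_equal(again.samples, small_run.samples)
        assert np.array_equal(again.distances, small_run.distances)


class TestMCMC:
    def test_zero_proposal_scale_freezes_chain(self):
        observed = w.generate_synthetic_data(TOY_DESIGN, w.ModelParams(0.5, 0.1, "A"), seed=3)
        res = w.abc_mcmc(TOY_DESIGN, w.PriorBox(model="A"), observed, TOY_SPEC,
                         epsilon=np.inf, chain_length=50, proposal_scales=(0.0, 0.0),
                         seed=2, theta0=(0.4, 0.05))
        assert (res.samples == [0.4, 0.05]).all()

    def test_vacuous_threshold_targets_the_prior(self):
        """epsilon = inf accepts every in-box proposal, so the chain's
        stationary law is the uniform prior; KS distance per marginal < 0.05."""
        observed = w.generate_synthetic_data(TOY_DESIGN, w.ModelParams(0.5, 0.1, "A"), seed=3)
        prior = w.PriorBox(model="A")
        res = w.abc_mcmc(TOY_DESIGN, prior, observed, TOY_SPEC, epsilon=np.inf,
                         chain_length=10_000, proposal_scales=0.4 * prior.widths(),
                         seed=11)
        assert res.acceptance_rate > 0.2
        for dim, (lo, hi) in enumerate([prior.pm_bounds, prior.alpha_bounds]):
            stat = kstest(res.samples[:, dim], "uniform", args=(lo, hi - lo)).statistic
            assert stat < 0.05

    def test_tighter_epsilon_accepts_less(self):
        observed = w.generate_synthetic_data(TOY_DESIGN, w.ModelParams(0.5, 0.1, "A"), seed=3)
        prior = w.PriorBox(model="A")
        kwargs = dict(chain_length=300, proposal_scales=0.3 * prior.widths(), seed=7)
        loose = w.abc_mcmc(TOY_DESIGN, prior, observed, TOY_SPEC, epsilon=np.inf, **kwargs)
        pilot = w.abc_rejection(TOY_DESIGN, prior, observed, TOY_SPEC, 60, 10, seed=1)
        eps = max(w.choose_epsilon(pilot, 0.25), 1e-9)  # an exact-match pilot distance can be 0
        tight = w.abc_mcmc(TOY_DESIGN, prior, observed, TOY_SPEC, epsilon=eps, **kwargs)
        assert tight.acceptance_rate <= loose.acceptance_rate

    def test_validation(self):
        observed = w.generate_synthetic_data(TOY_DESIGN, w.ModelParams(0.5, 0.1, "A"), seed=3)
        prior = w.PriorBox(model="A")
        with pytest.raises(ValueError, match="epsilon"):
            w.abc_mcmc(TOY_DESIGN, prior, observed, TOY_SPEC, epsilon=-1.0)
        with pytest.raises(ValueError, match="outside the prior"):
            w.abc_mcmc(TOY_DESIGN, prior, observed, TOY_SPEC, epsilon=1.0,
                       theta0=(2.0, 0.0))


class TestChooseEpsilon:
    def test_nearest_rank_examples(self):
        pilot = w.PosteriorResult(
            samples=np.zeros((3, 2)), distances=np.array([1.0, 2.0, 3.0]),
            prior=w.PriorBox(model="A"), spec=TOY_SPEC, seed=0, method="rejection",
            all_distances=np.array([1.0, 2.0, 3.0]),
        )
        assert w.choose_epsilon(pilot, 1.0) == 3.0
        assert w.choose_epsilon(pilot, 0.5) == 2.0
        pilot100 = w.PosteriorResult(
            samples=np.zeros((100, 2)), distances=np.arange(100.0),
            prior=w.PriorBox(model="A"), spec=TOY_SPEC, seed=0, method="rejection",
            all_distances=np.arange(100.0) + 1,
        )
        assert w.choose_epsilon(pilot100, 0.01) == 1.0

    def test_empty_pilot_errors(self):
        pilot = w.PosteriorResult(
            samples=np.zeros((0, 2)), distances=np.array([]),
            prior=w.PriorBox(model="A"), spec=TOY_SPEC, seed=0, method="rejection",
            all_distances=np.array([]),
        )
        with pytest.raises(ValueError, match="no distances"):
            w.choose_epsilon(pilot, 0.5)
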