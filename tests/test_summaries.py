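"""Summary statistics: worked examples, conservation, CSR calibration."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import woundabc as w
from woundabc.gillespie import SimulationRecord
from woundabc.lattice import LatticeDomain, ModelParams


def _state(Lx, Ly, cols, rows, ids=None, col0=None):
    n = len(cols)
    return w.OccupancyState(Lx, Ly, ids=ids if ids is not None else np.arange(n),
                            col=cols, row=rows, col0=col0)


def _record(initial, final, t=100.0):
    domain = LatticeDomain(initial.Lx, initial.Ly)
    return SimulationRecord(domain, ModelParams(0.5, 0.0, "A"), (t,), {t: final},
                            initial, seed=0)


class TestDisplacement:
    def test_no_movement_is_zero(self):
        s = _state(5, 3, [1, 4], [1, 2])
        assert w.average_horizontal_displacement(_record(s, s.copy()), 0, 100.0) == 0.0

    def test_mean_of_absolute_column_shifts(self):
        s0 = _state(6, 2, [2, 3], [1, 1])
        s1 = _state(6, 2, [4, 3], [1, 2])  # agent 0 moves 2->4, agent 1 stays (row move only)
        assert w.average_horizontal_displacement(_record(s0, s1), 0, 100.0) == 1.0

    def test_single_agent(self):
        s0 = _state(6, 1, [2], [1])
        s1 = _state(6, 1, [5], [1])
        assert w.average_horizontal_displacement(_record(s0, s1), 0, 100.0) == 3.0

    def test_only_agents_present_at_both_times_count(self):
        s0 = _state(6, 2, [1, 3], [1, 1], ids=[0, 1])
        s1 = _state(6, 2, [3, 2], [1, 2], ids=[1, 7])  # agent 0 exited, agent 7 replenished
        assert w.average_horizontal_displacement(_record(s0, s1), 0, 100.0) == 0.0

    def test_no_common_agents_errors(self):
        s0 = _state(6, 2, [1], [1], ids=[0])
        s1 = _state(6, 2, [1], [1], ids=[5])
        with pytest.raises(ValueError, match="no agent present"):
            w.average_horizontal_displacement(_record(s0, s1), 0, 100.0)


class TestDensityProfile:
    def test_extremes_and_fractions(self):
        empty = w.OccupancyState(3, 4, ids=[], col=[], row=[])
        assert (w.density_profile(empty) == 0).all()
        full = w.OccupancyState.from_grid(np.ones((4, 3), dtype=np.uint8))
        assert (w.density_profile(full) == 1).all()
        one = _state(3, 4, [2], [3])
        assert w.density_profile(one)[1] == 0.25


class TestPairCounts:
    def test_two_agents_on_strip(self):
        s = _state(3, 1, [1, 3], [1, 1])
        assert list(w.pair_counts(s)) == [0, 1]

    def test_single_agent_all_zero(self):
        s = _state(4, 2, [2], [1])
        assert (w.pair_counts(s) == 0).all()

    def test_full_lattice_closed_form(self):
        Lx, Ly = 6, 3
        s = w.OccupancyState.from_grid(np.ones((Ly, Lx), dtype=np.uint8))
        m = np.arange(1, Lx)
        assert (w.pair_counts(s) == Ly**2 * (Lx - m)).all()

    @given(st.integers(2, 12), st.data())
    def test_pair_count_budget(self, n, data):
        """Sum of horizontal pair counts plus same-column pairs is N(N-1)/2."""
        Lx, Ly = 6, 5
        sites = data.draw(st.lists(st.integers(0, Lx * Ly - 1), min_size=n, max_size=n,
                                   unique=True))
        sites = np.array(sites)
        s = w.OccupancyState(Lx, Ly, np.arange(n), sites // Ly + 1, sites % Ly + 1)
        assert w.pair_counts(s).sum() + w.same_column_pairs(s) == n * (n - 1) // 2

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            Lx, Ly, n = 7, 4, 9
            sites = rng.choice(Lx * Ly, n, replace=False)
            s = w.OccupancyState(Lx, Ly, np.arange(n), sites // Ly + 1, sites % Ly + 1)
            brute = np.zeros(Lx - 1, dtype=int)
            for a, b in itertools.combinations(s.col, 2):
                if a != b:
                    brute[abs(a - b) - 1] += 1
            assert (w.pair_counts(s) == brute).all()


class TestPCF:
    def test_normalisation_closed_forms(self):
        Lx, Ly = 5, 3
        full = w.pcf_normalisation(Lx, Ly, Lx * Ly)
        m = np.arange(1, Lx)
        assert full == pytest.approx(Ly**2 * (Lx - m))
        assert w.pcf_normalisation(3, 1, 2)[1] == pytest.approx(1 / 3)
        diffs = np.diff(w.pcf_normalisation(10, 4, 7))
        assert (diffs < 0).all()  # strictly decreasing in m

    def test_normalisation_needs_two_agents(self):
        with pytest.raises(ValueError, match="at least 2"):
            w.pcf_normalisation(5, 5, 1)

    def test_full_lattice_pcf_is_one(self):
        s = w.OccupancyState.from_grid(np.ones((4, 7), dtype=np.uint8))
        assert w.pcf(s) == pytest.approx(np.ones(6))

    def test_worked_example_strip(self):
        s = _state(3, 1, [1, 3], [1, 1])
        assert w.pcf(s) == pytest.approx([0.0, 3.0])

    def test_csr_mean_is_one(self):
        """Uniform random placement has expected pair counts equal to the
        normalisation, so the mean PCF is 1 within Monte-Carlo error."""
        Lx, Ly, n, draws = 10, 8, 24, 2000
        rng = np.random.default_rng(42)
        qs = np.empty((draws, Lx - 1))
        for i in range(draws):
            sites = rng.choice(Lx * Ly, n, replace=False)
            s = w.OccupancyState(Lx, Ly, np.arange(n), sites // Ly + 1, sites % Ly + 1,
                                 validate=False)
            qs[i] = w.pcf(s)
        mean = qs.mean(axis=0)
        se = qs.std(axis=0, ddof=1) / np.sqrt(draws)
        assert (np.abs(mean - 1.0) < 3 * se + 1e-9).all()

    def test_depends_only_on_columns(self):
        s1 = _state(5, 4, [1, 1, 4], [1, 2, 3])
        s2 = _state(5, 4, [1, 1, 4], [4, 1, 2])  # same columns, rows permuted
        assert w.pcf(s1) == pytest.approx(w.pcf(s2))


class TestEnsembles:
    def _vecs(self, rows):
        return [w.StatisticVector("pcf", 240.0, r) for r in rows]

    def test_identical_replicates_have_zero_variance(self):
        vecs = self._vecs([[1.0, 2.0]] * 4)
        assert w.statistic_variance(vecs) == pytest.approx([0.0, 0.0])

    def test_mean_and_unbiased_variance(self):
        vecs = self._vecs([[0.0, 0.0], [2.0, 2.0]])
        assert w.ensemble_average(vecs).values == pytest.approx([1.0, 1.0])
        assert w.statistic_variance(vecs) == pytest.approx([2.0, 2.0])

    def test_single_replicate_variance_undefined(self):
        vecs = self._vecs([[1.0, 2.0]])
        assert w.ensemble_average(vecs).values == pytest.approx([1.0, 2.0])
        with pytest.raises(ValueError, match="single replicate"):
            w.statistic_variance(vecs)

    def test_mixed_statistics_rejected(self):
        mixed = [w.StatisticVector("pcf", 240.0, [1.0]),
                 w.StatisticVector("displacement", 240.0, [1.0])]
        with pytest.raises(ValueError, match="mixed"):
            w.ensemble_average(mixed)

    def test_dataset_ensemble_average_matches_replicate_mean(self):
        design = w.unrealistic_design(20, 8, n_replicates=3, times=(60.0,))
        ds = w.generate_synthetic_data(design, w.ModelParams(0.5, 0.1, "A"), seed=4)
        mat = ds.replicates("density_profile", 60.0)
        assert ds.mean("density_profile", 60.0) == pytest.approx(mat.mean(axis=0))
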