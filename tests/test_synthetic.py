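import numpy as np
import pytest

from enmkit.change import centroid, change_map, change_stats, binarize
from enmkit.grids import GridHeader, Raster
from enmkit.selection import pearson_matrix
from enmkit.synthetic import (
    default_scenario,
    make_future,
    make_stack,
    make_truth,
    sample_occurrences,
)


class TestMakeStack:
    def test_same_seed_bit_identical(self):
        a = make_stack(3, nrows=40, ncols=40, seed=5)
        b = make_stack(3, nrows=40, ncols=40, seed=5)
        for n in a.names:
            np.testing.assert_array_equal(a[n].values, b[n].values)

    def test_identity_mixing_nearly_independent(self):
        stack = make_stack(2, nrows=100, ncols=100, corr_length_cells=0.0, seed=6)
        r = pearson_matrix(stack).to_frame().iloc[0, 1]
        assert abs(r) < 0.1

    def test_duplicating_mixing_row_gives_unit_correlation(self):
        M = np.array([[1.0, 0.0], [1.0, 0.0]])
        stack = make_stack(2, nrows=50, ncols=50, seed=7, mixing=M)
        r = pearson_matrix(stack).to_frame().iloc[0, 1]
        assert r == pytest.approx(1.0)

    def test_bad_mixing_rejected(self):
        with pytest.raises(ValueError):
            make_stack(2, nrows=10, ncols=10, mixing=np.zeros((2, 2)))

    def test_layers_standardized(self):
        stack = make_stack(2, nrows=60, ncols=60, seed=8)
        for n in stack.names:
            v = stack[n].values
            assert v.mean() == pytest.approx(0.0, abs=1e-9)
            assert v.std() == pytest.approx(1.0, abs=1e-9)


class TestMakeTruth:
    def test_zero_coefficients_give_half(self):
        stack = make_stack(2, nrows=20, ncols=20, seed=9)
        truth = make_truth(stack)
        np.testing.assert_allclose(truth.values, 0.5)

    def test_monotone_in_single_positive_linear_term(self):
        stack = make_stack(1, nrows=30, ncols=30, seed=10)
        truth = make_truth(stack, linear={"env1": 2.0})
        x = stack["env1"].values.ravel()
        y = truth.values.ravel()
        order = np.argsort(x)
        assert np.all(np.diff(y[order]) >= -1e-12)

    def test_quadratic_optimum_location(self):
        stack = make_stack(1, nrows=50, ncols=50, seed=11)
        x0 = 0.3
        truth = make_truth(stack, intercept=1.0, quadratic={"env1": (-2.0, x0)})
        x = stack["env1"].values.ravel()
        best = x[np.argmax(truth.values.ravel())]
        # best cell is the one with layer value closest to the optimum
        assert best == pytest.approx(x[np.argmin(np.abs(x - x0))])

    def test_unknown_layer_rejected(self):
        stack = make_stack(1, nrows=10, ncols=10, seed=12)
        with pytest.raises(KeyError):
            make_truth(stack, linear={"nope": 1.0})


class TestSampleOccurrences:
    def test_single_candidate_cell(self):
        h = GridHeader(ncols=3, nrows=1, xll=0, yll=0, cellsize=1.0)
        truth = Raster(h, np.array([[0.0, 0.9, 0.0]]))
        occ = sample_occurrences(truth, 1, seed=0)
        assert occ.lon[0] == pytest.approx(1.5)

    def test_sampling_prefers_high_suitability(self, scenario):
        vals = scenario.truth.sample(scenario.occurrences.lon, scenario.occurrences.lat)
        assert vals.mean() > scenario.truth.values[scenario.truth.mask].mean()

    def test_deterministic_given_seed(self, scenario):
        occ2 = sample_occurrences(scenario.truth, len(scenario.occurrences),
                                  seed=scenario.seed + 1)
        np.testing.assert_array_equal(occ2.lon, scenario.occurrences.lon)

    def test_too_many_samples_rejected(self):
        h = GridHeader(ncols=2, nrows=1, xll=0, yll=0, cellsize=1.0)
        truth = Raster(h, np.array([[0.5, 0.5]]))
        with pytest.raises(ValueError):
            sample_occurrences(truth, 5)


class TestMakeFuture:
    def test_zero_deltas_identical(self, scenario):
        fut = make_future(scenario.stack, {})
        for n in scenario.stack.names:
            np.testing.assert_array_equal(fut[n].values, scenario.stack[n].values)

    def test_unknown_layer_rejected(self, scenario):
        with pytest.raises(KeyError):
            make_future(scenario.stack, {"nope": 1.0})

    def test_warming_moves_band_by_delta_over_gradient(self):
        # gradient-only temperature: +delta warming translates the narrow
        # thermal band exactly delta/g degrees poleward (here g = 1/degree)
        h = GridHeader(ncols=40, nrows=120, xll=100.0, yll=20.0, cellsize=2.5 / 60.0)
        lat = h.lat_centers()
        temp = np.broadcast_to((-(lat - lat.mean()))[:, None], (120, 40)).copy()
        stack = make_stack(1, header=h, seed=0, layer_names=["temp"])
        stack = type(stack)({"temp": Raster(h, temp)})
        truth_now = make_truth(stack, intercept=2.0, quadratic={"temp": (-3.0, 0.0)})
        truth_fut = make_truth(make_future(stack, {"temp": 0.5}),
                               intercept=2.0, quadratic={"temp": (-3.0, 0.0)})
        c_now = np.average(lat, weights=truth_now.values.sum(axis=1))
        c_fut = np.average(lat, weights=truth_fut.values.sum(axis=1))
        assert c_fut - c_now == pytest.approx(0.5, abs=h.cellsize / 2)

    def test_default_scenario_warming_is_poleward(self, scenario):
        lat = scenario.truth.header.lat_centers()
        c_now = np.average(lat, weights=scenario.truth.values.sum(axis=1))
        c_fut = np.average(lat, weights=scenario.future_truth.values.sum(axis=1))
        assert c_fut > c_now  # north of the current band

    def test_pure_translation_balances_gain_and_loss(self):
        # gradient-only temperature field: warming is an exact translation,
        # so expansion and contraction areas match (up to latitude weights)
        h = GridHeader(ncols=40, nrows=120, xll=100.0, yll=20.0, cellsize=2.5 / 60.0)
        lat = h.lat_centers()
        temp = np.broadcast_to((-(lat - lat.mean()))[:, None], (120, 40)).copy()
        stack_now = make_stack(1, header=h, seed=0, layer_names=["temp"])
        stack_now = type(stack_now)({"temp": Raster(h, temp)})
        truth_now = make_truth(stack_now, intercept=2.0, quadratic={"temp": (-3.0, 0.0)})
        stack_fut = make_future(stack_now, {"temp": 0.5})
        truth_fut = make_truth(stack_fut, intercept=2.0, quadratic={"temp": (-3.0, 0.0)})
        cm = change_map(binarize(truth_now, 0.5), binarize(truth_fut, 0.5))
        st = change_stats(cm)
        assert st.gain == pytest.approx(st.loss, rel=0.02)


class TestDefaultScenario:
    def test_invariants(self, scenario):
        t = scenario.truth.values
        assert t.min() >= 0.0 and t.max() <= 1.0
        assert len(scenario.occurrences) == scenario.config["n_presence"]
        # occurrences on valid cells
        vals = scenario.truth.sample(scenario.occurrences.lon, scenario.occurrences.lat)
        assert not np.isnan(vals).any()

    def test_collinear_pair_present(self, scenario):
        r = pearson_matrix(scenario.stack).to_frame()
        assert abs(r.loc["wet", "wet2"]) > 0.8
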