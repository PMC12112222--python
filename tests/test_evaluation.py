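import numpy as np
import pytest

from enmkit.evaluation import (
    auc,
    auc_band,
    evaluate,
    jackknife,
    percent_contribution,
    permutation_importance,
    response_curve,
    threshold_crossings,
    tss,
)
from enmkit.model import MaxEnt
from enmkit.synthetic import make_stack, make_truth, sample_occurrences


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_all_tied(self):
        assert auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_hand_counted_pairs(self):
        assert auc([0.8, 0.4], [0.6, 0.2]) == 0.75  # 3 of 4 pairs concordant

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        p, b = rng.normal(1, 1, 40), rng.normal(0, 1, 60)
        assert auc(p, b) == pytest.approx(auc(np.exp(p), np.exp(b)), abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            auc([], [0.1])


class TestTss:
    def test_perfect_at_separating_threshold(self):
        assert tss([0.9, 0.8], [0.1, 0.2], 0.5) == pytest.approx(1.0)

    def test_hand_confusion_table(self):
        assert tss([0.9, 0.3], [0.8, 0.1], 0.5) == pytest.approx(0.0)

    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=2000)
        y = rng.uniform(size=2000)
        assert abs(tss(x, y, 0.5)) < 0.05


class TestBands:
    @pytest.mark.parametrize(
        "value,band",
        [(0.95, "excellent"), (0.9, "excellent"), (0.85, "good"), (0.8, "good"),
         (0.75, "fair"), (0.7, "fair"), (0.6, "poor"), (0.3, "fail")],
    )
    def test_band_boundaries_left_closed(self, value, band):
        assert auc_band(value) == band

    def test_evaluate_bundles(self):
        rep = evaluate([0.9, 0.8], [0.85, 0.7], [0.1, 0.2, 0.3], threshold=0.5)
        assert rep.band == "excellent"
        assert rep.tss == pytest.approx(1.0)


@pytest.fixture(scope="module")
def two_signal_fit():
    """Model on two equally informative independent layers + one noise layer."""
    stack = make_stack(3, nrows=70, ncols=70, corr_length_cells=5.0, seed=21,
                       layer_names=["s1", "s2", "noise"])
    truth = make_truth(stack, intercept=0.0, linear={"s1": 1.2, "s2": 1.2})
    occ = sample_occurrences(truth, 150, seed=22)
    mdl = MaxEnt.from_stack(stack, occ, fc="LQ", rm=1.0, n_background=2000, seed=23)
    return mdl, mdl.fit()


class TestJackknife:
    def test_noise_alone_gains_little_and_bounds(self, two_signal_fit):
        mdl, full = two_signal_fit
        df = jackknife(mdl)
        assert df.loc["noise", "rtg_alone"] == pytest.approx(0.0, abs=0.05)
        for v in df.index:
            assert df.loc[v, "rtg_alone"] <= df.attrs["gain_full"] + 1e-6

    def test_duplicated_variable_is_redundant(self):
        rng = np.random.default_rng(30)
        X_b = rng.normal(size=(1500, 2))
        X_b = np.column_stack([X_b[:, 0], X_b[:, 0], X_b[:, 1]])  # dup layer
        w = np.exp(1.5 * X_b[:, 0])
        idx = rng.choice(1500, size=100, p=w / w.sum())
        mdl = MaxEnt(X_b[idx], X_b, ["a", "a2", "b"], fc="L", rm=1.0)
        df = jackknife(mdl)
        full = df.attrs["gain_full"]
        assert df.loc["a", "gain_without"] == pytest.approx(full, abs=0.05)
        assert df.loc["a2", "gain_without"] == pytest.approx(full, abs=0.05)


class TestImportance:
    def test_percent_contribution_sums_to_100(self, two_signal_fit):
        _, res = two_signal_fit
        pc = percent_contribution(res)
        assert pc.sum() == pytest.approx(100.0, abs=1e-6)

    def test_single_variable_gets_all_credit(self):
        rng = np.random.default_rng(31)
        X_b = rng.normal(size=(800, 1))
        w = np.exp(2 * X_b[:, 0])
        idx = rng.choice(800, size=60, p=w / w.sum())
        res = MaxEnt(X_b[idx], X_b, ["only"], fc="LQ", rm=1.0).fit()
        assert percent_contribution(res)["only"] == pytest.approx(100.0)

    def test_symmetric_signals_share_contribution(self):
        # equally informative independent signals split the credit ~50/50
        # on average over replicate landscapes
        shares = []
        for seed in range(6):
            stack = make_stack(3, nrows=60, ncols=60, corr_length_cells=5.0,
                               seed=100 + seed, layer_names=["s1", "s2", "noise"])
            truth = make_truth(stack, linear={"s1": 1.2, "s2": 1.2})
            occ = sample_occurrences(truth, 150, seed=200 + seed)
            res = MaxEnt.from_stack(stack, occ, fc="LQ", rm=1.0,
                                    n_background=1500, seed=seed).fit()
            pc = percent_contribution(res)
            shares.append(pc["s1"])
            assert pc["noise"] < 15.0
        assert np.mean(shares) == pytest.approx(50.0, abs=10.0)

    def test_permutation_importance_finds_noise(self, two_signal_fit):
        _, res = two_signal_fit
        pi = permutation_importance(res, seed=0)
        assert pi.sum() == pytest.approx(100.0, abs=1e-6)
        assert pi["noise"] < 5.0

    def test_permutation_importance_sole_informative(self):
        rng = np.random.default_rng(32)
        X_b = rng.normal(size=(800, 2))
        w = np.exp(2 * X_b[:, 0])
        idx = rng.choice(800, size=60, p=w / w.sum())
        res = MaxEnt(X_b[idx], X_b, ["sig", "noi"], fc="L", rm=1.0).fit()
        pi = permutation_importance(res, seed=1)
        assert pi["sig"] > 95.0

    def test_permutation_importance_stable_across_seeds(self, two_signal_fit):
        _, res = two_signal_fit
        a = permutation_importance(res, seed=10, n_repeats=10)
        b = permutation_importance(res, seed=11, n_repeats=10)
        assert np.max(np.abs(a.values - b.values)) < 2.0


class TestResponseCurves:
    def test_positive_linear_coefficient_monotone_curve(self):
        rng = np.random.default_rng(33)
        X_b = rng.normal(size=(800, 1))
        w = np.exp(1.5 * X_b[:, 0])
        idx = rng.choice(800, size=80, p=w / w.sum())
        res = MaxEnt(X_b[idx], X_b, ["x"], fc="L", rm=1.0).fit()
        df = response_curve(res, "x")
        assert np.all(np.diff(df["logistic"]) >= -1e-12)
        assert np.all((df["logistic"] >= 0) & (df["logistic"] <= 1))

    def test_quadratic_truth_argmax_recovered(self):
        stack = make_stack(2, nrows=70, ncols=70, corr_length_cells=5.0, seed=34,
                           layer_names=["temp", "wet"])
        opt = 0.4
        truth = make_truth(stack, intercept=1.0, quadratic={"temp": (-1.5, opt)},
                           linear={"wet": 0.5})
        occ = sample_occurrences(truth, 180, seed=35)
        res = MaxEnt.from_stack(stack, occ, fc="LQ", rm=1.0,
                                n_background=2000, seed=36).fit()
        df = response_curve(res, "temp", n_grid=201)
        step = df["temp"].iloc[1] - df["temp"].iloc[0]
        assert df.attrs["argmax"] == pytest.approx(opt, abs=20 * step)

    def test_unknown_variable_raises(self, two_signal_fit):
        _, res = two_signal_fit
        with pytest.raises(KeyError):
            response_curve(res, "missing")


class TestThresholdCrossings:
    def test_linear_interpolation(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.0, 1.0, 0.0])
        assert threshold_crossings(x, y, 0.5) == pytest.approx([0.5, 1.5])

    def test_exact_hit_reported(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([0.2, 0.5, 0.9])
        out = threshold_crossings(x, y, 0.2)
        assert out[0] == 0.0
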