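import numpy as np
import pandas as pd
import pytest

from ftirpred._exceptions import ConfigError, DataError
from ftirpred.cv import (
    assign_batch_out,
    assign_herd_out,
    assign_tenfold,
    calibration_slope,
    r_squared,
    rd_vs_h2_regression,
    relative_difference,
    rmse,
    run_experiment,
    wavelength_trait_correlations,
)


class TestTenfold:
    def test_twenty_cows_ten_folds_of_two(self):
        scheme = assign_tenfold(20, seed=0)
        sizes = [v.size for _, v in scheme.splits]
        assert sizes == [2] * 10

    def test_balance_at_odd_n(self):
        scheme = assign_tenfold(1019, seed=1)
        sizes = sorted(v.size for _, v in scheme.splits)
        assert max(sizes) - min(sizes) <= 1
        all_valid = np.concatenate([v for _, v in scheme.splits])
        assert np.array_equal(np.sort(all_valid), np.arange(1019))

    def test_disjoint_and_deterministic(self):
        s1 = assign_tenfold(57, seed=9)
        s2 = assign_tenfold(57, seed=9)
        for (t1, v1), (t2, v2) in zip(s1.splits, s2.splits):
            assert np.array_equal(v1, v2)
            assert np.intersect1d(t1, v1).size == 0

    def test_too_few(self):
        with pytest.raises(ConfigError):
            assign_tenfold(5)


class TestBatchOut:
    def _data(self, rng, n_per=10, n_batches=8, separation=0.0):
        batches = np.repeat(np.arange(n_batches), n_per)
        n = batches.size
        # block-structured G: a small outlying cluster of batches (5, 6, 7)
        cluster = (batches >= n_batches - 3).astype(float)
        base = rng.normal(size=(n, 5)) * 0.1
        base[:, 0] += cluster * separation
        G = base @ base.T
        return batches, G

    def test_every_batch_validated_at_least_once(self, rng):
        batches, G = self._data(rng)
        scheme = assign_batch_out(batches, G, n_valid_batches=3, n_replicates=5)
        seen = set()
        for tr, va in scheme.splits:
            assert np.intersect1d(tr, va).size == 0
            seen |= set(np.unique(batches[va]))
        assert seen == set(range(8))

    def test_far_cluster_prioritized(self, rng):
        batches, G = self._data(rng, separation=5.0)
        scheme = assign_batch_out(batches, G, n_valid_batches=3, n_replicates=5)
        first_valid_batches = set(np.unique(batches[scheme.splits[0][1]]))
        assert first_valid_batches == {5, 6, 7}

    def test_degenerate_distances_still_cover(self, rng):
        batches = np.repeat(np.arange(4), 5)
        G = np.eye(20)
        scheme = assign_batch_out(batches, G, n_valid_batches=1, n_replicates=4)
        seen = set()
        for _, va in scheme.splits:
            seen |= set(np.unique(batches[va]))
        assert seen == set(range(4))

    def test_too_few_batches(self, rng):
        with pytest.raises(ConfigError):
            assign_batch_out(np.repeat([0, 1], 5), np.eye(10), n_valid_batches=3)


class TestHerdOut:
    def test_both_directions(self):
        herd = np.r_[np.ones(945), np.full(75, 2)]
        scheme = assign_herd_out(herd)
        (t1, v1), (t2, v2) = scheme.splits
        assert t1.size == 945 and v1.size == 75
        assert t2.size == 75 and v2.size == 945
        assert np.intersect1d(t1, v1).size == 0

    def test_single_herd_rejected(self):
        with pytest.raises(ConfigError):
            assign_herd_out(np.ones(10))


class TestMetrics:
    def test_r2_perfect_and_affine_invariant(self, rng):
        y = rng.normal(size=20)
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, 3 * y - 2) == pytest.approx(1.0)

    def test_r2_hand_oracle(self):
        a = np.array([1.0, 2, 3, 4])
        b = np.array([1.1, 1.9, 3.2, 3.8])
        r = np.sum((a - a.mean()) * (b - b.mean())) / np.sqrt(
            np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2)
        )
        assert r_squared(a, b) == pytest.approx(r**2, abs=1e-12)

    def test_r2_errors(self):
        with pytest.raises(DataError):
            r_squared([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DataError):
            r_squared([1.0, 1, 1], [1.0, 2, 3])

    def test_rmse(self, rng):
        y = rng.normal(size=15)
        assert rmse(y, y) == 0.0
        assert rmse(y, y + 2.5) == pytest.approx(2.5)
        yhat = y + rng.normal(size=15)
        assert rmse(y, yhat) == pytest.approx(
            np.sqrt(np.mean((y - yhat) ** 2)), abs=1e-12
        )

    def test_slope(self, rng):
        y = rng.normal(size=30)
        assert calibration_slope(y, y) == pytest.approx(1.0)
        # halved predictions are "deflated": slope 2
        assert calibration_slope(y, y / 2) == pytest.approx(2.0)
        with pytest.raises(DataError):
            calibration_slope(y, np.ones(30))

    def test_slope_ols_oracle(self, rng):
        y = rng.normal(size=25)
        p = 0.5 * y + rng.normal(size=25) * 0.2
        b = np.polyfit(p, y, 1)[0]
        assert calibration_slope(y, p) == pytest.approx(b, abs=1e-10)


class TestRelativeDifference:
    @pytest.mark.parametrize(
        "rm, r1, expected",
        [
            (0.63, 0.53, 18.87),
            (0.48, 0.41, 17.07),
            (0.70, 0.63, 11.11),
            (0.5, 0.5, 0.0),
        ],
    )
    def test_reported_gaps(self, rm, r1, expected):
        assert relative_difference(rm, r1) == pytest.approx(expected, abs=0.005)

    def test_baseline_must_be_positive(self):
        with pytest.raises(DataError):
            relative_difference(0.5, 0.0)

    def test_antisymmetry_identity(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.1, 0.9, 2)
            rd_ab = relative_difference(a, b)
            rd_ba = relative_difference(b, a)
            assert rd_ab == pytest.approx(-100 * rd_ba / (100 + rd_ba))


class TestRdVsH2:
    def test_perfectly_linear(self):
        h2 = np.array([0.1, 0.3, 0.5, 0.7])
        rd = 20 * h2 + 3
        slope, intercept, r2 = rd_vs_h2_regression(rd, h2)
        assert slope == pytest.approx(20) and intercept == pytest.approx(3)
        assert r2 == pytest.approx(1.0)

    def test_null_association(self, rng):
        h2 = rng.uniform(0, 1, 200)
        rd = rng.normal(size=200)
        assert rd_vs_h2_regression(rd, h2)[2] < 0.05

    def test_hand_oracle(self):
        h2 = np.array([0.1, 0.2, 0.4])
        rd = np.array([1.0, 3.0, 4.0])
        slope, intercept, _ = rd_vs_h2_regression(rd, h2)
        b, a = np.polyfit(h2, rd, 1)
        assert slope == pytest.approx(b) and intercept == pytest.approx(a)

    def test_too_few_traits(self):
        with pytest.raises(DataError):
            rd_vs_h2_regression([1.0, 2.0], [0.1, 0.2])


class TestWavelengthCorrelations:
    def test_copy_correlates_perfectly(self, rng):
        S = rng.normal(size=(50, 5))
        traits = pd.DataFrame({"t": S[:, 2]})
        tab = wavelength_trait_correlations(S, traits)
        assert tab.loc[2, "t"] == pytest.approx(1.0)

    def test_independent_near_zero(self, rng):
        S = rng.normal(size=(2000, 3))
        traits = pd.DataFrame({"t": rng.normal(size=2000)})
        tab = wavelength_trait_correlations(S, traits)
        assert np.abs(tab["t"]).max() < 0.08

    def test_zero_variance_skipped_with_warning(self, rng):
        S = np.column_stack([np.ones(30), rng.normal(size=30)])
        traits = pd.DataFrame({"t": rng.normal(size=30)})
        with pytest.warns(UserWarning):
            tab = wavelength_trait_correlations(S, traits)
        assert list(tab.index) == [1]


class TestRunExperiment:
    def test_shape_and_fold_fixing(self, small_analysis):
        data, _, _ = small_analysis
        kwargs = dict(
            methods=("bayesb",),
            schemes=("tenfold",),
            traits=["t1"],
            seed=3,
            bayesb_params=dict(n_iter=400, burn_in=100, thin=2),
            n_folds=4,
        )
        res = run_experiment(data, models=("M1", "M2"), **kwargs)
        assert len(res.results) == 2 * 4  # models x folds
        again = run_experiment(data, models=("M1",), **kwargs)
        merged = res.results.query("model == 'M1'").reset_index(drop=True)
        np.testing.assert_allclose(merged["r2"], again.results["r2"])
        rd = res.rd_table()
        assert set(rd["model"]) == {"M2"}
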