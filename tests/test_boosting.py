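import numpy as np
import pytest
from sklearn.ensemble import GradientBoostingRegressor

import ftirpred as fp
from ftirpred._exceptions import DataError
from ftirpred.boosting import (
    GBMSearchSpace,
    TunedGBMRegressor,
    sample_search_space,
    shared_wavelength_counts,
    significant_wavelengths,
    variable_importance,
)

SMALL_SPACE = GBMSearchSpace(
    ntree=(100, 200, 100),
    learn_rate=(0.1, 0.3, 0.1),
    max_depth=(5, 10, 5),
    min_leaf=(20, 40, 20),
    max_models=4,
)


class TestSearchSpace:
    def test_grid_membership(self):
        configs = sample_search_space(GBMSearchSpace(max_models=50), seed=1)
        assert len(configs) == 50
        for c in configs:
            assert 100 <= c["ntree"] <= 3000 and c["ntree"] % 20 == 0
            assert 0.0 <= c["learn_rate"] <= 1.0
            assert c["max_depth"] % 5 == 0 and 5 <= c["max_depth"] <= 80
            assert c["min_leaf"] in (20, 40, 60, 80, 100)

    def test_seed_determinism(self):
        s = GBMSearchSpace(max_models=30)
        assert sample_search_space(s, seed=7) == sample_search_space(s, seed=7)

    def test_exhaustive_small_grid_no_duplicates(self):
        configs = sample_search_space(
            GBMSearchSpace(
                ntree=(100, 200, 100), learn_rate=(0.1, 0.3, 0.1),
                max_depth=(5, 10, 5), min_leaf=(20, 40, 20), max_models=100,
            ),
            seed=0,
        )
        assert len(configs) == 2 * 3 * 2 * 2
        seen = {tuple(sorted(c.items())) for c in configs}
        assert len(seen) == len(configs)


class TestTunedGBM:
    def test_zero_learning_rate_predicts_mean(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.normal(size=60) + 5.0
        space = GBMSearchSpace(
            ntree=(100, 100, 100), learn_rate=(0.0, 0.0, 0.1),
            max_depth=(5, 5, 5), min_leaf=(20, 20, 20), max_models=1,
        )
        m = TunedGBMRegressor(space=space, seed=0).fit(X, y)
        np.testing.assert_allclose(m.predict(X), y.mean())

    def test_pure_noise_null_r2(self, rng):
        n = 600
        X = rng.normal(size=(n, 20))
        y = rng.normal(size=n)
        m = TunedGBMRegressor(space=SMALL_SPACE, seed=1).fit(X[:450], y[:450])
        pred = m.predict(X[450:])
        if pred.std() > 0:
            assert np.corrcoef(pred, y[450:])[0, 1] ** 2 < 0.05

    def test_noiseless_step_function_recovered(self, rng):
        n = 400
        X = rng.normal(size=(n, 5))
        y = np.where(X[:, 2] > 0, 1.0, -1.0)
        m = TunedGBMRegressor(space=SMALL_SPACE, seed=2).fit(X[:300], y[:300])
        pred = m.predict(X[300:])
        assert np.corrcoef(pred, y[300:])[0, 1] ** 2 > 0.95

    def test_training_loss_monotone(self, rng):
        X = rng.normal(size=(200, 5))
        y = X[:, 0] + rng.normal(size=200) * 0.3
        g = GradientBoostingRegressor(
            n_estimators=100, learning_rate=0.1, max_depth=3,
            min_samples_leaf=20, random_state=0,
        ).fit(X, y)
        assert (np.diff(g.train_score_) <= 1e-12).all()

    def test_degenerate_response_rejected(self, rng):
        with pytest.raises(DataError):
            TunedGBMRegressor(space=SMALL_SPACE).fit(
                rng.normal(size=(50, 3)), np.ones(50)
            )


class TestVariableImportance:
    def test_single_split_gets_all_importance(self, rng):
        X = rng.normal(size=(200, 4))
        y = np.where(X[:, 1] > 0, 1.0, 0.0)
        g = GradientBoostingRegressor(
            n_estimators=1, max_depth=1, learning_rate=1.0, random_state=0
        ).fit(X, y)
        vi = variable_importance(g)
        assert vi[1] == pytest.approx(100.0)
        assert vi.sum() == pytest.approx(100.0)

    def test_sums_to_100(self, rng):
        X = rng.normal(size=(300, 8))
        y = X[:, 0] - X[:, 3] + rng.normal(size=300) * 0.2
        g = GradientBoostingRegressor(
            n_estimators=50, max_depth=3, random_state=1
        ).fit(X, y)
        assert variable_importance(g).sum() == pytest.approx(100.0, abs=1e-6)

    def test_permuting_columns_permutes_vi(self, rng):
        X = rng.normal(size=(300, 6))
        y = 2 * X[:, 0] + X[:, 4] + rng.normal(size=300) * 0.1
        perm = np.array([3, 0, 5, 1, 2, 4])
        g1 = GradientBoostingRegressor(
            n_estimators=30, max_depth=2, random_state=2
        ).fit(X, y)
        g2 = GradientBoostingRegressor(
            n_estimators=30, max_depth=2, random_state=2
        ).fit(X[:, perm], y)
        vi1, vi2 = variable_importance(g1), variable_importance(g2)
        # tiny tie-break differences on noise features are tolerated
        np.testing.assert_allclose(vi2, vi1[perm], atol=0.01)

    def test_duplicated_feature_splits_importance(self, rng):
        X = rng.normal(size=(400, 3))
        y = X[:, 0] + rng.normal(size=400) * 0.2
        Xdup = np.column_stack([X, X[:, 0]])
        g1 = GradientBoostingRegressor(
            n_estimators=30, max_depth=2, random_state=3
        ).fit(X, y)
        g2 = GradientBoostingRegressor(
            n_estimators=30, max_depth=2, random_state=3
        ).fit(Xdup, y)
        vi1, vi2 = variable_importance(g1), variable_importance(g2)
        assert vi2[0] + vi2[3] == pytest.approx(vi1[0], abs=2.0)

    def test_mean_model_has_no_importance(self, rng):
        space = GBMSearchSpace(
            ntree=(100, 100, 100), learn_rate=(0.0, 0.0, 0.1),
            max_depth=(5, 5, 5), min_leaf=(20, 20, 20), max_models=1,
        )
        m = TunedGBMRegressor(space=space, seed=0).fit(
            rng.normal(size=(50, 2)), rng.normal(size=50)
        )
        with pytest.raises(DataError):
            variable_importance(m)


class TestSignificantWavelengths:
    def test_uniform_vi_selects_nothing(self):
        vi = np.full(1060, 100.0 / 1060)
        assert significant_wavelengths(vi).size == 0

    def test_singleton(self):
        vi = np.zeros(10)
        vi[4] = 100.0
        np.testing.assert_array_equal(significant_wavelengths(vi), [4])

    def test_overlap_counts(self):
        sel = {"a": np.array([1, 2]), "b": np.array([2, 3])}
        counts = shared_wavelength_counts(sel)
        assert counts[2] == 2 and counts[1] == 1 and counts[3] == 1

    def test_planted_window_recovery(self):
        # spectra-driven trait: wavelengths selected by VI should fall inside
        # the planted loading windows
        fracs = []
        for seed in range(3):
            cfg = fp.SimConfig(
                n_cows=250, n_snps=40, n_wavelengths=300, n_batches=5,
                herd_sizes=(200, 50),
                traits={"t": fp.TraitTargets(0.3, 0.1)},
                spectral_signal=0.9, channel_noise_sd=0.02, rng_seed=seed,
            )
            b = fp.simulate_dataset(cfg)
            clean, _ = fp.preprocess_pipeline(b.spectra)
            pos = {a: i for i, a in enumerate(clean.ids)}
            idx = [pos[a] for a in b.cow_table["animal"] if a in pos]
            keep = [a in pos for a in b.cow_table["animal"]]
            S = clean.values[idx]
            y = b.cow_table.loc[keep, "t"].to_numpy()
            m = TunedGBMRegressor(space=SMALL_SPACE, seed=seed).fit(S, y)
            vi = variable_importance(m)
            sel = significant_wavelengths(vi, threshold=0.8)
            mask = b.truth.loading_masks["t"]
            if sel.size:
                fracs.append(mask[sel].mean())
        assert np.median(fracs) >= 0.8
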