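"""Decoding protocol: oversampling, manifolds, CV, metrics, MRMR."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import f1_score

from skillcontext import decoding as dec
from skillcontext import features as ft
from skillcontext import synthetic as syn


def binomial_band(p, n, conf=0.99):
    lo, hi = stats.binom.interval(conf, n, p)
    return 100.0 * lo / n, 100.0 * hi / n


class TestOversample:
    def test_study_class_counts_balanced(self):
        # mean per-class sample counts reported for the study's sessions
        counts = {4: 426, 1: 219, 2: 205, 3: 209}
        y = np.concatenate([np.full(n, k) for k, n in counts.items()])
        X = np.arange(len(y), dtype=float)[:, None]
        _, y_res, _ = dec.oversample_minority(X, y, seed=0)
        assert all((y_res == k).sum() == 426 for k in counts)

    def test_balanced_input_unchanged(self):
        y = np.repeat([1, 2, 3], 10)
        X = np.random.default_rng(0).standard_normal((30, 2))
        X_res, y_res, prov = dec.oversample_minority(X, y, seed=1)
        assert np.array_equal(X_res, X) and np.array_equal(y_res, y)
        assert np.array_equal(prov, np.arange(30))

    def test_deterministic_under_seed(self):
        y = np.repeat([1, 2], [5, 20])
        X = np.random.default_rng(2).standard_normal((25, 3))
        a = dec.oversample_minority(X, y, seed=7)
        b = dec.oversample_minority(X, y, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[2], b[2])

    def test_single_class_noop_with_warning(self):
        X = np.zeros((4, 2))
        with pytest.warns(UserWarning, match="single-class"):
            X_res, y_res, _ = dec.oversample_minority(X, np.ones(4), seed=0)
        assert len(y_res) == 4

    def test_oversampled_rows_come_from_source(self):
        rng = np.random.default_rng(3)
        y = np.repeat([1, 2], [4, 12])
        X = rng.standard_normal((16, 2))
        X_res, y_res, prov = dec.oversample_minority(X, y, seed=0)
        assert np.array_equal(X_res, X[prov]) and np.array_equal(y_res, y[prov])


class TestManifold:
    def test_supervised_dims_follow_class_count(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((80, 10))
        y4 = np.repeat([1, 2, 3, 4], 20)
        assert dec.fit_manifold(X, y4, "lda").transform(X).shape[1] == 3
        y5 = np.repeat([0, 1, 2, 3, 4], 16)
        assert dec.fit_manifold(X, y5, "lda").transform(X).shape[1] == 4

    def test_too_many_components_rejected(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 5))
        y = np.repeat([0, 1], 10)
        with pytest.raises(ValueError, match="at most"):
            dec.ManifoldModel("lda", n_components=3).fit(X, y)

    def test_separated_classes_stay_separated(self):
        rng = np.random.default_rng(2)
        X = np.concatenate([rng.normal(-5, 0.01, 50), rng.normal(5, 0.01, 50)])[:, None]
        X = np.hstack([X, rng.standard_normal((100, 3))])
        y = np.repeat([0, 1], 50)
        Z = dec.fit_manifold(X, y, "lda").transform(X)
        gap = abs(Z[y == 0].mean() - Z[y == 1].mean())
        within = max(Z[y == 0].std(), Z[y == 1].std())
        assert gap > 50 * within

    def test_transform_requires_fit(self):
        with pytest.raises(RuntimeError):
            dec.ManifoldModel("pca").transform(np.zeros((3, 2)))

    @pytest.mark.parametrize("method", ["none", "pca", "mds", "mrmr"])
    def test_reducers_roundtrip_shapes(self, method):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 8))
        y = np.repeat([0, 1, 2], 20)
        m = dec.ManifoldModel(method, n_components=4).fit(X, y)
        assert m.transform(X[:10]).shape == (10, 8 if method == "none" else 4)


class TestTrainEval:
    def test_separable_clusters_perfect_accuracy(self):
        fm = syn.gaussian_class_matrix(40, 6, 4, separation=50.0, seed=0)
        res = dec.train_eval(fm, dec.DecoderConfig(seed=0))
        assert res.accuracy == pytest.approx(100.0)

    def test_pure_noise_within_chance_band(self):
        fm = syn.noise_feature_matrix(400, 10, 4, seed=1)
        res = dec.train_eval(fm, dec.DecoderConfig(seed=1))
        n_preds = int(res.confusion.sum())
        lo, hi = binomial_band(0.25, n_preds)
        assert lo <= 100.0 * np.trace(res.confusion) / n_preds <= hi

    def test_deterministic_under_seed_and_config(self):
        fm = syn.gaussian_class_matrix(30, 5, 4, separation=3.0, seed=2)
        cfg = dec.DecoderConfig(seed=9)
        a, b = dec.train_eval(fm, cfg), dec.train_eval(fm, cfg)
        assert a.accuracy == b.accuracy
        assert np.array_equal(a.confusion, b.confusion)

    def test_selection_ignores_test_rows(self):
        # zeroing the (seed-determined) test rows cannot change model selection
        fm = syn.gaussian_class_matrix(30, 5, 4, separation=2.0, seed=3)
        cfg = dec.DecoderConfig(seed=4, n_iterations=3)
        base = dec.train_eval(fm, cfg)
        from sklearn.model_selection import StratifiedShuffleSplit

        for it in range(cfg.n_iterations):
            spl = StratifiedShuffleSplit(
                n_splits=1, test_size=cfg.test_fraction, random_state=cfg.seed + it
            )
            (tr, te), = spl.split(fm.X, fm.y)
            X2 = fm.X.copy()
            X2[te] = 0.0
            fm2 = ft.FeatureMatrix(
                X=X2, y=fm.y, feature_names=fm.feature_names, meta=fm.meta
            )
            res2 = dec.train_eval(fm2, cfg)
            assert res2.best_params[it] == base.best_params[it]

    def test_metric_identities_against_sklearn(self):
        fm = syn.gaussian_class_matrix(30, 6, 4, separation=2.0, seed=5)
        res = dec.train_eval(fm, dec.DecoderConfig(seed=5))
        cm = res.confusion.astype(int)
        # reconstruct a label stream from the confusion matrix (independent path)
        y_true, y_pred = [], []
        for i, ci in enumerate(res.classes):
            for j, cj in enumerate(res.classes):
                y_true += [ci] * cm[i, j]
                y_pred += [cj] * cm[i, j]
        ref = f1_score(y_true, y_pred, average="weighted", labels=res.classes)
        assert res.weighted_f1 == pytest.approx(ref, abs=1e-12)
        acc = 100.0 * np.trace(cm) / cm.sum()
        per_class = f1_score(y_true, y_pred, average=None, labels=res.classes)
        for c, f in zip(res.classes, per_class):
            assert res.per_class_f1[c] == pytest.approx(f, abs=1e-12)
        assert np.trace(cm) / cm.sum() == pytest.approx(
            np.mean(np.array(y_true) == np.array(y_pred)), abs=1e-12
        )

    def test_fold_reduction_warns_on_small_class(self):
        fm = syn.gaussian_class_matrix(40, 4, 2, separation=4.0, seed=6)
        # shrink one class below the fold count
        keep = np.concatenate([np.flatnonzero(fm.y == 1)[:6], np.flatnonzero(fm.y == 2)])
        fm2 = ft.FeatureMatrix(
            X=fm.X[keep], y=fm.y[keep], feature_names=fm.feature_names,
            meta=fm.meta.iloc[keep].reset_index(drop=True),
        )
        with pytest.warns(UserWarning, match="reducing folds"):
            dec.train_eval(fm2, dec.DecoderConfig(seed=0, n_iterations=1))

    @pytest.mark.parametrize("clf", ["nb", "knn", "dt"])
    def test_alternative_classifiers_run(self, clf):
        fm = syn.gaussian_class_matrix(20, 4, 3, separation=30.0, seed=7)
        cfg = dec.DecoderConfig(classifier=clf, reducer="none", seed=0, n_iterations=2)
        assert dec.train_eval(fm, cfg).accuracy > 90.0


class TestWindowOptimization:
    def test_tie_breaks_to_smallest_window(self):
        ts = ft.SourceTimeSeries(np.zeros((2, 3000)), srate=600.0)
        ev = pd.DataFrame(
            {
                "onset": 0.2 + 0.4 * np.arange(8),
                "key": [1, 2] * 4,
                "trial": 1,
                "is_correct": True,
                "ordinal_position": 1.0,
            }
        )
        grid = ft.window_grid([0, 50], [25, 100])
        cfg = dec.DecoderConfig(
            seed=0, n_folds=2, oversample=False, classifier="nb", reducer="none"
        )
        w, _ = dec.optimize_window(ts, ev, grid, cfg, full_result=False)
        assert (w.t, w.dt) == (0.0, 25.0)

    def test_single_window_grid_returned(self):
        ts = ft.SourceTimeSeries(np.random.default_rng(0).standard_normal((2, 3000)))
        ev = pd.DataFrame(
            {
                "onset": 0.2 + 0.4 * np.arange(8),
                "key": [1, 2] * 4,
                "trial": 1,
                "is_correct": True,
                "ordinal_position": 1.0,
            }
        )
        grid = [ft.EpochWindow(10, 150)]
        cfg = dec.DecoderConfig(seed=0, n_folds=2, oversample=False)
        w, _ = dec.optimize_window(ts, ev, grid, cfg, full_result=False)
        assert w == grid[0]

    def test_finds_planted_signal_window(self):
        # class signal present only 0-100 ms after KeyDown
        rng = np.random.default_rng(1)
        srate = 600.0
        n_ev = 60
        onsets = 0.3 + 0.4 * np.arange(n_ev)
        keys = np.tile([1, 2], n_ev // 2)
        data = 0.5 * rng.standard_normal((4, int(onsets[-1] * srate) + 600))
        pat = {1: rng.standard_normal(4), 2: rng.standard_normal(4)}
        for o, k in zip(onsets, keys):
            s0 = int(np.ceil(o * srate))
            data[:, s0 : s0 + 60] += pat[k][:, None]
        ts = ft.SourceTimeSeries(data, srate=srate)
        ev = pd.DataFrame(
            {"onset": onsets, "key": keys, "trial": 1, "is_correct": True,
             "ordinal_position": 1.0}
        )
        grid = ft.window_grid([0, 50, 100], [50, 150, 300])
        cfg = dec.DecoderConfig(seed=0, n_folds=4, oversample=False, reducer="none")
        w, _ = dec.optimize_window(ts, ev, grid, cfg, full_result=False)
        assert w.t < 100.0  # chosen window overlaps the planted 0-100 ms interval


class TestSequenceElementDecoding:
    def test_recode_splits_index_by_context(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((10, 3))
        meta = pd.DataFrame(
            {
                "trial": 1,
                "onset": np.arange(10.0),
                "ordinal_position": [1, 2, 3, 4, 5] * 2,
            }
        )
        fm = ft.FeatureMatrix(
            X=X, y=np.array([4, 1, 3, 2, 4] * 2), feature_names=list("abc"), meta=meta
        )
        out = dec.recode_sequence_elements(fm)
        assert sorted(set(out.y)) == ["Index_OP1", "Index_OP5", "Little", "Middle", "Ring"]
        assert (out.y == "Index_OP1").sum() == 2 and (out.y == "Index_OP5").sum() == 2

    def test_insufficient_samples_rejected(self):
        rng = np.random.default_rng(1)
        fm = ft.FeatureMatrix(
            X=rng.standard_normal((5, 3)),
            y=np.array([4, 1, 3, 2, 4]),
            feature_names=list("abc"),
            meta=pd.DataFrame(
                {"trial": 1, "onset": np.arange(5.0), "ordinal_position": [1, 2, 3, 4, 5]}
            ),
        )
        with pytest.raises(ValueError, match="at least 2 samples"):
            dec.decode_sequence_elements(fm, dec.DecoderConfig(seed=0))


class TestPerTrialTwoClass:
    def _fm(self, n_trials, n1, n5, rng, sep=0.0):
        rows, X = [], []
        for tr in range(1, n_trials + 1):
            for i in range(n1):
                rows.append(dict(trial=tr, onset=20 * tr + i, ordinal_position=1.0))
                X.append(rng.standard_normal(4) - sep / 2 * np.array([1, 0, 0, 0]))
            for i in range(n5):
                rows.append(dict(trial=tr, onset=20 * tr + 10 + i, ordinal_position=5.0))
                X.append(rng.standard_normal(4) + sep / 2 * np.array([1, 0, 0, 0]))
        meta = pd.DataFrame(rows)
        y = np.where(meta["ordinal_position"] == 1.0, "Index_OP1", "Index_OP5")
        return ft.FeatureMatrix(
            X=np.array(X), y=y.astype(str), feature_names=list("wxyz"), meta=meta
        )

    def test_first_k_instances_used(self):
        rng = np.random.default_rng(0)
        fm = self._fm(1, 7, 9, rng)
        out = dec.per_trial_two_class(fm, k=5)
        assert out.loc[0, "n_samples"] == 10

    def test_short_trial_marked_missing(self):
        rng = np.random.default_rng(1)
        fm = self._fm(2, 3, 8, rng)
        out = dec.per_trial_two_class(fm, k=5)
        assert out["accuracy"].isna().all()

    def test_no_divergence_stays_at_chance(self):
        rng = np.random.default_rng(2)
        fm = self._fm(10, 8, 8, rng, sep=0.0)
        out = dec.per_trial_two_class(fm, k=8)
        # pooled over trials: 99% band around 50%
        accs = out["accuracy"].to_numpy()
        n = 16 * 10
        correct = int(np.nansum(accs / 100.0 * 16))
        lo, hi = stats.binom.interval(0.99, n, 0.5)
        assert lo <= correct <= hi

    def test_growing_divergence_tracks_trials(self):
        rng = np.random.default_rng(3)
        fms = []
        for tr in range(1, 13):
            sep = 0.5 * (tr - 1)
            fms.append(self._fm(1, 8, 8, rng, sep=sep).X)
        # assemble one matrix with per-trial separations
        rows, X = [], []
        for tr in range(1, 13):
            sep = 0.45 * (tr - 1)
            sub = self._fm(1, 8, 8, rng, sep=sep)
            sub.meta["trial"] = tr
            rows.append(sub.meta)
            X.append(sub.X)
        fm = ft.FeatureMatrix(
            X=np.vstack(X),
            y=np.concatenate([np.where(m["ordinal_position"] == 1, "Index_OP1", "Index_OP5") for m in rows]).astype(str),
            feature_names=list("wxyz"),
            meta=pd.concat(rows, ignore_index=True),
        )
        out = dec.per_trial_two_class(fm, k=8)
        rho = stats.spearmanr(out["trial"], out["accuracy"]).statistic
        assert rho > 0.8


class TestShuffleControl:
    def test_four_class_chance_mean(self):
        fm = syn.gaussian_class_matrix(40, 5, 4, separation=8.0, seed=0)
        cfg = dec.DecoderConfig(seed=0)
        accs = dec.shuffle_control(fm, cfg, n_shuffles=400)
        assert abs(accs.mean() - 25.0) < 6.0

    def test_five_class_chance_mean(self):
        fm = syn.gaussian_class_matrix(40, 5, 5, separation=8.0, seed=1)
        accs = dec.shuffle_control(fm, dec.DecoderConfig(seed=1), n_shuffles=400)
        assert abs(accs.mean() - 20.0) < 6.0

    def test_zero_shuffles_empty(self):
        fm = syn.gaussian_class_matrix(20, 4, 3, separation=5.0, seed=2)
        assert len(dec.shuffle_control(fm, dec.DecoderConfig(seed=0), 0)) == 0


class TestMrmr:
    def test_label_feature_ranked_first(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1, 2, 3], 50)
        X = rng.standard_normal((200, 6))
        X[:, 3] = y + 0.05 * rng.standard_normal(200)
        fm = ft.FeatureMatrix(
            X=X, y=y, feature_names=[f"f{i}" for i in range(6)],
            meta=pd.DataFrame({"trial": np.ones(200, dtype=int)}),
        )
        ranked = dec.mrmr_importance(fm)
        assert ranked.iloc[0]["feature"] == "f3"

    def test_duplicate_informative_feature_penalized(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 100)
        informative = y + 0.1 * rng.standard_normal(200)
        second = -2.0 * y + 0.1 * rng.standard_normal(200)  # equal relevance, distinct
        X = np.column_stack([informative, informative.copy(), second,
                             rng.standard_normal(200)])
        rank = dec.mrmr_rank(X, y)
        order = rank["index"].tolist()
        # the duplicate of the first pick ranks below the non-redundant feature
        assert order.index(2) < max(order.index(0), order.index(1))

    def test_constant_feature_zero_relevance(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 30)
        X = np.column_stack([np.full(60, 3.0), y + 0.1 * rng.standard_normal(60)])
        rank = dec.mrmr_rank(X, y)
        assert rank.loc[rank["index"] == 0, "score"].iloc[0] <= 1e-12

    def test_identical_noise_small_score_spread(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 100)
        base = rng.standard_normal(200)
        X = np.tile(base[:, None], (1, 4))
        rank = dec.mrmr_rank(X, y)
        assert len(rank) == 4
        assert rank["score"].iloc[1:].max() - rank["score"].iloc[1:].min() < 1e-9

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            dec.mrmr_rank(np.zeros((10, 1)), np.repeat([0, 1], 5))
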