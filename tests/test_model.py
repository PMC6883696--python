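"""Dataset assembly, screening, training, calibration and evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from intronscore import model as mod
from intronscore.model import (FeatureMatrix, FprCalibratedForest,
                               assemble_datasets, calibrate_fpr, evaluate,
                               screen_features, train)


def _feature_df(rng, n, region, label_signal=None, maf=None):
    df = pd.DataFrame({
        "variant_id": [f"v{region}{i}" for i in range(n)],
        "region_class": region,
        "maf": maf if maf is not None else np.nan,
        "min_distance": rng.integers(1, 70, size=n),
        "f_signal": rng.normal(loc=label_signal or 0.0, size=n),
        "f_noise": rng.normal(size=n),
    })
    return df


class TestAssembleDatasets:
    def _inputs(self, seed=0):
        rng = np.random.default_rng(seed)
        path = pd.concat([_feature_df(rng, 60, "on-ss", 2.0),
                          _feature_df(rng, 120, "off-ss", 2.0)],
                         ignore_index=True)
        neut = pd.concat([
            _feature_df(rng, 60, "on-ss", 0.0,
                        maf=rng.uniform(0.0, 0.5, size=60)),
            _feature_df(rng, 300, "off-ss", 0.0,
                        maf=rng.uniform(0.0, 0.5, size=300))],
            ignore_index=True)
        neut["variant_id"] = [f"n{i}" for i in range(len(neut))]
        return path, neut

    def test_maf_filter_is_strict(self):
        path, neut = self._inputs()
        neut = neut.copy()
        neut.loc[neut.index[:3], "maf"] = [0.05, 0.10, 0.101]
        ds = assemble_datasets(path, neut, seed=1)
        kept = pd.concat([ds["on-ss"]["train"].data, ds["on-ss"]["validation"].data,
                          ds["off-ss"]["train"].data,
                          ds["off-ss"]["validation"].data])
        kept_neut = kept[kept["label"] == "neutral"]
        assert (kept_neut["maf"] > 0.10).all()
        ids = set(kept_neut["variant_id"])
        assert "n0" not in ids and "n1" not in ids  # 0.05 and 0.10 excluded

    def test_distance_matching_bin_counts(self):
        path, neut = self._inputs(3)
        ds = assemble_datasets(path, neut, seed=2)
        both = pd.concat([ds["off-ss"]["train"].data,
                          ds["off-ss"]["validation"].data])
        p = both[both["label"] == "pathogenic"]
        n = both[both["label"] == "neutral"]
        avail = neut[(neut["region_class"] == "off-ss")
                     & (neut["maf"] > 0.10)]
        for b in range(8):
            lo, hi = b * 10 + 1, (b + 1) * 10
            target = ((p["min_distance"] >= lo) & (p["min_distance"] <= hi)).sum()
            got = ((n["min_distance"] >= lo) & (n["min_distance"] <= hi)).sum()
            pool = ((avail["min_distance"] >= lo)
                    & (avail["min_distance"] <= hi)).sum()
            assert got == min(target, pool)

    def test_split_is_deterministic_and_two_thirds(self):
        path, neut = self._inputs(5)
        a = assemble_datasets(path, neut, seed=9)
        b = assemble_datasets(path, neut, seed=9)
        for region in ("on-ss", "off-ss"):
            pd.testing.assert_frame_equal(a[region]["train"].data,
                                          b[region]["train"].data)
            n_train = len(a[region]["train"])
            n_val = len(a[region]["validation"])
            assert n_train / (n_train + n_val) == pytest.approx(2 / 3, abs=0.03)

    def test_region_classes_not_mixed(self):
        path, neut = self._inputs(7)
        ds = assemble_datasets(path, neut, seed=0)
        assert set(ds["on-ss"]["train"].data["region_class"]) == {"on-ss"}
        assert set(ds["off-ss"]["validation"].data["region_class"]) == {"off-ss"}


class TestScreenFeatures:
    def _fm(self, xp, xn, region="on-ss"):
        df = pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(len(xp) + len(xn))],
            "region_class": region,
            "label": ["pathogenic"] * len(xp) + ["neutral"] * len(xn),
            "maf": np.nan, "min_distance": 1,
            "feat": np.concatenate([xp, xn]),
        })
        return FeatureMatrix(df, region)

    def test_small_sample_p_equals_exact_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n, m = int(rng.integers(3, 9)), int(rng.integers(3, 9))
            pool = rng.normal(size=n + m)
            xp, xn = pool[:n], pool[n:]
            res = screen_features(self._fm(xp, xn))
            # oracle: enumerate all label assignments of the pooled sample
            ranks = stats.rankdata(pool)
            u_obs = ranks[:n].sum() - n * (n + 1) / 2
            us = np.array([ranks[list(c)].sum() - n * (n + 1) / 2
                           for c in itertools.combinations(range(n + m), n)])
            stat = min(u_obs, n * m - u_obs)
            p_exact = np.mean(np.minimum(us, n * m - us) <= stat)
            assert res.loc[res["feature"] == "feat", "p_value"].iloc[0] == \
                pytest.approx(p_exact, abs=1e-12)

    def test_null_features_not_significant(self):
        rng = np.random.default_rng(1)
        xp, xn = rng.normal(size=300), rng.normal(size=300)
        res = screen_features(self._fm(xp, xn))
        row = res[res["feature"] == "feat"].iloc[0]
        assert row["q_value"] > 0.05
        assert abs(row["delta_median"]) < 0.3

    def test_constant_feature_flagged_p_one(self):
        res = screen_features(self._fm(np.ones(10), np.ones(10)))
        row = res[res["feature"] == "feat"].iloc[0]
        assert row["p_value"] == 1.0 and row["constant"]

    def test_rescaling_maps_extremes_to_unit_interval(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(40)],
            "region_class": "on-ss",
            "label": ["pathogenic"] * 20 + ["neutral"] * 20,
            "maf": np.nan, "min_distance": 1,
            "a": np.r_[rng.normal(5, 1, 20), rng.normal(0, 1, 20)],
            "b": np.r_[rng.normal(-5, 1, 20), rng.normal(0, 1, 20)],
            "c": rng.normal(size=40),
        })
        res = screen_features(FeatureMatrix(df, "on-ss"))
        r = res.set_index("feature")["delta_median_rescaled"]
        assert r.max() == pytest.approx(1.0)
        assert r.min() == pytest.approx(-1.0)
        assert r["a"] == 1.0 and r["b"] == -1.0

    def test_bh_adjustment_equals_brute_force(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "variant_id": [f"v{i}" for i in range(60)],
            "region_class": "on-ss",
            "label": ["pathogenic"] * 30 + ["neutral"] * 30,
            "maf": np.nan, "min_distance": 1,
        })
        for j in range(8):
            df[f"f{j}"] = np.r_[rng.normal(j * 0.2, 1, 30), rng.normal(0, 1, 30)]
        res = screen_features(FeatureMatrix(df, "on-ss"))
        p = res["p_value"].to_numpy()
        n = len(p)
        order = np.argsort(p)
        q_brute = np.empty(n)
        running = 1.0
        for rank in range(n - 1, -1, -1):
            i = order[rank]
            running = min(running, p[i] * n / (rank + 1))
            q_brute[i] = running
        np.testing.assert_allclose(res["q_value"].to_numpy(), q_brute,
                                   atol=1e-12)


def _labeled_fm(rng, n=120, sep=3.0, region="on-ss"):
    y = np.r_[np.ones(n // 2, dtype=int), np.zeros(n // 2, dtype=int)]
    df = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(n)],
        "region_class": region,
        "label": np.where(y == 1, "pathogenic", "neutral"),
        "maf": np.nan, "min_distance": 1,
        "f1": rng.normal(loc=sep * y, scale=1.0),
        "f2": rng.normal(size=n),
    })
    return FeatureMatrix(df, region)


class TestTrainPredict:
    def test_separable_data_trains_to_perfect_auroc(self):
        rng = np.random.default_rng(0)
        fm = _labeled_fm(rng, sep=8.0)
        est = train(fm, seed=0, n_estimators_grid=(50,), max_depth_grid=(5,))
        probs = est.decision_function(fm.X)
        assert evaluate(fm.y, probs)["auroc"] == 1.0

    def test_single_grid_point_selected(self):
        rng = np.random.default_rng(1)
        fm = _labeled_fm(rng)
        est = train(fm, seed=0, n_estimators_grid=(42,), max_depth_grid=(7,))
        assert est.best_params_ == {"n_estimators": 42, "max_depth": 7}

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(2)
        fm = _labeled_fm(rng, sep=1.0)
        a = train(fm, seed=3, n_estimators_grid=(25, 50), max_depth_grid=(5, 10))
        b = train(FeatureMatrix(fm.data.copy(), fm.region_class), seed=3,
                  n_estimators_grid=(25, 50), max_depth_grid=(5, 10))
        assert a.best_params_ == b.best_params_
        np.testing.assert_array_equal(a.decision_function(fm.X),
                                      b.decision_function(fm.X))

    def test_single_class_training_errors(self):
        rng = np.random.default_rng(3)
        fm = _labeled_fm(rng)
        one = FeatureMatrix(fm.data[fm.data["label"] == "neutral"], "on-ss")
        with pytest.raises(ValueError):
            train(one, seed=0, n_estimators_grid=(25,), max_depth_grid=(5,))

    def test_unknown_and_missing_columns_error_by_name(self):
        rng = np.random.default_rng(4)
        fm = _labeled_fm(rng)
        est = train(fm, seed=0, n_estimators_grid=(25,), max_depth_grid=(5,))
        bad = fm.X.rename(columns={"f2": "mystery"})
        with pytest.raises(ValueError, match="mystery"):
            est.decision_function(bad)

    def test_median_imputation_of_absent_values(self):
        rng = np.random.default_rng(5)
        fm = _labeled_fm(rng, sep=5.0)
        est = train(fm, seed=0, n_estimators_grid=(25,), max_depth_grid=(5,))
        X = fm.X.copy()
        X.loc[X.index[:3], "f2"] = np.nan
        probs = est.decision_function(X)
        assert np.isfinite(probs).all()


class TestCalibration:
    def _trained(self, seed=0):
        rng = np.random.default_rng(seed)
        fm = _labeled_fm(rng, n=200, sep=2.0)
        est = train(fm, seed=0, n_estimators_grid=(50,), max_depth_grid=(5,))
        val = _labeled_fm(np.random.default_rng(seed + 1), n=200, sep=2.0)
        calibrate_fpr(est, val)
        return est, val

    def test_table_matches_brute_force_counting(self):
        est, val = self._trained()
        probs = est.decision_function(val.X)
        neutral = probs[val.y == 0]
        for t, fpr in est.calibration_table_.itertuples(index=False):
            assert fpr == pytest.approx((neutral >= t).mean())

    def test_extreme_thresholds(self):
        est, val = self._trained(1)
        neutral_max = est.calibration_neutral_probs_.max()
        assert est.fpr_of(np.array([neutral_max + 1e-9]))[0] == 0.0
        assert est.fpr_of(np.array([0.0]))[0] == 1.0

    def test_monotone_lookup(self):
        est, _ = self._trained(2)
        grid = np.linspace(0, 1, 101)
        fpr = est.fpr_of(grid)
        assert np.all(np.diff(fpr) <= 0)

    def test_categories_follow_fpr_cutpoints(self):
        est, _ = self._trained(3)
        cats = est.categorize(np.array([0.03, 0.05, 0.07, 0.10, 0.50]))
        assert list(cats) == ["Damaging", "Possibly Damaging",
                              "Possibly Damaging", "Benign", "Benign"]

    def test_cross_region_prediction_is_hard_error(self):
        est, val = self._trained(4)
        other = FeatureMatrix(val.data.assign(region_class="off-ss"), "off-ss")
        with pytest.raises(ValueError, match="off-ss"):
            est.predict_records(other)

    def test_no_neutrals_errors(self):
        est, val = self._trained(5)
        pos_only = val.data[val.data["label"] == "pathogenic"]
        with pytest.raises(ValueError):
            est.calibrate(FeatureMatrix(pos_only, "on-ss").X,
                          FeatureMatrix(pos_only, "on-ss").y)


class TestEvaluate:
    def test_perfect_ranking(self):
        y = np.array([1, 1, 0, 0])
        p = np.array([0.9, 0.8, 0.2, 0.1])
        m = evaluate(y, p)
        assert m["auroc"] == 1.0 and m["mcc"] == 1.0

    def test_auroc_equals_pairwise_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = rng.integers(0, 2, size=40)
            if len(np.unique(y)) < 2:
                continue
            p = rng.uniform(size=40)
            m = evaluate(y, p)
            pos, neg = p[y == 1], p[y == 0]
            wins = sum((a > b) + 0.5 * (a == b)
                       for a in pos for b in neg)
            assert m["auroc"] == pytest.approx(wins / (len(pos) * len(neg)))

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(1)
        aucs = []
        for _ in range(50):
            y = np.r_[np.ones(30, int), np.zeros(30, int)]
            p = rng.uniform(size=60)
            aucs.append(evaluate(y, p)["auroc"])
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            evaluate(np.ones(5, int), np.random.uniform(size=5))


def test_model_roundtrip_serialization(tmp_path):
    rng = np.random.default_rng(9)
    fm = _labeled_fm(rng, n=100, sep=2.0)
    est = train(fm, seed=0, n_estimators_grid=(25,), max_depth_grid=(5,))
    calibrate_fpr(est, fm)
    mod.save_model(est, tmp_path / "m")
    back = mod.load_model(tmp_path / "m")
    np.testing.assert_array_equal(est.decision_function(fm.X),
                                  back.decision_function(fm.X))
    np.testing.assert_array_equal(est.fpr_of(np.linspace(0, 1, 11)),
                                  back.fpr_of(np.linspace(0, 1, 11)))
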