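"""Random-forest model stage: extraction, tuning, CV, importance, mapping."""

import numpy as np
import pandas as pd
import pytest

from habitatrf.points import OccurrenceSet, PRESENCE, PSEUDO_ABSENCE
from habitatrf.raster import EnvironmentalStack, GridGeometry, RasterGrid
from habitatrf.sdm_model import (
    FeatureTable,
    balanced_fold_sample,
    extract_features,
    feature_importance,
    fit_final,
    fold_assignments,
    predict_class,
    predict_hsi,
    repeated_cv,
    tune_oob,
)


def make_table(n_pos=56, n_neg=440, n_features=5, seed=0, separable=False):
    """Synthetic feature table; optionally labels = threshold of feature 0."""
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    X = pd.DataFrame(
        rng.normal(0, 1, (n, n_features)),
        columns=[f"f{i}" for i in range(n_features)],
    )
    if separable:
        order = np.argsort(X["f0"].to_numpy())
        y = np.zeros(n, dtype=int)
        y[order[-n_pos:]] = 1  # top f0 values are presences
        X.loc[y == 1, "f0"] += 3.0  # wide margin: separable with room to spare
    else:
        y = np.array([1] * n_pos + [0] * n_neg)
    return FeatureTable(X, y)


class TestExtractFeatures:
    def _stack(self):
        geom = GridGeometry(0, 3, 1.0, 1.0, 3, 3)
        v = np.full((3, 3), 21.7)
        return EnvironmentalStack({"bio01": RasterGrid(v, geom)})

    def test_reads_cell_value_under_point(self):
        occ = OccurrenceSet.from_arrays([1.5], [1.5], PRESENCE)
        table = extract_features(self._stack(), occ)
        assert table.X.loc[0, "bio01"] == 21.7
        assert table.y[0] == 1

    def test_56_presences_and_440_absences_give_496_rows(self):
        geom = GridGeometry(0, 30, 1.0, 1.0, 30, 30)
        rng = np.random.default_rng(2)
        stack = EnvironmentalStack({"a": RasterGrid(rng.uniform(0, 1, (30, 30)), geom)})
        cells = rng.choice(900, size=496, replace=False)
        r, c = np.divmod(cells, 30)
        x, y = geom.cell_center(r, c)
        labels = np.array([PRESENCE] * 56 + [PSEUDO_ABSENCE] * 440, dtype=object)
        table = extract_features(stack, OccurrenceSet.from_arrays(x, y, labels))
        assert len(table) == 496
        assert table.y.sum() == 56
        assert table.n_dropped == 0

    def test_nodata_rows_dropped_and_counted(self):
        stack = self._stack()
        stack["bio01"].values[0, 0] = stack["bio01"].nodata
        occ = OccurrenceSet.from_arrays([0.5, 1.5], [2.5, 1.5], PRESENCE)
        table = extract_features(stack, occ)
        assert len(table) == 1 and table.n_dropped == 1

    def test_all_on_nodata_rejected(self):
        stack = self._stack()
        stack["bio01"].values[:] = stack["bio01"].nodata
        occ = OccurrenceSet.from_arrays([1.5], [1.5], PRESENCE)
        with pytest.raises(ValueError, match="nodata"):
            extract_features(stack, occ)

    def test_point_outside_extent_rejected(self):
        occ = OccurrenceSet.from_arrays([99.0], [1.5], PRESENCE)
        with pytest.raises(ValueError, match="outside"):
            extract_features(self._stack(), occ)


class TestTuneOOB:
    def test_grid_shape_and_best_attains_minimum(self):
        table = make_table(n_pos=40, n_neg=60, seed=1, separable=True)
        res = tune_oob(table, ntree_grid=(20, 50), mtry_grid=(1, 2, 3), seed=0)
        assert res.oob_error.shape == (2, 3)
        best_err = res.oob_error.loc[res.best[0], res.best[1]]
        assert best_err == res.oob_error.to_numpy().min()

    def test_tie_break_prefers_cheaper_model(self):
        # perfectly separable: many grid cells hit zero error; the
        # reported best must be the smallest ntree, then smallest mtry
        table = make_table(n_pos=50, n_neg=50, seed=3, separable=True)
        res = tune_oob(table, ntree_grid=(100, 200), mtry_grid=(2, 3), seed=0)
        zero_cells = [
            (nt, mt)
            for nt in (100, 200)
            for mt in (2, 3)
            if res.oob_error.loc[nt, mt] == res.oob_error.to_numpy().min()
        ]
        assert res.best == zero_cells[0]

    def test_label_independent_of_predictors_tracks_majority_error(self):
        # permutation oracle: with labels independent of X, OOB error
        # should sit near the minority-class rate
        rng = np.random.default_rng(4)
        n = 300
        X = pd.DataFrame(rng.normal(0, 1, (n, 4)), columns=list("abcd"))
        y = rng.permutation(np.array([1] * 90 + [0] * 210))
        table = FeatureTable(X, y)
        res = tune_oob(table, ntree_grid=(300,), mtry_grid=(2,), seed=0)
        err = res.oob_error.iloc[0, 0]
        p = 90 / 300
        se = np.sqrt(p * (1 - p) / n)
        assert abs(err - p) < 5 * se

    def test_mtry_exceeding_predictors_rejected(self):
        table = make_table(n_features=3)
        with pytest.raises(ValueError, match="exceed"):
            tune_oob(table, ntree_grid=(10,), mtry_grid=(5,), seed=0)

    def test_single_class_rejected(self):
        table = make_table(n_pos=20, n_neg=30)
        single = FeatureTable(table.X[table.y == 1], table.y[table.y == 1])
        with pytest.raises(ValueError, match="both classes"):
            tune_oob(single, ntree_grid=(10,), mtry_grid=(2,), seed=0)


class TestBalancedFoldSample:
    def test_matches_negative_count_with_replacement_for_positives(self):
        table = make_table(n_pos=56, n_neg=440)
        idx = balanced_fold_sample(table, seed=0)
        y = table.y[idx]
        neg_idx = idx[y == 0]
        pos_idx = idx[y == 1]
        assert len(neg_idx) == 440 and len(pos_idx) == 440
        assert len(np.unique(neg_idx)) == 440  # without replacement
        assert len(np.unique(pos_idx)) < 440  # repeats certain at 440 from 56

    def test_abundant_positives_drawn_without_repetition(self):
        table = make_table(n_pos=100, n_neg=50)
        idx = balanced_fold_sample(table, seed=0)
        pos_idx = idx[table.y[idx] == 1]
        assert len(pos_idx) == 50 == len(np.unique(pos_idx))

    def test_positive_inclusion_counts_match_multinomial_oracle(self):
        table = make_table(n_pos=56, n_neg=440)
        pos = np.flatnonzero(table.y == 1)
        counts = {i: 0 for i in pos}
        reps = 1000
        for s in range(reps):
            idx = balanced_fold_sample(table, seed=s)
            for i in idx[table.y[idx] == 1]:
                counts[i] += 1
        expected = reps * 440 / 56  # mean inclusion count per positive
        se = np.sqrt(reps * 440 * (1 / 56) * (1 - 1 / 56))
        for i in pos:
            assert abs(counts[i] - expected) < 5 * se


class TestRepeatedCV:
    def test_exactly_k_times_repeats_records(self):
        table = make_table(n_pos=30, n_neg=60, seed=5, separable=True)
        report = repeated_cv(table, ntree=30, mtry=2, k=5, repeats=10, seed=0)
        assert len(report.records) == 50
        assert sorted(report.records["repeat"].unique()) == list(range(1, 11))
        assert sorted(report.records["fold"].unique()) == list(range(1, 6))

    def test_every_record_validates_once_per_repeat(self):
        table = make_table(n_pos=30, n_neg=60)
        for rep in (1, 2, 3):
            folds = fold_assignments(table, k=5, repeat=rep, seed=0)
            vals = np.concatenate([va for _, va in folds])
            assert sorted(vals) == list(range(len(table)))

    def test_separable_problem_validates_perfectly(self):
        table = make_table(n_pos=40, n_neg=80, seed=6, separable=True)
        report = repeated_cv(table, ntree=50, mtry=2, k=5, repeats=2, seed=0)
        assert report.mean_val_acc_pct == 100.0

    def test_training_accuracy_bounds_validation(self):
        # overfitting direction, over 10 random-label replicates
        diffs = []
        for s in range(10):
            rng = np.random.default_rng(s)
            X = pd.DataFrame(rng.normal(0, 1, (120, 4)), columns=list("abcd"))
            y = rng.permutation(np.array([1] * 40 + [0] * 80))
            report = repeated_cv(FeatureTable(X, y), ntree=30, mtry=2, k=5, repeats=1, seed=s)
            diffs.append(report.mean_train_acc_pct - report.mean_val_acc_pct)
        assert np.mean(diffs) > 0

    def test_class_smaller_than_k_rejected(self):
        table = make_table(n_pos=3, n_neg=60)
        with pytest.raises(ValueError, match="class"):
            repeated_cv(table, ntree=10, mtry=2, k=5, repeats=1, seed=0)


class TestFeatureImportance:
    def test_constant_predictor_pruned_at_exact_zero(self):
        table = make_table(n_pos=40, n_neg=60, seed=7, separable=True)
        X = table.X.copy()
        X["const"] = 3.14
        table = FeatureTable(X, table.y)
        imp = feature_importance(table, seeds=(11, 17), ntree=50, mtry=2)
        assert imp.importances["const"] == 0.0
        assert imp.pruned == ["const"]

    def test_causal_layer_ranked_first_in_9_of_10_seeds(self):
        # label thresholds feature 0; nine noise features compete
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(0, 1, (200, 10)), columns=[f"f{i}" for i in range(10)])
        y = (X["f0"] > 0.2).astype(int).to_numpy()
        table = FeatureTable(X, y)
        firsts = 0
        for s in (11, 17, 22, 34, 54, 68, 96, 108, 224, 312):
            imp = feature_importance(table, seeds=(s,), ntree=100, mtry=3)
            firsts += imp.ranked().index[0] == "f0"
        assert firsts >= 9

    def test_seed_list_recorded(self):
        table = make_table(n_pos=20, n_neg=30, separable=True)
        imp = feature_importance(table, ntree=20, mtry=2)
        assert imp.seed_list == (11, 17, 22, 34, 54, 68, 96, 108, 224, 312)

    def test_empty_seed_list_rejected(self):
        table = make_table(n_pos=20, n_neg=30)
        with pytest.raises(ValueError, match="seed list"):
            feature_importance(table, seeds=(), ntree=10, mtry=2)


class TestFitPredict:
    def _separable_world(self):
        geom = GridGeometry(0, 20, 1.0, 1.0, 20, 20)
        jj, ii = np.meshgrid(np.arange(20), np.arange(20))
        driver = (jj < 10).astype(float)  # presence habitat: left half
        rng = np.random.default_rng(9)
        stack = EnvironmentalStack(
            {
                "driver": RasterGrid(driver + rng.normal(0, 0.01, (20, 20)), geom),
                "noise": RasterGrid(rng.uniform(0, 1, (20, 20)), geom),
            }
        )
        pres_cells = rng.choice(np.flatnonzero(driver.ravel()), 40, replace=False)
        abs_cells = rng.choice(np.flatnonzero(driver.ravel() == 0), 60, replace=False)
        r, c = np.divmod(np.concatenate([pres_cells, abs_cells]), 20)
        x, y = geom.cell_center(r, c)
        labels = np.array([PRESENCE] * 40 + [PSEUDO_ABSENCE] * 60, dtype=object)
        occ = OccurrenceSet.from_arrays(x, y, labels)
        return stack, extract_features(stack, occ), occ

    def test_binary_map_is_thresholded_hsi(self):
        stack, table, _ = self._separable_world()
        model = fit_final(table, ntree=50, mtry=1, seed=0)
        hsi = predict_hsi(model, stack)
        cls = predict_class(model, stack)
        np.testing.assert_array_equal(cls.values, (hsi.values >= 0.5).astype(float))
        assert hsi.valid_values.min() >= 0 and hsi.valid_values.max() <= 1

    def test_memorized_presence_region_scores_high(self):
        stack, table, occ = self._separable_world()
        model = fit_final(table, ntree=100, mtry=1, seed=0)
        hsi = predict_hsi(model, stack)
        at_presences = hsi.sample(occ.lon[:40], occ.lat[:40])
        assert (at_presences >= 0.9).all()

    def test_missing_layer_named(self):
        stack, table, _ = self._separable_world()
        model = fit_final(table, ntree=10, mtry=1, seed=0)
        with pytest.raises(KeyError, match="noise"):
            predict_hsi(model, stack.subset(["driver"]))

    def test_pruned_layer_cannot_influence_predictions(self):
        stack, table, _ = self._separable_world()
        X = table.X.copy()
        X["const"] = 1.0
        table2 = FeatureTable(X, table.y)
        imp = feature_importance(table2, seeds=(11, 17), ntree=30, mtry=2)
        assert "const" in imp.pruned
        kept = table2.drop_layers(imp.pruned)
        model = fit_final(kept, ntree=30, mtry=2, seed=0)
        geom = stack.geometry
        stack.add("const", RasterGrid(np.ones(geom.shape), geom))
        hsi1 = predict_hsi(model, stack)
        # perturbing the pruned layer's raster leaves predictions bit-identical
        stack["const"].values[:] = 42.0
        hsi2 = predict_hsi(model, stack)
        np.testing.assert_array_equal(hsi1.values, hsi2.values)

    def test_deterministic_given_seed(self):
        stack, table, _ = self._separable_world()
        h1 = predict_hsi(fit_final(table, ntree=30, mtry=1, seed=5), stack)
        h2 = predict_hsi(fit_final(table, ntree=30, mtry=1, seed=5), stack)
        np.testing.assert_array_equal(h1.values, h2.values)
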