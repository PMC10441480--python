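import numpy as np
import pytest

from protscreen.aa_encoding import PropertyDictionary, PropertyScale, random_scales
from protscreen.ensemble import (
    DEFAULT_FAMILIES,
    NEIGHBOR_FAMILY,
    NETWORK_FAMILY,
    TREE_FAMILY,
    ContributorModel,
    StackedEnsemble,
    SweepCache,
    SweepResult,
    build_stacked_ensemble,
    enumerate_sweep_jobs,
    evaluate,
    predict_ensemble,
    predictions_to_frame,
    rank_scales,
    run_property_sweep,
    select_features,
    tune_and_fit,
)
from protscreen.library_io import AMINO_ACIDS, deduplicate_average, split_train_test
from protscreen.simulate import SyntheticLibraryConfig, simulate_library

SMALL_GRIDS = {
    TREE_FAMILY: {"n_estimators": [30], "max_depth": [None]},
    NEIGHBOR_FAMILY: {"n_neighbors": [2, 5], "weights": ["uniform", "distance"]},
    NETWORK_FAMILY: {"hidden_layer_sizes": [(16,)], "alpha": [1e-3]},
}


def brute_force_f_scores(X, y):
    """Univariate regression F-statistic, from the definition."""
    n = len(y)
    out = []
    for j in range(X.shape[1]):
        x = X[:, j]
        if np.std(x) == 0:
            out.append(-np.inf)
            continue
        r = np.corrcoef(x, y)[0, 1]
        out.append(r**2 / (1 - r**2) * (n - 2) if abs(r) < 1 else np.inf)
    return np.array(out)


@pytest.fixture(scope="module")
def small_sim(dict10):
    cfg = SyntheticLibraryConfig(
        true_scale_id="KYTJ820101",
        n_variants=120,
        base_length=40,
        n_mutable_positions=12,
        effect_size=0.5,
        noise_sd=0.05,
        seed=3,
    )
    lib = deduplicate_average(simulate_library(cfg, dict10))
    split = split_train_test(lib, 0.8, 42)
    return lib, split


class TestEvaluate:
    def test_perfect_fit(self):
        r2, mse = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r2, mse) == (1.0, 0.0)

    def test_mean_predictor_scores_zero(self):
        truth = [1.0, 2.0, 3.0, 4.0]
        r2, _ = evaluate([2.5] * 4, truth)
        assert r2 == pytest.approx(0.0)

    def test_toy_hand_computation(self):
        # SS_res = 1, SS_tot = 2 -> R2 = 0.5; MSE = 1/3
        r2, mse = evaluate([1.0, 2.0, 4.0], [1.0, 2.0, 3.0])
        assert r2 == pytest.approx(0.5)
        assert mse == pytest.approx(1.0 / 3.0)

    def test_constant_truth_sentinel(self):
        r2, mse = evaluate([1.0, 2.0], [3.0, 3.0])
        assert np.isnan(r2)
        assert mse == pytest.approx(2.5)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate([1.0], [1.0, 2.0])


class TestSelectFeatures:
    def test_perfect_feature_wins(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=50)
        X = rng.normal(size=(50, 5))
        X[:, 3] = y
        assert select_features(X, y, 1) == (3,)

    def test_k_equals_d_orders_by_score(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=40)
        X = rng.normal(size=(40, 4))
        got = select_features(X, y, 4)
        expected = tuple(np.argsort(-brute_force_f_scores(X, y), kind="stable"))
        assert got == expected

    def test_top2_matches_brute_force(self):
        # 3-feature toy with hand-checkable F-scores
        rng = np.random.default_rng(2)
        n = 30
        y = rng.normal(size=n)
        X = np.column_stack([
            y + rng.normal(scale=0.1, size=n),   # strong
            y + rng.normal(scale=1.0, size=n),   # weak
            rng.normal(size=n),                   # noise
        ])
        scores = brute_force_f_scores(X, y)
        expected = tuple(np.argsort(-scores, kind="stable")[:2])
        assert select_features(X, y, 2) == expected

    def test_tie_breaks_to_lowest_index(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([x, x, x])
        assert select_features(X, y, 2) == (0, 1)

    def test_constant_columns_rank_last(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=20)
        X = np.column_stack([np.ones(20), y])
        assert select_features(X, y, 2) == (1, 0)

    def test_k_out_of_range(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        y = X[:, 0]
        with pytest.raises(ValueError):
            select_features(X, y, 4)

    def test_constant_target_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="constant target"):
            select_features(X, np.ones(10), 1)


class TestTuneAndFit:
    def _data(self, n=40, d=3, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, d))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(scale=0.05, size=n)
        return X[:30], y[:30], X[30:], y[30:]

    def test_single_grid_point_is_best(self):
        Xtr, ytr, Xte, yte = self._data()
        grid = {"n_neighbors": [3], "weights": ["uniform"]}
        _, params, r2, mse = tune_and_fit(NEIGHBOR_FAMILY, Xtr, ytr, Xte, yte, 0, grid)
        assert params == {"n_neighbors": 3, "weights": "uniform"}

    def test_exact_match_retrieval_one_neighbor(self):
        Xtr, ytr, _, _ = self._data()
        grid = {"n_neighbors": [1], "weights": ["uniform"]}
        est, _, _, _ = tune_and_fit(
            NEIGHBOR_FAMILY, Xtr, ytr, Xtr[:5], ytr[:5], 0, grid
        )
        assert est.predict(Xtr[:1])[0] == pytest.approx(ytr[0])

    def test_constant_target_predicts_constant(self):
        rng = np.random.default_rng(0)
        Xtr = rng.normal(size=(20, 3))
        ytr = np.full(20, 4.2)
        Xte = rng.normal(size=(5, 3))
        yte = np.full(5, 4.2)
        est, _, r2, mse = tune_and_fit(
            TREE_FAMILY, Xtr, ytr, Xte, yte, 0, {"n_estimators": [10], "max_depth": [None]}
        )
        assert np.allclose(est.predict(Xte), 4.2)
        assert np.isnan(r2)  # zero-variance truth sentinel

    def test_non_finite_target_rejected(self):
        Xtr, ytr, Xte, yte = self._data()
        ytr = ytr.copy()
        ytr[0] = np.nan
        with pytest.raises(ValueError):
            tune_and_fit(TREE_FAMILY, Xtr, ytr, Xte, yte, 0)

    def test_too_few_rows(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match=">= 10"):
            tune_and_fit(TREE_FAMILY, X, np.zeros(5), X, np.zeros(5), 0)

    def test_grid_exhaustive_picks_max_r2(self):
        Xtr, ytr, Xte, yte = self._data()
        grid = {"n_neighbors": [1, 3, 5, 10], "weights": ["uniform", "distance"]}
        _, best_params, best_r2, _ = tune_and_fit(NEIGHBOR_FAMILY, Xtr, ytr, Xte, yte, 0, grid)
        from protscreen.ensemble import make_estimator
        from sklearn.model_selection import ParameterGrid

        all_r2 = []
        for params in ParameterGrid(grid):
            est = make_estimator(NEIGHBOR_FAMILY, params, 0).fit(Xtr, ytr)
            all_r2.append(evaluate(est.predict(Xte), yte)[0])
        assert best_r2 == pytest.approx(max(all_r2))


class TestSweep:
    def test_result_count_and_pairs(self, small_sim, dict10):
        lib, split = small_sim
        sweep = run_property_sweep(
            lib, split, dict10, families=[NEIGHBOR_FAMILY], grids=SMALL_GRIDS, seed=0
        )
        assert len(sweep) == 10
        assert {r.scale_id for r in sweep} == {s.scale_id for s in dict10}

    def test_enumerate_jobs_554x3(self):
        scales = random_scales(554, seed=0)
        jobs = enumerate_sweep_jobs(PropertyDictionary(scales), DEFAULT_FAMILIES)
        assert len(jobs) == 1662

    def test_enumerate_jobs_fixture(self, dict10):
        assert len(enumerate_sweep_jobs(dict10, DEFAULT_FAMILIES)) == 30

    def test_cache_determinism_zero_refits(self, small_sim, dict10, tmp_path):
        lib, split = small_sim
        cache_path = tmp_path / "sweep.jsonl"
        kwargs = dict(families=[NEIGHBOR_FAMILY], grids=SMALL_GRIDS, seed=0)
        first = run_property_sweep(
            lib, split, dict10, cache=SweepCache(cache_path), **kwargs
        )
        # warm rerun must reproduce results byte-identically from cache
        before = cache_path.read_text()
        second = run_property_sweep(
            lib, split, dict10, cache=SweepCache(cache_path), **kwargs
        )
        assert cache_path.read_text() == before  # zero refits appended
        assert [r.to_dict() for r in first] == [r.to_dict() for r in second]

    def test_empty_dictionary(self, small_sim):
        lib, split = small_sim
        with pytest.raises(ValueError):
            run_property_sweep(lib, split, PropertyDictionary([]), seed=0)


class _ConstantEstimator:
    def __init__(self, value):
        self.value = value

    def predict(self, X):
        return np.full(X.shape[0], self.value)


def _constant_ensemble(values, dictionary):
    scale = dictionary.scales[0]
    contributors = [
        ContributorModel(
            family=TREE_FAMILY,
            scale_id=scale.scale_id,
            estimator=_ConstantEstimator(v),
            selected_features=(0,),
            best_params={},
            seed=0,
        )
        for v in values
    ]
    return StackedEnsemble(contributors=contributors, target_attribute="y", dictionary=dictionary)


class TestStackedEnsemble:
    def test_top5_times_3_is_15(self, small_sim, dict10):
        lib, split = small_sim
        sweep = run_property_sweep(
            lib, split, dict10, families=DEFAULT_FAMILIES, grids=SMALL_GRIDS, seed=0
        )
        ens = build_stacked_ensemble(sweep, lib, split, dict10, top_n=5, seed=0)
        assert len(ens) == 15

    def test_top1_one_family(self, small_sim, dict10):
        lib, split = small_sim
        sweep = run_property_sweep(
            lib, split, dict10, families=[NEIGHBOR_FAMILY], grids=SMALL_GRIDS, seed=0
        )
        ens = build_stacked_ensemble(sweep, lib, split, dict10, top_n=1, seed=0)
        assert len(ens) == 1

    def test_insufficient_scales(self, small_sim, dict10):
        lib, split = small_sim
        sweep = run_property_sweep(
            lib, split, dict10, families=[NEIGHBOR_FAMILY], grids=SMALL_GRIDS, seed=0
        )
        with pytest.raises(ValueError, match="need 11"):
            build_stacked_ensemble(sweep, lib, split, dict10, top_n=11, seed=0)

    def test_rank_tie_breaks_lexicographic(self):
        mk = lambda sid, r2: SweepResult(NEIGHBOR_FAMILY, sid, {}, r2, 0.1, (0,))
        sweep = [mk("BBB", 0.5), mk("AAA", 0.5), mk("CCC", 0.9)]
        ranked = rank_scales(sweep, NEIGHBOR_FAMILY)
        assert [r.scale_id for r in ranked] == ["CCC", "AAA", "BBB"]

    def test_nan_r2_excluded_from_ranking(self):
        mk = lambda sid, r2: SweepResult(NEIGHBOR_FAMILY, sid, {}, r2, 0.1, (0,))
        ranked = rank_scales([mk("A", float("nan")), mk("B", 0.2)], NEIGHBOR_FAMILY)
        assert [r.scale_id for r in ranked] == ["B"]


class TestPredictEnsemble:
    def test_all_constant_contributors(self, small_sim, dict10):
        lib, _ = small_sim
        ens = _constant_ensemble([2.0, 2.0, 2.0], dict10)
        recs = predict_ensemble(ens, lib)
        assert all(r.mean_prediction == pytest.approx(2.0) for r in recs)

    def test_mean_of_1_to_15_is_8(self, small_sim, dict10):
        lib, _ = small_sim
        ens = _constant_ensemble([float(i) for i in range(1, 16)], dict10)
        rec = predict_ensemble(ens, lib)[0]
        assert rec.mean_prediction == pytest.approx(8.0)
        assert len(rec.contributor_predictions) == 15

    def test_base_control_present(self, small_sim, dict10):
        lib, _ = small_sim
        ens = _constant_ensemble([1.0, 2.0], dict10)
        recs = predict_ensemble(ens, lib)
        assert "base" in {r.variant_id for r in recs}

    def test_mean_bounded_and_permutation_invariant(self, small_sim, dict10):
        lib, split = small_sim
        sweep = run_property_sweep(
            lib, split, dict10, families=[NEIGHBOR_FAMILY, TREE_FAMILY],
            grids=SMALL_GRIDS, seed=0,
        )
        ens = build_stacked_ensemble(sweep, lib, split, dict10, top_n=2, seed=0)
        recs = predict_ensemble(ens, lib.subset(split.test_ids))
        for r in recs:
            lo, hi = min(r.contributor_predictions), max(r.contributor_predictions)
            assert lo <= r.mean_prediction <= hi
            assert r.mean_prediction == pytest.approx(
                float(np.mean(r.contributor_predictions))
            )
        ens.contributors = ens.contributors[::-1]
        flipped = predict_ensemble(ens, lib.subset(split.test_ids))
        for a, b in zip(recs, flipped):
            assert a.mean_prediction == pytest.approx(b.mean_prediction)

    def test_length_mismatch_raises(self, small_sim, dict10, tiny_base):
        from protscreen.library_io import VariantLibrary, VariantRecord

        lib, _ = small_sim
        ens = _constant_ensemble([1.0], dict10)
        ens.sequence_length = len(lib.base)
        bad = VariantLibrary(
            base=tiny_base,
            records=[VariantRecord(id="x", mutations=(), sequence="ACDEF")],
            target_attribute="y",
        )
        with pytest.raises(ValueError, match="length"):
            predict_ensemble(ens, bad)

    def test_predictions_frame_layout(self, small_sim, dict10):
        lib, _ = small_sim
        ens = _constant_ensemble([1.0, 3.0], dict10)
        recs = predict_ensemble(ens, lib)
        df = predictions_to_frame(recs, ["c1", "c2"])
        assert list(df.columns) == ["id", "mean", "c1", "c2"]
        assert df["mean"].iloc[0] == pytest.approx(2.0)


class TestRecoveryProperties:
    """Synthetic parameter recovery on the shared session-scoped run."""

    def test_true_scale_ranks_first_in_at_least_two_families(self, recovery):
        hits = sum(
            1 for fam in DEFAULT_FAMILIES if recovery["rank1"][fam] == recovery["true_scale"]
        )
        assert hits >= 2

    def test_ensemble_test_r2_at_least_08(self, recovery):
        assert recovery["test_r2"] >= 0.8

    def test_large_noise_destroys_fit(self, dict10):
        # sanity ceiling: noise far above the signal cannot be fit
        cfg = SyntheticLibraryConfig(
            true_scale_id="KYTJ820101",
            n_variants=150,
            base_length=40,
            n_mutable_positions=12,
            effect_size=0.5,
            noise_sd=50.0,
            seed=5,
        )
        lib = deduplicate_average(simulate_library(cfg, dict10))
        split = split_train_test(lib, 0.8, 42)
        sweep = run_property_sweep(
            lib, split, dict10, families=[NEIGHBOR_FAMILY], grids=SMALL_GRIDS, seed=0
        )
        ens = build_stacked_ensemble(sweep, lib, split, dict10, top_n=5, seed=0)
        test_lib = lib.subset(split.test_ids)
        recs = predict_ensemble(ens, test_lib)
        r2, _ = evaluate([r.mean_prediction for r in recs], test_lib.target_values())
        assert r2 < 0.3
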