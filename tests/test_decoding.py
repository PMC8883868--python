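"""kNN decoding: grid rule, deterministic votes, permutation chance, group stats."""

import numpy as np
import pytest

from ci_attention.decoding import (
    DecodingConfig,
    DecodingResult,
    _folds,
    build_features,
    decode_subject,
    grid_search_k,
    group_stats,
    knn_predict,
    make_k_grid,
    permutation_decode,
    standardize,
)
from ci_attention.reconstruction import TrialSeries
from ci_attention.spectral import trial_psd


def brute_force_knn(train, labels, test, k):
    """Independent distance-sort oracle with the same tie-break contract."""
    preds = []
    for x in test:
        d = [(float(np.sqrt(((x - t) ** 2).sum())), i) for i, t in enumerate(train)]
        d.sort()  # distance first, then training index
        votes = [labels[i] for _, i in d[:k]]
        preds.append(1 if sum(v == 1 for v in votes) * 2 > k else 0)
    return np.array(preds)


class TestKGrid:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (488, list(range(1, 48, 2))),  # 24 candidates, 1..47
            (100, [1, 3, 5, 7, 9]),
            (20, [1]),
            (9, [1]),
        ],
    )
    def test_rule(self, n, expected):
        grid = make_k_grid(n)
        assert grid == expected

    def test_488_has_24_candidates(self):
        assert len(make_k_grid(488)) == 24


class TestStandardize:
    def test_population_and_sample_conventions(self):
        col = np.array([[1.0], [2.0], [3.0]])
        pop = standardize(col, "population")
        assert np.allclose(pop.ravel(), [-1.2247449, 0.0, 1.2247449])
        samp = standardize(col, "sample")
        assert np.allclose(samp.ravel(), [-1.0, 0.0, 1.0])

    def test_already_standardized_unchanged(self):
        x = np.array([[-1.0, 1.0], [1.0, -1.0]])
        assert np.allclose(standardize(x, "population"), x)

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError):
            standardize(np.ones((5, 2)))


class TestBuildFeatures:
    def _spectra(self, rng, n):
        out = []
        for i in range(n):
            s = TrialSeries(subject_id="T", trial_index=i, cue="", samples=rng.normal(size=65))
            out.append(trial_psd(s))
        return out

    @pytest.mark.parametrize("foi,n_cols", [("theta", 4), ("alpha", 5), ("beta", 11), ("broadband", 22)])
    def test_band_column_counts(self, rng, foi, n_cols):
        spectra = self._spectra(rng, 6)
        X, y = build_features(spectra, ["auditory", "visual"] * 3, foi)
        assert X.shape == (6, n_cols)

    def test_labels_align_with_cues(self, rng):
        spectra = self._spectra(rng, 6)
        cues = ["auditory", "visual", "visual", "auditory", "visual", "auditory"]
        _, y = build_features(spectra, cues, "theta")
        assert y.tolist() == [1, 0, 0, 1, 0, 1]


class TestKNNPredict:
    def test_exact_training_point_returns_its_label(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array([0, 1] * 5)
        assert knn_predict(X, y, X[[4]], 1)[0] == y[4]

    def test_k_equal_n_train_gives_majority_class(self, rng):
        X = rng.normal(size=(9, 2))
        y = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0])
        preds = knn_predict(X, y, rng.normal(size=(20, 2)), 9)
        assert np.all(preds == 1)

    def test_even_k_rejected(self, rng):
        with pytest.raises(ValueError):
            knn_predict(rng.normal(size=(6, 2)), np.array([0, 1] * 3), rng.normal(size=(2, 2)), 2)

    def test_k_exceeding_train_rejected(self, rng):
        with pytest.raises(ValueError):
            knn_predict(rng.normal(size=(4, 2)), np.array([0, 1, 0, 1]), rng.normal(size=(2, 2)), 5)

    @pytest.mark.parametrize("k", [1, 3, 5, 7])
    def test_matches_brute_force_on_toy_sets(self, rng, k):
        for _ in range(5):
            X = rng.normal(size=(rng.integers(8, 30), 4))
            y = (rng.random(len(X)) < 0.5).astype(int)
            if min((y == 0).sum(), (y == 1).sum()) == 0 or k > len(X):
                continue
            test = rng.normal(size=(12, 4))
            assert np.array_equal(knn_predict(X, y, test, k), brute_force_knn(X, y, test, k))

    def test_distance_ties_take_lowest_training_index(self):
        # two training points equidistant from the test point, opposite labels
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [5.0, 5.0]])
        y = np.array([1, 0, 0])
        assert knn_predict(X, y, np.array([[0.0, 0.0]]), 1)[0] == 1
        assert knn_predict(X[[1, 0, 2]], y[[1, 0, 2]], np.array([[0.0, 0.0]]), 1)[0] == 0

    def test_matches_sklearn_without_ties(self, rng):
        from sklearn.neighbors import KNeighborsClassifier

        X = rng.normal(size=(40, 5))
        y = (rng.random(40) < 0.5).astype(int)
        test = rng.normal(size=(15, 5))
        for k in (1, 3, 7):
            clf = KNeighborsClassifier(n_neighbors=k).fit(X, y)
            assert np.array_equal(knn_predict(X, y, test, k), clf.predict(test))


class TestGridSearch:
    def test_perfect_separation_scores_one(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(20, 2)), rng.normal(10, 0.1, size=(20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        best_k, score = grid_search_k(X, y, config=DecodingConfig(seed=1))
        assert score == 1.0

    def test_tie_takes_smallest_k(self, rng):
        # features carry no label information and CV scores tie exactly when
        # every candidate k yields identical predictions; engineered by a
        # single informative-free dimension with k-independent neighbourhoods
        X = np.array([[0.0], [1.0], [2.0], [3.0], [10.0], [11.0], [12.0], [13.0]])
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        cfg = DecodingConfig(seed=0)
        best_k, score = grid_search_k(X, y, grid=[1, 3], config=cfg)
        assert score == 1.0 and best_k == 1  # both k perfect -> smallest wins

    def test_selected_k_matches_exhaustive_evaluation(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array([0, 1] * 6)
        cfg = DecodingConfig(seed=42)
        grid = [1, 3, 5]
        best_k, best_score = grid_search_k(X, y, grid=grid, config=cfg)
        # brute-force oracle using knn_predict over the same folds
        from ci_attention._rng import STAGE_DECODE_FOLDS, child_int

        folds = _folds(y, 2, True, child_int(cfg.seed, STAGE_DECODE_FOLDS))
        scores = []
        for k in grid:
            accs = []
            for tr, te in folds:
                pred = knn_predict(X[tr], y[tr], X[te], k)
                accs.append((pred == y[te]).mean())
            scores.append(np.mean(accs))
        assert best_score == pytest.approx(max(scores))
        assert best_k == grid[int(np.argmax(scores))]

    def test_undersized_class_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array([1, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            grid_search_k(X, y, config=DecodingConfig(seed=0))


class TestPermutationDecode:
    def test_perfectly_separable_gives_min_p(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(20, 2)), rng.normal(50, 0.1, size=(20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        res = permutation_decode(X, y, 1, config=DecodingConfig(n_permutations=1000, seed=2))
        assert res.observed_accuracy == 1.0
        assert res.p_value == pytest.approx(1 / 1001)

    def test_chance_level_near_half_for_null_features(self, rng):
        X = rng.normal(size=(100, 4))
        y = np.array([0, 1] * 50)
        res = permutation_decode(X, y, 3, config=DecodingConfig(n_permutations=300, seed=3))
        assert res.chance_level == pytest.approx(0.5, abs=0.02)
        assert res.chance_level == pytest.approx(res.permutation_scores.mean())

    def test_determinism_under_fixed_seed(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.array([0, 1] * 20)
        cfg = DecodingConfig(n_permutations=50, seed=11)
        r1 = permutation_decode(X, y, 3, config=cfg)
        r2 = permutation_decode(X, y, 3, config=cfg)
        assert r1.observed_accuracy == r2.observed_accuracy
        assert np.array_equal(r1.permutation_scores, r2.permutation_scores)

    def test_even_best_k_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_decode(rng.normal(size=(10, 2)), np.array([0, 1] * 5), 2)


class TestGroupStats:
    def _results(self, obs_offset, noise, rng, n_sub=16):
        out = []
        for s in range(n_sub):
            for foi in ("broadband", "theta", "alpha", "beta"):
                chance = 0.5 + rng.normal(0, noise)
                out.append(
                    DecodingResult(
                        subject_id=f"S{s:02d}",
                        foi=foi,
                        best_k=3,
                        observed_accuracy=chance + obs_offset + rng.normal(0, noise),
                        permutation_scores=np.array([chance]),
                        chance_level=chance,
                        p_value=0.2,
                    )
                )
        return out

    def test_identical_observed_and_chance_give_zero_t(self, rng):
        res = self._results(0.0, 0.0, rng)
        stats_out = group_stats(res)
        assert all(v["t"] == 0.0 for v in stats_out.per_foi_t.values())

    def test_constant_offset_loads_on_type_main_effect(self, rng):
        stats_out = group_stats(self._results(0.03, 0.005, rng))
        anova = stats_out.anova.set_index("Source")
        assert anova.loc["type", "F"] > anova.loc["foi", "F"]
        assert anova.loc["type", "F"] > anova.loc["foi * type", "F"]
        assert anova.loc["type", "np2"] > 0.5

    def test_anova_degrees_of_freedom_for_16_subjects(self, rng):
        stats_out = group_stats(self._results(0.02, 0.01, rng))
        anova = stats_out.anova.set_index("Source")
        assert (anova.loc["foi", "ddof1"], anova.loc["foi", "ddof2"]) == (3, 45)
        assert (anova.loc["type", "ddof1"], anova.loc["type", "ddof2"]) == (1, 15)
        assert (anova.loc["foi * type", "ddof1"], anova.loc["foi * type", "ddof2"]) == (3, 45)
        assert all(v["df"] == 15 for v in stats_out.per_foi_t.values())

    def test_counts_subjects_with_significant_decoding(self, rng):
        res = self._results(0.02, 0.01, rng)
        for r in res[:8]:  # first two subjects' results
            r.p_value = 0.01
        assert group_stats(res).n_subjects_significant == 2

    def test_incomplete_table_rejected(self, rng):
        res = self._results(0.02, 0.01, rng)[:-1]
        with pytest.raises(ValueError):
            group_stats(res)


class TestEndToEndSubject:
    def test_decode_subject_runs_on_simulated_trials(self):
        from conftest import small_config, subject_spectra
        from ci_attention.synthetic_session import EffectSpec

        _, spectra, cues = subject_spectra(small_config(seed=5, trials_per_block=20), EffectSpec())
        res = decode_subject(spectra, cues, config=DecodingConfig(n_permutations=30, seed=1))
        assert 0.0 <= res.observed_accuracy <= 1.0
        assert res.best_k in make_k_grid(len(cues))
        assert len(res.permutation_scores) == 30
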