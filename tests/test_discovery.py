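import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from protpanel import (
    ProteinMatrix,
    SampleMetadata,
    auc_ci,
    build_panel_classifier,
    evaluate_on_modality,
    log2_and_standardize,
    permutation_pvalue,
    roc_auc,
    sa_rank_proteins,
    small_config,
    sweep_panel_sizes,
)
from protpanel.discovery import (
    DiscoveryError,
    RankedProteins,
    cv_folds,
    subset_fitness,
)
from protpanel.synth import generate_cohort


class TestRocAuc:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], 1.0),        # perfect ranking
        ([0.5, 0.5, 0.5, 0.5], [0, 1, 0, 1], 0.5),        # all-tied convention
        ([0.6, 0.4, 0.2, 0.9], [0, 1, 0, 1], 0.75),       # 3 of 4 pairs concordant
        ([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1], 0.0),        # perfectly inverted
    ])
    def test_known_values(self, scores, labels, expected):
        assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_matches_pairwise_enumeration(self, rng):
        # oracle: count concordant / tied case-control pairs directly
        for _ in range(20):
            n = int(rng.integers(6, 20))
            scores = rng.choice(np.linspace(0, 1, 7), size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            cases = scores[labels == 1]
            controls = scores[labels == 0]
            conc = sum(
                1.0 if c > d else 0.5 if c == d else 0.0
                for c in cases for d in controls
            )
            expected = conc / (len(cases) * len(controls))
            assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_monotone_transform(self, rng):
        scores = rng.normal(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        a1 = roc_auc(scores, labels)
        a2 = roc_auc(np.exp(3 * scores) + 7, labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DiscoveryError):
            roc_auc([0.1, 0.9], [1, 1])


class TestPermutationP:
    def test_floor_at_add_one_estimator(self, rng):
        # clearly separated scores: no permutation can beat the observed
        # AUC, so p hits the estimator floor 1/(B+1)
        scores = np.concatenate([np.zeros(20), np.ones(20)])
        labels = np.concatenate([np.zeros(20, int), np.ones(20, int)])
        assert permutation_pvalue(scores, labels, 9999, seed=0) == pytest.approx(1e-4)
        assert permutation_pvalue(labels.astype(float), labels, 99, seed=0) == pytest.approx(0.01)

    def test_null_rejection_rate_calibrated(self):
        # pre-permuted labels: the permutation p must be ~uniform, so the
        # rejection rate at alpha = 0.05 stays within [0.02, 0.09]
        rng = np.random.default_rng(42)
        rejections = 0
        reps = 200
        for i in range(reps):
            scores = rng.normal(0, 1, 40)
            labels = np.array([0] * 20 + [1] * 20)
            rng.shuffle(labels)
            p = permutation_pvalue(scores, labels, 999, seed=i)
            rejections += p <= 0.05
        assert 0.02 <= rejections / reps <= 0.09


class TestAucCI:
    def test_separated_sample_concentrates_near_one(self, rng):
        scores = np.concatenate([rng.normal(0, 0.1, 100), rng.normal(5, 0.1, 100)])
        labels = np.array([0] * 100 + [1] * 100)
        lo, hi = auc_ci(scores, labels, 500, seed=0)
        assert lo > 0.95 and hi <= 1.0

    def test_single_bootstrap_degenerates(self, rng):
        scores = rng.normal(0, 1, 30)
        labels = np.array([0, 1] * 15)
        lo, hi = auc_ci(scores, labels, 1, seed=0)
        assert lo == hi

    def test_coverage_of_analytic_auc(self):
        # two Gaussians: true AUC = Phi(delta / sqrt(2)); interval
        # coverage over repeated draws should be near 95%
        from scipy.stats import norm

        rng = np.random.default_rng(7)
        delta = 1.0
        true_auc = norm.cdf(delta / np.sqrt(2))
        covered = 0
        reps = 200
        for i in range(reps):
            controls = rng.normal(0, 1, 60)
            cases = rng.normal(delta, 1, 60)
            scores = np.concatenate([controls, cases])
            labels = np.array([0] * 60 + [1] * 60)
            lo, hi = auc_ci(scores, labels, 300, seed=i)
            covered += lo <= true_auc <= hi
        assert abs(covered / reps - 0.95) < 0.05


class TestSubsetFitness:
    def test_matches_independent_logistic_on_same_folds(self):
        # oracle: statsmodels logistic per fold + explicit out-of-fold
        # log-likelihood bookkeeping
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 120
        X = rng.normal(0, 1, (n, 5))
        y = (rng.random(n) < expit(0.8 * X[:, 0] - 0.5 * X[:, 2])).astype(int)
        folds = cv_folds(y, 5, seed=1)
        cols = np.array([0, 2, 4])
        oof = np.empty(n)
        for train, test in folds:
            Xtr = sm.add_constant(X[train][:, cols])
            fit = sm.GLM(y[train], Xtr, family=sm.families.Binomial()).fit(tol=1e-12)
            oof[test] = fit.predict(sm.add_constant(X[test][:, cols]))
        expected = np.mean(
            y * np.log(oof + 1e-12) + (1 - y) * np.log(1 - oof + 1e-12)
        )
        got = subset_fitness(X, y, cols, folds, metric="deviance")
        assert got == pytest.approx(expected, abs=1e-8)

        from protpanel.discovery import _oof_probabilities

        got_auc = subset_fitness(X, y, cols, folds, metric="auc")
        assert got_auc == pytest.approx(roc_auc(oof, y), abs=1e-10)


@pytest.fixture(scope="module")
def separable_cohort():
    """1 perfectly separating protein + 10 noise proteins, n = 100."""
    rng = np.random.default_rng(0)
    n = 100
    y = np.array([1] * 50 + [0] * 50)
    X = rng.normal(0, 1, (n, 11))
    X[:, 5] = y * 4.0 + rng.normal(0, 0.1, n)  # protein "P05" separates
    ids = [f"S{i}" for i in range(n)]
    proteins = [f"P{j:02d}" for j in range(11)]
    matrix = ProteinMatrix(
        pd.DataFrame(X, index=ids, columns=proteins), "standardized"
    )
    meta = SampleMetadata(pd.DataFrame({
        "sample_id": ids,
        "status": np.where(y == 1, "case", "control"),
    }))
    return matrix, meta


class TestSARanking:
    def test_dominant_protein_ranks_first(self, separable_cohort):
        matrix, meta = separable_cohort
        ranked = sa_rank_proteins(matrix, meta, n_iterations=300, seed=0,
                                  size_range=(2, 8))
        assert ranked.top(1) == ["P05"]
        assert ranked.table.iloc[0]["rank"] == 1

    def test_deterministic_under_seed(self, separable_cohort):
        matrix, meta = separable_cohort
        r1 = sa_rank_proteins(matrix, meta, n_iterations=100, seed=3,
                              size_range=(2, 8))
        r2 = sa_rank_proteins(matrix, meta, n_iterations=100, seed=3,
                              size_range=(2, 8))
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_rank_is_dense_permutation_with_ties(self, separable_cohort):
        matrix, meta = separable_cohort
        ranked = sa_rank_proteins(matrix, meta, n_iterations=100, seed=1,
                                  size_range=(2, 8))
        t = ranked.table
        assert (t.selection_count <= ranked.n_iterations).all()
        ranks = t["rank"].to_numpy()
        assert ranks.min() == 1
        assert set(ranks) == set(range(1, ranks.max() + 1))
        # counts strictly decrease across rank levels
        by_rank = t.groupby("rank")["selection_count"].first()
        assert (np.diff(by_rank.to_numpy()) < 0).all()

    def test_bad_arguments_rejected(self, separable_cohort):
        matrix, meta = separable_cohort
        with pytest.raises(DiscoveryError):
            sa_rank_proteins(matrix, meta, n_iterations=0)


class TestPanels:
    def test_separating_panel_reaches_perfect_training_accuracy(self, separable_cohort):
        matrix, meta = separable_cohort
        ranked = sa_rank_proteins(matrix, meta, n_iterations=200, seed=0,
                                  size_range=(2, 8))
        clf = build_panel_classifier(matrix, meta, ranked, N=1,
                                     rf_params={"n_estimators": 100}, seed=0)
        assert clf.members == ["P05"]
        assert clf.train_accuracy == 1.0

    def test_full_panel_equals_whole_matrix(self, separable_cohort):
        matrix, meta = separable_cohort
        ranked = sa_rank_proteins(matrix, meta, n_iterations=100, seed=0,
                                  size_range=(2, 8))
        clf = build_panel_classifier(matrix, meta, ranked, N=11,
                                     rf_params={"n_estimators": 50}, seed=0)
        assert sorted(clf.members) == sorted(matrix.protein_ids)

    def test_same_seed_reproduces_probabilities(self, separable_cohort):
        matrix, meta = separable_cohort
        ranked = sa_rank_proteins(matrix, meta, n_iterations=100, seed=0,
                                  size_range=(2, 8))
        kw = dict(rf_params={"n_estimators": 50}, seed=9)
        c1 = build_panel_classifier(matrix, meta, ranked, 3, **kw)
        c2 = build_panel_classifier(matrix, meta, ranked, 3, **kw)
        s1, _ = evaluate_on_modality(c1, matrix)
        s2, _ = evaluate_on_modality(c2, matrix)
        pd.testing.assert_series_equal(s1, s2)

    def test_sweep_length_and_rebuild_consistency(self, separable_cohort):
        matrix, meta = separable_cohort
        ranked = sa_rank_proteins(matrix, meta, n_iterations=100, seed=0,
                                  size_range=(2, 8))
        panels = sweep_panel_sizes(matrix, meta, ranked, 2, 6,
                                   rf_params={"n_estimators": 50}, seed=4)
        assert [c.N for c in panels] == [2, 3, 4, 5, 6]
        rebuilt = build_panel_classifier(matrix, meta, ranked, 4,
                                         rf_params={"n_estimators": 50}, seed=4)
        assert panels[2].train_accuracy == rebuilt.train_accuracy
        assert panels[2].members == rebuilt.members

    def test_single_size_sweep(self, separable_cohort):
        matrix, meta = separable_cohort
        ranked = sa_rank_proteins(matrix, meta, n_iterations=50, seed=0,
                                  size_range=(2, 8))
        panels = sweep_panel_sizes(matrix, meta, ranked, 5, 5,
                                   rf_params={"n_estimators": 20}, seed=0)
        assert len(panels) == 1 and panels[0].N == 5


class TestEvaluate:
    def _clf(self, separable):
        matrix, meta = separable
        ranked = sa_rank_proteins(matrix, meta, n_iterations=100, seed=0,
                                  size_range=(2, 8))
        return matrix, meta, build_panel_classifier(
            matrix, meta, ranked, 5, rf_params={"n_estimators": 50}, seed=0)

    def test_training_set_reproduces_training_predictions(self, separable_cohort):
        matrix, meta, clf = self._clf(separable_cohort)
        scores, report = evaluate_on_modality(clf, matrix)
        expected = clf.model.predict_proba(
            matrix.values.loc[:, clf.members].to_numpy())[:, 1]
        np.testing.assert_allclose(scores.to_numpy(), expected)
        assert report["missing_proteins"] == []

    def test_missing_proteins_reported_and_scored(self, separable_cohort):
        matrix, meta, clf = self._clf(separable_cohort)
        keep = [p for p in matrix.protein_ids if p not in clf.members[:2]]
        sub = matrix.subset_proteins(keep)
        for policy in ("drop_and_refit", "impute_mean"):
            scores, report = evaluate_on_modality(clf, sub, missing=policy)
            assert sorted(report["missing_proteins"]) == sorted(clf.members[:2])
            assert len(scores) == matrix.n_samples
        with pytest.raises(DiscoveryError):
            evaluate_on_modality(clf, sub, missing="error")

    def test_label_permuted_test_set_near_chance(self, separable_cohort):
        matrix, meta, clf = self._clf(separable_cohort)
        scores, _ = evaluate_on_modality(clf, matrix)
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(20):
            y = meta.status_binary().to_numpy().copy()
            rng.shuffle(y)
            aucs.append(roc_auc(scores.to_numpy(), y))
        assert abs(np.mean(aucs) - 0.5) < 0.1
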