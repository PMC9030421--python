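"""Stepwise Wilks-lambda selection, LDA fitting, cross-validation and
unknown-group allocation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seedmorph as sm
from seedmorph.classify import AllocationTable, _fit_arrays
from seedmorph.morphometry import CSV_COLUMNS, FEATURE_NAMES
from conftest import gaussian_feature_table, wilks_oracle


def _table_from_matrix(X: np.ndarray, y, feature_count: int | None = None):
    """Wrap an (n, p) matrix into a FeatureTable, padding the remaining
    descriptor columns with constants (zero within-group variance, so they
    can never enter the model)."""
    n, p = X.shape
    rows = []
    for i in range(n):
        rows.append(
            {
                "specimen_id": f"s{i}",
                "class_label": y[i],
                **{FEATURE_NAMES[j]: X[i, j] for j in range(p)},
                **{FEATURE_NAMES[j]: 0.0 for j in range(p, len(FEATURE_NAMES))},
            }
        )
    return sm.FeatureTable(data=pd.DataFrame(rows, columns=CSV_COLUMNS))


class TestStepwiseSelect:
    def test_single_informative_feature_enters_first(self):
        """With one truly discriminating descriptor (Feret, delta = 5 sd)
        among 25 pure-noise columns, the first entry must be Feret — the
        same choice as an exhaustive single-feature F ranking."""
        rng = np.random.default_rng(0)
        rows = []
        j_feret = FEATURE_NAMES.index("Feret")
        for name, shift in [("A", 0.0), ("B", 5.0)]:
            X = rng.normal(0, 1, (50, 26))
            X[:, j_feret] += shift
            for i in range(50):
                rows.append({"specimen_id": f"{name}{i}", "class_label": name,
                             **{f: X[i, j] for j, f in enumerate(FEATURE_NAMES)}})
        table = sm.FeatureTable(data=pd.DataFrame(rows, columns=CSV_COLUMNS))
        selected, log = sm.stepwise_select(table)
        assert log[0]["action"] == "enter"
        assert log[0]["feature"] == "Feret"
        # oracle: Feret has the best single-feature Wilks lambda
        X = table.features.to_numpy()
        y = table.labels.to_numpy()
        lambdas = [wilks_oracle(X, y, [j]) for j in range(26)]
        assert int(np.argmin(lambdas)) == j_feret
        assert "Feret" in selected

    def test_duplicated_column_blocked_by_tolerance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (80, 3))
        X[40:, 0] += 4.0
        X[:, 1] = X[:, 0]  # exact copy
        y = ["A"] * 40 + ["B"] * 40
        table = _table_from_matrix(X, y)
        selected, _ = sm.stepwise_select(table)
        pair = {FEATURE_NAMES[0], FEATURE_NAMES[1]}
        assert len(pair & set(selected)) <= 1

    def test_saturated_threshold_gives_empty_model_error(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (40, 4))
        X[20:, 0] += 3.0
        table = _table_from_matrix(X, ["A"] * 20 + ["B"] * 20)
        with pytest.raises(sm.EmptyModelError):
            sm.stepwise_select(table, sm.StepwiseConfig(f_to_enter=1e9, f_to_remove=1e8))

    def test_matches_exhaustive_best_subset_on_small_instances(self):
        """On 50 seeded instances (<=6 features, <=3 classes, independent
        features with well-separated effects) the greedy selection equals
        the exhaustive Wilks-optimal subset of the same size."""
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(50):
            p = int(rng.integers(3, 7))
            g = int(rng.integers(2, 4))
            n = int(rng.integers(20, 31))
            n_eff = int(rng.integers(1, p))
            mags = np.array([2.4, 1.6, 1.0, 0.6, 0.4, 0.3])[:n_eff]
            feat_idx = rng.permutation(p)[:n_eff]
            X_parts, y = [], []
            for ci in range(g):
                X = rng.normal(0, 1, (n, p))
                for k, fi in enumerate(feat_idx):
                    X[:, fi] += ci * mags[k]
                X_parts.append(X)
                y += [f"c{ci}"] * n
            X = np.vstack(X_parts)
            table = _table_from_matrix(X, y)
            try:
                selected, _ = sm.stepwise_select(table)
            except sm.EmptyModelError:
                continue
            k = len(selected)
            yarr = np.asarray(y)
            best = min(
                itertools.combinations(range(p), k),
                key=lambda s: wilks_oracle(X, yarr, s),
            )
            got = tuple(sorted(FEATURE_NAMES.index(f) for f in selected))
            assert got == tuple(sorted(best))
            checked += 1
        assert checked >= 40  # nearly every instance admits a model

    def test_step_log_lambdas_match_independent_computation(self):
        table = gaussian_feature_table(np.random.default_rng(21), 40, 1.2)
        selected, log = sm.stepwise_select(table)
        X = table.features.to_numpy()
        y = table.labels.to_numpy()
        current: list[int] = []
        for entry in log:
            j = FEATURE_NAMES.index(entry["feature"])
            if entry["action"] == "enter":
                current.append(j)
            else:
                current.remove(j)
            assert entry["wilks"] == pytest.approx(
                wilks_oracle(X, y, current), rel=1e-8
            )


class TestFitLda:
    @staticmethod
    def _exact_1d_table():
        # class A: mean 0, class B: mean 4, pooled within-variance exactly 1
        c = math.sqrt(0.5)
        X = np.array([[-c], [c], [4 - c], [4 + c]])
        return _table_from_matrix(X, ["A", "A", "B", "B"])

    def test_decision_boundary_at_midpoint(self):
        model = sm.fit_lda(self._exact_1d_table(), [FEATURE_NAMES[0]])
        assert model.predict(np.array([[1.99]]))[0] == "A"
        assert model.predict(np.array([[2.01]]))[0] == "B"

    def test_posterior_closed_form(self):
        # N(0,1) vs N(4,1), equal priors: P(A | x=0) = 1/(1+exp(-8))
        model = sm.fit_lda(self._exact_1d_table(), [FEATURE_NAMES[0]])
        post = model.posteriors(np.array([[0.0]]))[0]
        assert post[model.class_labels.index("A")] == pytest.approx(
            1.0 / (1.0 + math.exp(-8.0)), abs=1e-9
        )
        assert post.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_within_variance_is_collinearity_error(self):
        X = np.array([[1.0, 0.5], [1.0, -0.5], [2.0, 3.5], [2.0, 4.5]])
        table = _table_from_matrix(X, ["A", "A", "B", "B"])
        with pytest.raises(sm.CollinearityError):
            sm.fit_lda(table, [FEATURE_NAMES[0]])

    def test_matches_sklearn_reference(self):
        """Class assignments and posteriors agree with the reference LDA
        implementation on a random 3-class problem."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(13)
        X = rng.normal(0, 1, (90, 4))
        X[30:60, 0] += 2.5
        X[60:, 1] += 2.5
        y = ["a"] * 30 + ["b"] * 30 + ["c"] * 30
        table = _table_from_matrix(X, y)
        model = sm.fit_lda(table, [FEATURE_NAMES[i] for i in range(4)])
        ref = LinearDiscriminantAnalysis(priors=[1 / 3] * 3, solver="svd")
        ref.fit(X, y)
        Xnew = rng.normal(0.5, 1.5, (40, 4))
        assert (model.predict(Xnew) == ref.predict(Xnew)).all()
        assert model.posteriors(Xnew) == pytest.approx(
            ref.predict_proba(Xnew), abs=1e-8
        )

    def test_json_round_trip(self, tmp_path):
        model = sm.fit_lda(self._exact_1d_table(), [FEATURE_NAMES[0]])
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = sm.DiscriminantModel.from_json(path)
        assert loaded.selected_features == model.selected_features
        assert loaded.class_labels == model.class_labels
        assert np.allclose(loaded.class_means, model.class_means)


class TestCrossValidate:
    def test_separated_classes_recovered(self):
        """Realized Mahalanobis separation >= 6 implies Bayes error below
        0.2%, so LOO accuracy must reach 95%."""
        rng = np.random.default_rng(42)
        table = gaussian_feature_table(rng, 100, 6.5 / math.sqrt(3))
        lab = table.labelled()
        X = lab.features.to_numpy()[:, :3]
        y = lab.labels.to_numpy()
        _, means, cov, _ = _fit_arrays(X, y, "equal")
        d = means[1] - means[0]
        realized = math.sqrt(float(d @ np.linalg.solve(cov, d)))
        assert realized >= 6.0  # precondition of the scenario
        cv = sm.cross_validate(table)
        assert cv.overall_correct >= 95.0

    def test_identical_distributions_score_at_chance(self):
        """Two classes drawn from the same distribution: LOO accuracy must
        land in the 95% binomial band around 50% (n=200)."""
        rng = np.random.default_rng(43)
        table = gaussian_feature_table(rng, 100, 0.0)
        cv = sm.cross_validate(table, features=list(FEATURE_NAMES))
        half_width = 196.0 * math.sqrt(0.25 / 200.0)  # 6.93 percentage points
        assert 50.0 - half_width <= cv.overall_correct <= 50.0 + half_width

    def test_point_masses_are_perfectly_classified(self):
        X = np.repeat(np.array([[0.0, 0.0], [10.0, 10.0]]), 20, axis=0)
        X += np.random.default_rng(3).normal(0, 1e-6, X.shape)
        table = _table_from_matrix(X, ["A"] * 20 + ["B"] * 20)
        cv = sm.cross_validate(table, features=[FEATURE_NAMES[0], FEATURE_NAMES[1]])
        assert cv.overall_correct == 100.0

    def test_loo_reproducible_bit_for_bit(self):
        table = gaussian_feature_table(np.random.default_rng(8), 30, 1.0)
        a = sm.cross_validate(table)
        b = sm.cross_validate(table)
        assert np.array_equal(a.counts, b.counts)
        assert a.overall_correct == b.overall_correct

    def test_kfold_reproducible_under_seed(self):
        table = gaussian_feature_table(np.random.default_rng(9), 30, 1.5)
        a = sm.cross_validate(table, scheme="kfold", k=5, seed=17)
        b = sm.cross_validate(table, scheme="kfold", k=5, seed=17)
        assert np.array_equal(a.counts, b.counts)

    def test_affine_rescaling_leaves_assignments_unchanged(self):
        """Selection F statistics and LDA assignments are invariant to
        per-descriptor affine rescaling, so a refit on rescaled data must
        reproduce the confusion table exactly."""
        rng = np.random.default_rng(10)
        table = gaussian_feature_table(rng, 40, 1.5)
        cv1 = sm.cross_validate(table)
        data = table.data.copy()
        scales = rng.uniform(0.1, 30.0, len(FEATURE_NAMES))
        offsets = rng.uniform(-5.0, 5.0, len(FEATURE_NAMES))
        data[FEATURE_NAMES] = data[FEATURE_NAMES] * scales + offsets
        cv2 = sm.cross_validate(sm.FeatureTable(data=data))
        assert np.array_equal(cv1.counts, cv2.counts)


class TestAllocation:
    @staticmethod
    def _three_class_model(rng):
        X = rng.normal(0, 1, (150, 3))
        X[50:100, 0] += 8.0
        X[100:, 1] += 8.0
        y = ["a"] * 50 + ["b"] * 50 + ["c"] * 50
        table = _table_from_matrix(X, y)
        model = sm.fit_lda(table, [FEATURE_NAMES[i] for i in range(3)])
        return model, table

    def test_cohort_from_one_class_mostly_allocated_there(self):
        rng = np.random.default_rng(20)
        model, _ = self._three_class_model(rng)
        Xu = rng.normal(0, 1, (70, 3))
        Xu[:, 0] += 8.0  # drawn from class b's fitted Gaussian
        unk = _table_from_matrix(Xu, ["UNKNOWN"] * 70)
        alloc, posteriors = sm.allocate_unknowns(model, unk)
        pct = dict(zip(alloc.column_labels, alloc.percentages[0]))
        assert pct["b"] >= 80.0
        assert len(posteriors) == 70
        assert np.allclose(
            posteriors[model.class_labels].to_numpy().sum(axis=1), 1.0
        )

    def test_class_mean_is_assigned_to_its_class(self):
        rng = np.random.default_rng(22)
        model, _ = self._three_class_model(rng)
        for i, label in enumerate(model.class_labels):
            unk = _table_from_matrix(model.class_means[i][None, :], ["UNKNOWN"])
            alloc, post = sm.allocate_unknowns(model, unk)
            assert post["assigned"].iloc[0] == label
            assert post[label].iloc[0] == post[model.class_labels].iloc[0].max()

    def test_unit_mismatch_rejected(self):
        rng = np.random.default_rng(23)
        model, _ = self._three_class_model(rng)
        unk = _table_from_matrix(rng.normal(0, 1, (5, 3)), ["UNKNOWN"] * 5)
        unk.units = "mm"
        with pytest.raises(sm.ValidationError, match="unit"):
            sm.allocate_unknowns(model, unk)

    def test_allocation_row_sums_to_100(self):
        rng = np.random.default_rng(24)
        model, _ = self._three_class_model(rng)
        unk = _table_from_matrix(rng.normal(2, 3, (37, 3)), ["UNKNOWN"] * 37)
        alloc, _ = sm.allocate_unknowns(model, unk)
        assert alloc.rounded_percentages()[0].sum() == pytest.approx(100.0, abs=0.1)


class TestReporting:
    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(0, 500), min_size=2, max_size=8).filter(
            lambda c: sum(c) > 0
        )
    )
    def test_largest_remainder_rows_total_exactly_100(self, counts):
        labels = [f"c{i}" for i in range(len(counts))]
        tab = AllocationTable(
            row_labels=["row"], column_labels=labels,
            counts=np.array([counts], dtype=float),
        )
        rounded = tab.rounded_percentages()
        assert rounded.sum() == pytest.approx(100.0, abs=1e-9)
        # each rounded cell within one quantum of the exact percentage
        assert np.abs(rounded - tab.percentages).max() <= 0.1 + 1e-9

    def test_write_report_layout(self, tmp_path):
        conf = AllocationTable(
            row_labels=["a", "b", "c"], column_labels=["a", "b", "c"],
            counts=np.diag([10.0, 20.0, 30.0]) + 1.0, overall_correct=85.0,
        )
        unk = AllocationTable(
            row_labels=["Archaeological samples"], column_labels=["a", "b", "c"],
            counts=np.array([[2.0, 45.0, 23.0]]),
        )
        files = sm.write_report(
            {"cross_validation": conf, "unknown_allocation": unk},
            tmp_path, step_log=[{"step": 1, "action": "enter", "feature": "Feret"}],
        )
        assert len(files) == 3
        cv_lines = (tmp_path / "cross_validation.csv").read_text().strip().splitlines()
        assert len(cv_lines) == 1 + 3 + 1  # header + rows + overall
        assert cv_lines[-1].startswith("overall")
        unk_lines = (tmp_path / "unknown_allocation.csv").read_text().strip().splitlines()
        assert unk_lines[1].endswith("100.0")

    def test_empty_report_warns(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            files = sm.write_report({}, tmp_path)
        assert files == []
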