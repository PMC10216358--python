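import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vgerp import (
    count_feature_grid,
    expected_false_positives,
    pca_fit_transform,
    ttest_screen,
)


class TestFeatureGridArithmetic:
    def test_default_grid(self):
        assert count_feature_grid(15, 6, 11, 1, 6) == 5976

    def test_trivial_grid(self):
        assert count_feature_grid(1, 1, 1, 0, 1) == 1

    def test_per_condition_slice(self):
        assert count_feature_grid(15, 6, 11, 1, 1) == 996

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            count_feature_grid(-1, 6, 11, 1, 6)


class TestExpectedFalsePositives:
    def test_full_grid(self):
        assert expected_false_positives(5976, 0.01) == 60

    def test_per_condition(self):
        assert expected_false_positives(996, 0.01) == 10

    def test_zero_alpha(self):
        assert expected_false_positives(1000, 0.0) == 0


def frame(groups, values):
    df = pd.DataFrame(np.asarray(values, dtype=float))
    df.columns = [f"f{i}" for i in range(df.shape[1])]
    df.insert(0, "group", groups)
    return df


class TestTTestScreen:
    def test_identical_groups_not_selected(self):
        df = frame(["a"] * 3 + ["b"] * 3, [[1.0]] * 6)
        res = ttest_screen(df, "a", "b", alpha=0.01)
        assert res.t[0] == 0.0 and res.p[0] == 1.0
        assert res.n_selected == 0

    def test_textbook_pooled_t(self):
        df = frame(["a"] * 3 + ["b"] * 3, [[1], [2], [3], [4], [5], [6]])
        res = ttest_screen(df, "a", "b", alpha=0.05)
        assert abs(res.t[0]) == pytest.approx(3.674, abs=1e-3)
        # two-tailed p from the pooled-t formula with df = 4
        assert res.p[0] == pytest.approx(2 * stats.t.sf(3.6742, 4), rel=1e-3)
        assert res.p[0] == pytest.approx(0.0213, abs=5e-4)
        assert res.selected[0]

    def test_null_selection_rate_is_binomial(self):
        """On iid Gaussian null columns the selected count falls in the
        central 99% binomial(m, alpha) interval."""
        rng = np.random.default_rng(12)
        m, alpha = 2000, 0.01
        df = frame(["a"] * 8 + ["b"] * 8, rng.standard_normal((16, m)))
        res = ttest_screen(df, "a", "b", alpha=alpha)
        lo, hi = stats.binom.ppf([0.005, 0.995], m, alpha)
        assert lo <= res.n_selected <= hi

    def test_small_group_rejected(self):
        df = frame(["a"] * 1 + ["b"] * 3, [[1], [2], [3], [4]])
        with pytest.raises(ValueError):
            ttest_screen(df, "a", "b")

    def test_mask_reapplies_to_third_group_rows(self):
        """A mask screened on one pair indexes any group's rows (the
        generalization path)."""
        rng = np.random.default_rng(5)
        X = rng.standard_normal((12, 6))
        X[:4, 0] += 10.0  # big effect in column 0 for group a
        df = frame(["a"] * 4 + ["b"] * 4 + ["c"] * 4, X)
        res = ttest_screen(df, "a", "b", alpha=0.01)
        assert res.selected_columns == ["f0"]
        third = df[df["group"] == "c"][res.selected_columns]
        assert third.shape == (4, 1)

    def test_screening_is_idempotent(self):
        rng = np.random.default_rng(6)
        df = frame(["a"] * 5 + ["b"] * 5, rng.standard_normal((10, 50)))
        r1 = ttest_screen(df, "a", "b")
        r2 = ttest_screen(df, "a", "b")
        assert np.array_equal(r1.selected, r2.selected)
        assert np.allclose(r1.p, r2.p)

    def test_alpha_one_selects_everything(self):
        rng = np.random.default_rng(7)
        df = frame(["a"] * 4 + ["b"] * 4, rng.standard_normal((8, 20)))
        res = ttest_screen(df, "a", "b", alpha=1.0)
        assert res.n_selected == 20


def test_selection_localizes_to_planted_channel_and_band():
    """A strong phase-locked alpha oscillation confined to one channel, with
    group-scaled power, should dominate the selected columns: at least 80%
    of them carry the (channel, band) key of the planted effect."""
    from vgerp import (
        OscComponent,
        SyntheticConfig,
        extract_features,
        generate_cohort,
        preprocess_cohort,
    )

    cfg = SyntheticConfig(
        n_subjects_per_group={"AD": 10, "RNE": 10},
        n_trials=24,
        channels=("Fz", "Cz", "Pz"),
        conditions=("OC",),
        osc_components=(
            OscComponent("alpha", 40.0, {"AD": 0.05},
                         channels=("Fz",), phase_locked=True),
        ),
        noise_sd=6.0,
        seed=5,
    )
    epochs = generate_cohort(cfg)
    averaged = preprocess_cohort(epochs, bands=["delta", "alpha"])
    feats, _ = extract_features(averaged)
    res = ttest_screen(feats, "AD", "RNE", alpha=0.01)
    assert res.n_selected > 0
    hits = [c for c in res.selected_columns
            if "__alpha__" in c and c.endswith("__Fz")]
    assert len(hits) / res.n_selected >= 0.8


class TestPCA:
    def test_full_rank_projection_preserves_distances(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 5))
        Z, _, _ = pca_fit_transform(X, None, k=5, scale=False)
        d_orig = np.linalg.norm(X[:, None] - X[None], axis=-1)
        d_proj = np.linalg.norm(Z[:, None] - Z[None], axis=-1)
        assert np.allclose(d_orig, d_proj)

    def test_component_variances_non_increasing(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((30, 8)) * np.arange(1, 9)
        _, _, proj = pca_fit_transform(X, None, k=6)
        assert np.all(np.diff(proj.magnitudes) <= 1e-9)

    def test_first_component_follows_dominant_axis(self):
        rng = np.random.default_rng(2)
        X = rng.multivariate_normal([0, 0], [[4, 0], [0, 1]], size=500)
        _, _, proj = pca_fit_transform(X, None, k=2, scale=False)
        assert abs(proj.components[0, 0]) > 0.95  # aligned with the var-4 axis

    def test_k_too_large_rejected(self):
        X = np.random.default_rng(3).standard_normal((5, 10))
        with pytest.raises(ValueError):
            pca_fit_transform(X, None, k=5)  # k > n-1

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((10, 4))
        X[:, 2] = 7.0
        with pytest.warns(UserWarning):
            Ztr, Zte, proj = pca_fit_transform(X, X[:3], k=2)
        assert proj.kept_columns.tolist() == [0, 1, 3]
        assert Zte.shape == (3, 2)

    def test_test_rows_projected_with_train_statistics(self):
        rng = np.random.default_rng(5)
        train = rng.standard_normal((15, 4))
        test = rng.standard_normal((6, 4)) + 50.0  # far outside train
        _, Zte, proj = pca_fit_transform(train, test, k=2)
        assert np.allclose(Zte, proj.transform(test))
        assert np.abs(Zte).max() > 10  # offset not absorbed: train stats used
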