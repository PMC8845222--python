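"""Base learners: folds, count weighting, cross-fitting, tuning."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from vgscmap.features import Design
from vgscmap.learners import (
    DEFAULT_SPECS,
    LearnerSpec,
    _expand_weighted,
    assign_folds,
    fit_full,
    fit_predict_out_of_sample,
    make_learner,
    tune_learner,
)


class TestFoldAssignment:
    def test_exact_divisibility(self):
        folds = assign_folds(range(20), K=10, seed=0)
        assert folds.value_counts().eq(2).all()

    def test_partition_property(self):
        ids = [f"s{i}" for i in range(37)]
        folds = assign_folds(ids, K=10, seed=1)
        assert sorted(folds.index) == sorted(ids)
        assert set(folds.unique()) == set(range(1, 11))

    def test_pigeonhole_sizes_for_n23_k10(self):
        sizes = assign_folds(range(23), K=10, seed=2).value_counts()
        assert sorted(sizes) == [2] * 7 + [3] * 3

    def test_deterministic_and_seed_sensitive(self):
        a = assign_folds(range(50), K=5, seed=3)
        b = assign_folds(range(50), K=5, seed=3)
        c = assign_folds(range(50), K=5, seed=4)
        assert a.equals(b)
        assert not a.equals(c)

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(range(5), K=10, seed=0)


class TestCountWeighting:
    def test_counts_become_per_class_weights(self):
        X = np.array([[1.0, 2.0]])
        counts = np.array([[3, 7, 0]])
        Xr, y, w = _expand_weighted(X, counts)
        got = sorted(zip(y.tolist(), w.tolist()))
        assert got == [(0, 3.0), (1, 7.0)]
        assert (Xr == X[0]).all()


def make_design(rng, n=120, j=3):
    """Minimal design: one informative feature driving class 1."""
    x = rng.normal(size=n)
    noise = rng.normal(size=n)
    eta = 2.0 * x
    p1 = 1.0 / (1.0 + np.exp(-eta))
    p = np.column_stack([(1 - p1) * 0.7, p1, (1 - p1) * 0.3])
    p = p / p.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(40, row) for row in p])[:, :j]
    # renormalise counts if j < 3 by folding the dropped class into class 0
    if j == 2:
        counts = np.column_stack([40 - counts[:, 1], counts[:, 1]])
    X = pd.DataFrame(
        {
            "driver": x,
            "noise": noise,
            "species": pd.Categorical(
                rng.choice(["gambiae", "arabiensis"], n),
                categories=["gambiae", "coluzzii", "arabiensis", "gambiae_sl"],
            ),
            "year": 2010.0,
        },
        index=pd.RangeIndex(n, name="sample_id"),
    )
    cols = [f"count_{k}" for k in ("995L", "995F", "995S")[:j]]
    return Design(X, pd.DataFrame(counts, index=X.index, columns=cols)), p


class TestOutOfSamplePredictions:
    def test_stub_learner_reproduces_leave_fold_out_frequencies(self, rng):
        """Counting oracle: the constant-frequency stub's out-of-sample row
        must equal the class frequencies of the other folds' counts."""
        design, _ = make_design(rng, n=30)
        folds = assign_folds(design.X.index, K=5, seed=0)
        oos = fit_predict_out_of_sample(LearnerSpec.of("mean"), design, folds)
        for f in range(1, 6):
            hold = folds == f
            train_counts = design.counts[~hold].to_numpy().sum(axis=0)
            expected = train_counts / train_counts.sum()
            block = oos[hold.to_numpy()].to_numpy()
            np.testing.assert_allclose(
                block, np.tile(expected, (block.shape[0], 1)), atol=1e-12
            )

    def test_fold_rows_identical_computed_in_isolation(self, rng):
        design, _ = make_design(rng, n=40)
        folds = assign_folds(design.X.index, K=4, seed=1)
        spec = DEFAULT_SPECS["xgb"]
        oos = fit_predict_out_of_sample(spec, design, folds)
        f = 2
        hold = folds == f
        solo = make_learner(spec).fit(design.X[~hold], design.counts[~hold])
        np.testing.assert_allclose(
            oos[hold.to_numpy()].to_numpy(), solo.predict(design.X[hold]),
            atol=1e-12,
        )

    def test_memorising_learner_cannot_leak_held_out_labels(self, rng):
        """Leak check: a stub that memorises training labels and answers
        uniformly for unseen rows yields uniform out-of-sample predictions
        everywhere, proving held-out labels never reach the learner."""
        from vgscmap.learners import FrequencyLearner, register_family

        class Memoriser(FrequencyLearner):
            def fit(self, X, counts):
                self._seen = counts.div(counts.sum(axis=1), axis=0)
                return self

            def predict(self, X):
                out = np.full((len(X), self._seen.shape[1]),
                              1.0 / self._seen.shape[1])
                known = X.index.intersection(self._seen.index)
                pos = X.index.get_indexer(known)
                out[pos] = self._seen.loc[known].to_numpy()
                return out

        register_family("memo", Memoriser)
        design, _ = make_design(rng, n=24)
        folds = assign_folds(design.X.index, K=4, seed=0)
        oos = fit_predict_out_of_sample(LearnerSpec.of("memo"), design, folds)
        np.testing.assert_allclose(oos.to_numpy(), 1.0 / 3.0, atol=1e-12)

    @pytest.mark.parametrize("family", ["xgb", "rf", "nn"])
    def test_simplex_rows_and_completeness(self, rng, family):
        design, _ = make_design(rng, n=60)
        folds = assign_folds(design.X.index, K=3, seed=2)
        oos = fit_predict_out_of_sample(DEFAULT_SPECS[family], design, folds)
        p = oos.to_numpy()
        assert np.isfinite(p).all()
        assert ((p >= 0) & (p <= 1)).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)

    @pytest.mark.parametrize("family", ["xgb", "rf", "nn"])
    def test_full_fit_deterministic_given_seed(self, rng, family):
        design, _ = make_design(rng, n=60)
        p1 = fit_full(DEFAULT_SPECS[family], design).predict(design.X)
        p2 = fit_full(DEFAULT_SPECS[family], design).predict(design.X)
        np.testing.assert_array_equal(p1, p2)

    @pytest.mark.parametrize("family", ["xgb", "rf", "nn"])
    def test_recovery_of_generating_frequency(self, rng, family):
        """Each learner's predicted class-1 frequency tracks the latent
        generating frequency (Spearman > 0.5) on 5,000 weighted draws."""
        design, p_true = make_design(rng, n=125)  # 125 x 40 alleles = 5000
        learner = fit_full(DEFAULT_SPECS[family], design)
        pred = learner.predict(design.X)
        rho = spearmanr(pred[:, 1], p_true[:, 1]).statistic
        assert rho > 0.5

    def test_binary_variant_same_code_path(self, rng):
        design, _ = make_design(rng, n=60, j=2)
        folds = assign_folds(design.X.index, K=3, seed=0)
        for family in ("xgb", "rf", "nn", "mean"):
            oos = fit_predict_out_of_sample(
                DEFAULT_SPECS.get(family, LearnerSpec.of(family)), design, folds
            )
            assert oos.shape == (60, 2)
            np.testing.assert_allclose(oos.sum(axis=1), 1.0, atol=1e-9)

    def test_degenerate_single_class_training_fold(self, rng, caplog):
        design, _ = make_design(rng, n=20)
        counts = design.counts.copy()
        counts[["count_995F", "count_995S"]] = 0
        counts["count_995L"] = 40
        degenerate = Design(design.X, counts)
        learner = make_learner(DEFAULT_SPECS["xgb"]).fit(
            degenerate.X, degenerate.counts
        )
        p = learner.predict(design.X)
        np.testing.assert_allclose(p[:, 0], 1.0, atol=1e-12)


class TestTuning:
    def test_singleton_grid_returned_unchanged(self, rng):
        design, _ = make_design(rng, n=60)
        grid = [{"max_depth": 4, "learning_rate": 0.2, "n_estimators": 30}]
        result = tune_learner("xgb", design, grid=grid, seed=0)
        assert result.spec.param_dict == grid[0]
        assert len(result.trace) == 1

    def test_selected_spec_attains_best_validation_score(self, rng):
        design, _ = make_design(rng, n=90)
        result = tune_learner("xgb", design, seed=1)
        best_row = result.trace["val_loglik"].max()
        chosen = {
            k: v for k, v in result.spec.param_dict.items()
        }
        row = result.trace
        match = row
        for k, v in chosen.items():
            match = match[match[k] == v]
        assert match["val_loglik"].iloc[0] == best_row

    def test_empty_grid_rejected(self, rng):
        design, _ = make_design(rng, n=30)
        with pytest.raises(ValueError, match="empty"):
            tune_learner("xgb", design, grid=[], seed=0)

    def test_interaction_favours_deeper_trees(self):
        """Planted multiplicative interaction: depth-1 stumps cannot
        represent it, so depth-3 must win the validation score in >= 90%
        of 20 seeded repetitions."""
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            n = 300
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            eta = 3.0 * a * b
            p1 = 1.0 / (1.0 + np.exp(-eta))
            n0 = rng.binomial(40, 1 - p1)
            counts = np.column_stack([n0, 40 - n0])
            X = pd.DataFrame({"a": a, "b": b},
                             index=pd.RangeIndex(n, name="sample_id"))
            design = Design(
                X,
                pd.DataFrame(counts, index=X.index,
                             columns=["count_995L", "count_995F"]),
            )
            grid = [
                {"max_depth": 1, "learning_rate": 0.1, "n_estimators": 60},
                {"max_depth": 3, "learning_rate": 0.1, "n_estimators": 60},
            ]
            result = tune_learner("xgb", design, grid=grid, seed=s)
            if result.spec.param_dict["max_depth"] == 3:
                wins += 1
        assert wins >= 18
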