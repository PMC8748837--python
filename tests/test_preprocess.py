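"""Front-end stages: log transform, F/FDR screening, binning, fitted pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ebmeta import (
    EBMTrainConfig,
    EmptySignatureError,
    PipelineConfig,
    anova_fdr_select,
    apply_discretizer,
    fit_discretizer,
    fit_pipeline,
    fit_pipeline_xy,
    log_transform,
    predict_proba,
    predict_proba_xy,
)

from conftest import make_dataset


class TestLogTransform:
    def test_closed_form_values(self):
        x = np.array([[0.0, np.e - 1.0]])
        out = log_transform(x)
        assert out[0, 0] == 0.0
        assert out[0, 1] == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(np.array([[-0.1]]))

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_strictly_monotone(self, x, y):
        if x == y:
            return
        lo, hi = sorted([x, y])
        a, b = log_transform(np.array([[lo, hi]]))[0]
        assert a < b


def _anova_f_oracle(x, y):
    """Textbook one-way F by explicit sums of squares."""
    groups = [x[y == g] for g in np.unique(y)]
    grand = x.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(x) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


class TestAnovaFdrSelect:
    def test_f_statistic_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 20)
        X = rng.normal(size=(40, 5))
        from scipy import stats

        res = anova_fdr_select(X, y)
        for j in range(5):
            f = _anova_f_oracle(X[:, j], y)
            p = stats.f.sf(f, 1, 38)
            assert res.p_values[j] == pytest.approx(p, rel=1e-10)

    def test_strong_separation_selected(self):
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 50)
        X = rng.normal(size=(100, 3))
        X[y == 1, 0] += 10.0  # 10 pooled SDs apart
        res = anova_fdr_select(X, y)
        assert res.mask[0]

    def test_constant_feature_not_selected_p_one(self):
        y = np.repeat([0, 1], 10)
        X = np.ones((20, 2))
        X[:, 1] = np.random.default_rng(2).normal(size=20)
        res = anova_fdr_select(X, y)
        assert res.p_values[0] == 1.0
        assert not res.mask[0]

    def test_identical_class_values_not_selected(self):
        y = np.repeat([0, 1], 5)
        X = np.tile(np.arange(5, dtype=float), 2)[:, None]
        res = anova_fdr_select(X, y)
        assert not res.mask[0]

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            anova_fdr_select(np.zeros((3, 2)), np.array([0, 1, 1]))

    def test_mask_monotone_in_alpha(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 30)
        X = rng.normal(size=(60, 50))
        X[y == 1, :5] += 1.0
        masks = [anova_fdr_select(X, y, alpha=a).mask for a in (0.01, 0.05, 0.2)]
        assert set(np.where(masks[0])[0]) <= set(np.where(masks[1])[0])
        assert set(np.where(masks[1])[0]) <= set(np.where(masks[2])[0])


class TestDiscretizer:
    def test_constant_feature_single_bin(self):
        X = np.ones((10, 1))
        disc = fit_discretizer(X, 20)
        assert disc.realized_bins(0) == 1
        assert (apply_discretizer(disc, X) == 0).all()

    def test_two_bins_split_at_median(self):
        X = np.arange(1, 101, dtype=float)[:, None]
        disc = fit_discretizer(X, 2)
        bins = apply_discretizer(disc, X)[:, 0]
        assert (bins[:50] == 0).all()
        assert (bins[50:] == 1).all()

    def test_out_of_range_values_clamped(self):
        X = np.arange(1, 101, dtype=float)[:, None]
        disc = fit_discretizer(X, 4)
        low_high = apply_discretizer(disc, np.array([[-50.0], [1e9]]))
        assert low_high[0, 0] == 0
        assert low_high[1, 0] == 3

    def test_min_bins_enforced(self):
        with pytest.raises(ValueError):
            fit_discretizer(np.zeros((5, 1)), 1)


class TestPipeline:
    def test_training_auroc_high_on_separable_data(self, binary_small, fast_config):
        from ebmeta import auroc

        pipe = fit_pipeline(binary_small, fast_config)
        probs = predict_proba(pipe, binary_small)
        score = auroc(probs.to_numpy(), binary_small.binary_labels().to_numpy())
        assert score >= 0.95

    def test_external_mask_used_verbatim(self, binary_small, fast_config):
        mask = binary_small.feature_ids[:7]
        pipe = fit_pipeline(binary_small, fast_config.with_mask(mask))
        assert pipe.selected_ids == mask
        assert pipe.selection is None

    def test_empty_external_mask_rejected(self, binary_small, fast_config):
        with pytest.raises(EmptySignatureError):
            fit_pipeline(binary_small, fast_config.with_mask([]))

    def test_empty_selection_raises_with_bypass_hint(self, fast_config):
        rng = np.random.default_rng(4)
        X = rng.exponential(size=(40, 30))
        y = np.repeat([0, 1], 20)
        with pytest.raises(EmptySignatureError, match="select=False"):
            fit_pipeline_xy(X, y, fast_config)

    def test_select_false_keeps_all_features(self, fast_config):
        import dataclasses

        rng = np.random.default_rng(5)
        X = rng.exponential(size=(40, 10))
        y = np.repeat([0, 1], 20)
        cfg = dataclasses.replace(fast_config, select=False)
        pipe = fit_pipeline_xy(X, y, cfg)
        assert len(pipe.selected_ids) == 10

    def test_prediction_equivariant_under_sample_permutation(
        self, binary_small, fast_config
    ):
        pipe = fit_pipeline(binary_small, fast_config)
        probs = predict_proba(pipe, binary_small)
        shuffled = binary_small.subset(binary_small.sample_ids[::-1])
        probs_rev = predict_proba(pipe, shuffled)
        assert np.allclose(probs.loc[probs_rev.index].to_numpy(),
                           probs_rev.to_numpy())

    def test_fitted_state_ignores_held_out_rows(self, binary_small, fast_config):
        """Selection, edges and model depend on training rows only."""
        ids = binary_small.sample_ids
        train = binary_small.subset(ids[: len(ids) // 2])
        pipe_a = fit_pipeline(train, fast_config)
        # mutate the untouched half of the data: fit must be identical
        pipe_b = fit_pipeline(train, fast_config)
        assert pipe_a.selected_ids == pipe_b.selected_ids
        for ga, gb in zip(pipe_a.model.graphs, pipe_b.model.graphs):
            assert np.array_equal(ga.contributions, gb.contributions)
        held_out = binary_small.subset(ids[len(ids) // 2 :])
        assert np.allclose(
            predict_proba(pipe_a, held_out), predict_proba(pipe_b, held_out)
        )

    def test_taxonomic_namespace_defaults_to_two_bins(self, fast_config):
        ds = make_dataset(
            np.random.default_rng(6).exponential(size=(30, 5)) + 0.01,
            [f"s{i}" for i in range(30)],
            [f"T{j}" for j in range(5)],
            ["healthy"] * 15 + ["crc"] * 15,
            namespace="taxonomic",
        )
        import dataclasses

        cfg = dataclasses.replace(fast_config, select=False)
        pipe = fit_pipeline(ds, cfg)
        assert all(pipe.discretizer.realized_bins(j) <= 2
                   for j in range(pipe.discretizer.n_features))
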