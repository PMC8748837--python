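"""AUROC scoring and the CV / cross-dataset / LOPO / o-LOPO designs."""

import itertools

import numpy as np
import pytest

from ebmeta import (
    auroc,
    cross_dataset_matrix,
    cv_split_plan,
    functional_mode_config,
    generate_dataset,
    lopo,
    olopo,
)


def _auroc_bruteforce(scores, labels):
    """Probability a random positive outranks a random negative, ties 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_ordering(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_known_mixed_case(self):
        # pairs: (.9,.8)+, (.9,.1)+, (.4,.8)-, (.4,.1)+ -> 3/4
        assert auroc([0.9, 0.8, 0.4, 0.1], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_all_ties_half(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        assert np.isnan(auroc([0.1, 0.2], [1, 1]))

    def test_matches_bruteforce_on_small_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(2, 9)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.choice([0.1, 0.3, 0.3, 0.7, 0.9], size=n)
            assert auroc(scores, labels) == pytest.approx(
                _auroc_bruteforce(scores, labels)
            )


class TestCvPlan:
    def test_same_seed_identical_folds(self, binary_small):
        a = cv_split_plan(binary_small, k=4, repeats=2, seed=9)
        b = cv_split_plan(binary_small, k=4, repeats=2, seed=9)
        assert a.splits == b.splits

    def test_folds_partition_samples(self, binary_small):
        plan = cv_split_plan(binary_small, k=4, repeats=1, seed=0)
        ids = set(binary_small.sample_ids)
        for train, test in plan.splits:
            assert set(train) | set(test) == ids
            assert not set(train) & set(test)

    def test_k_reduced_with_warning_when_class_small(self):
        from conftest import make_dataset

        ds = make_dataset(
            np.random.default_rng(1).exponential(size=(8, 3)),
            [f"s{i}" for i in range(8)],
            ["A", "B", "C"],
            ["healthy"] * 5 + ["crc"] * 3,
        )
        with pytest.warns(UserWarning, match="reducing k"):
            plan = cv_split_plan(ds, k=10, repeats=1, seed=0)
        assert len(plan) == 3


@pytest.fixture(scope="module")
def two_project_data():
    config = functional_mode_config(
        seed=501,
        n_projects=2,
        samples_per_condition={"healthy": 25, "crc": 25},
        n_features=80,
        n_signal=10,
        low_depth_project=None,
    )
    return generate_dataset(config)


class TestLopo:
    def test_shared_signal_transfers_across_projects(
        self, two_project_data, fast_config
    ):
        ds, _ = two_project_data
        res = lopo(ds, fast_config)
        assert set(res.aurocs) == {"project_1", "project_2"}
        assert all(v >= 0.9 for v in res.aurocs.values())

    def test_relevance_vectors_cover_full_feature_space(
        self, two_project_data, fast_config
    ):
        ds, truth = two_project_data
        res = lopo(ds, fast_config)
        assert list(res.relevances.columns) == ds.feature_ids
        assert (res.relevances.to_numpy() >= 0).all()
        # unselected features carry zero relevance
        assert (res.relevances.to_numpy() == 0).any()

    def test_shuffled_labels_in_held_out_project_score_near_chance(self, fast_config):
        config = functional_mode_config(
            seed=503,
            n_projects=4,
            samples_per_condition={"healthy": 25, "crc": 25},
            n_features=80,
            n_signal=10,
            low_depth_project=None,
        )
        ds, _ = generate_dataset(config)
        rng = np.random.default_rng(7)
        meta = ds.metadata.copy()
        mask = meta["project_id"] == "project_4"
        meta.loc[mask, "condition"] = rng.permutation(
            meta.loc[mask, "condition"].to_numpy()
        )
        from ebmeta import ProfileDataset

        shuffled = ProfileDataset(ds.matrix, meta)
        baseline = lopo(ds, fast_config)
        res = lopo(shuffled, fast_config)
        # the shuffled project's own labels are noise -> near-chance score
        assert abs(res.aurocs["project_4"] - 0.5) < 0.25
        assert baseline.aurocs["project_4"] >= 0.9
        # intact projects stay clearly predictable: the shuffled third of each
        # training union dilutes the signal but does not erase it
        for pid in ("project_1", "project_2", "project_3"):
            assert res.aurocs[pid] >= 0.65
            assert res.aurocs[pid] > res.aurocs["project_4"] + 0.15

    def test_single_project_rejected(self, binary_small, fast_config):
        single = binary_small.subset(
            list(
                binary_small.metadata.index[
                    binary_small.metadata["project_id"] == "project_1"
                ]
            )
        )
        with pytest.raises(ValueError, match="2 projects"):
            lopo(single, fast_config)


class TestOlopo:
    def test_full_mask_equals_lopo_without_selection(
        self, two_project_data, fast_config
    ):
        import dataclasses

        ds, _ = two_project_data
        no_select = dataclasses.replace(fast_config, select=False)
        a = lopo(ds, no_select)
        b = olopo(ds, ds.feature_ids, fast_config)
        for pid in a.aurocs:
            assert a.aurocs[pid] == pytest.approx(b.aurocs[pid])

    def test_signal_only_mask_performs(self, two_project_data, fast_config):
        ds, truth = two_project_data
        res = olopo(ds, truth.signal_feature_ids, fast_config)
        assert all(v >= 0.9 for v in res.aurocs.values())

    def test_mask_excluding_signal_near_chance(self, two_project_data, fast_config):
        ds, truth = two_project_data
        nulls = [f for f in ds.feature_ids if f not in truth.signal_feature_ids]
        res = olopo(ds, nulls, fast_config)
        assert all(abs(v - 0.5) < 0.2 for v in res.aurocs.values())

    def test_empty_mask_rejected(self, two_project_data, fast_config):
        ds, _ = two_project_data
        with pytest.raises(ValueError, match="mask"):
            olopo(ds, [], fast_config)


class TestCrossDatasetMatrix:
    def test_layout_and_transfer(self, two_project_data, fast_config):
        ds, _ = two_project_data
        matrix = cross_dataset_matrix(
            ds, fast_config, cv_repeats=2, seed=0, include_lopo=True
        )
        table = matrix.table
        assert list(table.columns) == ["project_1", "project_2"]
        assert list(table.index) == ["project_1", "project_2", "LOPO", "oLOPO"]
        # off-diagonal transfer is strong for identically generated projects
        assert table.loc["project_1", "project_2"] >= 0.9
        assert table.loc["project_2", "project_1"] >= 0.9
        # diagonal holds the CV mean, defined and plausible
        assert 0.5 <= table.loc["project_1", "project_1"] <= 1.0
        # oLOPO row requested without a mask stays undefined
        assert table.loc["oLOPO"].isna().all()

    def test_label_free_target_scores_near_chance(self, fast_config):
        config = functional_mode_config(
            seed=502,
            n_projects=2,
            samples_per_condition={"healthy": 25, "crc": 25},
            n_features=60,
            n_signal=8,
            low_depth_project=None,
        )
        ds, _ = generate_dataset(config)
        rng = np.random.default_rng(8)
        meta = ds.metadata.copy()
        mask = meta["project_id"] == "project_2"
        meta.loc[mask, "condition"] = rng.permutation(
            meta.loc[mask, "condition"].to_numpy()
        )
        from ebmeta import ProfileDataset

        shuffled = ProfileDataset(ds.matrix, meta)
        matrix = cross_dataset_matrix(
            shuffled, fast_config, cv_repeats=2, seed=0, include_lopo=False
        )
        assert abs(matrix.table.loc["project_1", "project_2"] - 0.5) < 0.25
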