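"""Automatic sample matching and masked-marker generation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsimpute.genotype_io import GenotypeMatrix
from gsimpute.matching import (
    general_mask_augment,
    knn_impute,
    manhattan_distances,
    matching_oracle,
    mean_fill,
    random_mask,
    reconstructive_mask,
)
from conftest import make_gm, random_gm


class TestMeanFill:
    def test_no_missing_unchanged(self):
        tr = make_gm([[1, 1], [3, 3]])
        te = make_gm([[2, 3]])
        assert np.array_equal(mean_fill(te, tr), [[2.0, 3.0]])

    def test_column_mean_inserted(self):
        tr = make_gm([[1, 1], [1, 1], [3, 3]])
        te = make_gm([[0, 2]])
        filled = mean_fill(te, tr)
        assert filled[0, 0] == pytest.approx(5 / 3)
        assert filled[0, 1] == 2.0

    def test_all_missing_column(self):
        tr = make_gm([[1], [2], [3]])
        te = make_gm([[0], [0]])
        assert np.allclose(mean_fill(te, tr), 2.0)

    def test_requires_missing_free_training(self):
        with pytest.raises(ValueError):
            mean_fill(make_gm([[1]]), make_gm([[0]]))


class TestManhattan:
    def test_hand_computed(self):
        d = manhattan_distances(np.array([[1, 2, 3]]), np.array([[3, 2, 1]]))
        assert d.values[0, 0] == 4.0

    def test_identical_vectors_zero(self):
        d = manhattan_distances(np.array([[1.5, 2.0]]), np.array([[1.5, 2.0]]))
        assert d.values[0, 0] == 0.0

    def test_symmetry_on_random(self):
        rng = np.random.default_rng(3)
        a = rng.random((5, 7))
        assert np.allclose(
            manhattan_distances(a, a).values, manhattan_distances(a, a).values.T
        )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            manhattan_distances(np.ones((2, 3)), np.ones((2, 4)))


class TestReconstructiveMask:
    def test_no_missing_gives_uncorrupted_copy(self):
        rng = np.random.default_rng(0)
        tr, te = random_gm(rng, 5, 12), random_gm(rng, 3, 12)
        plan, corr = reconstructive_mask(tr, te)
        assert np.array_equal(corr.codes, tr.codes)
        assert all(len(plan.masked_indices(i)) == 0 for i in range(5))

    def test_single_testing_sample_masks_every_row(self):
        tr = make_gm([[1, 2, 3, 1], [3, 2, 1, 3], [2, 2, 2, 2]])
        te = make_gm([[0, 2, 0, 1]])
        plan, corr = reconstructive_mask(tr, te)
        for i in range(3):
            assert plan.masked_indices(i) == frozenset({0, 2})
        assert (corr.codes[:, [0, 2]] == 0).all()
        assert np.array_equal(corr.codes[:, [1, 3]], tr.codes[:, [1, 3]])

    def test_without_replacement_within_round(self):
        rng = np.random.default_rng(7)
        tr, te = random_gm(rng, 6, 20), random_gm(rng, 6, 20, missing=0.3)
        plan, _ = reconstructive_mask(tr, te)
        assert set(plan.assignments) == set(range(6))  # every row claimed once

    def test_pattern_fidelity(self):
        rng = np.random.default_rng(9)
        tr, te = random_gm(rng, 8, 30), random_gm(rng, 3, 30, missing=0.4)
        plan, corr = reconstructive_mask(tr, te)
        miss_of = {
            sid: frozenset(np.flatnonzero(te.codes[j] == 0).tolist())
            for j, sid in enumerate(te.sample_ids)
        }
        for i, (sid, idx) in plan.assignments.items():
            assert idx == miss_of[sid]
            assert frozenset(np.flatnonzero(corr.codes[i] != tr.codes[i]).tolist()) == idx

    def test_zero_testing_samples_rejected(self):
        tr = make_gm([[1, 2]])
        te = GenotypeMatrix([], tr.markers, np.empty((0, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            reconstructive_mask(tr, te)

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_random_instances(self, seed):
        """Vectorized matching equals the literal step-by-step transcription."""
        rng = np.random.default_rng(seed)
        n, m, p = int(rng.integers(1, 9)), int(rng.integers(1, 9)), int(rng.integers(2, 31))
        tr = random_gm(rng, n, p)
        te = random_gm(rng, m, p, missing=float(rng.uniform(0, 0.6)))
        plan, _ = reconstructive_mask(tr, te)
        assert plan.assignments == matching_oracle(tr, te).assignments


class TestKNNImpute:
    def test_unanimous_neighbors(self):
        te = make_gm([[0, 1], [3, 1], [3, 1], [3, 2]])
        out = knn_impute(te, k=3)
        assert out.codes[0, 0] == 3

    def test_k1_copies_nearest(self):
        te = make_gm([[0, 1, 1, 1], [2, 1, 1, 1], [3, 3, 3, 3]])
        out = knn_impute(te, k=1)
        assert out.codes[0, 0] == 2  # nearest sample is row 1

    def test_output_complete(self):
        rng = np.random.default_rng(5)
        te = random_gm(rng, 10, 15, missing=0.3)
        assert not knn_impute(te, k=3).has_missing()

    def test_fully_missing_marker_rejected(self):
        te = make_gm([[0, 1], [0, 2], [0, 3]])
        with pytest.raises(ValueError, match="every sample"):
            knn_impute(te, k=1)

    def test_needs_enough_samples(self):
        te = make_gm([[1], [2]])
        with pytest.raises(ValueError):
            knn_impute(te, k=2)


class TestGeneralMaskAugment:
    def test_diagonal_dominates_after_2max_rule(self):
        # exercised indirectly: no row may match itself unless forced
        rng = np.random.default_rng(1)
        tr, te = random_gm(rng, 4, 20), random_gm(rng, 5, 20, missing=0.2)
        aug = general_mask_augment(tr, te, k=2)
        # each augmented row matched some other sample
        for i in range(5):
            sid, _ = aug.augment_plan.assignments[i]
            assert sid != te.sample_ids[i]

    def test_row_count_and_origin(self):
        rng = np.random.default_rng(2)
        tr, te = random_gm(rng, 6, 15), random_gm(rng, 4, 15, missing=0.3)
        aug = general_mask_augment(tr, te, k=2)
        assert aug.clean.shape[0] == 10
        assert aug.origin == ["panel"] * 6 + ["augmented"] * 4

    def test_self_missing_excluded_from_masks(self):
        rng = np.random.default_rng(3)
        tr, te = random_gm(rng, 5, 25), random_gm(rng, 6, 25, missing=0.35)
        aug = general_mask_augment(tr, te, k=3)
        for i in range(6):
            own = set(np.flatnonzero(te.codes[i] == 0).tolist())
            assert not (set(aug.augment_plan.masked_indices(i)) & own)

    def test_corrupted_differs_only_at_masked_zeros(self):
        rng = np.random.default_rng(4)
        tr, te = random_gm(rng, 5, 25), random_gm(rng, 5, 25, missing=0.3)
        aug = general_mask_augment(tr, te, k=2)
        diff = aug.clean != aug.corrupted
        assert (aug.corrupted[diff] == 0).all()

    def test_no_missing_degenerates_to_plain_stack(self):
        rng = np.random.default_rng(6)
        tr, te = random_gm(rng, 4, 12), random_gm(rng, 3, 12)
        aug = general_mask_augment(tr, te, k=1)
        assert np.array_equal(aug.clean, aug.corrupted)
        assert np.array_equal(aug.clean[4:], te.codes)

    def test_needs_two_testing_samples(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            general_mask_augment(random_gm(rng, 3, 5), random_gm(rng, 1, 5), k=1)


class TestRandomMaskControl:
    def test_mask_count_matches_testing_rate(self):
        rng = np.random.default_rng(0)
        tr = random_gm(rng, 6, 40)
        te_codes = rng.integers(1, 4, size=(4, 40)).astype(np.int8)
        te_codes[:, :10] = 0  # 25% systematic
        te = make_gm(te_codes)
        _, corr = random_mask(tr, te, np.random.default_rng(1))
        assert ((corr.codes == 0).sum(axis=1) == 10).all()
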