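"""Data-adaptive masked-marker generation by automatic sample matching.

The denoising autoencoder must be trained on corrupted panel samples whose
missingness looks like the missingness it will actually have to impute.
Instead of masking at random, each testing sample is matched to its nearest
panel samples (Manhattan distance on numeric genotype codes) and its own
missing-marker pattern is stamped onto them. For general imputation the
training set is additionally augmented with KNN-imputed testing samples
carrying masks borrowed from their nearest testing neighbours.

Two variants are provided:

* ``reconstructive_mask`` — the seven-step matching procedure used when a
  population is reconstructed at another chip's positions (systematic
  missingness, optionally mixed with sporadic gaps).
* ``general_mask_augment`` — the augmented procedure for ordinary
  panel-based imputation of sporadically missing data.

``matching_oracle`` is a deliberately naive plain-loop transcription of the
matching steps kept for cross-checking the vectorized implementation in
tests; the pipeline never calls it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "MaskPlan",
    "AugmentedTrainingSet",
    "mean_fill",
    "manhattan_distances",
    "reconstructive_mask",
    "knn_impute",
    "general_mask_augment",
    "random_mask",
    "matching_oracle",
]


@dataclass
class DistanceMatrix:
    """Pairwise Manhattan distances between two sample sets."""

    values: np.ndarray
    row_ids: list[str]
    col_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("distance matrix shape does not match id lists")
        if (self.values < 0).any():
            raise ValueError("distances must be nonnegative")


@dataclass
class MaskPlan:
    """Which testing sample each corrupted training row imitates.

    assignments maps a training-row index to the matched testing sample id
    and the set of marker indices masked in that row.
    """

    assignments: dict[int, tuple[str, frozenset[int]]] = field(default_factory=dict)

    def masked_indices(self, row: int) -> frozenset[int]:
        return self.assignments.get(row, ("", frozenset()))[1]

    def to_table(self):
        """Diagnostic table: training row, matched testing sample, mask size."""
        import pandas as pd

        rows = [
            {"train_row": r, "matched_sample": sid, "n_masked": len(idx)}
            for r, (sid, idx) in sorted(self.assignments.items())
        ]
        return pd.DataFrame(rows, columns=["train_row", "matched_sample", "n_masked"])


@dataclass
class AugmentedTrainingSet:
    """Panel rows stacked with KNN-imputed testing rows, plus the corrupted copy.

    ``origin`` flags each row as 'panel' or 'augmented'. The corrupted codes
    differ from the clean codes only at masked positions, which are set to 0.
    """

    clean: np.ndarray
    corrupted: np.ndarray
    origin: list[str]
    panel_plan: MaskPlan
    augment_plan: MaskPlan


def _check_aligned(a: GenotypeMatrix, b: GenotypeMatrix) -> None:
    if a.keys() != b.keys():
        raise ValueError("marker sets/orders differ between matrices")


def mean_fill(te: GenotypeMatrix, tr: GenotypeMatrix) -> np.ndarray:
    """Replace missing testing codes with the training-column mean (real valued)."""
    _check_aligned(te, tr)
    if tr.has_missing():
        raise ValueError("training set must be missing-free")
    col_mean = tr.codes.astype(float).mean(axis=0)
    out = te.codes.astype(float)
    miss = te.codes == MISSING
    out[miss] = np.broadcast_to(col_mean, out.shape)[miss]
    return out


def manhattan_distances(
    a: np.ndarray, b: np.ndarray, row_ids=None, col_ids=None
) -> DistanceMatrix:
    """Manhattan (cityblock) distance between row vectors of a and b."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError(f"marker dimension mismatch: {a.shape[1]} vs {b.shape[1]}")
    values = cdist(a, b, metric="cityblock")
    row_ids = list(row_ids) if row_ids is not None else [str(i) for i in range(a.shape[0])]
    col_ids = list(col_ids) if col_ids is not None else [str(j) for j in range(b.shape[0])]
    return DistanceMatrix(values, row_ids, col_ids)


def _greedy_match(
    dist: np.ndarray, te_order: np.ndarray, n_rows: int
) -> list[tuple[int, int]]:
    """Cycle through the ordered testing list, each testing sample claiming its
    nearest still-unclaimed row, until every row is claimed (or, if there are
    more testing samples than rows in one round, until rows run out).

    Returns (row_index, testing_index) pairs. Ties break to the smallest row
    index (np.argmin is stable).
    """
    remaining = np.ones(n_rows, dtype=bool)
    pairs: list[tuple[int, int]] = []
    while remaining.any():
        for j in te_order:
            if not remaining.any():
                break
            col = np.where(remaining, dist[:, j], np.inf)
            i = int(np.argmin(col))
            remaining[i] = False
            pairs.append((i, int(j)))
    return pairs


def _mean_distance_order(dist: np.ndarray, descending: bool) -> np.ndarray:
    """Order testing samples by their mean distance to all rows; ties keep
    ascending sample index (stable mergesort)."""
    mean_d = dist.mean(axis=0)
    key = -mean_d if descending else mean_d
    return np.argsort(key, kind="stable")


def reconstructive_mask(
    tr: GenotypeMatrix, te: GenotypeMatrix
) -> tuple[MaskPlan, GenotypeMatrix]:
    """Match panel samples to testing samples and stamp missing patterns.

    Steps: numeric codes; mean-fill the testing set from training column
    means; Manhattan distance matrix D (n x m); mean distance per testing
    sample; testing samples processed in descending mean-distance order;
    each claims its nearest remaining training sample without replacement
    and masks it at its own missing positions; rounds over the ordered
    testing list repeat until every training sample is claimed. Masked
    entries are set to code 0 in the returned corrupted copy.
    """
    if te.n_samples == 0:
        raise ValueError("testing set has no samples")
    _check_aligned(tr, te)
    if tr.has_missing():
        raise ValueError("training set (reference panel) must be missing-free")

    te_filled = mean_fill(te, tr)
    dist = cdist(tr.codes.astype(float), te_filled, metric="cityblock")
    order = _mean_distance_order(dist, descending=True)
    pairs = _greedy_match(dist, order, tr.n_samples)

    miss_idx = [np.flatnonzero(te.codes[j] == MISSING) for j in range(te.n_samples)]
    plan = MaskPlan()
    corrupted = tr.codes.copy()
    for i, j in pairs:
        idx = miss_idx[j]
        plan.assignments[i] = (te.sample_ids[j], frozenset(int(x) for x in idx))
        corrupted[i, idx] = MISSING
    return plan, GenotypeMatrix(tr.sample_ids, tr.markers, corrupted, validate=False)


def random_mask(
    tr: GenotypeMatrix, te: GenotypeMatrix, rng: np.random.Generator
) -> tuple[MaskPlan, GenotypeMatrix]:
    """Ablation control: mask each training row uniformly at random with the
    same number of masked entries as the testing set's mean per-sample
    missing count (no matching)."""
    _check_aligned(tr, te)
    n_miss = int(np.round((te.codes == MISSING).sum(axis=1).mean()))
    plan = MaskPlan()
    corrupted = tr.codes.copy()
    for i in range(tr.n_samples):
        idx = rng.choice(tr.n_markers, size=min(n_miss, tr.n_markers), replace=False)
        plan.assignments[i] = ("random", frozenset(int(x) for x in idx))
        corrupted[i, idx] = MISSING
    return plan, GenotypeMatrix(tr.sample_ids, tr.markers, corrupted, validate=False)


def knn_impute(te: GenotypeMatrix, k: int = 5) -> GenotypeMatrix:
    """Fill missing testing genotypes by majority vote among nearest samples.

    Distances are Manhattan on the self mean-filled codes. For each gap the
    vote is over the k nearest other samples with an observed call at that
    marker (vote ties go to the smallest code). A marker missing in every
    sample cannot be voted on and raises an error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if te.n_samples < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples for {k}-NN imputation")
    codes = te.codes
    miss = codes == MISSING
    if not miss.any():
        return te.copy()
    if miss.all(axis=0).any():
        j = int(np.flatnonzero(miss.all(axis=0))[0])
        raise ValueError(f"marker {te.markers[j].key} is missing in every sample")

    filled = codes.astype(float)
    col_mean = np.where(miss, np.nan, filled).astype(float)
    col_mean = np.nanmean(col_mean, axis=0)
    filled[miss] = np.broadcast_to(col_mean, filled.shape)[miss]
    dist = cdist(filled, filled, metric="cityblock")

    out = codes.copy()
    for i in range(te.n_samples):
        gaps = np.flatnonzero(miss[i])
        if gaps.size == 0:
            continue
        order = np.argsort(dist[i], kind="stable")
        order = order[order != i]
        for j in gaps:
            votes = np.zeros(4, dtype=int)
            found = 0
            for nb in order:
                c = codes[nb, j]
                if c != MISSING:
                    votes[c] += 1
                    found += 1
                    if found == k:
                        break
            out[i, j] = int(np.argmax(votes[1:])) + 1  # tie -> smallest code
    return GenotypeMatrix(te.sample_ids, te.markers, out, validate=False)


def general_mask_augment(
    tr: GenotypeMatrix, te: GenotypeMatrix, k: int = 5
) -> AugmentedTrainingSet:
    """Augmented masked-marker generation for general imputation.

    Runs the reconstructive matching to corrupt the panel rows, then
    KNN-imputes the testing set and builds m additional corrupted rows:
    the testing-testing Manhattan matrix (diagonal set to twice its
    maximum so no sample matches itself) orders samples by mean distance
    both descending and ascending; each pass greedily matches every
    arranged sample to its nearest remaining KNN row without replacement
    and stamps the arranged sample's missing pattern onto it, never
    masking positions where the matched row itself was originally missing
    (there the clean value is only a KNN estimate); each row's masks from
    the two passes are unioned. Clean and corrupted panel+augmented stacks
    are returned.
    """
    if te.n_samples < 2:
        raise ValueError("general imputation augmentation needs at least 2 testing samples")
    plan_tr, tr_corr = reconstructive_mask(tr, te)
    te_knn = knn_impute(te, k=k)

    m = te.n_samples
    dist = cdist(te_knn.codes.astype(float), te_knn.codes.astype(float), metric="cityblock")
    np.fill_diagonal(dist, 2.0 * dist.max())

    miss_idx = [set(np.flatnonzero(te.codes[j] == MISSING).tolist()) for j in range(m)]
    masks: list[set[int]] = [set() for _ in range(m)]
    matched_by: list[str] = [""] * m
    for descending in (True, False):
        order = _mean_distance_order(dist, descending=descending)
        pairs = _greedy_match(dist, order, m)
        for i, j in pairs:  # row i receives arranged sample j's pattern
            masks[i] |= miss_idx[j] - miss_idx[i]
            matched_by[i] = matched_by[i] or te.sample_ids[j]

    plan_aug = MaskPlan()
    te_knn_corr = te_knn.codes.copy()
    for i in range(m):
        idx = np.asarray(sorted(masks[i]), dtype=int)
        plan_aug.assignments[i] = (matched_by[i], frozenset(masks[i]))
        te_knn_corr[i, idx] = MISSING

    clean = np.concatenate([tr.codes, te_knn.codes], axis=0)
    corrupted = np.concatenate([tr_corr.codes, te_knn_corr], axis=0)
    origin = ["panel"] * tr.n_samples + ["augmented"] * m
    return AugmentedTrainingSet(clean, corrupted, origin, plan_tr, plan_aug)


# ---------------------------------------------------------------------------
# Plain-loop oracle (test cross-check only)
# ---------------------------------------------------------------------------

def matching_oracle(tr: GenotypeMatrix, te: GenotypeMatrix) -> MaskPlan:
    """Literal, unvectorized transcription of the reconstructive matching
    steps. Kept as an independent cross-check; never used by the pipeline."""
    n, m = tr.n_samples, te.n_samples
    p = tr.n_markers
    # step 2: mean-fill testing samples from training column means
    te_filled = [[0.0] * p for _ in range(m)]
    for jm in range(p):
        col_mean = sum(int(tr.codes[i, jm]) for i in range(n)) / n
        for j in range(m):
            v = int(te.codes[j, jm])
            te_filled[j][jm] = col_mean if v == MISSING else float(v)
    # step 3: Manhattan distance matrix D (n x m)
    D = [[0.0] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            D[i][j] = sum(abs(float(tr.codes[i, jm]) - te_filled[j][jm]) for jm in range(p))
    # steps 4-5: mean distance per testing sample, descending order
    mean_d = [sum(D[i][j] for i in range(n)) / n for j in range(m)]
    order = sorted(range(m), key=lambda j: (-mean_d[j], j))
    # steps 6-7: rounds of greedy nearest-neighbour claiming without replacement
    remaining = set(range(n))
    plan = MaskPlan()
    while remaining:
        for j in order:
            if not remaining:
                break
            best = min(remaining, key=lambda i: (D[i][j], i))
            remaining.discard(best)
            masked = frozenset(
                jm for jm in range(p) if int(te.codes[j, jm]) == MISSING
            )
            plan.assignments[best] = (te.sample_ids[j], masked)
    return plan
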