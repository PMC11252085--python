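import math

import numpy as np
import pytest

from quartetqc import (
    Embedding,
    SimilarityMatrix,
    ValidationError,
    adjusted_rand_index,
    batch_balance,
    compute_snr,
    rmse,
    snr_from_embedding,
    snr_from_similarity,
)
from quartetqc.synthetic_data import SimulationConfig, simulate_multiomics
from conftest import make_dataset


def brute_force_snr(scores, weights, labels, row_vectors=False):
    """Independent oracle: explicit double loop over all sample pairs."""
    scores = np.asarray(scores, float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if not row_vectors:
        p = min(2, scores.shape[1])
        pts = scores[:, :p] * np.sqrt(np.asarray(weights, float)[:p])
    else:
        pts = scores
    labels = list(labels)
    n = len(labels)
    between = within = 0.0
    nb = nw = 0
    for i in range(n):
        for j in range(i + 1, n):
            d2 = float(np.sum((pts[i] - pts[j]) ** 2))
            if labels[i] == labels[j]:
                within += d2
                nw += 1
            else:
                between += d2
                nb += 1
    return 10 * math.log10((between / nb) / (within / nw))


def brute_force_ari(a, b):
    """Independent oracle: pair-agreement counting over all item pairs."""
    n = len(a)
    ss = sd = ds = dd = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = a[i] == a[j]
            same_b = b[i] == b[j]
            ss += same_a and same_b
            sd += same_a and not same_b
            ds += not same_a and same_b
            dd += not same_a and not same_b
    total = ss + sd + ds + dd
    expected = (ss + sd) * (ss + ds) / total
    max_index = ((ss + sd) + (ss + ds)) / 2
    if max_index == expected:
        return 1.0 if sd == ds == 0 else 0.0
    return (ss - expected) / (max_index - expected)


class TestSNRFromEmbedding:
    def test_hand_case_two_groups_1d(self):
        # groups {0,1} and {10,11}: between sum 402 / 4 pairs, within 2 / 2
        e = Embedding(scores=np.array([0.0, 1.0, 10.0, 11.0]), weights=[1.0],
                      group_labels=["a", "a", "b", "b"])
        assert snr_from_embedding(e) == pytest.approx(10 * math.log10(100.5), abs=1e-9)

    def test_matches_brute_force_on_random_embeddings(self):
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            m = rng.integers(2, 5)
            n = rng.integers(2, 4)
            p = rng.integers(1, 4)
            scores = rng.normal(size=(m * n, p))
            weights = rng.random(p) + 0.05
            labels = [f"g{x}" for x in range(m) for _ in range(n)]
            e = Embedding(scores=scores, weights=weights, group_labels=labels)
            worst = max(worst, abs(snr_from_embedding(e)
                                   - brute_force_snr(scores, weights, labels)))
        assert worst < 1e-10

    def test_translation_and_scaling_invariance(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(8, 2))
        labels = ["a"] * 4 + ["b"] * 4
        e = Embedding(scores, [0.7, 0.3], labels)
        base = snr_from_embedding(e)
        shifted = Embedding(scores + 5.0, [0.7, 0.3], labels)
        scaled = Embedding(scores * 3.0, [0.7, 0.3], labels)
        assert snr_from_embedding(shifted) == pytest.approx(base, abs=1e-10)
        assert snr_from_embedding(scaled) == pytest.approx(base, abs=1e-10)

    def test_identical_groups_of_identical_points_degenerate(self):
        e = Embedding(np.zeros((4, 1)), [1.0], ["a", "a", "b", "b"])
        with pytest.raises(ValidationError, match="degenerate"):
            snr_from_embedding(e)

    def test_zero_within_distance_is_infinite_with_warning(self):
        e = Embedding(np.array([0.0, 0.0, 5.0, 5.0]), [1.0],
                      ["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="infinity"):
            assert snr_from_embedding(e) == math.inf

    def test_unequal_replicate_counts_rejected(self):
        e = Embedding(np.arange(5.0), [1.0], ["a", "a", "a", "b", "b"])
        with pytest.raises(ValidationError, match="equal replicate"):
            snr_from_embedding(e)


class TestComputeSNR:
    def test_strong_signal_scores_high(self, quartet_batch):
        assert compute_snr(quartet_batch) > 10.0

    def test_permuted_labels_score_near_zero(self, quartet_batch):
        rng = np.random.default_rng(7)
        donors = np.array(quartet_batch.donor_labels())
        vals = []
        for _ in range(50):
            perm = rng.permutation(len(donors))
            ds = make_dataset(quartet_batch.values.to_numpy()[:, perm],
                              donors.tolist())
            vals.append(compute_snr(ds))
        assert abs(np.median(vals)) < 1.5

    def test_feature_duplication_invariance(self, quartet_batch):
        doubled = make_dataset(
            np.vstack([quartet_batch.values.to_numpy()] * 2),
            [s.donor for s in quartet_batch.samples])
        assert compute_snr(doubled) == pytest.approx(compute_snr(quartet_batch),
                                                     abs=1e-8)

    def test_missing_values_rejected(self, quartet_batch):
        ds = quartet_batch
        ds.values.iloc[0, 0] = np.nan
        with pytest.raises(ValidationError, match="complete"):
            compute_snr(ds)


class TestSNRFromSimilarity:
    def _block_matrix(self, within, between, eps=0.0):
        S = np.full((4, 4), between)
        S[:2, :2] = within
        S[2:, 2:] = within
        S[0, 1] = S[1, 0] = within - eps
        np.fill_diagonal(S, within)
        return S

    def test_perfect_blocks_infinite(self):
        S = self._block_matrix(1.0, 0.0)
        sm = SimilarityMatrix(S, ["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="infinity"):
            assert snr_from_similarity(sm) == math.inf

    def test_matches_brute_force_on_rows(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            A = rng.random((6, 6))
            S = (A + A.T) / 2
            labels = ["a", "a", "b", "b", "c", "c"]
            sm = SimilarityMatrix(S, labels)
            assert snr_from_similarity(sm) == pytest.approx(
                brute_force_snr(S, None, labels, row_vectors=True), abs=1e-10)

    def test_as_printed_is_the_negation(self):
        rng = np.random.default_rng(3)
        A = rng.random((6, 6))
        S = (A + A.T) / 2
        sm = SimilarityMatrix(S, ["a", "a", "b", "b", "c", "c"])
        assert snr_from_similarity(sm, as_printed=True) == pytest.approx(
            -snr_from_similarity(sm), abs=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        A = rng.random((6, 6))
        S = (A + A.T) / 2
        labels = ["a", "a", "b", "b", "c", "c"]
        perm = rng.permutation(6)
        sm = SimilarityMatrix(S, labels)
        smp = SimilarityMatrix(S[np.ix_(perm, perm)],
                               [labels[i] for i in perm])
        assert snr_from_similarity(smp) == pytest.approx(
            snr_from_similarity(sm), abs=1e-10)

    def test_constant_matrix_rejected(self):
        sm = SimilarityMatrix(np.ones((4, 4)), ["a", "a", "b", "b"])
        with pytest.raises(ValidationError, match="constant"):
            snr_from_similarity(sm)


class TestAdjustedRandIndex:
    def test_identical_labelings(self):
        assert adjusted_rand_index([0, 0, 1, 1], ["x", "x", "y", "y"]) == 1.0

    def test_hand_case_minus_half(self):
        assert adjusted_rand_index([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(-0.5)

    def test_one_cluster_vs_singletons_is_zero(self):
        assert adjusted_rand_index([0, 0, 0, 0], [0, 1, 2, 3]) == 0.0

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = rng.integers(2, 13)
            a = rng.integers(0, 4, n).tolist()
            b = rng.integers(0, 4, n).tolist()
            assert adjusted_rand_index(a, b) == pytest.approx(
                brute_force_ari(a, b), abs=1e-12)

    def test_matches_sklearn(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        for _ in range(30):
            a = rng.integers(0, 3, 10)
            b = rng.integers(0, 3, 10)
            assert adjusted_rand_index(a, b) == pytest.approx(
                sklearn_metrics.adjusted_rand_score(a, b), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            adjusted_rand_index([0, 1], [0, 1, 2])


class TestRMSE:
    def test_identity_is_zero(self):
        assert rmse({"f1": 1.0, "f2": 2.0}, {"f1": 1.0, "f2": 2.0}).value == 0.0

    def test_hand_case(self):
        r = rmse({"f1": 1.0, "f2": 2.0}, {"f1": 2.0, "f2": 4.0})
        assert r.value == pytest.approx(math.sqrt(2.5), abs=1e-9)

    def test_coverage_over_shared_features(self):
        r = rmse({"f1": 1.0}, {"f1": 2.0, "f2": 99.0})
        assert r.value == pytest.approx(1.0)
        assert r.n_shared == 1 and r.coverage == 1.0 and r.n_test == 2

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValidationError, match="shared"):
            rmse({"f1": 1.0}, {"f2": 1.0})


class TestBatchBalance:
    def test_identical_batch_sets(self):
        assert batch_balance({d: {"1", "2"} for d in "ABCD"}) == 1.0

    def test_quartet_enumeration(self):
        # D5:{1} D6:{2} F7:{1} M8:{2} -> pairs (0,1,0,0,1,0)/6
        val = batch_balance({"D5": {"1"}, "D6": {"2"}, "F7": {"1"}, "M8": {"2"}})
        assert val == pytest.approx(1 / 3)

    def test_disjoint_singletons(self):
        assert batch_balance({"A": {"1"}, "B": {"2"}, "C": {"3"}}) == 0.0

    def test_empty_batch_set_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            batch_balance({"A": {"1"}, "B": set()})


class TestSNRMonotonicity:
    def test_snr_nondecreasing_in_donor_effect(self):
        import dataclasses
        vals = []
        for sd in (0.0, 0.25, 0.5, 1.0, 2.0):
            cfg = SimulationConfig(seed=123, layers={"rna": 200}, n_batches=1,
                                   donor_effect_sd=sd, twin_divergence_sd=sd / 2,
                                   n_planted_defs=0, n_planted_pairs=0)
            ds = simulate_multiomics(cfg).layers["rna"][0]
            vals.append(compute_snr(ds))
        assert all(b >= a for a, b in zip(vals, vals[1:]))
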