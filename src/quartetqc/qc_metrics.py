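"""Quartet QC statistics: SNR, adjusted Rand index, RMSE, group-batch balance.

The SNR metric asks the one question a multi-group reference design can
answer objectively: is the average distance between different donors'
profiles (signal) large compared with the average distance between technical
replicates of the same donor (noise)?  It is reported in decibels —
10·log10 of the ratio of pair-averaged squared distances — either on a
weighted two-component PCA embedding of the samples or on the rows of a
sample-to-sample similarity matrix produced by an integration tool.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import OmicsDataset, ValidationError

#: Sentinel used in tabular output when the within-group distance is exactly
#: zero and the true SNR is +infinity.
SNR_CAP_DB = 999.0


def cap_snr(value: float) -> float:
    """Clamp an SNR value for tabular output (+inf -> 999 dB sentinel)."""
    return min(value, SNR_CAP_DB) if math.isfinite(value) or value > 0 else value


@dataclass
class Embedding:
    """Sample scores in a low-dimensional space with per-component weights.

    ``scores`` is samples × components; ``weights`` holds one non-negative
    weight per component (for PCA: the explained-variance fractions);
    ``group_labels`` gives the donor of each sample.  SNR requires at least
    two groups with the same replicate count n ≥ 2.
    """

    scores: np.ndarray
    weights: np.ndarray
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        if self.scores.ndim == 1:
            self.scores = self.scores[:, None]
        self.weights = np.asarray(self.weights, float)
        if self.weights.shape[0] != self.scores.shape[1]:
            raise ValidationError("one weight required per embedding component")
        if np.any(self.weights < 0):
            raise ValidationError("component weights must be non-negative")
        if len(self.group_labels) != self.scores.shape[0]:
            raise ValidationError("one group label required per sample")


@dataclass
class SimilarityMatrix:
    """Square sample-to-sample similarity matrix with donor labels."""

    matrix: np.ndarray
    group_labels: list[str]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        n = self.matrix.shape[0]
        if self.matrix.ndim != 2 or self.matrix.shape[1] != n:
            raise ValidationError("similarity matrix must be square")
        if len(self.group_labels) != n:
            raise ValidationError("one group label required per sample")
        if np.max(np.abs(self.matrix - self.matrix.T)) > 1e-8:
            raise ValidationError("similarity matrix must be symmetric (tol 1e-8)")
        if np.any(self.matrix < 0):
            raise ValidationError("similarity matrix must be non-negative")


def _group_index(labels: list[str]) -> tuple[list[str], list[np.ndarray], int]:
    groups = list(dict.fromkeys(labels))
    arr = np.asarray(labels)
    idx = [np.flatnonzero(arr == g) for g in groups]
    sizes = {len(i) for i in idx}
    if len(sizes) != 1:
        raise ValidationError(
            f"SNR requires equal replicate counts per group, got "
            f"{dict((g, len(i)) for g, i in zip(groups, idx))}"
        )
    n = sizes.pop()
    if len(groups) < 2:
        raise ValidationError("SNR requires at least 2 sample groups")
    if n < 2:
        raise ValidationError("SNR requires at least 2 replicates per group")
    return groups, idx, n


def _snr_db(between_sum: float, within_sum: float,
            n_between_pairs: int, n_within_pairs: int) -> float:
    between_avg = between_sum / n_between_pairs
    within_avg = within_sum / n_within_pairs
    if within_avg == 0.0 and between_avg == 0.0:
        raise ValidationError("degenerate embedding: all pairwise distances are zero")
    if within_avg == 0.0:
        warnings.warn("zero within-group distance; SNR is +infinity")
        return math.inf
    return 10.0 * math.log10(between_avg / within_avg)


def _pair_sums(points: np.ndarray, idx: list[np.ndarray]) -> tuple[float, float]:
    """Sum of squared distances over between-group and within-group sample
    pairs, for row vectors ``points`` (weights already folded in)."""
    m = len(idx)
    between = 0.0
    within = 0.0
    for x in range(m):
        px = points[idx[x]]
        d_within = px[:, None, :] - px[None, :, :]
        within += float(np.sum(d_within ** 2)) / 2.0  # each unordered pair once
        for y in range(x + 1, m):
            py = points[idx[y]]
            d = px[:, None, :] - py[None, :, :]
            between += float(np.sum(d ** 2))
    return between, within


def snr_from_embedding(e: Embedding) -> float:
    """SNR (dB) of a weighted embedding.

    Distances use the first two components, each squared difference weighted
    by its component weight; the between-group sum is averaged over
    C(m,2)·n·n ordered cross-group pairs and the within-group sum over
    m·C(n,2) replicate pairs, then SNR = 10·log10(between / within).
    """
    groups, idx, n = _group_index(e.group_labels)
    m = len(groups)
    p = min(2, e.scores.shape[1])
    if not np.any(e.weights[:p] > 0):
        raise ValidationError("at least one positive component weight required")
    pts = e.scores[:, :p] * np.sqrt(e.weights[:p])[None, :]
    between, within = _pair_sums(pts, idx)
    return _snr_db(between, within,
                   n_between_pairs=(m * (m - 1) // 2) * n * n,
                   n_within_pairs=m * (n * (n - 1) // 2))


def compute_snr(ds: OmicsDataset) -> float:
    """SNR (dB) of a dataset via feature-standardized PCA.

    Features are centered and scaled to unit variance (zero-variance features
    dropped with a warning), samples are embedded by PCA, and the first two
    components — weighted by their explained-variance fractions — are scored
    with :func:`snr_from_embedding` against donor labels.
    """
    if ds.n_samples < 3:
        raise ValidationError("SNR requires at least 3 samples")
    if ds.values.isna().any().any():
        raise ValidationError("compute_snr requires a complete matrix; impute first")
    X = ds.values.to_numpy(float).T  # samples x features
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance feature(s) before PCA")
    if keep.sum() < 2:
        raise ValidationError("fewer than 2 informative features for PCA")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    scores = U * s
    var = s ** 2
    weights = var / var.sum()
    emb = Embedding(scores=scores[:, :2], weights=weights[:2],
                    group_labels=ds.donor_labels())
    return snr_from_embedding(emb)


def snr_from_similarity(sm: SimilarityMatrix, as_printed: bool = False) -> float:
    """SNR (dB) of a sample-to-sample similarity matrix.

    Each sample's similarity-matrix row is treated as its profile vector and
    the same pair-count-normalized between/within ratio is applied.  The
    default orientation puts the between-group distance in the numerator so
    that better-separated clusterings score higher; ``as_printed=True``
    inverts the ratio (within-group in the numerator), the literal published
    orientation.
    """
    groups, idx, n = _group_index(sm.group_labels)
    m = len(groups)
    if np.allclose(sm.matrix, sm.matrix.flat[0]):
        raise ValidationError("constant similarity matrix: SNR undefined")
    between, within = _pair_sums(sm.matrix, idx)
    value = _snr_db(between, within,
                    n_between_pairs=(m * (m - 1) // 2) * n * n,
                    n_within_pairs=m * (n * (n - 1) // 2))
    return -value if as_printed else value


# ---------------------------------------------------------------------------
# Adjusted Rand index (Hubert–Arabie, pair-counting contingency form)


def adjusted_rand_index(true_labels, predicted_labels) -> float:
    """Adjusted Rand index between two labelings.

    Pair-counting contingency form: with n_ij the contingency counts,
    a_i / b_j the row/column sums, and comb2(x) = x(x-1)/2,

        ARI = (Σ comb2(n_ij) - E) / (max_index - E),
        E = Σ comb2(a_i)·Σ comb2(b_j) / comb2(n),
        max_index = (Σ comb2(a_i) + Σ comb2(b_j)) / 2.

    1 iff the partitions are identical up to relabeling; ~0 for random
    assignment; can be negative for worse-than-chance agreement.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape or t.ndim != 1:
        raise ValidationError("label vectors must be 1-D and of equal length")
    n = t.size
    if n < 2:
        raise ValidationError("ARI requires at least 2 items")
    _, ti = np.unique(t, return_inverse=True)
    _, pi = np.unique(p, return_inverse=True)
    contingency = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ti, pi), 1)

    def comb2(x):
        return x * (x - 1) // 2

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        # both partitions trivial (all-singletons or one cluster): define as 1
        # when identical, else 0 by the usual convention
        return 1.0 if sum_ij == max_index and sum_a == sum_b else 0.0
    return float((sum_ij - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# RMSE with coverage accounting


@dataclass
class RMSEResult:
    """RMSE over the shared features plus coverage bookkeeping."""

    value: float
    n_shared: int
    n_reference: int
    n_test: int
    provenance: dict = field(default_factory=dict)

    @property
    def coverage(self) -> float:
        """Fraction of reference features present in the test table."""
        return self.n_shared / self.n_reference if self.n_reference else float("nan")

    def __float__(self) -> float:
        return self.value


def rmse(reference: pd.Series | dict, test: pd.Series | dict) -> RMSEResult:
    """Root-mean-square difference over the features shared by both tables.

    Features absent from either side are excluded and counted in the coverage
    report; an empty intersection is an error.
    """
    ref = pd.Series(reference, dtype=float)
    tst = pd.Series(test, dtype=float)
    shared = ref.index.intersection(tst.index)
    if len(shared) == 0:
        raise ValidationError("no shared features between reference and test tables")
    resid = ref.loc[shared].to_numpy() - tst.loc[shared].to_numpy()
    return RMSEResult(
        value=float(np.sqrt(np.mean(resid ** 2))),
        n_shared=len(shared),
        n_reference=len(ref),
        n_test=len(tst),
    )


# ---------------------------------------------------------------------------
# Group-batch balance


def batch_balance(assignments: dict[str, set[str]]) -> float:
    """Mean pairwise Jaccard index of the batch sets each donor appears in.

    1 means every donor was measured in the same batches (fully balanced);
    values near 0 flag donor-batch confounding.  Six pairs for four donors.
    """
    donors = sorted(assignments)
    if len(donors) < 2:
        raise ValidationError("balance requires at least 2 donors")
    for d in donors:
        if not assignments[d]:
            raise ValidationError(f"donor {d!r} has an empty batch set")
    vals = []
    for i in range(len(donors)):
        for j in range(i + 1, len(donors)):
            a, b = set(assignments[donors[i]]), set(assignments[donors[j]])
            vals.append(len(a & b) / len(a | b))
    return float(np.mean(vals))
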