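"""Vertical (cross-omics) integration evaluation.

Builds per-omics sample-affinity networks, fuses them into one consensus
network by cross-diffusion, clusters the fused network with PAM, and scores
the result against the study design's built-in truth: the four donor groups
(ARI_4), the three genetically driven family groups — twin daughters
together, father, mother — (ARI_3), the similarity-matrix SNR, and the mean
twin-block similarity.

The fusion step is a consensus-preserving variant of similarity-network
fusion: each layer's row-normalized network is nudged, through its own
K-nearest-neighbor local kernel, toward the average of the other layers'
networks.  Agreement between layers is therefore a fixed point — fusing
identical networks returns the normalized input — while disagreements are
diffused along each layer's local sample graph.  See docs/methods.md.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core_data import OmicsDataset, ValidationError
from .qc_metrics import SimilarityMatrix, adjusted_rand_index, snr_from_similarity

_BANDWIDTH_FLOOR = 1e-12


@dataclass(frozen=True)
class FusionConfig:
    """Fusion hyperparameters.

    k_neighbors
        Neighborhood size of the local kernels; defaults to round(sqrt(N))
        when built via :meth:`for_n_samples` (K = 3 for the 12-sample Quartet
        batch design).
    alpha
        Bandwidth multiplier of the scaled exponential affinity kernel.
    iterations
        Number of cross-diffusion steps.
    """

    k_neighbors: int = 3
    alpha: float = 0.5
    iterations: int = 10

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValidationError("k_neighbors must be positive")
        if self.alpha <= 0:
            raise ValidationError("alpha must be positive")
        if self.iterations < 1:
            raise ValidationError("iterations must be positive")

    @classmethod
    def for_n_samples(cls, n: int, alpha: float = 0.5, iterations: int = 10) -> "FusionConfig":
        return cls(k_neighbors=max(1, round(math.sqrt(n))), alpha=alpha,
                   iterations=iterations)


def select_top_variable(ds: OmicsDataset, k: int = 1000,
                        standardize: bool = True) -> OmicsDataset:
    """Keep the k features with the largest sample standard deviation, then
    center/scale each to mean 0, sd 1.

    Ties in sd break lexicographically on feature id for determinism.  k
    larger than the feature count keeps everything (with a warning).
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    if ds.values.isna().any().any():
        raise ValidationError("select_top_variable requires a complete matrix")
    sd = ds.values.std(axis=1, ddof=1)
    if k > len(sd):
        warnings.warn(f"k={k} exceeds feature count {len(sd)}; keeping all features")
        k = len(sd)
    order = sorted(zip(-sd.to_numpy(), sd.index))  # descending sd, ascending id
    chosen = [fid for _, fid in order[:k]]
    sub = ds.values.loc[chosen].copy()
    if standardize:
        mu = sub.mean(axis=1)
        sigma = sub.std(axis=1, ddof=1)
        sub = sub.sub(mu, axis=0).div(sigma.replace(0.0, np.nan), axis=0).fillna(0.0)
    return ds.with_values(sub)


def shift_nonnegative(ds: OmicsDataset) -> OmicsDataset:
    """Per feature containing any negative value, add |min| so the feature's
    minimum becomes 0; all-non-negative features are unchanged.  Needed by
    factorization methods that require non-negative inputs."""
    values = ds.values.copy()
    mins = values.min(axis=1)
    neg = mins < 0
    values.loc[neg] = values.loc[neg].sub(mins[neg], axis=0)
    return ds.with_values(values)


def affinity_matrix(ds: OmicsDataset, cfg: FusionConfig) -> SimilarityMatrix:
    """Sample-affinity network from a (standardized) feature matrix.

    Scaled exponential kernel of Euclidean distances with local bandwidth:
    W(i,j) = exp(-d(i,j)^2 / (alpha * eps_ij^2)) where eps_ij averages the
    mean distances of i and j to their K nearest neighbors and d(i,j).  The
    squared bandwidth makes the exponent dimensionless, so affinities are
    invariant to a global rescaling of the feature space.  Symmetric, entries
    in (0, 1], unit diagonal.  Duplicate samples giving zero bandwidth are
    handled by flooring eps at 1e-12 (warned).
    """
    n = ds.n_samples
    if cfg.k_neighbors + 1 > n:
        raise ValidationError(
            f"k_neighbors={cfg.k_neighbors} requires at least {cfg.k_neighbors + 1} samples"
        )
    X = ds.values.to_numpy(float).T  # samples x features
    if np.isnan(X).any():
        raise ValidationError("affinity_matrix requires a complete matrix")
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=2)
    d = np.sqrt(np.maximum(d2, 0.0))
    # mean distance to the K nearest neighbors (self excluded)
    sorted_d = np.sort(d, axis=1)
    eps_i = sorted_d[:, 1:cfg.k_neighbors + 1].mean(axis=1)
    eps = (eps_i[:, None] + eps_i[None, :] + d) / 3.0
    if np.any(eps < _BANDWIDTH_FLOOR):
        warnings.warn("zero local bandwidth (duplicate samples); flooring at 1e-12")
        eps = np.maximum(eps, _BANDWIDTH_FLOOR)
    W = np.exp(-d2 / (cfg.alpha * eps ** 2))
    W = (W + W.T) / 2.0
    return SimilarityMatrix(matrix=W, group_labels=ds.donor_labels(),
                            sample_ids=ds.sample_ids)


def _row_normalized(W: np.ndarray) -> np.ndarray:
    P = W / W.sum(axis=1, keepdims=True)
    return (P + P.T) / 2.0


def _local_kernel(W: np.ndarray, k: int) -> np.ndarray:
    """Row-normalized K-NN sparsification (self always kept).

    Entries tied with the K-th neighbor are all kept, so identical samples
    (exact ties) are treated symmetrically instead of by index order."""
    n = W.shape[0]
    S = np.zeros_like(W)
    for i in range(n):
        off = np.array([j for j in range(n) if j != i])
        vals = W[i, off]
        thresh = np.sort(vals)[::-1][min(k, len(off)) - 1]
        keep = off[vals >= thresh].tolist() + [i]
        S[i, keep] = W[i, keep]
    S = S / S.sum(axis=1, keepdims=True)
    return S


def snf_fuse(networks: list[SimilarityMatrix], cfg: FusionConfig,
             damping: float = 0.5) -> SimilarityMatrix:
    """Fuse per-omics affinity networks into one consensus network.

    Each network is row-normalized and symmetrized; a K-NN local kernel is
    derived per network; then for ``cfg.iterations`` steps every network
    moves toward the average of the other networks, the correction diffused
    through its own local kernel:

        P_v <- P_v + damping * offdiag( S_v (mean_{u != v} P_u - P_v) S_v^T )

    Only off-diagonal structure is exchanged — a sample's self-similarity
    carries no information about sample relationships, and letting it enter
    the block averages would let dense diagonals masquerade as cluster
    cohesion.  The difference term is likewise taken off-diagonal.  The
    fused output is the average of the final networks, symmetrized and
    clipped at zero.  A single network (or identical networks) returns its
    row-normalized symmetrized form unchanged — fusion adds no information
    when the layers already agree.
    """
    if not networks:
        raise ValidationError("no networks to fuse")
    labels = networks[0].group_labels
    n = networks[0].matrix.shape[0]
    for net in networks[1:]:
        if net.matrix.shape[0] != n or net.group_labels != labels:
            raise ValidationError("networks must share the same samples in the same order")
    P = [_row_normalized(net.matrix) for net in networks]
    if len(P) == 1:
        return SimilarityMatrix(matrix=P[0], group_labels=list(labels),
                                sample_ids=networks[0].sample_ids)
    S = [_local_kernel(net.matrix, cfg.k_neighbors) for net in networks]
    m = len(P)

    def offdiag(M: np.ndarray) -> np.ndarray:
        out = M.copy()
        np.fill_diagonal(out, 0.0)
        return out

    for _ in range(cfg.iterations):
        new_P = []
        for v in range(m):
            others = sum(P[u] for u in range(m) if u != v) / (m - 1)
            delta = S[v] @ offdiag(others - P[v]) @ S[v].T
            upd = P[v] + damping * offdiag(delta)
            new_P.append((upd + upd.T) / 2.0)
        P = new_P
    fused = sum(P) / m
    fused = np.clip((fused + fused.T) / 2.0, 0.0, None)
    return SimilarityMatrix(matrix=fused, group_labels=list(labels),
                            sample_ids=networks[0].sample_ids)


# ---------------------------------------------------------------------------
# PAM clustering (classic BUILD + SWAP, deterministic)


def pam_cluster(dissimilarity: np.ndarray, k: int, max_swaps: int = 200) -> np.ndarray:
    """Partitioning around medoids on a dissimilarity matrix.

    Deterministic: the BUILD step seeds the medoids (first medoid minimizes
    total dissimilarity, each next greedily maximizes the cost reduction),
    then SWAP exchanges (medoid, non-medoid) pairs while any exchange lowers
    the total cost.  Returns integer labels 0..k-1.
    """
    D = np.asarray(dissimilarity, float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValidationError("dissimilarity matrix must be square")
    if not 2 <= k < n:
        raise ValidationError(f"cluster count k={k} must satisfy 2 <= k < {n}")

    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, -1
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(current - D[:, j], 0.0).sum()
            if gain > best_gain:
                best_gain, best_j = gain, j
        medoids.append(best_j)

    def cost(meds: list[int]) -> float:
        return float(D[:, meds].min(axis=1).sum())

    best = cost(medoids)
    for _ in range(max_swaps):
        improved = False
        for mi, m in enumerate(list(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = list(medoids)
                trial[mi] = h
                c = cost(trial)
                if c < best - 1e-12:
                    medoids, best, improved = trial, c, True
        if not improved:
            break
    medoids = sorted(medoids)
    return np.argmin(D[:, medoids], axis=1)


@dataclass
class ClusterScore:
    """PAM labels on a fused network and the design-truth scores."""

    predicted: np.ndarray
    ari_4: float
    ari_3: float
    snr_similarity: float


def cluster_and_score(sm: SimilarityMatrix, labels4: list[str],
                      labels3: list[str], k: int) -> ClusterScore:
    """PAM-cluster a similarity matrix and score against both truths.

    PAM runs on dissimilarity 1 - S/max(S) with ``k`` clusters; ARI_4 scores
    the labels against the four donor groups, ARI_3 against the three
    family-based groups (the twin daughters share a label); the
    similarity-matrix SNR uses the four-group labels.
    """
    n = sm.matrix.shape[0]
    if k >= n:
        raise ValidationError(f"k={k} must be below the sample count {n}")
    if len(labels4) != n or len(labels3) != n:
        raise ValidationError("label vectors must match the sample count")
    D = 1.0 - sm.matrix / sm.matrix.max()
    np.fill_diagonal(D, 0.0)
    predicted = pam_cluster(D, k)
    return ClusterScore(
        predicted=predicted,
        ari_4=adjusted_rand_index(labels4, predicted),
        ari_3=adjusted_rand_index(labels3, predicted),
        snr_similarity=snr_from_similarity(
            SimilarityMatrix(sm.matrix, list(labels4), sm.sample_ids)),
    )


def twin_block_similarity(sm: SimilarityMatrix, donor_a: str, donor_b: str) -> float:
    """Mean similarity between the replicates of two donors (the 3×3 = 9
    cross entries in the Quartet design).  Used to quantify how strongly an
    integration pulls the twin daughters together."""
    labels = np.asarray(sm.group_labels)
    ia = np.flatnonzero(labels == donor_a)
    ib = np.flatnonzero(labels == donor_b)
    if ia.size == 0 or ib.size == 0:
        missing = donor_a if ia.size == 0 else donor_b
        raise ValidationError(f"donor {missing!r} absent from similarity matrix")
    return float(sm.matrix[np.ix_(ia, ib)].mean())
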