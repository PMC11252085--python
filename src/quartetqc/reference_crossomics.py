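"""Cross-omics feature-relationship reference construction.

Six-step workflow: pair features of two omics types through shared gene
annotations, align samples by donor and replicate, correlate each pair in
every batch combination (one batch per omics type), classify each
correlation as positive (r ≥ 0.5, P < 0.05), negative (r ≤ -0.5, P < 0.05)
or none, consensus-vote the categories across batch combinations, and
evaluate test datasets against the resulting high-confidence reference by
RMSE and sign agreement.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
import math

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import (
    AnnotationMap,
    CrossOmicsReferenceSet,
    OmicsDataset,
    ValidationError,
)
from .qc_metrics import rmse


@dataclass(frozen=True)
class FeaturePair:
    """Two features of different omics types annotated to the same gene."""

    omics_a: str
    omics_b: str
    feature_a: str
    feature_b: str
    shared_gene: str

    def __post_init__(self) -> None:
        if self.omics_a == self.omics_b:
            raise ValidationError("cross-omics pairs require two distinct omics types")


def pair_features(map_a: AnnotationMap, map_b: AnnotationMap,
                  omics_a: str, omics_b: str) -> list[FeaturePair]:
    """All (feature_a, feature_b) pairs sharing at least one gene, one record
    per shared (pair, gene), deduplicated and deterministically ordered."""
    if len(map_a) == 0 or len(map_b) == 0:
        raise ValidationError("annotation maps must be non-empty")
    genes_a = map_a.by_gene()
    genes_b = map_b.by_gene()
    out = set()
    for gene in set(genes_a) & set(genes_b):
        for fa in genes_a[gene]:
            for fb in genes_b[gene]:
                out.add((fa, fb, gene))
    return [FeaturePair(omics_a, omics_b, fa, fb, g)
            for fa, fb, g in sorted(out)]


def correlate_pair(values_a, values_b) -> tuple[float, float]:
    """Pearson r and two-sided p (t distribution, n-2 df) for two aligned
    per-sample vectors.  Zero variance on either side yields (nan, nan) —
    classified as 'none' with a degenerate flag downstream."""
    x = np.asarray(values_a, float)
    y = np.asarray(values_b, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("aligned vectors must be 1-D and of equal length")
    if x.size < 4:
        raise ValidationError("correlation requires at least 4 paired samples")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValidationError("aligned vectors must not contain missing values")
    if np.std(x) == 0 or np.std(y) == 0:
        return (math.nan, math.nan)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def classify_relationship(r: float, p: float, r_cutoff: float = 0.5,
                          p_cutoff: float = 0.05) -> str:
    """'positive' (r ≥ cutoff, P < cutoff), 'negative' (r ≤ -cutoff,
    P < cutoff), else 'none'.  The rule grid's uncovered cells — significant
    but weak (|r| < cutoff, P < cutoff) and strong but non-significant —
    both map to 'none'.  NaN inputs (degenerate pairs) map to 'none'."""
    if math.isnan(r) or math.isnan(p):
        return "none"
    if not -1.0 <= r <= 1.0 + 1e-12:
        raise ValidationError(f"correlation {r} outside [-1, 1]")
    if p < p_cutoff and r >= r_cutoff:
        return "positive"
    if p < p_cutoff and r <= -r_cutoff:
        return "negative"
    return "none"


def align_samples(ds_a: OmicsDataset, ds_b: OmicsDataset) -> tuple[list[str], list[str]]:
    """Column orders aligning two single-batch datasets by (donor, replicate).

    Replicate pairing is positional within each donor after sorting replicate
    numbers, so two batches with independently numbered replicates still
    align donor-wise.
    """
    def by_donor(ds: OmicsDataset) -> dict[str, list[str]]:
        out: dict[str, list[tuple[int, str]]] = {}
        for s in ds.samples:
            out.setdefault(s.donor, []).append((s.replicate, s.sample_id))
        return {d: [sid for _, sid in sorted(v)] for d, v in out.items()}

    a, b = by_donor(ds_a), by_donor(ds_b)
    donors = sorted(set(a) & set(b))
    if not donors:
        raise ValidationError("datasets share no donors")
    ids_a, ids_b = [], []
    for d in donors:
        k = min(len(a[d]), len(b[d]))
        ids_a.extend(a[d][:k])
        ids_b.extend(b[d][:k])
    return ids_a, ids_b


def correlate_across_batches(batches_a: list[OmicsDataset],
                             batches_b: list[OmicsDataset],
                             pairs: list[FeaturePair],
                             r_cutoff: float = 0.5,
                             p_cutoff: float = 0.05) -> pd.DataFrame:
    """Correlate every feature pair in every (batch_a, batch_b) combination.

    Returns a long table with columns feature_a, feature_b, batch_a, batch_b,
    r, p, category.  Pairs whose features are absent from a combination are
    simply not recorded for it (they count as unobserved in the vote).
    """
    rows = []
    for ds_a, ds_b in itertools.product(batches_a, batches_b):
        ids_a, ids_b = align_samples(ds_a, ds_b)
        A = ds_a.values[ids_a]
        B = ds_b.values[ids_b]
        batch_a = ds_a.batches[0]
        batch_b = ds_b.batches[0]
        for pair in pairs:
            if pair.feature_a not in A.index or pair.feature_b not in B.index:
                continue
            x = A.loc[pair.feature_a].to_numpy(float)
            y = B.loc[pair.feature_b].to_numpy(float)
            if np.isnan(x).any() or np.isnan(y).any():
                continue
            r, p = correlate_pair(x, y)
            rows.append({
                "feature_a": pair.feature_a,
                "feature_b": pair.feature_b,
                "batch_a": batch_a,
                "batch_b": batch_b,
                "r": r,
                "p": p,
                "category": classify_relationship(r, p, r_cutoff, p_cutoff),
            })
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "batch_a",
                                       "batch_b", "r", "p", "category"])


def presence_threshold(n_batches_a: int, n_batches_b: int,
                       rate_a: float, rate_b: float,
                       rounding: str = "ceil") -> int:
    """Minimum batch-combination count for a pair to enter the vote: the
    product of each omics type's (batch count × presence rate), rounded up
    by default (``rounding='floor'`` rounds down)."""
    op = math.ceil if rounding == "ceil" else math.floor
    if rounding not in ("ceil", "floor"):
        raise ValidationError(f"unknown rounding {rounding!r}")
    return int(op(rate_a * n_batches_a)) * int(op(rate_b * n_batches_b))


def build_crossomics_reference(correlations: pd.DataFrame,
                               omics_pair: tuple[str, str],
                               n_batches_a: int, n_batches_b: int,
                               rate_a: float, rate_b: float,
                               vote_threshold: float = 0.7,
                               rounding: str = "ceil") -> CrossOmicsReferenceSet:
    """Consensus-vote per-combination correlations into a reference set.

    (1) keep pairs observed in more than the presence threshold of batch
    combinations; (2) per pair, the fraction of its observed combinations in
    each signed category; (3) when the positive or negative fraction exceeds
    ``vote_threshold``, emit the pair with reference_r = mean r over exactly
    the combinations in that category.
    """
    thr = presence_threshold(n_batches_a, n_batches_b, rate_a, rate_b, rounding)
    records = []
    if len(correlations):
        grouped = correlations.groupby(["feature_a", "feature_b"], sort=True)
        for (fa, fb), sub in grouped:
            n_obs = len(sub)
            if n_obs <= thr:
                continue
            for category in ("positive", "negative"):
                in_cat = sub[sub["category"] == category]
                support = len(in_cat) / n_obs
                if support > vote_threshold:
                    records.append({
                        "feature_a": fa,
                        "feature_b": fb,
                        "category": category,
                        "reference_r": float(in_cat["r"].mean()),
                        "support_fraction": support,
                    })
    frame = pd.DataFrame(records, columns=[
        "feature_a", "feature_b", "category", "reference_r", "support_fraction"])
    return CrossOmicsReferenceSet(
        omics_pair=omics_pair,
        records=frame,
        provenance={
            "n_batches": [n_batches_a, n_batches_b],
            "presence_rates": [rate_a, rate_b],
            "presence_threshold_combinations": thr,
            "vote_threshold": vote_threshold,
            "rounding": rounding,
        },
    )


def evaluate_crossomics(test_r: pd.Series | dict,
                        reference: CrossOmicsReferenceSet):
    """Score a test dataset's pair correlations against the reference.

    ``test_r`` maps (feature_a, feature_b) to a Pearson r.  Returns
    (RMSEResult, sign-agreement fraction over shared pairs).
    """
    ref = reference.r_series()
    tst = pd.Series(test_r, dtype=float)
    result = rmse(ref, tst)
    shared = ref.index.intersection(tst.index)
    agree = np.sign(ref.loc[shared].to_numpy()) == np.sign(tst.loc[shared].to_numpy())
    return result, float(np.mean(agree))
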