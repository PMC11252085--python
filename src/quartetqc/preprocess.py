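"""Preprocessing rules for quantitative omics tables.

Covers flooring + log2 transform, the multi-batch detection filter,
iterative-PCA imputation of missing values, technical-replicate CV,
binary genotype encoding, and promoter-level collapsing of methylation
probes to genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_data import (
    AnnotationMap,
    OmicsDataset,
    SampleMeta,
    ValidationError,
)

GENOTYPE_CALLS = ("hom_ref", "het", "hom_alt", "missing")


@dataclass
class GenotypeTable:
    """Genotype calls per locus per sample.

    ``calls`` is a DataFrame indexed by locus id with one column per sample;
    entries are 'hom_ref', 'het', 'hom_alt' or 'missing' (NaN also counts as
    missing).
    """

    calls: pd.DataFrame
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            dups = self.calls.index[self.calls.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate locus ids: {dups[:5]}")
        if len(self.samples) != self.calls.shape[1]:
            raise ValidationError("one SampleMeta required per genotype column")
        tokens = set(pd.unique(self.calls.values.ravel()))
        bad = {t for t in tokens if not (t is None or (isinstance(t, float) and np.isnan(t)))
               and t not in GENOTYPE_CALLS}
        if bad:
            raise ValidationError(f"unknown genotype call token(s): {sorted(map(str, bad))}")


def load_genotype_table(path: str | Path, meta_path: str | Path) -> GenotypeTable:
    """Read a wide TSV (locus id column + one column per sample) and the
    matching sample metadata TSV."""
    meta = pd.read_csv(meta_path, sep="\t", dtype=str, comment="#")
    calls = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    calls = calls.replace("", "missing")
    samples = [
        SampleMeta(sample_id=row.sample_id, donor=row.donor,
                   replicate=int(row.replicate), batch=row.batch)
        for row in meta.itertuples()
    ]
    ids = [s.sample_id for s in samples]
    if sorted(calls.columns) != sorted(ids):
        raise ValidationError("genotype columns do not match metadata sample ids")
    return GenotypeTable(calls=calls[ids], samples=samples)


# ---------------------------------------------------------------------------


def floor_log2(values: pd.DataFrame, floor: float = 0.01) -> pd.DataFrame:
    """log2(value + floor) on a linear-scale table; missing stays missing.

    The floor keeps zero counts finite (log2(0 + 0.01) ≈ -6.64).  Negative
    inputs are a unit error upstream and are rejected with the offending cell
    named.
    """
    if floor <= 0:
        raise ValidationError("floor must be positive")
    arr = values.to_numpy(float)
    neg = np.argwhere(arr < 0)
    if neg.size:
        i, j = neg[0]
        raise ValidationError(
            f"negative linear-scale value {arr[i, j]!r} at "
            f"feature {values.index[i]!r}, sample {values.columns[j]!r}"
        )
    return pd.DataFrame(np.log2(arr + floor), index=values.index, columns=values.columns)


def filter_detection(ds: OmicsDataset, detection_rate: float = 0.9,
                     methylation_strict: bool | None = None) -> OmicsDataset:
    """Drop under-detected features.

    Default rule: keep a feature when it is detected (non-missing) in strictly
    more than ``detection_rate`` of the samples.  In strict mode — the default
    for methylation, where any missing value disqualifies the feature — a
    single missing value drops it.  Idempotent.
    """
    if ds.n_samples < 1:
        raise ValidationError("dataset has no samples")
    if methylation_strict is None:
        methylation_strict = ds.omics_type == "methylation"
    observed = ds.values.notna()
    if methylation_strict:
        keep = observed.all(axis=1)
    else:
        keep = (observed.mean(axis=1) > detection_rate)
    if not keep.any():
        warnings.warn("detection filter removed every feature")
    return ds.with_values(ds.values.loc[keep[keep].index].copy())


def impute_iterative_pca(ds: OmicsDataset, n_components: int | str = 2,
                         tol: float = 1e-6, max_iter: int = 500,
                         random_state: int = 0) -> OmicsDataset:
    """Fill missing values by iterative low-rank (PCA/SVD) completion.

    Missing cells start at their feature means; the matrix is then repeatedly
    replaced on the missing cells by its rank-``n_components`` reconstruction
    (feature-mean centered) until the largest change on a missing cell falls
    below ``tol`` or ``max_iter`` iterations pass (then: warning + best
    iterate).  Observed cells are never altered.

    ``n_components='auto'`` selects the rank (1..5) by masking a random 10%
    of the observed cells and picking the rank that reconstructs them best.
    """
    X = ds.values.to_numpy(float)
    missing = np.isnan(X)
    if not missing.any():
        return ds.with_values(ds.values.copy())
    if missing.all(axis=1).any():
        bad = ds.values.index[missing.all(axis=1)][0]
        raise ValidationError(f"feature {bad!r} has no observed values")
    if missing.all(axis=0).any():
        bad = ds.values.columns[missing.all(axis=0)][0]
        raise ValidationError(f"sample {bad!r} has no observed values")
    frac = missing.mean()
    if frac >= 0.5:
        raise ValidationError(f"{frac:.0%} of cells missing; imputation requires < 50%")

    if n_components == "auto":
        n_components = _select_rank_by_holdout(X, missing, random_state)
    k = int(n_components)

    filled = _complete(X, missing, k, tol, max_iter)
    out = pd.DataFrame(filled, index=ds.values.index, columns=ds.values.columns)
    return ds.with_values(out)


def _complete(X: np.ndarray, missing: np.ndarray, k: int,
              tol: float, max_iter: int) -> np.ndarray:
    filled = X.copy()
    row_means = np.nanmean(X, axis=1)
    filled[missing] = np.broadcast_to(row_means[:, None], X.shape)[missing]
    for _ in range(max_iter):
        mu = filled.mean(axis=1, keepdims=True)
        centered = filled - mu
        U, s, Vt = np.linalg.svd(centered, full_matrices=False)
        recon = (U[:, :k] * s[:k]) @ Vt[:k] + mu
        delta = np.max(np.abs(recon[missing] - filled[missing])) if missing.any() else 0.0
        filled[missing] = recon[missing]
        if delta < tol:
            break
    else:
        warnings.warn(f"imputation did not converge in {max_iter} iterations "
                      f"(last change {delta:.2e}); returning best iterate")
    return filled


def _select_rank_by_holdout(X: np.ndarray, missing: np.ndarray,
                            random_state: int) -> int:
    rng = np.random.default_rng(random_state)
    obs = np.argwhere(~missing)
    n_hold = max(1, int(0.1 * len(obs)))
    hold = obs[rng.choice(len(obs), size=n_hold, replace=False)]
    mask = missing.copy()
    mask[hold[:, 0], hold[:, 1]] = True
    # guard: do not hold out a row/column's last observation
    ok = ~mask.all(axis=1).any() and ~mask.all(axis=0).any()
    if not ok:
        return 2
    best_k, best_err = 2, np.inf
    kmax = min(5, min(X.shape) - 1)
    for k in range(1, max(2, kmax) + 1):
        filled = _complete(X, mask, k, 1e-5, 200)
        err = float(np.mean((filled[hold[:, 0], hold[:, 1]] -
                             X[hold[:, 0], hold[:, 1]]) ** 2))
        if err < best_err:
            best_k, best_err = k, err
    return best_k


def replicate_cv(ds: OmicsDataset, on_linear_scale: bool = True) -> pd.DataFrame:
    """Coefficient of variation across technical replicates.

    Returns a tidy table (feature, donor, batch, cv) with cv = sample standard
    deviation / mean per feature within each (donor, batch) replicate group.
    By default values are back-transformed from log2 to the linear scale first
    (the CV bench scientists report); ``on_linear_scale=False`` computes it on
    the stored values.  Groups with mean 0 yield missing CV (warned).
    """
    groups: dict[tuple[str, str], list[str]] = {}
    for s in ds.samples:
        groups.setdefault((s.donor, s.batch), []).append(s.sample_id)
    for (donor, batch), ids in groups.items():
        if len(ids) < 2:
            raise ValidationError(
                f"donor {donor!r} batch {batch!r} has {len(ids)} replicate(s); ≥2 required"
            )
    rows = []
    n_zero_mean = 0
    for (donor, batch), ids in groups.items():
        sub = ds.values[ids].to_numpy(float)
        if on_linear_scale:
            sub = np.power(2.0, sub)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(sub, axis=1)
            sd = np.nanstd(sub, axis=1, ddof=1)
        cv = np.where(mean == 0, np.nan, sd / np.where(mean == 0, np.nan, mean))
        n_zero_mean += int(np.sum(mean == 0))
        rows.append(pd.DataFrame({
            "feature_id": ds.values.index,
            "donor": donor,
            "batch": batch,
            "cv": cv,
        }))
    if n_zero_mean:
        warnings.warn(f"{n_zero_mean} feature-group(s) had mean 0; CV reported as missing")
    return pd.concat(rows, ignore_index=True)


def encode_genotypes(gt: GenotypeTable) -> OmicsDataset:
    """Binary-encode genotypes for vertical integration with quantitative
    layers: homozygous-reference -> 0, any alternate-containing genotype
    (het or hom-alt) -> 1, missing stays missing."""
    mapping = {"hom_ref": 0.0, "het": 1.0, "hom_alt": 1.0, "missing": np.nan}
    values = gt.calls.apply(lambda col: col.map(mapping)).astype(float)
    return OmicsDataset(values=values, samples=list(gt.samples), omics_type="dna")


def collapse_promoter_methylation(ds: OmicsDataset,
                                  probe_to_gene: AnnotationMap) -> OmicsDataset:
    """Collapse promoter-probe M values to gene level by the arithmetic mean
    of each gene's mapped probes per sample (missing probes omitted from the
    mean).  Genes with no mapped probe present in the dataset are absent from
    the output.  The map should be restricted to promoter probes upstream."""
    feats = set(ds.feature_ids)
    out_rows, out_index = [], []
    for gene, probes in sorted(probe_to_gene.by_gene().items()):
        present = sorted(probes & feats)
        if not present:
            continue
        out_rows.append(ds.values.loc[present].mean(axis=0, skipna=True))
        out_index.append(gene)
    values = pd.DataFrame(out_rows, index=out_index, columns=ds.values.columns)
    return ds.with_values(values)
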