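"""Differential-feature calling and consensus reference construction.

A differential feature (DEF) between two donors is called per batch by a
two-sided Welch t-test on the log-scale replicate values combined with a
log2 fold-change cutoff — deliberately an unadjusted P cutoff with
fold-change ranking (the MAQC recommendation for small-replicate designs);
no multiple-testing correction is applied here.  Reference DEF sets are then
built by consensus voting across batches: a feature enters the reference
when it is called with a consistent direction in more than the voting
threshold of the batches where it was quantifiable, and its reference log2
fold change is the mean over exactly those batches.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import OmicsDataset, OmicsTypeConfig, ReferenceDEFSet, ValidationError
from .qc_metrics import RMSEResult, rmse


def intrabatch_qc_filter(ds: OmicsDataset, cfg: OmicsTypeConfig) -> OmicsDataset:
    """Intra-batch QC before the consensus vote.

    A feature is dropped when, in ANY donor's replicate group of this batch,
    it is missing in more than one technical replicate or its replicate CV
    (linear scale) exceeds ``cfg.cv_cutoff``.  Requires a single batch with
    at least two replicates per donor.
    """
    if len(ds.batches) != 1:
        raise ValidationError(
            f"intra-batch QC expects a single batch, got {ds.batches}"
        )
    groups: dict[str, list[str]] = {}
    for s in ds.samples:
        groups.setdefault(s.donor, []).append(s.sample_id)
    for donor, ids in groups.items():
        if len(ids) < 2:
            raise ValidationError(f"donor {donor!r} has fewer than 2 replicates")
    keep = pd.Series(True, index=ds.values.index)
    for donor, ids in groups.items():
        sub = ds.values[ids]
        n_missing = sub.isna().sum(axis=1)
        keep &= n_missing <= 1
        linear = np.power(2.0, sub.to_numpy(float))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(linear, axis=1)
            sd = np.nanstd(linear, axis=1, ddof=1)
            cv = np.where(mean > 0, sd / np.where(mean > 0, mean, np.nan), np.inf)
        keep &= pd.Series(cv <= cfg.cv_cutoff, index=ds.values.index)
    return ds.with_values(ds.values.loc[keep[keep].index].copy())


def call_defs(ds: OmicsDataset, contrast: tuple[str, str],
              cfg: OmicsTypeConfig) -> pd.DataFrame:
    """Call differential features for one ordered donor contrast in one batch.

    Returns a table with columns feature_id, lfc, p_value, direction
    ('up'/'down'/'none') and degenerate (True when both groups had zero
    variance, making the test undefined; such features never become DEFs).
    lfc = mean(first donor) - mean(second donor) on the stored log scale.
    """
    a, b = contrast
    ids_a = ds.sample_ids_for(donor=a)
    ids_b = ds.sample_ids_for(donor=b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValidationError(
            f"contrast {contrast} needs ≥2 replicates per donor "
            f"(got {len(ids_a)} and {len(ids_b)})"
        )
    X = ds.values[ids_a].to_numpy(float)
    Y = ds.values[ids_b].to_numpy(float)
    lfc = np.nanmean(X, axis=1) - np.nanmean(Y, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(X, Y, axis=1, equal_var=False, nan_policy="omit")
    p = np.asarray(res.pvalue, float)
    degenerate = ~np.isfinite(p)
    direction = np.full(len(lfc), "none", dtype=object)
    sig = (~degenerate) & (p < cfg.def_p_cutoff)
    direction[sig & (lfc >= cfg.def_lfc_cutoff)] = "up"
    direction[sig & (lfc <= -cfg.def_lfc_cutoff)] = "down"
    return pd.DataFrame({
        "feature_id": ds.values.index,
        "lfc": lfc,
        "p_value": p,
        "direction": direction,
        "degenerate": degenerate,
    })


def build_def_reference(per_batch_calls: list[tuple[str, pd.DataFrame]],
                        cfg: OmicsTypeConfig,
                        contrast: tuple[str, str],
                        vote_threshold: float = 0.7,
                        denominator: str = "quantifiable") -> ReferenceDEFSet:
    """Consensus-vote per-batch DEF calls into a reference set.

    Steps: (1) keep features quantifiable (present in the batch's post-QC
    call table) in more than ``cfg.batch_presence_rate`` of the batches;
    (2) per feature, find the fraction of batches calling it DEF with the
    same direction — the denominator is the feature's quantifiable batches
    (``denominator='all'`` uses the total batch count instead); (3) when that
    fraction exceeds ``vote_threshold``, emit the feature with its direction
    and reference_lfc = mean lfc over exactly the batches voting that
    direction.  With a threshold above 0.5 conflicting directions cannot both
    qualify.  Batch order is irrelevant.
    """
    if len(per_batch_calls) < 3:
        raise ValidationError("consensus voting requires at least 3 batches")
    if denominator not in ("quantifiable", "all"):
        raise ValidationError(f"unknown denominator {denominator!r}")
    n_batches = len(per_batch_calls)
    batch_names = [b for b, _ in per_batch_calls]
    if len(set(batch_names)) != n_batches:
        raise ValidationError("duplicate batch names in per-batch calls")

    presence: dict[str, int] = {}
    votes: dict[str, dict[str, list[float]]] = {}
    for _, calls in per_batch_calls:
        tab = calls.set_index("feature_id")
        for f in tab.index:
            presence[f] = presence.get(f, 0) + 1
        for f, row in tab.iterrows():
            if row["direction"] in ("up", "down"):
                votes.setdefault(f, {}).setdefault(row["direction"], []).append(
                    float(row["lfc"])
                )

    records = []
    for f in sorted(presence):
        quantifiable = presence[f]
        if quantifiable / n_batches <= cfg.batch_presence_rate:
            continue
        denom = quantifiable if denominator == "quantifiable" else n_batches
        for direction in ("up", "down"):
            lfcs = votes.get(f, {}).get(direction, [])
            support = len(lfcs) / denom
            if support > vote_threshold:
                records.append({
                    "feature_id": f,
                    "direction": direction,
                    "reference_lfc": float(np.mean(lfcs)),
                    "support_fraction": support,
                })
    frame = pd.DataFrame(records, columns=[
        "feature_id", "direction", "reference_lfc", "support_fraction"])
    return ReferenceDEFSet(
        contrast=contrast,
        records=frame,
        provenance={
            "n_batches": n_batches,
            "batches": sorted(batch_names),
            "vote_threshold": vote_threshold,
            "denominator": denominator,
            "batch_presence_rate": cfg.batch_presence_rate,
            "def_p_cutoff": cfg.def_p_cutoff,
            "def_lfc_cutoff": cfg.def_lfc_cutoff,
        },
    )


def evaluate_defs(test_lfc: pd.Series | dict, reference: ReferenceDEFSet,
                  contrast: tuple[str, str] | None = None) -> RMSEResult:
    """RMSE of a test dataset's log2 fold changes against the reference set.

    ``contrast`` (numerator, denominator) must match the reference's stored
    orientation when given — a reversed contrast would silently flip every
    sign, so it is rejected instead.
    """
    if contrast is not None and tuple(contrast) != tuple(reference.contrast):
        raise ValidationError(
            f"contrast mismatch: test {tuple(contrast)} vs reference "
            f"{tuple(reference.contrast)}"
        )
    result = rmse(reference.lfc_series(), pd.Series(test_lfc, dtype=float))
    result.provenance["contrast"] = tuple(reference.contrast)
    return result
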