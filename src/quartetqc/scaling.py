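"""Horizontal-integration transforms.

Absolute profiles of the same specimen are not reproducible across batches
because the instrument sensitivity f in I = f(C) drifts with platform,
reagent lot and lab.  When a common reference sample is profiled in every
batch, dividing by it (subtracting in log space) cancels f exactly for
multiplicative sensitivity, leaving the biologically meaningful ratio
C_study / C_reference.  This module implements that ratio scaling, the
per-batch z-score alternative, and batch merging.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_data import OmicsDataset, SampleMeta, ValidationError


def ratio_scale(ds: OmicsDataset, reference_donor: str) -> OmicsDataset:
    """Convert log-scale absolute profiles to ratios against a reference donor.

    For each batch and feature, the mean of the reference donor's replicates
    (over observed values) is subtracted from every sample of that batch —
    including the reference replicates themselves, whose values become
    deviations from their own mean, so downstream four-group statistics stay
    computable.  Features with no observed reference value in a batch become
    missing in that batch.
    """
    if ds.scale != "absolute":
        raise ValidationError(
            f"ratio_scale expects absolute-scale input, got scale={ds.scale!r}"
        )
    for batch in ds.batches:
        if not ds.sample_ids_for(donor=reference_donor, batch=batch):
            raise ValidationError(
                f"batch {batch!r} has no replicate of reference donor {reference_donor!r}"
            )
    out = ds.values.copy()
    for batch in ds.batches:
        batch_ids = ds.sample_ids_for(batch=batch)
        ref_ids = ds.sample_ids_for(donor=reference_donor, batch=batch)
        ref_mean = ds.values[ref_ids].mean(axis=1, skipna=True)  # NaN where no ref observed
        out[batch_ids] = ds.values[batch_ids].sub(ref_mean, axis=0)
    return ds.with_values(out, scale="ratio", reference_donor=reference_donor)


def zscore_by_batch(ds: OmicsDataset) -> OmicsDataset:
    """Standardize each feature within each batch (mean 0, sample sd 1).

    Features with zero within-batch sd are set to 0 for that batch.
    """
    for batch in ds.batches:
        if len(ds.sample_ids_for(batch=batch)) < 2:
            raise ValidationError(f"batch {batch!r} has fewer than 2 samples")
    out = ds.values.copy()
    for batch in ds.batches:
        ids = ds.sample_ids_for(batch=batch)
        sub = ds.values[ids]
        mean = sub.mean(axis=1, skipna=True)
        sd = sub.std(axis=1, ddof=1, skipna=True)
        z = sub.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
        zero_sd = sd == 0
        z.loc[zero_sd] = z.loc[zero_sd].where(sub.loc[zero_sd].isna(), 0.0)
        out[ids] = z
    return ds.with_values(out, scale="zscore")


def merge_batches(datasets: list[OmicsDataset],
                  feature_policy: str = "intersection") -> OmicsDataset:
    """Merge per-batch datasets of one omics type into a single table.

    ``intersection`` keeps features present in every batch; ``union`` keeps
    all features, filling absences with missing values (to be handled by the
    detection filter / imputation downstream).  Mixing scales — e.g. absolute
    with ratio — is an error.  Sample ids are prefixed with their batch when
    needed to stay unique.
    """
    if not datasets:
        raise ValidationError("no datasets to merge")
    if feature_policy not in ("intersection", "union"):
        raise ValidationError(f"unknown feature_policy {feature_policy!r}")
    first = datasets[0]
    for d in datasets[1:]:
        if d.omics_type != first.omics_type:
            raise ValidationError("cannot merge datasets of different omics types")
        if d.scale != first.scale:
            raise ValidationError(
                f"cannot merge datasets of different scales ({first.scale!r} vs {d.scale!r})"
            )
        if d.scale == "ratio" and d.reference_donor != first.reference_donor:
            raise ValidationError("ratio datasets use different reference donors")

    if feature_policy == "intersection":
        feats = set(first.feature_ids)
        for d in datasets[1:]:
            feats &= set(d.feature_ids)
        index = [f for f in first.feature_ids if f in feats]
    else:
        seen: dict[str, None] = {}
        for d in datasets:
            for f in d.feature_ids:
                seen.setdefault(f)
        index = list(seen)

    all_ids = [sid for d in datasets for sid in d.sample_ids]
    prefix = len(set(all_ids)) != len(all_ids)

    blocks, samples = [], []
    for d in datasets:
        block = d.values.reindex(index)
        if prefix:
            rename = {s.sample_id: f"{s.batch}_{s.sample_id}" for s in d.samples}
            block = block.rename(columns=rename)
            metas = [SampleMeta(rename[s.sample_id], s.donor, s.replicate, s.batch)
                     for s in d.samples]
        else:
            metas = list(d.samples)
        blocks.append(block)
        samples.extend(metas)
    values = pd.concat(blocks, axis=1)
    return OmicsDataset(values=values, samples=samples, omics_type=first.omics_type,
                        scale=first.scale, reference_donor=first.reference_donor)
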