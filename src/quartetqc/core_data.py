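"""Core containers and text-table IO for quantitative omics profiling.

The universal currency of the toolkit is the :class:`OmicsDataset`: a
feature-by-sample matrix of log-scale abundances (methylation M values,
log2 CPM, log2 FPKM, log2 FOT, log2 intensity) together with per-sample
metadata — donor, technical replicate, batch — and an omics-type tag.
Everything is plain TSV/JSON so artifacts stay inspectable as text.

Donor, replicate and batch labels are free strings/integers; the Quartet
family names (D5/D6 twin daughters, father F7, mother M8) are defaults of
the synthetic generator, not assumptions of the containers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

OMICS_TYPES = ("methylation", "mirna", "rna", "protein", "metabolite", "dna")
SCALES = ("absolute", "ratio", "zscore")

#: Quartet donor labels used as defaults throughout (twin daughters, father, mother).
QUARTET_DONORS = ("D5", "D6", "F7", "M8")


class ValidationError(ValueError):
    """Raised when a dataset, table or reference set violates its contract."""


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one profiled sample: which donor, which technical replicate,
    which batch (lab/platform/run)."""

    sample_id: str
    donor: str
    replicate: int
    batch: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("sample_id must be non-empty")
        if int(self.replicate) < 1:
            raise ValidationError(
                f"replicate must be a positive integer, got {self.replicate!r} "
                f"for sample {self.sample_id!r}"
            )


@dataclass
class OmicsDataset:
    """Feature-by-sample value table plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample, in the
        same order as ``samples``.  Values are on the per-omics log scale;
        missing entries are NaN.
    samples
        One :class:`SampleMeta` per value column.
    omics_type
        One of methylation, mirna, rna, protein, metabolite, dna.
    scale
        'absolute' (as measured), 'ratio' (relative to a reference donor's
        within-batch replicate mean) or 'zscore' (per-feature per-batch).
    reference_donor
        Recorded when ``scale == 'ratio'``: the donor used as the common
        reference sample.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    omics_type: str
    scale: str = "absolute"
    reference_donor: str | None = None

    def __post_init__(self) -> None:
        if self.omics_type not in OMICS_TYPES:
            raise ValidationError(
                f"unknown omics_type {self.omics_type!r}; expected one of {OMICS_TYPES}"
            )
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.scale == "ratio" and not self.reference_donor:
            raise ValidationError("ratio-scale datasets must record the reference donor")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        if len(self.samples) != self.values.shape[1]:
            raise ValidationError(
                f"{self.values.shape[1]} value columns but {len(self.samples)} "
                "sample metadata rows"
            )
        col_ids = list(self.values.columns)
        meta_ids = [s.sample_id for s in self.samples]
        if col_ids != meta_ids:
            extra = sorted(set(col_ids) - set(meta_ids))
            missing = sorted(set(meta_ids) - set(col_ids))
            raise ValidationError(
                f"value columns do not match sample metadata; "
                f"columns without metadata: {extra}; metadata without columns: {missing}"
            )
        triples = [(s.donor, s.replicate, s.batch) for s in self.samples]
        if len(set(triples)) != len(triples):
            seen, dup = set(), None
            for t in triples:
                if t in seen:
                    dup = t
                    break
                seen.add(t)
            raise ValidationError(f"duplicate (donor, replicate, batch) triple: {dup}")

    # -- convenience views -------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def donors(self) -> list[str]:
        """Distinct donors in first-appearance order."""
        return list(dict.fromkeys(s.donor for s in self.samples))

    @property
    def batches(self) -> list[str]:
        """Distinct batches in first-appearance order."""
        return list(dict.fromkeys(s.batch for s in self.samples))

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def meta_frame(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame (one row per sample, in column order)."""
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "donor": [s.donor for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
                "batch": [s.batch for s in self.samples],
            }
        )

    def sample_ids_for(self, donor: str | None = None, batch: str | None = None) -> list[str]:
        out = []
        for s in self.samples:
            if donor is not None and s.donor != donor:
                continue
            if batch is not None and s.batch != batch:
                continue
            out.append(s.sample_id)
        return out

    def subset(
        self,
        features: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "OmicsDataset":
        values = self.values
        samples = self.samples
        if features is not None:
            values = values.loc[list(features)]
        if sample_ids is not None:
            keep = list(sample_ids)
            values = values[keep]
            by_id = {s.sample_id: s for s in self.samples}
            samples = [by_id[sid] for sid in keep]
        return OmicsDataset(
            values=values.copy(),
            samples=list(samples),
            omics_type=self.omics_type,
            scale=self.scale,
            reference_donor=self.reference_donor,
        )

    def with_values(self, values: pd.DataFrame, scale: str | None = None,
                    reference_donor: str | None = None) -> "OmicsDataset":
        """Copy carrying new values (and optionally a new scale tag)."""
        return OmicsDataset(
            values=values,
            samples=list(self.samples),
            omics_type=self.omics_type,
            scale=self.scale if scale is None else scale,
            reference_donor=self.reference_donor if reference_donor is None else reference_donor,
        )

    def donor_labels(self) -> list[str]:
        return [s.donor for s in self.samples]


# ---------------------------------------------------------------------------
# Per-omics threshold configuration


@dataclass(frozen=True)
class OmicsTypeConfig:
    """Declarative per-omics thresholds.

    cv_cutoff
        Replicate coefficient-of-variation above which a feature is dropped
        in intra-batch QC (0.15 for methylation, 0.3 otherwise).
    def_p_cutoff, def_lfc_cutoff
        Differential-feature rule: two-sided Welch P below the cutoff AND
        |log2 fold change| at or above the cutoff (0.5; 2 for M values).
    batch_presence_rate
        Fraction of batches a feature must be quantifiable in to enter the
        cross-batch vote (0.7 methylation/miRNA/RNA, 0.3 protein/metabolite).
    detection_rate
        Multi-batch detection filter: keep features detected in strictly
        more than this fraction of samples (0.9).
    floor_value
        Linear-scale offset added before log2 transform (0.01 for CPM/FPKM),
        or None where no flooring is applied.
    """

    cv_cutoff: float = 0.3
    def_p_cutoff: float = 0.05
    def_lfc_cutoff: float = 0.5
    batch_presence_rate: float = 0.7
    detection_rate: float = 0.9
    floor_value: float | None = None

    def __post_init__(self) -> None:
        for name in ("batch_presence_rate", "detection_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("cv_cutoff", "def_p_cutoff", "def_lfc_cutoff"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.floor_value is not None and self.floor_value <= 0:
            raise ValidationError("floor_value must be positive or None")


def load_omics_config(omics_type: str, overrides: Mapping[str, float] | None = None,
                      path: str | Path | None = None) -> OmicsTypeConfig:
    """Load the packaged per-omics defaults, optionally overriding fields.

    ``path`` may point at a user YAML with the same layout (a mapping from
    omics type to field/value pairs)."""
    if path is None:
        text = resources.files(__package__).joinpath("omics_defaults.yaml").read_text()
    else:
        text = Path(path).read_text()
    table = yaml.safe_load(text)
    if omics_type not in table:
        raise ValidationError(f"no defaults for omics type {omics_type!r}")
    kwargs = dict(table[omics_type])
    if overrides:
        kwargs.update(overrides)
    return OmicsTypeConfig(**kwargs)


# ---------------------------------------------------------------------------
# Annotation map (feature -> gene, many-to-many)


@dataclass
class AnnotationMap:
    """Many-to-many feature-to-gene associations used for cross-omics pairing.

    Also serves pathway-based pairing (pathway members supplied as 'genes')
    and promoter-probe-to-gene maps for methylation collapsing.
    """

    pairs: set[tuple[str, str]] = field(default_factory=set)
    n_rejected: int = 0

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AnnotationMap":
        clean: set[tuple[str, str]] = set()
        rejected = 0
        for f, g in pairs:
            f = "" if f is None else str(f).strip()
            g = "" if g is None else str(g).strip()
            if not f or not g or f.lower() == "nan" or g.lower() == "nan":
                rejected += 1
                continue
            clean.add((f, g))
        if rejected:
            warnings.warn(f"annotation map: rejected {rejected} rows with empty ids")
        return cls(pairs=clean, n_rejected=rejected)

    def genes_for(self, feature_id: str) -> set[str]:
        return {g for f, g in self.pairs if f == feature_id}

    def features_for(self, gene_id: str) -> set[str]:
        return {f for f, g in self.pairs if g == gene_id}

    def by_gene(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for f, g in self.pairs:
            out.setdefault(g, set()).add(f)
        return out

    def by_feature(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for f, g in self.pairs:
            out.setdefault(f, set()).add(g)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


def load_annotation_map(path: str | Path) -> AnnotationMap:
    """Read a two-column (feature_id, gene_id) TSV; duplicate rows collapse,
    rows with an empty field are rejected (counted, warned)."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=0, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValidationError(f"annotation map {path} needs two columns, found {df.shape[1]}")
    if df.shape[0] == 0:
        raise ValidationError(f"annotation map {path} is empty")
    return AnnotationMap.from_pairs(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# Reference sets (JSON-serializable)


@dataclass
class ReferenceDEFSet:
    """Consensus reference of differential features for one donor-pair contrast.

    ``records`` columns: feature_id, direction ('up'/'down'), reference_lfc
    (mean log2 fold change over the batches voting that direction),
    support_fraction.  ``contrast`` is ordered (numerator, denominator):
    lfc = mean(first donor) - mean(second donor) on the log scale.
    """

    contrast: tuple[str, str]
    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"feature_id", "direction", "reference_lfc", "support_fraction"}
        missing = need - set(self.records.columns)
        if missing:
            raise ValidationError(f"DEF reference records missing columns {sorted(missing)}")
        bad = set(self.records["direction"]) - {"up", "down"}
        if bad:
            raise ValidationError(f"invalid DEF directions {sorted(bad)}")

    def lfc_series(self) -> pd.Series:
        return self.records.set_index("feature_id")["reference_lfc"]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": "reference_def_set",
            "contrast": list(self.contrast),
            "provenance": self.provenance,
            "records": self.records.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ReferenceDEFSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            contrast=tuple(payload["contrast"]),
            records=pd.DataFrame(payload["records"]),
            provenance=payload.get("provenance", {}),
        )


@dataclass
class CrossOmicsReferenceSet:
    """High-confidence cross-omics feature pairs with sign category and
    reference Pearson r (mean over the batch combinations voting that sign).

    ``records`` columns: feature_a, feature_b, category ('positive'/'negative'),
    reference_r, support_fraction.
    """

    omics_pair: tuple[str, str]
    records: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"feature_a", "feature_b", "category", "reference_r", "support_fraction"}
        missing = need - set(self.records.columns)
        if missing:
            raise ValidationError(f"cross-omics records missing columns {sorted(missing)}")
        bad = set(self.records["category"]) - {"positive", "negative"}
        if bad:
            raise ValidationError(f"invalid categories {sorted(bad)}")
        r = self.records["reference_r"].to_numpy(float)
        sign_ok = np.where(
            self.records["category"].to_numpy() == "positive", r > 0, r < 0
        )
        if not bool(np.all(sign_ok)):
            raise ValidationError("reference_r sign must match category")

    def r_series(self) -> pd.Series:
        idx = pd.MultiIndex.from_frame(self.records[["feature_a", "feature_b"]])
        return pd.Series(self.records["reference_r"].to_numpy(), index=idx)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": "crossomics_reference_set",
            "omics_pair": list(self.omics_pair),
            "provenance": self.provenance,
            "records": self.records.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CrossOmicsReferenceSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            omics_pair=tuple(payload["omics_pair"]),
            records=pd.DataFrame(payload["records"]),
            provenance=payload.get("provenance", {}),
        )


# ---------------------------------------------------------------------------
# Dataset IO (TSV, features as rows / samples as columns, "NA" for missing)


def load_dataset(values_path: str | Path, meta_path: str | Path,
                 omics_type: str) -> OmicsDataset:
    """Load a feature-by-sample TSV plus a sample-metadata TSV.

    The values table's first column holds feature ids; the metadata table has
    sample_id, donor, replicate and batch columns.  Columns are reordered to
    follow the metadata row order.  A ``# scale=...`` comment line written by
    :func:`save_dataset` restores the scale tag and reference donor.
    """
    scale, reference_donor = "absolute", None
    with open(meta_path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        for tok in first[1:].strip().split():
            if "=" in tok:
                key, val = tok.split("=", 1)
                if key == "scale":
                    scale = val
                elif key == "reference_donor" and val != "NA":
                    reference_donor = val
    meta = pd.read_csv(meta_path, sep="\t", dtype=str, comment="#")
    for col in ("sample_id", "donor", "replicate", "batch"):
        if col not in meta.columns:
            raise ValidationError(f"metadata table lacks required column {col!r}")
    values = pd.read_csv(values_path, sep="\t", index_col=0, na_values=["NA"])
    values.index = values.index.astype(str)
    values.index.name = None

    meta_ids = meta["sample_id"].tolist()
    col_ids = [str(c) for c in values.columns]
    orphans = sorted(set(col_ids) - set(meta_ids))
    if orphans:
        raise ValidationError(f"value columns missing from metadata: {orphans}")
    absent = sorted(set(meta_ids) - set(col_ids))
    if absent:
        raise ValidationError(f"metadata samples missing from values table: {absent}")

    samples = [
        SampleMeta(sample_id=row.sample_id, donor=row.donor,
                   replicate=int(row.replicate), batch=row.batch)
        for row in meta.itertuples()
    ]
    return OmicsDataset(
        values=values[meta_ids].astype(float),
        samples=samples,
        omics_type=omics_type,
        scale=scale,
        reference_donor=reference_donor,
    )


def save_dataset(ds: OmicsDataset, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.values.tsv`` and ``<prefix>.meta.tsv``.

    Missing values are written as "NA"; floats are written with enough digits
    to round-trip bit-exactly.  The metadata sidecar's first line records the
    scale tag (and reference donor for ratio-scale data) as a comment.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    values_path = out_prefix.with_suffix(".values.tsv")
    meta_path = out_prefix.with_suffix(".meta.tsv")

    values = ds.values.copy()
    values.index.name = "feature_id"
    values.to_csv(values_path, sep="\t", na_rep="NA", float_format="%.17g")
    header = f"# scale={ds.scale} reference_donor={ds.reference_donor or 'NA'} omics_type={ds.omics_type}\n"
    with open(meta_path, "w") as fh:
        fh.write(header)
        ds.meta_frame().to_csv(fh, sep="\t", index=False)
    return values_path, meta_path
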