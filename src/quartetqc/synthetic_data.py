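"""Synthetic Quartet-family multi-omics generator with known ground truth.

The measurement model is log-additive: the instrument reads I = f(C), with a
sensitivity f that drifts per feature per batch; in log2 space this becomes

    value = baseline(feature) + donor_effect(feature, donor)
          + batch_offset(feature, batch) + global_shift(batch)
          + replicate_noise,

i.e. batch effects are additive in log space (multiplicative sensitivity on
the linear scale) — exactly the regime where ratio scaling against a common
reference donor cancels the batch terms identically; replicate noise then
breaks the exactness, which the tests quantify.

The default design mirrors the Quartet family: four donors (twin daughters
D5/D6 sharing the genetic layer, father F7, mother M8), three technical
replicates per donor per batch, several batches.  Ground truth — realized
donor effects, batch offsets, planted differential features, planted
cross-omics correlated pairs, and the Mendelian genotype matrix with twins
identical — is emitted alongside the data for recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .core_data import OmicsDataset, SampleMeta, ValidationError
from .qc_metrics import batch_balance
from .scaling import merge_batches

#: Standardized 4-level donor score pattern for planted cross-omics pairs
#: (population sd 1; permuted over donors per pair).  A fixed pattern keeps
#: the planted correlation at its nominal strength instead of diluting it
#: through the luck of four Gaussian draws.
_DONOR_SCORES = np.array([-1.5, -0.5, 0.5, 1.5]) / np.sqrt(1.25)

_CALL_NAMES = {0: "hom_ref", 1: "het", 2: "hom_alt"}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and effect-size parameters of the generator.

    All effect scales are log2 units.  Defaults describe a moderate-quality
    multi-batch study: donor-to-donor biological spread of 0.5, per-feature
    batch offsets of 1.0 (batch effects comparable to or larger than
    biology), replicate noise of 0.2, and twin daughters diverging by 0.2 on
    quantitative layers while sharing the DNA layer exactly.
    """

    donors: tuple[str, ...] = ("D5", "D6", "F7", "M8")
    twins: tuple[str, str] = ("D5", "D6")
    replicates: int = 3
    n_batches: int = 3
    layers: dict = field(default_factory=lambda: {"rna": 800, "protein": 400})
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    donor_effect_sd: float = 0.5
    twin_divergence_sd: float = 0.2
    batch_offset_sd: float = 1.0
    global_batch_shift_sd: float = 0.25
    noise_sd: float = 0.2
    contrasts: tuple[tuple[str, str], ...] = (("D5", "F7"), ("D5", "M8"), ("F7", "M8"))
    n_planted_defs: int = 25
    def_effect_size: float = 1.0
    n_planted_pairs: int = 20
    pair_target_r: float = 0.8
    pair_layers: tuple[str, str] = ("rna", "protein")
    pair_negative_fraction: float = 0.0
    mnar_midpoint: float | None = None
    mnar_slope: float = 1.0
    mcar_rate: float = 0.0
    allele_freq: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_sd", "donor_effect_sd", "twin_divergence_sd",
                     "batch_offset_sd", "global_batch_shift_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.replicates < 1 or self.n_batches < 1:
            raise ValidationError("replicates and n_batches must be positive")
        if not all(n > 0 for n in self.layers.values()):
            raise ValidationError("layer feature counts must be positive")
        if not 0.0 <= self.pair_target_r < 1.0:
            raise ValidationError("pair_target_r must be in [0, 1)")
        if not 0.0 <= self.mcar_rate < 1.0:
            raise ValidationError("mcar_rate must be in [0, 1)")
        for t in self.twins:
            if t not in self.donors:
                raise ValidationError(f"twin {t!r} not among donors")

    @property
    def batch_names(self) -> list[str]:
        return [f"B{i + 1}" for i in range(self.n_batches)]


@dataclass
class SimulationGroundTruth:
    """Everything a recovery test needs to score an analysis of the
    generated data against what was planted."""

    donor_effects: dict[str, pd.DataFrame]       # layer -> features x donors
    batch_offsets: dict[str, pd.DataFrame]       # layer -> features x batches
    global_shifts: dict[str, pd.Series]          # layer -> per-batch shift
    planted_defs: pd.DataFrame                   # layer, feature_id, donor, effect
    planted_pairs: pd.DataFrame                  # layer_a, feature_a, layer_b, feature_b, sign, target_r
    genotypes: pd.DataFrame | None = None        # loci x donors, encoded 0/1

    def true_lfc(self, layer: str, contrast: tuple[str, str]) -> pd.Series:
        """Exact log2 fold change of every feature for an ordered contrast,
        from the realized donor-effect matrix."""
        eff = self.donor_effects[layer]
        return eff[contrast[0]] - eff[contrast[1]]

    def true_def_features(self, layer: str, contrast: tuple[str, str],
                          min_abs_lfc: float = 1e-9) -> set[str]:
        lfc = self.true_lfc(layer, contrast)
        return set(lfc.index[lfc.abs() >= min_abs_lfc])


@dataclass
class SimulationResult:
    """Per-layer, per-batch datasets plus the planted truth."""

    layers: dict[str, list[OmicsDataset]]
    truth: SimulationGroundTruth
    config: SimulationConfig

    def batches_of(self, layer: str) -> list[OmicsDataset]:
        return self.layers[layer]


def _omics_type_of(layer: str) -> str:
    # layer names are omics types; anything unrecognized profiles like a
    # generic quantitative layer and is tagged 'metabolite'
    from .core_data import OMICS_TYPES

    return layer if layer in OMICS_TYPES else "metabolite"


def simulate_multiomics(cfg: SimulationConfig) -> SimulationResult:
    """Generate a Quartet-like multi-batch multi-omics study.

    Quantitative layers follow the log-additive model above; a layer named
    'dna' is emitted as 0/1-encoded Mendelian genotypes (parents drawn at the
    configured allele frequency, daughters inheriting one allele from each
    parent, twins copied exactly), constant across replicates and batches.
    Abundance-dependent (MNAR) and completely-random (MCAR) missingness are
    applied when configured; a configuration expected to mask more than half
    of all cells is rejected.
    """
    rng = np.random.default_rng(cfg.seed)
    donors = list(cfg.donors)
    twin_a, twin_b = cfg.twins
    parents = [d for d in donors if d not in cfg.twins]

    donor_effects: dict[str, pd.DataFrame] = {}
    batch_offsets: dict[str, pd.DataFrame] = {}
    global_shifts: dict[str, pd.Series] = {}
    planted_def_rows: list[dict] = []
    planted_pair_rows: list[dict] = []
    genotypes: pd.DataFrame | None = None
    layers_out: dict[str, list[OmicsDataset]] = {}

    # reserve pair features at the tail of each pair layer
    pair_feature_ids: dict[str, list[str]] = {}
    if cfg.n_planted_pairs > 0:
        la, lb = cfg.pair_layers
        for layer in (la, lb):
            if layer not in cfg.layers:
                raise ValidationError(f"pair layer {layer!r} not among layers")
            if cfg.layers[layer] < cfg.n_planted_pairs:
                raise ValidationError(f"layer {layer!r} too small for planted pairs")
        pair_feature_ids = {
            layer: [f"{layer}_{i:05d}" for i in
                    range(cfg.layers[layer] - cfg.n_planted_pairs, cfg.layers[layer])]
            for layer in (la, lb)
        }
        lam = (1.0 if cfg.noise_sd == 0 else
               cfg.noise_sd * np.sqrt(cfg.pair_target_r / (1.0 - cfg.pair_target_r)))
        pair_signs = np.where(
            rng.random(cfg.n_planted_pairs) < cfg.pair_negative_fraction, -1.0, 1.0)
        pair_scores = np.stack([
            _DONOR_SCORES[rng.permutation(4)] if len(donors) == 4
            else rng.standard_normal(len(donors))
            for _ in range(cfg.n_planted_pairs)
        ])  # pairs x donors

    for layer, n_features in cfg.layers.items():
        feats = [f"{layer}_{i:05d}" for i in range(n_features)]
        if layer == "dna":
            geno = _mendelian_genotypes(rng, n_features, donors, cfg.twins,
                                        cfg.allele_freq, feats)
            genotypes = geno
            layers_out[layer] = _emit_dna_batches(geno, cfg)
            donor_effects[layer] = geno.astype(float)
            batch_offsets[layer] = pd.DataFrame(
                0.0, index=feats, columns=cfg.batch_names)
            global_shifts[layer] = pd.Series(0.0, index=cfg.batch_names)
            continue

        baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, n_features)
        eff = pd.DataFrame(0.0, index=feats, columns=donors)
        g = rng.normal(0.0, cfg.donor_effect_sd, n_features)
        eff[twin_a] = g + rng.normal(0.0, cfg.twin_divergence_sd, n_features)
        eff[twin_b] = g + rng.normal(0.0, cfg.twin_divergence_sd, n_features)
        for p in parents:
            eff[p] = rng.normal(0.0, cfg.donor_effect_sd, n_features)

        # planted DEFs: dedicated features at the head of the layer, one
        # contrast per block; the planted effect replaces the background
        # biology on that feature so the truth is exactly the planted value
        n_def_total = cfg.n_planted_defs * len(cfg.contrasts)
        reserved_tail = len(pair_feature_ids.get(layer, []))
        if n_def_total + reserved_tail > n_features:
            raise ValidationError(
                f"layer {layer!r}: {n_features} features cannot hold "
                f"{n_def_total} planted DEFs plus {reserved_tail} pair features")
        for ci, (da, db) in enumerate(cfg.contrasts):
            block = feats[ci * cfg.n_planted_defs:(ci + 1) * cfg.n_planted_defs]
            signs = rng.choice([-1.0, 1.0], size=len(block))
            for f, s in zip(block, signs):
                eff.loc[f, :] = 0.0
                eff.loc[f, da] = s * cfg.def_effect_size
                planted_def_rows.append({
                    "layer": layer, "feature_id": f, "donor": da,
                    "contrast_a": da, "contrast_b": db,
                    "effect": s * cfg.def_effect_size,
                })

        # planted cross-omics pairs: shared standardized donor score
        if layer in pair_feature_ids:
            side = 0 if layer == cfg.pair_layers[0] else 1
            for pi, f in enumerate(pair_feature_ids[layer]):
                sign = 1.0 if side == 0 else pair_signs[pi]
                eff.loc[f, :] = sign * lam * pair_scores[pi]
                if side == 0:
                    la, lb = cfg.pair_layers
                    planted_pair_rows.append({
                        "layer_a": la,
                        "feature_a": f,
                        "layer_b": lb,
                        "feature_b": pair_feature_ids[lb][pi],
                        "sign": int(pair_signs[pi]),
                        "target_r": cfg.pair_target_r,
                    })

        offs = pd.DataFrame(
            rng.normal(0.0, cfg.batch_offset_sd, (n_features, cfg.n_batches)),
            index=feats, columns=cfg.batch_names)
        shifts = pd.Series(rng.normal(0.0, cfg.global_batch_shift_sd, cfg.n_batches),
                           index=cfg.batch_names)

        donor_effects[layer] = eff
        batch_offsets[layer] = offs
        global_shifts[layer] = shifts

        batch_list = []
        for b in cfg.batch_names:
            cols, metas = [], []
            for d in donors:
                for r in range(1, cfg.replicates + 1):
                    signal = (baseline + eff[d].to_numpy() + offs[b].to_numpy()
                              + shifts[b]
                              + rng.normal(0.0, cfg.noise_sd, n_features))
                    cols.append(signal)
                    metas.append(SampleMeta(f"{d}_r{r}", d, r, b))
            values = pd.DataFrame(np.column_stack(cols), index=feats,
                                  columns=[m.sample_id for m in metas])
            values = _apply_missingness(values, cfg, rng)
            batch_list.append(OmicsDataset(values=values, samples=metas,
                                           omics_type=_omics_type_of(layer)))
        layers_out[layer] = batch_list

    truth = SimulationGroundTruth(
        donor_effects=donor_effects,
        batch_offsets=batch_offsets,
        global_shifts=global_shifts,
        planted_defs=pd.DataFrame(planted_def_rows, columns=[
            "layer", "feature_id", "donor", "contrast_a", "contrast_b", "effect"]),
        planted_pairs=pd.DataFrame(planted_pair_rows, columns=[
            "layer_a", "feature_a", "layer_b", "feature_b", "sign", "target_r"]),
        genotypes=genotypes,
    )
    return SimulationResult(layers=layers_out, truth=truth, config=cfg)


def simulate_null(cfg: SimulationConfig) -> SimulationResult:
    """Same design with all biology switched off: donor effects, twin
    divergence and planted structure all zero.  Replicates of different
    donors are then exchangeable, which calibrates SNR near 0 dB."""
    null_cfg = dataclasses.replace(
        cfg, donor_effect_sd=0.0, twin_divergence_sd=0.0,
        n_planted_defs=0, n_planted_pairs=0)
    return simulate_multiomics(null_cfg)


def _apply_missingness(values: pd.DataFrame, cfg: SimulationConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    if cfg.mnar_midpoint is None and cfg.mcar_rate == 0.0:
        return values
    arr = values.to_numpy(float)
    p = np.zeros_like(arr)
    if cfg.mnar_midpoint is not None:
        p = expit(cfg.mnar_slope * (cfg.mnar_midpoint - arr))
    p = p + cfg.mcar_rate * (1.0 - p)
    if p.mean() > 0.5:
        raise ValidationError(
            f"missingness configuration would mask {p.mean():.0%} of cells (> 50%)")
    mask = rng.random(arr.shape) < p
    arr[mask] = np.nan
    return pd.DataFrame(arr, index=values.index, columns=values.columns)


def _mendelian_genotypes(rng: np.random.Generator, n_loci: int,
                         donors: list[str], twins: tuple[str, str],
                         allele_freq: float, loci: list[str]) -> pd.DataFrame:
    """0/1-encoded genotypes: parents drawn at the allele frequency, the twin
    daughters built by Mendelian inheritance (one allele from each parent)
    and copied to be identical."""
    parents = [d for d in donors if d not in twins]
    if len(parents) != 2:
        raise ValidationError("Mendelian layer requires exactly two non-twin donors")
    father_alleles = rng.random((n_loci, 2)) < allele_freq
    mother_alleles = rng.random((n_loci, 2)) < allele_freq
    child_f = father_alleles[np.arange(n_loci), rng.integers(0, 2, n_loci)]
    child_m = mother_alleles[np.arange(n_loci), rng.integers(0, 2, n_loci)]
    counts = {
        parents[0]: father_alleles.sum(axis=1),
        parents[1]: mother_alleles.sum(axis=1),
        twins[0]: child_f.astype(int) + child_m.astype(int),
    }
    counts[twins[1]] = counts[twins[0]]  # monozygotic
    encoded = {d: (c > 0).astype(float) for d, c in counts.items()}
    return pd.DataFrame(encoded, index=loci)[donors]


def _emit_dna_batches(genotypes: pd.DataFrame,
                      cfg: SimulationConfig) -> list[OmicsDataset]:
    out = []
    for b in cfg.batch_names:
        cols, metas = [], []
        for d in cfg.donors:
            for r in range(1, cfg.replicates + 1):
                cols.append(genotypes[d].to_numpy(float))
                metas.append(SampleMeta(f"{d}_r{r}", d, r, b))
        values = pd.DataFrame(np.column_stack(cols), index=genotypes.index,
                              columns=[m.sample_id for m in metas])
        out.append(OmicsDataset(values=values, samples=metas, omics_type="dna"))
    return out


def sample_scenario(batch_datasets: list[OmicsDataset], mode: str,
                    draw: int, seed: int) -> tuple[OmicsDataset, float]:
    """Draw a balanced or confounded subset of a multi-batch replicate pool.

    The pool orders each donor's replicates by (batch, replicate).  Balanced
    sampling picks one set of ``draw`` unique pool indices and applies it to
    every donor, so donors land in the same batches; confounded sampling
    draws an independent index set per donor, so donors scatter across
    batches.  Returns the sampled dataset and its group-batch balance (mean
    pairwise Jaccard index of the selected batch sets).
    """
    if mode not in ("balanced", "confounded"):
        raise ValidationError(f"unknown scenario mode {mode!r}")
    merged = merge_batches(batch_datasets, feature_policy="intersection")
    rng = np.random.default_rng(seed)
    pools: dict[str, list[SampleMeta]] = {}
    batch_order = {b: i for i, b in enumerate(merged.batches)}
    for s in merged.samples:
        pools.setdefault(s.donor, []).append(s)
    for d in pools:
        pools[d].sort(key=lambda s: (batch_order[s.batch], s.replicate))
    sizes = {len(v) for v in pools.values()}
    if len(sizes) != 1:
        raise ValidationError("scenario sampling requires equal pool sizes per donor")
    pool_size = sizes.pop()
    if draw > pool_size:
        raise ValidationError(f"draw {draw} exceeds pool size {pool_size}")

    donors = sorted(pools)
    if mode == "balanced":
        idx = np.sort(rng.choice(pool_size, size=draw, replace=False))
        chosen = {d: [pools[d][i] for i in idx] for d in donors}
    else:
        chosen = {}
        for d in donors:
            idx = np.sort(rng.choice(pool_size, size=draw, replace=False))
            chosen[d] = [pools[d][i] for i in idx]

    sample_ids = [s.sample_id for d in donors for s in chosen[d]]
    subset = merged.subset(sample_ids=sample_ids)
    balance = batch_balance({d: {s.batch for s in chosen[d]} for d in donors})
    return subset, balance
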