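"""Synthetic paired BT/AT multi-omics cohorts with known ground truth.

The generator emulates the statistical structure of a small paired
intervention cohort: 12 participants sampled before (BT) and after (AT)
therapy in three blocks — buccal-cell histone PTMs, PBMC histone PTMs and
plasma protein groups — plus six additional BT-only dropout participants in
the plasma block, so the three plasma batches of 8/16/6 samples add up and
unpaired handling is exercised.

Baseline log2 intensities follow a log-normal-like model: per-feature means
uniform over a configurable range, a participant-level offset, and Gaussian
residual noise on the log2 scale.  A subset of planted marker features
receives a BT->AT shift whose magnitude is modulated per participant by his
ordinal performance category according to a planted trend shape (linear or
plateau), so the trend classifier has exact truth.  Latent participant
clusters are induced by cluster-correlated change shifts in the epigenetic
blocks.  Plasma samples get additive+multiplicative batch effects, and all
blocks get intensity-censored (left-censoring, NMAR) plus completely random
missingness, with the true mechanism recorded per masked cell.

PTM features are organized as precursor groups of 2-5 co-measured modified
forms so relative-abundance logic is exercised downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (OmicsBlock, ParticipantSheet, SampleSheet,
                        ValidationError, logger)
from .response import PERFORMANCE_ORDER

TREND_MULTIPLIERS: dict[str, tuple[float, float, float]] = {
    # over (moderate, intermediate, max)
    "increasing_linear": (0.5, 1.0, 1.5),
    "decreasing_linear": (1.5, 1.0, 0.5),
    "plateau_first_two": (0.5, 0.5, 1.5),
    "plateau_last_two": (0.5, 1.5, 1.5),
    "constant": (1.0, 1.0, 1.0),  # plain planted shift, no category trend
}

HEALTHY_CATEGORIES = {"exercise_class": "sportive",
                      "diet_class": "balanced",
                      "bmi_class": "normal"}
UNHEALTHY_CATEGORIES = {"exercise_class": ("moderate", "sedentary"),
                        "diet_class": ("mixed", "unbalanced"),
                        "bmi_class": ("overweight",)}

BLOCKS = ("buccal", "pbmc", "plasma")


@dataclass
class SynthConfig:
    """Study conditions of the synthetic cohort (defaults emulate the
    12-participant paired design with three plasma batches of 8/16/6)."""

    n_participants: int = 12
    n_features: Mapping[str, int] = field(
        default_factory=lambda: {"buccal": 60, "pbmc": 60, "plasma": 340})
    n_planted: Mapping[str, int] = field(
        default_factory=lambda: {"buccal": 8, "pbmc": 8, "plasma": 30})
    effect_size: float = 1.0          # log2 units at the max-category multiplier 1
    noise_sd: float = 0.5             # residual SD, log2 units
    participant_sd: float = 0.3       # participant-level offset SD
    mean_range: tuple[float, float] = (14.0, 26.0)
    n_unpaired_bt: int = 6            # plasma-only BT dropouts
    batch_sizes: tuple[int, ...] = (8, 16, 6)
    batch_shift: float = 1.0          # additive log2 units between batches
    batch_scale: float = 1.3          # multiplicative factor between batches
    mnar_censor_quantile: float = 0.15
    mnar_censor_prob: float = 0.95    # masking probability for censored features
    mcar_rate: float = 0.02
    n_clusters: int = 3
    cluster_sd: float = 0.8           # SD of cluster-correlated change shifts
    trend_shapes: Mapping[str, str] | str | None = None
    # marker id -> shape; a bare shape name applies to all planted markers;
    # None cycles through the four trend shapes
    healthy_fraction: float = 0.5
    agility_change_means: tuple[float, float, float] = (5.0, 25.0, 60.0)
    agility_change_sd: float = 2.0
    heavy_tails: bool = False         # Student-t (df=4) residuals instead of Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mnar_censor_quantile", "mnar_censor_prob", "mcar_rate",
                     "healthy_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        for b in BLOCKS:
            if self.n_planted[b] > self.n_features[b]:
                raise ValidationError(f"n_planted > n_features for {b}")
        if self.n_clusters > self.n_participants:
            raise ValidationError("clusters > participants is infeasible")
        n_plasma = 2 * self.n_participants + self.n_unpaired_bt
        if sum(self.batch_sizes) != n_plasma:
            raise ValidationError(
                f"batch_sizes sum to {sum(self.batch_sizes)}, expected "
                f"{n_plasma} plasma samples")


@dataclass
class TruthTable:
    """Ground truth of a generated cohort (the test oracle)."""

    planted: dict[str, list[str]]              # block -> planted feature ids
    marker_sign: dict[str, dict[str, int]]     # block -> feature -> +-1
    trend_shape: dict[str, dict[str, str]]     # block -> feature -> shape of
                                               # the observed effect profile
    cluster: pd.Series = None                  # participant -> cluster label
    performance: pd.Series = None
    missingness: dict[str, pd.DataFrame] = field(default_factory=dict)
    # block -> per-masked-cell (feature, sample, mechanism)
    batch_params: dict[str, dict[str, float]] = field(default_factory=dict)


def _noise(rng: np.random.Generator, size, sd: float,
           heavy: bool) -> np.ndarray:
    if heavy:
        return sd * rng.standard_t(df=4, size=size) / np.sqrt(2.0)
    return rng.normal(0.0, sd, size=size)


def _ptm_meta(n: int, prefix: str, rng: np.random.Generator) -> pd.DataFrame:
    """Feature metadata for a PTM block: precursor groups of 2-5 modified
    forms of one histone peptide."""
    histones = ("H3.1", "H3.3", "H3", "H4")
    mods = ("me1", "me2", "me3", "ac")
    rows, g = [], 0
    while len(rows) < n:
        size = int(rng.integers(2, 6))
        hist = histones[int(rng.integers(len(histones)))]
        site = f"K{int(rng.integers(4, 80))}"
        chosen = rng.choice(len(mods), size=min(size, n - len(rows)),
                            replace=True)
        for k, mi in enumerate(chosen):
            rows.append({"feature": f"{prefix}_{hist}_{site}{mods[mi]}_g{g}.{k}",
                         "histone": hist, "site": site,
                         "modification": mods[mi],
                         "precursor_group": f"{prefix}_g{g}"})
        g += 1
    meta = pd.DataFrame(rows[:n]).set_index("feature")
    return meta


def _protein_meta(n: int) -> pd.DataFrame:
    ids = [f"PG{i:04d}" for i in range(n)]
    return pd.DataFrame({"group_id": ids,
                         "leading_protein": [f"PROT{i:04d}" for i in range(n)]},
                        index=pd.Index(ids, name="feature"))


def generate_cohort(config: SynthConfig
                    ) -> tuple[dict[str, OmicsBlock], SampleSheet,
                               ParticipantSheet, TruthTable]:
    """Generate the three blocks, sheets and ground truth. Reproducible
    given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    pids = [f"P{i + 1:02d}" for i in range(n)]
    dropouts = [f"D{i + 1:02d}" for i in range(config.n_unpaired_bt)]

    # --- participant annotation -------------------------------------------
    perf = pd.Series([PERFORMANCE_ORDER[i % 3] for i in range(n)], index=pids)
    perf = perf.iloc[rng.permutation(n)].set_axis(pids)
    sa_levels = ("improving", "unimpaired", "stagnating", "worsening")
    sa = pd.Series([sa_levels[i % 4] for i in range(n)], index=pids)
    sa = sa.iloc[rng.permutation(n)].set_axis(pids)
    cluster = pd.Series([i % config.n_clusters for i in range(n)], index=pids)
    cluster = cluster.iloc[rng.permutation(n)].set_axis(pids)

    lifestyle: dict[str, pd.Series] = {}
    for comp, healthy in HEALTHY_CATEGORIES.items():
        labs = []
        for _ in pids:
            if rng.random() < config.healthy_fraction:
                labs.append(healthy)
            else:
                opts = UNHEALTHY_CATEGORIES[comp]
                labs.append(opts[int(rng.integers(len(opts)))])
        lifestyle[comp] = pd.Series(labs, index=pids)

    perf_idx = {c: i for i, c in enumerate(PERFORMANCE_ORDER)}
    ag_bt = rng.uniform(200.0, 400.0, size=(n, 3))
    pct = np.array([rng.normal(config.agility_change_means[perf_idx[perf[p]]],
                               config.agility_change_sd, size=3)
                    for p in pids])
    ag_at = ag_bt * (1.0 + pct / 100.0)
    participants = ParticipantSheet(pd.DataFrame({
        "participant_id": pids,
        "exercise_class": lifestyle["exercise_class"].values,
        "diet_class": lifestyle["diet_class"].values,
        "bmi_class": lifestyle["bmi_class"].values,
        "performance": perf.values,
        "self_assessment": sa.values,
        "flexion_bt": ag_bt[:, 0], "flexion_at": ag_at[:, 0],
        "extension_bt": ag_bt[:, 1], "extension_at": ag_at[:, 1],
        "rotation_bt": ag_bt[:, 2], "rotation_at": ag_at[:, 2],
    }))

    # --- sample sheet ------------------------------------------------------
    rows = []
    for b in BLOCKS:
        for p in pids:
            for tp in ("BT", "AT"):
                rows.append({"sample_id": f"{p}_{b}_{tp}", "participant_id": p,
                             "timepoint": tp, "sample_type": b, "batch": "1"})
        if b == "plasma":
            for d in dropouts:
                rows.append({"sample_id": f"{d}_plasma_BT", "participant_id": d,
                             "timepoint": "BT", "sample_type": "plasma",
                             "batch": "1"})
    sheet_df = pd.DataFrame(rows)
    plasma_idx = sheet_df.index[sheet_df["sample_type"] == "plasma"].to_numpy()
    order = rng.permutation(len(plasma_idx))
    assign = np.repeat([f"batch{i + 1}" for i in range(len(config.batch_sizes))],
                       config.batch_sizes)
    sheet_df.loc[plasma_idx[order], "batch"] = assign
    sheet = SampleSheet(sheet_df)

    # --- trend shapes for planted markers ---------------------------------
    shapes = [s for s in TREND_MULTIPLIERS if s != "constant"]
    truth = TruthTable(planted={}, marker_sign={}, trend_shape={},
                       cluster=cluster, performance=perf)

    blocks: dict[str, OmicsBlock] = {}
    for b in BLOCKS:
        nf = config.n_features[b]
        meta = (_protein_meta(nf) if b == "plasma"
                else _ptm_meta(nf, b, rng))
        feats = list(meta.index)
        planted = [feats[i] for i in
                   rng.choice(nf, size=config.n_planted[b], replace=False)]
        signs = {f: int(rng.choice([-1, 1])) for f in planted}
        shape_of = {}
        for k, f in enumerate(planted):
            if isinstance(config.trend_shapes, str):
                shape = config.trend_shapes
            elif config.trend_shapes:
                shape = config.trend_shapes.get(f, shapes[k % 4])
            else:
                shape = shapes[k % 4]
            if shape not in TREND_MULTIPLIERS:
                raise ValidationError(f"unknown trend shape {shape!r}")
            shape_of[f] = shape
        truth.planted[b] = planted
        truth.marker_sign[b] = signs
        observed_shape = {}
        for f, shape in shape_of.items():
            if signs[f] > 0:
                observed_shape[f] = shape
            else:
                flip = {"increasing_linear": "decreasing_linear",
                        "decreasing_linear": "increasing_linear"}
                observed_shape[f] = flip.get(shape, shape)
        truth.trend_shape[b] = observed_shape

        mu = rng.uniform(*config.mean_range, size=nf)
        p_off = rng.normal(0.0, config.participant_sd, size=n)
        cluster_shift = (rng.normal(0.0, config.cluster_sd,
                                    size=(config.n_clusters, nf))
                         if b != "plasma" else
                         np.zeros((config.n_clusters, nf)))

        cols, data = [], []
        all_parts = pids + (dropouts if b == "plasma" else [])
        d_off = rng.normal(0.0, config.participant_sd, size=len(dropouts))
        for j, p in enumerate(all_parts):
            is_drop = p.startswith("D")
            off = d_off[j - n] if is_drop else p_off[j]
            bt = mu + off + _noise(rng, nf, config.noise_sd, config.heavy_tails)
            cols.append(f"{p}_{b}_BT")
            data.append(bt)
            if is_drop:
                continue
            delta = np.zeros(nf)
            mult_idx = perf_idx[perf[p]]
            for f in planted:
                i = feats.index(f)
                m = TREND_MULTIPLIERS[shape_of[f]][mult_idx]
                delta[i] = signs[f] * config.effect_size * m
            delta += cluster_shift[cluster[p]]
            at = (mu + off + delta
                  + _noise(rng, nf, config.noise_sd, config.heavy_tails))
            cols.append(f"{p}_{b}_AT")
            data.append(at)
        values = pd.DataFrame(np.array(data).T, index=feats, columns=cols)
        block = OmicsBlock(values, meta)

        if b == "plasma" and len(config.batch_sizes) > 1:
            block = inject_batch_effects(block, sheet, config.batch_shift,
                                         config.batch_scale,
                                         seed=int(rng.integers(2 ** 31)))
            truth.batch_params[b] = {"shift": config.batch_shift,
                                     "scale": config.batch_scale}
        block, miss_truth = inject_missingness(
            block, config.mnar_censor_quantile, config.mcar_rate,
            seed=int(rng.integers(2 ** 31)),
            censor_prob=config.mnar_censor_prob)
        truth.missingness[b] = miss_truth
        blocks[b] = block
    return blocks, sheet, participants, truth


def inject_batch_effects(block: OmicsBlock, sheet: SampleSheet,
                         shift: float, scale: float, seed: int = 0
                         ) -> OmicsBlock:
    """Apply additive+multiplicative batch effects.

    Per batch b: value <- scale_b * (value - feature mean) + feature mean
    + shift_b.  The per-batch parameters are centered around the configured
    magnitudes: for B batches the additive centers are shift * (i - mean(i))
    (adjacent batches differ by one shift unit) with a small jitter, and the
    multiplicative factors scale ** (i - mean(i)).  A single batch returns
    the input unchanged with a warning.
    """
    batches = sheet.batch_of(block.sample_ids)
    levels = list(pd.unique(batches))
    if len(levels) < 2:
        logger.warning("single batch: batch-effect injection is the identity")
        return block.copy()
    rng = np.random.default_rng(seed)
    z = np.arange(len(levels), dtype=float)
    z -= z.mean()
    shift_b = {lev: shift * z[k] + rng.normal(0.0, 0.05 * abs(shift))
               for k, lev in enumerate(levels)}
    scale_b = {lev: float(scale) ** z[k] for k, lev in enumerate(levels)}
    X = block.values.to_numpy(dtype=float)
    fmean = np.nanmean(X, axis=1, keepdims=True)
    out = X.copy()
    for lev in levels:
        cols = np.flatnonzero((batches == lev).to_numpy())
        out[:, cols] = (scale_b[lev] * (X[:, cols] - fmean) + fmean
                        + shift_b[lev])
    return OmicsBlock(pd.DataFrame(out, index=block.values.index,
                                   columns=block.values.columns),
                      block.feature_meta)


def inject_missingness(block: OmicsBlock, censor_quantile: float,
                       mcar_rate: float, seed: int = 0,
                       censor_prob: float = 0.95
                       ) -> tuple[OmicsBlock, pd.DataFrame]:
    """Mask cells by left-censoring plus completely-at-random dropout.

    Left-censoring acts at the feature level, the way a detection limit
    does: features whose mean intensity falls below the per-block
    ``censor_quantile`` of feature means drop out of detection, and each of
    their cells is masked with probability ``censor_prob`` (mechanism NMAR;
    the rare survivors model sporadic near-limit detections).  Every
    remaining cell is masked independently with ``mcar_rate`` (mechanism
    MCAR).  Returns the masked block and the per-masked-cell truth labels.
    """
    if not 0 <= censor_quantile <= 1 or not 0 <= mcar_rate <= 1:
        raise ValidationError("rates must be in [0,1]")
    rng = np.random.default_rng(seed)
    X = block.values.to_numpy(dtype=float)
    out = X.copy()
    rows = []
    if censor_quantile > 0:
        fmean = np.nanmean(X, axis=1)
        thresh = np.quantile(fmean, censor_quantile)
        low_feature = (fmean < thresh)[:, None] & np.ones_like(X, dtype=bool)
        censored = low_feature & (rng.random(X.shape) < censor_prob)
    else:
        censored = np.zeros_like(X, dtype=bool)
    mcar = (~censored) & ~np.isnan(X) & (rng.random(X.shape) < mcar_rate)
    out[censored | mcar] = np.nan
    feats, cols = block.values.index, block.values.columns
    for i, j in np.argwhere(censored):
        rows.append({"feature": feats[i], "sample": cols[j],
                     "mechanism": "NMAR"})
    for i, j in np.argwhere(mcar):
        rows.append({"feature": feats[i], "sample": cols[j],
                     "mechanism": "MCAR"})
    masked = OmicsBlock(pd.DataFrame(out, index=feats, columns=cols),
                        block.feature_meta)
    return masked, pd.DataFrame(rows, columns=["feature", "sample", "mechanism"])
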