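"""Feature filtering, quantile normalization, censoring-aware imputation,
empirical-Bayes batch adjustment and PTM relative abundances.

Missing values in label-free proteomics arise from two regimes: left-censored
low-intensity signals (not missing at random, NMAR) and sporadic losses
(missing at random, MAR).  The two are distinguished per (feature, BT/AT
condition) by the fraction of missing values — more than 75% missing within a
condition is treated as censoring — and imputed from different Gaussians:

* NMAR cells are drawn around the mean of all observed intensities below the
  block-wide first percentile, with SD equal to the median per-feature SD;
* MAR cells are drawn around the feature's observed condition mean with a
  fixed SD of 0.5 log2 units.

Batch effects are removed with a parametric empirical-Bayes location/scale
model (the ComBat procedure): features are standardized, per-batch additive
effects get a normal prior and multiplicative effects an inverse-gamma prior,
hyperparameters are estimated by method of moments and the posterior batch
parameters are solved iteratively before back-transformation.

For histone-PTM blocks, intensities of the modified forms sharing one
precursor peptide are converted (on the linear scale) into relative
abundances that sum to 100% per precursor group and sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datamodel import (OmicsBlock, PairedDesign, SampleSheet,
                        ValidationError, logger)

OBSERVED, MAR, NMAR = "OBSERVED", "MAR", "NMAR"


@dataclass
class ImputationParams:
    """Parameters of the two-regime imputation (all on the log2 scale)."""

    nmar_threshold: float = 0.75   # missing fraction above which a condition is censored
    nmar_percentile: float = 0.01  # intensity quantile defining "low"
    mar_sd: float = 0.5            # SD of MAR draws, log2 units
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.nmar_threshold < 1:
            raise ValidationError("nmar_threshold must be in (0,1)")
        if not 0 < self.nmar_percentile < 1:
            raise ValidationError("nmar_percentile must be in (0,1)")
        if self.mar_sd <= 0:
            raise ValidationError("mar_sd must be positive")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_ptm_features(block: OmicsBlock, design: PairedDesign,
                        max_missing: int = 10,
                        sample_type: str | None = None
                        ) -> tuple[OmicsBlock, pd.DataFrame]:
    """Drop PTM features with ``max_missing`` or more missing values over the
    paired samples.  Returns the retained block and a drop report."""
    stype = sample_type or _infer_sample_type(block, design)
    paired_ids = [s for s in design.paired_sample_ids(stype)
                  if s in block.values.columns]
    miss = block.values[paired_ids].isna().sum(axis=1)
    dropped = miss[miss >= max_missing]
    report = pd.DataFrame({"feature": dropped.index,
                           "n_missing_paired": dropped.values,
                           "rule": f"missing >= {max_missing} over paired samples"})
    keep = miss.index[miss < max_missing]
    return block.subset_features(keep), report


def filter_protein_groups(block: OmicsBlock, design: PairedDesign,
                          min_paired: int = 9,
                          sample_type: str = "plasma"
                          ) -> tuple[OmicsBlock, pd.DataFrame]:
    """Retain protein groups observed in at least ``min_paired`` paired
    participants at BT *and* at AT (80% of a 11/12-pair cohort at 9)."""
    pairs = [p for p in design.pairs_for(sample_type)
             if p.bt_sample in block.values.columns
             and p.at_sample in block.values.columns]
    bt_cols = [p.bt_sample for p in pairs]
    at_cols = [p.at_sample for p in pairs]
    n_bt = block.values[bt_cols].notna().sum(axis=1)
    n_at = block.values[at_cols].notna().sum(axis=1)
    keep = (n_bt >= min_paired) & (n_at >= min_paired)
    report = pd.DataFrame({"feature": block.values.index[~keep],
                           "n_bt": n_bt[~keep].values,
                           "n_at": n_at[~keep].values,
                           "rule": f"observed pairs < {min_paired} at BT or AT"})
    return block.subset_features(block.values.index[keep]), report


def _infer_sample_type(block: OmicsBlock, design: PairedDesign) -> str:
    cols = set(block.values.columns)
    best, best_n = None, -1
    for stype in design.pairs:
        n = len(cols & set(design.paired_sample_ids(stype)))
        if n > best_n:
            best, best_n = stype, n
    if best is None or best_n == 0:
        raise ValidationError("no sample type of the design matches the block")
    return best


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(block: OmicsBlock) -> OmicsBlock:
    """Map every sample onto the cross-sample mean quantile distribution.

    Ranks ignore missing values: each sample's observed values are placed at
    plotting positions (rank - 0.5)/n_observed and mapped through the mean
    quantile curve, so samples with different observed counts are comparable.
    On complete matrices this is the classical procedure (each column's sorted
    vector becomes the mean of the sorted columns) and it is idempotent.
    """
    X = block.values.to_numpy(dtype=float)
    m, n = X.shape
    if n < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    grid = (np.arange(m) + 0.5) / m
    ref = np.zeros(m)
    for j in range(n):
        obs = np.sort(X[~np.isnan(X[:, j]), j])
        if obs.size < 2:
            raise ValidationError(
                f"sample {block.values.columns[j]!r} has < 2 observed values")
        pos = (np.arange(obs.size) + 0.5) / obs.size
        ref += np.interp(grid, pos, obs)
    ref /= n

    out = X.copy()
    for j in range(n):
        idx = ~np.isnan(X[:, j])
        obs = X[idx, j]
        ranks = rankdata(obs, method="average")
        out[idx, j] = np.interp((ranks - 0.5) / obs.size, grid, ref)
    return OmicsBlock(pd.DataFrame(out, index=block.values.index,
                                   columns=block.values.columns),
                      block.feature_meta)


# ---------------------------------------------------------------------------
# Missingness classification and imputation
# ---------------------------------------------------------------------------

def classify_missingness(block: OmicsBlock, design: PairedDesign,
                         params: ImputationParams,
                         sample_type: str | None = None) -> pd.DataFrame:
    """Label each (feature, condition) as OBSERVED, MAR or NMAR.

    The condition of a sample is its BT/AT timepoint; a condition with a
    missing fraction strictly above ``nmar_threshold`` is called censored
    (NMAR), any other condition with at least one missing value is MAR.
    """
    stype = sample_type or _infer_sample_type(block, design)
    tp_map = design.timepoint_map(stype)
    cols_by_cond = {tp: [s for s in block.values.columns if tp_map.get(s) == tp]
                    for tp in ("BT", "AT")}
    rows = []
    for tp, cols in cols_by_cond.items():
        if not cols:
            continue
        frac = block.values[cols].isna().mean(axis=1)
        label = np.where(frac == 0, OBSERVED,
                         np.where(frac > params.nmar_threshold, NMAR, MAR))
        for feat, lab, f in zip(block.values.index, label, frac):
            rows.append({"feature": feat, "condition": tp,
                         "label": lab, "missing_fraction": float(f)})
    return pd.DataFrame(rows)


def impute(block: OmicsBlock, labels: pd.DataFrame, params: ImputationParams,
           design: PairedDesign | None = None,
           sample_type: str | None = None) -> OmicsBlock:
    """Fill missing cells according to their MAR/NMAR label.

    Observed cells are never altered.  A MAR feature-condition with no
    observed value falls back to the NMAR rule with a warning.
    """
    rng = np.random.default_rng(params.seed)
    X = block.values.to_numpy(dtype=float)
    obs = X[~np.isnan(X)]
    if obs.size == 0:
        raise ValidationError("block has no observed values")
    q1 = np.quantile(obs, params.nmar_percentile)
    low = obs[obs < q1]
    mu_low = float(np.mean(low)) if low.size else float(q1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        feat_sd = np.nanstd(X, axis=1, ddof=1)
    sd_med = float(np.nanmedian(feat_sd))

    if design is not None:
        stype = sample_type or _infer_sample_type(block, design)
        tp_map = design.timepoint_map(stype)
    else:  # condition membership from the label table alone is impossible;
        tp_map = {}
    cond_of = {s: tp_map.get(s) for s in block.values.columns}

    lab = labels.set_index(["feature", "condition"])["label"]
    out = X.copy()
    features = list(block.values.index)
    columns = list(block.values.columns)
    for i, feat in enumerate(features):
        for tp in ("BT", "AT"):
            cols = [j for j, s in enumerate(columns) if cond_of[s] == tp]
            if not cols:
                continue
            vals = X[i, cols]
            miss = np.isnan(vals)
            if not miss.any():
                continue
            label = lab.get((feat, tp), MAR)
            if label == MAR:
                observed = vals[~miss]
                if observed.size == 0:
                    logger.warning("feature %s condition %s: MAR with no "
                                   "observed values, falling back to NMAR",
                                   feat, tp)
                    label = NMAR
                else:
                    mu = float(np.mean(observed))
                    draws = rng.normal(mu, params.mar_sd, size=int(miss.sum()))
            if label == NMAR:
                draws = rng.normal(mu_low, sd_med, size=int(miss.sum()))
            out[i, np.array(cols)[miss]] = draws
    return OmicsBlock(pd.DataFrame(out, index=block.values.index,
                                   columns=block.values.columns),
                      block.feature_meta)


# ---------------------------------------------------------------------------
# Empirical-Bayes batch adjustment (parametric ComBat)
# ---------------------------------------------------------------------------

def combat_adjust(block: OmicsBlock, sheet: SampleSheet) -> OmicsBlock:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Requires a complete matrix (run after :func:`impute`) and at least two
    batches of two or more samples.  No covariates are modelled.
    """
    if block.values.isna().to_numpy().any():
        raise ValidationError("combat_adjust requires a complete matrix; "
                              "impute first")
    batches = sheet.batch_of(block.sample_ids)
    levels = list(pd.unique(batches))
    if len(levels) < 2:
        raise ValidationError("combat_adjust needs >= 2 batches")
    sizes = batches.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValidationError(f"batch of size 1: {list(small.index)}")

    X = block.values.to_numpy(dtype=float)
    G, N = X.shape
    idx = {b: np.flatnonzero((batches == b).to_numpy()) for b in levels}
    n_b = np.array([len(idx[b]) for b in levels], dtype=float)

    batch_means = np.stack([X[:, idx[b]].mean(axis=1) for b in levels], axis=1)
    grand = batch_means @ (n_b / N)
    col_batch = np.array([levels.index(b) for b in batches])
    resid = X - batch_means[:, col_batch]
    var_pooled = (resid ** 2).mean(axis=1)
    var_pooled = np.maximum(var_pooled, 1e-12)
    s = (X - grand[:, None]) / np.sqrt(var_pooled)[:, None]

    gamma_star = np.empty((G, len(levels)))
    delta_star = np.empty((G, len(levels)))
    for k, b in enumerate(levels):
        sb = s[:, idx[b]]
        g_hat = sb.mean(axis=1)
        d_hat = sb.var(axis=1, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        d_mean, d_var = d_hat.mean(), d_hat.var(ddof=1)
        a_prior = (2 * d_var + d_mean ** 2) / max(d_var, 1e-12)
        b_prior = (d_mean * d_var + d_mean ** 3) / max(d_var, 1e-12)
        nk = n_b[k]
        g_new, d_new = g_hat.copy(), d_hat.copy()
        for _ in range(200):
            g_old, d_old = g_new, d_new
            g_new = (t2 * nk * g_hat + d_old * g_bar) / (t2 * nk + d_old)
            sum2 = ((sb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (0.5 * sum2 + b_prior) / (nk / 2 + a_prior - 1)
            change = max(np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                         np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)))
            if change < 1e-4:
                break
        gamma_star[:, k] = g_new
        delta_star[:, k] = d_new

    out = s.copy()
    for k, b in enumerate(levels):
        out[:, idx[b]] = ((s[:, idx[b]] - gamma_star[:, [k]])
                          / np.sqrt(delta_star[:, [k]]))
    out = out * np.sqrt(var_pooled)[:, None] + grand[:, None]
    return OmicsBlock(pd.DataFrame(out, index=block.values.index,
                                   columns=block.values.columns),
                      block.feature_meta)


# ---------------------------------------------------------------------------
# Relative abundance
# ---------------------------------------------------------------------------

def relative_abundance(block: OmicsBlock,
                       group_col: str = "precursor_group") -> OmicsBlock:
    """Convert log2 intensities of co-measured modified peptide forms into
    within-precursor percentages.

    Per sample and precursor group: p_i = 100 * 2^x_i / sum_j 2^x_j over the
    observed group members; an all-missing (group, sample) stays missing.
    Percentages of log values would be meaningless, so the conversion to the
    linear scale is explicit here.
    """
    if group_col not in block.feature_meta.columns:
        raise ValidationError(f"feature_meta lacks column {group_col!r}")
    lin = np.power(2.0, block.values)
    out = pd.DataFrame(np.nan, index=block.values.index,
                       columns=block.values.columns)
    for _, members in block.feature_meta.groupby(group_col).groups.items():
        sub = lin.loc[members]
        denom = sub.sum(axis=0, skipna=True)
        present = sub.notna().any(axis=0)
        pct = 100.0 * sub.div(denom.where(present), axis=1)
        out.loc[members] = pct
    return OmicsBlock(out, block.feature_meta)


# ---------------------------------------------------------------------------
# Stage driver
# ---------------------------------------------------------------------------

def preprocess_block(block: OmicsBlock, sheet: SampleSheet,
                     design: PairedDesign, params: ImputationParams,
                     kind: str,
                     max_missing: int = 10, min_paired: int = 9
                     ) -> dict[str, object]:
    """Run the fixed stage order for one block:
    filter -> quantile normalize -> classify -> impute -> batch adjust
    (multi-batch blocks only) -> relative abundance (PTM blocks only).

    ``kind`` is ``"ptm"`` or ``"protein"``.  Returns a dict with the
    intermediate and final blocks, labels and drop report.
    """
    if kind == "ptm":
        filtered, report = filter_ptm_features(block, design, max_missing)
    elif kind == "protein":
        filtered, report = filter_protein_groups(block, design, min_paired)
    else:
        raise ValidationError(f"unknown block kind {kind!r}")
    normalized = quantile_normalize(filtered)
    labels = classify_missingness(normalized, design, params)
    imputed = impute(normalized, labels, params, design)
    n_batches = sheet.batch_of(imputed.sample_ids).nunique()
    if n_batches >= 2:
        adjusted = combat_adjust(imputed, sheet)
    else:
        adjusted = imputed
    result: dict[str, object] = {"filtered": filtered, "drop_report": report,
                                 "labels": labels, "imputed": imputed,
                                 "adjusted": adjusted}
    if kind == "ptm":
        result["relative_abundance"] = relative_abundance(adjusted)
    return result
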