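"""Composite biomarker discovery for the paired BT/AT design.

A feature is called a therapy marker only when three independent criteria
agree: the BH-adjusted p-values of both a paired t-test and a paired Wilcoxon
signed-rank test fall below alpha, *and* the lower bound of the jackknife 95%
confidence interval of its PLS-DA variable-importance-in-projection (VIP)
score is at least 1.  Effect sizes are the average log2-fold change (plasma
protein groups) or the average change in percentage points (histone-PTM
relative abundances) over the paired participants.

The PLS-DA model is fitted on autoscaled sample profiles with the BT/AT
status as a centered class indicator.  VIP for feature j over A components:

    VIP_j = sqrt( p * sum_a SS_a w_ja^2 / sum_a SS_a )

with p the number of features, w_a the unit-norm weight vectors and SS_a the
response variance explained by component a; the identity mean(VIP^2) = 1
holds exactly.  The jackknife removes one participant at a time (both his BT
and AT samples), refits, and builds delete-1 pseudo-value standard errors
with a Student-t quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

from .datamodel import OmicsBlock, PairedDesign, ValidationError, logger

_P_FLOOR = 1e-300  # stand-in for a zero-variance, nonzero-mean paired t


# ---------------------------------------------------------------------------
# Classical paired tests
# ---------------------------------------------------------------------------

def paired_tests(block: OmicsBlock, design: PairedDesign,
                 alpha: float = 0.05,
                 sample_type: str | None = None) -> pd.DataFrame:
    """Two-sided paired t and Wilcoxon signed-rank per feature, BH-adjusted.

    Differences are AT - BT over complete pairs.  The Wilcoxon test uses the
    exact null for n <= 25 and drops zero differences (signed-rank
    convention).  A feature whose differences are all zero carries no
    evidence and gets p = 1 for both tests.
    """
    from .preprocess import _infer_sample_type
    stype = sample_type or _infer_sample_type(block, design)
    pairs = [p for p in design.pairs_for(stype)
             if p.bt_sample in block.values.columns
             and p.at_sample in block.values.columns]
    bt = block.values[[p.bt_sample for p in pairs]].to_numpy()
    at = block.values[[p.at_sample for p in pairs]].to_numpy()
    diffs = at - bt

    p_t = np.full(len(block.values), np.nan)
    p_w = np.full(len(block.values), np.nan)
    for i, d in enumerate(diffs):
        d = d[~np.isnan(d)]
        if d.size < 3:
            continue
        if np.all(d == 0):
            p_t[i] = p_w[i] = 1.0
            logger.info("feature %s: all paired differences zero",
                        block.values.index[i])
            continue
        if np.std(d, ddof=1) == 0:
            p_t[i] = _P_FLOOR  # constant nonzero shift: below machine floor
        else:
            p_t[i] = stats.ttest_1samp(d, 0.0).pvalue
        nz = d[d != 0]
        if nz.size == 0:
            p_w[i] = 1.0
        else:
            method = "exact" if nz.size <= 25 else "approx"
            p_w[i] = stats.wilcoxon(nz, zero_method="wilcox",
                                    method=method).pvalue

    def _bh(p: np.ndarray) -> np.ndarray:
        q = np.full_like(p, np.nan)
        ok = ~np.isnan(p)
        if ok.any():
            q[ok] = multipletests(p[ok], method="fdr_bh")[1]
        return q

    return pd.DataFrame({"p_t": p_t, "p_wilcoxon": p_w,
                         "q_t": _bh(p_t), "q_wilcoxon": _bh(p_w)},
                        index=block.values.index)


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class PlsdaModel:
    """A fitted PLS-DA model on autoscaled features.

    ``weights`` are the unit-norm x-weights (features x components),
    ``scores`` the sample scores, ``ss`` the response variance explained per
    component (used by the VIP formula).
    """

    feature_ids: list[str]
    excluded: list[str]
    classes: list[str]
    x_mean: np.ndarray
    x_std: np.ndarray
    weights: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    y_loadings: np.ndarray
    rotations: np.ndarray
    ss: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def transform(self, profiles: pd.DataFrame) -> np.ndarray:
        """Project new sample profiles (rows = samples) with the stored
        centering/scaling and rotations — an affine map, no refitting."""
        missing = [f for f in self.feature_ids if f not in profiles.columns]
        if missing:
            raise ValidationError(f"profiles lack model features: {missing}")
        X = profiles[self.feature_ids].to_numpy(dtype=float)
        return ((X - self.x_mean) / self.x_std) @ self.rotations


def _class_matrix(classes: pd.Series) -> tuple[np.ndarray, list[str]]:
    levels = list(pd.unique(classes))
    if len(levels) < 2:
        raise ValidationError("PLS-DA needs >= 2 classes")
    if len(levels) == 2:
        y = (classes == levels[1]).to_numpy(float)[:, None]
    else:
        y = np.stack([(classes == l).to_numpy(float) for l in levels], axis=1)
    return y, levels


def plsda_fit(profiles: pd.DataFrame, classes: pd.Series,
              n_components: int = 2) -> PlsdaModel:
    """Fit PLS-DA on sample profiles (rows = samples, columns = features).

    Features are autoscaled (mean 0, SD 1); zero-variance features are
    excluded with a warning.  Deterministic.
    """
    classes = classes.loc[profiles.index]
    y, levels = _class_matrix(classes)
    sd = profiles.std(axis=0, ddof=1)
    excluded = list(profiles.columns[(sd == 0) | sd.isna()])
    if excluded:
        logger.warning("PLS-DA: excluding %d zero-variance features",
                       len(excluded))
    kept = [c for c in profiles.columns if c not in set(excluded)]
    X = profiles[kept].to_numpy(dtype=float)
    n, p = X.shape
    max_comp = min(p, n - 1)
    if n_components > max_comp:
        raise ValidationError(
            f"n_components={n_components} exceeds min(features, samples-1)={max_comp}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pls = PLSRegression(n_components=n_components, scale=True)
        pls.fit(X, y)
    t = pls.x_scores_
    q = pls.y_loadings_
    # response variance explained by each (orthogonal) score direction
    ss = np.array([(q[:, a] ** 2).sum() * (t[:, a] ** 2).sum()
                   for a in range(n_components)])
    return PlsdaModel(feature_ids=kept, excluded=excluded, classes=levels,
                      x_mean=pls._x_mean, x_std=pls._x_std,
                      weights=pls.x_weights_, loadings=pls.x_loadings_,
                      scores=t, y_loadings=q, rotations=pls.x_rotations_,
                      ss=ss)


def plsda_fit_block(block: OmicsBlock, classes: pd.Series,
                    n_components: int = 2) -> PlsdaModel:
    """Convenience wrapper taking a (complete) block; classes indexed by
    sample id."""
    return plsda_fit(block.values.T, classes, n_components)


def vip_scores(model: PlsdaModel) -> pd.Series:
    """VIP_j = sqrt(p * sum_a SS_a w_ja^2 / sum_a SS_a)."""
    w2 = model.weights ** 2
    num = w2 @ model.ss
    p = len(model.feature_ids)
    vip = np.sqrt(p * num / model.ss.sum())
    return pd.Series(vip, index=model.feature_ids, name="vip")


def vip_jackknife(block: OmicsBlock, design: PairedDesign,
                  n_components: int = 2, level: float = 0.95,
                  sample_type: str | None = None) -> pd.DataFrame:
    """Leave-one-participant-out jackknife 95% CI of the VIP scores.

    For each paired participant, both his BT and AT samples are removed and
    the PLS-DA model refitted.  Pseudo-values n*VIP_full - (n-1)*VIP_(-i)
    give the delete-1 SE; the CI is VIP_full +/- t_{n-1,(1+level)/2} * SE.
    """
    from .preprocess import _infer_sample_type
    stype = sample_type or _infer_sample_type(block, design)
    pairs = [p for p in design.pairs_for(stype)
             if p.bt_sample in block.values.columns
             and p.at_sample in block.values.columns]
    n = len(pairs)
    if n < 5:
        raise ValidationError("jackknife needs >= 5 paired participants")
    cols = [p.bt_sample for p in pairs] + [p.at_sample for p in pairs]
    classes = pd.Series(["BT"] * n + ["AT"] * n, index=cols)
    profiles = block.values[cols].T

    full = plsda_fit(profiles, classes, n_components)
    vip_full = vip_scores(full)

    replicates = []
    for p in pairs:
        keep = [c for c in cols if c not in (p.bt_sample, p.at_sample)]
        try:
            m = plsda_fit(profiles.loc[keep], classes.loc[keep], n_components)
            replicates.append(vip_scores(m).reindex(vip_full.index))
        except (ValidationError, np.linalg.LinAlgError) as exc:
            logger.warning("jackknife refit failed leaving out %s: %s",
                           p.participant_id, exc)
    if len(replicates) < 3:
        raise ValidationError("fewer than 3 successful jackknife replicates")
    rep = pd.concat(replicates, axis=1).to_numpy()  # features x replicates
    r = rep.shape[1]
    pseudo = n * vip_full.to_numpy()[:, None] - (n - 1) * rep
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        se = np.sqrt(np.nanvar(pseudo, axis=1, ddof=1) / r)
    tq = stats.t.ppf(0.5 + level / 2, df=n - 1)
    return pd.DataFrame({"vip": vip_full,
                         "vip_lb": vip_full - tq * se,
                         "vip_ub": vip_full + tq * se},
                        index=vip_full.index)


# ---------------------------------------------------------------------------
# Effect sizes and selection
# ---------------------------------------------------------------------------

def effect_size(block: OmicsBlock, design: PairedDesign,
                mode: str = "lfc",
                sample_type: str | None = None) -> pd.Series:
    """Average paired change AT - BT per feature.

    ``mode="lfc"`` reads the block as log2 intensities (average log2-fold
    change); ``mode="delta_pp"`` reads it as relative-abundance percentages
    (average change in percentage points).  Features without a complete pair
    get a missing effect.
    """
    if mode not in ("lfc", "delta_pp"):
        raise ValidationError(f"unknown effect mode {mode!r}")
    from .preprocess import _infer_sample_type
    stype = sample_type or _infer_sample_type(block, design)
    pairs = [p for p in design.pairs_for(stype)
             if p.bt_sample in block.values.columns
             and p.at_sample in block.values.columns]
    bt = block.values[[p.bt_sample for p in pairs]].to_numpy()
    at = block.values[[p.at_sample for p in pairs]].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        eff = np.nanmean(at - bt, axis=1)
    return pd.Series(eff, index=block.values.index, name="effect")


@dataclass
class MarkerRecord:
    feature: str
    p_t: float
    p_wilcoxon: float
    q_t: float
    q_wilcoxon: float
    vip: float
    vip_lb: float
    vip_ub: float
    effect: float
    selected: bool


def select_markers(tests: pd.DataFrame, vips: pd.DataFrame,
                   effects: pd.Series, alpha: float = 0.05,
                   vip_threshold: float = 1.0) -> list[MarkerRecord]:
    """Apply the composite rule: q_t <= alpha AND q_wilcoxon <= alpha AND
    jackknife VIP lower bound >= vip_threshold."""
    records = []
    for feat in tests.index:
        row = tests.loc[feat]
        v = vips.loc[feat] if feat in vips.index else pd.Series(
            {"vip": np.nan, "vip_lb": np.nan, "vip_ub": np.nan})
        sel = bool(row["q_t"] <= alpha and row["q_wilcoxon"] <= alpha
                   and v["vip_lb"] >= vip_threshold)
        records.append(MarkerRecord(
            feature=str(feat), p_t=float(row["p_t"]),
            p_wilcoxon=float(row["p_wilcoxon"]), q_t=float(row["q_t"]),
            q_wilcoxon=float(row["q_wilcoxon"]), vip=float(v["vip"]),
            vip_lb=float(v["vip_lb"]), vip_ub=float(v["vip_ub"]),
            effect=float(effects.get(feat, np.nan)), selected=sel))
    return records


def discover_markers(block: OmicsBlock, design: PairedDesign,
                     mode: str = "lfc", alpha: float = 0.05,
                     vip_threshold: float = 1.0, n_components: int = 2,
                     sample_type: str | None = None) -> list[MarkerRecord]:
    """Full composite discovery on one block: paired tests, VIP jackknife,
    effect sizes, selection."""
    tests = paired_tests(block, design, alpha, sample_type=sample_type)
    vips = vip_jackknife(block, design, n_components, sample_type=sample_type)
    effects = effect_size(block, design, mode, sample_type=sample_type)
    return select_markers(tests, vips, effects, alpha, vip_threshold)


def records_frame(records: list[MarkerRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records]).set_index("feature")
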