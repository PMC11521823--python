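"""Ordinal therapy-response categories and effect-size trend shapes.

Agility gains (isometric maximum strength in flexion, extension and
rotation) are expressed as percent change and adjusted for the baseline: the
raw percent change is regressed on the BT value per metric and the residuals,
re-centered to the cohort mean change, remove the advantage or handicap of
starting strong or weak.  A Gaussian mixture model (diagonal covariances,
BIC-selected component count) on the adjusted three-metric change vectors
partitions participants into ordinal performance categories — moderate,
intermediate, max — ordered by mean overall gain.

Marker effect sizes averaged within each ordinal category form a 3-point
profile per marker, classified into a linear trend (increasing/decreasing
with approximately equal steps) or a plateau (first two or last two
categories level) by a deterministic rule with a tolerance expressed as a
fraction of the profile range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .datamodel import (AGILITY_METRICS, ParticipantSheet, ValidationError,
                        logger)

TREND_LABELS = ("increasing_linear", "decreasing_linear",
                "plateau_first_two", "plateau_last_two", "none")

#: ordinal category orders per response class
PERFORMANCE_ORDER = ("moderate", "intermediate", "max")
SELF_ASSESSMENT_ORDER = ("improving", "stagnating", "worsening")


# ---------------------------------------------------------------------------
# Baseline adjustment
# ---------------------------------------------------------------------------

def baseline_adjust(participants: ParticipantSheet) -> pd.DataFrame:
    """Baseline-corrected percent change per participant and agility metric.

    raw = 100*(AT-BT)/BT; the adjusted value is the residual of regressing
    raw on BT, re-centered to the cohort mean change.  With no baseline
    variation the regression is skipped and raw changes are returned.
    """
    bt = participants.agility("bt")
    at = participants.agility("at")
    if (bt <= 0).any().any():
        raise ValidationError("BT agility values must be positive")
    raw = 100.0 * (at - bt) / bt
    adjusted = pd.DataFrame(index=raw.index, columns=AGILITY_METRICS,
                            dtype=float)
    for metric in AGILITY_METRICS:
        x = bt[metric].to_numpy(dtype=float)
        y = raw[metric].to_numpy(dtype=float)
        if np.std(x) == 0:
            adjusted[metric] = y
            continue
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        adjusted[metric] = resid + y.mean()
    return adjusted


# ---------------------------------------------------------------------------
# Gaussian-mixture performance categories
# ---------------------------------------------------------------------------

@dataclass
class GmmFit:
    k: int
    means: np.ndarray          # k x metrics
    covariances: np.ndarray    # k x metrics (diagonal)
    weights: np.ndarray
    responsibilities: pd.DataFrame  # participants x components
    hard_labels: pd.Series
    bic_trace: dict[int, float]


def gmm_categories(adjusted: pd.DataFrame, k_max: int = 4,
                   seed: int = 0) -> tuple[GmmFit, pd.Series]:
    """Fit diagonal-covariance Gaussian mixtures for k = 1..k_max with
    multiple seeded restarts, pick k by BIC, and order components by mean
    overall change into ordinal labels (moderate < intermediate < max when
    k = 3; numeric levels otherwise)."""
    n = adjusted.shape[0]
    if n < k_max + 2:
        raise ValidationError(f"need >= k_max+2={k_max + 2} participants, got {n}")
    X = adjusted.to_numpy(dtype=float)
    reg_covar = 1e-6
    fits: dict[int, GaussianMixture] = {}
    bic: dict[int, float] = {}
    usable: list[int] = []
    for k in range(1, k_max + 1):
        gm = GaussianMixture(n_components=k, covariance_type="diag",
                             n_init=10, random_state=seed,
                             reg_covar=reg_covar)
        gm.fit(X)
        if not gm.converged_:
            logger.warning("GMM k=%d did not converge", k)
        fits[k] = gm
        bic[k] = float(gm.bic(X))
        # guard against the small-n failure mode of likelihood-based
        # selection: a component collapsing onto <2 points with vanishing
        # variance drives the BIC to favor spurious extra components
        counts = np.bincount(gm.predict(X), minlength=k)
        degenerate = counts.min() < 2 or gm.covariances_.min() <= 10 * reg_covar
        if degenerate:
            logger.warning("GMM k=%d degenerate (component with <2 members "
                           "or collapsed variance), excluded from selection", k)
        else:
            usable.append(k)
    if not usable:
        raise ValidationError("all GMM fits degenerate")
    k_best = min(usable, key=bic.get)
    gm = fits[k_best]
    order = np.argsort(gm.means_.mean(axis=1))  # ascending overall change
    rank_of = {int(comp): r for r, comp in enumerate(order)}
    if k_best == 3:
        names = {r: PERFORMANCE_ORDER[r] for r in range(3)}
    else:
        names = {r: f"level_{r + 1}" for r in range(k_best)}
    resp = gm.predict_proba(X)[:, order]
    hard = pd.Series([names[rank_of[int(c)]] for c in gm.predict(X)],
                     index=adjusted.index, name="performance")
    fit = GmmFit(k=k_best, means=gm.means_[order],
                 covariances=gm.covariances_[order],
                 weights=gm.weights_[order],
                 responsibilities=pd.DataFrame(resp, index=adjusted.index,
                                               columns=[names[r] for r in range(k_best)]),
                 hard_labels=hard, bic_trace=bic)
    return fit, hard


# ---------------------------------------------------------------------------
# Trend profiles and classification
# ---------------------------------------------------------------------------

def category_effect_profile(effects: pd.DataFrame, labels: pd.Series,
                            category_order: tuple[str, ...] = PERFORMANCE_ORDER,
                            exclude: tuple[str, ...] = ()
                            ) -> pd.DataFrame:
    """Markers x categories matrix of category-wise mean effects.

    ``effects`` is participants x markers (per-participant paired changes),
    ``labels`` the ordinal category per participant.  Categories listed in
    ``exclude`` (e.g., "unimpaired" for self-assessment profiles) are dropped
    before averaging; an empty category yields a missing mean.
    """
    labels = labels.loc[effects.index]
    keep = ~labels.isin(exclude)
    eff, lab = effects[keep], labels[keep]
    unknown = set(lab) - set(category_order)
    if unknown:
        raise ValidationError(f"labels outside category order: {sorted(unknown)}")
    profile = pd.DataFrame(index=effects.columns, columns=list(category_order),
                           dtype=float)
    for cat in category_order:
        members = lab.index[lab == cat]
        if len(members):
            profile[cat] = eff.loc[members].mean(axis=0)
    return profile


def trend_classify(profile, tol: float = 0.25) -> str:
    """Classify a 3-category mean-effect profile.

    A linear trend requires strict monotonicity with both steps equal within
    ``tol`` x range; a plateau requires two adjacent means equal within
    tolerance and the third clearly apart.  Anything else — including a flat
    or non-finite profile — is ``none``.
    """
    m = np.asarray(profile, dtype=float)
    if m.size != 3 or not np.isfinite(m).all():
        return "none"
    rng = m.max() - m.min()
    if rng == 0:
        return "none"
    band = tol * rng
    step1, step2 = m[1] - m[0], m[2] - m[1]
    if m[0] < m[1] < m[2] and abs(step1 - step2) <= band:
        return "increasing_linear"
    if m[0] > m[1] > m[2] and abs(step1 - step2) <= band:
        return "decreasing_linear"
    if abs(step1) <= band and abs(step2) > band:
        return "plateau_first_two"
    if abs(step2) <= band and abs(step1) > band:
        return "plateau_last_two"
    return "none"


def classify_trends(effects: pd.DataFrame, labels: pd.Series,
                    category_order: tuple[str, ...] = PERFORMANCE_ORDER,
                    exclude: tuple[str, ...] = (),
                    tol: float = 0.25) -> pd.DataFrame:
    """Per-marker trend classification over ordinal categories."""
    profile = category_effect_profile(effects, labels, category_order, exclude)
    out = profile.copy()
    out["trend"] = [trend_classify(profile.loc[f], tol) for f in profile.index]
    return out
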