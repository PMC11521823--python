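"""Health-awareness indicators: lifestyle PLS-DA maps, therapy-effect
distance, cross-sample-type concordance and similarity to the healthy range.

For each (sample type, lifestyle component) combination a 2-component PLS-DA
model is fitted on BT profiles with the lifestyle categories as outcome.  AT
profiles are projected into the same variate plane (no refitting); the
Euclidean distance d_BT-AT between a participant's BT and projected AT
points is a proxy for the molecular therapy effect on that lifestyle axis.
Concordance of the participant rankings by d_BT-AT across sample types is
quantified by Kendall's coefficient of concordance W (tie-corrected).

Because d_BT-AT is unoriented, similarity to the healthiest category is
scored explicitly: the features with VIP >= 1 are the health-awareness
indicators; each is min-max normalized against the cohort AT values; the
healthy category's members define a jackknife 95% range per indicator; and a
participant's VIP-weighted similarity score averages, over indicators, 1
inside the range and a linear decay (floor 0) over one range-width outside.
One-sided paired t-tests (AT > BT) on the scores, BH-adjusted across the
nine (sample type x lifestyle) cells, test for convergence toward health.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .datamodel import ValidationError, logger
from .markers import PlsdaModel, plsda_fit, vip_scores

EPS_RANGE = 0.05  # floor on the range width used by the decay, normalized units


# ---------------------------------------------------------------------------
# Lifestyle maps and therapy-effect distance
# ---------------------------------------------------------------------------

@dataclass
class HealthMap:
    lifestyle_component: str
    sample_type: str
    model: PlsdaModel
    bt_coords: pd.DataFrame            # participants x 2
    at_coords: pd.DataFrame | None = None
    healthy_category: str | None = None
    healthy_centroid: np.ndarray | None = None

    @property
    def d_bt_at(self) -> pd.Series:
        if self.at_coords is None:
            raise ValidationError("AT coordinates not projected yet")
        d = np.linalg.norm(self.bt_coords.to_numpy()
                           - self.at_coords.loc[self.bt_coords.index].to_numpy(),
                           axis=1)
        return pd.Series(d, index=self.bt_coords.index, name="d_bt_at")

    @property
    def bt_distance_to_healthy(self) -> pd.Series:
        if self.healthy_centroid is None:
            raise ValidationError("healthy centroid undefined")
        d = np.linalg.norm(self.bt_coords.to_numpy()
                           - self.healthy_centroid[None, :], axis=1)
        return pd.Series(d, index=self.bt_coords.index, name="d_bt_healthy")


def fit_health_map(bt_profiles: pd.DataFrame, labels: pd.Series,
                   lifestyle_component: str = "", sample_type: str = "",
                   healthy_category: str | None = None,
                   n_components: int = 2) -> HealthMap:
    """Fit a lifestyle PLS-DA map on BT participant profiles.

    ``bt_profiles`` is participants x features; ``labels`` the lifestyle
    category per participant.  Categories with a single member are retained
    (with a warning) — at n = 12 dropping them would be worse.
    """
    labels = labels.loc[bt_profiles.index]
    counts = labels.value_counts()
    for cat, cnt in counts.items():
        if cnt == 1:
            logger.warning("lifestyle category %r has a single member", cat)
    model = plsda_fit(bt_profiles, labels, n_components)
    coords = pd.DataFrame(model.transform(bt_profiles)[:, :2],
                          index=bt_profiles.index, columns=["c1", "c2"])
    hm = HealthMap(lifestyle_component=lifestyle_component,
                   sample_type=sample_type, model=model, bt_coords=coords,
                   healthy_category=healthy_category)
    if healthy_category is not None:
        members = labels.index[labels == healthy_category]
        if len(members) == 0:
            raise ValidationError(
                f"healthy category {healthy_category!r} has no members")
        hm.healthy_centroid = coords.loc[members].mean(axis=0).to_numpy()
    return hm


def project_at(hmap: HealthMap, at_profiles: pd.DataFrame) -> pd.DataFrame:
    """Project AT profiles into the BT-fitted variate plane (affine map with
    the stored centering/scaling; no refitting)."""
    coords = pd.DataFrame(hmap.model.transform(at_profiles)[:, :2],
                          index=at_profiles.index, columns=["c1", "c2"])
    hmap.at_coords = coords
    return coords


def therapy_effect_distance(hmap: HealthMap) -> pd.Series:
    """Per-participant Euclidean distance between BT and projected AT points."""
    return hmap.d_bt_at


# ---------------------------------------------------------------------------
# Kendall's W
# ---------------------------------------------------------------------------

def kendalls_w(values: pd.DataFrame) -> tuple[float, float, int, float]:
    """Tie-corrected Kendall coefficient of concordance.

    ``values`` is items x raters; items are ranked within each rater (mean
    ranks for ties).  Returns (W, chi2, df, p) with
    W = 12 S / (m^2 (n^3 - n) - m sum(T)), chi2 = m (n-1) W, df = n - 1.
    """
    X = values.to_numpy(dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValidationError("Kendall's W needs >= 2 raters")
    if n < 3:
        raise ValidationError("Kendall's W needs >= 3 items")
    ranks = np.empty_like(X)
    T = np.zeros(m)
    for j in range(m):
        col = X[:, j]
        if np.all(col == col[0]):
            logger.warning("rater %s gives constant ratings (all ranks tied)",
                           values.columns[j])
        ranks[:, j] = stats.rankdata(col, method="average")
        _, counts = np.unique(col, return_counts=True)
        T[j] = float(np.sum(counts ** 3 - counts))
    denom = m ** 2 * (n ** 3 - n) - m * T.sum()
    if denom <= 0:
        raise ValidationError("all raters constant: W undefined")
    R = ranks.sum(axis=1)
    S = float(np.sum((R - R.mean()) ** 2))
    W = 12.0 * S / denom
    chi2 = m * (n - 1) * W
    df = n - 1
    p = float(stats.chi2.sf(chi2, df))
    return float(W), float(chi2), df, p


# ---------------------------------------------------------------------------
# Healthy range and weighted similarity
# ---------------------------------------------------------------------------

@dataclass
class HealthyRange:
    feature: str
    weight: float   # VIP score of the indicator (>= 1 by the gate)
    lo: float
    hi: float


@dataclass
class SimilarityScore:
    participant: str
    timepoint: str
    n_in_range: int
    weighted_score: float


def normalize_indicators(profiles: pd.DataFrame, reference: pd.DataFrame,
                         indicators: list[str]) -> pd.DataFrame:
    """Min-max normalize indicator columns to [0,1] using the reference
    (cohort AT) values; values beyond the reference extremes are clipped."""
    lo = reference[indicators].min(axis=0)
    hi = reference[indicators].max(axis=0)
    span = (hi - lo).replace(0, 1.0)
    norm = (profiles[indicators] - lo) / span
    return norm.clip(0.0, 1.0)


def healthy_range(hmap: HealthMap, profiles: pd.DataFrame,
                  labels: pd.Series, reference: pd.DataFrame | None = None,
                  level: float = 0.95,
                  vip_threshold: float = 1.0) -> list[HealthyRange]:
    """Jackknife 95% range of the healthy category per VIP-gated indicator.

    ``profiles`` supplies the healthy members' values (participants x
    features); ``reference`` the normalization scale (defaults to
    ``profiles``, the pipeline passes the cohort AT profiles).  The range is
    the jackknife mean +/- t_{h-1,(1+level)/2} * SE of the healthy members'
    normalized values, clipped to [0,1].
    """
    if hmap.healthy_category is None:
        raise ValidationError("health map lacks a healthy category")
    labels = labels.loc[profiles.index.intersection(labels.index)]
    members = labels.index[labels == hmap.healthy_category]
    h = len(members)
    if h < 3:
        raise ValidationError(
            f"healthy category needs >= 3 members, got {h}")
    vip = vip_scores(hmap.model)
    indicators = list(vip.index[vip >= vip_threshold])
    ref = reference if reference is not None else profiles
    norm = normalize_indicators(profiles, ref, indicators)
    tq = stats.t.ppf(0.5 + level / 2, df=h - 1)
    ranges = []
    for feat in indicators:
        x = norm.loc[members, feat].to_numpy(dtype=float)
        theta = x.mean()
        loo = (x.sum() - x) / (h - 1)          # delete-1 means
        se = np.sqrt((h - 1) / h * np.sum((loo - loo.mean()) ** 2))
        lo = float(np.clip(theta - tq * se, 0.0, 1.0))
        hi = float(np.clip(theta + tq * se, 0.0, 1.0))
        ranges.append(HealthyRange(feature=feat, weight=float(vip[feat]),
                                   lo=lo, hi=hi))
    return ranges


def similarity_score(profile_norm: pd.Series, ranges: list[HealthyRange],
                     participant: str = "", timepoint: str = ""
                     ) -> SimilarityScore:
    """VIP-weighted similarity of one normalized profile to the healthy range.

    Per indicator: s = 1 inside the (inclusive) range, else a linear decay
    max(0, 1 - dist/r) over one range-width r (floored at EPS_RANGE).
    """
    s_vals, weights, n_in = [], [], 0
    for r in ranges:
        if r.feature not in profile_norm.index:
            raise ValidationError(f"profile lacks indicator {r.feature!r}")
        x = float(profile_norm[r.feature])
        if r.lo <= x <= r.hi:
            s = 1.0
            n_in += 1
        else:
            dist = (r.lo - x) if x < r.lo else (x - r.hi)
            width = max(r.hi - r.lo, EPS_RANGE)
            s = max(0.0, 1.0 - dist / width)
        s_vals.append(s)
        weights.append(r.weight)
    w = np.asarray(weights)
    score = float(np.asarray(s_vals) @ w / w.sum()) if w.sum() else np.nan
    return SimilarityScore(participant=participant, timepoint=timepoint,
                           n_in_range=n_in, weighted_score=score)


def score_cohort(profiles_bt: pd.DataFrame, profiles_at: pd.DataFrame,
                 ranges: list[HealthyRange],
                 reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Similarity scores for every participant at BT and AT."""
    indicators = [r.feature for r in ranges]
    ref = reference if reference is not None else profiles_at
    rows = []
    for tp, prof in (("BT", profiles_bt), ("AT", profiles_at)):
        norm = normalize_indicators(prof, ref, indicators)
        for pid in prof.index:
            s = similarity_score(norm.loc[pid], ranges, str(pid), tp)
            rows.append(s.__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BT vs AT comparison and robust regression
# ---------------------------------------------------------------------------

def _paired_t_greater(at: np.ndarray, bt: np.ndarray) -> tuple[float, float]:
    """One-sided paired t (AT > BT) with a zero-variance limit: constant
    positive differences drive p to 0, constant zero to 0.5."""
    d = at - bt
    if np.std(d, ddof=1) == 0:
        mean = d.mean()
        if mean > 0:
            return np.inf, 0.0
        if mean < 0:
            return -np.inf, 1.0
        return 0.0, 0.5
    res = stats.ttest_rel(at, bt, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def compare_bt_at(scores: pd.DataFrame) -> pd.DataFrame:
    """One-sided paired t (AT > BT) on weighted similarity scores per
    (sample_type, lifestyle) cell, BH-adjusted across cells.

    ``scores`` needs columns sample_type, lifestyle, participant, timepoint,
    weighted_score, n_in_range.  Also reports the count of participants
    whose n_in_range increased.
    """
    from statsmodels.stats.multitest import multipletests
    rows = []
    for (stype, life), grp in scores.groupby(["sample_type", "lifestyle"]):
        wide = grp.pivot(index="participant", columns="timepoint",
                         values="weighted_score").dropna()
        nir = grp.pivot(index="participant", columns="timepoint",
                        values="n_in_range").dropna()
        n_improved = int((nir["AT"] > nir["BT"]).sum()) if {"BT", "AT"} <= set(nir.columns) else 0
        if len(wide) < 3 or not {"BT", "AT"} <= set(wide.columns):
            t_stat, p = np.nan, np.nan
        else:
            t_stat, p = _paired_t_greater(wide["AT"].to_numpy(),
                                          wide["BT"].to_numpy())
        rows.append({"sample_type": stype, "lifestyle": life,
                     "n_pairs": len(wide), "t": t_stat, "p": p,
                     "n_in_range_increased": n_improved})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def robust_regress(y: pd.Series | np.ndarray,
                   x: pd.Series | np.ndarray) -> tuple[float, float, float]:
    """Huber M-estimation of y on x (tuning constant 1.345), IRLS to 1e-8.

    Returns (slope, intercept, Wald p of the slope).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValidationError("robust regression needs >= 5 points")
    if np.std(x) == 0:
        raise ValidationError("zero variance in x")
    X = sm.add_constant(x)
    fit = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit(
        conv="coefs", tol=1e-8, maxiter=500)
    slope = float(fit.params[1])
    intercept = float(fit.params[0])
    p = float(fit.pvalues[1])
    return slope, intercept, p
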