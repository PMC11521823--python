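"""Calibration and recovery experiments on synthetic cohorts.

Each experiment generates its inputs with the synthetic-cohort machinery,
runs the corresponding pipeline stage from scratch and measures how well the
planted truth is recovered.  They serve two purposes: quantitative sanity
checks a user can run against their own expectations, and the quantities
reported by the repository's acceptance script.

All experiments are deterministic given their seed; simulation sizes follow
the cohort design (12 paired participants) with feature counts chosen to
keep each experiment in the seconds-to-minutes range on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import health as H
from . import integrate as I
from . import markers as M
from . import preprocess as P
from . import synth as S
from .datamodel import OmicsBlock, SampleSheet, build_paired_design
from .response import PERFORMANCE_ORDER, category_effect_profile, trend_classify


def _sub(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2 ** 31))


def _paired_block(bt: np.ndarray, at: np.ndarray):
    n = bt.shape[1]
    rows = []
    for i in range(n):
        pid = f"P{i + 1:02d}"
        for tp in ("BT", "AT"):
            rows.append({"sample_id": f"{pid}_{tp}", "participant_id": pid,
                         "timepoint": tp, "sample_type": "plasma",
                         "batch": "1"})
    sheet = SampleSheet(pd.DataFrame(rows))
    cols = [f"P{i + 1:02d}_{tp}" for i in range(n) for tp in ("BT", "AT")]
    vals = np.empty((bt.shape[0], 2 * n))
    vals[:, 0::2] = bt
    vals[:, 1::2] = at
    values = pd.DataFrame(vals, index=[f"f{i}" for i in range(bt.shape[0])],
                          columns=cols)
    block = OmicsBlock(values, pd.DataFrame(index=values.index))
    return block, sheet, build_paired_design(sheet)


# ---------------------------------------------------------------------------
# Imputation calibration
# ---------------------------------------------------------------------------

def mar_imputation_calibration(seed: int, n_draws: int = 1000,
                               condition_mean: float = 18.4) -> dict:
    """Impute ``n_draws`` MAR cells whose condition mean is known and report
    the empirical mean and SD of the draws (targets: mean, SD 0.5)."""
    n = 2 * n_draws
    bt = np.full((1, n), condition_mean)
    at = np.full((1, n), condition_mean)
    at[0, n_draws:] = np.nan
    block, _, design = _paired_block(bt, at)
    params = P.ImputationParams(seed=_sub(seed, 1))
    labels = P.classify_missingness(block, design, params,
                                    sample_type="plasma")
    out = P.impute(block, labels, params, design, sample_type="plasma")
    drawn = out.values.to_numpy()[0][block.values.isna().to_numpy()[0]]
    return {"mar_mean": float(drawn.mean()),
            "mar_sd": float(drawn.std(ddof=1)),
            "n": n_draws}


def nmar_imputation_calibration(seed: int) -> dict:
    """On a censored synthetic block, the NMAR draws must concentrate in the
    low-intensity tail (below the block median)."""
    rng = np.random.default_rng(_sub(seed, 2))
    n = 12
    vals = rng.normal(20, 2, (200, 2 * n))
    vals[:5, :n] = np.nan          # five features censored at BT
    vals[:5, n:] = rng.normal(13, 0.5, (5, n))
    block, _, design = _paired_block(vals[:, :n], vals[:, n:])
    params = P.ImputationParams(seed=_sub(seed, 3))
    labels = P.classify_missingness(block, design, params,
                                    sample_type="plasma")
    out = P.impute(block, labels, params, design, sample_type="plasma")
    imputed = out.values.to_numpy()[block.values.isna().to_numpy()]
    median = float(np.nanmedian(block.values.to_numpy()))
    return {"nmar_below_median_fraction": float((imputed < median).mean()),
            "n": int(imputed.size)}


# ---------------------------------------------------------------------------
# Composite-selector calibration and power
# ---------------------------------------------------------------------------

def _selector_run(seed: int, n_features: int, n_planted: int,
                  effect: float) -> tuple[set, set]:
    cfg = S.SynthConfig(
        seed=seed,
        n_features={"buccal": 4, "pbmc": 4, "plasma": n_features},
        n_planted={"buccal": 0, "pbmc": 0, "plasma": n_planted},
        effect_size=effect, trend_shapes="constant",
        batch_shift=0.0, batch_scale=1.0,
        mnar_censor_quantile=0.0, mcar_rate=0.0)
    blocks, sheet, _, truth = S.generate_cohort(cfg)
    design = build_paired_design(sheet)
    recs = M.discover_markers(blocks["plasma"], design, mode="lfc",
                              sample_type="plasma")
    selected = {r.feature for r in recs if r.selected}
    return selected, set(truth.planted["plasma"])


def selector_null_calibration(seed: int, n_repeats: int = 50,
                              n_features: int = 200) -> dict:
    """Global null (no planted effect, 12 pairs): the composite rule should
    select about nothing — at most one feature per repeat on average."""
    counts = [len(_selector_run(_sub(seed, 100 + r), n_features, 0, 0.0)[0])
              for r in range(n_repeats)]
    return {"null_mean_selected": float(np.mean(counts)), "n": n_repeats}


def selector_power(seed: int, n_seeds: int = 25, n_features: int = 200,
                   n_planted: int = 20, noise_sd: float = 0.5) -> dict:
    """20 planted markers at 1.5x the SD of the paired change (Cohen's d_z
    scale): sensitivity and empirical FDR of the composite selector."""
    effect = 1.5 * np.sqrt(2.0) * noise_sd
    sens, fdr = [], []
    for r in range(n_seeds):
        selected, planted = _selector_run(_sub(seed, 200 + r), n_features,
                                          n_planted, effect)
        sens.append(len(selected & planted) / len(planted))
        fdr.append(len(selected - planted) / max(len(selected), 1))
    return {"power_sensitivity": float(np.mean(sens)),
            "power_fdr": float(np.mean(fdr)), "n": n_seeds}


# ---------------------------------------------------------------------------
# Algebraic identities
# ---------------------------------------------------------------------------

def algebraic_identities(seed: int) -> dict:
    """Worst-case deviations of three exact identities: mean VIP^2 = 1,
    relative-abundance group sums = 100, and shared sorted vectors after
    quantile normalization of complete samples."""
    rng = np.random.default_rng(_sub(seed, 4))
    vip_dev = 0.0
    for rep in range(5):
        n, p = 24, 30 + 7 * rep
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         index=[f"s{i}" for i in range(n)])
        cls = pd.Series(["BT", "AT"] * (n // 2), index=X.index)
        model = M.plsda_fit(X, cls, 2)
        v = M.vip_scores(model)
        vip_dev = max(vip_dev, abs(float((v ** 2).mean()) - 1.0))

    cfg = S.SynthConfig(seed=_sub(seed, 5), mnar_censor_quantile=0.0,
                        mcar_rate=0.0)
    blocks, _, _, _ = S.generate_cohort(cfg)
    ra = P.relative_abundance(blocks["pbmc"])
    ra_dev = 0.0
    for _, members in ra.feature_meta.groupby("precursor_group").groups.items():
        sums = ra.values.loc[members].sum(axis=0).to_numpy()
        ra_dev = max(ra_dev, float(np.abs(sums - 100.0).max()))

    qn = P.quantile_normalize(blocks["plasma"]).values.to_numpy()
    ref = np.sort(qn[:, 0])
    qn_dev = max(float(np.abs(np.sort(qn[:, j]) - ref).max())
                 for j in range(1, qn.shape[1]))
    return {"vip_identity_deviation": vip_dev,
            "ra_sum_deviation": ra_dev,
            "qnorm_sorted_deviation": qn_dev, "n": 5}


# ---------------------------------------------------------------------------
# SNF recovery
# ---------------------------------------------------------------------------

def snf_recovery(seed: int, n_seeds: int = 25) -> dict:
    """Three well-separated planted participant clusters (4 each) seen
    through two noisy views with independent random cluster centers: ARI of
    spectral clustering on the fused matrix vs the single views."""
    from sklearn.metrics import adjusted_rand_score
    f = 10
    labels = np.repeat([0, 1, 2], 4)
    ids = [f"P{i:02d}" for i in range(12)]
    ari_f, ari_best_single, wins = [], [], 0
    for r in range(n_seeds):
        rng = np.random.default_rng(_sub(seed, 300 + r))
        views = []
        for _ in range(2):
            # mutually orthogonal cluster centers (pairwise distance
            # 4*sqrt(2)) in a random per-view orientation; noise 0.6 keeps
            # the separation at ~2x the within-cluster pair distance
            q, _r = np.linalg.qr(rng.normal(size=(f, 3)))
            centers = 4.0 * q.T
            ch = pd.DataFrame([centers[c] + rng.normal(0, 0.6, f)
                               for c in labels], index=ids)
            views.append(I.build_affinity(ch, K=3))
        fused = I.snf_fuse(views, K=3, t=20)
        af = adjusted_rand_score(labels,
                                 I.spectral_cluster(fused, k=3, seed=0)[0])
        singles = [adjusted_rand_score(
            labels, I.spectral_cluster(v, k=3, seed=0)[0]) for v in views]
        ari_f.append(af)
        ari_best_single.append(max(singles))
        wins += af >= max(singles)
    return {"snf_fused_ari": float(np.mean(ari_f)),
            "snf_best_single_view_ari": float(np.mean(ari_best_single)),
            "snf_fused_not_worse_fraction": wins / n_seeds, "n": n_seeds}


# ---------------------------------------------------------------------------
# Batch adjustment
# ---------------------------------------------------------------------------

def batch_adjustment_recovery(seed: int) -> dict:
    """Two batches shifted by 2 log2 units, orthogonal to a planted BT/AT
    effect: systematic shift removed, effect preserved."""
    rng = np.random.default_rng(_sub(seed, 6))
    n = 15
    bt = rng.normal(20, 0.5, (200, n))
    effect = rng.normal(0, 0.8, 200)
    at = bt + effect[:, None] + rng.normal(0, 0.5, (200, n))
    block, sheet, design = _paired_block(bt, at)
    tab = sheet.table.copy()
    half = n // 2
    tab["batch"] = np.where(
        tab["participant_id"].str[1:].astype(int) <= half, "b1", "b2")
    sheet = SampleSheet(tab)
    shifted = S.inject_batch_effects(block, sheet, shift=2.0, scale=1.0,
                                     seed=_sub(seed, 7))
    adjusted = P.combat_adjust(shifted, sheet)
    b = sheet.batch_of(adjusted.sample_ids)
    post = (adjusted.values.loc[:, (b == "b1").values].mean(axis=1)
            - adjusted.values.loc[:, (b == "b2").values].mean(axis=1))
    eff_pre = M.effect_size(block, design, "lfc", sample_type="plasma")
    eff_post = M.effect_size(adjusted, design, "lfc", sample_type="plasma")
    return {"batch_mean_diff_post": float(abs(post.mean())),
            "batch_effect_preservation_corr":
                float(np.corrcoef(eff_pre, eff_post)[0, 1]), "n": 200}


# ---------------------------------------------------------------------------
# Trend recovery
# ---------------------------------------------------------------------------

def trend_recovery(seed: int, n_repeats: int = 100, effect: float = 2.0,
                   noise_fraction: float = 0.1) -> dict:
    """Planted linear/plateau shapes with per-participant noise of
    0.1 x effect: recovery rate of the rule-based classifier."""
    rng = np.random.default_rng(_sub(seed, 8))
    labels = pd.Series(np.repeat(PERFORMANCE_ORDER, 4),
                       index=[f"P{i:02d}" for i in range(12)])
    mult_idx = labels.map({c: i for i, c in enumerate(PERFORMANCE_ORDER)})
    hits = total = 0
    for shape, mult in S.TREND_MULTIPLIERS.items():
        if shape == "constant":
            continue
        for _ in range(n_repeats):
            per_part = (effect * np.asarray(mult)[mult_idx]
                        + rng.normal(0, noise_fraction * effect, 12))
            effects = pd.DataFrame({"m": per_part}, index=labels.index)
            prof = category_effect_profile(effects, labels)
            hits += trend_classify(prof.loc["m"]) == shape
            total += 1
    return {"trend_recovery_rate": hits / total, "n": total}


# ---------------------------------------------------------------------------
# Kendall's W reference checks
# ---------------------------------------------------------------------------

def kendall_checks(seed: int) -> dict:
    """W on identical and reversed rankings, plus agreement with a direct
    evaluation of the concordance formula on a 3-rater x 4-item table."""
    rng = np.random.default_rng(_sub(seed, 9))
    base = rng.normal(size=12)
    w_id, *_ = H.kendalls_w(pd.DataFrame({"a": base, "b": base, "c": base}))
    x = np.arange(10, dtype=float)
    w_rev, *_ = H.kendalls_w(pd.DataFrame({"a": x, "b": -x}))
    toy = pd.DataFrame({"r1": [1.0, 2.0, 3.0, 4.0],
                        "r2": [2.0, 1.0, 4.0, 3.0],
                        "r3": [1.0, 3.0, 2.0, 4.0]})
    w_toy, *_ = H.kendalls_w(toy)
    R = toy.to_numpy().sum(axis=1)
    S_ = ((R - R.mean()) ** 2).sum()
    w_expect = 12 * S_ / (9 * (64 - 4))
    return {"kendall_w_identical": float(w_id),
            "kendall_w_reversed": float(w_rev),
            "kendall_w_toy_error": float(abs(w_toy - w_expect)), "n": 4}


# ---------------------------------------------------------------------------
# Health-awareness scoring
# ---------------------------------------------------------------------------

def health_shift_power(seed: int, n_seeds: int = 100, shift: float = 0.2,
                       alpha: float = 0.05) -> dict:
    """Power of the one-sided paired t on weighted similarity scores when AT
    profiles move a fraction ``shift`` of the way toward the healthy
    centroid (n = 12 participants)."""
    detected = 0
    for r in range(n_seeds):
        rng = np.random.default_rng(_sub(seed, 400 + r))
        n, p, n_healthy = 12, 16, 5
        idx = [f"P{i + 1:02d}" for i in range(n)]
        bt = pd.DataFrame(rng.normal(0, 1, (n, p)), index=idx,
                          columns=[f"f{j}" for j in range(p)])
        labels = pd.Series(["sportive"] * n_healthy
                           + ["sedentary"] * (n - n_healthy), index=idx)
        bt.iloc[:n_healthy, :8] += 2.0
        centroid = bt.loc[labels == "sportive"].mean(axis=0)
        at = bt + shift * (centroid - bt) + rng.normal(0, 0.1, (n, p))
        hmap = H.fit_health_map(bt, labels, healthy_category="sportive")
        try:
            ranges = H.healthy_range(hmap, at, labels, reference=at)
        except Exception:
            continue
        if not ranges:
            continue
        scores = H.score_cohort(bt, at, ranges, reference=at)
        scores["sample_type"] = "plasma"
        scores["lifestyle"] = "exercise"
        out = H.compare_bt_at(scores)
        detected += bool(out.loc[0, "p"] < alpha)
    return {"health_shift_power": detected / n_seeds, "n": n_seeds}


def score_gate_check(seed: int) -> dict:
    """Weighted similarity equals 1 exactly when every indicator is inside
    its healthy range, and drops below 1 as soon as one leaves."""
    ranges = [H.HealthyRange("a", 1.5, 0.4, 0.6),
              H.HealthyRange("b", 1.2, 0.2, 0.5),
              H.HealthyRange("c", 2.0, 0.7, 0.9)]
    inside = H.similarity_score(
        pd.Series({"a": 0.5, "b": 0.3, "c": 0.8}), ranges)
    outside = H.similarity_score(
        pd.Series({"a": 0.5, "b": 0.3, "c": 0.95}), ranges)
    return {"score_all_in_range": float(inside.weighted_score),
            "score_one_outside": float(outside.weighted_score), "n": 3}
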