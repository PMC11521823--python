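"""Lifestyle maps, therapy-effect distance, Kendall's W, healthy ranges,
weighted similarity and robust regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pairedomics as po
from pairedomics.datamodel import ValidationError
from pairedomics.health import HealthyRange, _paired_t_greater


def lifestyle_profiles(rng, n=12, p=16, n_healthy=5, sep=2.0,
                       n_informative=8):
    """BT participant profiles where the healthy category is shifted on the
    informative features."""
    idx = [f"P{i + 1:02d}" for i in range(n)]
    X = pd.DataFrame(rng.normal(0, 1, (n, p)), index=idx,
                     columns=[f"f{j}" for j in range(p)])
    labels = pd.Series(["sportive"] * n_healthy
                       + ["sedentary"] * (n - n_healthy), index=idx)
    X.iloc[:n_healthy, :n_informative] += sep
    return X, labels


class TestHealthMap:
    def test_identical_at_profile_projects_onto_bt_point(self):
        rng = np.random.default_rng(0)
        X, labels = lifestyle_profiles(rng)
        hmap = po.fit_health_map(X, labels, healthy_category="sportive")
        po.project_at(hmap, X)
        assert np.allclose(po.therapy_effect_distance(hmap), 0.0, atol=1e-10)

    def test_projection_is_affine(self):
        rng = np.random.default_rng(1)
        X, labels = lifestyle_profiles(rng)
        hmap = po.fit_health_map(X, labels)
        x, y = X.iloc[[0]], X.iloc[[1]].set_axis(X.index[:1])
        a = 0.3
        mix = a * x + (1 - a) * y
        pa = hmap.model.transform(x)
        pb = hmap.model.transform(y)
        pm = hmap.model.transform(mix)
        np.testing.assert_allclose(pm, a * pa + (1 - a) * pb, atol=1e-10)

    def test_displacement_along_first_loading_moves_component_one_only(self):
        """Linear-algebra oracle: scores are X_scaled @ R with
        R = W (P'W)^{-1}, so P'R = I and a feature-space step of
        delta * p1 (undone autoscaling) displaces the projection by exactly
        (delta, 0)."""
        rng = np.random.default_rng(2)
        X, labels = lifestyle_profiles(rng)
        hmap = po.fit_health_map(X, labels)
        m = hmap.model
        delta = 0.5
        step = delta * m.loadings[:, 0] * m.x_std
        shifted = X.copy()
        shifted.loc[:, m.feature_ids] += step
        d = m.transform(shifted) - m.transform(X)
        np.testing.assert_allclose(d[:, 0], delta, atol=1e-8)
        np.testing.assert_allclose(d[:, 1], 0.0, atol=1e-8)

    def test_bt_coordinates_separate_categories(self):
        rng = np.random.default_rng(3)
        X, labels = lifestyle_profiles(rng, sep=3.0)
        hmap = po.fit_health_map(X, labels)
        c1 = hmap.bt_coords["c1"]
        healthy = c1[labels == "sportive"]
        other = c1[labels == "sedentary"]
        assert (healthy.mean() - other.mean()) ** 2 > 4 * max(
            healthy.var(), other.var())

    def test_distance_is_rotation_invariant(self):
        rng = np.random.default_rng(4)
        X, labels = lifestyle_profiles(rng)
        hmap = po.fit_health_map(X, labels)
        at = X + rng.normal(0, 0.5, X.shape)
        po.project_at(hmap, at)
        d = po.therapy_effect_distance(hmap)
        theta = 0.77
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        bt_rot = hmap.bt_coords.to_numpy() @ R.T
        at_rot = hmap.at_coords.to_numpy() @ R.T
        np.testing.assert_allclose(
            np.linalg.norm(bt_rot - at_rot, axis=1), d, atol=1e-10)

    def test_pythagorean_distance(self):
        rng = np.random.default_rng(5)
        X, labels = lifestyle_profiles(rng)
        hmap = po.fit_health_map(X, labels)
        hmap.bt_coords.iloc[0] = [0.0, 0.0]
        hmap.at_coords = hmap.bt_coords.copy()
        hmap.at_coords.iloc[0] = [3.0, 4.0]
        assert po.therapy_effect_distance(hmap).iloc[0] == pytest.approx(5.0)


class TestKendallsW:
    def test_identical_rankings_give_one(self):
        rng = np.random.default_rng(6)
        base = rng.normal(size=12)
        table = pd.DataFrame({"buccal": base, "pbmc": base, "plasma": base})
        W, chi2, df, p = po.kendalls_w(table)
        assert W == pytest.approx(1.0)
        assert df == 11

    def test_two_reversed_rankings_give_zero(self):
        x = np.arange(10, dtype=float)
        table = pd.DataFrame({"a": x, "b": -x})
        W, *_ = po.kendalls_w(table)
        assert W == pytest.approx(0.0)

    def test_toy_table_matches_brute_force_formula(self):
        table = pd.DataFrame({"r1": [1.0, 2.0, 3.0, 4.0],
                              "r2": [2.0, 1.0, 4.0, 3.0],
                              "r3": [1.0, 3.0, 2.0, 4.0]})
        W, chi2, df, p = po.kendalls_w(table)
        # brute force: ranks are the values themselves (no ties)
        R = table.to_numpy().sum(axis=1)
        S = ((R - R.mean()) ** 2).sum()
        m, n = 3, 4
        W_expect = 12 * S / (m ** 2 * (n ** 3 - n))
        assert W == pytest.approx(W_expect, abs=1e-12)
        assert chi2 == pytest.approx(m * (n - 1) * W_expect, abs=1e-12)

    def test_tie_correction_with_tied_ratings(self):
        table = pd.DataFrame({"a": [1.0, 1.0, 2.0, 3.0],
                              "b": [1.0, 2.0, 2.0, 3.0]})
        W, *_ = po.kendalls_w(table)
        assert 0.0 <= W <= 1.0

    def test_all_constant_raters_rejected(self):
        table = pd.DataFrame({"a": [1.0] * 4, "b": [2.0] * 4})
        with pytest.raises(ValidationError, match="undefined"):
            po.kendalls_w(table)

    def test_shared_latent_effect_gives_high_concordance(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(25):
            latent = rng.uniform(0, 3, 12)
            table = pd.DataFrame({
                s: latent + rng.normal(0, 0.2, 12)
                for s in ("buccal", "pbmc", "plasma")})
            W, *_ = po.kendalls_w(table)
            hits += W >= 0.8
        assert hits >= 24


class TestHealthyRange:
    def _map(self, rng):
        X, labels = lifestyle_profiles(rng, sep=2.5)
        hmap = po.fit_health_map(X, labels, healthy_category="sportive")
        return X, labels, hmap

    def test_indicator_count_equals_vip_gate(self):
        rng = np.random.default_rng(8)
        X, labels, hmap = self._map(rng)
        ranges = po.healthy_range(hmap, X, labels)
        vip = po.vip_scores(hmap.model)
        assert len(ranges) == int((vip >= 1.0).sum())
        assert all(r.weight >= 1.0 for r in ranges)

    def test_equal_healthy_members_give_zero_width(self):
        rng = np.random.default_rng(9)
        X, labels, hmap = self._map(rng)
        members = labels.index[labels == "sportive"]
        X.loc[members] = np.tile(X.loc[members].iloc[0].to_numpy(),
                                 (len(members), 1))
        ranges = po.healthy_range(hmap, X, labels)
        assert all(r.hi == pytest.approx(r.lo, abs=1e-12) for r in ranges)

    def test_fewer_than_three_healthy_members_rejected(self):
        rng = np.random.default_rng(10)
        X, labels, hmap = self._map(rng)
        labels.iloc[:3] = "sedentary"  # leaves 2 healthy
        with pytest.raises(ValidationError, match=">= 3 members"):
            po.healthy_range(hmap, X, labels)

    def test_tight_healthy_cluster_yields_narrow_in_range(self):
        hits = 0
        for seed in range(25):
            rng = np.random.default_rng(100 + seed)
            X, labels, hmap = self._map(rng)
            members = labels.index[labels == "sportive"]
            vip = po.vip_scores(hmap.model)
            indicators = list(vip.index[vip >= 1.0])
            # healthy members tightly around the 0.8 quantile of the scale
            lo = X[indicators].min(axis=0).to_numpy()
            hi = X[indicators].max(axis=0).to_numpy()
            center = lo + 0.8 * (hi - lo)
            jitter = (rng.normal(0, 1, (len(members), len(indicators)))
                      * 0.02 * (hi - lo))
            X.loc[members, indicators] = center + jitter
            ranges = po.healthy_range(hmap, X, labels, reference=X)
            ok = all(0.6 <= r.lo and r.hi <= 1.0 for r in ranges)
            hits += ok
        assert hits >= 24


class TestSimilarityScore:
    RANGES = [HealthyRange("a", 1.5, 0.4, 0.6),
              HealthyRange("b", 1.0, 0.2, 0.5),
              HealthyRange("c", 2.0, 0.7, 0.9)]

    def test_all_inside_scores_one(self):
        prof = pd.Series({"a": 0.5, "b": 0.3, "c": 0.8})
        s = po.similarity_score(prof, self.RANGES)
        assert s.weighted_score == 1.0 and s.n_in_range == 3

    def test_bound_is_inclusive(self):
        prof = pd.Series({"a": 0.6, "b": 0.2, "c": 0.7})
        s = po.similarity_score(prof, self.RANGES)
        assert s.weighted_score == 1.0 and s.n_in_range == 3

    def test_far_outside_indicator_loses_its_weight(self):
        prof = pd.Series({"a": 0.5, "b": 0.3, "c": 0.0})  # c far below 0.7
        s = po.similarity_score(prof, self.RANGES)
        expect = (1.5 + 1.0) / (1.5 + 1.0 + 2.0)
        assert s.weighted_score == pytest.approx(expect)
        assert s.n_in_range == 2

    def test_linear_decay_over_one_range_width(self):
        # 'a' has width 0.2; value 0.7 is 0.1 above hi -> s = 1 - 0.5
        prof = pd.Series({"a": 0.7, "b": 0.3, "c": 0.8})
        s = po.similarity_score(prof, self.RANGES)
        w = np.array([1.5, 1.0, 2.0])
        expect = (0.5 * 1.5 + 1.0 + 2.0) / w.sum()
        assert s.weighted_score == pytest.approx(expect)

    def test_moving_toward_range_never_decreases_score(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            x = rng.uniform(-0.5, 1.5)
            prof = pd.Series({"a": x, "b": 0.3, "c": 0.8})
            closer = x + 0.05 if x < 0.4 else (x - 0.05 if x > 0.6 else x)
            prof2 = pd.Series({"a": closer, "b": 0.3, "c": 0.8})
            s1 = po.similarity_score(prof, self.RANGES).weighted_score
            s2 = po.similarity_score(prof2, self.RANGES).weighted_score
            assert s2 >= s1 - 1e-12


class TestCompareBtAt:
    def _scores(self, bt, at):
        rows = []
        for i, (b, a) in enumerate(zip(bt, at)):
            rows.append({"sample_type": "plasma", "lifestyle": "exercise",
                         "participant": f"P{i:02d}", "timepoint": "BT",
                         "weighted_score": b, "n_in_range": 0})
            rows.append({"sample_type": "plasma", "lifestyle": "exercise",
                         "participant": f"P{i:02d}", "timepoint": "AT",
                         "weighted_score": a, "n_in_range": 1})
        return pd.DataFrame(rows)

    def test_no_change_gives_half_p(self):
        bt = np.linspace(0.2, 0.8, 12)
        out = po.compare_bt_at(self._scores(bt, bt))
        assert out.loc[0, "t"] == 0.0 and out.loc[0, "p"] == 0.5

    def test_constant_positive_shift_drives_p_to_zero(self):
        bt = np.linspace(0.2, 0.6, 12)
        out = po.compare_bt_at(self._scores(bt, bt + 0.2))
        assert out.loc[0, "p"] < 1e-4

    def test_bh_adjusted_at_least_raw(self):
        rng = np.random.default_rng(12)
        rows = []
        for st in ("buccal", "pbmc", "plasma"):
            for life in ("exercise", "diet", "bmi"):
                bt = rng.uniform(0.2, 0.8, 8)
                at = bt + rng.normal(0.05, 0.1, 8)
                for i, (b, a) in enumerate(zip(bt, at)):
                    rows += [{"sample_type": st, "lifestyle": life,
                              "participant": f"P{i}", "timepoint": "BT",
                              "weighted_score": b, "n_in_range": 0},
                             {"sample_type": st, "lifestyle": life,
                              "participant": f"P{i}", "timepoint": "AT",
                              "weighted_score": a, "n_in_range": 1}]
        out = po.compare_bt_at(pd.DataFrame(rows))
        assert len(out) == 9
        assert (out["q"] >= out["p"] - 1e-12).all()

    def test_zero_variance_limits(self):
        assert _paired_t_greater(np.ones(5), np.zeros(5)) == (np.inf, 0.0)
        assert _paired_t_greater(np.zeros(5), np.ones(5)) == (-np.inf, 1.0)
        assert _paired_t_greater(np.ones(5), np.ones(5)) == (0.0, 0.5)


class TestRobustRegress:
    def test_exact_line_recovered(self):
        x = np.linspace(0, 5, 10)
        slope, intercept, p = po.robust_regress(2 * x + 1, x)
        assert slope == pytest.approx(2.0, abs=1e-6)
        assert intercept == pytest.approx(1.0, abs=1e-6)
        assert p < 1e-10

    def test_huber_beats_ols_under_contamination(self):
        wins = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 4, 20)
            y = 2 * x + 1 + rng.normal(0, 0.3, 20)
            y[np.argmax(x)] += 10 * 0.3  # gross outlier at high leverage
            slope_h, _, _ = po.robust_regress(y, x)
            slope_ols = np.polyfit(x, y, 1)[0]
            wins += abs(slope_h - 2) <= abs(slope_ols - 2)
        assert wins >= 38

    def test_constant_x_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            po.robust_regress(np.arange(6, dtype=float), np.ones(6))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError, match=">= 5"):
            po.robust_regress(np.arange(4, dtype=float),
                              np.arange(4, dtype=float))
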