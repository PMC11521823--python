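"""Filters, quantile normalization, two-regime imputation, batch adjustment
and relative abundances."""

import numpy as np
import pandas as pd
import pytest
from pathlib import Path

import pairedomics as po
from pairedomics.datamodel import ValidationError
from pairedomics.preprocess import ImputationParams

from conftest import make_block, make_sheet, paired_block

DATA = Path(__file__).parent / "data"


class TestFilters:
    def _ptm_block(self, missing_per_feature):
        """12 paired participants; per feature, the first k paired cells NaN."""
        n = 12
        vals = np.full((len(missing_per_feature), 2 * n), 20.0)
        for i, k in enumerate(missing_per_feature):
            vals[i, :k] = np.nan
        return paired_block(vals[:, :n], vals[:, n:])

    def test_threshold_drops_at_ten_keeps_at_nine(self):
        block, _, design = self._ptm_block([10, 9, 0])
        kept, report = po.filter_ptm_features(block, design,
                                              sample_type="plasma")
        assert list(kept.values.index) == ["f1", "f2"]
        assert list(report["feature"]) == ["f0"]

    def test_protein_filter_requires_both_conditions(self):
        n = 12
        bt = np.full((3, n), 20.0)
        at = np.full((3, n), 20.0)
        # f0: 9 BT / 9 AT observed -> retained
        bt[0, 9:] = np.nan; at[0, 9:] = np.nan
        # f1: 11 BT / 8 AT -> dropped (AND-rule)
        bt[1, 11:] = np.nan; at[1, 8:] = np.nan
        # f2: never observed -> dropped
        bt[2, :] = np.nan; at[2, :] = np.nan
        block, _, design = paired_block(bt, at)
        kept, report = po.filter_protein_groups(block, design)
        assert list(kept.values.index) == ["f0"]
        assert set(report["feature"]) == {"f1", "f2"}


class TestQuantileNormalize:
    def test_two_sample_hand_example(self):
        block = make_block([[1.0, 2.0], [3.0, 4.0]])
        out = po.quantile_normalize(block)
        np.testing.assert_allclose(out.values.to_numpy(),
                                   [[1.5, 1.5], [3.5, 3.5]])

    def test_complete_columns_share_sorted_vector(self):
        rng = np.random.default_rng(0)
        block = make_block(rng.normal(20, 3, (50, 6)))
        out = po.quantile_normalize(block).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_array_equal(np.sort(out[:, j]), ref)

    def test_idempotent_on_complete_matrices(self):
        rng = np.random.default_rng(1)
        block = make_block(rng.normal(0, 1, (40, 5)))
        once = po.quantile_normalize(block)
        twice = po.quantile_normalize(once)
        np.testing.assert_allclose(twice.values.to_numpy(),
                                   once.values.to_numpy(), atol=1e-9)

    def test_missing_cells_stay_missing(self):
        vals = np.random.default_rng(2).normal(20, 1, (30, 4))
        vals[3, 1] = np.nan
        block = make_block(vals)
        out = po.quantile_normalize(block)
        assert np.isnan(out.values.iat[3, 1]) and out.n_missing == 1

    def test_sample_with_one_observed_value_rejected(self):
        vals = np.full((3, 3), 20.0)
        vals[1:, 0] = np.nan
        with pytest.raises(ValidationError, match="< 2 observed"):
            po.quantile_normalize(make_block(vals))


class TestClassifyMissingness:
    def _labels(self, n_missing_bt, n_missing_at=0):
        n = 12
        bt = np.full((1, n), 20.0)
        at = np.full((1, n), 20.0)
        bt[0, :n_missing_bt] = np.nan
        at[0, :n_missing_at] = np.nan
        block, _, design = paired_block(bt, at)
        lab = po.classify_missingness(block, design, ImputationParams(),
                                      sample_type="plasma")
        return lab.set_index(["feature", "condition"])["label"]

    def test_83_percent_missing_is_nmar(self):
        assert self._labels(10)[("f0", "BT")] == "NMAR"

    def test_50_percent_missing_is_mar(self):
        assert self._labels(0, 6)[("f0", "AT")] == "MAR"

    def test_complete_condition_is_observed(self):
        lab = self._labels(0, 0)
        assert lab[("f0", "BT")] == lab[("f0", "AT")] == "OBSERVED"

    def test_exactly_75_percent_resolves_to_mar(self):
        assert self._labels(9)[("f0", "BT")] == "MAR"  # 9/12 = 0.75, ties -> MAR

    def test_mechanism_recovery_on_strong_censoring(self, default_cohort):
        truth = default_cohort["truth"]
        design = default_cohort["design"]
        agree = total = 0
        for name, block in default_cohort["blocks"].items():
            lab = po.classify_missingness(block, design, ImputationParams(),
                                          sample_type=name)
            lab = lab.set_index(["feature", "condition"])["label"]
            tp_map = design.timepoint_map(name)
            for _, row in truth.missingness[name].iterrows():
                cond = tp_map.get(row["sample"])
                if cond is None:
                    continue
                got = lab[(row["feature"], cond)]
                want = "NMAR" if row["mechanism"] == "NMAR" else "MAR"
                agree += got == want
                total += 1
        assert total > 500
        assert agree / total >= 0.90


class TestImpute:
    def test_observed_cells_untouched_and_count_matches(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(20, 1, (30, 24))
        holes = rng.random(vals.shape) < 0.15
        vals[holes] = np.nan
        block, _, design = paired_block(vals[:, :12], vals[:, 12:])
        params = ImputationParams(seed=1)
        labels = po.classify_missingness(block, design, params,
                                         sample_type="plasma")
        out = po.impute(block, labels, params, design, sample_type="plasma")
        assert out.n_missing == 0
        obs = block.mask.to_numpy()
        np.testing.assert_array_equal(out.values.to_numpy()[obs],
                                      block.values.to_numpy()[obs])

    def test_mar_draws_match_condition_mean_and_sd(self):
        # one feature, many AT participants; 1000 seeded MAR draws
        n = 2000
        bt = np.full((1, n), 18.4)
        at = np.full((1, n), 18.4)
        at[0, 1000:] = np.nan  # MAR: 50% missing
        block, _, design = paired_block(bt, at)
        params = ImputationParams(seed=7)
        labels = po.classify_missingness(block, design, params,
                                         sample_type="plasma")
        out = po.impute(block, labels, params, design, sample_type="plasma")
        imputed = out.values.to_numpy()[0][block.values.isna().to_numpy()[0]]
        assert imputed.size == 1000
        assert abs(imputed.mean() - 18.4) < 0.05
        assert abs(imputed.std(ddof=1) - 0.5) < 0.03

    def test_nmar_draws_fall_in_censored_tail(self):
        rng = np.random.default_rng(9)
        n = 12
        vals = rng.normal(20, 2, (200, 2 * n))
        # censor one feature's BT condition almost completely
        vals[0, :n] = np.nan
        vals[0, n - 1] = 13.0
        block, _, design = paired_block(vals[:, :n], vals[:, n:])
        params = ImputationParams(seed=2)
        labels = po.classify_missingness(block, design, params,
                                         sample_type="plasma")
        lab = labels.set_index(["feature", "condition"])["label"]
        assert lab[("f0", "BT")] == "NMAR"
        out = po.impute(block, labels, params, design, sample_type="plasma")
        imputed = out.values.to_numpy()[0, :n - 1]
        median = np.nanmedian(block.values.to_numpy())
        assert (imputed < median).mean() >= 0.99

    def test_mar_without_observed_values_falls_back_to_nmar(self, caplog):
        rng = np.random.default_rng(4)
        n = 12
        vals = rng.normal(20, 1, (50, 2 * n))
        vals[0, :n] = np.nan  # BT fully missing for f0
        block, _, design = paired_block(vals[:, :n], vals[:, n:])
        params = ImputationParams(seed=3)
        labels = po.classify_missingness(block, design, params,
                                         sample_type="plasma")
        # force the MAR label despite full missingness
        labels.loc[(labels["feature"] == "f0")
                   & (labels["condition"] == "BT"), "label"] = "MAR"
        import logging
        logging.disable(logging.NOTSET)
        with caplog.at_level("WARNING", logger="pairedomics"):
            out = po.impute(block, labels, params, design,
                            sample_type="plasma")
        logging.disable(logging.INFO)
        assert "falling back to NMAR" in caplog.text
        assert out.n_missing == 0


class TestCombat:
    def test_matches_reference_empirical_bayes_fit(self):
        """Frozen oracle computed once with the reference R implementation
        (sva::ComBat) on this fixture."""
        x = np.loadtxt(DATA / "combat_fixture.tsv")
        oracle = np.loadtxt(DATA / "combat_oracle.tsv")
        samples = [f"S{i}" for i in range(10)]
        block = make_block(x, sample_ids=samples)
        sheet = po.SampleSheet(pd.DataFrame({
            "sample_id": samples, "participant_id": [f"P{i}" for i in range(10)],
            "timepoint": ["BT"] * 10, "sample_type": ["plasma"] * 10,
            "batch": ["A"] * 5 + ["B"] * 5}))
        adj = po.combat_adjust(block, sheet)
        np.testing.assert_allclose(adj.values.to_numpy(), oracle, atol=1e-8)

    def test_single_batch_rejected(self):
        block = make_block(np.random.default_rng(0).normal(size=(5, 4)))
        sheet = po.SampleSheet(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(4)],
            "participant_id": [f"P{i}" for i in range(4)],
            "timepoint": ["BT"] * 4, "sample_type": ["plasma"] * 4,
            "batch": ["A"] * 4}))
        with pytest.raises(ValidationError, match=">= 2 batches"):
            po.combat_adjust(block, sheet)

    def test_singleton_batch_named_in_error(self):
        block = make_block(np.random.default_rng(0).normal(size=(5, 5)))
        sheet = po.SampleSheet(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(5)],
            "participant_id": [f"P{i}" for i in range(5)],
            "timepoint": ["BT"] * 5, "sample_type": ["plasma"] * 5,
            "batch": ["A"] * 4 + ["Z"]}))
        with pytest.raises(ValidationError, match="Z"):
            po.combat_adjust(block, sheet)

    def test_removes_planted_shift_keeps_condition_effect(self):
        rng = np.random.default_rng(5)
        n = 15  # participants per batch arrangement: 15 BT + 15 AT
        bt = rng.normal(20, 0.5, (200, n))
        effect = rng.normal(0, 0.8, 200)
        at = bt + effect[:, None] + rng.normal(0, 0.5, (200, n))
        block, _, design = paired_block(bt, at)
        # whole participants per batch: batch orthogonal to the BT/AT effect
        sheet = make_sheet(n, batches=["b1"] * 2 * (n // 2) + ["b2"] * 2 * (n - n // 2))
        shifted = po.inject_batch_effects(block, sheet, shift=2.0, scale=1.0,
                                          seed=6)
        adj = po.combat_adjust(shifted, sheet)
        b = sheet.batch_of(adj.sample_ids)
        diff = (adj.values.loc[:, (b == "b1").values].mean(axis=1)
                - adj.values.loc[:, (b == "b2").values].mean(axis=1))
        pre_diff = (shifted.values.loc[:, (b == "b1").values].mean(axis=1)
                    - shifted.values.loc[:, (b == "b2").values].mean(axis=1))
        # the systematic batch shift (mean over features) collapses to ~0;
        # per-feature noise-level deviations are deliberately shrunk, not
        # zeroed, by the empirical-Bayes priors
        assert abs(pre_diff.mean()) > 1.5
        assert abs(diff.mean()) < 0.1
        eff_pre = po.effect_size(block, design, "lfc", sample_type="plasma")
        eff_post = po.effect_size(adj, design, "lfc", sample_type="plasma")
        assert np.corrcoef(eff_pre, eff_post)[0, 1] >= 0.95

    def test_gentle_when_no_true_batch_effect(self):
        rng = np.random.default_rng(6)
        noise_sd = 0.5
        block = make_block(rng.normal(20, noise_sd, (200, 20)))
        sheet = po.SampleSheet(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(20)],
            "participant_id": [f"P{i}" for i in range(20)],
            "timepoint": ["BT"] * 20, "sample_type": ["plasma"] * 20,
            "batch": ["A", "B"] * 10}))
        adj = po.combat_adjust(block, sheet)
        rms = np.sqrt(np.mean((adj.values.to_numpy()
                               - block.values.to_numpy()) ** 2))
        assert rms < noise_sd


class TestRelativeAbundance:
    def _meta(self, groups):
        return pd.DataFrame({"precursor_group": groups},
                            index=[f"f{i}" for i in range(len(groups))])

    def test_equal_intensities_split_evenly(self):
        block = make_block([[5.0], [5.0]], meta=self._meta(["g1", "g1"]))
        out = po.relative_abundance(block)
        np.testing.assert_allclose(out.values.to_numpy().ravel(), [50.0, 50.0])

    def test_log2_one_one_two_gives_25_25_50(self):
        block = make_block([[1.0], [1.0], [2.0]],
                           meta=self._meta(["g1", "g1", "g1"]))
        out = po.relative_abundance(block)
        np.testing.assert_allclose(out.values.to_numpy().ravel(),
                                   [25.0, 25.0, 50.0])

    def test_all_missing_group_sample_stays_missing(self):
        vals = np.array([[np.nan, 1.0], [np.nan, 1.0]])
        block = make_block(vals, meta=self._meta(["g1", "g1"]))
        out = po.relative_abundance(block)
        assert out.values.iloc[:, 0].isna().all()
        np.testing.assert_allclose(out.values.iloc[:, 1], [50.0, 50.0])

    def test_group_sums_are_100_for_complete_samples(self):
        rng = np.random.default_rng(7)
        groups = ["g1"] * 3 + ["g2"] * 2 + ["g3"] * 4
        block = make_block(rng.normal(15, 2, (9, 6)), meta=self._meta(groups))
        out = po.relative_abundance(block)
        for g in ("g1", "g2", "g3"):
            members = out.feature_meta.index[out.feature_meta["precursor_group"] == g]
            np.testing.assert_allclose(out.values.loc[members].sum(axis=0),
                                       100.0, atol=1e-6)
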