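"""Correlation layer, group-scale null models, sweep, subsampling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import badgenet as bn
from badgenet import analysis
from badgenet.netmetrics import FEATURE_COLUMNS


def toy_features(n=60, n_orgs=3, seed=0, effect=-0.5):
    """Hand-built feature table with a controllable linear effect."""
    rng = np.random.default_rng(seed)
    rows = []
    for o in range(n_orgs):
        for i in range(n // n_orgs):
            feats = {c: rng.normal() for c in FEATURE_COLUMNS}
            cesd = 20 + effect * 10 * feats["Clustering w(B)"] + rng.normal(0, 3)
            rows.append({"person_id": f"O{o}_{i}", "org_id": f"O{o:02d}",
                         **feats, "cesd_total": cesd})
    return pd.DataFrame(rows)


class TestIndividualCorrelations:
    def test_perfect_feature(self):
        f = toy_features(seed=1)
        f["Degree"] = f["cesd_total"]
        out = bn.individual_correlations(f).set_index("feature")
        assert out.loc["Degree", "pearson_r"] == pytest.approx(1.0)
        assert out.loc["Degree", "pearson_p_adj"] < 1e-10

    def test_zero_variance_flagged(self):
        f = toy_features(seed=2)
        f["Weight"] = 1.0
        out = bn.individual_correlations(f).set_index("feature")
        assert np.isnan(out.loc["Weight", "pearson_r"])
        assert bool(out.loc["Weight", "flagged"])

    def test_bh_monotone_and_identity_for_single_feature(self):
        f = toy_features(seed=3)
        out = bn.individual_correlations(f)
        assert (out["pearson_p_adj"] >= out["pearson_p"] - 1e-15).all()
        solo = bn.individual_correlations(f, feature_cols=["Degree"])
        assert solo["pearson_p_adj"].iloc[0] == pytest.approx(
            solo["pearson_p"].iloc[0])

    def test_low_degree_exclusion_drops_conventional_zeros(self):
        f = toy_features(seed=20)
        f["Degree"] = np.where(np.arange(len(f)) < 10, 0, 5)
        out_keep = bn.individual_correlations(f).set_index("feature")
        out_excl = bn.individual_correlations(
            f, exclude_low_degree_clustering=True).set_index("feature")
        assert out_excl.loc["Clustering", "n"] == out_keep.loc["Clustering", "n"] - 10
        # non-clustering features are untouched
        assert out_excl.loc["Weight", "n"] == out_keep.loc["Weight", "n"]

    def test_planted_effect_detected(self):
        out = bn.individual_correlations(toy_features(n=300, effect=-0.8,
                                                      seed=4)).set_index("feature")
        row = out.loc["Clustering w(B)"]
        assert row["pearson_r"] < 0 and row["pearson_significant"]
        assert row["spearman_r"] < 0 and row["spearman_significant"]


class TestWithinOrgSummary:
    def test_identical_orgs_zero_width_ci(self):
        # same data in every org -> identical r -> bootstrap CI collapses
        base = toy_features(n=20, n_orgs=1, seed=5, effect=-0.5)
        frames = []
        for o in range(4):
            f = base.copy()
            f["org_id"] = f"O{o:02d}"
            f["person_id"] = f["person_id"] + f"_{o}"
            frames.append(f)
        f = pd.concat(frames, ignore_index=True)
        out = bn.within_org_summary(f, n_boot=200, seed=0,
                                    feature_cols=["Clustering w(B)"])
        pe = out[out["method"] == "pearson"].iloc[0]
        assert pe["ci_low"] == pytest.approx(pe["mean_r"])
        assert pe["ci_high"] == pytest.approx(pe["mean_r"])

    def test_planted_effect_ci_excludes_zero(self):
        f = toy_features(n=400, n_orgs=8, seed=6, effect=-0.8)
        out = bn.within_org_summary(f, n_boot=500, seed=1,
                                    feature_cols=["Clustering w(B)"])
        pe = out[out["method"] == "pearson"].iloc[0]
        assert pe["ci_high"] < 0

    def test_single_boot_degenerate(self):
        f = toy_features(seed=7)
        out = bn.within_org_summary(f, n_boot=1, seed=2,
                                    feature_cols=["Degree"])
        pe = out[out["method"] == "pearson"].iloc[0]
        assert pe["ci_low"] == pe["ci_high"]  # one resample -> point interval

    def test_reproducible_under_seed(self):
        f = toy_features(seed=8)
        o1 = bn.within_org_summary(f, n_boot=100, seed=3)
        o2 = bn.within_org_summary(f, n_boot=100, seed=3)
        pd.testing.assert_frame_equal(o1, o2)


class TestGroupNulls:
    def _communities(self, f, size=10):
        ids = f["person_id"].tolist()
        return {p: i // size for i, p in enumerate(ids)}

    def test_empirical_p_bounds_and_floor(self):
        nd = analysis.NullDistribution("x", observed=-1.0,
                                       null_values=np.linspace(0, 1, 99))
        assert nd.empirical_p_one_tailed == pytest.approx(1 / 100)
        nd2 = analysis.NullDistribution("x", observed=2.0,
                                        null_values=np.linspace(0, 1, 99))
        assert nd2.empirical_p_one_tailed == 1.0

    def test_exchangeable_null_centered(self):
        f = toy_features(n=120, n_orgs=3, seed=9, effect=0.0)
        nd = bn.community_level_test(f, self._communities(f), n_null=300, seed=0)
        assert abs(np.mean(nd.null_values)) < 0.1
        assert nd.empirical_p_one_tailed > 0.01

    def test_too_few_communities_error(self):
        f = toy_features(n=30, n_orgs=3, seed=10)
        comm = {p: 0 if i < 15 else 1 for i, p in enumerate(f["person_id"])}
        with pytest.raises(ValueError):
            bn.community_level_test(f, comm, n_null=10, seed=0)

    def test_org_test_needs_three_orgs(self):
        f = toy_features(n=40, n_orgs=2, seed=11)
        with pytest.raises(ValueError):
            bn.organization_level_test(f, n_null=10, seed=0)

    def test_org_statistic_invariant_to_within_org_relabeling(self):
        f = toy_features(n=90, n_orgs=3, seed=12)
        nd1 = bn.organization_level_test(f, n_null=50, seed=5)
        shuffled = f.sample(frac=1.0, random_state=1).reset_index(drop=True)
        nd2 = bn.organization_level_test(shuffled, n_null=50, seed=5)
        assert nd1.observed == pytest.approx(nd2.observed)

    def test_reproducible_under_seed(self):
        f = toy_features(n=120, n_orgs=4, seed=13)
        comm = self._communities(f)
        a = bn.community_level_test(f, comm, n_null=100, seed=7)
        b = bn.community_level_test(f, comm, n_null=100, seed=7)
        assert np.array_equal(a.null_values, b.null_values)

    def test_planted_group_effect_detected(self):
        """Community-mean gradient -> observed below the null."""
        rng = np.random.default_rng(14)
        rows = []
        for c in range(12):
            level = rng.normal()
            for i in range(12):
                cb = level + rng.normal(0, 0.3)
                rows.append({"person_id": f"c{c}_{i}", "org_id": f"O{c % 3:02d}",
                             **{k: rng.normal() for k in FEATURE_COLUMNS
                                if k != "Clustering w(B)"},
                             "Clustering w(B)": cb,
                             "cesd_total": 20 - 8 * level + rng.normal(0, 2)})
        f = pd.DataFrame(rows)
        comm = {p: int(p[1:p.index("_")]) for p in f["person_id"]}
        nd = bn.community_level_test(f, comm, n_null=500, seed=3)
        assert nd.observed < np.percentile(nd.null_values, 2.5)
        assert nd.empirical_p_one_tailed < 0.05

    def test_within_org_null_tracks_org_structure(self):
        """With systematic org offsets the within-org null sits closer to the
        observed statistic than the global pool null."""
        rng = np.random.default_rng(15)
        rows = []
        for o in range(4):
            org_cb = o * 1.0
            org_cesd = 30 - 8 * o
            for c in range(4):
                for i in range(10):
                    cb = org_cb + rng.normal(0, 0.2)
                    rows.append({"person_id": f"o{o}c{c}_{i}",
                                 "org_id": f"O{o:02d}",
                                 **{k: rng.normal() for k in FEATURE_COLUMNS
                                    if k != "Clustering w(B)"},
                                 "Clustering w(B)": cb,
                                 "cesd_total": org_cesd + rng.normal(0, 2)})
        f = pd.DataFrame(rows)
        comm = {p: p[: p.index("_")] for p in f["person_id"]}
        glob = bn.community_level_test(f, comm, null_mode="global_pool",
                                       n_null=400, seed=4)
        within = bn.community_level_test(f, comm, null_mode="within_org",
                                         n_null=400, seed=4)
        assert within.observed == pytest.approx(glob.observed)
        assert abs(np.mean(within.null_values) - within.observed) < abs(
            np.mean(glob.null_values) - glob.observed)


class TestSweepAndSubsampling:
    def test_threshold_zero_equals_full_network(self, small_study):
        d = small_study
        res = bn.activity_sweep(d.episodes, d.roster, d.cesd, thresholds=[0],
                                retained=d.retained, n_days=d.config.n_days,
                                n_boot=50, seed=0)
        active0 = res[(res["mode"] == "active_net")
                      & (res["feature"] == "Clustering w(B)")].iloc[0]
        full = bn.individual_correlations(d.features).set_index("feature")
        assert active0["pearson_entire"] == pytest.approx(
            full.loc["Clustering w(B)", "pearson_r"], abs=1e-6)
        assert active0["removed_fraction"] == 0.0

    def test_removed_fraction_monotone(self, small_study):
        d = small_study
        res = bn.activity_sweep(d.episodes, d.roster, d.cesd,
                                thresholds=[0, 80, 130, 200],
                                retained=d.retained, n_days=d.config.n_days,
                                n_boot=10, seed=0)
        act = res[(res["mode"] == "active_net")
                  & (res["feature"] == "Clustering")]
        fracs = act.sort_values("threshold")["removed_fraction"].tolist()
        assert fracs == sorted(fracs)

    def test_unsorted_thresholds_rejected(self, small_study):
        d = small_study
        with pytest.raises(ValueError):
            bn.activity_sweep(d.episodes, d.roster, d.cesd, thresholds=[100, 0])

    def test_full_span_window_reproduces_full_correlations(self, small_study):
        d = small_study
        res = bn.window_subsample(d.log.detections, d.config.n_days, d.roster,
                                  d.cesd, retained=d.retained)
        assert res["start_day"].nunique() == 1
        full = bn.individual_correlations(d.features).set_index("feature")
        win = res.set_index("feature")
        for feat in ("Clustering", "Clustering w(B)"):
            assert win.loc[feat, "pearson_r"] == pytest.approx(
                full.loc[feat, "pearson_r"], abs=1e-12)

    def test_shorter_windows_noisier(self, small_study):
        d = small_study
        r1 = bn.window_subsample(d.log.detections, 1, d.roster, d.cesd,
                                 retained=d.retained,
                                 feature_cols=["Clustering w(B)"])
        r3 = bn.window_subsample(d.log.detections, 3, d.roster, d.cesd,
                                 retained=d.retained,
                                 feature_cols=["Clustering w(B)"])
        # day-level estimates scatter at least as widely as 3-day estimates
        assert r1["pearson_r"].std() >= r3["pearson_r"].std() - 0.02

    def test_window_longer_than_span_rejected(self, small_study):
        with pytest.raises(ValueError):
            bn.window_subsample(small_study.log.detections, 99,
                                small_study.roster, small_study.cesd)


class TestPerItemCorrelations:
    def test_shape_and_sign(self, small_study):
        d = small_study
        mat = bn.per_item_correlations(d.features, d.cesd)
        assert mat.shape == (20, 11)
        # item-level effect points the same way as the total on average
        assert mat["Clustering w(B)"].mean() < 0

    def test_constant_item_flagged(self, small_study):
        d = small_study
        items = d.cesd.copy()
        items["item_01"] = 2
        mat = bn.per_item_correlations(d.features, items)
        assert np.isnan(mat.loc["item_01", "Clustering w(B)"])
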