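"""Inferential layer.

Individual-scale Pearson/Spearman correlations between the 11 network
characteristics and the CES-D total, with Benjamini-Hochberg adjustment
applied across the 11 features separately within each correlation family;
within-organization summaries with bootstrap confidence intervals;
community- and organization-scale permutation null models; the
activity-threshold sweep; consecutive-day window subsampling; and
per-CES-D-item correlations.

Persons are treated as independent observations in the individual-scale
correlations even though neighbouring clustering values are dependent;
this mirrors the standard practice for such field studies and is a known
limitation rather than an oversight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .netmetrics import FEATURE_COLUMNS, feature_table
from .preprocess import build_networks, merge_episodes, subnetwork_by_activity
from .synthgen import MINUTES_PER_DAY, Roster

__all__ = [
    "NullDistribution",
    "individual_correlations",
    "within_org_summary",
    "community_level_test",
    "organization_level_test",
    "activity_sweep",
    "window_subsample",
    "per_item_correlations",
    "SWEEP_THRESHOLDS_DEFAULT",
]

N_BOOT_DEFAULT = 1000
N_NULL_DEFAULT = 5000
#: Covers the 100 and 160 zero-cross/min landmarks.
SWEEP_THRESHOLDS_DEFAULT = tuple(range(0, 201, 20))


@dataclass(frozen=True)
class NullDistribution:
    """Observed group-level statistic versus a resampled null.

    ``empirical_p_one_tailed`` uses the add-one correction
    (1 + #{null <= observed}) / (B + 1), testing "observed more negative
    than expected by chance"; it therefore always lies in (0, 1].
    """

    statistic: str
    observed: float
    null_values: np.ndarray
    empirical_p_one_tailed: float = field(init=False)

    def __post_init__(self) -> None:
        nv = np.asarray(self.null_values, dtype=float)
        object.__setattr__(self, "null_values", nv)
        p = (1.0 + np.sum(nv <= self.observed)) / (len(nv) + 1.0)
        object.__setattr__(self, "empirical_p_one_tailed", float(p))


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    else:
        r, p = stats.spearmanr(x, y)  # average ranks for ties
    return float(r), float(p)


_CLUSTERING_COLS = ("Clustering", "Clustering w(B)", "Clustering w(O)",
                    "Clustering w(Z)")


def individual_correlations(
    features: pd.DataFrame,
    feature_cols: Sequence[str] = FEATURE_COLUMNS,
    alpha: float = 0.05,
    exclude_low_degree_clustering: bool = False,
) -> pd.DataFrame:
    """Entire-dataset correlations of each feature with the CES-D total.

    Rows with a missing CES-D total (or missing feature value) are dropped
    per feature. Benjamini-Hochberg adjustment runs across the features,
    separately within the Pearson and within the Spearman family.
    Zero-variance features yield NaN coefficients and are flagged.

    ``exclude_low_degree_clustering`` drops persons with fewer than two
    interaction partners from the clustering correlations (their
    coefficient is 0 by convention, not observation) instead of keeping
    them at 0.
    """
    if exclude_low_degree_clustering and "Degree" in features.columns:
        features = features.copy()
        low = features["Degree"] < 2
        for col in _CLUSTERING_COLS:
            if col in features.columns:
                features.loc[low, col] = np.nan
    rows = []
    for feat in feature_cols:
        sub = features[[feat, "cesd_total"]].dropna()
        x = sub[feat].to_numpy(dtype=float)
        y = sub["cesd_total"].to_numpy(dtype=float)
        row = {"feature": feat, "n": len(sub)}
        for method in ("pearson", "spearman"):
            r, p = _corr(x, y, method)
            row[f"{method}_r"], row[f"{method}_p"] = r, p
        row["flagged"] = np.isnan(row["pearson_r"])
        rows.append(row)
    out = pd.DataFrame(rows)
    for method in ("pearson", "spearman"):
        pvals = out[f"{method}_p"]
        ok = pvals.notna()
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok.to_numpy()] = multipletests(
                pvals[ok].to_numpy(), alpha=alpha, method="fdr_bh"
            )[1]
        out[f"{method}_p_adj"] = adj
        out[f"{method}_significant"] = (out[f"{method}_p_adj"] < alpha) & ok
    return out


def _org_coefficients(
    features: pd.DataFrame, feat: str, method: str
) -> np.ndarray:
    rs = []
    for _, sub in features.groupby("org_id", sort=True):
        sub = sub[[feat, "cesd_total"]].dropna()
        r, _ = _corr(
            sub[feat].to_numpy(dtype=float),
            sub["cesd_total"].to_numpy(dtype=float),
            method,
        )
        if not np.isnan(r):
            rs.append(r)
    return np.array(rs)


def within_org_summary(
    features: pd.DataFrame,
    n_boot: int = N_BOOT_DEFAULT,
    seed: int = 0,
    feature_cols: Sequence[str] = FEATURE_COLUMNS,
) -> pd.DataFrame:
    """Mean within-organization correlation per feature with a 95% CI.

    The correlation coefficient is computed inside each organization; the
    bootstrap resamples the set of organization-level coefficients with
    replacement (``n_boot`` draws) and reports the percentile 2.5/97.5
    interval of the mean. Organizations with undefined coefficients
    (zero variance or fewer than 3 complete rows) are dropped.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for feat in feature_cols:
        for method in ("pearson", "spearman"):
            rs = _org_coefficients(features, feat, method)
            if len(rs) == 0:
                rows.append(
                    {"feature": feat, "method": method, "n_orgs": 0,
                     "mean_r": np.nan, "ci_low": np.nan, "ci_high": np.nan}
                )
                continue
            boots = rng.choice(rs, size=(n_boot, len(rs)), replace=True).mean(axis=1)
            lo, hi = np.percentile(boots, [2.5, 97.5])
            rows.append(
                {
                    "feature": feat,
                    "method": method,
                    "n_orgs": len(rs),
                    "mean_r": float(rs.mean()),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group-scale null models


def _group_statistic(
    values: pd.DataFrame, groups: Sequence[np.ndarray], feat: str
) -> float:
    """Spearman r between group means of (feat, cesd_total).

    ``groups`` are integer index arrays into ``values``; persons with a
    missing CES-D total are excluded from both means.
    """
    f = values[feat].to_numpy(dtype=float)
    c = values["cesd_total"].to_numpy(dtype=float)
    mf, mc = [], []
    for idx in groups:
        ok = ~np.isnan(c[idx]) & ~np.isnan(f[idx])
        if ok.sum() == 0:
            continue
        mf.append(f[idx][ok].mean())
        mc.append(c[idx][ok].mean())
    r, _ = _corr(np.array(mf), np.array(mc), "spearman")
    return r


def community_level_test(
    features: pd.DataFrame,
    community_of: Mapping,
    null_mode: str = "global_pool",
    n_null: int = N_NULL_DEFAULT,
    seed: int = 0,
    feat: str = "Clustering w(B)",
) -> NullDistribution:
    """Community-scale correlation against randomly constructed communities.

    Observed statistic: Spearman r between community means of ``feat`` and
    of the CES-D total. Null communities preserve the observed
    community-size multiset; ``global_pool`` samples members without
    replacement from the entire dataset, ``within_org`` permutes members
    within each organization (community sizes stay attached to their
    organization). One-tailed empirical p for "observed more negative
    than null" with the add-one correction.
    """
    if null_mode not in ("global_pool", "within_org"):
        raise ValueError("null_mode must be 'global_pool' or 'within_org'")
    feats = features.reset_index(drop=True)
    comm = feats["person_id"].map(dict(community_of))
    if comm.isna().any():
        feats = feats[comm.notna()].reset_index(drop=True)
        comm = comm.dropna().reset_index(drop=True)
    groups = [np.flatnonzero(comm == c) for c in sorted(comm.unique(), key=str)]
    if len(groups) < 3:
        raise ValueError("community-scale test needs at least 3 communities")
    observed = _group_statistic(feats, groups, feat)
    rng = np.random.default_rng(seed)

    org = feats["org_id"].to_numpy()
    null_vals = np.empty(n_null)
    if null_mode == "global_pool":
        sizes = [len(g) for g in groups]
        n_total = len(feats)
        for b in range(n_null):
            perm = rng.permutation(n_total)
            null_groups, at = [], 0
            for s in sizes:
                null_groups.append(perm[at : at + s])
                at += s
            null_vals[b] = _group_statistic(feats, null_groups, feat)
    else:
        org_rows = {o: np.flatnonzero(org == o) for o in np.unique(org)}
        group_org = [org[g[0]] for g in groups]
        group_sizes = [len(g) for g in groups]
        for b in range(n_null):
            perms = {o: rng.permutation(rows) for o, rows in org_rows.items()}
            used = {o: 0 for o in org_rows}
            null_groups = []
            for o, s in zip(group_org, group_sizes):
                at = used[o]
                null_groups.append(perms[o][at : at + s])
                used[o] = at + s
            null_vals[b] = _group_statistic(feats, null_groups, feat)
    return NullDistribution(
        statistic=f"community spearman r ({feat}, {null_mode})",
        observed=observed,
        null_values=null_vals,
    )


def organization_level_test(
    features: pd.DataFrame,
    n_null: int = N_NULL_DEFAULT,
    seed: int = 0,
    feat: str = "Clustering w(B)",
) -> NullDistribution:
    """Organization-scale correlation against randomly mixed organizations.

    Observed statistic: Spearman r over organization means; the null
    reshuffles persons across organizations preserving organization sizes.
    """
    feats = features.reset_index(drop=True)
    orgs = sorted(feats["org_id"].unique())
    if len(orgs) < 3:
        raise ValueError("organization-scale test needs at least 3 organizations")
    groups = [np.flatnonzero(feats["org_id"] == o) for o in orgs]
    observed = _group_statistic(feats, groups, feat)
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    null_vals = np.empty(n_null)
    for b in range(n_null):
        perm = rng.permutation(len(feats))
        null_groups, at = [], 0
        for s in sizes:
            null_groups.append(perm[at : at + s])
            at += s
        null_vals[b] = _group_statistic(feats, null_groups, feat)
    return NullDistribution(
        statistic=f"organization spearman r ({feat})",
        observed=observed,
        null_values=null_vals,
    )


# ---------------------------------------------------------------------------
# Activity-threshold sweep


CLUSTERING_VARIANTS = [
    "Clustering",
    "Clustering w(B)",
    "Clustering w(O)",
    "Clustering w(Z)",
]


def activity_sweep(
    episodes: pd.DataFrame,
    roster: Roster,
    cesd: pd.DataFrame,
    thresholds: Sequence[float] = SWEEP_THRESHOLDS_DEFAULT,
    retained: set | None = None,
    n_days: int | None = None,
    n_boot: int = N_BOOT_DEFAULT,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlation of the clustering variants with CES-D across an
    activity-threshold sweep.

    For each threshold and mode ("active_net" keeps active + mixed
    episodes, "inactive_net" keeps inactive + mixed), the sub-network is
    rebuilt, the four clustering variants recomputed, and the
    entire-dataset Pearson r plus the within-organization mean and 95%
    bootstrap CI reported, along with the fraction of episodes removed.
    Points whose sub-network has fewer than 3 nodes with data are flagged
    missing (NaN).
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for t_i, threshold in enumerate(thresholds):
        for mode in ("active_net", "inactive_net"):
            sub, removed = subnetwork_by_activity(episodes, threshold, mode)
            nets = build_networks(sub, roster, retained=retained, n_days=n_days)
            feats = feature_table(nets, cesd)
            for feat in CLUSTERING_VARIANTS:
                data = feats[[feat, "cesd_total"]].dropna()
                row = {
                    "threshold": threshold,
                    "mode": mode,
                    "feature": feat,
                    "removed_fraction": removed,
                }
                if len(data) < 3:
                    row.update(pearson_entire=np.nan, mean_r=np.nan,
                               ci_low=np.nan, ci_high=np.nan)
                else:
                    r, _ = _corr(
                        data[feat].to_numpy(float),
                        data["cesd_total"].to_numpy(float),
                        "pearson",
                    )
                    row["pearson_entire"] = r
                    summ = within_org_summary(
                        feats, n_boot=n_boot,
                        seed=seed + 1000 * t_i + (mode == "inactive_net"),
                        feature_cols=[feat],
                    )
                    pe = summ[summ["method"] == "pearson"].iloc[0]
                    row.update(mean_r=pe["mean_r"], ci_low=pe["ci_low"],
                               ci_high=pe["ci_high"])
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Robustness analyses


def window_subsample(
    detections: pd.DataFrame,
    window_days: int,
    roster: Roster,
    cesd: pd.DataFrame,
    gap_limit: int = 5,
    retained: set | None = None,
    feature_cols: Sequence[str] = FEATURE_COLUMNS,
) -> pd.DataFrame:
    """Recompute the individual-scale correlations on every window of
    ``window_days`` consecutive observed days.

    Networks are rebuilt from the window's detections with the window
    length as the per-day denominator; empty windows are skipped. Returns
    the concatenated correlation tables with a ``start_day`` column.
    """
    if len(detections) == 0:
        return pd.DataFrame()
    days = np.sort((detections["minute"] // MINUTES_PER_DAY).unique())
    span = days.max() - days.min() + 1
    if window_days > span:
        raise ValueError("window exceeds the observation span")
    frames = []
    for start in range(int(days.min()), int(days.max()) - window_days + 2):
        mask = (detections["minute"] // MINUTES_PER_DAY >= start) & (
            detections["minute"] // MINUTES_PER_DAY < start + window_days
        )
        win = detections[mask]
        if len(win) == 0:
            continue
        eps = merge_episodes(win, gap_limit)
        nets = build_networks(eps, roster, retained=retained, n_days=window_days)
        feats = feature_table(nets, cesd)
        corr = individual_correlations(feats, feature_cols=feature_cols)
        corr.insert(0, "start_day", start)
        frames.append(corr)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def per_item_correlations(
    features: pd.DataFrame,
    cesd_items: pd.DataFrame,
    positive_items: Sequence[int] = (4, 8, 12, 16),
    feature_cols: Sequence[str] = FEATURE_COLUMNS,
) -> pd.DataFrame:
    """Spearman r between each CES-D item and each network feature.

    Positive items are reverse-coded (3 - raw) before correlating, so all
    items point in the depressive direction. Returns a 20 x len(features)
    frame; constant items give NaN rows (flagged by being NaN).
    """
    merged = features.merge(cesd_items, on="person_id", how="inner")
    out = np.full((20, len(feature_cols)), np.nan)
    for i in range(1, 21):
        col = f"item_{i:02d}"
        vals = merged[col].to_numpy(dtype=float)
        if i in positive_items:
            vals = 3 - vals
        for j, feat in enumerate(feature_cols):
            x = merged[feat].to_numpy(dtype=float)
            ok = ~np.isnan(x) & ~np.isnan(vals)
            r, _ = _corr(x[ok], vals[ok], "spearman")
            out[i - 1, j] = r
    return pd.DataFrame(
        out,
        index=[f"item_{i:02d}" for i in range(1, 21)],
        columns=list(feature_cols),
    )
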