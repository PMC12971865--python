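"""Skill-level clustering and group statistics.

Sessions are clustered on the six z-standardized behavioral metrics with
k-means++ (best of ``n_init`` restarts), the number of clusters is chosen
at the elbow of the within-cluster-sum-of-squares (WCSS) curve, and
clusters are merged into ordered skill levels by pairwise Games-Howell
comparisons of completion times: clusters whose completion times do not
differ significantly are assigned the same level, and levels are ordered
by ascending mean completion time (fastest = HIGH).

The module also provides the per-metric group tests used to characterize
the clusters (one-way ANOVA with Tukey HSD, or Welch ANOVA with
Games-Howell when Levene's test rejects homogeneous variances) and the
paired / independent t-tests across trainer types.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@lru_cache(maxsize=4096)
def _q_crit(alpha: float, k: int, df: float) -> float:
    """Cached studentized-range critical value (scipy's ppf is expensive)."""
    return float(stats.studentized_range.ppf(1.0 - alpha, k, df))

from gazeskill.metrics import FEATURE_COLUMNS

__all__ = [
    "ClusterModel",
    "SkillAssignment",
    "GroupTestResult",
    "PairwiseComparison",
    "kmeans_pp",
    "elbow_select",
    "welch_anova",
    "games_howell",
    "oneway_anova",
    "tukey_hsd",
    "oneway_anova_with_tukey",
    "levene_test",
    "auto_group_test",
    "assign_skill_levels",
    "compare_trainers",
    "adjusted_rand_index",
]


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    difference: float  # mean(a) - mean(b)
    ci_low: float
    ci_high: float
    p: float

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-9 <= self.difference <= self.ci_high + 1e-9):
            raise ValueError("confidence interval must contain the point difference")


@dataclass
class GroupTestResult:
    name: str
    statistic: float
    df: tuple[float, float]
    p: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    note: str = ""

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group_a": [c.group_a for c in self.pairwise],
                "group_b": [c.group_b for c in self.pairwise],
                "difference": [c.difference for c in self.pairwise],
                "ci_low": [c.ci_low for c in self.pairwise],
                "ci_high": [c.ci_high for c in self.pairwise],
                "p": [c.p for c in self.pairwise],
            }
        )


@dataclass
class ClusterModel:
    k: int
    assignments: np.ndarray
    centers: np.ndarray
    wcss_curve: dict[int, float]
    seed: int
    n_init: int
    feature_names: list[str]
    dropped_features: list[str] = field(default_factory=list)


@dataclass
class SkillAssignment:
    levels: np.ndarray  # per-session level name
    merge_map: dict[int, str]  # cluster id -> level name
    level_order: list[str]  # fastest first
    evidence: list[PairwiseComparison]


# ---------------------------------------------------------------------------
# k-means++ and elbow
# ---------------------------------------------------------------------------


def _standardize(table: pd.DataFrame, features: Sequence[str]) -> tuple[np.ndarray, list[str], list[str]]:
    kept, dropped = [], []
    cols = []
    for name in features:
        col = table[name].to_numpy(float)
        sd = col.std()
        if sd == 0 or not np.isfinite(sd):
            dropped.append(name)
            continue
        kept.append(name)
        cols.append((col - col.mean()) / sd)
    if dropped:
        warnings.warn(f"constant features dropped before clustering: {dropped}", UserWarning)
    if not kept:
        raise ValueError("no non-constant features available for clustering")
    return np.column_stack(cols), kept, dropped


def kmeans_pp(
    metrics_table: pd.DataFrame,
    k: int,
    seed: int = 0,
    n_init: int = 50,
    features: Sequence[str] | None = None,
    k_max: int = 8,
) -> ClusterModel:
    """Cluster sessions with k-means++ on z-standardized features.

    Also computes the WCSS curve for k = 1..k_max (used by
    :func:`elbow_select`).  Raises if ``k`` exceeds the number of
    sessions.
    """
    from sklearn.cluster import KMeans

    features = list(features or FEATURE_COLUMNS)
    X, kept, dropped = _standardize(metrics_table, features)
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of sessions ({n})")
    curve: dict[int, float] = {}
    for kk in range(1, min(k_max, n) + 1):
        km = KMeans(n_clusters=kk, init="k-means++", n_init=n_init, random_state=seed)
        km.fit(X)
        curve[kk] = float(km.inertia_)
        if kk == k:
            model = km
    if k not in curve:
        model = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed).fit(X)
    return ClusterModel(
        k=k,
        assignments=model.labels_.copy(),
        centers=model.cluster_centers_.copy(),
        wcss_curve=curve,
        seed=seed,
        n_init=n_init,
        feature_names=kept,
        dropped_features=dropped,
    )


def elbow_select(wcss_curve: Mapping[int, float]) -> int:
    """Pick k at the maximum second difference (discrete curvature) of WCSS.

    Ties (including a perfectly linear curve, which has no elbow) resolve
    to the smallest candidate k, with a warning when no clear elbow
    exists.
    """
    ks = sorted(wcss_curve)
    if len(ks) < 3 or ks[-1] < 3:
        raise ValueError("elbow selection needs the WCSS curve up to k >= 3")
    w = {k: float(wcss_curve[k]) for k in ks}
    candidates = ks[1:-1]
    curv = {k: w[k - 1] - 2.0 * w[k] + w[k + 1] for k in candidates}
    best = max(curv.values())
    scale = max(abs(v) for v in w.values()) or 1.0
    if best <= 1e-12 * scale:
        warnings.warn("no clear elbow in the WCSS curve; defaulting to the smallest k", UserWarning)
        return candidates[0]
    for k in candidates:  # ascending: first max wins the tie
        if curv[k] >= best - 1e-12 * scale:
            return k
    return candidates[0]  # pragma: no cover


def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Permutation-invariant clustering agreement (ARI)."""
    from sklearn.metrics import adjusted_rand_score

    return float(adjusted_rand_score(labels_a, labels_b))


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------


def _group_arrays(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    out = [np.asarray(g, dtype=float) for g in groups]
    if len(out) < 2:
        raise ValueError("need at least two groups")
    for g in out:
        if g.size < 2:
            raise ValueError("each group needs at least two values")
    return out


def welch_anova(groups: Sequence[Sequence[float]]) -> GroupTestResult:
    """One-way Welch ANOVA (unequal variances), Satterthwaite-style df."""
    gs = _group_arrays(groups)
    k = len(gs)
    n = np.array([g.size for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    s2 = np.array([g.var(ddof=1) for g in gs])
    if np.any(s2 == 0):
        if np.allclose(m, m[0]):
            return GroupTestResult(
                name="welch_anova",
                statistic=float("nan"),
                df=(k - 1.0, float("nan")),
                p=float("nan"),
                note="degenerate: all groups constant and equal; F undefined",
            )
        raise ValueError("a group has zero variance; Welch ANOVA undefined")
    w = n / s2
    W = w.sum()
    mw = float(np.sum(w * m) / W)
    a = float(np.sum(w * (m - mw) ** 2)) / (k - 1)
    h = np.sum((1.0 - w / W) ** 2 / (n - 1))
    b = 1.0 + 2.0 * (k - 2) / (k**2 - 1) * h
    f_stat = a / b
    df2 = (k**2 - 1) / (3.0 * h)
    p = float(stats.f.sf(f_stat, k - 1, df2))
    return GroupTestResult(name="welch_anova", statistic=float(f_stat), df=(k - 1.0, float(df2)), p=p)


def games_howell(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[PairwiseComparison]:
    """Games-Howell pairwise comparisons (unequal variances and sizes).

    Uses the studentized range distribution with Welch-Satterthwaite
    degrees of freedom per pair; CIs at the 1 - alpha level.
    """
    gs = _group_arrays(groups)
    k = len(gs)
    names = list(names) if names is not None else [str(i) for i in range(k)]
    out = []
    for i, j in itertools.combinations(range(k), 2):
        a, b = gs[i], gs[j]
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        se2 = va + vb
        if se2 == 0:
            out.append(PairwiseComparison(names[i], names[j], float(a.mean() - b.mean()), 0.0, 0.0, 1.0))
            continue
        se = np.sqrt(se2)
        diff = float(a.mean() - b.mean())
        df = se2**2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        q = abs(diff) / (se / np.sqrt(2.0))
        p = float(stats.studentized_range.sf(q, k, df))
        margin = _q_crit(alpha, k, float(df)) * se / np.sqrt(2.0)
        out.append(
            PairwiseComparison(names[i], names[j], diff, diff - margin, diff + margin, min(p, 1.0))
        )
    return out


def oneway_anova(groups: Sequence[Sequence[float]]) -> GroupTestResult:
    """Classic one-way (fixed effects) ANOVA."""
    gs = _group_arrays(groups)
    k = len(gs)
    all_vals = np.concatenate(gs)
    n_total = all_vals.size
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in gs)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, n_total - k
    if ss_within == 0:
        note = "degenerate: zero within-group variance"
        if ss_between == 0:
            return GroupTestResult("oneway_anova", float("nan"), (float(df1), float(df2)), float("nan"), note=note)
        return GroupTestResult("oneway_anova", float("inf"), (float(df1), float(df2)), 0.0, note=note)
    f_stat = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(f_stat, df1, df2))
    return GroupTestResult("oneway_anova", float(f_stat), (float(df1), float(df2)), p)


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[PairwiseComparison]:
    """Tukey(-Kramer) HSD pairwise comparisons with pooled error variance."""
    gs = _group_arrays(groups)
    k = len(gs)
    names = list(names) if names is not None else [str(i) for i in range(k)]
    df_err = sum(g.size for g in gs) - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in gs) / df_err
    out = []
    for i, j in itertools.combinations(range(k), 2):
        a, b = gs[i], gs[j]
        diff = float(a.mean() - b.mean())
        se = np.sqrt(mse / 2.0 * (1.0 / a.size + 1.0 / b.size))
        if se == 0:
            out.append(PairwiseComparison(names[i], names[j], diff, diff, diff, 1.0 if diff == 0 else 0.0))
            continue
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_err))
        margin = _q_crit(alpha, k, float(df_err)) * se
        out.append(
            PairwiseComparison(names[i], names[j], diff, diff - margin, diff + margin, min(p, 1.0))
        )
    return out


def oneway_anova_with_tukey(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> GroupTestResult:
    res = oneway_anova(groups)
    res.pairwise = tukey_hsd(groups, names=names, alpha=alpha)
    return res


def levene_test(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    gs = _group_arrays(groups)
    stat, p = stats.levene(*gs, center="median")
    return float(stat), float(p)


def auto_group_test(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> GroupTestResult:
    """One-way ANOVA + Tukey, switching to Welch + Games-Howell when
    Levene's test rejects homogeneity of variances at ``alpha``."""
    _, p_lev = levene_test(groups)
    if p_lev < alpha:
        res = welch_anova(groups)
        res.pairwise = games_howell(groups, names=names, alpha=alpha)
        res.note = (res.note + f" levene_p={p_lev:.4g} -> Welch").strip()
        return res
    res = oneway_anova_with_tukey(groups, names=names, alpha=alpha)
    res.note = (res.note + f" levene_p={p_lev:.4g} -> classic ANOVA").strip()
    return res


# ---------------------------------------------------------------------------
# Cluster -> skill level merging
# ---------------------------------------------------------------------------

_LEVEL_NAMES = {1: ["ALL"], 2: ["HIGH", "MID_LOW"], 3: ["HIGH", "MID", "LOW"]}


def assign_skill_levels(
    assignments: np.ndarray | ClusterModel,
    completion_times: Sequence[float],
    alpha: float = 0.05,
) -> SkillAssignment:
    """Merge clusters into ordered skill levels via completion times.

    Clusters joined by a non-significant Games-Howell completion-time
    comparison (at ``alpha``) fall into the same level (transitively, via
    connected components); levels are ordered by ascending mean completion
    time, so the fastest component is labeled HIGH.
    """
    if isinstance(assignments, ClusterModel):
        assignments = assignments.assignments
    labels = np.asarray(assignments)
    times = np.asarray(completion_times, dtype=float)
    if labels.shape != times.shape:
        raise ValueError("assignments and completion_times must align")
    clusters = sorted(np.unique(labels).tolist())
    if len(clusters) == 1:
        warnings.warn("single cluster; a single skill level is returned", UserWarning)
        return SkillAssignment(
            levels=np.array(["ALL"] * labels.size),
            merge_map={clusters[0]: "ALL"},
            level_order=["ALL"],
            evidence=[],
        )
    groups = [times[labels == c] for c in clusters]
    if all(g.size >= 2 for g in groups):
        evidence = games_howell(groups, names=[str(c) for c in clusters], alpha=alpha)
    else:
        # Singleton clusters cannot be tested; pairs involving them are
        # treated as unresolved (no merge) and flagged with p = NaN.
        warnings.warn(
            "cluster(s) with fewer than two sessions: their completion-time "
            "comparisons are unresolvable and they stay unmerged",
            UserWarning,
        )
        evidence = []
        for i, j in itertools.combinations(range(len(clusters)), 2):
            a, b = groups[i], groups[j]
            if a.size >= 2 and b.size >= 2:
                evidence.extend(
                    games_howell([a, b], names=[str(clusters[i]), str(clusters[j])], alpha=alpha)
                )
            else:
                diff = float(a.mean() - b.mean())
                evidence.append(
                    PairwiseComparison(str(clusters[i]), str(clusters[j]), diff, diff, diff, float("nan"))
                )
    # Union-find over non-significant pairs.
    parent = {c: c for c in clusters}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for comp, (i, j) in zip(evidence, itertools.combinations(range(len(clusters)), 2)):
        if comp.p >= alpha:
            parent[find(clusters[i])] = find(clusters[j])
    components: dict[int, list[int]] = {}
    for c in clusters:
        components.setdefault(find(c), []).append(c)
    comps = list(components.values())
    comp_means = [times[np.isin(labels, comp)].mean() for comp in comps]
    order = np.argsort(comp_means, kind="stable")
    m = len(comps)
    names = _LEVEL_NAMES.get(m, [f"LEVEL_{i + 1}" for i in range(m)])
    merge_map: dict[int, str] = {}
    for rank, ci in enumerate(order):
        for c in comps[ci]:
            merge_map[c] = names[rank]
    levels = np.array([merge_map[c] for c in labels])
    return SkillAssignment(
        levels=levels, merge_map=merge_map, level_order=list(names[:m]), evidence=evidence
    )


# ---------------------------------------------------------------------------
# Trainer-type comparisons (paired + independent t-tests)
# ---------------------------------------------------------------------------


def compare_trainers(
    table: pd.DataFrame,
    metric_columns: Sequence[str] | None = None,
    participant_col: str = "participant_id",
    trainer_col: str = "trainer",
) -> dict[str, dict[str, GroupTestResult | None]]:
    """Per-metric trainer-type comparison.

    Participants with one session on each trainer form the repeated-
    measures subset (paired t-test); the remaining sessions are compared
    with an independent Welch t-test.
    """
    metric_columns = list(metric_columns or FEATURE_COLUMNS)
    trainers = sorted(table[trainer_col].unique())
    if len(trainers) != 2:
        raise ValueError(f"expected exactly two trainer types, got {trainers}")
    t_a, t_b = trainers
    per_part = table.groupby(participant_col)[trainer_col].nunique()
    paired_ids = set(per_part[per_part == 2].index)
    paired = table[table[participant_col].isin(paired_ids)]
    rest = table[~table[participant_col].isin(paired_ids)]
    out: dict[str, dict[str, GroupTestResult | None]] = {}
    for col in metric_columns:
        entry: dict[str, GroupTestResult | None] = {"paired": None, "independent": None}
        if paired_ids:
            wide = paired.pivot_table(index=participant_col, columns=trainer_col, values=col)
            a = wide[t_a].to_numpy(float)
            b = wide[t_b].to_numpy(float)
            if np.allclose(a, b):
                entry["paired"] = GroupTestResult(
                    "paired_t", 0.0, (float(a.size - 1), 0.0), 1.0, note="identical pairs"
                )
            else:
                t_stat, p = stats.ttest_rel(a, b)
                entry["paired"] = GroupTestResult(
                    "paired_t", float(t_stat), (float(a.size - 1), 0.0), float(p)
                )
        else:
            warnings.warn("no paired participants; paired t-test skipped", UserWarning)
        ga = rest.loc[rest[trainer_col] == t_a, col].to_numpy(float)
        gb = rest.loc[rest[trainer_col] == t_b, col].to_numpy(float)
        if ga.size >= 2 and gb.size >= 2:
            t_stat, p = stats.ttest_ind(ga, gb, equal_var=False)
            # Welch-Satterthwaite df for the report
            va, vb = ga.var(ddof=1) / ga.size, gb.var(ddof=1) / gb.size
            if va + vb > 0:
                df = (va + vb) ** 2 / (va**2 / (ga.size - 1) + vb**2 / (gb.size - 1))
            else:
                df = float(ga.size + gb.size - 2)
            entry["independent"] = GroupTestResult(
                "welch_t", float(t_stat), (float(df), 0.0), float(p) if np.isfinite(p) else 1.0
            )
        out[col] = entry
    return out
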