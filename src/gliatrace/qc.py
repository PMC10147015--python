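"""Cell-inclusion rules and nonparametric group statistics.

Quality control mirrors the study design: only cells with a DAPI+
nucleus fully inside the z-stack enter, and cells below the 10th
percentile on *any* of filament length, Sholl sum, sphericity or convex
hull volume are excluded (these are typically cells clipped by the stack
border).  Statistics are nonparametric throughout: Mann–Whitney U for
two groups, Kruskal–Wallis for more, Dunn post hoc with Bonferroni
correction over the planned comparisons only, and a two-sample
Kolmogorov–Smirnov test on the pooled Sholl intersection-radius
distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "DEFAULT_QC_METRICS",
    "percentile_filter",
    "per_animal_summary",
    "mann_whitney_u",
    "kruskal_wallis",
    "dunn_posthoc",
    "ks_sholl",
    "sholl_group_curve",
]

DEFAULT_QC_METRICS = (
    "total_filament_length_um",
    "sholl_sum",
    "sphericity",
    "hull_volume_um3",
)


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p_value: float
    df: float | None = None
    adjusted_p: float | None = None
    comparison: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "comparison": list(self.comparison),
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "adjusted_p": self.adjusted_p,
        }


# ---------------------------------------------------------------------------
# QC filtering
# ---------------------------------------------------------------------------


def percentile_filter(
    table: pd.DataFrame,
    metrics=DEFAULT_QC_METRICS,
    q: float = 0.10,
    scope: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Drop cells strictly below the q-quantile on any listed metric.

    Quantiles use linear interpolation of order statistics and are
    computed per cohort (default scope: one ``model`` × ``age`` cohort
    when those columns exist, pooling treatment groups so that all groups
    share one cutoff).  Rows failing the nucleus-in-stack rule and cells
    with a degenerate (flat) hull never enter the analysis.
    """
    if table.empty:
        return table.copy()
    for m in metrics:
        if m not in table.columns:
            raise KeyError(f"metric {m!r} not in table")
    t = table.copy()
    if "nucleus_ok" in t.columns:
        t = t[t["nucleus_ok"].astype(bool)]
    if "hull_degenerate" in t.columns:
        t = t[~t["hull_degenerate"].astype(bool)]
    if t.empty:
        return t

    if scope is None:
        scope = tuple(c for c in ("model", "age") if c in t.columns)

    def _filter(sub: pd.DataFrame) -> pd.DataFrame:
        keep = np.ones(len(sub), dtype=bool)
        for m in metrics:
            cutoff = np.quantile(sub[m].to_numpy(dtype=float), q)  # linear interp
            keep &= ~(sub[m].to_numpy(dtype=float) < cutoff)
        return sub[keep]

    if scope:
        parts = [
            _filter(sub) for _, sub in t.groupby(list(scope), sort=True, dropna=False)
        ]
        out = pd.concat(parts)
        return out.loc[[i for i in t.index if i in set(out.index)]]
    return _filter(t)


def per_animal_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-animal means of every numeric metric, plus the cell count per
    field (one row per animal; grouping labels are carried along)."""
    if "animal_id" not in table.columns:
        raise KeyError("table must carry animal_id")
    label_cols = [c for c in ("group", "age", "model") if c in table.columns]
    num_cols = [
        c
        for c in table.columns
        if pd.api.types.is_numeric_dtype(table[c])
        and c not in ("nucleus_ok", "hull_degenerate")
    ]
    grouped = table.groupby(["animal_id"] + label_cols, sort=True, dropna=False)
    out = grouped[num_cols].mean()
    out["n_cells"] = grouped.size()
    return out.reset_index()


# ---------------------------------------------------------------------------
# Nonparametric tests
# ---------------------------------------------------------------------------


def mann_whitney_u(x, y) -> GroupComparison:
    """Two-sided Mann–Whitney U.

    Exact p by enumeration when n_x + n_y <= 12 with no ties; otherwise
    the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) + len(y) <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return GroupComparison(
        test="mann_whitney_u", statistic=float(res.statistic), p_value=float(res.pvalue)
    )


def kruskal_wallis(groups: dict[str, np.ndarray]) -> GroupComparison:
    """Tie-corrected Kruskal–Wallis H with chi-square upper-tail p."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        raise ValueError("all observations identical; tie correction degenerates")
    h, p = sps.kruskal(*arrays)
    return GroupComparison(
        test="kruskal_wallis",
        statistic=float(h),
        df=float(len(arrays) - 1),
        p_value=float(p),
        comparison=tuple(groups),
    )


def _pooled_ranks(groups: dict[str, np.ndarray]):
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    out, start = {}, 0
    for name, a in zip(names, arrays):
        out[name] = ranks[start : start + len(a)]
        start += len(a)
    return out, pooled, ranks


def dunn_posthoc(
    groups: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]],
    method: str = "bonferroni",
) -> list[GroupComparison]:
    """Dunn z-tests on pooled ranks for the planned comparisons.

    The rank variance uses the standard pooled tie-corrected form
    ``(N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j)``.  Bonferroni
    multiplies raw p by the number of *requested* comparisons (planned
    contrasts, not all pairs), capped at 1.
    """
    for a, b in comparisons:
        if a not in groups or b not in groups:
            raise KeyError(f"unknown group label in comparison ({a}, {b})")
    rank_by_group, pooled, _ = _pooled_ranks(groups)
    n_total = len(pooled)
    _, t_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((t_counts**3 - t_counts).sum()) / (12.0 * (n_total - 1))) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(comparisons)
    out = []
    for a, b in comparisons:
        ra, rb = rank_by_group[a], rank_by_group[b]
        se2 = base_var * (1.0 / len(ra) + 1.0 / len(rb))
        if se2 <= 0:
            z = 0.0
        else:
            z = (ra.mean() - rb.mean()) / np.sqrt(se2)
        p = 2.0 * sps.norm.sf(abs(z))
        adj = min(1.0, m * p) if method == "bonferroni" else p
        out.append(
            GroupComparison(
                test="dunn",
                statistic=float(z),
                p_value=float(p),
                adjusted_p=float(adj),
                comparison=(a, b),
            )
        )
    return out


def _pooled_radii(profiles: list[dict[float, int]]) -> np.ndarray:
    radii, counts = [], []
    for prof in profiles:
        for r, c in prof.items():
            if c > 0:
                radii.append(r)
                counts.append(c)
    if not radii:
        return np.array([])
    return np.repeat(np.asarray(radii, dtype=float), np.asarray(counts, dtype=int))


def ks_sholl(
    profiles_a: list[dict[float, int]], profiles_b: list[dict[float, int]]
) -> GroupComparison:
    """Two-sample KS test on pooled Sholl intersection radii.

    Each cell's profile is expanded to a multiset of shell radii (each
    radius repeated by its intersection count); the two groups' pooled
    multisets are compared — i.e. the test asks whether intersections sit
    at different distances from the soma in the two groups.
    """
    xa, xb = _pooled_radii(profiles_a), _pooled_radii(profiles_b)
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("both groups need nonzero total Sholl intersections")
    d, p = sps.ks_2samp(xa, xb, method="asymp")
    return GroupComparison(test="ks_sholl", statistic=float(d), p_value=float(p))


def sholl_group_curve(
    profiles: list[dict[float, int]], resolution_um: float = 1.0
) -> pd.DataFrame:
    """Per-radius mean ± SEM over cells (absent radii count as 0).

    Returns columns radius_um, mean, sem, n; SEM is 0 by convention for a
    single cell.
    """
    if not profiles:
        return pd.DataFrame(columns=["radius_um", "mean", "sem", "n"])
    rmax = max((max(p) for p in profiles if p), default=0.0)
    kmax = int(round(rmax / resolution_um))
    radii = resolution_um * np.arange(1, kmax + 1)
    n = len(profiles)
    mat = np.zeros((n, kmax))
    for i, p in enumerate(profiles):
        for r, c in p.items():
            k = int(round(r / resolution_um)) - 1
            if 0 <= k < kmax:
                mat[i, k] = c
    mean = mat.mean(axis=0)
    if n > 1:
        sem = mat.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros(kmax)
    return pd.DataFrame({"radius_um": radii, "mean": mean, "sem": sem, "n": n})
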