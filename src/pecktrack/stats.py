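"""Nonparametric statistics for feeding-kinematics records.

Kinematic variables from feeding recordings are far from normal, so group
comparisons use rank- and median-based tests: Spearman's rank correlation
for association between morphometrics and kinematics, Mood's median test for
kinematic differences between feed types and mandibulation orders, and the
Pearson chi-square test for catch-and-throw frequency differences.  The
descriptive summary reports mean, standard error and median per variable,
mandibulation order and feed type, and catch-and-throw occurrence is
summarised as percentages per feed and per order within feed.

All tests are implemented explicitly (ranks, contingency tables, Pearson
chi-square) and return a common :class:`StatResult`.  No multiple-testing
correction is applied by default; a Bonferroni helper is available.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "spearman",
    "moods_median_test",
    "chi_square_independence",
    "descriptive_table",
    "catch_and_throw_summary",
    "bonferroni",
    "KINEMATIC_VARIABLES",
]

KINEMATIC_VARIABLES = ["max_gape_mm", "displacement_mm", "duration_ms", "speed_mm_s"]


@dataclass
class StatResult:
    """Outcome of one statistical test."""

    test: str
    statistic: float
    p_value: float
    df: int | None = None
    n: tuple[int, ...] = ()
    auxiliary: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "df": self.df,
            "n": list(self.n),
            "auxiliary": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.auxiliary.items()
            },
            "flags": list(self.flags),
        }


def _rank_average_ties(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mean rank."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, float)
    sx = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman(x, y, method: str = "t") -> StatResult:
    """Spearman rank correlation with average ranks for ties.

    rho is the Pearson correlation of the rank vectors.  The two-sided
    p-value uses the t approximation with n-2 df (appropriate for the
    hundreds of records a recording session yields); ``method="exact"``
    enumerates rank permutations for n <= 10.  Constant input leaves rho
    undefined and flags the result.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D samples")
    if x.size < 4:
        raise ValueError("need n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    n = x.size
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return StatResult(
            "spearman", float("nan"), float("nan"), df=n - 2, n=(n,),
            flags=["constant-input"],
        )
    rx = _rank_average_ties(x)
    ry = _rank_average_ties(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    rho = max(-1.0, min(1.0, rho))
    if method == "exact":
        if n > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        obs = abs(rho)
        count = total = 0
        ry_base = ry.copy()
        sx = math.sqrt(np.dot(rx, rx))
        for perm in itertools.permutations(range(n)):
            ryp = ry_base[list(perm)]
            r = np.dot(rx, ryp) / (sx * math.sqrt(np.dot(ryp, ryp)))
            count += abs(r) >= obs - 1e-12
            total += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return StatResult(
        "spearman", rho, p, df=n - 2, n=(n,), auxiliary={"rho": rho}
    )


def chi_square_independence(table) -> StatResult:
    """Pearson chi-square test of independence on an r x k count table.

    Expected counts come from the margins; df = (r-1)(k-1).  A zero row or
    column margin is a hard error.  No continuity correction.
    """
    t = np.asarray(table, float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold nonnegative integer counts")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin in contingency table")
    expected = np.outer(rows, cols) / t.sum()
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    flags = ["low-expected-counts"] if (expected < 5).any() else []
    return StatResult(
        "chi-square-independence",
        stat,
        float(sps.chi2.sf(stat, df)),
        df=df,
        n=tuple(int(c) for c in cols),
        auxiliary={"expected": expected},
        flags=flags,
    )


def moods_median_test(groups, ties: str = "below") -> StatResult:
    """Mood's median test across k groups.

    Pools all values, takes the grand median, builds the 2 x k table of
    counts above vs at-or-below it per group, and applies the Pearson
    chi-square with k-1 df.  ``ties`` controls values equal to the grand
    median: "below" (default) counts them in the at-or-below row, "above" in
    the above row, "ignore" discards them.  All-identical input is
    degenerate and returns a flagged NaN result.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("need >= 2 groups, each with >= 1 value")
    pooled = np.concatenate(groups)
    if pooled.size < 4:
        raise ValueError("need >= 4 pooled values")
    if ties not in ("below", "above", "ignore"):
        raise ValueError("ties must be 'below', 'above' or 'ignore'")
    grand = float(np.median(pooled))
    above = np.array([int((g > grand).sum()) for g in groups])
    below = np.array([int((g < grand).sum()) for g in groups])
    equal = np.array([int((g == grand).sum()) for g in groups])
    if ties == "below":
        below = below + equal
    elif ties == "above":
        above = above + equal
    table = np.vstack([above, below])
    ns = tuple(int(g.size) for g in groups)
    if np.ptp(pooled) == 0 or table.sum(axis=1).min() == 0 or (table.sum(axis=0) == 0).any():
        return StatResult(
            "moods-median", float("nan"), float("nan"), df=len(groups) - 1,
            n=ns, auxiliary={"grand_median": grand, "table": table},
            flags=["degenerate"],
        )
    inner = chi_square_independence(table)
    return StatResult(
        "moods-median",
        inner.statistic,
        inner.p_value,
        df=inner.df,
        n=ns,
        auxiliary={
            "grand_median": grand,
            "table": table,
            "group_medians": [float(np.median(g)) for g in groups],
        },
        flags=inner.flags,
    )


def descriptive_table(
    records: pd.DataFrame, variables: list[str] | None = None
) -> pd.DataFrame:
    """Mean, standard error and median per (variable, order, feed type).

    SE is the sample standard deviation (ddof=1) over sqrt(n); the median
    uses the average-of-middle-two convention.  Cells with a single record
    report SE as missing; empty cells are simply absent from the table.
    """
    if len(records) == 0:
        raise ValueError("records table is empty")
    variables = variables or [v for v in KINEMATIC_VARIABLES if v in records.columns]
    rows = []
    for (order, feed), grp in records.groupby(["order", "feed_type"], sort=True):
        for var in variables:
            vals = grp[var].to_numpy(float)
            n = vals.size
            rows.append(
                {
                    "variable": var,
                    "order": order,
                    "feed_type": feed,
                    "n": n,
                    "mean": float(vals.mean()),
                    "se": float(vals.std(ddof=1) / math.sqrt(n)) if n > 1 else np.nan,
                    "median": float(np.median(vals)),
                }
            )
    return pd.DataFrame(rows)


def catch_and_throw_summary(records: pd.DataFrame) -> dict:
    """Catch-and-throw percentages per feed and per order within feed.

    Percentages are 100 * flagged / total; feeds or orders with no records
    are reported as missing (absent keys).
    """
    if "catch_and_throw" not in records.columns:
        raise ValueError("records carry no catch_and_throw flags")
    per_feed = {}
    per_order = {}
    for feed, grp in records.groupby("feed_type"):
        if len(grp) == 0:
            continue
        per_feed[feed] = 100.0 * float(grp["catch_and_throw"].mean())
        per_order[feed] = {
            int(order): 100.0 * float(og["catch_and_throw"].mean())
            for order, og in grp.groupby("order")
        }
    return {"per_feed_pct": per_feed, "per_order_pct": per_order}


def bonferroni(p_values: list[float]) -> list[float]:
    """Bonferroni-adjusted p-values (off by default everywhere; the battery
    mirrors an uncorrected analysis)."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]


# ---------------------------------------------------------------------------
# Whole-battery convenience


def run_battery(records: pd.DataFrame) -> dict:
    """The full comparison battery on a tidy records table.

    Spearman correlations among kinematic variables (whole dataset and per
    mandibulation order), Mood's median tests between feed types per
    variable and order, the chi-square test on catch-and-throw counts per
    feed, descriptives, and catch-and-throw percentages.
    """
    out: dict = {"spearman": {}, "spearman_by_order": {}, "moods": {}}
    vars_present = [v for v in KINEMATIC_VARIABLES if v in records.columns]
    for a, b in itertools.combinations(vars_present, 2):
        out["spearman"][f"{a}~{b}"] = spearman(records[a], records[b]).to_dict()
    for order, grp in records.groupby("order"):
        if len(grp) < 4:
            continue
        d = {}
        for a, b in itertools.combinations(vars_present, 2):
            if grp[a].nunique() > 1 and grp[b].nunique() > 1:
                d[f"{a}~{b}"] = spearman(grp[a], grp[b]).to_dict()
        out["spearman_by_order"][int(order)] = d
    feeds = sorted(records["feed_type"].unique())
    for var in vars_present:
        groups = [records.loc[records.feed_type == f, var].to_numpy() for f in feeds]
        if len(groups) >= 2 and all(g.size >= 1 for g in groups):
            out["moods"][var] = moods_median_test(groups).to_dict()
    if "catch_and_throw" in records.columns and len(feeds) >= 2:
        table = np.array(
            [
                [
                    int(records[(records.feed_type == f)].catch_and_throw.sum()),
                    int((~records[records.feed_type == f].catch_and_throw.astype(bool)).sum()),
                ]
                for f in feeds
            ]
        ).T
        out["catch_and_throw_chi2"] = chi_square_independence(table).to_dict()
        out["catch_and_throw"] = catch_and_throw_summary(records)
    out["descriptives"] = descriptive_table(records).to_dict(orient="records")
    return out
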