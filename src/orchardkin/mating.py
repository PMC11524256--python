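"""Gametic contributions, effective numbers of parents and crop summaries.

Each seedling contributes two gametes.  Both-parents seedlings give one
gamete to each assigned parent (two to the same parent when selfed);
single-parent seedlings give one gamete to the known parent and one to their
unknown-donor group; unassigned seedlings contribute nothing.  Relative
reproductive success P_suc is a contributor's share of the counted gametes.

The effective number of parents uses the sampling-bias-corrected effective
number of types,

    N_ep = (n - 1)^2 / [ sum_i P_suc_i^2 (n + 1)(n - 2) + 3 - n ],

with n the number of seedlings sampled.  N_ep is computed over orchard
contributors (including rootstock) with P_suc renormalized to them; N_ep2
includes every unique contributor (each unknown-donor group once).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

CONTRIBUTOR_CLASSES = ("orchard", "rootstock", "ungenotyped", "external")

#: CropSummary columns used for the cross-crop rank-correlation matrix.
SUMMARY_PARAMS = [
    "h_obs",
    "h_exp",
    "f_is",
    "bpc",
    "selfing",
    "n_ep",
    "n_ep2",
    "age",
    "census_parents",
    "var_logit_psuc",
]


@dataclass
class ContributionTable:
    """Per-contributor gamete counts and shares for one crop."""

    crop_id: str
    n_seedlings: int
    entries: pd.DataFrame  # contributor, contributor_class, gametes, p_suc

    def subset(self, classes: tuple[str, ...]) -> pd.DataFrame:
        return self.entries[self.entries.contributor_class.isin(classes)]


def contributions(
    records: pd.DataFrame,
    crop_id: str = "",
    parent_classes: dict[str, str] | None = None,
) -> ContributionTable:
    """Gamete bookkeeping from assignment records.

    ``parent_classes`` maps known parent ids to "orchard" or "rootstock"
    (default orchard).  Unknown-donor groups are classed "ungenotyped" when
    the category says so, else "external".
    """
    parent_classes = parent_classes or {}
    counts: dict[str, int] = {}
    classes: dict[str, str] = {}

    def add(contributor: str, cls: str, k: int = 1) -> None:
        counts[contributor] = counts.get(contributor, 0) + k
        classes[contributor] = cls

    for row in records.itertuples():
        cat = row.category
        if cat == "unassigned":
            continue
        p1 = row.assigned_parent_1
        cls1 = parent_classes.get(p1, "orchard")
        if cat == "selfing":
            add(p1, cls1, 2)
        elif cat == "both_parents":
            add(p1, cls1, 1)
            add(row.assigned_parent_2, parent_classes.get(row.assigned_parent_2, "orchard"), 1)
        elif cat in ("bpc", "ungenotyped_parent"):
            add(p1, cls1, 1)
            donor_cls = "ungenotyped" if cat == "ungenotyped_parent" else "external"
            add(str(row.donor_group_id), donor_cls, 1)
        else:
            raise ValueError(f"unknown category {cat!r}")
    total = sum(counts.values())
    entries = pd.DataFrame(
        {
            "contributor": list(counts),
            "contributor_class": [classes[c] for c in counts],
            "gametes": list(counts.values()),
        }
    ).sort_values("gametes", ascending=False, kind="stable", ignore_index=True)
    entries["p_suc"] = entries.gametes / total if total else np.nan
    return ContributionTable(crop_id=crop_id, n_seedlings=len(records), entries=entries)


def n_ep(table: ContributionTable, include_external: bool = False) -> float:
    """Bias-corrected effective number of parents.

    With ``include_external`` every contributor group counts (N_ep2);
    otherwise only orchard and rootstock contributors, with shares
    renormalized over that subset.
    """
    n = table.n_seedlings
    if n < 3:
        raise ValueError("need at least 3 seedlings for the bias-corrected estimate")
    if include_external:
        sub = table.entries
    else:
        sub = table.subset(("orchard", "rootstock"))
    if sub.empty:
        raise ValueError("no contributors in the requested class subset")
    p = sub.gametes.to_numpy(float)
    p = p / p.sum()
    denom = np.sum(p**2) * (n + 1) * (n - 2) + 3 - n
    return float((n - 1) ** 2 / denom)


def contribution_curve(table: ContributionTable) -> tuple[np.ndarray, int, float]:
    """Cumulative descending contribution of orchard parents.

    Returns (cumulative shares, smallest k reaching 80%, k / number of
    contributing orchard parents).
    """
    sub = table.subset(("orchard", "rootstock"))
    shares = np.sort(sub.p_suc.to_numpy(float))[::-1]
    shares = shares / shares.sum()
    cum = np.cumsum(shares)
    k = int(np.searchsorted(cum, 0.80 - 1e-9) + 1)
    return cum, k, k / shares.size


def var_logit_psuc(table: ContributionTable) -> float:
    """Sample variance of logit reproductive success over orchard parents.

    Contributors with P_suc of 0 or 1 are excluded (logit undefined).
    """
    sub = table.subset(("orchard", "rootstock"))
    p = sub.p_suc.to_numpy(float)
    p = p[(p > 0) & (p < 1)]
    if p.size < 2:
        return float("nan")
    logit = np.log(p / (1.0 - p))
    return float(np.var(logit, ddof=1))


@dataclass
class CropSummary:
    """One row of the cross-crop comparison table."""

    crop_id: str
    h_obs: float = np.nan
    h_exp: float = np.nan
    f_is: float = np.nan
    bpc: float = np.nan
    selfing: float = np.nan
    n_ep: float = np.nan
    n_ep2: float = np.nan
    age: float = np.nan
    census_parents: float = np.nan
    var_logit_psuc: float = np.nan


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    from itertools import permutations

    n = len(x)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    count = total = 0
    target = abs(rho)
    for perm in permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        total += 1
        if abs(r) >= target - 1e-12:
            count += 1
    return count / total


def spearman_matrix(
    summaries: list[CropSummary] | pd.DataFrame, exact_below: int = 8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rank correlations across crop summary parameters.

    Returns (rho, p) DataFrames over ``SUMMARY_PARAMS`` columns present in
    the input.  p-values use the t-approximation for n >= ``exact_below``
    and exhaustive permutation below (n! grows fast, so the exact route is
    reserved for very small tables).
    """
    if isinstance(summaries, pd.DataFrame):
        df = summaries
    else:
        df = pd.DataFrame([vars(s) for s in summaries])
    if len(df) < 4:
        raise ValueError("need at least 4 crops for rank correlations")
    cols = [c for c in SUMMARY_PARAMS if c in df.columns and df[c].notna().any()]
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            pair = df[[a, b]].dropna()
            x, y = pair[a].to_numpy(float), pair[b].to_numpy(float)
            res = sps.spearmanr(x, y)
            r, p = float(res.statistic), float(res.pvalue)
            if len(x) < exact_below and np.isfinite(r):
                p = _exact_spearman_p(x, y, r)
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


def significance_stars(p: float) -> str:
    """Legend thresholds: * p<0.05, ** p<0.01, *** p<0.0001."""
    if p < 0.0001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
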