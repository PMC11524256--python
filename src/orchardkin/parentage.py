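"""Parentage assignment and pollen-source classification for one crop.

Each seedling is compared against all genotyped candidate parents (orchard
clones and, where genotyped, rootstock).  Candidates passing both a Ritland
relatedness threshold and a genotype-score-correlation threshold are accepted,
at most two per seedling.  A seedling whose single accepted parent shows
selfing-level relatedness is classed as selfed.  Seedlings with exactly one
accepted parent are then cross-compared: groups of such seedlings that are
mutually related through their unknown father are attributed to a shared
un-genotyped orchard parent, while isolated external fathers count as
background pollen contamination (BPC).

Thresholds are inferred from the empirical pairwise distribution (an
Otsu-style two-class variance split between the unrelated mode near 0 and the
parent-offspring mode near 0.5) and can be overridden.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import AlleleFrequencies, GenotypeMatrix
from .relatedness import PairwiseStats, pairwise_matrix

logger = logging.getLogger(__name__)

CATEGORIES = ("both_parents", "selfing", "bpc", "ungenotyped_parent", "unassigned")


@dataclass
class ThresholdSet:
    """Decision thresholds for parentage assignment.

    ``r_po``/``c_po`` gate seedling-parent acceptance; ``r_self`` separates a
    selfed seedling (expected relatedness twice the parent-offspring level)
    from an ordinary single parent; the two ``r_share`` thresholds link
    single-parent seedlings that share an unknown father (paternal half-sibs
    when mothers differ, full-sibs when mothers coincide); components of at
    least ``min_group`` such seedlings are attributed to an un-genotyped
    orchard parent rather than to background pollen.
    """

    r_po: float = 0.25
    c_po: float = 0.15
    r_self: float = 0.75
    r_share_diffmother: float = 0.125
    r_share_samemother: float = 0.375
    min_group: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.r_po < self.r_self:
            raise ValueError("require 0 < r_po < r_self")
        if not self.r_share_diffmother < self.r_share_samemother:
            raise ValueError("require r_share_diffmother < r_share_samemother")
        if self.min_group < 2:
            raise ValueError("min_group must be >= 2")


def _otsu_split(values: np.ndarray) -> tuple[float, float, float] | None:
    """Two-class split maximizing between-class variance.

    Returns (threshold, lower-class mean, upper-class mean) with the
    threshold placed mid-gap between the two classes, or None when either
    class would be empty.
    """
    v = np.sort(values[np.isfinite(values)])
    n = v.size
    if n < 4:
        return None
    csum = np.cumsum(v)
    total = csum[-1]
    k = np.arange(1, n)  # lower class size
    mu0 = csum[:-1] / k
    mu1 = (total - csum[:-1]) / (n - k)
    between = k * (n - k) * (mu0 - mu1) ** 2
    kbest = int(np.argmax(between)) + 1
    thr = 0.5 * (v[kbest - 1] + v[kbest])
    return thr, float(v[:kbest].mean()), float(v[kbest:].mean())


def infer_thresholds(
    po_stats: PairwiseStats,
    defaults: ThresholdSet | None = None,
    min_separation: float = 0.15,
    override: ThresholdSet | None = None,
) -> ThresholdSet:
    """Derive thresholds from the seedling x candidate-parent distribution.

    The Ritland values of all reliable seedling-parent pairs form two modes:
    unrelated pairs near 0 and true parent-offspring pairs near 0.5 (biased
    downward by genotyping error).  A two-class variance split locates the
    gap; the selfing threshold is set midway between the parent-offspring
    center and its doubled (selfed) expectation, and the unknown-father
    sharing thresholds are scaled from the same center (half-sib expectation
    = half the parent-offspring level).  If the distribution shows no usable
    second mode the defaults are returned with a warning.
    """
    if override is not None:
        return override
    defaults = defaults or ThresholdSet()
    t = po_stats.table[po_stats.table.reliable]
    split = _otsu_split(t.ritland_r.to_numpy())
    if split is None or (split[2] - split[1]) < min_separation:
        warnings.warn(
            "pairwise relatedness distribution is unimodal; using default thresholds",
            stacklevel=2,
        )
        return defaults
    r_thr, _, po_center = split
    csplit = _otsu_split(t.score_corr.to_numpy())
    c_thr = csplit[0] if csplit is not None else defaults.c_po
    self_center = min(2.0 * po_center, 1.0)
    hs_center = po_center / 2.0
    return ThresholdSet(
        r_po=r_thr,
        c_po=c_thr,
        r_self=0.5 * (po_center + self_center),
        r_share_diffmother=0.5 * hs_center,
        r_share_samemother=0.5 * (hs_center + po_center),
        min_group=defaults.min_group,
    )


def assign_parents(
    po_stats: PairwiseStats, thresholds: ThresholdSet
) -> dict[str, list[tuple[str, float, float]]]:
    """Accepted candidate parents per seedling, ranked by relatedness.

    A candidate passes with ritland_r >= r_po and score_corr >= c_po; at most
    two are retained (ties at rank 2/3 broken by score correlation, then by
    parent id; conflicts logged).
    """
    t = po_stats.table
    passing = t[
        t.reliable & (t.ritland_r >= thresholds.r_po) & (t.score_corr >= thresholds.c_po)
    ]
    out: dict[str, list[tuple[str, float, float]]] = {}
    for seedling, grp in passing.groupby("sample_a"):
        ranked = grp.sort_values(
            ["ritland_r", "score_corr", "sample_b"], ascending=[False, False, True]
        )
        if len(ranked) > 2:
            logger.info(
                "seedling %s: %d candidate parents pass; keeping top 2", seedling, len(ranked)
            )
        out[str(seedling)] = [
            (str(row.sample_b), float(row.ritland_r), float(row.score_corr))
            for row in ranked.head(2).itertuples()
        ]
    return out


def resolve_unknown_donors(
    single_parent: dict[str, str],
    ss_stats: PairwiseStats,
    thresholds: ThresholdSet,
) -> tuple[dict[str, str], dict[str, str]]:
    """Group single-parent seedlings by shared unknown father.

    Builds a graph over single-parent seedlings with an edge when the pair's
    relatedness reaches the half-sib-sharing threshold (mothers differ) or the
    full-sib threshold (same mother).  Connected components with at least
    ``min_group`` members are attributed to an un-genotyped orchard parent;
    smaller components are background pollen, sharing one donor id when
    linked.  Returns (category map, donor-group map); group ids are
    canonical in the sorted member lists, so input order cannot change them.
    """
    seedlings = sorted(single_parent)
    g = nx.Graph()
    g.add_nodes_from(seedlings)
    t = ss_stats.table
    sel = t[t.sample_a.isin(single_parent) & t.sample_b.isin(single_parent) & t.reliable]
    for row in sel.itertuples():
        same_mother = single_parent[row.sample_a] == single_parent[row.sample_b]
        thr = thresholds.r_share_samemother if same_mother else thresholds.r_share_diffmother
        if row.ritland_r >= thr:
            g.add_edge(row.sample_a, row.sample_b)
    categories: dict[str, str] = {}
    donor_group: dict[str, str] = {}
    components = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    n_up = n_ex = 0
    for comp in components:
        if len(comp) >= thresholds.min_group:
            gid = f"UP{n_up:03d}"
            n_up += 1
            cat = "ungenotyped_parent"
        else:
            gid = f"EX{n_ex:03d}"
            n_ex += 1
            cat = "bpc"
        for s in comp:
            categories[s] = cat
            donor_group[s] = gid
    return categories, donor_group


@dataclass
class ClassificationResult:
    """Per-seedling assignment records plus run metadata."""

    records: pd.DataFrame
    thresholds: ThresholdSet
    summary: dict

    @property
    def bpc_rate(self) -> float:
        return self.summary["rates"]["bpc"]

    @property
    def selfing_rate(self) -> float:
        return self.summary["rates"]["selfing"]


def _summarize(records: pd.DataFrame, thresholds: ThresholdSet) -> dict:
    n = len(records)
    counts = {c: int((records.category == c).sum()) for c in CATEGORIES}
    # selfing is a sub-category of "both parents assigned"
    counts_nested = dict(counts)
    counts_nested["both_parents_incl_selfing"] = counts["both_parents"] + counts["selfing"]
    counts_nested["single_parent"] = counts["bpc"] + counts["ungenotyped_parent"]
    rates = {k: (v / n if n else float("nan")) for k, v in counts_nested.items()}
    return {
        "n_seedlings": n,
        "counts": counts_nested,
        "rates": rates,
        "thresholds": vars(thresholds).copy(),
    }


def classify_crop(
    gm: GenotypeMatrix,
    parent_ids: list[str],
    seedling_ids: list[str],
    freqs: AlleleFrequencies,
    thresholds: ThresholdSet | str = "auto",
    min_overlap: int = 100,
) -> ClassificationResult:
    """Full per-crop pipeline: pairwise stats, thresholds, categories.

    Rates use all genotyped seedlings in the crop as denominator; selfing is
    reported separately and nested inside the both-parents total.
    """
    if not parent_ids:
        raise ValueError("no genotyped candidate parents supplied")
    if not seedling_ids:
        raise ValueError("no seedlings supplied")
    sp = pairwise_matrix(gm, seedling_ids, parent_ids, freqs, min_overlap=min_overlap)
    if isinstance(thresholds, str):
        if thresholds != "auto":
            raise ValueError("thresholds must be a ThresholdSet or 'auto'")
        thresholds = infer_thresholds(sp)
    candidates = assign_parents(sp, thresholds)

    rows = []
    single_parent: dict[str, str] = {}
    for s in seedling_ids:
        cand = candidates.get(s, [])
        if len(cand) == 2:
            (p1, r1, c1), (p2, r2, c2) = cand
            rows.append((s, p1, p2, "both_parents", None, r1, c1, r2, c2))
        elif len(cand) == 1:
            p1, r1, c1 = cand[0]
            if r1 >= thresholds.r_self:
                rows.append((s, p1, p1, "selfing", None, r1, c1, r1, c1))
            else:
                single_parent[s] = p1
                rows.append((s, p1, None, "single", None, r1, c1, np.nan, np.nan))
        else:
            rows.append((s, None, None, "unassigned", None, np.nan, np.nan, np.nan, np.nan))
    records = pd.DataFrame(
        rows,
        columns=[
            "seedling_id",
            "assigned_parent_1",
            "assigned_parent_2",
            "category",
            "donor_group_id",
            "r_parent_1",
            "corr_parent_1",
            "r_parent_2",
            "corr_parent_2",
        ],
    )

    if single_parent:
        ss = pairwise_matrix(gm, seedling_ids, seedling_ids, freqs, min_overlap=min_overlap)
        cats, groups = resolve_unknown_donors(single_parent, ss, thresholds)
        records.loc[records.category == "single", "donor_group_id"] = records.loc[
            records.category == "single", "seedling_id"
        ].map(groups)
        records.loc[records.category == "single", "category"] = records.loc[
            records.category == "single", "seedling_id"
        ].map(cats)

    summary = _summarize(records, thresholds)
    return ClassificationResult(records=records, thresholds=thresholds, summary=summary)


def category_rates(counts: dict[str, int], n_total: int) -> dict[str, float]:
    """Count -> rate conversion with total genotyped seedlings as denominator."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return {k: v / n_total for k, v in counts.items()}
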