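"""Pairwise relatedness and genotype-score correlation.

Two statistics underpin parentage assignment:

* Ritland's method-of-moments relatedness on biallelic dosages.  With
  x_A = dosage_x / 2 and x_a = 1 - x_A, the per-locus estimate at reference
  frequency p is ``r_l = 2 (x_A y_A / p + x_a y_a / (1 - p) - 1)`` and the
  multi-locus estimate is the unweighted mean over loci non-missing in both
  samples and polymorphic in the frequency panel.  Expectations under
  Hardy-Weinberg: 0 for unrelated pairs, 0.25 for half-sibs, 0.5 for
  parent-offspring and full-sibs, 1.0 between a parent and its selfed
  offspring.
* Pearson correlation of genotype scores (0/1/2) over shared loci, a
  frequency-free control for genotype similarity.

Both are computed for sample-group grids with blocked matrix algebra so
hundreds of seedlings against hundreds of seedlings stay fast and bounded
in memory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, AlleleFrequencies, GenotypeMatrix

#: Pairs sharing fewer informative loci than this are flagged unreliable.
DEFAULT_MIN_OVERLAP = 100


@dataclass
class PairwiseStats:
    """Long-format pairwise statistics.

    ``table`` columns: sample_a, sample_b, ritland_r, score_corr,
    n_shared_loci, reliable.  Within-group grids hold each unordered pair
    once; both statistics are symmetric.
    """

    table: pd.DataFrame
    min_overlap: int = DEFAULT_MIN_OVERLAP

    def lookup(self, a: str, b: str) -> pd.Series:
        t = self.table
        hit = t[((t.sample_a == a) & (t.sample_b == b)) | ((t.sample_a == b) & (t.sample_b == a))]
        if hit.empty:
            raise KeyError(f"pair ({a}, {b}) not present")
        return hit.iloc[0]


def _prepare(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x)
    valid = x != MISSING
    return np.where(valid, x, 0).astype(float), valid


def ritland_r(x: np.ndarray, y: np.ndarray, freqs: AlleleFrequencies) -> tuple[float, int]:
    """Ritland relatedness for one pair of dosage vectors.

    Returns (r, n_shared_loci).  Loci monomorphic or unobserved in the
    frequency panel are excluded; callers treat pairs with fewer than
    ``min_overlap`` shared informative loci as unreliable.
    """
    x0, vx = _prepare(x)
    y0, vy = _prepare(y)
    ok = vx & vy & freqs.informative
    n = int(ok.sum())
    if n == 0:
        return float("nan"), 0
    p = freqs.freq[ok]
    xa, ya = x0[ok] / 2.0, y0[ok] / 2.0
    r_l = 2.0 * (xa * ya / p + (1.0 - xa) * (1.0 - ya) / (1.0 - p) - 1.0)
    return float(r_l.mean()), n


def score_correlation(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Pearson correlation of genotype scores over loci non-missing in both.

    NaN (flagged) when either vector is constant on the shared loci.
    """
    x0, vx = _prepare(x)
    y0, vy = _prepare(y)
    ok = vx & vy
    n = int(ok.sum())
    if n < 2:
        return float("nan"), n
    xs, ys = x0[ok], y0[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan"), n
    return float(np.corrcoef(xs, ys)[0, 1]), n


def _block_stats(
    XA: np.ndarray,
    MA: np.ndarray,
    XB: np.ndarray,
    MB: np.ndarray,
    p: np.ndarray,
    inf_mask: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Ritland r, score correlation and locus counts for a block pair.

    All quantities are sums over loci expressed as matrix products with
    missing entries zeroed, so each pairwise grid costs a handful of GEMMs.
    """
    # Ritland over informative loci only
    MAi = MA & inf_mask[None, :]
    MBi = MB & inf_mask[None, :]
    psafe = np.where(inf_mask, p, 0.5)
    A1 = np.where(MAi, XA / 2.0, 0.0)
    B1 = np.where(MBi, XB / 2.0, 0.0)
    A2 = np.where(MAi, 1.0 - XA / 2.0, 0.0)
    B2 = np.where(MBi, 1.0 - XB / 2.0, 0.0)
    w1 = 1.0 / psafe
    w2 = 1.0 / (1.0 - psafe)
    S1 = (A1 * w1[None, :]) @ B1.T
    S2 = (A2 * w2[None, :]) @ B2.T
    N_r = MAi.astype(float) @ MBi.T.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (2.0 * (S1 + S2) - 2.0 * N_r) / N_r

    # Pearson over all shared loci
    A0 = np.where(MA, XA, 0.0)
    B0 = np.where(MB, XB, 0.0)
    MAf, MBf = MA.astype(float), MB.astype(float)
    N = MAf @ MBf.T
    Sx = A0 @ MBf.T
    Sy = MAf @ B0.T
    Sxx = (A0 * A0) @ MBf.T
    Syy = MAf @ (B0 * B0).T
    Sxy = A0 @ B0.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = Sxy - Sx * Sy / N
        vx = Sxx - Sx * Sx / N
        vy = Syy - Sy * Sy / N
        denom = np.sqrt(vx * vy)
        C = np.where(denom > 0, cov / denom, np.nan)
    return R, C, N_r, N


def pairwise_matrix(
    gm: GenotypeMatrix,
    group_a: list[str],
    group_b: list[str],
    freqs: AlleleFrequencies,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    block: int = 256,
) -> PairwiseStats:
    """Both pairwise statistics for every pair (a, b), a != b.

    When the groups are identical each unordered pair is reported once.
    """
    if not group_a or not group_b:
        raise ValueError("empty sample group")
    same = list(group_a) == list(group_b)
    ia = [gm.sample_index(s) for s in group_a]
    ib = [gm.sample_index(s) for s in group_b]
    X = gm.dosage.astype(float)
    M = gm.dosage != MISSING
    inf_mask = freqs.informative
    p = freqs.freq

    rows: list[pd.DataFrame] = []
    for a0 in range(0, len(ia), block):
        a_idx = ia[a0 : a0 + block]
        XA, MA = X[a_idx], M[a_idx]
        for b0 in range(0, len(ib), block):
            b_idx = ib[b0 : b0 + block]
            R, C, Nr, _ = _block_stats(XA, MA, X[b_idx], M[b_idx], p, inf_mask)
            aa, bb = np.meshgrid(np.arange(len(a_idx)), np.arange(len(b_idx)), indexing="ij")
            keep = np.ones(R.shape, dtype=bool)
            ga = np.asarray(group_a)[a0 : a0 + len(a_idx)]
            gb = np.asarray(group_b)[b0 : b0 + len(b_idx)]
            if same:
                # unordered pairs once, no self-pairs
                keep = (a0 + aa) < (b0 + bb)
            else:
                keep = ga[aa] != gb[bb]
            rows.append(
                pd.DataFrame(
                    {
                        "sample_a": ga[aa][keep],
                        "sample_b": gb[bb][keep],
                        "ritland_r": R[keep],
                        "score_corr": C[keep],
                        "n_shared_loci": Nr[keep].astype(int),
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    table["reliable"] = (table.n_shared_loci >= min_overlap) & table.ritland_r.notna()
    return PairwiseStats(table=table, min_overlap=min_overlap)


def write_pairwise_tsv(stats: PairwiseStats, path) -> None:
    stats.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_pairwise_tsv(path, min_overlap: int = DEFAULT_MIN_OVERLAP) -> PairwiseStats:
    table = pd.read_csv(path, sep="\t")
    if "reliable" not in table.columns:
        table["reliable"] = (table.n_shared_loci >= min_overlap) & table.ritland_r.notna()
    return PairwiseStats(table=table, min_overlap=min_overlap)
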