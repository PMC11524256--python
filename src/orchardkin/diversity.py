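"""Heterozygosity and inbreeding statistics per sample group.

Observed heterozygosity H_O is the per-locus fraction of heterozygous calls
among non-missing genotypes; expected heterozygosity H_E uses Nei's unbiased
per-locus gene diversity ``2 p (1-p) * 2n / (2n - 1)``.  The inbreeding
coefficient is computed from ratio of locus means, F_IS = 1 - mean(H_O) /
mean(H_E), and its 95% confidence interval by repeatedly subsampling
L / frac_divisor loci without replacement and taking percentiles of the
replicate F_IS values.

Samples with low breadth of coverage bias H_O downward, so groups are gated
to samples covering at least 80% of the locus panel before estimation
(see :func:`orchardkin.genotypes.select_high_breadth`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeMatrix, select_high_breadth


@dataclass
class DiversityEstimate:
    group_id: str
    n_samples_used: int
    h_obs: float
    h_obs_se: float
    h_exp: float
    h_exp_se: float
    f_is: float
    f_is_ci: tuple[float, float]


def _per_locus(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus (H_O, H_E, n_obs); NaN where a locus has no calls."""
    miss = gm.missing_mask()
    n_obs = (~miss).sum(axis=0).astype(float)
    het = np.where(miss, False, gm.dosage == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ho = np.where(n_obs > 0, het / n_obs, np.nan)
        p = np.where(miss, 0, gm.dosage).sum(axis=0) / (2.0 * n_obs)
        he = np.where(n_obs > 0, 2.0 * p * (1.0 - p) * (2.0 * n_obs) / (2.0 * n_obs - 1.0), np.nan)
    return ho, he, n_obs


def observed_het(gm: GenotypeMatrix) -> tuple[np.ndarray, float, float]:
    """Per-locus H_O plus mean and SE (SD over loci / sqrt(L))."""
    if gm.n_samples == 0:
        raise ValueError("empty group")
    ho, _, _ = _per_locus(gm)
    valid = ho[~np.isnan(ho)]
    return ho, float(valid.mean()), float(valid.std(ddof=1) / np.sqrt(valid.size))


def expected_het(gm: GenotypeMatrix) -> tuple[np.ndarray, float, float]:
    """Per-locus Nei unbiased H_E plus mean and SE."""
    if gm.n_samples == 0:
        raise ValueError("empty group")
    _, he, _ = _per_locus(gm)
    valid = he[~np.isnan(he)]
    return he, float(valid.mean()), float(valid.std(ddof=1) / np.sqrt(valid.size))


def fis(gm: GenotypeMatrix) -> float:
    """F_IS = 1 - mean(H_O) / mean(H_E) over the group's loci."""
    ho, he, _ = _per_locus(gm)
    ok = ~np.isnan(ho) & ~np.isnan(he)
    mean_he = he[ok].mean()
    if mean_he == 0.0:
        return float("nan")
    return float(1.0 - ho[ok].mean() / mean_he)


def fis_ci(
    gm: GenotypeMatrix,
    reps: int = 100_000,
    frac_divisor: int = 60,
    seed: int | None = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile confidence interval for F_IS from locus subsampling.

    Each replicate draws ceil(L / frac_divisor) loci without replacement and
    recomputes 1 - mean(H_O)/mean(H_E) on them; the CI is the percentile
    interval of the replicate values.
    """
    ho, he, _ = _per_locus(gm)
    ok = ~np.isnan(ho) & ~np.isnan(he)
    ho, he = ho[ok], he[ok]
    L = ho.size
    if L < frac_divisor:
        raise ValueError(f"need at least {frac_divisor} informative loci, got {L}")
    if reps < 100:
        import warnings

        warnings.warn("fewer than 100 resamples gives unstable percentiles", stacklevel=2)
    d = int(np.ceil(L / frac_divisor))
    rng = np.random.default_rng(seed)
    # vectorized subsampling without replacement via argpartition of random
    # keys, chunked to bound memory at ~chunk x L floats
    chunk = max(1, int(2e7 // max(L, 1)))
    parts = []
    for start in range(0, reps, chunk):
        m = min(chunk, reps - start)
        keys = rng.random((m, L))
        idx = np.argpartition(keys, d, axis=1)[:, :d]
        with np.errstate(invalid="ignore", divide="ignore"):
            parts.append(1.0 - ho[idx].mean(axis=1) / he[idx].mean(axis=1))
    f = np.concatenate(parts)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(f[np.isfinite(f)], [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def diversity_summary(
    gm: GenotypeMatrix,
    group_id: str = "",
    breadth_threshold: float = 0.8,
    reps: int = 100_000,
    frac_divisor: int = 60,
    seed: int | None = None,
) -> DiversityEstimate:
    """Breadth-gated H_O, H_E and F_IS with subsample CI for one group."""
    gated = select_high_breadth(gm, breadth_threshold)
    if gated.n_samples == 0:
        raise ValueError("no samples pass the breadth-of-coverage gate")
    _, ho, ho_se = observed_het(gated)
    _, he, he_se = expected_het(gated)
    return DiversityEstimate(
        group_id=group_id,
        n_samples_used=gated.n_samples,
        h_obs=ho,
        h_obs_se=ho_se,
        h_exp=he,
        h_exp_se=he_se,
        f_is=fis(gated),
        f_is_ci=fis_ci(gated, reps=reps, frac_divisor=frac_divisor, seed=seed),
    )
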