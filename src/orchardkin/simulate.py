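"""Forward simulation of an open-pollinated seed-orchard crop.

The simulator produces a crop with known pedigree so that parentage
reconstruction, contamination estimation and diversity statistics can be
validated against ground truth.  The mating model:

* Orchard parents are unrelated clones drawn under Hardy-Weinberg from
  per-locus frequencies uniform on ``maf_range``.
* Each seedling's mother is drawn from Dirichlet-distributed female fecundity
  weights over the genotyped parents (cones are harvested from orchard trees).
* The father is the mother itself with probability ``selfing_rate``; an
  external background donor with probability ``bpc_rate``; otherwise an
  orchard male (genotyped or ungenotyped) drawn from male fecundity weights.
* The background pollen pool has allele frequencies diverged from the orchard
  pool by a Balding-Nichols model at ``background_fst``.
* Observed genotypes are one Mendelian gamete from each parent, degraded by a
  symmetric per-allele flip error and per-genotype missingness.

Ground truth (mother, father, father class) is recorded before noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, AlleleFrequencies, GenotypeMatrix

FATHER_CLASSES = ("orchard", "self", "external_unique", "external_shared", "ungenotyped_parent")

#: Symmetric-Dirichlet concentration at which roughly half of the parents
#: sire 80% of the progeny, matching the contribution skew typical of
#: conifer orchards.
DEFAULT_FECUNDITY_SKEW = 1.4


@dataclass
class OrchardSimConfig:
    """Study-design parameters for one simulated crop.

    Defaults describe a mid-sized northern conifer orchard: tens of clonal
    parents, a few hundred sampled seedlings, ~5,000 informative SNPs,
    a few percent selfing, substantial background pollen contamination and
    GBS-like genotype error and missingness.
    """

    n_parents: int = 50
    n_seedlings: int = 300
    n_loci: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    selfing_rate: float = 0.03
    bpc_rate: float = 0.30
    background_fst: float = 0.05
    female_fecundity_skew: float = DEFAULT_FECUNDITY_SKEW
    male_fecundity_skew: float = DEFAULT_FECUNDITY_SKEW
    n_ungenotyped_parents: int = 0
    external_donor_reuse: float = 0.0
    genotype_error_rate: float = 0.005
    missing_rate: float = 0.10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parents < 1:
            raise ValueError("n_parents must be >= 1")
        if not 0.0 <= self.background_fst < 1.0:
            raise ValueError("background_fst must be in [0, 1)")
        for name in (
            "selfing_rate",
            "bpc_rate",
            "external_donor_reuse",
            "genotype_error_rate",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.selfing_rate + self.bpc_rate > 1.0:
            raise ValueError("selfing_rate + bpc_rate must be <= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must satisfy 0 < low <= high < 1")


@dataclass
class OrchardSimulation:
    """Bundle of simulator outputs: genotypes, truth and frequency pools."""

    parents: GenotypeMatrix
    seedlings: GenotypeMatrix
    pedigree: pd.DataFrame  # seedling_id, mother_id, father_id, father_class
    orchard_freqs: AlleleFrequencies
    background_freqs: AlleleFrequencies
    ungenotyped_parent_ids: list[str] = field(default_factory=list)


def _hwe_genotypes(rng: np.random.Generator, p: np.ndarray, n: int) -> np.ndarray:
    return rng.binomial(2, p[None, :], size=(n, p.size)).astype(np.int8)


def simulate_parents(
    cfg: OrchardSimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, AlleleFrequencies]:
    """Draw orchard-pool frequencies and unrelated parent genotypes under HWE."""
    rng = rng or np.random.default_rng(cfg.rng_seed)
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_loci)
    locus_ids = [f"L{j:05d}" for j in range(cfg.n_loci)]
    ids = [f"P{i:03d}" for i in range(cfg.n_parents)]
    gm = GenotypeMatrix(
        sample_ids=ids,
        roles=["parent"] * cfg.n_parents,
        crop_labels=[""] * cfg.n_parents,
        locus_ids=locus_ids,
        dosage=_hwe_genotypes(rng, p, cfg.n_parents),
    )
    freqs = AlleleFrequencies(
        locus_ids=locus_ids, freq=p, n_obs=np.full(cfg.n_loci, cfg.n_parents), source_samples=ids
    )
    return gm, freqs


def simulate_background_pool(
    cfg: OrchardSimConfig,
    orchard_freqs: AlleleFrequencies,
    rng: np.random.Generator | None = None,
) -> AlleleFrequencies:
    """Background-pollen frequencies diverged from the orchard pool.

    Balding-Nichols: p' ~ Beta with mean p and variance Fst * p(1-p);
    Fst = 0 returns the orchard frequencies exactly.
    """
    rng = rng or np.random.default_rng(cfg.rng_seed + 1)
    p = orchard_freqs.freq
    if cfg.background_fst == 0.0:
        q = p.copy()
    else:
        c = (1.0 - cfg.background_fst) / cfg.background_fst
        q = rng.beta(c * p, c * (1.0 - p))
        # keep the pool polymorphic so gamete draws stay well-defined
        q = np.clip(q, 1e-6, 1.0 - 1e-6)
    return AlleleFrequencies(
        locus_ids=list(orchard_freqs.locus_ids),
        freq=q,
        n_obs=np.zeros(len(orchard_freqs.locus_ids), dtype=int),
        source_samples=[],
    )


def _gametes(rng: np.random.Generator, dosages: np.ndarray) -> np.ndarray:
    """One Mendelian gamete (0/1 allele per locus) per row of parent dosages."""
    prob = dosages / 2.0
    return (rng.random(dosages.shape) < prob).astype(np.int8)


def simulate_crop(
    cfg: OrchardSimConfig,
    parents: GenotypeMatrix,
    background: AlleleFrequencies,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Mate the orchard and return noisy seedling genotypes plus true pedigree."""
    rng = rng or np.random.default_rng(cfg.rng_seed + 2)
    n_par = parents.n_samples
    n_loci = parents.n_loci
    par_dos = parents.dosage.astype(np.int8)

    # ungenotyped orchard parents: real HWE genotypes, absent from output
    unge_ids = [f"U{i:03d}" for i in range(cfg.n_ungenotyped_parents)]
    unge_dos = _hwe_genotypes(rng, _orchard_p(parents), cfg.n_ungenotyped_parents)

    female_w = rng.dirichlet([cfg.female_fecundity_skew] * n_par)
    male_pool = n_par + cfg.n_ungenotyped_parents
    male_w = rng.dirichlet([cfg.male_fecundity_skew] * male_pool)

    mothers = rng.choice(n_par, size=cfg.n_seedlings, p=female_w)
    u = rng.random(cfg.n_seedlings)
    is_self = u < cfg.selfing_rate
    is_ext = (~is_self) & (u < cfg.selfing_rate + cfg.bpc_rate)

    father_idx = np.full(cfg.n_seedlings, -1)  # index into orchard male pool
    father_ids: list[str] = [""] * cfg.n_seedlings
    father_class: list[str] = [""] * cfg.n_seedlings

    ext_donor_dos: list[np.ndarray] = []
    ext_donor_uses: list[int] = []
    ext_assign = np.full(cfg.n_seedlings, -1)

    for k in range(cfg.n_seedlings):
        if is_self[k]:
            father_class[k] = "self"
            father_ids[k] = parents.sample_ids[mothers[k]]
        elif is_ext[k]:
            if ext_donor_dos and rng.random() < cfg.external_donor_reuse:
                d = int(rng.integers(len(ext_donor_dos)))
            else:
                d = len(ext_donor_dos)
                ext_donor_dos.append(rng.binomial(2, background.freq).astype(np.int8))
                ext_donor_uses.append(0)
            ext_donor_uses[d] += 1
            ext_assign[k] = d
            father_ids[k] = f"X{d:03d}"
            father_class[k] = "external"  # refined to unique/shared below
        else:
            # outcross within the orchard: selfing happens only through the
            # explicit selfing branch, so the mother is excluded here
            w = male_w.copy()
            if male_pool > 1:
                w[mothers[k]] = 0.0
                w = w / w.sum()
            j = int(rng.choice(male_pool, p=w))
            father_idx[k] = j
            if j < n_par:
                father_ids[k] = parents.sample_ids[j]
                father_class[k] = "orchard"
            else:
                father_ids[k] = unge_ids[j - n_par]
                father_class[k] = "ungenotyped_parent"
    for k in range(cfg.n_seedlings):
        if father_class[k] == "external":
            father_class[k] = (
                "external_shared" if ext_donor_uses[ext_assign[k]] > 1 else "external_unique"
            )

    # gametes
    maternal = _gametes(rng, par_dos[mothers])
    pat_dos = np.empty((cfg.n_seedlings, n_loci), dtype=np.int8)
    for k in range(cfg.n_seedlings):
        if is_self[k]:
            pat_dos[k] = par_dos[mothers[k]]
        elif ext_assign[k] >= 0:
            pat_dos[k] = ext_donor_dos[ext_assign[k]]
        elif father_idx[k] < n_par:
            pat_dos[k] = par_dos[father_idx[k]]
        else:
            pat_dos[k] = unge_dos[father_idx[k] - n_par]
    paternal = _gametes(rng, pat_dos)

    # genotyping noise: symmetric per-allele flips, then missingness
    if cfg.genotype_error_rate > 0:
        flip_m = rng.random(maternal.shape) < cfg.genotype_error_rate
        flip_p = rng.random(paternal.shape) < cfg.genotype_error_rate
        maternal = maternal ^ flip_m
        paternal = paternal ^ flip_p
    dosage = (maternal + paternal).astype(np.int8)
    if cfg.missing_rate > 0:
        dosage[rng.random(dosage.shape) < cfg.missing_rate] = MISSING

    seedling_ids = [f"S{k:04d}" for k in range(cfg.n_seedlings)]
    gm = GenotypeMatrix(
        sample_ids=seedling_ids,
        roles=["seedling"] * cfg.n_seedlings,
        crop_labels=["sim"] * cfg.n_seedlings,
        locus_ids=list(parents.locus_ids),
        dosage=dosage,
    )
    pedigree = pd.DataFrame(
        {
            "seedling_id": seedling_ids,
            "mother_id": [parents.sample_ids[m] for m in mothers],
            "father_id": father_ids,
            "father_class": father_class,
        }
    )
    return gm, pedigree


def _orchard_p(parents: GenotypeMatrix) -> np.ndarray:
    """Empirical orchard-pool frequency used for ungenotyped-parent genotypes."""
    return parents.dosage.mean(axis=0) / 2.0


def simulate_orchard(cfg: OrchardSimConfig) -> OrchardSimulation:
    """Run the full simulator with child seeds fanned out from ``rng_seed``."""
    ss = np.random.SeedSequence(cfg.rng_seed)
    r_par, r_bg, r_crop = (np.random.default_rng(s) for s in ss.spawn(3))
    parents, freqs = simulate_parents(cfg, r_par)
    background = simulate_background_pool(cfg, freqs, r_bg)
    seedlings, pedigree = simulate_crop(cfg, parents, background, r_crop)
    unge = sorted(
        set(pedigree.loc[pedigree.father_class == "ungenotyped_parent", "father_id"])
    )
    return OrchardSimulation(
        parents=parents,
        seedlings=seedlings,
        pedigree=pedigree,
        orchard_freqs=freqs,
        background_freqs=background,
        ungenotyped_parent_ids=unge,
    )


def write_truth(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)
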