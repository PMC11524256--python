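"""Genotype matrices: VCF / dosage-TSV input, QC masking and filtering.

The central container is :class:`GenotypeMatrix`, a samples x loci matrix of
alternate-allele dosages (0, 1, 2, or missing) with per-sample roles
(parent / seedling / rootstock / reference) and optional per-genotype read
depth (DP) and genotype quality (GQ).  All downstream statistics (relatedness,
parentage, diversity) operate on this container.

Filtering follows a fixed order: per-genotype confidence masking, then
per-sample missingness removal, then per-locus removal (MAF, missingness,
excess heterozygosity, multi-allelic sites).  Boundary conventions are strict
where stated: depth < 5 and GQ < 20 are masked, samples with *more than* 40%
missing are dropped, loci with MAF *below* 0.05 are dropped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing dosage call.
MISSING: int = -1

ROLES = ("parent", "seedling", "rootstock", "reference")


@dataclass
class FilterConfig:
    """Thresholds for genotype masking and sample/locus filtering.

    Defaults mirror a GBS-style QC: genotypes below 5 reads or GQ 20 are
    unreliable, samples and loci with > 40% missing calls are uninformative,
    loci with > 70% heterozygotes are likely paralog collapses, and
    MAF < 0.05 loci carry little information for moment-based relatedness.
    """

    min_depth: int = 5
    min_gq: float = 20.0
    max_sample_missing: float = 0.40
    maf_min: float = 0.05
    max_locus_missing: float = 0.40
    max_locus_het: float = 0.70
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        for name in ("max_sample_missing", "maf_min", "max_locus_missing", "max_locus_het"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class GenotypeMatrix:
    """Samples x biallelic loci alternate-allele dosage matrix.

    ``dosage`` holds values in {0, 1, 2, MISSING}; ``n_alleles`` records the
    ALT-allele count + 1 per locus so that multi-allelic records read from a
    VCF can be flagged for removal rather than silently coerced.
    """

    sample_ids: list[str]
    roles: list[str]
    crop_labels: list[str]
    locus_ids: list[str]
    dosage: np.ndarray  # (n_samples, n_loci) int8
    depth: np.ndarray | None = None
    gq: np.ndarray | None = None
    n_alleles: np.ndarray | None = None  # per-locus allele count, default 2

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, L = self.dosage.shape
        if len(self.sample_ids) != n or len(self.roles) != n or len(self.crop_labels) != n:
            raise ValueError("sample metadata length does not match dosage rows")
        if len(self.locus_ids) != L:
            raise ValueError("locus_ids length does not match dosage columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.locus_ids)) != L:
            raise ValueError("duplicate locus ids")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"dosage contains values outside {{0,1,2,{MISSING}}}")
        for name in ("depth", "gq"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.dosage.shape:
                    raise ValueError(f"{name} shape does not match dosage")
                if np.nanmin(arr) < 0 if arr.size else False:
                    raise ValueError(f"negative values in {name}")
                setattr(self, name, arr)
        if self.n_alleles is None:
            self.n_alleles = np.full(L, 2, dtype=np.int16)
        else:
            self.n_alleles = np.asarray(self.n_alleles, dtype=np.int16)
            if self.n_alleles.shape != (L,):
                raise ValueError("n_alleles length does not match loci")
        unknown = set(self.roles) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown roles: {sorted(unknown)}")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id}") from None

    def samples_with_role(self, *roles: str) -> list[str]:
        want = set(roles)
        return [s for s, r in zip(self.sample_ids, self.roles) if r in want]

    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def sample_missing_fraction(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def locus_missing_fraction(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    # -- subsetting ------------------------------------------------------

    def take_samples(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            roles=[self.roles[i] for i in idx],
            crop_labels=[self.crop_labels[i] for i in idx],
            locus_ids=list(self.locus_ids),
            dosage=self.dosage[idx],
            depth=None if self.depth is None else self.depth[idx],
            gq=None if self.gq is None else self.gq[idx],
            n_alleles=self.n_alleles.copy(),
        )

    def take_loci(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            roles=list(self.roles),
            crop_labels=list(self.crop_labels),
            locus_ids=[self.locus_ids[i] for i in idx],
            dosage=self.dosage[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
            gq=None if self.gq is None else self.gq[:, idx],
            n_alleles=self.n_alleles[idx],
        )

    def select_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        return self.take_samples([self.sample_index(s) for s in sample_ids])


@dataclass
class AlleleFrequencies:
    """Per-locus alternate-allele frequencies from a sample subset.

    ``freq`` is NaN for loci with zero non-missing calls in the subset; such
    loci, and loci fixed at 0 or 1, are excluded by relatedness computations
    (``informative`` marks usable loci).
    """

    locus_ids: list[str]
    freq: np.ndarray
    n_obs: np.ndarray
    source_samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=int)
        if not (len(self.locus_ids) == self.freq.size == self.n_obs.size):
            raise ValueError("locus_ids, freq and n_obs must have equal length")
        with np.errstate(invalid="ignore"):
            if np.nanmax(self.freq, initial=0.0) > 1.0 or np.nanmin(self.freq, initial=0.0) < 0.0:
                raise ValueError("frequencies must lie in [0, 1]")

    @property
    def informative(self) -> np.ndarray:
        """Loci usable for moment estimators: observed and polymorphic."""
        with np.errstate(invalid="ignore"):
            return (self.n_obs > 0) & (self.freq > 0.0) & (self.freq < 1.0)


def concat_samples(*matrices: GenotypeMatrix) -> GenotypeMatrix:
    """Stack matrices sample-wise; all must share the same locus list."""
    first = matrices[0]
    for gm in matrices[1:]:
        if gm.locus_ids != first.locus_ids:
            raise ValueError("matrices have different locus lists")
    has_depth = all(gm.depth is not None for gm in matrices)
    has_gq = all(gm.gq is not None for gm in matrices)
    return GenotypeMatrix(
        sample_ids=[s for gm in matrices for s in gm.sample_ids],
        roles=[r for gm in matrices for r in gm.roles],
        crop_labels=[c for gm in matrices for c in gm.crop_labels],
        locus_ids=list(first.locus_ids),
        dosage=np.vstack([gm.dosage for gm in matrices]),
        depth=np.vstack([gm.depth for gm in matrices]) if has_depth else None,
        gq=np.vstack([gm.gq for gm in matrices]) if has_gq else None,
        n_alleles=first.n_alleles.copy(),
    )


# ---------------------------------------------------------------------------
# manifest + I/O


def read_manifest(path) -> pd.DataFrame:
    """Read a sample manifest TSV with columns sample_id, role, crop_label."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "role"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}; got {list(df.columns)}")
    if "crop_label" not in df.columns:
        df["crop_label"] = ""
    df["crop_label"] = df["crop_label"].fillna("")
    bad = set(df["role"]) - set(ROLES)
    if bad:
        raise ValueError(f"manifest contains unknown roles: {sorted(bad)}")
    if df["sample_id"].duplicated().any():
        raise ValueError("manifest contains duplicate sample ids")
    return df


def _apply_manifest(sample_ids: list[str], manifest: pd.DataFrame | None):
    if manifest is None:
        return ["reference"] * len(sample_ids), [""] * len(sample_ids)
    lut = manifest.set_index("sample_id")
    missing = [s for s in lut.index if s not in set(sample_ids)]
    if missing:
        raise ValueError(f"manifest samples not present in genotype data: {missing}")
    roles, crops = [], []
    unlisted = []
    for s in sample_ids:
        if s in lut.index:
            roles.append(str(lut.loc[s, "role"]))
            crops.append(str(lut.loc[s, "crop_label"]))
        else:
            unlisted.append(s)
            roles.append("reference")
            crops.append("")
    if unlisted:
        warnings.warn(
            f"{len(unlisted)} samples absent from manifest assigned role 'reference'",
            stacklevel=3,
        )
    return roles, crops


def _safe_format(var, key: str):
    """FORMAT field or None when the tag is absent from record or header."""
    try:
        return var.format(key)
    except KeyError:
        return None


def read_vcf(path, manifest: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    GT is required; DP and GQ are carried along when present in FORMAT.
    Multi-allelic records are retained with their allele count recorded, so
    that :func:`filter_loci` can drop them under ``biallelic_only``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    roles, crops = _apply_manifest(samples, manifest)

    locus_ids: list[str] = []
    dosage_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    gq_cols: list[np.ndarray] = []
    nall: list[int] = []
    has_depth = has_gq = False
    for var in vcf:
        lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        locus_ids.append(lid)
        nall.append(1 + len(var.ALT))
        # gts012: 0/1/2 = ALT dosage, 3 = unknown
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING
        dosage_cols.append(gt)
        dp = _safe_format(var, "DP")
        if dp is not None:
            has_depth = True
            dp = dp.astype(float).reshape(-1)
            dp[dp < 0] = np.nan
            depth_cols.append(dp)
        else:
            depth_cols.append(np.full(len(samples), np.nan))
        gq = _safe_format(var, "GQ")
        if gq is not None:
            has_gq = True
            gq = gq.astype(float).reshape(-1)
            gq[gq < 0] = np.nan
            gq_cols.append(gq)
        else:
            gq_cols.append(np.full(len(samples), np.nan))
    vcf.close()
    if not locus_ids:
        raise ValueError(f"no variant records in {path}")
    dosage = np.column_stack(dosage_cols)
    return GenotypeMatrix(
        sample_ids=samples,
        roles=roles,
        crop_labels=crops,
        locus_ids=locus_ids,
        dosage=dosage,
        depth=np.column_stack(depth_cols) if has_depth else None,
        gq=np.column_stack(gq_cols) if has_gq else None,
        n_alleles=np.asarray(nall),
    )


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal VCF 4.2 (GT only, one pseudo-contig)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=orchardkin\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        for j, lid in enumerate(gm.locus_ids):
            gts = "\t".join(gt_map[int(d)] for d in gm.dosage[:, j])
            fh.write(f"1\t{j + 1}\t{lid}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


def read_dosage_tsv(path, manifest: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Read a samples x loci dosage TSV (first column sample id, NA missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dosage = df.to_numpy(dtype=float)
    out = np.full(dosage.shape, MISSING, dtype=np.int8)
    ok = ~np.isnan(dosage)
    out[ok] = dosage[ok].astype(np.int8)
    samples = [str(s) for s in df.index]
    roles, crops = _apply_manifest(samples, manifest)
    return GenotypeMatrix(
        sample_ids=samples,
        roles=roles,
        crop_labels=crops,
        locus_ids=[str(c) for c in df.columns],
        dosage=out,
    )


def write_dosage_tsv(gm: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        gm.dosage.astype(float), index=gm.sample_ids, columns=gm.locus_ids
    )
    df[gm.dosage == MISSING] = np.nan
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA", float_format="%.0f")


# ---------------------------------------------------------------------------
# masking and filtering


def mask_low_confidence(gm: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Mask genotypes with depth < min_depth or GQ < min_gq as missing."""
    if gm.depth is None and gm.gq is None:
        warnings.warn("no depth/GQ information; confidence masking skipped", stacklevel=2)
        return gm
    mask = np.zeros(gm.dosage.shape, dtype=bool)
    if gm.depth is not None:
        with np.errstate(invalid="ignore"):
            mask |= gm.depth < cfg.min_depth
    if gm.gq is not None:
        with np.errstate(invalid="ignore"):
            mask |= gm.gq < cfg.min_gq
    dosage = gm.dosage.copy()
    dosage[mask] = MISSING
    logger.info("masked %d genotypes below confidence thresholds", int(mask.sum()))
    return replace(gm, dosage=dosage)


def filter_samples(gm: GenotypeMatrix, cfg: FilterConfig) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop samples whose missing fraction exceeds ``max_sample_missing``.

    Returns the filtered matrix and a report of removed samples.
    """
    miss = gm.sample_missing_fraction()
    drop = miss > cfg.max_sample_missing
    report = pd.DataFrame(
        {"sample_id": np.asarray(gm.sample_ids)[drop], "missing_fraction": miss[drop]}
    )
    if drop.all():
        warnings.warn("all samples removed by missingness filter", stacklevel=2)
    return gm.take_samples(np.flatnonzero(~drop)), report


def filter_loci(gm: GenotypeMatrix, cfg: FilterConfig) -> tuple[GenotypeMatrix, dict]:
    """Drop loci failing MAF, missingness, heterozygosity or allele-count rules.

    A locus is removed if its minor allele frequency is below ``maf_min``, its
    missing fraction exceeds ``max_locus_missing``, its heterozygote fraction
    among non-missing calls exceeds ``max_locus_het``, or (when
    ``biallelic_only``) it has more than two alleles.  Per-rule removal counts
    are returned; a locus may trip several rules.
    """
    miss = gm.missing_mask()
    n_obs = (~miss).sum(axis=0)
    dos = np.where(miss, 0, gm.dosage).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dos.sum(axis=0) / (2.0 * n_obs)
        maf = np.minimum(p, 1.0 - p)
        het = (np.where(miss, 0, gm.dosage == 1)).sum(axis=0) / n_obs
    frac_missing = miss.mean(axis=0)

    no_calls = n_obs == 0
    fail_maf = no_calls | (maf < cfg.maf_min)
    fail_missing = frac_missing > cfg.max_locus_missing
    fail_het = ~no_calls & (het > cfg.max_locus_het)
    fail_multi = cfg.biallelic_only & (gm.n_alleles > 2)
    drop = fail_maf | fail_missing | fail_het | fail_multi
    report = {
        "n_input": gm.n_loci,
        "n_kept": int((~drop).sum()),
        "removed_maf": int(fail_maf.sum()),
        "removed_missing": int(fail_missing.sum()),
        "removed_het": int(fail_het.sum()),
        "removed_multiallelic": int(fail_multi.sum()),
    }
    return gm.take_loci(np.flatnonzero(~drop)), report


def apply_filters(gm: GenotypeMatrix, cfg: FilterConfig | None = None) -> tuple[GenotypeMatrix, dict]:
    """Full QC in fixed order: mask genotypes, drop samples, drop loci."""
    cfg = cfg or FilterConfig()
    gm = mask_low_confidence(gm, cfg) if (gm.depth is not None or gm.gq is not None) else gm
    gm, sample_report = filter_samples(gm, cfg)
    gm, locus_report = filter_loci(gm, cfg)
    report = {
        "samples_removed": sample_report.to_dict(orient="records"),
        "n_samples_kept": gm.n_samples,
        "loci": locus_report,
    }
    return gm, report


# ---------------------------------------------------------------------------
# allele frequencies and coverage


def allele_frequencies(gm: GenotypeMatrix, samples: list[str] | None = None) -> AlleleFrequencies:
    """Alternate-allele frequency per locus over the given sample subset.

    freq_l = (sum of dosages at l over non-missing) / (2 * non-missing count).
    Loci with zero non-missing calls get NaN and are flagged via
    ``AlleleFrequencies.informative``.
    """
    sub = gm if samples is None else gm.select_samples(samples)
    if sub.n_samples == 0:
        raise ValueError("empty sample subset for allele frequencies")
    miss = sub.missing_mask()
    n_obs = (~miss).sum(axis=0)
    total = np.where(miss, 0, sub.dosage).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, total / (2.0 * n_obs), np.nan)
    return AlleleFrequencies(
        locus_ids=list(sub.locus_ids),
        freq=freq,
        n_obs=n_obs,
        source_samples=list(sub.sample_ids),
    )


def breadth_of_coverage(gm: GenotypeMatrix, sample_id: str) -> float:
    """Fraction of loci with a non-missing call for one sample."""
    i = gm.sample_index(sample_id)
    return float((gm.dosage[i] != MISSING).mean())


def select_high_breadth(gm: GenotypeMatrix, threshold: float = 0.8) -> GenotypeMatrix:
    """Samples whose breadth of coverage is >= threshold (inclusive)."""
    frac = 1.0 - gm.sample_missing_fraction()
    return gm.take_samples(np.flatnonzero(frac >= threshold))
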