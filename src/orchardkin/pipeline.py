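"""End-to-end orchestration: filter -> relate -> assign -> summarize -> gain.

``run_all`` executes the whole analysis from a genotype file and manifest,
writing per-stage TSV/JSON outputs plus a provenance record into the output
directory.  ``recovery_report`` scores inferred assignments against a
simulator truth pedigree and is the package's parameter-recovery harness.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import diversity_summary
from .gain import GainSpec, gain_table
from .genotypes import (
    FilterConfig,
    GenotypeMatrix,
    allele_frequencies,
    apply_filters,
    read_dosage_tsv,
    read_manifest,
    read_vcf,
)
from .mating import (
    ContributionTable,
    CropSummary,
    contribution_curve,
    contributions,
    n_ep,
    spearman_matrix,
    var_logit_psuc,
)
from .parentage import ClassificationResult, ThresholdSet, classify_crop


@dataclass
class RunConfig:
    """Inputs and knobs for one reproducible pipeline run."""

    genotypes: str
    manifest: str
    out_dir: str
    gains: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    thresholds: ThresholdSet | str = "auto"
    freq_panel: str = "reference"  # or "all"
    breadth_threshold: float = 0.8
    fis_reps: int = 10_000
    min_overlap: int = 100
    rng_seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "rng_seed" not in raw:
            raise ValueError("rng_seed is mandatory in run configs")
        if "filter" in raw and isinstance(raw["filter"], dict):
            raw["filter"] = FilterConfig(**raw["filter"])
        if "thresholds" in raw and isinstance(raw["thresholds"], dict):
            raw["thresholds"] = ThresholdSet(**raw["thresholds"])
        return cls(**raw)


def _load_genotypes(cfg: RunConfig) -> GenotypeMatrix:
    manifest_path = Path(cfg.manifest)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {cfg.manifest}")
    manifest = read_manifest(manifest_path)
    path = Path(cfg.genotypes)
    if not path.exists():
        raise FileNotFoundError(f"genotype file not found: {cfg.genotypes}")
    if path.suffix in (".vcf", ".gz", ".bcf"):
        return read_vcf(path, manifest)
    return read_dosage_tsv(path, manifest)


def _freq_panel(gm: GenotypeMatrix, which: str):
    if which == "reference":
        panel = gm.samples_with_role("reference")
        if not panel:
            warnings.warn(
                "no reference-stand samples; allele frequencies use all samples", stacklevel=2
            )
            return allele_frequencies(gm), "all"
        return allele_frequencies(gm, panel), "reference"
    if which == "all":
        return allele_frequencies(gm), "all"
    raise ValueError("freq_panel must be 'reference' or 'all'")


def run_all(cfg: RunConfig) -> Path:
    """Execute every stage and return the output directory.

    Per-crop outputs: assignments.tsv, contributions.tsv, diversity.tsv,
    crop_summary.tsv, spearman.tsv (>= 4 crops), gain.tsv (if a gain spec
    file is given), summary.json, provenance.json.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.rng_seed)
    crop_seed_root = ss.spawn(1)[0]

    gm = _load_genotypes(cfg)
    gm, filter_report = apply_filters(gm, cfg.filter)
    freqs, panel_used = _freq_panel(gm, cfg.freq_panel)

    parent_ids = gm.samples_with_role("parent", "rootstock")
    parent_classes = {
        s: ("rootstock" if r == "rootstock" else "orchard")
        for s, r in zip(gm.sample_ids, gm.roles)
        if r in ("parent", "rootstock")
    }
    crops = sorted(
        {c for c, r in zip(gm.crop_labels, gm.roles) if r == "seedling" and c}
    )
    if not crops:
        raise ValueError("no seedling crops in manifest")

    all_records = []
    all_contribs = []
    summaries: list[CropSummary] = []
    crop_reports: dict[str, dict] = {}
    for crop, child in zip(crops, crop_seed_root.spawn(len(crops))):
        seedlings = [
            s
            for s, r, c in zip(gm.sample_ids, gm.roles, gm.crop_labels)
            if r == "seedling" and c == crop
        ]
        result: ClassificationResult = classify_crop(
            gm, parent_ids, seedlings, freqs, thresholds=cfg.thresholds, min_overlap=cfg.min_overlap
        )
        rec = result.records.copy()
        rec.insert(0, "crop", crop)
        all_records.append(rec)

        table = contributions(result.records, crop_id=crop, parent_classes=parent_classes)
        ct = table.entries.copy()
        ct.insert(0, "crop", crop)
        all_contribs.append(ct)

        nep = n_ep(table, include_external=False)
        nep2 = n_ep(table, include_external=True)
        _, k80, frac80 = contribution_curve(table)
        div = diversity_summary(
            gm.select_samples(seedlings),
            group_id=crop,
            breadth_threshold=cfg.breadth_threshold,
            reps=cfg.fis_reps,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        summaries.append(
            CropSummary(
                crop_id=crop,
                h_obs=div.h_obs,
                h_exp=div.h_exp,
                f_is=div.f_is,
                bpc=result.bpc_rate,
                selfing=result.selfing_rate,
                n_ep=nep,
                n_ep2=nep2,
                census_parents=len(parent_ids),
                var_logit_psuc=var_logit_psuc(table),
            )
        )
        crop_reports[crop] = {
            "assignment": result.summary,
            "n_ep": nep,
            "n_ep2": nep2,
            "parents_for_80pct": k80,
            "parents_for_80pct_fraction": frac80,
            "diversity": {
                "n_samples_used": div.n_samples_used,
                "h_obs": div.h_obs,
                "h_obs_se": div.h_obs_se,
                "h_exp": div.h_exp,
                "h_exp_se": div.h_exp_se,
                "f_is": div.f_is,
                "f_is_ci": list(div.f_is_ci),
            },
        }

    pd.concat(all_records, ignore_index=True).to_csv(
        out / "assignments.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pd.concat(all_contribs, ignore_index=True).to_csv(
        out / "contributions.tsv", sep="\t", index=False, float_format="%.6g"
    )
    summary_df = pd.DataFrame([vars(s) for s in summaries])
    summary_df.to_csv(out / "crop_summary.tsv", sep="\t", index=False, float_format="%.6g")
    if len(summaries) >= 4:
        rho, pval = spearman_matrix(summaries)
        rho.to_csv(out / "spearman.tsv", sep="\t", float_format="%.4g")
        pval.to_csv(out / "spearman_p.tsv", sep="\t", float_format="%.4g")

    if cfg.gains:
        with open(cfg.gains) as fh:
            specs = [GainSpec(**row) for row in json.load(fh)]
        bpc_by_crop = {s.crop_id: s.bpc for s in summaries}
        gain_table(specs, observed_bpc=bpc_by_crop).to_csv(
            out / "gain.tsv", sep="\t", index=False
        )

    summary = {"filters": filter_report, "frequency_panel": panel_used, "crops": crop_reports}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    provenance = {
        "package_version": __version__,
        "config": _config_dict(cfg),
        "thresholds_used": {c: crop_reports[c]["assignment"]["thresholds"] for c in crop_reports},
        "frequency_panel": panel_used,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return out


def _config_dict(cfg: RunConfig) -> dict:
    return asdict(cfg)  # nested dataclasses (filter, thresholds) recurse


# ---------------------------------------------------------------------------
# parameter-recovery harness


_TRUTH_TO_CATEGORY = {
    "orchard": "both_parents",
    "self": "selfing",
    "external_unique": "bpc",
    "external_shared": "bpc",
    "ungenotyped_parent": "ungenotyped_parent",
}


def truth_records(pedigree: pd.DataFrame) -> pd.DataFrame:
    """Assignment records implied by a truth pedigree (perfect assignment)."""
    rows = []
    for row in pedigree.itertuples():
        cat = _TRUTH_TO_CATEGORY[row.father_class]
        if cat in ("both_parents", "selfing"):
            rows.append((row.seedling_id, row.mother_id, row.father_id, cat, None))
        else:
            rows.append((row.seedling_id, row.mother_id, None, cat, row.father_id))
    return pd.DataFrame(
        rows,
        columns=["seedling_id", "assigned_parent_1", "assigned_parent_2", "category", "donor_group_id"],
    )


def recovery_report(
    pedigree: pd.DataFrame, records: pd.DataFrame, contributions_table: ContributionTable | None = None
) -> dict:
    """Score inferred assignments against simulator truth.

    Reports parent-pair accuracy over truth orchard-father seedlings, a
    category confusion matrix, absolute BPC and selfing errors, and the
    N_ep error against truth-derived contributions.
    """
    truth = pedigree.set_index("seedling_id")
    rec = records.set_index("seedling_id")
    common = truth.index.intersection(rec.index)
    truth, rec = truth.loc[common], rec.loc[common]
    truth_cat = truth.father_class.map(_TRUTH_TO_CATEGORY)

    confusion: dict[str, dict[str, int]] = {}
    for tc, ic in zip(truth_cat, rec.category):
        confusion.setdefault(tc, {}).setdefault(ic, 0)
        confusion[tc][ic] += 1

    orch = truth_cat[truth_cat == "both_parents"].index
    n_pair_ok = 0
    for s in orch:
        inferred = {rec.loc[s, "assigned_parent_1"], rec.loc[s, "assigned_parent_2"]}
        if rec.loc[s, "category"] == "both_parents" and inferred == {
            truth.loc[s, "mother_id"],
            truth.loc[s, "father_id"],
        }:
            n_pair_ok += 1
    pair_acc = n_pair_ok / len(orch) if len(orch) else float("nan")

    n = len(common)
    truth_bpc = float((truth_cat == "bpc").sum() / n)
    est_bpc = float((rec.category == "bpc").sum() / n)
    truth_self = float((truth_cat == "selfing").sum() / n)
    est_self = float((rec.category == "selfing").sum() / n)

    report = {
        "n_seedlings": n,
        "parent_pair_accuracy": pair_acc,
        "category_confusion": confusion,
        "category_accuracy": float((truth_cat == rec.category).mean()),
        "bpc_truth": truth_bpc,
        "bpc_estimated": est_bpc,
        "bpc_abs_error": abs(est_bpc - truth_bpc),
        "selfing_truth": truth_self,
        "selfing_estimated": est_self,
        "selfing_abs_error": abs(est_self - truth_self),
    }
    if contributions_table is not None:
        tt = contributions(truth_records(pedigree))
        report["n_ep_truth"] = n_ep(tt)
        report["n_ep_estimated"] = n_ep(contributions_table)
        report["n_ep_abs_error"] = abs(report["n_ep_estimated"] - report["n_ep_truth"])
    return report


def permutation_baseline(pedigree: pd.DataFrame, records: pd.DataFrame, seed: int = 0) -> dict:
    """Chance-level reference: score records with seedling ids shuffled."""
    rng = np.random.default_rng(seed)
    shuffled = records.copy()
    shuffled["seedling_id"] = rng.permutation(shuffled["seedling_id"].to_numpy())
    return recovery_report(pedigree, shuffled)
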