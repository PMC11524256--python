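# orchardkin

Parentage, pollen contamination and genetic diversity analysis for conifer
seed-orchard crops, from biallelic SNP genotypes.

Seed orchards are plantations of selected (plus) trees managed to mass-produce
genetically improved seed. Open pollination means a crop's realized genetic
makeup can drift far from the design: external *background pollen
contamination* (BPC) dilutes breeding gain, fecundity differences skew
parental contributions, and a few percent of seed is usually selfed.
`orchardkin` reconstructs all of this from genotypes of the orchard parents
and a sample of seedlings:

- **QC filtering** of VCF or dosage-matrix genotypes (per-genotype DP/GQ
  masking, sample and locus missingness, MAF, excess heterozygosity,
  multi-allelic removal).
- **Pairwise relatedness** with Ritland's method-of-moments estimator on
  0/1/2 genotype scores. For dosages x, y at a locus with reference allele
  frequency p, the per-locus estimate is
  `r_l = 2 (x_A y_A / p + x_a y_a / (1-p) - 1)` with `x_A = x/2`,
  `x_a = 1 - x_A`, averaged over loci typed in both samples. Expectations:
  0 unrelated, 0.25 half-sib, 0.5 parent-offspring, 1.0 parent vs. selfed
  offspring. Genotype-score (Pearson) correlation serves as a
  frequency-free control.
- **Parentage assignment**: data-driven thresholds (Otsu-style two-class
  split of the pairwise distribution) accept up to two parents per seedling;
  elevated single-parent relatedness flags selfing; groups of single-parent
  seedlings related through their unknown father are attributed to
  un-genotyped orchard parents, the rest count as BPC.
- **Mating statistics**: gametic contribution tables, relative reproductive
  success `P_suc`, and the bias-corrected effective number of parents
  `N_ep = (n-1)^2 / [Σ P_suc_i^2 (n+1)(n-2) + 3 - n]`
  over orchard contributors only (`N_ep`) or all unique contributors
  including external donors (`N_ep2`), plus `Var(logit(P_suc))` and
  cross-crop Spearman correlations.
- **Diversity**: breadth-of-coverage-gated observed/expected heterozygosity
  (Nei's unbiased per-locus gene diversity), `F_IS = 1 - H_O / H_E`, with a
  percentile confidence interval from repeated subsampling of `L/60` loci.
- **Realized gain**: expected gain `G` quoted under an assumed BPC `a`
  converts to a contamination-free gain `G0 = G / (1 - a)` and a realized
  gain `G0 (1 - b)` at the observed BPC `b`.
- **A forward orchard simulator** with known pedigree (Dirichlet fecundity
  skew, selfing, Balding-Nichols-diverged background pollen pool,
  un-genotyped fathers, genotype error and missingness) so every stage is
  validated by parameter recovery against ground truth.

## Worked example

Simulate a mid-sized orchard crop (28 parents, 300 seedlings, 2,000 SNPs,
3% selfing, 30% contamination, GBS-like 0.5% allele error and 10%
missingness), then reconstruct its mating structure:

```python
from orchardkin import (OrchardSimConfig, simulate_orchard, concat_samples,
                        classify_crop, contributions, n_ep, contribution_curve,
                        recovery_report, GainSpec, realized_gain)

cfg = OrchardSimConfig(n_parents=28, n_seedlings=300, n_loci=2000,
                       selfing_rate=0.03, bpc_rate=0.30,
                       genotype_error_rate=0.005, missing_rate=0.10, rng_seed=7)
sim = simulate_orchard(cfg)
gm = concat_samples(sim.parents, sim.seedlings)
res = classify_crop(gm, sim.parents.sample_ids, sim.seedlings.sample_ids,
                    sim.orchard_freqs)
table = contributions(res.records)
rep = recovery_report(sim.pedigree, res.records)
gain = realized_gain(GainSpec("sim", 19.0, 0.40, res.bpc_rate))
```

Output for this seed:

```
both parents: 231 (77.0%)
  of which selfed: 10 (3.3%)
BPC: 69 (23.0%)
un-genotyped parent: 0  unassigned: 0
N_ep = 26.1   N_ep2 = 33.9
19 parents (68%) sire 80% of the progeny
truth check: pair accuracy 1.000, BPC error 0.000, selfing error 0.000
realized gain at observed BPC: 24.4% (expected 19% at 40% BPC)
```

Reading: of 300 seedlings, 231 were assigned both parents (including 10
selfed), and 69 carried pollen from outside the orchard — a 23.0% measured
contamination rate, matching the simulation's realized truth exactly.
Skewed fecundity reduces the effective number of parents from the census 28
to 26.1; counting each unique external donor raises it to 33.9. Because
this crop is *less* contaminated than the 40% its expected gain assumed,
the realized gain (24.4%) exceeds the quoted 19%.

The same pipeline runs from the shell on real data:

```bash
orchardkin filter --vcf crop.vcf --manifest manifest.tsv --out gm.tsv --report filters.json
orchardkin assign --genotypes gm.tsv --manifest manifest.tsv --out-dir run1/
orchardkin summarize --assignments run1/assignments.tsv --out-dir run1/
orchardkin diversity --genotypes gm.tsv --manifest manifest.tsv --seed 1 --out diversity.tsv
orchardkin gain --specs gains.json --summaries run1/crop_summary.tsv --out gain.tsv
```

or end-to-end with `orchardkin run --config run.json`. The manifest is a
TSV of `sample_id`, `role` (parent / seedling / rootstock / reference) and
`crop_label`.

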