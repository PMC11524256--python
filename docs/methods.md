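# Methods

## Scope and data model

The package analyses one or more open-pollinated seed-orchard crops from
biallelic SNP genotypes coded as alternate-allele dosages 0/1/2 with an
explicit missing sentinel. Samples carry a role (`parent`, `seedling`,
`rootstock`, `reference`) and a crop label. All estimators are single-locus
moment methods averaged over loci, so linkage between markers is ignored
throughout.

## Quality control

Filtering happens in a fixed order so that per-rule removal counts are
well defined:

1. **Genotype masking** — calls with read depth < 5 or genotype quality
   < 20 become missing (strict inequalities; a depth-5/GQ-20 call is kept).
2. **Sample removal** — samples with *more than* 40% missing calls are
   dropped (a sample at exactly 40% is kept).
3. **Locus removal** — computed on the surviving samples: MAF < 0.05,
   missing fraction > 40%, heterozygote fraction among non-missing calls
   > 70% (a paralog-collapse signature), or more than two alleles.

Alignment-level masks (mapping quality, indel proximity, repeats) are
assumed already applied in the input VCF by the upstream variant caller.
Heterozygosity and MAF share the same denominator — non-missing calls at
the locus. All thresholds are fields of `FilterConfig`.

## Relatedness

For a pair of dosage vectors x, y and reference allele frequencies p, the
biallelic Ritland method-of-moments estimate is the unweighted mean over
shared loci of

    r_l = 2 ( x_A y_A / p_l  +  x_a y_a / (1 - p_l)  -  1 ),

where `x_A = x_l / 2` and `x_a = 1 - x_A`. With two alleles per locus every
locus carries the same weight (n_alleles - 1 = 1). Loci that are missing in
either sample, or fixed (p of 0 or 1) or uncalled in the frequency panel,
are excluded; pairs sharing fewer than `min_overlap` (default 100)
informative loci are flagged unreliable and never enter assignment.

Exhaustive single-locus enumeration over Hardy-Weinberg parental genotypes
and Mendelian gamete transmissions (reproduced in the test suite as an
independent oracle) gives E[r] = 0 for unrelated pairs, 0.25 for half-sibs,
0.5 for parent-offspring and 1.0 between a parent and its selfed offspring,
independent of p. Genotyping error biases all of these toward zero, which
is why assignment thresholds are inferred from the data rather than fixed
at the theoretical values.

The frequency panel defaults to reference-stand samples when the manifest
contains any, else to all loaded samples; the choice is recorded in run
provenance. Pearson correlation of raw genotype scores over shared loci is
computed alongside as a frequency-free control; it is undefined (flagged)
when either vector is constant on the shared set.

Pairwise grids are evaluated with blocked masked matrix products (three
GEMMs for the Ritland terms, five for the correlation sums), keeping a
500 x 500-sample grid at 5,000 loci within seconds on one CPU.

## Parentage assignment

Candidate parents for a seedling are all genotyped orchard parents and
rootstock. Acceptance requires both `ritland_r >= r_po` and
`score_corr >= c_po`; at most two candidates are retained, ranked by
relatedness (ties at the 2/3 boundary broken by score correlation, then by
parent id, and logged). A single accepted candidate with
`ritland_r >= r_self` is recorded as a selfing (same parent twice) —
matching the doubled expectation for a parent and its selfed offspring —
rather than requiring a separate two-gamete consistency test, since the
relatedness statistic is what the pipeline actually measures.

**Threshold inference.** The Ritland values of all reliable
seedling x candidate-parent pairs form a mixture of an unrelated mode near
0 and a parent-offspring mode near 0.5 (shifted down under noise). A
two-class split maximizing between-class variance (Otsu's criterion on the
sorted values) locates the boundary, and the threshold is placed mid-gap
between the two classes. The score-correlation threshold is derived the
same way. Derived thresholds scale with the empirical parent-offspring
center `m`: `r_self = (m + min(2m, 1))/2`, the unknown-father sharing
thresholds are `m/4` (half-sib level, mothers differ) and `3m/4` (full-sib
level, same mother). If the distribution has no usable second mode (e.g.
no candidate parents genotyped) the configured defaults are returned with a
prominent warning. Every threshold is overridable and echoed into the run
report; automatic inference is a reproducible stand-in for manual
per-dataset tuning.

**Unknown-donor resolution.** Seedlings with exactly one accepted parent
were sired by pollen from outside the genotyped candidate set. A graph
over these seedlings links pairs whose relatedness reaches the half-sib
threshold when their known mothers differ (paternal half-sibs) or the
full-sib threshold when the mothers coincide. Connected components with at
least `min_group` members (default 3) are attributed to a single
un-genotyped orchard parent — lost clones, rootstock or supplemental
plantings — and excluded from contamination; smaller components are
background pollen contamination (BPC), with linked pairs sharing one donor
id so a reused external donor is counted once in `N_ep2`. A pair could be
a reused external donor, hence the default minimum group of three.
Component ids are canonicalized from sorted member lists, so input order
cannot change any grouping.

Category rates use all genotyped seedlings in the crop as denominator.
Selfing is reported separately and nested inside the both-parents total;
`bpc` and `ungenotyped_parent` are reported separately plus as a combined
single-parent rate, so either convention for "contamination" is
recoverable.

## Contributions and effective numbers of parents

Each seedling carries two gametes: one to each assigned parent
(both-parents), two to the parent (selfing), or one to the known parent and
one to the unknown-donor group (single-parent). Unassigned seedlings
contribute nothing. `P_suc` is a contributor's share of counted gametes.

The effective number of parents uses the sampling-bias-corrected effective
number of types,

    N_ep = (n - 1)^2 / [ Σ_i P_suc_i^2 (n + 1)(n - 2) + 3 - n ],

with `n` the number of seedlings sampled (not gametes). `N_ep` is computed
over orchard and rootstock contributors with `P_suc` renormalized over that
subset; `N_ep2` over all unique contributors, each donor group counted
once. A single contributor gives exactly 1 by algebraic identity. Near
uniform contributions the corrected estimate can slightly exceed the census
number of parents; this is a property of the bias correction and is
regression-tested rather than "fixed". `Var(logit(P_suc))` is the sample
variance of `ln(P/(1-P))` over orchard contributors, excluding (and
counting) contributors at exactly 0 or 1 where the logit is undefined.

Cross-crop Spearman correlations are computed with mid-ranked ties and
t-approximation p-values; below 8 crops an exhaustive permutation p-value
is substituted (n! permutations are cheap there and the t-approximation is
poor).

## Diversity

Per locus, `H_O` is the heterozygote fraction among non-missing calls and
`H_E` is Nei's unbiased gene diversity `2 p̂ (1 - p̂) · 2n/(2n - 1)` with n
the non-missing sample count (a single heterozygous individual gives the
degenerate value 1.0, flagged at the boundary). `F_IS = 1 - H_O/H_E` uses
the ratio of locus means, not the mean of per-locus ratios, and the same
functional is applied at the resample level: each of `reps` replicates
(default 100,000) draws `⌈L/60⌉` loci without replacement and the 95% CI is
the 2.5th/97.5th percentile of replicate values. Repeated random
subsampling is used in place of a formal delete-d jackknife; at d = L -
L/60 and 10^5 replicates the two are indistinguishable in practice. The
point estimate is not forced inside the percentile interval, but low ≤ high
always holds. Standard errors on `H_O`/`H_E` are over loci (SD/√L) and are
labeled as such.

Because low breadth of coverage biases `H_O` downward, groups are gated to
samples covering ≥ 80% of the locus panel (inclusive) before any diversity
computation; the gated-out count is reported.

## Realized gain under contamination

Deployment expectations quote a gain `G` under an assumed contamination
`a`. Treating contaminating pollen as carrying zero breeding gain, gain is
proportional to the non-contaminating fraction: `G0 = G/(1 - a)` and the
realized gain at observed contamination `b` is `G0 (1 - b)`. The linear
`(1 - b)` factor reproduces the published reference values exactly; a
`(1 - b/2)` variant — contaminated seeds keep the maternal half of the
gain — is exposed via `half_genome=True` but is not the default, since the
question of whether a contaminated seed carries zero or half gain is a
biological reading the data here cannot settle. Rounding to one decimal
happens only at presentation; internal values keep full precision.

## Simulator

The generator emulates the study design the analysis targets: tens to
hundreds of clonal parents, 137-431 sampled seedlings, ~5,000 biallelic
SNPs with MAF ≥ 0.05, selfing of a few percent, BPC anywhere from a few
percent to most of the crop, skewed parental contributions, optional
un-genotyped fathers, and GBS-like noise. Defaults (28-204 parents scaled
to 50, 300 seedlings, 5,000 loci, selfing 0.03, BPC 0.30, error 0.005,
missingness 0.10) sit mid-range of those conditions.

- Orchard-pool frequencies are uniform on `maf_range`; parents are drawn
  under Hardy-Weinberg and are unrelated by construction (matching the
  absence of parental relatedness the analysis assumes).
- The background pollen pool diverges by a Balding-Nichols Beta draw with
  mean p and variance `Fst · p(1-p)` (default Fst 0.05, a mild
  provenance-level shift); Fst = 0 reproduces the orchard pool exactly.
- Fecundity skew is a symmetric Dirichlet over parents. The default
  concentration 1.4 was calibrated once so that roughly half of the parents
  sire 80% of the progeny, the contribution concentration typical of these
  orchards; it is a stand-in, as no quantitative fecundity model is
  available.
- Mother drawn from female weights over genotyped parents (cones are
  harvested from known trees); father = mother with probability
  `selfing_rate`, an external donor with probability `bpc_rate` (fresh
  genotype from the background pool, or reuse of an existing donor with
  probability `external_donor_reuse`), else an orchard male — genotyped or
  un-genotyped — drawn from male weights with the mother excluded, so
  selfing occurs only through the explicit branch and the pedigree
  invariant `father_class = self ⟺ father_id = mother_id` holds.
  Un-genotyped parents sire but never mother seedlings (they model lost or
  thinned clones and rootstock pollen).
- The seedling genotype is one Mendelian gamete from each parent; noise is
  an independent symmetric per-allele flip (producing both false
  heterozygotes and false homozygotes) followed by per-genotype
  missingness. Truth is recorded before noise. External donors used more
  than once are classed `external_shared`, otherwise `external_unique`.

A single `rng_seed` fans out to per-stage child streams via
`numpy.random.SeedSequence`, so identical configs give bit-identical
output.

**What passing recovery tests do and do not show.** The simulator's loci
are independent and in Hardy-Weinberg proportions, its parents are exactly
unrelated, its error model is symmetric, and the true allele frequencies
are available to the estimators. Perfect or near-perfect recovery under
these conditions validates the estimator algebra, the threshold logic and
the bookkeeping — not robustness to linked loci, related or structured
parental populations, asymmetric error, null alleles, or frequency panels
estimated from small reference samples. Those effects must be judged on
real data.

## Numerical choices and problem sizes

- Missing dosage sentinel is -1 (int8); TSV dialect uses `NA`.
- Otsu splitting needs ≥ 4 finite values and a class separation of ≥ 0.15
  to accept a bimodal reading; otherwise defaults are used with a warning.
- The 80%-contribution count uses a 1e-9 tolerance against accumulated
  floating-point in the cumulative sum.
- Test and validation runs use 2,000 loci and 200-300 seedlings — enough
  that parent-offspring relatedness (SE ≈ 0.01 across loci) separates
  cleanly from unrelated pairs — with the subsample CI at 10,000 replicates
  rather than the 100,000 default.

## Known limitations

- Likelihood-based parentage (CERVUS/COLONY-style) and other relatedness
  estimators (Lynch-Ritland, Wang, KING) are out of scope; the
  method-of-moments estimator with data-driven thresholds is the design.
- No imputation; missing genotypes only ever shrink the shared-locus count.
- Sibship structure beyond unknown-father grouping is not reconstructed.
- Multi-allelic sites are removed, not modeled.
- The automatic threshold procedure assumes a visible gap between the
  unrelated and parent-offspring modes; with very high error rates or very
  few loci it will fall back to defaults and should be overridden manually.
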