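# Methods

## Setting and notation

Two genotyping platforms call the same biallelic SNPs on the same
samples: a *sequence* platform (direct next-generation sequencing or
imputation to a sequence panel) and a SNP *microarray*. At each variant
the calls are coded against that variant's (major, minor) allele pair:
`AA` = major-allele homozygote, `AB` = heterozygote, `BB` = minor-allele
homozygote, `XX` = missing. By convention the major allele is written A
and the minor allele B, so a call pair *i–j* means the sequence platform
called *i* and the microarray called *j*. Neither platform is treated as
a gold standard: all statistics are symmetric descriptions of agreement,
and conditional rates are read as conservative estimates of the
platforms' error rates (conservative because independent errors almost
always surface as discordance, while correlated errors can cancel).

## Harmonization

Variants are matched across the two call sets by rs identifier alone;
chromosome/position disagreement at a matched rs id is logged as a
warning but is not an exclusion. Samples present in only one call set
are dropped with a logged count. Each matched variant's allele pairs are
then classified:

* **identical** — same (major, minor) pair;
* **swapped** — same alleles, roles exchanged; the second matrix is
  re-oriented by relabelling `AA`↔`BB` and swapping its allele metadata
  (an involution: applying it twice restores the input);
* **strand_flip / strand_flip_swapped** — Watson–Crick complement of
  the first pair (optionally also swapped); rescued only when
  `allow_strand_flip` is on, by complementing allele metadata (calls are
  unchanged);
* **ambiguous_palindromic** — A/T and C/G sites under
  `allow_strand_flip`, where a flip is indistinguishable from a swap;
  excluded by default;
* **mismatch** — anything else; excluded.

The default policy is `allow_strand_flip = off`, so *any* allele-pair
difference is an exclusion. This is the stricter choice and matches how
dual-platform QC is usually run first; strand-flip rescue is opt-in
because a complement relation is only a hypothesis about the cause of
the disagreement. The accounting invariant `matched = retained +
excluded` is enforced by the `HarmonizedPair` constructor, and
harmonization is idempotent.

For formats that do not carry allele roles (PLINK text), the major
allele is the more frequent allele among called genotypes in that file,
ties broken alphabetically — deterministic and file-local. For VCF, REF
maps to the major slot and ALT to the minor slot (the reference-allele
orientation customary for sequencing pipelines); if a cohort's ALT is in
fact the more frequent allele this shows up, correctly, as a `swapped`
relation against the partner file rather than as an error.

## Cross-classification and discordance proportions

Pooling over SNPs and samples gives a 4×4 table N with
N[i, j] = #{(variant, sample) : seq = i, micro = j}; the grand total is
(number of SNPs) × (number of samples) because every pair lands in
exactly one cell. Two overall proportions are reported, both with the
grand total as denominator:

* **called-only discordance** — the six off-diagonal cells among
  {AA, AB, BB}²;
* **discordance including missing** — those six cells plus all pairs
  where exactly one platform is missing. `XX–XX` pairs count as
  concordant-missing; this choice is configurable in effect (the
  one-sided-missing count is exposed separately) and does not move the
  headline figure at its printed precision.

The grand-total denominator is used for both proportions because it is
the convention under which the published pooled table of the GAW18
dual-platform study (shipped in `gtconcord.datasets`) reproduces its
printed percentages exactly (0.23% called, 2.63% including missing); a
called-pairs-only denominator would give 0.24%.

## Conditional concordance rates

Per SNP s and microarray call j with positive column count,
P̂(seq = i | micro = j) = N_s[i, j] / Σ_i N_s[i, j]. Columns with zero
denominator are flagged invalid and excluded from downstream averages
rather than erroring. Across-SNP summaries are unweighted (each SNP
counts once), with the mean, the across-SNP standard deviation, the
standard error of the mean, and the per-cell SNP count all reported; a
count-weighted (pooled) alternative is available by flag since either
convention is defensible and they differ when column denominators vary
strongly across SNPs. The SD and SE are reported side by side and
labelled explicitly because a single parenthetical "(SE)" is ambiguous
between them at typical panel sizes.

MAF stratification assigns each SNP to a half-open bin [lo, hi) (last
bin closed at 0.5) by the minor-allele frequency of the chosen source
platform's called genotypes (microarray by default, since its calls are
near-complete); default edges 0.05, 0.1, 0.2, 0.3, 0.4, 0.5 cover the
common-variant range a dual-platform panel shares. Monomorphic SNPs
(MAF 0) fall in the lowest bin; SNPs whose source calls are all missing
are left unbinned and reported.

## Phenotype strata and differential tests

Strata are derived from raw records and recomputed at construction so
they can never go stale: *hypertensive* = systolic > 140 mm Hg or
diastolic > 90 mm Hg at any of up to four exams (strict inequalities;
exactly 140/90 is not hypertensive); *smoker* = self-report positive at
any of up to four waves; both `unknown` when no usable record exists,
and unknowns are excluded from comparisons. The technology stratifier
splits samples by sequence source (directly sequenced vs imputed).

For each of the 16 cells, the per-SNP rates of the two strata are
compared with an unpaired two-sample Welch (unequal-variance) t-test
across SNPs. SNPs lacking a valid conditioning denominator in either
group are dropped from that cell's test (complete case per cell). A
paired-per-SNP variant is available by flag for the technology
comparison, where the two rates at the same SNP are natural pairs.
Welch is the default because the group variances genuinely differ (the
groups have different sizes, hence different denominators). Cells where
either group has fewer than two usable SNPs, or where both rate vectors
are constant and unequal-meaned, are reported as undefined; two constant
identical vectors give t = 0, p = 1. No multiple-testing correction is
applied across cells (raw p-values are the convention for this QC
table), but a Bonferroni column is emitted. p-values below ~2.2e-16 are
floored at the smallest positive double for numeric output and printed
as "< 2.2e-16".

The tests treat SNPs as independent observations; linkage
disequilibrium and pedigree structure are ignored, so the p-values are
descriptive QC statistics, not family-aware inference.

## Dosage resolution

Discordant called pairs are resolved by 50-50 weighting: the resolved
genotype is the mean of the two calls' minor-allele dosages
(AA = 0, AB = 1, BB = 2), giving 0.5 for major-homozygote/heterozygote
pairs and 1.5 for heterozygote/minor-homozygote pairs. The rule is
symmetric in the platforms and every value lies in {0, 0.5, 1, 1.5, 2}.
Two extensions beyond the adjacent-class cases are package choices,
marked in the per-cell provenance codes: opposite-homozygote pairs
(AA vs BB) resolve to 1.0 by the same mean rule, and one-missing pairs
take the available call's dosage rather than propagating missingness
(maximising retained information); only double-missing cells stay
missing.

## Synthetic-data generator

Truth genotypes are i.i.d. Hardy–Weinberg draws per SNP: with
minor-allele frequency q, P(AA, AB, BB) = ((1−q)², 2q(1−q), q²). Each
platform then observes the *same* truth through a 3×3 row-stochastic
confusion matrix over called genotypes, followed by independent masking
to `XX` at a platform missing rate. Optional mechanisms: a MAF-dependent
multiplier on the off-diagonal error mass (diagonal re-normalised; the
generator rejects multipliers that push row mass past 1), and
phenotype-differential errors via separate confusion matrices per binary
phenotype group. Because the truth is shared, every conditional rate has
a closed-form expectation in the configured matrices, which is what the
parameter-recovery and null-calibration tests exploit.

Default dimensions follow the dual-platform study the pipeline is
modelled on: 959 samples with a 464/495 directly-sequenced/imputed
split, MAF uniform on [0.05, 0.5] (the common-variant range a microarray
panel shares with sequencing), sequence-platform missingness 2.4% versus
0.02% for the microarray, adjacent-class-dominated confusion matrices
giving roughly 0.2% called discordance, hypertension prevalence 0.30 and
smoking prevalence 0.25 (typical adult-cohort values). Phenotype raw
records are generated so the derivation rules round-trip exactly:
hypertensive samples get one exam drawn above 141 mm Hg systolic, others
stay at or below 138/88; smoker waves analogously. MAF boundary q = 0 is
allowed for testing (all-AA truth) even though the dual-platform setting
itself starts at 0.05.

What the generator deliberately omits — linkage disequilibrium, pedigree
transmission, imputation-specific error correlation across SNPs, read
depth — means passing tests certify the *statistics* (counting,
conditioning, testing, resolution) rather than realism of real-data
error processes; on real data the t-tests' independence assumption is an
approximation, as noted above.

Reproducibility: a single integer seed; each purpose (variant metadata,
MAFs, truth, sequence errors, microarray errors, phenotypes) draws from
`numpy.random.default_rng([seed, stream_id])` with a fixed per-purpose
stream id, so any one piece regenerates identically regardless of call
order, and full reruns are byte-identical.

## Verification problem sizes

The suite verifies each stage at the smallest size that makes the check
meaningful: exhaustive brute-force recounts on ≤5×5 fixtures; binomial
Monte-Carlo bounds at 3 standard errors for rate recovery (10⁵ call
pairs: 100 SNPs × 1000 samples); null calibration of the group Welch
test over 1000 replicates of 40 SNPs × 80 samples with a
diagonal-0.9-ish confusion matrix (large enough error rates that the
per-SNP rates are not degenerate at 1), checking the empirical size
against 0.05 ± 0.02 and approximate uniformity of the p-values; and the
published pooled table for the exact headline proportions.

## Known limitations

* Biallelic SNPs only; multiallelic records and indels are excluded at
  read time, and there is no liftover between genome builds.
* rs-id matching will mismatch variants if the two files use different
  annotation releases with re-assigned ids; the position-disagreement
  warning is the only guard.
* Group tests require exactly two non-empty strata; multi-level
  stratifiers (e.g. a three-way source split) are out of scope.
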