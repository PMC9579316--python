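# Methods

This note documents the statistical models, thresholds and design choices
behind `mhkit`, and what its synthetic-data tests do and do not establish
about real sequencing data.

## Genotype calling model

A microhaplotype locus is defined by 2–6 SNP positions inside an amplicon
of at most 300 bp. The caller operates on fragments: the reads sharing a
query name (a 2 × 150 bp pair on a ≤ 300 bp amplicon usually overlap in
the middle). For each SNP position the fragment's best base is taken;
where mates disagree, the higher-quality base wins. A fragment
contributes one haplotype string — one symbol per SNP, in genomic order —
only if it covers **all** SNP positions with base quality ≥ `min_base_quality`
(default Q20); otherwise it is counted as discarded. Partial haplotypes
are never imputed: requiring full-fragment coverage trades a small amount
of depth for unambiguous phase. A deletion spanning a SNP maps to the
`-` symbol; soft-clipped bases do not cover a position (amplicon reads
are expected to be full length, so no realignment is attempted).

Haplotype counts reduce to a diploid call with four thresholds
(`CallerThresholds`):

| parameter | default | meaning |
|---|---|---|
| `min_doc` | 30 reads | minimum locus (or, in mixture mode, per-allele) depth of coverage |
| `min_balance` | 0.15 | minimum heterozygote allele balance, minor/major depth |
| `noise_fraction` | 0.02 | haplotypes below this fraction of locus depth are artifacts |
| `min_base_quality` | 20 (Phred) | minimum base quality at a SNP position |

The 30× and 0.15 values are the conventional analytical thresholds for
forensic amplicon sequencing on desktop MPS instruments; the noise
fraction is standard MPS analytical practice and is exposed in
configuration because no single community value exists. Order of
operations: noise filter → depth check (LOW_DOC below 30×) → allele-count
check (> 2 above-noise haplotypes flags EXCESS_ALLELES, a possible
mixture) → balance check. A two-haplotype call below the balance
threshold **demotes the minor allele** and reports a flagged homozygote
(IMBALANCED) rather than silently calling a heterozygote — the flag keeps
the decision auditable. The balance comparison is `>=` on the ratio, so a
balance of exactly 0.15 passes.

In mixture mode (`call_mixture_alleles`) the diploid cap is removed:
every above-noise haplotype with per-allele depth ≥ 30× is reported as
detected, and above-noise haplotypes below 30× are reported separately as
sub-threshold, so detected + sub-threshold + noise depths always sum to
the extracted total.

## Forensic parameters

With allele frequencies `p_i` estimated by gene counting over QC-passing
calls (a locus with no-calls uses its reduced sample size):

* **Ae** = 1/Σpᵢ² — the number of equifrequent alleles giving the same
  homozygosity; 1 iff monomorphic.
* **He** is *observed* heterozygosity (fraction of heterozygous
  individuals), not the HWE expectation; the expectation 1 − Σpᵢ² is
  exposed separately as `he_exp`. This matters because the reported
  TPI = 1/(2(1 − He)) is defined on observed He and is computed from the
  full-precision count ratio, never from a rounded display value
  (80/92 → 3.8333, whereas the rounded 0.8696 would give 3.8344).
* **MP** = Σgⱼ² over *observed* genotype-class frequencies (the
  with-replacement probability that two sampled individuals match), and
  **PD** = 1 − MP. An HWE-expected variant is available as an option.
* **PED/PET** use the classic allele-frequency exclusion formulas
  (Garber–Morris): with Sₖ = Σpᵏ,
  PED = 1 − 4S₂ + 4S₃ − 3S₄ + 2S₂²,
  PET = 1 − 2S₂ + S₃ + 2S₄ − 3S₅ − 2S₂² + 3S₂S₃.
  Both are validated in the test suite against brute-force enumeration of
  all mother/child/random-man genotype combinations under HWE (agreement
  to 1e-12 for up to 4 alleles).
* **Combined powers**: CPD = 1 − ΠMPᵢ, CPED = 1 − Π(1 − PEDᵢ),
  CPET = 1 − Π(1 − PETᵢ). Complements are accumulated as sums of log₁₀
  and reported as mantissa × 10^exponent, so a 48-locus complement near
  10⁻⁴⁴ is represented exactly rather than underflowing.

### Hardy–Weinberg exact test

A Monte-Carlo exact test in the Guo–Thompson tradition: the 2n observed
gene copies are permuted into n random diploids `n_perm` times (default
10,000), and the conditional probability of each permuted genotype
configuration given the allele counts is compared with the observed one.
The p-value is `(1 + #{perm ≤ obs}) / (1 + n_perm)` (add-one correction;
ties count at a 1e-9 log-tolerance). Monomorphic loci return p = 1 by
convention. Permutations are vectorized (argsort of a uniform matrix),
making a 1,000-replicate null calibration run in ~2 s. Under simulated
HWE the test's type-I error at α = 0.05 and p-value uniformity are
verified in the acceptance suite. Multiple testing across a panel is
handled by Bonferroni (α' = 0.05 / number of loci).

### Linkage disequilibrium

Two-locus haplotype frequencies are estimated from unphased diploid MH
genotypes by EM (initialization at linkage equilibrium, tolerance 1e-9 on
the log-likelihood, 1,000 iterations maximum, non-convergence flagged
with the last iterate). The reported statistic is the normalized
multi-allelic association r² = ΣᵢⱼDᵢⱼ² / ((1 − Σpᵢ²)(1 − Σqⱼ²)) with
Dᵢⱼ = hᵢⱼ − pᵢqⱼ, which reduces to the classic r² for biallelic loci.
The panel-pruning screen treats r² ≥ 0.8 between same-chromosome loci as
disqualifying. Only individuals callable at both loci enter the
estimate (≥ 10 required).

## Ancestry statistics

**Informativeness** (Rosenberg's In, natural log): per locus,
In = Σⱼ[−p̄ⱼ ln p̄ⱼ + (1/K)Σᵢ pᵢⱼ ln pᵢⱼ] with p̄ⱼ the unweighted mean
frequency across the K populations and 0·ln 0 ≡ 0. In = 0 iff all
populations share a frequency vector and In = ln K when K populations are
fixed for distinct alleles; markers with In > 0.185 are conventionally
considered useful for ancestry inference. Whether to compute In on whole
MH alleles or component SNPs is a genuine choice; `mhkit` uses whole MH
alleles, consistent with treating the MH as the marker. A converter
builds MH genotypes from externally phased SNP tables by concatenating
phased alleles per haplotype.

**Fst** is Nei's Gst computed pairwise: per locus
Gst = (Ht − Hs)/Ht with Hs the mean within-pair expected heterozygosity
and Ht that of the mean frequencies; per-locus negatives are truncated at
0 and loci monomorphic in the pooled pair are skipped before averaging
over loci. Gst was chosen over Weir–Cockerham because the input is
frequency tables (possibly without genotype-level data); it is the
estimator family used by frequency-driven population-tree software.

**Neighbor joining** (Saitou–Nei) over the Fst matrix is delegated to
scikit-bio with negative branch lengths clamped to zero; the output is an
unrooted Newick tree. Exactness on additive matrices is verified against
regenerated tip-to-tip distances.

## Mixtures

Contributor weights are interpreted as DNA mass fractions; with
normalized weights w_c the expected read fraction of allele a is
Σ_c w_c · dosage_c(a)/2. Read counts are a multinomial draw over these
fractions followed by an independent per-read per-SNP substitution error
channel. Scoring partitions the union of contributor alleles at each
locus into the **major contributor's alleles** and **minor-unique
alleles** (carried by at least one minor contributor and absent from the
major); an allele shared between the major and a minor counts toward the
major only, so the two sets always partition the union. Detection rates
are percentages rounded half-up to 2 decimals. The default simulated
locus depth draws around 2,301× (Gamma–Poisson with configurable
dispersion), matching a typical targeted-panel mean coverage, and the
detection threshold applied to mixture alleles is the absolute 30× DoC.
Real per-locus depths in published mixture experiments are not available,
so printed detection-rate tables are reproduced as arithmetic worked
examples, not as stochastic endpoints.

## Kinship

Per-locus duo LR: numerator P(child | AF is father) sums over the alleged
father's transmitted allele (½ each) with the maternal allele drawn from
the population; denominator is the child's HWE genotype probability.
Trio LRs condition on the mother analogously. **No mutation model**: a
genotype incompatibility gives LR = 0, and a true-father cohort therefore
never excludes. This is deliberate and prominently flagged — with a
mutation model the H2 point mass at LR = 0 would smear into finite values.
The simulation design: H1 pairs draw the father from HWE and build the
child from one paternal and one population allele; H2 keeps the child a
true child of an unknown father and draws the alleged father
independently — so the child's marginal distribution is identical under
both hypotheses and only the AF–child relationship differs. H2 exclusions
are kept as a −∞ point mass, not dropped; "no overlap" between cohorts is
judged with exclusions included. E[LR | H2] = 1 per locus (the classic
expectation identity) is verified by Monte Carlo in the test suite.

## Synthetic-data generator

The generator emulates a targeted MH study: 163 loci spread over
chromosomes 1–22 (2–6 SNPs each, amplicons ≤ 300 bp), 92 diploid
individuals, 2 × 150 bp proper read pairs at a mean locus depth of
2,301× with Gamma–Poisson dispersion, and a per-base substitution error
channel. Haplotype frequencies are Dirichlet-drawn with a **total**
concentration (default 1.6) split across the locus's haplotype space and
truncated at 1% — this keeps the effective allele count roughly
independent of the number of SNPs and calibrates the default panel to a
mean Ae between 2 and 3, the range typical of published MH panels;
rejection sampling (`ae_range=(3, 7)`) builds high-polymorphism
identification subpanels. Population divergence follows Balding–Nichols:
population frequencies are Dirichlet(p·(1 − F)/F) around the base vector,
so the drift parameter approximates the expected Fst and F = 0 yields
identical populations. Reads are emitted pre-aligned at truth positions
(sorted SAM, simple `M` CIGARs) so the toolkit never shells out to an
aligner; a paired FASTQ mirror supports external-aligner workflows.

What passing tests show — and don't. On error-free synthetic reads the
caller is exact by construction (100% concordance is a correctness check,
not a sequencing claim), and at error rate 10⁻³ and 2,000× the truth
haplotypes dominate the counts. The generator does **not** simulate PCR
stutter (absent for MHs by design), chimeric reads, primer artifacts,
index hopping, InDel sequencing errors (the error channel is
substitution-only) or strand bias; performance on real instrument data
therefore depends on upstream QC that these tests do not exercise.

## Problem sizes used in the test suite

The suite favors many small, seeded scenarios: end-to-end caller
concordance runs 12 samples × 20 loci at 60× in duplicate (byte-identical
repeat check); HWE calibration uses 1,000 null replicates of 60
individuals at 1,000 permutations each; kinship separation simulates
10,000 pair cohorts on a 48-locus Ae ∈ [3, 7] panel; LD and Fst
properties use n = 200–500. These sizes were chosen to make every
stochastic check stable under its fixed seed while keeping the default
test run fast.

## Numerical choices

* Combined-power complements, never the powers themselves, are carried in
  log₁₀ (the powers are all ≈ 1 and would lose the informative digits).
* Haplotype ties in calling are broken deterministically
  (depth-descending, then lexicographic), making repeat runs
  byte-identical.
* He = 1 makes TPI unbounded; it is returned as +inf with a warning
  rather than raising.
* Monte-Carlo p-values use the add-one (never-zero) estimator.
* Panel coordinates are 1-based inclusive on disk (the variant-file
  convention) and 0-based half-open in memory; BED export is 0-based.
* MH locus names are validated as `MH` + chromosome 01–22 + uppercase lab
  code + ≥ 1 serial digit (serial lengths vary across published labs).

## Known limitations

* No probabilistic-genotyping mixture interpretation (likelihood-ratio
  deconvolution) and no number-of-contributors estimation — scoring
  assumes truth profiles are known, as in designed mixture experiments.
* No mutation model, θ/Fst correction, or extended pedigrees in kinship.
* The caller requires full-fragment SNP coverage; loci whose amplicon
  cannot be covered by the configured read geometry yield no calls rather
  than partial haplotypes.
* Frequency tables must cover every allele appearing in a kinship case;
  unseen alleles raise instead of being assigned a minimum frequency.
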