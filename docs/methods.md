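# Methods

`foundercnv` reimplements, as a tested library, the analysis chain used to
characterise recurrent copy-number variants (rCNVs) in founder populations:
dual-caller consensus calling, recurrence detection by shared breakpoints,
identity-by-descent confirmation through flanking-haplotype sharing,
coalescence dating from shared-segment genetic lengths, and carrier
association / burden statistics. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Coordinates and units

All file coordinates are 1-based inclusive; an interval `[start, end]` has
`size = end − start + 1` bp. Genetic distances are carried internally in
Morgans because the age estimator's rate parameter is per Morgan;
centiMorgans appear only in file formats and display. Genetic maps are
piecewise linear in cumulative cM over anchor positions; queries beyond the
anchored range extrapolate with the terminal anchor's local rate (cM/Mb), so
a single-anchor map degenerates to a constant-rate map.

## Consensus calling and retention

A CNV call is retained only when two independent callers report it for the
same sample, chromosome, and copy-number direction. "Detected by both" is
operationalised as reciprocal overlap ≥ 0.5 (neither source states an
overlap rule beyond joint detection; 50% reciprocal overlap is the common
convention for array CNVs). The consensus interval is the *intersection* of
the two calls and its probe count the smaller of the two — both conservative
choices, deliberately so because downstream recurrence detection clusters on
exact breakpoints and the retention filter thresholds probe counts. Union
intervals are available as an option. Pairing is greedy by descending
overlap with deterministic tie-breaks, each input call used at most once;
the operation is symmetric in its two arguments.

Retention then requires ≥ 10 probes, ≥ 10 kb, and an autosomal location.
The filters commute with the consensus step when both callers' calls pass
them individually (tested). A call failing several rules increments each
rule's rejection counter.

## Recurrence by breakpoints

On one genotyping array, carriers of the same ancestral CNV are called with
probe-identical boundaries, so within-population recurrence clusters
same-state calls whose start and end boundaries each agree within
`bp_tolerance`, default **0 bp** (exact probe-boundary match). The tolerance
exists for noisier callers; clustering is single-linkage, deterministic, and
permutation-invariant (canonical sort, modal boundaries, smallest-coordinate
tie-breaks). Across populations typed on *different* arrays the probe grids
differ, so the same ancestral event is matched one-to-one by reciprocal
interval overlap, default 0.8.

Carrier frequency is carriers / individuals (the convention of carrier-count
tables; reports also emit a 2-decimal *truncated* column because published
tables sometimes truncate rather than round). Allele frequency is
carriers / 2N under an all-heterozygote assumption, counting two chromosomes
for carriers whose copy number indicates homozygosity (0 or 4).

Breakpoint clustering is only the candidate stage: confirmation that a
cluster is identical-by-descent comes from the haplotype analysis below.

## Flanking-haplotype sharing

For each candidate rCNV, the nearest 60 SNPs upstream and 60 downstream
(outside the CNV interval) are taken from phased haplotypes. The putative
ancestral background is the per-SNP modal allele among carrier haplotypes
(exact ties resolve to the lexicographically first carrier haplotype id, so
the consensus is deterministic). Each carrier haplotype is then walked
outward from each CNV boundary:

* a matching SNP extends the segment;
* a mismatching SNP is **rescued** — treated as a point mutation or
  genotyping error — when the next `rescue_k = 5` SNPs outward all match
  (all remaining SNPs, when fewer than five remain; at the window edge this
  is vacuously true);
* otherwise the segment ends at the last matching SNP.

`rescue_k = 0` disables rescue entirely. A walk reaching the window edge is
*censored*: the shared length is only bounded below. The terminus is the
last matching SNP's position, not the midpoint to the next SNP — simple and
deterministic, with a small explicit downward bias on measured lengths of
about half the inter-SNP gap per side.

The per-haplotype statistic is the genetic length

    l_i = [cM(CNV start) − cM(left terminus) + cM(right terminus) − cM(CNV end)] / 100   (Morgans)

using the local (sex-averaged) recombination map rather than a uniform rate.

Two measurement modes exist. The default measures every carrier against the
single modal consensus, which encodes the observation that each rCNV rides
one characteristic haplotype; a pairwise mode (longest extension against any
other carrier) is available. A caveat the simulation study makes explicit:
at flank distances where fewer than half the carriers still share the
ancestral segment (share fraction `exp(−τd) < 1/2`), the modal allele drifts
toward the background majority, so consensus-based lengths of the *longest*
haplotypes are conservatively truncated. The rescue rule bridges isolated
consensus failures; parameter-recovery results below are measured with this
effect included.

Related carriers violate the independence assumption of the dating step, so
first/second-degree pairs (computed externally, e.g. by KING) are removed
greedily: repeatedly drop the sample in the most remaining pairs (ties
lexicographic) until no pair remains.

## Gamma-method age estimation

Under independence, each side's shared length is exponential with rate τ per
Morgan, where τ is the variant's age in generations; the two-sided length
`l_i` has mean 2/τ, giving

    τ̂ = 2 / l_ave .

`l_ave` is computed in two exposed weighting modes — a plain per-haplotype
mean, and a weighted mean over breakpoint groups (haplotypes with identical
termini) with weights equal to group size. The two are algebraically
identical on every input (tested); both exist because verbal descriptions of
the weighting are ambiguous. Only the independence form is implemented; the
correlated-genealogy correction of the full Gamma method is out of scope.

Censored segments are excluded from `Σl` and `n` by default with a logged
count, since the estimator assumes fully observed lengths; widen the window
instead. An `include_censored=True` sensitivity mode treats censored lengths
as observed, which frames the result as "at least N generations".

**Confidence interval.** This package's addition (the original analysis
reports ages without a stated CI method): each `l_i` is a sum of two
independent Exp(τ) variables, so `2 τ Σ l_i ~ χ²(4n)` exactly, giving

    CI = [ χ²_{α/2}(4n) / (2 Σl),  χ²_{1−α/2}(4n) / (2 Σl) ] .

Under the continuous length model the interval's coverage is exact (verified
by simulation at τ=500, n=25: 95% ± MC error). A seeded bootstrap CI is the
config alternative. Conversion to years takes years-per-generation as an
explicit parameter with no default claim.

Age sets (e.g. rCNVs shared between two populations versus
population-specific ones) are compared by the Mann-Whitney rank test: exact
enumeration of all rank assignments when both groups have ≤ 8 members
(midranks, so ties are handled), otherwise the tie-corrected normal
approximation without continuity correction.

## Association, burden, power

Each testable rCNV (carrier count ≥ 25 by default and carrier frequency
strictly > 0.022) is cross-tabulated against a binary phenotype. The odds
ratio uses the Woolf log-normal interval,
`exp(ln OR ± z·√(1/a+1/b+1/c+1/d))`; a single zero cell triggers the
Haldane–Anscombe +0.5 correction (flagged), and an exact conditional CI is
available. Significance is the Pearson chi-square without continuity
correction (a warning fires when an expected cell is ≤ 5); both two-sided
and one-sided p-values are reported, because published single-rCNV p-values
are consistent with a one-sided convention (χ² = 5.73 gives two-sided 0.017,
one-sided 0.008). Families of tests are adjusted by Bonferroni and
Benjamini–Hochberg.

"Any psychiatric disorder" is the union of all diagnosis labels including
AUD, derived at phenotype load time.

Burden is per-individual: number of consensus CNV events, and gene load —
distinct genes overlapped by ≥ 1 bp by any of the sample's CNVs (partial
overlap counts; a gene hit twice counts once) — compared between phenotype
classes with the same Mann-Whitney machinery.

`power_by_simulation` reproduces the design computation behind the
carrier-frequency threshold: solve the non-carrier case probability so the
population prevalence is met given the carrier odds ratio (always feasible
for prevalence in (0,1)), simulate binomial carrier counts and case counts,
and report the fraction of chi-square rejections. At the nominal design
point (n = 387, prevalence 0.60, carrier frequency 0.022, OR 10) the
two-sided test at α = 0.05 yields ≈ 57% power by this simulation — about
74% one-sided, and 80% two-sided is reached near frequency 0.03 — so the
package reports computed power rather than asserting a round target.
At OR = 1 the rejection rate equals α within Monte-Carlo error (calibration
check).

## Synthetic data

The study's tribal genotypes are available only on request, so a generator
provides every input with known ground truth. It emulates exactly the
structure the analysis assumes:

* per-side shared genetic lengths Exp(τ) around the focal CNV — the
  generative counterpart of the estimator's independence assumption (no full
  coalescent: no demography, no genealogical correlation between carriers);
* i.i.d. per-SNP mismatches at rate ε on shared segments, covering point
  mutation and genotyping error without distinguishing them;
* two caller outputs with independent dropout and uniform boundary jitter,
  probe counts from a genome-wide array probe spacing (default 5,500 bp, a
  550k-probe/3-Gb array) — distinct from the 60-SNP analysis flank grid;
* binary phenotypes at a target prevalence with a specified carrier odds
  ratio (same solver as the power routine).

Defaults are the conditions of the motivating study: the 96-kb MHC-region
deletion on chromosome 6 with 60 carriers among 387 individuals; age τ = 750
generations; ε = 0.001 (duplicate-genotype reproducibility 0.999); AUD
prevalence 0.60 with carrier OR 3.18; 60 SNPs per flank over a 700-kb span
at a uniform 1 cM/Mb (≈ 5 mean per-side shared lengths at τ = 750, keeping
censoring near 1%). Background allele frequencies are per-SNP Uniform(0.1,
0.9). Every operation draws from a generator seeded from the config; outputs
are byte-identical under a fixed seed.

Two deliberate realism limits. First, *chance sharing*: beyond the true
recombination breakpoint a background haplotype keeps matching the ancestral
allele with probability ≈ 0.6 per SNP, so measured extents can exceed truth
— as in real data. The `mark_breakpoints` option forces a mismatch at the
first off-segment SNP, the configuration under which the ε = 0 exact-identity
check is a theorem. Second, the generator draws each carrier independently,
so it cannot exhibit the shared-genealogy correlation that the independence
assumption ignores in real cohorts; passing recovery tests therefore
validate the estimator under its own model, not the model itself.

## Numerical and procedural choices

* Tie-breaks are deterministic everywhere (lexicographic haplotype ids,
  smallest coordinates, leftmost intervals), making every stage
  permutation-invariant and reruns byte-identical.
* Unphased *heterozygous* VCF genotypes are rejected with the offending site
  named; homozygous genotypes are accepted regardless of separator. Sites
  with missing alleles are dropped (logged) by default.
* Multi-allelic VCF sites are skipped with a logged count.
* Empty cohorts produce flagged zero summaries rather than NaNs; zero-margin
  2×2 tables produce flagged NaNs.
* The Mann-Whitney exact branch enumerates `C(n_a+n_b, n_a)` assignments
  (≤ 12,870 at the 8-per-group cutoff).

## Problem sizes in the shipped checks

The test suite and acceptance script validate parameter recovery at
τ ∈ {100, 500, 1000} with 50 carriers and 200 replicates per setting
(median τ̂ within 10% of truth), CI coverage over 1,000 cohorts of 25
haplotypes, consensus recovery over 10,000 events at 10% dropout, and power
at 10,000 replicates — sizes chosen so each check is decisively powered
while the full suite runs in well under a minute of compute per check.

## Known limitations

* No LRR/BAF processing, phasing, or kinship estimation — inputs are
  upstream products (call tables, phased haplotypes, related-pair lists).
* The consensus-haplotype drift described above biases very long shared
  segments downward; pairwise mode or a wider window mitigates it.
* The chi-square pivot CI inherits the independence assumption; with related
  carriers it is anti-conservative.
* Reports of ages in years depend entirely on the caller-supplied
  years-per-generation.
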