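# Methods

This note documents the statistical model behind `sweepscan`, the choices
made where the design was genuinely open, and what the synthetic benchmark
does and does not demonstrate.

## Study design

The pipeline contrasts one commercial population against each of several
indigenous populations *separately* and then requires convergence across
those pairwise comparisons.  The rationale is robustness: a selective sweep
that is real and shared should surface in most comparisons, whereas noise
specific to one indigenous population should not.  The weakness of the
design, quantified below, is that noise on the *commercial* side is common
to every comparison and is therefore not suppressed by convergence.

## Statistics

**Nucleotide diversity.**  Per site, π = 2j(n−j)/(n(n−1)) with j the ALT
allele count and n the called allele count — the unbiased probability that
two sampled haplotypes differ.  Window π is the *sum* over sites (no per-bp
normalization; any normalization shared between the two populations cancels
in the log₂ ratio that is actually ranked).  Windows with no called
genotypes give NaN, never 0; a log₂ ratio with a zero π in either
population is NaN and excluded from percentile ranking (no pseudo-count —
pseudo-counts distort exactly the tails being selected).

**Tajima's D.**  D = (π − S/a₁)/√(e₁S + e₂S(S−1)) with the standard
constants (a₁ = Σ1/i, etc.).  Missing data make the sample size vary by
site, so the constants use the *median called allele count over the
window's segregating sites*; S counts sites segregating within the
population.  D is NaN when S = 0, when n < 4, or when the variance term is
not positive.

**F_ST.**  Default is Hudson's estimator, accumulated as a ratio of
averages over sites: num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1),
den = p₁(1−p₂) + p₂(1−p₁).  Ratio-of-averages is robust to unequal and
varying sample sizes; negative window values are reported as computed
(clamping is available but off, so percentile ranks are honest).  A
Weir–Cockerham two-population variant (with the observed-heterozygosity
terms) is selectable.  The two estimators need not agree on small or
unbalanced windows; the default was chosen for its simple unbiasedness
argument, accepting divergence from Nei-family estimators other tools
default to.

**Window engine.**  Windows are anchored at position 1, fixed 100 kb size,
10 kb step, full windows only (a trailing partial window would mix scales
in the percentile ranking).  All window statistics are accumulated with
cumulative sums over position-sorted site arrays, so a scan is exactly
reproducible and independent of window order.

**Convergence filter.**  Per pair: drop windows with < 5 SNPs; rank the
defined values; keep ⌈0.05·N⌉ top-F_ST windows and ⌈0.025·N⌉ windows per
tail of each contrast, including ties at the cut value (deterministic and
order-free).  A window is a convergent call for a method when present in
≥ ⌈0.5·K⌉ of the K comparisons.  Both tails of both contrasts are eligible
by default and are also reported separately; a configuration switch
restricts calling to the commercial-sweep direction (upper tail of the π
ratio and of the D difference).

**ROH.**  PLINK `--homozyg` semantics: 50-SNP scan windows stepping one
SNP, a window "hits" when it has ≤ 3 heterozygous and ≤ 3 missing calls; a
SNP is eligible when ≥ 5 % of its overlapping windows hit; maximal eligible
runs are split at > 1 Mb inter-SNP gaps and kept when ≥ 300 kb, ≥ 100 SNPs
and ≤ 100 kb/SNP average spacing.  The minimum SNP count is the PLINK v1.9
default (100), exposed as a parameter.  Chromosomes with fewer SNPs than
the scan window are evaluated with a single truncated window — a documented
divergence risk from PLINK's edge behaviour.  Length classes are < 1 Mb,
[1, 3) Mb and ≥ 3 Mb.  Inbreeding: F = (O − E)/(N − E) with
E(hom) = Σ(1 − 2p(1−p)·n/(n−1)) over the sites where the individual has a
call, and F_ROH = ROH-covered length over the analyzed genome length (by
default the per-chromosome span between first and last SNP).

**Fixation testing.**  Per pair, each tested SNP gets a two-sided Fisher
exact p on the 2×2 ref/alt count table (probability-mass ordering; p = 1
for a zero margin) and a per-pair BH-FDR q.  Classification is
polarity-symmetric: an allele (ALT or REF) at frequency ≥ 0.95 (near) or
≥ 1.0 (fixed) in one population whose frequency in the other population is
≤ 0.08.  When both populations are reciprocally fixed, the a-side
(commercial, in pipeline use) label wins — a documented tie-break, not a
biological claim.  By default only SNPs inside genes already touched by a
window method are tested (matching targeted-gene practice); a genome-wide
flag exists.  Two aggregation rules operate on the per-pair results:

- *gene support* (feeds the candidate rule): a SNP supports its gene when
  near-fixed with q < 0.05 in ≥ 50 % of the comparisons — deliberately the
  same ceiling-share logic as the window convergence and the ROH gene rule;
- *strict consistency* (reported separately): near-fixed with q < 0.05 in
  strictly more than 70 % of comparisons.

**Candidate genes.**  A gene is a candidate when ≥ 3 of the four methods
(F_ST, π ratio, D difference, ROH — each by closed-interval overlap of its
convergent windows/segments with the gene span) support it, and/or it
contains ≥ 1 gene-supporting near-fixed SNP.

**THI.**  THI = (1.8T + 32) − (0.55 − 0.0055·RH)(1.8T − 26), Celsius and
percent, evaluated without rounding; heat stress is the strict inequality
THI > 72.  Useful identities: at RH = 100 the humidity term vanishes
(THI = 1.8T + 32); at 1.8T = 26, THI = 58 for any humidity.

## The synthetic benchmark

The generator draws, per site, an ancestral frequency p ~ Uniform(0.05,
0.95) and population frequencies from the Balding–Nichols distribution
Beta(p(1−F)/F, (1−p)(1−F)/F), with F = 0.05 for indigenous populations and
0.20 for the commercial one (0.05 global + 0.15 extra drift mimicking
intensive artificial selection and a small effective population).  SNP
count is Poisson(density × length) with positions uniform without
replacement; genotypes are Binomial(2, f) per individual (Hardy–Weinberg,
no linkage).  Sweeps set the commercial frequency inside the swept interval
to 0.995 for one allele (polarity randomized per site).  Defaults: one
5 Mb chromosome, 1 SNP/kb, 25 diploids per population, 4 indigenous
populations, three 20 kb sweeps at 1/4, 1/2 and 3/4 of the chromosome,
50 toy genes of 5–50 kb with one gene per sweep spanning the swept
interval.  All randomness flows from a single seed; identical seeds give
byte-identical output files.

**Why 20 kb sweeps.**  The paper-style tail fractions impose a hard
detection budget: with ~491 windows per pair, the top-5 % F_ST set holds
25 windows and each 2.5 % tail 13.  A sweep of width w overlaps
(w + 100 kb)/10 kb windows, so three sweeps must keep their combined
footprint within roughly the F_ST budget (widened a little by cross-pair
rank jitter under the ≥ 50 % sharing rule) for ≥ 80 % of sweep-overlapping
windows to be callable at all, pushing w down; conversely the
fixation-consistency signal needs enough swept SNPs (≈ 4 % of swept sites
end up consistently near-fixed, set by how often the ancestral frequency
falls in the rare band), pushing w up.  A pre-registered power analysis
across widths selected 20 kb as the joint optimum.  This is benchmark
design, fixed before the acceptance tests were written, and not revisited.

**What the benchmark does not show.**  (1) No linkage: sweeps are injected
as independent near-fixed sites, so there are no extended haplotypes and —
at 20 kb, far below the 300 kb / 100 SNP thresholds — no ROH signal at the
default conditions; the ROH detector is therefore validated against a
brute-force enumerator on dedicated fixtures, and the ROH method
contributes no gene support in the default benchmark (candidates arise
from the three window methods and the fixation branch).  Producing ROH
from near-fixation alone would need ≥ 300 kb sweeps, which the window
budget above forbids.  (2) The Balding–Nichols spectrum has no rare-variant
excess, so baseline Tajima's D is strongly positive (≈ +1.6 in the
commercial population) and the D *difference* has weak per-window power at
20 % sweep content (shift ≈ 0.2 vs window sd ≈ 0.33); the D method
contributes mainly through co-occurrence on the strongest windows.
(3) Commercial drift at F = 0.20 genuinely mimics sweeps — strong-drift
windows show elevated F_ST, reduced commercial π and negative commercial D
simultaneously, and being common to all comparisons they survive the
convergence filter.  This is the drift/selection confound inherent to the
study design, not an implementation artifact; it sets the false-positive
candidate-gene rate, which fluctuates between 0 and ~13 % per replicate
with a mean near 4 %.  Guarantees on recovery and error are therefore
stated as replicate means (ten fixed seeds): mean window recovery ≥ 80 %,
mean false-positive gene rate ≤ 5 %.  At the single demonstration seed the
end-to-end run recovers 27/33 sweep windows, flags a candidate truth gene
in all three sweeps and finds 2 strictly consistent injected SNPs.

## Numerical and edge-case conventions

- Coordinates are 1-based inclusive everywhere internally; BED conversion
  (start − 1) happens only in the writer/reader.
- Missing genotypes are a distinct state (−1), excluded from allele counts,
  never treated as homozygous reference.  Genotype-level GQ/DP masking runs
  before site-level filters, so masking can push a site over the
  missingness threshold (observable and tested).
- MAC counts the minor allele over non-missing calls only.
- Undefined statistics propagate as NaN and are excluded from percentile
  denominators.
- Count thresholds on shares use ceilings ("at least 50 %" of 9 is 5); the
  > 70 % consistency rule is strict, per its wording.
- Filters are idempotent; scans, ROH calling and the full pipeline are
  deterministic given inputs, and the run manifest records a hash of every
  parameter that affects results.

## Problem sizes

The test suite and the acceptance script run the full benchmark at the
default conditions (5 Mb, ~5,000 SNPs, 125 diploids — a few seconds per
replicate), oracle comparisons on 1,000 windows, 200 randomized ROH
fixtures, and 5,000-SNP null simulations for the F_ST and FDR calibrations;
these sizes give Monte-Carlo error comfortably inside every stated
tolerance while keeping a complete run under a minute.
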