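# Methods

## Counting synonymous and nonsynonymous events

Sites and differences are classified with the Nei–Gojobori (1986) scheme.
Each codon contributes fractional synonymous/nonsynonymous site counts: at
every position the synonymous fraction is the share of non-stop single-base
neighbours coding for the same amino acid (the two fractions sum to exactly
3 per codon). Differences between two codons are averaged with equal
weights over all mutational pathways that avoid stop codons. Divergence
rates dN and dS apply a Jukes–Cantor multiple-hit correction separately per
class and error out at saturation (proportion ≥ 3/4) rather than returning
a clipped value.

Two caveats are inherent to the scheme and documented rather than patched:

- For codons hit at more than one position, pathway averaging can assign
  fractional nonsynonymous steps even when every real substitution was
  synonymous (e.g. CTT ↔ TTA passes through TTT on one of its two
  pathways). The "ω = 0 implies Dn = 0" identity therefore holds per
  single-hit codon, which is what the test suite asserts on short-branch
  simulations.
- NG86 is deliberately chosen over ML pairwise counting; group contrasts
  here are ratio-based and the scheme is fully specified and deterministic.
  Parity with codeml's pairwise ML counts is not promised.

Polymorphism counts trust the consequence annotation carried by the variant
record when present; a coding variant with no annotation is an error, not a
silent skip. Fixed differences (alt count = sample size) are not
polymorphisms.

## Group contrasts and tests

Group-level diversity (Pn/Ps) and divergence (Dn/Ds) are pooled ratios:
counts are summed across a group's genes before dividing, which keeps genes
with few synonymous events from contributing unstable per-gene ratios and
makes a zero denominator a surfaced error rather than a patched value.

The permutation test shuffles gene group labels keeping group sizes,
recomputes the pooled-ratio difference (degrading − biosynthetic), and uses
the two-sided add-one p-value (#{|null| ≥ |obs|} + 1)/(B + 1); a
permutation with a zero pooled denominator is redrawn and logged. The
statistic and sidedness are this package's choices; two-sided is the
conservative default when direction is not prespecified. Default B = 9999;
a seed is mandatory.

The McDonald–Kreitman test is the two-sided Fisher exact probability of
[[Dn, Ds], [Pn, Ps]] (fractional divergence counts are rounded to integers
for the exact test); the direction of departure is reported separately as
adaptive_excess (Dn/Ds > Pn/Ps) or constraint_excess. Domain enrichment of
selected sites and the excess of positively selected genes over a genome
background use a two-sided Fisher exact test and an upper-tail binomial
test respectively.

## GY94 codon models

The rate of a single-nucleotide codon change i → j is π_j, multiplied by κ
for transitions and by ω for nonsynonymous changes; multi-position changes
are instantaneous-rate zero. Codon frequencies default to F3x4 estimated
from the alignment with a +1 pseudocount per nucleotide per position, so no
sense codon has zero frequency (an explicit zero frequency is rejected:
the chain would be reducible). In the site-model likelihood the class
matrices share one mixture-average scaling factor, so branch lengths are
expected substitutions per codon averaged over classes; the standalone
rate-matrix builder scales its single matrix to unit expected rate.

Likelihoods use Felsenstein pruning with per-node rescaling; the matrix is
reversible, so one symmetric eigendecomposition per class per parameter set
yields all branch transition matrices cheaply, and the log-likelihood is
invariant to the rooting of an unrooted topology. Ambiguous leaf cells
(gap/N surviving masking) are treated as missing data.

Optimization is L-BFGS-B on transformed parameters: log for κ, ω (M0) and
branch lengths; logistic for ω0 ∈ (0,1); 1 + exp(·) for ω2 ≥ 1;
logistic stick-breaking for class proportions. Default 3 restarts (first
from neutral-ish values, the rest jittered, σ = 0.5 on the transformed
scale), lnL tolerance 1e-10 (relative), convergence reported as a flag —
non-convergence is a result, not an exception. On null-true data the M2a
optimum sits on the p2 = 0 boundary and the optimizer can stop a few
millinats below the M1a optimum; the LRT statistic is clipped at zero.

The M1a/M2a LRT uses the χ²₂ reference (p = exp(−Λ/2)) as is conventional
for this comparison even though the boundary makes it conservative; the
size calibration test verifies the rejection rate at α = 0.05 stays ≤ 8%.
Multiple genes are corrected by Bonferroni (α/m). Positively selected sites
are identified by Naive Empirical Bayes: posterior class membership is the
class proportion times the per-site class likelihood, normalized; sites
with posterior(ω > 1 class) > 0.5 are reported in ungapped reference
protein coordinates. BEB is not implemented.

## Population scans

The site frequency spectrum is polarized by an outgroup allele; sites with
a missing outgroup or an outgroup matching neither allele are dropped and
counted. Estimators: θπ, θH, θL, θW with the standard SFS weightings.
Fay & Wu's H is reported raw (θπ − θH) and normalized,
(θπ − θL)/√Var, with the neutral variance evaluated at θ̂ = S/a_n and
θ̂² = S(S−1)/(a_n² + b_n); Zeng's E (θL − θW, normalized) is also
available. Degenerate variance estimates yield NaN, flagged not zeroed.

F<sub>ST</sub> is the Weir–Cockerham (1984) variance-components estimator
in its allele-count (haploid-sample) form — the input carries per-population
allele counts, not genotypes, so the heterozygosity term is absent — with
windows aggregated as ratio of summed components Σa/Σ(a+b). Monomorphic
windows are undefined (NaN), never 0, to keep envelope minima honest.

Sliding windows tile the region at the step size; a final partial window is
kept and flagged; a region shorter than one window is a single window.
Defaults: 3 kb windows for F<sub>ST</sub>, 10 kb for H, 0.5 kb step, all
configurable (the two statistics resolve a source conflict between stated
window sizes in favour of the per-statistic values).

Subsample envelopes draw `subsample_size` individuals (default 546) without
replacement from the pooled panel, individuals keeping their population
labels, so per-population subsample sizes are multivariate hypergeometric;
a draw emptying a population is redrawn and logged. Because the input is
aggregate allele counts, each site's subsampled alt count is then a
hypergeometric draw of 2 × (chosen individuals) alleles — within-individual
and between-site linkage is not representable from aggregate counts, which
is adequate for the allele-frequency statistics computed here but would not
be for haplotype statistics.

## Variant screen

Coding SNP panels are binomially down-sampled to a fixed panel of 20
diploid individuals (40 chromosomes; new alt count ~ Binomial(40, p̂)),
which approximates without-replacement subsampling when the source panel is
large; sites becoming monomorphic are dropped and counted. High-frequency
extraction keeps nonsynonymous variants with alternate-allele frequency
strictly above 0.20 — alternate frequency, not folded minor-allele
frequency, since the screened panel includes frequencies above 0.5.
Replacements are scored with the standard Dayhoff PAM250 log-odds matrix
(via biopython's substitution-matrix collection); a strictly negative score
flags the change as evolutionarily uncommon. The package bundles the
21-change observed panel as a small TSV so the screen is exercisable
standalone.

## Synthetic data

- **Codon alignments**: per site a class is drawn from the ω mixture, a
  root codon from the stationary frequencies, and evolution proceeds down
  the tree with GY94 transition matrices (same mixture-average scaling as
  the inference engine). Truth labels are returned for recovery tests.
  Default recovery conditions: 8 taxa, 500 codons, ω = 0.3, κ = 2 for M0;
  (0.1, 1, 4) at (0.6, 0.25/0.3, 0.15/0.1) for M2a scenarios.
- **Gene counts**: independent Poisson Pn/Ps/Dn/Ds at group rates; default
  rates place pooled diversity at 0.28 vs 0.45 and pooled divergence at
  0.26 vs 0.39 for the two groups, the magnitude of difference the
  contrasts are expected to detect.
- **Neutral coalescent**: Kingman coalescent (exponential waiting times at
  rate k(k−1)/2, time in units of 2N generations) with infinite-sites
  mutations Poisson at rate θ/2 per branch per unit time; the outgroup
  carries the ancestral state at every site. E[S] = θ·a_n is the analytic
  check. No recombination or demography — adequate for SFS statistics, not
  for linkage-based ones.
- **Sweep spectra**: a mixture of the neutral 1/i spectrum with a mirrored
  1/(n−i) high-frequency component at the given weight. This emulates the
  SFS footprint of hitchhiking directly rather than through forward
  simulation; H consumes only SFS shape, so this is the structure that
  matters.
- **Structured frequencies**: Balding–Nichols — per-population frequencies
  Beta(p(1−F)/F, (1−p)(1−F)/F) around a uniform ancestral p ∈ (0.1, 0.9),
  binomial sampling at fixed per-population allele counts. F maps directly
  to expected F<sub>ST</sub>, enabling ±0.02 recovery checks.

All generators are deterministic given their seed.

## Problem sizes in tests

The test suite runs the recovery and calibration suites at the documented
study conditions where they are cheap (M0: 20 replicates at 8 taxa × 500
codons; F<sub>ST</sub>: 2000 sites × 10 populations; neutral H: 500
replicates at n = 20) and at reduced sizes where the full design would be
disproportionate for a routine suite: the LRT size calibration uses 100
replicates of 4 taxa × 80 codons with single-restart fits, and the
end-to-end planted-truth run uses 12 genes of 150 codons on a 6-taxon tree.
These sizes are the package's own defaults for its validation suites and
are stated in the tests themselves.

## Known limitations

- NG86 counting, not codeml's ML pairwise estimates; results are
  comparable in structure, not bit-identical.
- F3x4 is the only frequency model; the standard nuclear genetic code the
  only code.
- χ²₂ at the M2a boundary is conservative (documented above).
- The subsample envelope approximates individual resampling from aggregate
  counts (documented above).
- No branch or branch-site models, no tree search, no recombination in the
  coalescent generator.
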