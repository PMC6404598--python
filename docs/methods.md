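# Methods

## Read model

For one individual and one allele at a locus of ploidy *k*, a read matches
the allele with probability π_i = (1 − c)·i/k + c·p, where *i* is the true
allele copy number, *c* the cross-contamination rate and *p* the allele
frequency (the contamination term models reads that actually originate
from other samples in the library, so a homozygote for the other allele
can still show an occasional read). The count *a* of matching reads among
*a + b* total reads at the locus is beta-binomial with parameters
(d·π_i, d·(1 − π_i)); *d* is a genome-wide overdispersion parameter
absorbing sample-to-sample variation in allelic ratios (unequal
contamination, cut-site variants, size selection). All pmf evaluation runs
in log space through log-gamma functions. Degenerate success
probabilities are evaluated as their limits: π = 0 puts all mass on a = 0,
π = 1 on b = 0; with c > 0 only the i = 0, p = 0 and i = k, p = 1 corners
are degenerate. A genotype with zero reads has likelihood 1 for every copy
number.

Defaults: d = 9 (typical for RAD-seq allelic ratios; calibrate per dataset
with `test_overdispersion`), c = 0.001 (typical blank-barcode estimate; use
`estimate_contamination` when no-template controls were sequenced). Both
are single genome-wide values — per-locus error rates are deliberately not
estimated, so rare loci with context-specific sequencing error will have
overstated homozygote likelihoods.

### Contamination estimation

c = (mean total read depth of blank barcodes) / (mean total depth of
non-blank samples), clamped to [1e-6, 0.5). Blanks are excluded from every
other computation (filtering counts, allele frequencies, priors).

### Overdispersion selection

For each candidate d, every nonzero-depth genotype is assigned a copy
number drawn from its posterior (Hardy-Weinberg prior in the model's
allele frequencies × the candidate's likelihood); its read count is then
mapped to a randomized quantile of the assigned beta-binomial — a uniform
draw within the discrete pmf step, giving continuous quantiles — and the
candidate is scored by the Kolmogorov–Smirnov distance of the quantiles
from Uniform(0, 1). Ties select the smaller d. Sampling the copy number
(rather than taking the argmax) matters: conditioning on the most likely
genotype absorbs extreme allelic ratios into extreme dosage classes and
biases the selection toward too little overdispersion — in self-consistency
simulations the argmax variant reproducibly picked d = 14 for data
generated with d = 9, while the sampled variant recovers 9. Both uniform
draws are shared across candidates so the scores are comparable; pure
binomial data selects the largest candidate, as it should.

## Priors

**Hardy-Weinberg.** Binomial(k, p). For allopolyploid hypotheses the
per-subgenome binomials are convolved, which by Vandermonde's identity
equals the merged binomial — under HWE with no selfing, auto- and
allopolyploid hypotheses of equal total ploidy are therefore
indistinguishable (ploidy selection is only discriminative with mapping
designs or selfing; this is documented behavior, not an error).

**Selfing.** With partial selfing rate s, the prior is the fixed point of
prior ← (1 − s)·Binomial(k, p) + s·Self(prior), where Self convolves two
independent polysomic gametes of each dosage class (iterated to 1e-12,
at most 200 rounds; for multiple subgenomes the fixed point is taken per
subgenome and convolved). Selfing moves mass toward homozygous dosages but
preserves the mean k·p. At s = 1, p = 0.5 the diploid fixed point is
(0.5, 0, 0.5).

**Population structure.** Scaled dosages pmg/k are centered per allele and
decomposed by PCA across individuals; each allele's scaled dosage is
regressed on the leading axis scores and the fitted values become
individual-specific allele frequencies (clamped to
[1/(2·n·k), 1 − 1/(2·n·k)], renormalized within each locus), which drive
per-individual binomial priors and the contamination term. The number of
axes is chosen by Horn's parallel analysis on one representative allele
per locus: an axis is kept while its eigenvalue exceeds 1.05× the mean
eigenvalue of column-permuted copies at the same rank (3 permutations,
fixed internal seed), capped at 10. Two details are load-bearing. First,
within a locus the allele columns are linearly dependent (dosages sum to
k), and keeping all of them doubles every eigenvalue relative to any noise
baseline — the selection must run on deduplicated columns. Second, the
axis count is fixed once, from dosages computed under uniform priors,
instead of being re-selected each iteration: re-selection lets noise axes
feed back into the priors and reinforce themselves. With these choices a
panmictic panel selects zero axes (intercept-only regression = global
frequencies, matching the HWE pipeline to within ~1%), while a structured
panel keeps its real axes and gains 10–20% accuracy. A broken-stick rule
was tried first and retained ~10 spurious axes on noisy dosage PCA,
degrading panmictic panels by ~15%; parallel analysis replaced it.

**Linkage.** For each allele with a genomic position, up to
`max_neighbors` (default 10) alleles at other loci within `ld_distance` bp
whose dosages have the largest |Pearson correlation| with the target's are
used in a least-squares prediction of the target dosage; each individual's
prediction, scaled and clamped to a pseudo-frequency q, drives a
Binomial(k, q) prior that is mixed with the base prior at weight
`mix_weight` (default 0.5). Alleles without usable neighbors keep their
base prior. The regression is learned across all individuals, so a locus
covered in part of the panel imputes its zero-depth genotypes from linked
markers; a locus with no reads in any individual has nothing to learn
from and keeps its base prior — no method can do better there.

**Mapping populations.** Parental dosages are called by maximum likelihood
from the parents' own reads under uniform priors (uniform, to avoid
circularity with the progeny data). Each allele's progeny prior is the
segregation distribution of the cross: polysomic gametes are
hypergeometric draws of k/2 chromosomes without double reduction;
allopolyploid parents have their allele copies assigned to subgenomes
uniformly over all consistent placements (no phasing information) and
transmit one disomic gamete per subgenome. Backcross, intermating and
selfing generations are applied in that order as transitions on the
dosage distribution. Two fallbacks flag a locus and substitute HWE priors
from progeny allele frequencies: a parent with zero depth, and a
non-segregating contradiction (both parents called homozygous for the
same allele while the progeny minor-allele frequency exceeds 3c). Parents
receive point-mass priors at their called dosages. A caveat inherent to
the overdispersed read model: a mid-dosage parental call (e.g. simplex in
a tetraploid) cannot be made arbitrarily certain by depth alone, because
each genotype's allelic ratio is a single Beta draw — at depth 200 and
d = 9 roughly one simplex parent in ten is miscalled as duplex. Diploid
parents (boundary and heterozygote dosages) are immune.

## Pipelines

Iterative pipelines initialize allele frequencies from pooled depth
ratios (floored at 1/(4n), renormalized per locus), then loop: priors →
likelihoods → posteriors → posterior-mean dosages → frequency update
(mean scaled dosage over non-blank individuals, renormalized per locus),
until the largest per-allele frequency change drops below `tol` (default
1e-3) or `max_iter` (default 50) is reached; non-convergence warns and
returns the last state. The mapping pipeline estimates everything once.
With LD enabled, an uncounted pre-pass under plain priors produces the
dosage matrix the first LD adjustment regresses on; each counted
iteration then applies the adjustment, preserving the contract that an
infinite tolerance means exactly one iteration.

Posteriors are computed in linear space (k + 1 ≤ ~9 states); rows with a
constant likelihood return the prior bit-for-bit, which makes the
zero-depth-imputation identity exact. Rows whose prior mass lies entirely
on zero-likelihood states (e.g. a contaminated outlier under a point-mass
mapping prior) fall back to the prior with a warning rather than failing.
Discrete calls break ties toward the smaller dosage.

With several ploidy hypotheses, each is fitted independently and each
locus takes the hypothesis maximizing the sum over non-blank individuals
and alleles of the log marginal likelihood log Σ_i L_i·P_i (scores rounded
to 1e-9 so exact ties resolve to the first-listed hypothesis), letting
inheritance mode vary across the genome.

## Simulator

Biallelic loci; ancestral allele frequencies Uniform(0.05, 0.95) unless
supplied (a typical post-filtering discovered-SNP spectrum). Truth
dosages: Binomial(k, p) under HWE; Balding–Nichols subpopulation
frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) with F the target F_ST for
structured panels; the selfing fixed point for partially selfing panels;
the cross's segregation distribution for F1s (parents prepended as the
first two taxa). Depths: locus depth D_L ~ Gamma(shape 2, scale 5);
individual total depth round(Gamma(D_L/10, scale 10)) — the Gamma shape is
floored at 1e-6, so shallow loci produce mostly zero-depth genotypes, the
high-missing-data regime this method targets; allelic counts
beta-binomial around π_i with d = 9, c = 0.001 (Beta draw then binomial;
multi-allelic loci would factor sequentially, but the simulator emits
biallelic markers). What the simulator does not emulate: linked truth
genotypes (LD tests construct duplicated loci explicitly), per-locus
error-rate variation, allelic dropout from cut-site polymorphism tied to
relatedness, and reference bias — so passing tests demonstrate internal
consistency of the model family and correct inference under it, not
robustness to every artifact of real libraries.

Evaluation is RMSE between estimated and true dosages on the 0..k scale,
overall, per marker, or split into genotypes with and without reads.

## Numerical choices and degenerate inputs

- Frequency floors and clamps everywhere use 1/(2·n·k)-style epsilons to
  keep beta-binomial parameters positive.
- Loci reduced to one allele by filtering are dropped (the "other reads"
  count would be identically zero); filtering is idempotent and blanks
  never count toward thresholds.
- Marginal-likelihood scores are compared after rounding to 1e-9 to make
  the auto/allo tie deterministic.
- The problem sizes used in tests and validation (panels of 150–200
  individuals × 60–200 biallelic loci, mean depth ≈ 10) match the depth
  protocol above; larger panels change nothing structurally.

## Known limitations

- No double reduction in polysomic gametes and no preferential pairing in
  allopolyploids.
- One genome-wide d and c; no per-locus error model.
- Structure and LD priors are regression approximations, not a joint
  haplotype model; LD priors need genomic positions.
- Mapping designs are limited to two founding parents plus
  backcross/intermating/selfing generation counts.
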