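# polydose

Bayesian allele-dosage calling from sequencing read depth, for diploids and
polyploids.

Genotyping-by-sequencing (GBS) and RAD-seq deliver read depth that is low
and wildly uneven across loci. Hard genotype calls from such data miscall
heterozygotes as homozygotes, cannot resolve allele copy number in
polyploids, and leave large fractions of genotypes missing. polydose
instead estimates, for every individual, allele and possible copy number
*i* ∈ {0..k}, a posterior probability from which it exports either the most
probable dosage or — usually better for GWAS and genomic prediction — the
continuous *posterior mean genotype*. Audiences: breeders and population
geneticists working with polyploid crops (potato, sugarcane, *Miscanthus*,
wheat relatives) or with low-coverage diploid panels.

## Model

Every read at a locus is a Bernoulli trial of matching a given allele. With
allele copy number *i*, ploidy *k*, population allele frequency *p* and
cross-contamination rate *c*,

    π_i = (1 − c) · i / k + c · p

and the *a* reads of the allele among *a + b* reads at the locus are
beta-binomial,

    L(a, b | G_i) = C(a+b, a) · B(dπ_i + a, d(1−π_i) + b) / B(dπ_i, d(1−π_i)),

with overdispersion *d* (smaller = noisier allelic ratios; default 9;
`test_overdispersion` calibrates it, and *c* is estimated from blank
barcodes — no-template library controls). Priors over copy number come from
one of four population models and Bayes' theorem combines them:

    P(G_i | a, b) ∝ L(a, b | G_i) · P(G_i),
    pmg = Σ_i i · P(G_i | a, b).

* **Hardy-Weinberg** (`HWEGenotyper` / `iterate_hwe`): Binomial(k, p)
  priors, optionally driven to the fixed point of a partial-selfing
  recursion; allele frequencies re-estimated from dosages until they
  converge.
* **Population structure** (`PopStructGenotyper` / `iterate_popstruct`):
  binomial priors in individual-specific allele frequencies fitted by
  regressing scaled dosages on principal-component axes each iteration.
* **Linkage** (`use_ld=True` on either): priors blended with binomial
  priors in a pseudo-frequency predicted from correlated alleles at nearby
  loci — this is what imputes zero-depth genotypes from linked markers.
* **Mapping populations** (`MappingGenotyper` / `run_mapping`): the exact
  segregation distribution of a biparental cross (polysomic gametes drawn
  hypergeometrically, disomic subgenomes for allopolyploids, any number of
  backcross/intermating/selfing generations), estimated in a single pass.

Any set of ploidy hypotheses can be supplied (e.g. `4` autotetraploid vs
`2,2` allotetraploid); the best is chosen per locus by marginal likelihood.
A genotype with zero reads has a flat likelihood, so its posterior equals
its prior — missing-data imputation falls out of the same formula.

The package also ships the read-depth simulator used for validation
(Gamma-distributed locus and individual depths, beta-binomial allelic
counts) and an RMSE evaluator, so every claim is testable without any
external dataset.

## Worked example

Simulate an autotetraploid diversity panel under the RAD-seq-like depth
regime (Gamma locus depth, mean 10; many zero-depth genotypes) and call
dosages with the HWE pipeline:

```python
from polydose import (SimulationConfig, simulate, HWEGenotyper,
                      naive_ratio_genotypes, rmse)

truth = simulate(SimulationConfig(n_taxa=200, n_loci=100, ploidy=4, seed=1))
est = HWEGenotyper(ploidies=4, c=0.001, d=9.0).fit(truth.dataset)
print(f"converged after {est.n_iter_} iterations")

zero = truth.dataset.locus_totals()[:, truth.dataset.locus_index] == 0
e_reads, e_zero = rmse(est.dosage_, truth.genotypes, zero_read_mask=zero)
naive = naive_ratio_genotypes(truth.dataset, 4, est.model_.freq)
n_reads, n_zero = rmse(naive, truth.genotypes, zero_read_mask=zero)
print(f"dosage RMSE, genotypes with reads: {e_reads:.3f} (naive ratio: {n_reads:.3f})")
print(f"dosage RMSE, zero-read genotypes:  {e_zero:.3f} (naive fill:  {n_zero:.3f})")
```

Output:

```
converged after 26 iterations
dosage RMSE, genotypes with reads: 0.540 (naive ratio: 0.868)
dosage RMSE, zero-read genotypes:  0.850 (naive fill:  0.850)
```

The Bayesian caller cuts the dosage error of sequenced genotypes by more
than a third relative to the raw depth-ratio estimate `k·a/(a+b)`; for
genotypes with no reads both reduce to the prior mean `k·p` (with LD or
structure priors the zero-read error drops too). `est.dosage_` holds the
continuous dosage matrix, `est.discrete_` the most probable dosages, and
`est.posterior_` the full probability vectors.

The same workflow runs from the shell:

```sh
polydose simulate --n-taxa 200 --n-loci 100 --ploidy 4 --seed 1 \
    --out-vcf sim.vcf --out-truth truth.csv
polydose call-hwe sim.vcf -k 4 -o calls
polydose evaluate calls.continuous.csv truth.csv
```

Real data enters through `read_vcf_ad` (any VCF with a per-sample AD
field) or `read_depth_csv`; results export as CSV dosage matrices or as a
VCF with GT and DS fields (`write_genotypes`).

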