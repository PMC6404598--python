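"""End-to-end genotype estimation pipelines as scikit-learn style estimators.

Three estimators cover the population models:

* :class:`HWEGenotyper` — diversity panels without structure; allele
  frequencies and Hardy-Weinberg (optionally selfing-adjusted) priors are
  re-estimated iteratively until the frequencies converge.
* :class:`PopStructGenotyper` — structured diversity panels; priors are
  binomial in individual-specific allele frequencies fitted from principal
  components of the current dosage estimates, re-estimated each iteration.
* :class:`MappingGenotyper` — biparental mapping populations; parental
  genotypes and progeny allele frequencies are estimated once and the
  cross's segregation distribution serves as the prior (one pass, no
  iteration).

All three optionally blend linkage-informed priors from correlated alleles
at nearby loci, accept several ploidy hypotheses (the best one is chosen
per locus by marginal likelihood), and expose fitted attributes
``posterior_``, ``dosage_`` (posterior mean), ``discrete_``, ``model_``,
``n_iter_`` and ``converged_``. Module-level functions ``iterate_hwe``,
``iterate_popstruct`` and ``run_mapping`` are thin wrappers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .data import (AlleleDepthSet, DosageMatrix, GenotypeProbArray,
                   PloidyHypothesis, PopulationModel)
from .likelihood import (DEFAULT_CONTAMINATION, DEFAULT_OVERDISPERSION,
                         genotype_likelihoods)
from .posterior import most_probable, posterior, posterior_mean
from .priors import (CrossDesign, LinkageConfig, binomial_priors_from_freqs,
                     hwe_priors_matrix, ld_adjusted_priors, mapping_priors,
                     popstruct_individual_freqs, update_allele_freqs)

__all__ = [
    "PipelineResult",
    "HWEGenotyper",
    "PopStructGenotyper",
    "MappingGenotyper",
    "iterate_hwe",
    "iterate_popstruct",
    "run_mapping",
    "select_ploidy",
    "naive_ratio_genotypes",
]

logger = logging.getLogger("polydose")

DEFAULT_TOL = 1e-3
DEFAULT_MAX_ITER = 50


@dataclass
class PipelineResult:
    """Final state of a genotype-estimation pipeline."""

    posterior: GenotypeProbArray
    pmg: DosageMatrix
    discrete: DosageMatrix
    model: PopulationModel
    ploidy_choice: dict
    n_iterations: int
    converged: bool
    dataset: AlleleDepthSet
    locus_log_marginal: dict = field(default_factory=dict)

    def strip(self) -> "PipelineResult":
        """Drop everything but the posterior and dosage matrices."""
        return PipelineResult(self.posterior, self.pmg, self.discrete,
                              model=None, ploidy_choice=self.ploidy_choice,
                              n_iterations=self.n_iterations,
                              converged=self.converged, dataset=self.dataset)


def naive_ratio_genotypes(dataset: AlleleDepthSet, ploidy,
                          freq: np.ndarray | None = None) -> DosageMatrix:
    """Baseline estimator k*a/(a+b); zero-depth entries get k*p.

    The no-model comparison point: with ``freq`` absent, zero-depth entries
    get k/2 (an uninformative frequency of one half).
    """
    k = PloidyHypothesis.parse(ploidy).k
    a = dataset.depth.astype(float)
    n = a + dataset.other_allele_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(n > 0, k * a / np.where(n > 0, n, 1), np.nan)
    if freq is None:
        fill = np.full(dataset.n_alleles, 0.5)
    else:
        fill = np.asarray(freq, dtype=float)
    vals = np.where(np.isnan(vals), k * fill[None, :], vals)
    return DosageMatrix(vals, k=k, discrete=False)


def _initial_freqs(dataset: AlleleDepthSet) -> np.ndarray:
    """Raw depth-ratio start for allele frequencies, floored and normalized."""
    nonblank = dataset.nonblank_mask()
    asum = dataset.depth[nonblank].sum(axis=0).astype(float)
    loc_sum = np.zeros(dataset.n_loci)
    np.add.at(loc_sum, dataset.locus_index, asum)
    n_alleles_of = np.bincount(dataset.locus_index)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(loc_sum[dataset.locus_index] > 0,
                     asum / np.where(loc_sum[dataset.locus_index] > 0,
                                     loc_sum[dataset.locus_index], 1),
                     1.0 / n_alleles_of[dataset.locus_index])
    floor = 1.0 / (2.0 * max(int(nonblank.sum()), 1) * 2)
    p = np.maximum(p, floor)
    sums = np.zeros(dataset.n_loci)
    np.add.at(sums, dataset.locus_index, p)
    return p / sums[dataset.locus_index]


def _locus_log_marginal(priors, likelihoods, dataset) -> np.ndarray:
    """Per-locus sum over non-blank taxa and alleles of log marginal."""
    marg = (priors.values * likelihoods.values).sum(axis=2)
    logm = np.log(np.maximum(marg, 1e-300))
    logm = logm[dataset.nonblank_mask()]
    out = np.zeros(dataset.n_loci)
    np.add.at(out, dataset.locus_index, logm.sum(axis=0))
    return out


def select_ploidy(dataset: AlleleDepthSet, hypotheses,
                  per_locus_log_marginal) -> dict:
    """Per-locus choice among ploidy hypotheses by log marginal likelihood.

    ``per_locus_log_marginal`` maps each hypothesis to its per-locus scores;
    ties go to the first-listed hypothesis. Note that under pure HWE with no
    selfing, auto- and allopolyploid hypotheses of equal total ploidy have
    identical priors and likelihoods, so the choice is only discriminative
    with mapping designs or selfing.
    """
    hypotheses = [PloidyHypothesis.parse(h) for h in hypotheses]
    scores = np.stack([np.asarray(per_locus_log_marginal[h])
                       for h in hypotheses])            # (H, L)
    best = np.argmax(np.round(scores, 9), axis=0)       # first wins ties
    return {loc: hypotheses[best[li]] for li, loc in enumerate(dataset.loci)}


def _assemble(dataset, hypotheses, single_results, ploidy_choice):
    """Merge per-hypothesis results into one, per the per-locus choice."""
    hypotheses = [PloidyHypothesis.parse(h) for h in hypotheses]
    kmax = max(h.k for h in hypotheses)
    first = single_results[hypotheses[0]]
    post = np.zeros((dataset.n_taxa, dataset.n_alleles, kmax + 1))
    pmg = np.zeros((dataset.n_taxa, dataset.n_alleles))
    disc = np.zeros((dataset.n_taxa, dataset.n_alleles))
    for li, loc in enumerate(dataset.loci):
        h = ploidy_choice[loc]
        res = single_results[h]
        cols = dataset.locus_index == li
        post[:, cols, : h.k + 1] = res["posterior"].values[:, cols, :]
        pmg[:, cols] = res["pmg"].values[:, cols]
        disc[:, cols] = res["discrete"].values[:, cols]
    return (GenotypeProbArray(post, kind="posterior"),
            DosageMatrix(pmg, k=kmax),
            DosageMatrix(disc, k=kmax, discrete=True),
            first)


class _BaseGenotyper(BaseEstimator):
    """Shared fit machinery: per-hypothesis run + per-locus selection."""

    def _hypotheses(self):
        plo = self.ploidies
        if isinstance(plo, (int, str, PloidyHypothesis)):
            plo = [plo]
        return [PloidyHypothesis.parse(h) for h in plo]

    def fit(self, X: AlleleDepthSet, y=None):
        """Estimate genotype posteriors for every individual and allele."""
        if not isinstance(X, AlleleDepthSet):
            raise TypeError("X must be an AlleleDepthSet")
        if X.n_alleles == 0:
            raise ValueError("dataset has no markers")
        hypotheses = self._hypotheses()
        singles = {}
        marginals = {}
        for h in hypotheses:
            singles[h] = self._fit_single(X, h)
            marginals[h] = singles[h]["locus_log_marginal"]
        choice = select_ploidy(X, hypotheses, marginals)
        if len(hypotheses) == 1:
            h = hypotheses[0]
            res = singles[h]
            result = PipelineResult(
                res["posterior"], res["pmg"], res["discrete"], res["model"],
                choice, res["n_iterations"], res["converged"], X,
                {loc: marginals[h][li] for li, loc in enumerate(X.loci)})
        else:
            post, pmg, disc, first = _assemble(X, hypotheses, singles, choice)
            result = PipelineResult(
                post, pmg, disc, first["model"], choice,
                first["n_iterations"], first["converged"], X)
        self.result_ = result
        self.posterior_ = result.posterior
        self.dosage_ = result.pmg
        self.discrete_ = result.discrete
        self.model_ = result.model
        self.n_iter_ = result.n_iterations
        self.converged_ = result.converged
        self.ploidy_choice_ = result.ploidy_choice
        return self

    def fit_transform(self, X: AlleleDepthSet, y=None) -> np.ndarray:
        """Fit and return the posterior-mean dosage matrix."""
        return self.fit(X).dosage_.values

    def transform(self, X: AlleleDepthSet | None = None) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted
        check_is_fitted(self, "dosage_")
        return self.dosage_.values


class HWEGenotyper(_BaseGenotyper):
    """Iterative genotype caller for unstructured diversity panels.

    Starting from raw depth-ratio allele frequencies, the loop alternates
    Hardy-Weinberg (selfing-adjusted) priors, beta-binomial likelihoods,
    posteriors and posterior-mean dosages, and re-estimates allele
    frequencies from the dosages, until the largest frequency change drops
    below ``tol`` or ``max_iter`` is reached. With ``use_ld`` the priors are
    additionally blended with predictions from correlated nearby alleles
    (requires genomic positions).

    Parameters
    ----------
    ploidies : int, str, PloidyHypothesis or list thereof
        Candidate inheritance modes; with several, the best is picked per
        locus by marginal likelihood.
    c, d, s : float
        Contamination rate, overdispersion, selfing rate.
    tol, max_iter : float, int
        Convergence tolerance on max |change in allele frequency| and the
        iteration cap.
    use_ld : bool
    ld_config : LinkageConfig or None
    """

    def __init__(self, ploidies=2, c=DEFAULT_CONTAMINATION,
                 d=DEFAULT_OVERDISPERSION, s=0.0, tol=DEFAULT_TOL,
                 max_iter=DEFAULT_MAX_ITER, use_ld=False, ld_config=None):
        self.ploidies = ploidies
        self.c = c
        self.d = d
        self.s = s
        self.tol = tol
        self.max_iter = max_iter
        self.use_ld = use_ld
        self.ld_config = ld_config

    def _fit_single(self, X: AlleleDepthSet, ploidy: PloidyHypothesis):
        cfg = self.ld_config or LinkageConfig()
        p = _initial_freqs(X)
        pmg = None
        if self.use_ld:
            # uncounted pre-pass: the LD adjustment needs dosages to regress
            model = PopulationModel(freq=p, c=self.c, d=self.d, s=self.s)
            pri = GenotypeProbArray(np.broadcast_to(
                hwe_priors_matrix(p, ploidy, self.s),
                (X.n_taxa, X.n_alleles, ploidy.k + 1)).copy(), kind="prior")
            pmg = posterior_mean(posterior(
                pri, genotype_likelihoods(X, ploidy, model)))
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            model = PopulationModel(freq=p, c=self.c, d=self.d, s=self.s)
            prior_mat = hwe_priors_matrix(p, ploidy, self.s)     # (A, k+1)
            priors = GenotypeProbArray(
                np.broadcast_to(prior_mat, (X.n_taxa,) + prior_mat.shape).copy(),
                kind="prior")
            if self.use_ld and pmg is not None:
                priors = ld_adjusted_priors(priors, pmg, X, cfg, ploidy)
            lik = genotype_likelihoods(X, ploidy, model)
            post = posterior(priors, lik)
            pmg = posterior_mean(post)
            p_new = update_allele_freqs(pmg, X, ploidy)
            delta = float(np.max(np.abs(p_new - p)))
            logger.info("iter %d: max|dp|=%.3g mean pmg=%.3g",
                        n_iter, delta, float(pmg.values.mean()))
            p = p_new
            if delta < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn("allele frequencies did not converge within "
                          f"{self.max_iter} iterations", stacklevel=2)
        return {
            "posterior": post, "pmg": pmg, "discrete": most_probable(post),
            "model": PopulationModel(freq=p, c=self.c, d=self.d, s=self.s),
            "n_iterations": n_iter, "converged": converged,
            "locus_log_marginal": _locus_log_marginal(priors, lik, X),
        }


class PopStructGenotyper(_BaseGenotyper):
    """Iterative genotype caller for structured diversity panels.

    Like :class:`HWEGenotyper`, but each iteration fits individual-specific
    allele frequencies by regressing scaled dosages on principal-component
    axes of the current dosage matrix, and uses per-individual binomial
    priors in those frequencies. ``n_axes=None`` keeps the axes beating the
    parallel-analysis baseline (at most 10;
    possibly none, which reduces to global allele frequencies).
    """

    def __init__(self, ploidies=2, c=DEFAULT_CONTAMINATION,
                 d=DEFAULT_OVERDISPERSION, s=0.0, n_axes=None, tol=DEFAULT_TOL,
                 max_iter=DEFAULT_MAX_ITER, use_ld=False, ld_config=None):
        self.ploidies = ploidies
        self.c = c
        self.d = d
        self.s = s
        self.n_axes = n_axes
        self.tol = tol
        self.max_iter = max_iter
        self.use_ld = use_ld
        self.ld_config = ld_config

    def _fit_single(self, X: AlleleDepthSet, ploidy: PloidyHypothesis):
        cfg = self.ld_config or LinkageConfig()
        k = ploidy.k
        p = _initial_freqs(X)
        # iteration 0: dosages from uniform priors, to seed the PCA
        uniform = GenotypeProbArray(
            np.full((X.n_taxa, X.n_alleles, k + 1), 1.0 / (k + 1)), kind="prior")
        model0 = PopulationModel(freq=p, c=self.c, d=self.d, s=self.s)
        pmg = posterior_mean(posterior(uniform, genotype_likelihoods(X, ploidy, model0)))
        # the axis count is fixed from the likelihood-only dosages: letting it
        # float would let noise axes feed back into the priors and reinforce
        # themselves; axis scores are still recomputed every iteration
        if self.n_axes is None:
            from .priors import default_n_axes
            Xc = pmg.values / k
            Xc = Xc - Xc.mean(axis=0)
            _, rep = np.unique(X.locus_index, return_index=True)
            n_axes = default_n_axes(Xc[:, rep])
        else:
            n_axes = self.n_axes
        converged = False
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            ind_freq = popstruct_individual_freqs(pmg, X, ploidy,
                                                  n_axes=n_axes)
            model = PopulationModel(freq=p, c=self.c, d=self.d, s=self.s,
                                    ind_freq=ind_freq)
            priors = binomial_priors_from_freqs(ind_freq, ploidy, self.s)
            if self.use_ld:
                priors = ld_adjusted_priors(priors, pmg, X, cfg, ploidy)
            lik = genotype_likelihoods(X, ploidy, model)
            post = posterior(priors, lik)
            pmg = posterior_mean(post)
            p_new = update_allele_freqs(pmg, X, ploidy)
            delta = float(np.max(np.abs(p_new - p)))
            logger.info("iter %d: max|dp|=%.3g mean pmg=%.3g",
                        n_iter, delta, float(pmg.values.mean()))
            p = p_new
            if delta < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn("allele frequencies did not converge within "
                          f"{self.max_iter} iterations", stacklevel=2)
        return {
            "posterior": post, "pmg": pmg, "discrete": most_probable(post),
            "model": PopulationModel(freq=p, c=self.c, d=self.d, s=self.s,
                                     ind_freq=model.ind_freq),
            "n_iterations": n_iter, "converged": converged,
            "locus_log_marginal": _locus_log_marginal(priors, lik, X),
        }


class MappingGenotyper(_BaseGenotyper):
    """One-pass genotype caller for biparental mapping populations.

    Parental dosages are called by maximum likelihood from the parents' own
    reads; every progeny's prior is the segregation distribution of the
    cross (F1 by default; backcross/intermating/selfing generations via the
    :class:`CrossDesign`). Allele frequencies are estimated once from the
    progeny, never iterated. With ``use_ld`` the segregation priors are
    LD-adjusted using dosages from a preliminary pass.
    """

    def __init__(self, parent1=None, parent2=None, ploidies=2,
                 c=DEFAULT_CONTAMINATION, d=DEFAULT_OVERDISPERSION,
                 generations_selfing=0, generations_backcross=0,
                 recurrent_parent=None, generations_intermating=0,
                 use_ld=False, ld_config=None):
        self.parent1 = parent1
        self.parent2 = parent2
        self.ploidies = ploidies
        self.c = c
        self.d = d
        self.generations_selfing = generations_selfing
        self.generations_backcross = generations_backcross
        self.recurrent_parent = recurrent_parent
        self.generations_intermating = generations_intermating
        self.use_ld = use_ld
        self.ld_config = ld_config

    def _design(self) -> CrossDesign:
        if self.parent1 is None or self.parent2 is None:
            raise ValueError("parent1 and parent2 are required")
        return CrossDesign(self.parent1, self.parent2,
                           self.generations_selfing,
                           self.generations_backcross,
                           self.recurrent_parent,
                           self.generations_intermating)

    def _fit_single(self, X: AlleleDepthSet, ploidy: PloidyHypothesis):
        design = self._design()
        cfg = self.ld_config or LinkageConfig()
        parents = {design.parent1, design.parent2}
        # progeny allele frequencies, estimated once from raw depth ratios
        p = _progeny_freqs(X, parents)
        model = PopulationModel(freq=p, c=self.c, d=self.d)
        priors, flags = mapping_priors(X, design, ploidy, model)
        lik = genotype_likelihoods(X, ploidy, model)
        if self.use_ld:
            pre = posterior_mean(posterior(priors, lik))
            priors = ld_adjusted_priors(priors, pre, X, cfg, ploidy)
        post = posterior(priors, lik)
        pmg = posterior_mean(post)
        return {
            "posterior": post, "pmg": pmg, "discrete": most_probable(post),
            "model": model, "n_iterations": 1, "converged": True,
            "locus_log_marginal": _locus_log_marginal(priors, lik, X),
            "nonseg_flags": flags,
        }


def _progeny_freqs(dataset: AlleleDepthSet, parents: set) -> np.ndarray:
    mask = np.array([t not in parents and t not in dataset.blank_taxa
                     for t in dataset.taxa])
    asum = dataset.depth[mask].sum(axis=0).astype(float)
    loc_sum = np.zeros(dataset.n_loci)
    np.add.at(loc_sum, dataset.locus_index, asum)
    n_alleles_of = np.bincount(dataset.locus_index)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(loc_sum[dataset.locus_index] > 0,
                     asum / np.where(loc_sum[dataset.locus_index] > 0,
                                     loc_sum[dataset.locus_index], 1),
                     1.0 / n_alleles_of[dataset.locus_index])
    floor = 1.0 / (2.0 * max(int(mask.sum()), 1) * 2)
    p = np.maximum(p, floor)
    sums = np.zeros(dataset.n_loci)
    np.add.at(sums, dataset.locus_index, p)
    return p / sums[dataset.locus_index]


# ---------------------------------------------------------------------------
# functional wrappers

def iterate_hwe(dataset, ploidies=2, c=DEFAULT_CONTAMINATION,
                d=DEFAULT_OVERDISPERSION, s=0.0, tol=DEFAULT_TOL,
                max_iter=DEFAULT_MAX_ITER, use_ld=False,
                ld_config=None) -> PipelineResult:
    """Run the iterative HWE pipeline; see :class:`HWEGenotyper`."""
    est = HWEGenotyper(ploidies, c, d, s, tol, max_iter, use_ld, ld_config)
    return est.fit(dataset).result_


def iterate_popstruct(dataset, ploidies=2, c=DEFAULT_CONTAMINATION,
                      d=DEFAULT_OVERDISPERSION, s=0.0, n_axes=None,
                      tol=DEFAULT_TOL, max_iter=DEFAULT_MAX_ITER,
                      use_ld=False, ld_config=None) -> PipelineResult:
    """Run the population-structure pipeline; see :class:`PopStructGenotyper`."""
    est = PopStructGenotyper(ploidies, c, d, s, n_axes, tol, max_iter,
                             use_ld, ld_config)
    return est.fit(dataset).result_


def run_mapping(dataset, design: CrossDesign, ploidies=2,
                c=DEFAULT_CONTAMINATION, d=DEFAULT_OVERDISPERSION,
                use_ld=False, ld_config=None) -> PipelineResult:
    """Run the one-pass mapping pipeline; see :class:`MappingGenotyper`."""
    est = MappingGenotyper(design.parent1, design.parent2, ploidies, c, d,
                           design.generations_selfing,
                           design.generations_backcross,
                           design.recurrent_parent,
                           design.generations_intermating, use_ld, ld_config)
    return est.fit(dataset).result_
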