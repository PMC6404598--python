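"""Genotype prior probabilities.

Priors over allele copy number come from one of four population models:

* Hardy-Weinberg equilibrium — Binomial(k, p), optionally pushed to the
  fixed point of a partial-selfing recursion;
* population structure — per-individual allele frequencies fitted by
  regressing scaled dosages on principal-component axes, then binomial
  priors in those individual frequencies;
* linkage — a mixture of a base prior with a binomial prior in a
  pseudo-frequency predicted from correlated alleles at nearby loci;
* mapping populations — the exact segregation distribution of a biparental
  cross (polysomic gametes drawn hypergeometrically without double
  reduction; allopolyploid subgenomes handled disomically), propagated
  through any number of generations of backcrossing, intermating and
  selfing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import binom as _binom

from .data import (AlleleDepthSet, DosageMatrix, GenotypeProbArray,
                   PloidyHypothesis, PopulationModel)

__all__ = [
    "CrossDesign",
    "LinkageConfig",
    "hwe_prior",
    "hwe_priors_matrix",
    "binomial_priors_from_freqs",
    "popstruct_individual_freqs",
    "ld_adjusted_priors",
    "mapping_priors",
    "update_allele_freqs",
    "gamete_distribution",
    "selfing_transition_matrix",
    "progeny_dosage_distribution",
    "default_n_axes",
]

_FIXPOINT_TOL = 1e-12
_FIXPOINT_MAX_ITER = 200


@dataclass
class CrossDesign:
    """A biparental mapping-population design.

    An F1 when all generation counts are zero; ``generations_selfing`` selfs
    the progeny that many times (F2 = one generation), ``generations_backcross``
    crosses back to ``recurrent_parent`` first, and ``generations_intermating``
    randomly mates the progeny among themselves. Generations are applied in
    the order backcross, intermate, self.
    """

    parent1: str
    parent2: str
    generations_selfing: int = 0
    generations_backcross: int = 0
    recurrent_parent: str | None = None
    generations_intermating: int = 0

    def __post_init__(self):
        if min(self.generations_selfing, self.generations_backcross,
               self.generations_intermating) < 0:
            raise ValueError("generation counts must be >= 0")
        if self.generations_backcross > 0:
            if self.recurrent_parent not in (self.parent1, self.parent2):
                raise ValueError("recurrent_parent must be one of the parents")


@dataclass
class LinkageConfig:
    """Search window and mixture weight for LD-informed priors."""

    ld_distance: int = 10_000
    max_neighbors: int = 10
    mix_weight: float = 0.5

    def __post_init__(self):
        if self.ld_distance <= 0:
            raise ValueError("ld_distance must be > 0 basepairs")
        if self.max_neighbors < 1:
            raise ValueError("max_neighbors must be >= 1")
        if not (0 <= self.mix_weight <= 1):
            raise ValueError("mix_weight must be in [0, 1]")


# ---------------------------------------------------------------------------
# gametes and selfing

@lru_cache(maxsize=None)
def gamete_distribution(i: int, k: int) -> tuple:
    """Polysomic gamete: draw k/2 chromosomes without replacement.

    Returns P(gamete carries j copies) for j = 0..k/2, a hypergeometric in
    the parental dosage i. No double reduction.
    """
    if k % 2 != 0:
        raise ValueError("gamete formation requires an even ploidy")
    if not (0 <= i <= k):
        raise ValueError("dosage must be within 0..k")
    half = k // 2
    denom = math.comb(k, half)
    return tuple(math.comb(i, j) * math.comb(k - i, half - j) / denom
                 for j in range(half + 1))


@lru_cache(maxsize=None)
def selfing_transition_matrix(k: int) -> np.ndarray:
    """S[j, i] = P(selfed offspring dosage j | parent dosage i), ploidy k."""
    S = np.zeros((k + 1, k + 1))
    for i in range(k + 1):
        g = np.array(gamete_distribution(i, k))
        S[: 2 * (k // 2) + 1, i] = np.convolve(g, g)
    return S


def _selfing_fixed_point(base: np.ndarray, k: int, s: float) -> np.ndarray:
    """Fixed point of prior <- (1-s) * base + s * Self(prior).

    ``base`` may be (k+1,) or (..., k+1); iterated to 1e-9 or 100 rounds.
    """
    S = selfing_transition_matrix(k)
    prior = np.array(base, dtype=float)
    for _ in range(_FIXPOINT_MAX_ITER):
        nxt = (1.0 - s) * base + s * (prior @ S.T)
        if np.max(np.abs(nxt - prior)) < _FIXPOINT_TOL:
            prior = nxt
            break
        prior = nxt
    return prior


def _binom_vec(k: int, p) -> np.ndarray:
    """Binomial(k, p) pmf over 0..k; p scalar or (...,) -> (..., k+1)."""
    i = np.arange(k + 1)
    p = np.asarray(p, dtype=float)
    return _binom.pmf(i, k, p[..., None] if p.ndim else p)


def _convolve_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise polynomial product of (..., m) with (..., n)."""
    m, n = x.shape[-1], y.shape[-1]
    out = np.zeros(x.shape[:-1] + (m + n - 1,))
    for j in range(n):
        out[..., j:j + m] += x * y[..., j:j + 1]
    return out


def hwe_prior(p: float, ploidy: PloidyHypothesis, s: float = 0.0) -> np.ndarray:
    """Genotype prior under Hardy-Weinberg equilibrium with partial selfing.

    With s = 0 this is Binomial(k, p) (identical for auto- and allopolyploid
    hypotheses of the same total ploidy, by Vandermonde's identity). With
    s > 0, each subgenome's binomial is driven to the fixed point of the
    inbreeding recursion prior <- (1-s)*Binomial + s*Self(prior), where
    selfing convolves two independent polysomic gametes; subgenome fixed
    points are then convolved. Selfing redistributes mass toward homozygous
    dosages but never shifts the mean away from k*p.
    """
    ploidy = PloidyHypothesis.parse(ploidy)
    if not (0 <= p <= 1):
        raise ValueError("allele frequency must be in [0, 1]")
    if not (0 <= s <= 1):
        raise ValueError("selfing rate must be in [0, 1]")
    out = np.array([1.0])
    for k_sub in ploidy.subgenomes:
        sub = _binom_vec(k_sub, p)
        if s > 0:
            if k_sub % 2 != 0:
                raise ValueError("selfing requires even subgenome ploidy")
            sub = _selfing_fixed_point(sub, k_sub, s)
        out = np.convolve(out, sub)
    return out / out.sum()


def hwe_priors_matrix(freqs: np.ndarray, ploidy: PloidyHypothesis,
                      s: float = 0.0) -> np.ndarray:
    """Vectorized :func:`hwe_prior`: (A,) frequencies -> (A, k+1) priors."""
    ploidy = PloidyHypothesis.parse(ploidy)
    freqs = np.asarray(freqs, dtype=float)
    out = np.ones(freqs.shape + (1,))
    for k_sub in ploidy.subgenomes:
        sub = _binom_vec(k_sub, freqs)
        if s > 0:
            if k_sub % 2 != 0:
                raise ValueError("selfing requires even subgenome ploidy")
            sub = _selfing_fixed_point(sub, k_sub, s)
        out = _convolve_rows(out, sub)
    return out / out.sum(axis=-1, keepdims=True)


def binomial_priors_from_freqs(ind_freq: np.ndarray, ploidy: PloidyHypothesis,
                               s: float = 0.0) -> GenotypeProbArray:
    """Per-individual priors from a taxa x alleles frequency matrix."""
    values = hwe_priors_matrix(ind_freq, ploidy, s)
    return GenotypeProbArray(values, kind="prior")


# ---------------------------------------------------------------------------
# population structure

def default_n_axes(Xc: np.ndarray, cap: int = 10, n_perm: int = 3,
                   margin: float = 1.05, seed: int = 12345) -> int:
    """Number of significant PCA axes by Horn's parallel analysis.

    Leading eigenvalues of the centered matrix are compared against the mean
    eigenvalues of column-permuted copies (which destroy between-individual
    structure but keep each allele's marginal noise); axes are kept while
    they beat the permutation baseline at the same rank by ``margin`` (the
    usual guard against the baseline's own sampling noise). Scaled-dosage
    PCA has depth-dependent heteroscedastic noise, so a baseline built from
    the data itself separates real structure from noise where an
    exchangeability assumption (e.g. broken stick) keeps spurious axes.
    Returns 0 when no axis beats the baseline.
    """
    rng = np.random.default_rng(seed)
    ev = np.linalg.svd(Xc, compute_uv=False) ** 2
    if ev.sum() <= 0:
        return 0
    perm = np.zeros_like(ev)
    for _ in range(n_perm):
        Xp = rng.permuted(Xc, axis=0)
        perm += np.linalg.svd(Xp, compute_uv=False) ** 2
    perm /= n_perm
    n = 0
    for j in range(min(cap, len(ev))):
        if ev[j] > margin * perm[j]:
            n += 1
        else:
            break
    return n


def popstruct_individual_freqs(pmg: DosageMatrix, dataset: AlleleDepthSet,
                               ploidy: PloidyHypothesis,
                               n_axes: int | None = None,
                               clamp_eps: float | None = None) -> np.ndarray:
    """Individual-specific allele frequencies from population structure.

    Scaled dosages pmg/k are centered per allele and decomposed by PCA
    across individuals; each allele's scaled dosage is then regressed on the
    leading axis scores, and the fitted values — smooth functions of where
    an individual sits in the structure — become its personal allele
    frequencies, clamped away from 0 and 1 and renormalized within each
    locus. With no structure (no axis retained or no variance) this
    degrades to the global allele frequency for everyone.
    """
    ploidy = PloidyHypothesis.parse(ploidy)
    k = ploidy.k
    X = np.asarray(pmg.values, dtype=float) / k          # (T, A)
    n_taxa = X.shape[0]
    if clamp_eps is None:
        clamp_eps = 1.0 / (2.0 * n_taxa * k)
    mean = X.mean(axis=0)
    Xc = X - mean
    # one representative allele per locus: within a locus the allele columns
    # are linearly dependent (dosages sum to k), and duplicated columns
    # would inflate every eigenvalue relative to any noise baseline
    _, rep = np.unique(dataset.locus_index, return_index=True)
    Xr = Xc[:, rep]
    if n_axes is None:
        n_axes = default_n_axes(Xr)
    if n_taxa < n_axes + 1:
        raise ValueError("need more individuals than principal axes")
    if n_axes > 0:
        # economy SVD across individuals; axes = left singular vectors
        U, sv, _ = np.linalg.svd(Xr, full_matrices=False)
        n_axes = min(n_axes, len(sv))
        scores = U[:, :n_axes] * sv[:n_axes]             # (T, n_axes)
        design = np.column_stack([np.ones(n_taxa), scores])
    else:
        design = np.ones((n_taxa, 1))                    # intercept only
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    fitted = design @ beta
    fitted = np.clip(fitted, clamp_eps, 1.0 - clamp_eps)

    # renormalize within each locus so each individual's frequencies sum to 1
    sums = np.zeros((n_taxa, dataset.n_loci))
    for j in range(dataset.n_alleles):
        sums[:, dataset.locus_index[j]] += fitted[:, j]
    fitted = fitted / sums[:, dataset.locus_index]
    return fitted


# ---------------------------------------------------------------------------
# linkage

def ld_adjusted_priors(base_priors: GenotypeProbArray, pmg: DosageMatrix,
                       dataset: AlleleDepthSet, cfg: LinkageConfig,
                       ploidy: PloidyHypothesis) -> GenotypeProbArray:
    """Blend base priors with predictions from correlated nearby alleles.

    For each allele, up to ``max_neighbors`` alleles at *other* loci within
    ``ld_distance`` bp with the largest absolute Pearson correlation of
    dosages are used in a least-squares prediction of the target dosage;
    each individual's prediction, scaled to a pseudo-frequency, drives a
    binomial prior that is mixed with the base prior at weight
    ``mix_weight``. Alleles with no usable neighbor keep their base prior
    unchanged, as does everything when the mixture weight is zero.
    """
    if dataset.locus_pos is None:
        raise ValueError(
            "dataset has no genomic positions; use a pipeline without LD")
    ploidy = PloidyHypothesis.parse(ploidy)
    k = ploidy.k
    w = cfg.mix_weight
    values = base_priors.values.copy()
    if w == 0:
        return GenotypeProbArray(values, kind="prior")

    X = np.asarray(pmg.values, dtype=float)              # (T, A)
    n_taxa, n_alleles = X.shape
    eps = 1.0 / (2.0 * n_taxa * k)

    pos = np.array([dataset.locus_pos.get(l, -1) for l in dataset.loci])
    chrom = [None if dataset.locus_chrom is None
             else dataset.locus_chrom.get(l) for l in dataset.loci]
    al_pos = pos[dataset.locus_index]
    al_chrom = [chrom[li] for li in dataset.locus_index]

    sd = X.std(axis=0)
    Xc = X - X.mean(axis=0)

    for j in range(n_alleles):
        same_chrom = np.array([al_chrom[j] is not None and c == al_chrom[j]
                               for c in al_chrom])
        near = (same_chrom
                & (np.abs(al_pos - al_pos[j]) <= cfg.ld_distance)
                & (dataset.locus_index != dataset.locus_index[j]))
        cand = np.nonzero(near & (sd > 0))[0]
        if cand.size == 0 or sd[j] == 0:
            continue
        r = (Xc[:, cand].T @ Xc[:, j]) / (n_taxa * sd[cand] * sd[j])
        order = np.argsort(-np.abs(r))[: cfg.max_neighbors]
        nb = cand[order]
        design = np.column_stack([np.ones(n_taxa), X[:, nb]])
        beta, *_ = np.linalg.lstsq(design, X[:, j], rcond=None)
        pred = design @ beta
        q = np.clip(pred / k, eps, 1.0 - eps)
        ld_prior = _binom_vec(k, q)                      # (T, k+1)
        values[:, j, :] = (1.0 - w) * values[:, j, :] + w * ld_prior
    values /= values.sum(axis=2, keepdims=True)
    return GenotypeProbArray(values, kind="prior")


# ---------------------------------------------------------------------------
# mapping populations

def _allo_gamete_distribution(i: int, ploidy: PloidyHypothesis) -> np.ndarray:
    """Gamete dosage pmf for an allopolyploid parent with total dosage i.

    Parental allele copies are assigned to subgenomes uniformly over all
    consistent placements (hypergeometric weights, since no phasing is
    available); each subgenome contributes a disomic/polysomic gamete and the
    subgenome gametes convolve.
    """
    import itertools

    subs = ploidy.subgenomes
    half = ploidy.k // 2
    out = np.zeros(half + 1)
    total_w = 0.0
    for split in itertools.product(*(range(min(ks, i) + 1) for ks in subs)):
        if sum(split) != i:
            continue
        w = 1.0
        for i_s, k_s in zip(split, subs):
            w *= math.comb(k_s, i_s)
        g = np.array([1.0])
        for i_s, k_s in zip(split, subs):
            g = np.convolve(g, gamete_distribution(i_s, k_s))
        out += w * g          # g has length half + 1 by construction
        total_w += w
    return out / total_w


def parent_gamete_distribution(i: int, ploidy: PloidyHypothesis) -> np.ndarray:
    """Gamete dosage pmf (length k/2 + 1) for a parent with dosage i."""
    ploidy = PloidyHypothesis.parse(ploidy)
    if ploidy.k % 2 != 0:
        raise ValueError("gamete formation requires an even total ploidy")
    if len(ploidy.subgenomes) == 1:
        return np.array(gamete_distribution(i, ploidy.k))
    return _allo_gamete_distribution(i, ploidy)


def _gamete_pool(dist: np.ndarray, ploidy: PloidyHypothesis) -> np.ndarray:
    """Population gamete pmf from a genotype-dosage pmf."""
    k = ploidy.k
    pool = np.zeros(k // 2 + 1)
    for i, w in enumerate(dist):
        if w > 0:
            pool += w * parent_gamete_distribution(i, ploidy)
    return pool


def progeny_dosage_distribution(d1: int, d2: int, ploidy: PloidyHypothesis,
                                design: CrossDesign | None = None) -> np.ndarray:
    """Dosage pmf of the progeny of a cross, after any later generations.

    The F1 distribution is the convolution of the two parents' gamete
    distributions. Backcross generations cross the current population to the
    recurrent parent, intermating generations randomly mate it with itself,
    and selfing generations self every individual; each step acts on the
    dosage pmf.
    """
    ploidy = PloidyHypothesis.parse(ploidy)
    k = ploidy.k
    g1 = parent_gamete_distribution(d1, ploidy)
    g2 = parent_gamete_distribution(d2, ploidy)
    dist = np.convolve(g1, g2)
    dist = np.pad(dist, (0, k + 1 - len(dist)))
    if design is None:
        return dist

    d_rec = d1 if design.recurrent_parent == design.parent1 else d2
    for _ in range(design.generations_backcross):
        pool = _gamete_pool(dist, ploidy)
        dist = np.convolve(pool, parent_gamete_distribution(d_rec, ploidy))
        dist = np.pad(dist, (0, k + 1 - len(dist)))
    for _ in range(design.generations_intermating):
        pool = _gamete_pool(dist, ploidy)
        dist = np.pad(np.convolve(pool, pool), (0, 0))
        dist = np.pad(dist, (0, k + 1 - len(dist)))
    S = selfing_transition_matrix(k) if design.generations_selfing else None
    for _ in range(design.generations_selfing):
        dist = S @ dist
    return dist / dist.sum()


def call_parent_dosages(dataset: AlleleDepthSet, parent: str,
                        ploidy: PloidyHypothesis,
                        model: PopulationModel) -> np.ndarray:
    """Maximum-likelihood dosage per allele for one parent, uniform prior."""
    from .likelihood import betabinom_likelihood  # local to avoid cycle

    ploidy = PloidyHypothesis.parse(ploidy)
    k = ploidy.k
    ti = dataset.taxon_index(parent)
    a = dataset.depth[ti].astype(float)
    b = dataset.other_allele_counts()[ti].astype(float)
    i = np.arange(k + 1, dtype=float)
    pi = (1.0 - model.c) * i[None, :] / k + model.c * model.freq[:, None]
    lik = betabinom_likelihood(a[:, None], b[:, None], pi, model.d)
    return np.argmax(lik, axis=1)


def mapping_priors(dataset: AlleleDepthSet, design: CrossDesign,
                   ploidy: PloidyHypothesis, model: PopulationModel):
    """Segregation priors for a biparental mapping population.

    Parental dosages are called by maximum likelihood from the parents' own
    read depth (uniform priors, to avoid circularity with the progeny); each
    allele's progeny prior is the cross's dosage distribution, identical
    across progeny. Parents receive point-mass priors at their called
    dosages. Fallbacks to HWE priors from progeny frequencies: loci where a
    parent has zero depth, and loci flagged non-segregating (both parents
    called homozygous for the same allele while the progeny minor-allele
    frequency exceeds 3c, which contradicts the calls).

    Returns ``(priors, flags)`` where ``flags`` is a per-locus boolean array
    marking the fallback loci.
    """
    ploidy = PloidyHypothesis.parse(ploidy)
    k = ploidy.k
    for par in (design.parent1, design.parent2):
        if par not in dataset.taxa:
            raise KeyError(f"parent {par!r} not found in dataset")

    d1 = call_parent_dosages(dataset, design.parent1, ploidy, model)
    d2 = call_parent_dosages(dataset, design.parent2, ploidy, model)
    p1i = dataset.taxon_index(design.parent1)
    p2i = dataset.taxon_index(design.parent2)
    parent_rows = {p1i, p2i}

    totals = dataset.locus_totals()
    p1_cov = totals[p1i] > 0                              # per locus
    p2_cov = totals[p2i] > 0

    # progeny allele frequencies from raw depth ratios (parents excluded)
    prog = np.array([i not in parent_rows and t not in dataset.blank_taxa
                     for i, t in enumerate(dataset.taxa)])
    asum = dataset.depth[prog].sum(axis=0).astype(float)
    loc_sum = np.zeros(dataset.n_loci)
    np.add.at(loc_sum, dataset.locus_index, asum)
    with np.errstate(invalid="ignore", divide="ignore"):
        prog_freq = np.where(loc_sum[dataset.locus_index] > 0,
                             asum / loc_sum[dataset.locus_index],
                             1.0 / np.bincount(dataset.locus_index)[dataset.locus_index])

    flags = np.zeros(dataset.n_loci, dtype=bool)
    flags |= ~(p1_cov & p2_cov)
    # non-segregating check: both parents homozygous for the same allele but
    # the progeny still shows the other alleles well above contamination level
    for li in range(dataset.n_loci):
        cols = np.nonzero(dataset.locus_index == li)[0]
        hom1 = np.nonzero(d1[cols] == k)[0]
        hom2 = np.nonzero(d2[cols] == k)[0]
        if hom1.size and hom2.size and hom1[0] == hom2[0]:
            maf = 1.0 - prog_freq[cols[hom1[0]]]
            if maf > 3.0 * model.c:
                flags[li] = True

    values = np.empty((dataset.n_taxa, dataset.n_alleles, k + 1))
    hwe_fallback = hwe_priors_matrix(prog_freq, ploidy, s=0.0)
    for j in range(dataset.n_alleles):
        li = dataset.locus_index[j]
        if flags[li]:
            vec = hwe_fallback[j]
        else:
            vec = progeny_dosage_distribution(int(d1[j]), int(d2[j]),
                                              ploidy, design)
        values[:, j, :] = vec
    # parents: point mass at the called dosage (only where covered)
    for pi_row, dos in ((p1i, d1), (p2i, d2)):
        values[pi_row, :, :] = 0.0
        values[pi_row, np.arange(dataset.n_alleles), dos] = 1.0
    values = np.clip(values, 0.0, None)
    values /= values.sum(axis=2, keepdims=True)
    return GenotypeProbArray(values, kind="prior"), flags


# ---------------------------------------------------------------------------
# allele frequencies

def update_allele_freqs(pmg: DosageMatrix, dataset: AlleleDepthSet,
                        ploidy: PloidyHypothesis,
                        exclude: set | None = None) -> np.ndarray:
    """Allele frequencies as the mean scaled dosage across individuals.

    Blank taxa (and any extra taxa in ``exclude``, e.g. mapping parents) are
    left out; frequencies are renormalized within each locus.
    """
    ploidy = PloidyHypothesis.parse(ploidy)
    skip = set(dataset.blank_taxa) | (exclude or set())
    mask = np.array([t not in skip for t in dataset.taxa])
    p = np.asarray(pmg.values)[mask].mean(axis=0) / ploidy.k
    sums = np.zeros(dataset.n_loci)
    np.add.at(sums, dataset.locus_index, p)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(sums[dataset.locus_index] > 0,
                     p / sums[dataset.locus_index], p)
    return p
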