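"""Beta-binomial read-depth likelihoods.

Each sequencing read at a locus is a Bernoulli trial: success means the read
matches the allele under consideration. With allele copy number i, ploidy k,
population allele frequency p and cross-contamination rate c, the success
probability is

    pi_i = (1 - c) * i / k + c * p.

Allelic depth is overdispersed relative to a binomial (unequal contamination,
cut-site variation, size selection), so the count of successes a out of a + b
reads is modelled as beta-binomial with parameters (d * pi, d * (1 - pi)):
smaller d means more overdispersion, and d -> infinity recovers the binomial.
All probability-mass arithmetic runs in log space via log-gamma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln
from scipy.stats import betabinom as _sp_betabinom
from scipy.stats import kstest

from .data import AlleleDepthSet, GenotypeProbArray, PloidyHypothesis, PopulationModel

__all__ = [
    "read_success_prob",
    "betabinom_likelihood",
    "genotype_likelihoods",
    "estimate_contamination",
    "test_overdispersion",
    "OverdispersionReport",
    "DEFAULT_OVERDISPERSION",
    "DEFAULT_CONTAMINATION",
]

DEFAULT_OVERDISPERSION = 9.0
DEFAULT_CONTAMINATION = 0.001


def read_success_prob(i, k, p, c):
    """Probability that a read matches an allele present in i of k copies.

    Vectorized over all arguments; raises on copy numbers outside 0..k.
    """
    i = np.asarray(i)
    if (i < 0).any() or (i > np.asarray(k)).any():
        raise ValueError("allele copy number i must satisfy 0 <= i <= k")
    return (1.0 - c) * i / k + c * np.asarray(p)


def _betabinom_logpmf(a, b, pi, d):
    """log beta-binomial pmf; inputs broadcast, pi strictly inside (0, 1)."""
    n = a + b
    choose = gammaln(n + 1) - gammaln(a + 1) - gammaln(b + 1)
    return (choose
            + betaln(d * pi + a, d * (1.0 - pi) + b)
            - betaln(d * pi, d * (1.0 - pi)))


def betabinom_likelihood(a, b, pi, d):
    """Beta-binomial probability of a reads of an allele and b of others.

    Degenerate success probabilities are evaluated as their limits: at
    pi = 0 the mass sits on a = 0, at pi = 1 on b = 0. Zero total depth
    returns 1 (no evidence). Vectorized; scalar inputs give a scalar.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if not np.issubdtype(a.dtype, np.number) or not np.issubdtype(b.dtype, np.number):
        raise ValueError("counts must be numeric")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be >= 0")
    if not (np.allclose(a, np.round(a)) and np.allclose(b, np.round(b))):
        raise ValueError("counts must be integers")
    if np.any(np.asarray(d) <= 0):
        raise ValueError("overdispersion d must be > 0")

    a, b, pi, d_arr = np.broadcast_arrays(
        a.astype(float), b.astype(float), np.asarray(pi, dtype=float),
        np.asarray(d, dtype=float))
    out = np.zeros(a.shape, dtype=float)

    lo = pi <= 0.0
    hi = pi >= 1.0
    mid = ~(lo | hi)
    if mid.any():
        out[mid] = np.exp(_betabinom_logpmf(a[mid], b[mid], pi[mid], d_arr[mid]))
    out[lo] = (a[lo] == 0).astype(float)
    out[hi] = (b[hi] == 0).astype(float)
    return out if out.shape else float(out)


def genotype_likelihoods(dataset: AlleleDepthSet, ploidy: PloidyHypothesis,
                         model: PopulationModel) -> GenotypeProbArray:
    """Per-taxon, per-allele likelihood of each allele copy number 0..k.

    Genotypes with zero reads get an all-ones vector (no information). If the
    model carries individual-specific frequencies, the contamination term of
    the success probability uses them; otherwise the population frequency.
    """
    k = ploidy.k
    a = dataset.depth.astype(float)                     # (T, A)
    b = dataset.other_allele_counts().astype(float)     # (T, A)
    if model.ind_freq is not None:
        p = np.asarray(model.ind_freq, dtype=float)     # (T, A)
    else:
        p = np.broadcast_to(model.freq, a.shape)        # (T, A)

    i = np.arange(k + 1, dtype=float)
    pi = (1.0 - model.c) * i[None, None, :] / k + model.c * p[:, :, None]
    values = betabinom_likelihood(a[:, :, None], b[:, :, None], pi, model.d)
    values = np.asarray(values)
    zero = (a + b) == 0
    values[zero] = 1.0
    return GenotypeProbArray(values, kind="likelihood")


def estimate_contamination(dataset: AlleleDepthSet) -> float:
    """Contamination rate from no-template (blank barcode) controls.

    Mean total read depth of blank taxa divided by mean total depth of
    non-blank taxa, clamped to [1e-6, 0.5). Blanks carry an adapter barcode
    but no genomic DNA, so any reads they receive measure cross-sample
    contamination during library preparation.
    """
    if not dataset.blank_taxa:
        raise ValueError(
            "no blank taxa flagged; supply the contamination rate c directly")
    totals = dataset.depth.sum(axis=1).astype(float)
    blank = np.array([t in dataset.blank_taxa for t in dataset.taxa])
    if blank.all():
        raise ValueError("dataset contains only blank taxa")
    c = totals[blank].mean() / totals[~blank].mean()
    return float(np.clip(c, 1e-6, 0.5 - 1e-12))


@dataclass
class OverdispersionReport:
    """Goodness-of-fit scores for candidate overdispersion values.

    ``scores[i]`` is the Kolmogorov-Smirnov distance from uniformity of the
    randomized read-count quantiles under ``candidates[i]``; ``selected_d``
    minimizes it (ties go to the smaller candidate).
    """

    candidates: list
    scores: list
    selected_d: float


def test_overdispersion(dataset: AlleleDepthSet, ploidy: PloidyHypothesis,
                        model: PopulationModel, candidates,
                        seed: int | None = None) -> OverdispersionReport:
    """Pick the overdispersion parameter that best fits the read counts.

    For each candidate d, every genotype with nonzero depth is assigned a
    copy number drawn from its posterior under that d (Hardy-Weinberg
    priors in the model's allele frequencies; sampling rather than argmax,
    because conditioning on the most-likely genotype absorbs extreme read
    ratios into extreme dosage classes and systematically understates the
    dispersion). The observed allele-read count is then converted to a
    randomized quantile of its assigned beta-binomial (a uniform draw
    within the discrete pmf step, making the quantiles continuous), and the
    candidate is scored by the Kolmogorov-Smirnov distance of those
    quantiles from Uniform(0, 1); the minimizer wins, ties going to the
    smaller d. A well-calibrated d leaves no excess or deficit of extreme
    read-depth ratios. The random draws are shared across candidates so the
    scores are comparable.
    """
    candidates = [float(x) for x in candidates]
    if not candidates or any(x <= 0 for x in candidates):
        raise ValueError("candidates must be non-empty and > 0")
    rng = np.random.default_rng(seed)
    k = ploidy.k

    a = dataset.depth.astype(float)
    b = dataset.other_allele_counts().astype(float)
    nz = (a + b) > 0
    if not nz.any():
        raise ValueError("no genotypes with nonzero read depth")
    a_nz, b_nz = a[nz], b[nz]
    n_nz = a_nz + b_nz
    if model.ind_freq is not None:
        p_nz = np.broadcast_to(model.ind_freq, a.shape)[nz]
    else:
        p_nz = np.broadcast_to(model.freq, a.shape)[nz]
    from .priors import hwe_priors_matrix  # local import to avoid a cycle

    prior = hwe_priors_matrix(p_nz, ploidy, model.s)
    v = rng.uniform(size=a_nz.shape)       # quantile randomization
    v2 = rng.uniform(size=a_nz.shape)      # genotype-assignment draw

    i_grid = np.arange(k + 1, dtype=float)
    pi_all = (1.0 - model.c) * i_grid[None, :] / k + model.c * p_nz[:, None]

    scores = []
    for d in candidates:
        lik = betabinom_likelihood(a_nz[:, None], b_nz[:, None], pi_all, d)
        w = prior * lik
        w /= w.sum(axis=1, keepdims=True)
        drawn = (w.cumsum(axis=1) < v2[:, None]).sum(axis=1)
        pi = pi_all[np.arange(len(drawn)), drawn]
        u = np.empty_like(a_nz)
        interior = (pi > 0) & (pi < 1)
        if interior.any():
            alpha = d * pi[interior]
            beta = d * (1.0 - pi[interior])
            hi = _sp_betabinom.cdf(a_nz[interior], n_nz[interior], alpha, beta)
            lo = _sp_betabinom.cdf(a_nz[interior] - 1, n_nz[interior], alpha, beta)
            u[interior] = lo + v[interior] * (hi - lo)
        # degenerate point masses contribute a pure uniform draw
        u[~interior] = v[~interior]
        scores.append(float(kstest(u, "uniform").statistic))

    order = np.lexsort((candidates, scores))
    return OverdispersionReport(candidates, scores, candidates[order[0]])
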