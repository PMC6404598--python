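"""Bayes combination of genotype priors and likelihoods, and dosage export.

Posteriors are computed in linear space (at most ~9 states per genotype, so
no overflow risk once each vector is normalized). Genotypes with zero reads
carry an all-ones likelihood, so their posterior is exactly the prior —
missing data is imputed from the prior within the same paradigm.
"""

from __future__ import annotations

import warnings

import numpy as np

from .data import DosageMatrix, GenotypeProbArray

__all__ = ["posterior", "posterior_mean", "most_probable"]


def posterior(priors: GenotypeProbArray,
              likelihoods: GenotypeProbArray) -> GenotypeProbArray:
    """Posterior probability of each allele copy number.

    ``post[i] = L_i * P_i / sum_j L_j * P_j`` per taxon x allele. Rows whose
    likelihood vector is constant (no reads, hence no evidence) return the
    prior bit-for-bit. Rows where the prior puts all mass on
    likelihood-zero states are inconsistent (e.g. a contaminated outlier in
    a mapping population); they fall back to the prior with a warning rather
    than failing.
    """
    P = priors.values
    L = likelihoods.values
    if P.shape != L.shape:
        raise ValueError("priors and likelihoods must have the same shape")

    prod = P * L
    norm = prod.sum(axis=2, keepdims=True)
    constant = np.ptp(L, axis=2) < 1e-300          # all-equal likelihood rows
    bad = (norm[..., 0] <= 0) & ~constant
    if bad.any():
        warnings.warn(f"{int(bad.sum())} genotypes have priors inconsistent "
                      "with their read depth; posterior set to prior",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = prod / norm
    fallback = constant | bad
    out[fallback] = P[fallback]
    return GenotypeProbArray(out, kind="posterior")


def posterior_mean(post: GenotypeProbArray) -> DosageMatrix:
    """Posterior mean genotype: expected allele copy number, in [0, k].

    The continuous export value — e.g. a posterior of (0.6, 0.4, 0) over a
    diploid's copy numbers gives 0.4, carrying the 40% heterozygote
    probability into downstream analyses instead of a hard 0 call.
    """
    if post.kind != "posterior":
        raise ValueError("expected a posterior probability array")
    i = np.arange(post.k + 1, dtype=float)
    return DosageMatrix(post.values @ i, k=post.k, discrete=False)


def most_probable(post: GenotypeProbArray) -> DosageMatrix:
    """Most probable allele copy number; ties broken toward the smaller."""
    if post.kind != "posterior":
        raise ValueError("expected a posterior probability array")
    vals = np.argmax(post.values, axis=2).astype(float)
    return DosageMatrix(vals, k=post.k, discrete=True)
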