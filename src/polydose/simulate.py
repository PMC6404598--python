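"""Synthetic truth genotypes and RAD-seq-like allelic read depth, plus RMSE.

The depth model mirrors typical restriction-enzyme library behavior: overall
locus depth is Gamma(shape=2, scale=5) (mean 10, long right tail, so some
loci are far better sequenced than others), an individual's depth at a locus
is Gamma with shape = locus depth / 10 and scale = 10 rounded to an integer
(which leaves many genotypes at zero reads — the high-missing-data regime
these methods exist for), and allelic counts are beta-binomial with
overdispersion d = 9 and contamination c = 0.001 around the expected allelic
ratio of the true dosage. Truth dosages come from HWE, a structured
population (hierarchical Balding-Nichols frequencies), partial selfing, or
an F1 cross.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import AlleleDepthSet, DosageMatrix, PloidyHypothesis
from .priors import hwe_prior, progeny_dosage_distribution

__all__ = ["SimulationConfig", "TruthSet", "simulate_truth_genotypes",
           "simulate_depths", "simulate", "rmse"]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic panel.

    population is one of ``hwe``, ``structured`` (with ``n_subpops`` and
    ``fst``), ``selfing`` (with ``selfing_rate``) or ``f1`` (with
    ``parental_dosages``; parents are prepended as the first two taxa).
    Allele frequencies are drawn uniformly on (0.05, 0.95) unless
    ``allele_freqs`` supplies them. Depth parameters default to the
    RAD-seq-like regime described in the module docstring.
    """

    n_taxa: int = 200
    n_loci: int = 100
    ploidy: PloidyHypothesis | int = 2
    population: str = "hwe"
    n_subpops: int = 2
    fst: float = 0.3
    selfing_rate: float = 0.0
    parental_dosages: tuple[int, int] = (1, 1)
    allele_freqs: np.ndarray | None = None
    freq_low: float = 0.05
    freq_high: float = 0.95
    locus_depth_shape: float = 2.0
    locus_depth_scale: float = 5.0
    ind_depth_scale: float = 10.0
    d: float = 9.0
    c: float = 0.001
    parent_depth: float | None = None
    locus_spacing_bp: int = 10_000
    seed: int | None = None

    def __post_init__(self):
        self.ploidy = PloidyHypothesis.parse(self.ploidy)
        if self.n_taxa < 1 or self.n_loci < 1:
            raise ValueError("n_taxa and n_loci must be >= 1")
        for name in ("locus_depth_shape", "locus_depth_scale", "ind_depth_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.population not in ("hwe", "structured", "selfing", "f1"):
            raise ValueError(f"unknown population model: {self.population}")


@dataclass
class TruthSet:
    """Simulated truth dosages with the read-depth dataset derived from them."""

    genotypes: np.ndarray          # taxa x alleles integer dosages
    dataset: AlleleDepthSet
    freqs: np.ndarray              # per-allele truth frequencies used
    config: SimulationConfig
    subpop: np.ndarray | None = None

    def truth_dosage_matrix(self) -> DosageMatrix:
        return DosageMatrix(self.genotypes.astype(float),
                            k=self.config.ploidy.k, discrete=True)


def _locus_freqs(cfg: SimulationConfig, rng) -> np.ndarray:
    if cfg.allele_freqs is not None:
        p = np.asarray(cfg.allele_freqs, dtype=float)
        if len(p) != cfg.n_loci:
            raise ValueError("allele_freqs must have one entry per locus")
        return p
    return rng.uniform(cfg.freq_low, cfg.freq_high, size=cfg.n_loci)


def simulate_truth_genotypes(cfg: SimulationConfig,
                             rng: np.random.Generator | None = None):
    """Draw truth dosages for biallelic loci under the population model.

    Returns ``(genotypes, freqs, subpop)``: dosages of the first allele per
    taxon x locus, the per-locus frequency of that allele, and (for
    structured populations) each individual's subpopulation index.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    k = cfg.ploidy.k
    p = _locus_freqs(cfg, rng)
    subpop = None

    if cfg.population == "hwe":
        geno = rng.binomial(k, p[None, :].repeat(cfg.n_taxa, axis=0))
    elif cfg.population == "structured":
        F = cfg.fst
        a = p * (1 - F) / F
        b = (1 - p) * (1 - F) / F
        sub_p = rng.beta(a[None, :], b[None, :],
                         size=(cfg.n_subpops, cfg.n_loci))
        subpop = rng.integers(cfg.n_subpops, size=cfg.n_taxa)
        geno = rng.binomial(k, sub_p[subpop])
        p = sub_p.mean(axis=0)
    elif cfg.population == "selfing":
        geno = np.empty((cfg.n_taxa, cfg.n_loci), dtype=np.int64)
        for li in range(cfg.n_loci):
            prior = hwe_prior(p[li], cfg.ploidy, cfg.selfing_rate)
            geno[:, li] = rng.choice(k + 1, size=cfg.n_taxa, p=prior)
    else:  # f1
        d1, d2 = cfg.parental_dosages
        dist = progeny_dosage_distribution(d1, d2, cfg.ploidy)
        n_prog = cfg.n_taxa - 2
        if n_prog < 1:
            raise ValueError("f1 simulation needs n_taxa >= 3 (2 parents)")
        prog = rng.choice(k + 1, size=(n_prog, cfg.n_loci), p=dist)
        geno = np.vstack([np.full((1, cfg.n_loci), d1),
                          np.full((1, cfg.n_loci), d2), prog])
        p = np.full(cfg.n_loci, (dist * np.arange(k + 1)).sum() / k)
    return geno, p, subpop


def simulate_depths(genotypes: np.ndarray, freqs: np.ndarray,
                    cfg: SimulationConfig,
                    rng: np.random.Generator | None = None) -> AlleleDepthSet:
    """Allelic read depth given truth dosages of the first allele per locus.

    Locus depth D_L ~ Gamma(shape, scale); individual total depth
    n ~ round(Gamma(D_L/10, ind_scale)); reads of the first allele
    a ~ BetaBinomial(n, d*pi, d*(1-pi)) with pi from the contamination-aware
    allelic-ratio model; the second allele receives n - a.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_taxa, n_loci = genotypes.shape
    k = cfg.ploidy.k

    D_L = rng.gamma(cfg.locus_depth_shape, cfg.locus_depth_scale, size=n_loci)
    shape = np.maximum(D_L / 10.0, 1e-6)
    n = np.round(rng.gamma(shape[None, :].repeat(n_taxa, axis=0),
                           cfg.ind_depth_scale)).astype(np.int64)
    if cfg.population == "f1" and cfg.parent_depth is not None:
        n[:2, :] = rng.poisson(cfg.parent_depth, size=(2, n_loci))

    pi = (1.0 - cfg.c) * genotypes / k + cfg.c * freqs[None, :]
    a = _betabinom_rvs(n, pi, cfg.d, rng)
    b = n - a

    taxa = [f"sim{t:04d}" for t in range(n_taxa)]
    if cfg.population == "f1":
        taxa[0], taxa[1] = "parent1", "parent2"
    alleles, a2l, chrom, pos = [], {}, {}, {}
    for li in range(n_loci):
        loc = f"L{li:05d}"
        for suffix in ("A", "B"):
            al = f"{loc}_{suffix}"
            alleles.append(al)
            a2l[al] = loc
        chrom[loc] = "1"
        pos[loc] = li * cfg.locus_spacing_bp
    depth = np.empty((n_taxa, 2 * n_loci), dtype=np.int64)
    depth[:, 0::2] = a
    depth[:, 1::2] = b
    return AlleleDepthSet(taxa, alleles, depth, a2l,
                          locus_chrom=chrom, locus_pos=pos)


def _betabinom_rvs(n, pi, d, rng):
    """Beta-binomial sampler via a beta draw per trial set.

    Degenerate allelic ratios (pi = 0 or 1) are point masses at 0 or n.
    """
    q = np.empty_like(pi, dtype=float)
    interior = (pi > 0) & (pi < 1)
    q[interior] = rng.beta(d * pi[interior], d * (1.0 - pi[interior]))
    q[pi <= 0] = 0.0
    q[pi >= 1] = 1.0
    return rng.binomial(n, q)


def simulate(cfg: SimulationConfig) -> TruthSet:
    """Full simulation: truth dosages, then read depths, as one TruthSet.

    The returned genotype matrix covers both alleles of every locus (the
    second allele's dosage is k minus the first's), aligned with the
    dataset's allele columns.
    """
    rng = np.random.default_rng(cfg.seed)
    geno, p, subpop = simulate_truth_genotypes(cfg, rng)
    dataset = simulate_depths(geno, p, cfg, rng)
    k = cfg.ploidy.k
    full = np.empty((cfg.n_taxa, 2 * cfg.n_loci), dtype=np.int64)
    full[:, 0::2] = geno
    full[:, 1::2] = k - geno
    freqs = np.empty(2 * cfg.n_loci)
    freqs[0::2] = p
    freqs[1::2] = 1.0 - p
    return TruthSet(full, dataset, freqs, cfg, subpop)


def rmse(estimates: DosageMatrix | np.ndarray, truth: np.ndarray,
         per_marker: bool = False, zero_read_mask: np.ndarray | None = None):
    """Root mean squared error between estimated and true dosages.

    With ``zero_read_mask`` (True where a genotype had zero reads), returns
    a ``(rmse_with_reads, rmse_zero_reads)`` pair — the genotyping-error and
    imputation-error split. With ``per_marker``, errors are aggregated per
    column instead of overall.
    """
    est = estimates.values if isinstance(estimates, DosageMatrix) else np.asarray(estimates)
    truth = np.asarray(truth, dtype=float)
    if est.shape != truth.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {truth.shape}")
    sq = (est - truth) ** 2

    def _agg(mask=None):
        x = sq if mask is None else np.where(mask, sq, np.nan)
        if per_marker:
            with np.errstate(invalid="ignore"):
                return np.sqrt(np.nanmean(x, axis=0))
        return float(np.sqrt(np.nanmean(x)))

    if zero_read_mask is None:
        return _agg()
    zero_read_mask = np.asarray(zero_read_mask, dtype=bool)
    return _agg(~zero_read_mask), _agg(zero_read_mask)
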