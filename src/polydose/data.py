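"""Core containers for allelic read depth, ploidy, and genotype probabilities.

Read counts live in a dense individuals x alleles integer matrix; alleles are
grouped into loci (a locus has >= 2 alleles, so the "other alleles" count at a
locus is always derivable). Genotype probabilities over allele copy number
0..k are carried as a taxa x alleles x (k+1) array.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AlleleDepthSet",
    "PloidyHypothesis",
    "GenotypeProbArray",
    "PopulationModel",
    "DosageMatrix",
    "counts_for_allele",
    "filter_markers",
]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class PloidyHypothesis:
    """An inheritance-mode hypothesis: one or more subgenomes.

    ``(4,)`` is an autotetraploid with polysomic inheritance; ``(2, 2)`` is an
    allotetraploid with disomic inheritance in each of two subgenomes. All
    subgenomes must share the same ploidy. Total ploidy ``k`` is the sum.
    """

    subgenomes: tuple[int, ...]

    def __post_init__(self):
        subs = tuple(int(s) for s in self.subgenomes)
        object.__setattr__(self, "subgenomes", subs)
        if len(subs) == 0:
            raise ValueError("at least one subgenome required")
        if any(s < 1 for s in subs):
            raise ValueError("subgenome ploidies must be >= 1")
        if len(subs) > 1 and len(set(subs)) > 1:
            raise ValueError("all subgenomes must have the same ploidy")

    @property
    def k(self) -> int:
        """Total ploidy."""
        return sum(self.subgenomes)

    @classmethod
    def parse(cls, spec) -> "PloidyHypothesis":
        """Accept an int, an iterable of ints, or a string like '2,2'."""
        if isinstance(spec, PloidyHypothesis):
            return spec
        if isinstance(spec, int):
            return cls((spec,))
        if isinstance(spec, str):
            return cls(tuple(int(x) for x in spec.replace("+", ",").split(",")))
        return cls(tuple(int(x) for x in spec))

    def __str__(self) -> str:
        return "+".join(str(s) for s in self.subgenomes)


class AlleleDepthSet:
    """Individuals x alleles read-count matrix with an allele -> locus map.

    Parameters
    ----------
    taxa : sequence of str
        Unique individual identifiers (rows of ``depth``).
    alleles : sequence of str
        Unique allele identifiers (columns of ``depth``).
    depth : array-like of int, shape (n_taxa, n_alleles)
        Non-negative allelic read counts.
    allele_to_locus : mapping allele id -> locus id
        Every allele maps to exactly one locus; every locus must keep >= 2
        alleles so that the "reads of other alleles" count is well defined.
    locus_chrom, locus_pos : optional mappings locus id -> chromosome / bp
        Positions are 0-based internally; converted from 1-based on VCF import.
    blank_taxa : optional set of taxon ids
        No-template library controls; excluded from filtering counts and all
        estimation except contamination-rate estimation.
    """

    def __init__(self, taxa, alleles, depth, allele_to_locus,
                 locus_chrom=None, locus_pos=None, blank_taxa=None):
        self.taxa = list(taxa)
        self.alleles = list(alleles)
        self.depth = np.asarray(depth)
        if self.depth.shape != (len(self.taxa), len(self.alleles)):
            raise ValueError(
                f"depth shape {self.depth.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.alleles)} alleles")
        if not np.issubdtype(self.depth.dtype, np.integer):
            if not np.allclose(self.depth, np.round(self.depth)):
                raise ValueError("depth entries must be integers")
            self.depth = self.depth.astype(np.int64)
        if (self.depth < 0).any():
            raise ValueError("depth entries must be >= 0")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon identifiers must be unique")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError("allele identifiers must be unique")

        missing = [al for al in self.alleles if al not in allele_to_locus]
        if missing:
            raise KeyError(f"alleles missing from locus map: {missing[:5]}")
        self.allele_to_locus = {al: allele_to_locus[al] for al in self.alleles}

        # loci ordered by first appearance among alleles
        self.loci: list = []
        seen = {}
        for al in self.alleles:
            loc = self.allele_to_locus[al]
            if loc not in seen:
                seen[loc] = len(self.loci)
                self.loci.append(loc)
        self.locus_index = np.array(
            [seen[self.allele_to_locus[al]] for al in self.alleles], dtype=np.intp)

        counts = np.bincount(self.locus_index, minlength=len(self.loci))
        if (counts < 2).any():
            bad = [self.loci[i] for i in np.nonzero(counts < 2)[0]]
            raise ValueError(f"every locus needs >= 2 alleles; offending: {bad[:5]}")

        self.locus_chrom = dict(locus_chrom) if locus_chrom else None
        self.locus_pos = dict(locus_pos) if locus_pos else None
        if self.locus_pos is not None:
            for loc, pos in self.locus_pos.items():
                if pos < 0:
                    raise ValueError(f"negative basepair position for locus {loc}")

        self.blank_taxa = set(blank_taxa) if blank_taxa else set()
        unknown = self.blank_taxa - set(self.taxa)
        if unknown:
            raise KeyError(f"blank taxa not in dataset: {sorted(unknown)}")

        self._taxon_idx = {t: i for i, t in enumerate(self.taxa)}
        self._allele_idx = {a: i for i, a in enumerate(self.alleles)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def taxon_index(self, taxon) -> int:
        try:
            return self._taxon_idx[taxon]
        except KeyError:
            raise KeyError(f"unknown taxon: {taxon!r}") from None

    def allele_index(self, allele) -> int:
        try:
            return self._allele_idx[allele]
        except KeyError:
            raise KeyError(f"unknown allele: {allele!r}") from None

    def nonblank_mask(self) -> np.ndarray:
        return np.array([t not in self.blank_taxa for t in self.taxa])

    def alleles_of_locus(self, locus) -> list:
        li = self.loci.index(locus)
        return [self.alleles[j] for j in np.nonzero(self.locus_index == li)[0]]

    def locus_totals(self) -> np.ndarray:
        """Total read depth per taxon x locus, shape (n_taxa, n_loci)."""
        out = np.zeros((self.n_taxa, self.n_loci), dtype=np.int64)
        for j in range(self.n_alleles):
            out[:, self.locus_index[j]] += self.depth[:, j]
        return out

    def other_allele_counts(self) -> np.ndarray:
        """b matrix: per taxon x allele, reads of other alleles at the locus."""
        totals = self.locus_totals()
        return totals[:, self.locus_index] - self.depth

    def subset(self, allele_mask: np.ndarray) -> "AlleleDepthSet":
        """New dataset keeping only alleles where ``allele_mask`` is True."""
        keep = np.nonzero(allele_mask)[0]
        alleles = [self.alleles[j] for j in keep]
        kept_loci = {self.allele_to_locus[a] for a in alleles}
        return AlleleDepthSet(
            self.taxa, alleles, self.depth[:, keep],
            {a: self.allele_to_locus[a] for a in alleles},
            locus_chrom={l: c for l, c in (self.locus_chrom or {}).items()
                         if l in kept_loci} or None,
            locus_pos={l: p for l, p in (self.locus_pos or {}).items()
                       if l in kept_loci} or None,
            blank_taxa=self.blank_taxa,
        )

    def __repr__(self) -> str:
        return (f"AlleleDepthSet({self.n_taxa} taxa, {self.n_alleles} alleles, "
                f"{self.n_loci} loci, {len(self.blank_taxa)} blanks)")


@dataclass
class GenotypeProbArray:
    """taxa x alleles x (k+1) probability array over allele copy number.

    ``kind`` distinguishes priors and posteriors (normalized: each length-(k+1)
    vector sums to 1) from likelihoods (unnormalized, entries in [0, 1]).
    """

    values: np.ndarray
    kind: str  # prior | likelihood | posterior

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be taxa x alleles x (k+1)")
        if self.kind not in ("prior", "likelihood", "posterior"):
            raise ValueError(f"unknown kind: {self.kind}")
        if (self.values < 0).any():
            raise ValueError("probabilities must be >= 0")
        if self.kind in ("prior", "posterior"):
            sums = self.values.sum(axis=2)
            if not np.allclose(sums, 1.0, atol=1e-6):
                raise ValueError(f"{self.kind} vectors must sum to 1")

    @property
    def k(self) -> int:
        return self.values.shape[2] - 1


@dataclass
class PopulationModel:
    """Population-level parameters of the read model.

    freq
        Per-allele population frequency, aligned with a dataset's alleles;
        sums to 1 within each locus.
    c
        Cross-contamination rate (fraction of reads from other samples).
    d
        Beta-binomial overdispersion; smaller d = more overdispersion.
    s
        Self-fertilization rate.
    ind_freq
        Optional taxa x alleles matrix of individual-specific allele
        frequencies, used by the population-structure model.
    """

    freq: np.ndarray
    c: float = 0.001
    d: float = 9.0
    s: float = 0.0
    ind_freq: np.ndarray | None = None

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        if not (0 <= self.c < 0.5):
            raise ValueError("contamination rate c must be in [0, 0.5)")
        if self.d <= 0:
            raise ValueError("overdispersion d must be > 0")
        if not (0 <= self.s <= 1):
            raise ValueError("selfing rate s must be in [0, 1]")
        if ((self.freq < 0) | (self.freq > 1)).any():
            raise ValueError("allele frequencies must be in [0, 1]")

    def validate_locus_sums(self, dataset: AlleleDepthSet, atol=1e-6):
        sums = np.zeros(dataset.n_loci)
        np.add.at(sums, dataset.locus_index, self.freq)
        if not np.allclose(sums, 1.0, atol=atol):
            raise ValueError("allele frequencies must sum to 1 within each locus")


@dataclass
class DosageMatrix:
    """taxa x alleles matrix of genotypes on the 0..k dosage scale.

    Continuous (posterior-mean) unless ``discrete`` is set, in which case all
    entries are integer most-probable dosages.
    """

    values: np.ndarray
    k: int
    discrete: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if ((self.values < -1e-9) | (self.values > self.k + 1e-9)).any():
            raise ValueError(f"dosages must lie in [0, {self.k}]")
        if self.discrete and not np.allclose(self.values, np.round(self.values)):
            raise ValueError("discrete dosage matrix must be integer-valued")


# ---------------------------------------------------------------------------
# operations

def counts_for_allele(dataset: AlleleDepthSet, taxon, allele):
    """Reads of the given allele (a) and of other alleles at its locus (b)."""
    ti = dataset.taxon_index(taxon)
    aj = dataset.allele_index(allele)
    li = dataset.locus_index[aj]
    locus_cols = np.nonzero(dataset.locus_index == li)[0]
    total = int(dataset.depth[ti, locus_cols].sum())
    a = int(dataset.depth[ti, aj])
    return a, total - a


def filter_markers(dataset: AlleleDepthSet, min_ind_with_reads: int = 0,
                   min_ind_with_minor_allele: int = 0) -> AlleleDepthSet:
    """Drop under-sequenced loci and rare alleles.

    A locus is kept iff at least ``min_ind_with_reads`` non-blank individuals
    have nonzero total depth at it. Within kept loci, an allele is dropped if
    fewer than ``min_ind_with_minor_allele`` non-blank individuals have reads
    of it; loci left with fewer than two alleles are then dropped entirely.
    Blank (no-template control) individuals never count toward thresholds.
    """
    if min_ind_with_reads < 0 or min_ind_with_minor_allele < 0:
        raise ValueError("thresholds must be >= 0")
    nonblank = dataset.nonblank_mask()
    n_nonblank = int(nonblank.sum())
    if min(min_ind_with_reads, 1) > 0 and min_ind_with_reads > n_nonblank:
        warnings.warn("min_ind_with_reads exceeds the number of non-blank "
                      "individuals; no loci can pass", stacklevel=2)
    if min_ind_with_minor_allele > n_nonblank:
        warnings.warn("min_ind_with_minor_allele exceeds the number of "
                      "non-blank individuals; no alleles can pass", stacklevel=2)

    totals = dataset.locus_totals()[nonblank]          # nonblank x loci
    loci_ok = (totals > 0).sum(axis=0) >= min_ind_with_reads
    allele_ok = loci_ok[dataset.locus_index].copy()

    seen = (dataset.depth[nonblank] > 0).sum(axis=0)   # per allele
    allele_ok &= seen >= min_ind_with_minor_allele

    # drop loci reduced to < 2 alleles
    remaining = np.zeros(dataset.n_loci, dtype=int)
    np.add.at(remaining, dataset.locus_index[allele_ok], 1)
    allele_ok &= remaining[dataset.locus_index] >= 2

    if not allele_ok.any():
        warnings.warn("no markers passed filtering; returning empty dataset",
                      stacklevel=2)
        empty = AlleleDepthSet.__new__(AlleleDepthSet)
        empty.taxa = list(dataset.taxa)
        empty.alleles = []
        empty.depth = np.zeros((dataset.n_taxa, 0), dtype=np.int64)
        empty.allele_to_locus = {}
        empty.loci = []
        empty.locus_index = np.array([], dtype=np.intp)
        empty.locus_chrom = None
        empty.locus_pos = None
        empty.blank_taxa = set(dataset.blank_taxa)
        empty._taxon_idx = {t: i for i, t in enumerate(empty.taxa)}
        empty._allele_idx = {}
        return empty
    return dataset.subset(allele_ok)
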