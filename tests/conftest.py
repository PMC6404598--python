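import numpy as np
import pytest

from polydose import AlleleDepthSet


def make_dataset(depth, locus_sizes, taxa=None, blanks=None, positions=None,
                 chrom="1"):
    """Build an AlleleDepthSet from a depth matrix and locus sizes.

    ``locus_sizes`` gives the number of alleles per locus, in column order;
    ``positions`` optionally gives one basepair position per locus.
    """
    depth = np.asarray(depth)
    n_taxa, n_alleles = depth.shape
    assert sum(locus_sizes) == n_alleles
    taxa = taxa or [f"T{i}" for i in range(n_taxa)]
    alleles, a2l = [], {}
    loci = []
    j = 0
    for li, size in enumerate(locus_sizes):
        loc = f"L{li}"
        loci.append(loc)
        for s in range(size):
            al = f"{loc}_{s}"
            alleles.append(al)
            a2l[al] = loc
            j += 1
    pos = None
    chm = None
    if positions is not None:
        pos = dict(zip(loci, positions))
        chm = {loc: chrom for loc in loci}
    return AlleleDepthSet(taxa, alleles, depth, a2l, locus_chrom=chm,
                          locus_pos=pos, blank_taxa=blanks)


@pytest.fixture
def toy_dataset():
    """4 individuals, 2 biallelic loci; L0 read by all, L1 by two."""
    depth = np.array([
        [5, 2, 3, 0],
        [4, 0, 0, 0],
        [1, 3, 2, 1],
        [6, 1, 0, 0],
    ])
    return make_dataset(depth, [2, 2])


@pytest.fixture
def triallelic_dataset():
    """One taxon, one locus with three alleles, depths (5, 2, 1)."""
    return make_dataset(np.array([[5, 2, 1]]), [3])
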