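"""Readers and writers: VCF with allelic depth, CSV depth matrices, exports.

Import accepts any VCF (plain or bgzipped) carrying a per-sample AD field —
each record becomes one locus whose REF and ALT alleles are the locus's
alleles — or a CSV read-depth matrix with a separate allele -> locus map.
Export writes taxa x alleles matrices of continuous or discrete dosages
(dropping each locus's first allele, whose dosage is redundant given that
locus dosages sum to the ploidy), or a VCF with GT (most probable genotype)
and DS (posterior mean dosage) per sample. Positions are 1-based in VCF and
0-based internally.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data import AlleleDepthSet, PloidyHypothesis, filter_markers
from .pipelines import PipelineResult

__all__ = [
    "read_vcf_ad",
    "read_depth_csv",
    "write_depth_vcf",
    "write_depth_csv",
    "write_genotypes",
]


def read_vcf_ad(path, min_ind_with_reads: int = 0,
                min_ind_with_minor_allele: int = 0,
                blank_taxa=None) -> AlleleDepthSet:
    """Import allelic read depth from a VCF's AD field.

    One locus per record; REF plus all ALT alleles become the locus's
    alleles, identified as ``chrom:pos1_seq`` (1-based position, as printed
    in the file). Samples missing AD at a record get zero depth there;
    records with a malformed AD arity are skipped with a warning. Marker
    filtering (minimum individuals with reads of the locus / of each allele)
    runs before returning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    taxa = list(vcf.samples)
    alleles, a2l, chrom_map, pos_map, cols = [], {}, {}, {}, []
    saw_ad = False
    for var in vcf:
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        names = [var.REF] + list(var.ALT)
        locus = f"{var.CHROM}:{var.POS}"
        if ad is None:
            continue
        saw_ad = True
        ad = np.asarray(ad)
        if ad.shape != (len(taxa), len(names)):
            warnings.warn(f"record {locus}: AD arity {ad.shape} does not "
                          f"match {len(names)} alleles; skipped", stacklevel=2)
            continue
        ad = np.where(ad < 0, 0, ad).astype(np.int64)   # missing -> 0
        for j, seq in enumerate(names):
            al = f"{locus}_{seq}"
            alleles.append(al)
            a2l[al] = locus
            cols.append(ad[:, j])
        chrom_map[locus] = var.CHROM
        pos_map[locus] = var.POS - 1                    # 0-based internally
    vcf.close()
    if not saw_ad:
        raise ValueError(f"{path}: no AD (allelic depth) FORMAT field found "
                         "in any record")
    depth = np.column_stack(cols) if cols else np.zeros((len(taxa), 0), int)
    ds = AlleleDepthSet(taxa, alleles, depth, a2l, locus_chrom=chrom_map,
                        locus_pos=pos_map, blank_taxa=blank_taxa)
    if min_ind_with_reads or min_ind_with_minor_allele:
        ds = filter_markers(ds, min_ind_with_reads, min_ind_with_minor_allele)
    return ds


def read_depth_csv(path, locus_map_path, blank_taxa=None) -> AlleleDepthSet:
    """Import a taxa x alleles read-count CSV plus an allele -> locus map.

    The matrix file has taxa as rows (first column = taxon id) and alleles
    as columns; the map file has two columns, allele and locus. No genomic
    positions are available through this route.
    """
    mat = pd.read_csv(path, index_col=0)
    if mat.empty and mat.columns.empty:
        raise ValueError(f"{path}: empty read-depth matrix")
    if mat.index.duplicated().any():
        dups = mat.index[mat.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate taxon rows: {dups[:5]}")
    lmap = pd.read_csv(locus_map_path)
    if lmap.shape[1] < 2:
        raise ValueError(f"{locus_map_path}: expected two columns "
                         "(allele, locus)")
    a2l = dict(zip(lmap.iloc[:, 0].astype(str), lmap.iloc[:, 1].astype(str)))
    missing = [al for al in mat.columns if al not in a2l]
    if missing:
        raise KeyError(f"alleles absent from the locus map: {missing[:10]}")
    return AlleleDepthSet(mat.index.astype(str), mat.columns,
                          mat.to_numpy(), a2l, blank_taxa=blank_taxa)


def write_depth_csv(dataset: AlleleDepthSet, matrix_path, locus_map_path):
    """Write the read-depth matrix and allele -> locus map as CSV."""
    pd.DataFrame(dataset.depth, index=dataset.taxa,
                 columns=dataset.alleles).to_csv(matrix_path)
    pd.DataFrame({"allele": dataset.alleles,
                  "locus": [dataset.allele_to_locus[a] for a in dataset.alleles]
                  }).to_csv(locus_map_path, index=False)


_VCF_BASES = "ACGT"


def _locus_records(dataset: AlleleDepthSet):
    """Yield (locus, chrom, pos1, allele column indices) in locus order."""
    for li, loc in enumerate(dataset.loci):
        cols = np.nonzero(dataset.locus_index == li)[0]
        chrom = (dataset.locus_chrom or {}).get(loc, "1")
        pos0 = (dataset.locus_pos or {}).get(loc, li * 1000)
        yield loc, chrom, int(pos0) + 1, cols


def _allele_bases(n: int) -> list[str]:
    # synthetic single-base allele sequences for loci without real sequence
    return [_VCF_BASES[i % 4] if i < 4 else f"<ALT{i}>" for i in range(n)]


def vcf_allele_names(dataset: AlleleDepthSet) -> list[str]:
    """Allele names a dataset's alleles will carry after a VCF round trip.

    :func:`write_depth_vcf` emits synthetic allele sequences and
    :func:`read_vcf_ad` names alleles ``chrom:pos1_seq``; this returns those
    names in the dataset's column order, so truth tables written alongside a
    simulated VCF can share identifiers with the re-imported data.
    """
    names = [None] * dataset.n_alleles
    for _, chrom, pos1, cols in _locus_records(dataset):
        for base, j in zip(_allele_bases(len(cols)), cols):
            names[j] = f"{chrom}:{pos1}_{base}"
    return names


def write_depth_vcf(dataset: AlleleDepthSet, path):
    """Write a VCF 4.2 file carrying the read depths in the AD field.

    Loci lacking real allele sequences get synthetic single-base alleles
    (A, C, G, T in column order). Round-trips through
    :func:`read_vcf_ad` reproduce the depth matrix exactly.
    """
    contigs = sorted({c for _, c, _, _ in _locus_records(dataset)})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dataset.taxa) + "\n")
        for loc, chrom, pos1, cols in _locus_records(dataset):
            bases = _allele_bases(len(cols))
            samples = "\t".join(
                ",".join(str(int(x)) for x in dataset.depth[t, cols])
                for t in range(dataset.n_taxa))
            fh.write(f"{chrom}\t{pos1}\t{loc}\t{bases[0]}\t"
                     f"{','.join(bases[1:])}\t.\t.\t.\tAD\t{samples}\n")


def write_genotypes(result: PipelineResult, path, mode: str = "continuous"):
    """Export called genotypes.

    ``continuous`` / ``discrete`` write a taxa x alleles CSV of posterior
    mean / most probable dosages, dropping the first allele of each locus
    (its dosage is the ploidy minus the others', and keeping it would make
    downstream design matrices rank-deficient). ``vcf`` writes one record
    per locus with GT (most probable genotype, reference copies first) and
    DS (posterior mean dosage of each alt allele).
    """
    ds = result.dataset
    if mode in ("continuous", "discrete"):
        mat = result.pmg.values if mode == "continuous" else result.discrete.values
        keep = []
        dropped = []
        seen = set()
        for j, al in enumerate(ds.alleles):
            loc = ds.allele_to_locus[al]
            if loc in seen:
                keep.append(j)
            else:
                seen.add(loc)
                dropped.append(al)
        pd.DataFrame(np.asarray(mat)[:, keep], index=ds.taxa,
                     columns=[ds.alleles[j] for j in keep]).to_csv(
                         path, float_format="%.4f")
        return
    if mode != "vcf":
        raise ValueError(f"unknown export mode: {mode}")

    contigs = sorted({c for _, c, _, _ in _locus_records(ds)})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Most probable genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=A,Type=Float,'
                 'Description="Posterior mean dosage of each ALT allele">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ds.taxa) + "\n")
        for loc, chrom, pos1, cols in _locus_records(ds):
            k = result.ploidy_choice[loc].k
            bases = _allele_bases(len(cols))
            fields = []
            for t in range(ds.n_taxa):
                alt_doses = [int(result.discrete.values[t, j])
                             for j in cols[1:]]
                total_alt = min(sum(alt_doses), k)
                calls = ["0"] * (k - total_alt)
                left = total_alt
                for ai, dose in enumerate(alt_doses, start=1):
                    take = min(dose, left)
                    calls += [str(ai)] * take
                    left -= take
                gt = "/".join(calls)
                dsvals = ",".join(f"{result.pmg.values[t, j]:.4f}"
                                  for j in cols[1:])
                fields.append(f"{gt}:{dsvals}")
            fh.write(f"{chrom}\t{pos1}\t{loc}\t{bases[0]}\t"
                     f"{','.join(bases[1:])}\t.\t.\t.\tGT:DS\t"
                     + "\t".join(fields) + "\n")
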