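"""Sample-identity and expression-coverage quality control.

Two checks gate the pipeline: (i) every RNA-seq sample must match its
annotated DNA (fraction of concordant genotypes at covered variants >= 0.7,
the cutoff that cleanly separates matching from non-matching pairs), and
(ii) every sample must express a plausible number of genes (FPKM >= 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QCReport",
    "dna_rna_match_fraction",
    "count_expressed_genes",
    "expressed_position",
    "qc_report",
]

MATCH_CUTOFF = 0.7          # fraction >= 0.7 counts as matched (boundary inclusive)
HET_BAND = (0.02, 0.98)     # het concordant iff alt fraction within this band
HOM_ALT_MIN = 0.98          # hom-alt concordant iff alt fraction >= this


@dataclass
class QCReport:
    table: pd.DataFrame  # per sample: n_expressed_genes, dna_rna_match_fraction, matched, flags


def dna_rna_match_fraction(dna_genotypes, rna_counts, min_coverage=10,
                           het_band=HET_BAND, hom_alt_min=HOM_ALT_MIN,
                           cutoff=MATCH_CUTOFF):
    """Concordance between DNA genotype calls and RNA allelic evidence.

    Parameters
    ----------
    dna_genotypes : mapping (chromosome, position, ref, alt) -> "het" | "hom"
    rna_counts : DataFrame with chromosome, position, ref, alt, ref_count, alt_count
        RNA allelic counts for one sample.
    min_coverage : int
        Variants below this total RNA coverage are ignored.

    Returns
    -------
    (fraction, matched, status) where status is "ok" or
    "insufficient coverage" (fraction and matched are then NaN/None).

    A het call is concordant when both alleles are visible or the imbalance is
    still explainable (alt fraction inside ``het_band``); hom-alt requires alt
    fraction >= ``hom_alt_min``.  The decision is symmetric under swapping the
    ref/alt roles of a het variant.
    """
    t = rna_counts
    total = t["ref_count"].to_numpy() + t["alt_count"].to_numpy()
    covered = total >= min_coverage
    keys = list(zip(t["chromosome"], t["position"], t["ref"], t["alt"]))
    genotyped = np.array([k in dna_genotypes for k in keys])
    use = covered & genotyped
    if not use.any():
        return float("nan"), None, "insufficient coverage"
    alt_frac = np.where(total > 0, t["alt_count"].to_numpy() / np.maximum(total, 1), 0.0)
    lo, hi = het_band
    concordant = 0
    for i in np.flatnonzero(use):
        gt = dna_genotypes[keys[i]]
        if gt == "het":
            concordant += lo <= alt_frac[i] <= hi
        else:  # hom (alt)
            concordant += alt_frac[i] >= hom_alt_min
    fraction = concordant / use.sum()
    return fraction, fraction >= cutoff, "ok"


def fpkm(matrix, annotation):
    """FPKM_ij = count_ij * 1e9 / (libsize_j * length_i)."""
    counts = matrix.values().astype(float)
    libsize = counts.sum(axis=0)
    if (libsize == 0).any():
        zero = [matrix.sample_ids[j] for j in np.flatnonzero(libsize == 0)]
        raise ValueError(f"zero library size for samples {zero}")
    lengths = annotation.lengths(matrix.gene_ids)
    return counts * 1e9 / (libsize[None, :] * lengths[:, None])


def count_expressed_genes(matrix, annotation, fpkm_cutoff=1.0):
    """Per-sample number of genes expressed at FPKM >= cutoff."""
    return pd.Series((fpkm(matrix, annotation) >= fpkm_cutoff).sum(axis=0),
                     index=matrix.sample_ids, name="n_expressed_genes")


def expressed_position(coverage_per_sample, min_mean=10.0):
    """A genomic position is expressed iff mean coverage across samples >= 10."""
    cov = np.asarray(coverage_per_sample, dtype=float)
    if cov.size == 0:
        raise ValueError("at least one sample required")
    return bool(cov.mean() >= min_mean)


def qc_report(matrix, annotation, genotype_sets=None, allelic_tables=None,
              min_coverage=10):
    """Assemble the per-sample QC table (expressed genes + DNA-RNA match)."""
    expressed = count_expressed_genes(matrix, annotation)
    rows = []
    for s in matrix.sample_ids:
        frac, matched, status = (np.nan, None, "not tested")
        if genotype_sets and allelic_tables and s in genotype_sets and s in allelic_tables:
            frac, matched, status = dna_rna_match_fraction(
                genotype_sets[s], allelic_tables[s], min_coverage=min_coverage)
        flags = []
        if matched is False:
            flags.append("dna-rna-mismatch")
        if status == "insufficient coverage":
            flags.append("insufficient-coverage")
        rows.append((s, int(expressed[s]), frac, matched, ";".join(flags)))
    return QCReport(pd.DataFrame(
        rows, columns=["sample", "n_expressed_genes", "dna_rna_match_fraction",
                       "matched", "flags"]).set_index("sample"))
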