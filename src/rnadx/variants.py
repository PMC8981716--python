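"""Hard filtering and prioritization of RNA-seq-called variants.

Three independent hard filters remove technical artefacts (GATK-style
thresholds): quality-over-depth QD < 2, strand bias FS > 30 (Phred-scaled
Fisher score), and SNP clusters (3 or more SNVs within a 35 bp window).
Survivors outside repeat-masked regions with at least 3 alternative-allele
reads are prioritized.  Unknown QD/FS fails closed: the variant survives
filtering (not provably bad) but is never prioritized.

A strict-reading mode treats the cluster and strand-bias rules as conditions
on low-QD variants only (the grammatically alternative reading of the
published filter sentence).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["snp_cluster", "apply_filters", "precision_recall"]

QD_MIN = 2.0
FS_MAX = 30.0
CLUSTER_WINDOW = 35
CLUSTER_K = 3
MIN_ALT_READS = 3


def snp_cluster(positions, window=CLUSTER_WINDOW, k=CLUSTER_K):
    """Flag positions belonging to a cluster of >= k SNVs within a window.

    ``positions`` must be sorted (one chromosome).  A variant is flagged iff
    some run of k consecutive variants spanning at most ``window`` bases
    (inclusive of both endpoints) contains it.
    """
    pos = np.asarray(positions)
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted")
    n = len(pos)
    flags = np.zeros(n, dtype=bool)
    if n < k:
        return flags
    for i in range(n - k + 1):
        if pos[i + k - 1] - pos[i] <= window - 1:
            flags[i:i + k] = True
    return flags


def apply_filters(variants, mask=None, strict_reading=False,
                  qd_min=QD_MIN, fs_max=FS_MAX, min_alt_reads=MIN_ALT_READS,
                  window=CLUSTER_WINDOW, k=CLUSTER_K):
    """Apply hard filters and prioritization.

    Returns (survivors, prioritized), both VariantTable-shaped DataFrames with
    added boolean columns ``filtered_out`` and ``prioritized`` on the full
    input frame as well.
    """
    t = variants.table.copy()
    clustered = np.zeros(len(t), dtype=bool)
    snv = (t["ref"].str.len() == 1) & (t["alt"].str.len() == 1)
    for (_, _), idx in t.groupby(["sample", "chromosome"]).groups.items():
        idx = np.asarray(idx)
        idx = idx[snv.to_numpy()[idx]]
        if len(idx) == 0:
            continue
        order = idx[np.argsort(t["position"].to_numpy()[idx], kind="stable")]
        clustered[order] = snp_cluster(t["position"].to_numpy()[order], window, k)

    qd = t["qd"].to_numpy(dtype=float)
    fs = t["fs"].to_numpy(dtype=float)
    low_qd = qd < qd_min          # NaN compares False: unknown passes the filter...
    strand_biased = fs > fs_max
    if strict_reading:
        filtered_out = low_qd & (strand_biased | clustered)
    else:
        filtered_out = low_qd | strand_biased | clustered

    in_mask = t["in_repeat_mask"].to_numpy(dtype=bool)
    if mask is not None:
        in_mask = in_mask | mask.contains(t["chromosome"].to_numpy(), t["position"].to_numpy())
    known_quality = np.isfinite(qd) & np.isfinite(fs)
    alt_ok = t["alt_reads"].to_numpy(dtype=float) >= min_alt_reads
    # ...but unknown quality fails closed at prioritization.
    prioritized = ~filtered_out & ~in_mask & alt_ok & known_quality

    t["snp_cluster"] = clustered
    t["filtered_out"] = filtered_out
    t["prioritized"] = prioritized
    survivors = t[~filtered_out].reset_index(drop=True)
    prioritized_set = t[prioritized].reset_index(drop=True)
    return survivors, prioritized_set, t


def precision_recall(called, truth, coverage=None, min_coverage=3):
    """Benchmark called variants against a truth set, split het/hom.

    Variants match on (chromosome, position, ref, alt, genotype class); a het
    called as hom is both a false positive and a false negative.  Truth
    variants at positions with RNA coverage below ``min_coverage`` are
    excluded from the denominator, as are calls at such positions.

    Parameters
    ----------
    called, truth : DataFrame with chromosome, position, ref, alt, genotype
    coverage : mapping (chromosome, position) -> reads, optional

    Returns a DataFrame indexed by genotype class with precision and recall.
    """
    def keyed(df):
        return {(r.chromosome, r.position, r.ref, r.alt, r.genotype)
                for r in df.itertuples(index=False)}

    def covered(df):
        if coverage is None:
            return df
        ok = [coverage.get((r.chromosome, r.position), 0) >= min_coverage
              for r in df.itertuples(index=False)]
        return df[np.asarray(ok, dtype=bool)]

    called_c = covered(called)
    truth_c = covered(truth)
    rows = []
    for gclass in ("het", "hom"):
        c = keyed(called_c[called_c["genotype"] == gclass])
        tr = keyed(truth_c[truth_c["genotype"] == gclass])
        tp = len(c & tr)
        fp = len(c - tr)
        fn = len(tr - c)
        precision = tp / (tp + fp) if (tp + fp) else np.nan
        recall = tp / (tp + fn) if (tp + fn) else np.nan
        rows.append((gclass, tp, fp, fn, precision, recall))
    return pd.DataFrame(rows, columns=["genotype", "tp", "fp", "fn",
                                       "precision", "recall"]).set_index("genotype")
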