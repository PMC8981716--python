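"""Typed containers and TSV readers/writers for every table the pipeline touches.

All tables are UTF-8, tab-delimited text with a header row and a deterministic
column order, so that reader∘writer is the identity on valid instances.
Coordinates are 1-based inclusive throughout (VCF convention); BED input is
converted from 0-based half-open on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "GeneCountMatrix",
    "GeneAnnotation",
    "SpliceCountTable",
    "AllelicCountTable",
    "VariantTable",
    "RepeatMask",
    "read_count_matrix",
    "write_count_matrix",
    "read_annotation",
    "write_annotation",
    "read_splice_counts",
    "write_splice_counts",
    "read_allelic_counts",
    "write_allelic_counts",
    "read_variant_table",
    "write_variant_table",
    "read_repeat_mask",
    "load_gene_lists",
]


class ValidationError(ValueError):
    """A table failed schema or invariant validation."""


def _require_unique(values, what):
    dup = pd.Index(values)[pd.Index(values).duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate {what}: {sorted(set(dup))}")


@dataclass
class GeneCountMatrix:
    """Gene x sample matrix of non-negative integer read counts."""

    counts: pd.DataFrame  # index = gene ids, columns = sample ids
    strandedness: str = "unstranded"  # "stranded" | "unstranded"

    def __post_init__(self):
        _require_unique(self.counts.index, "gene id")
        _require_unique(self.counts.columns, "sample id")
        if self.strandedness not in ("stranded", "unstranded"):
            raise ValidationError(f"unknown strandedness {self.strandedness!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr), atol=0):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("counts must be non-negative")

    @property
    def gene_ids(self):
        return self.counts.index

    @property
    def sample_ids(self):
        return self.counts.columns

    @property
    def shape(self):
        return self.counts.shape

    def values(self):
        return self.counts.to_numpy()

    def copy(self):
        return GeneCountMatrix(self.counts.copy(), self.strandedness)


_ANN_COLUMNS = ["gene_id", "chromosome", "start", "end", "gene_length", "n_exons"]


@dataclass
class GeneAnnotation:
    """Minimal per-gene annotation: coordinates, exonic length, exon count,
    gene-list memberships and optional generator side-car columns."""

    table: pd.DataFrame  # indexed by gene_id
    gene_lists: dict = field(default_factory=dict)  # list name -> set of gene ids

    def __post_init__(self):
        t = self.table
        if t.index.name != "gene_id":
            if "gene_id" in t.columns:
                t = t.set_index("gene_id")
            else:
                raise ValidationError("annotation requires a gene_id column or index")
        _require_unique(t.index, "gene id")
        for col in ("gene_length", "n_exons", "start", "end"):
            if col in t.columns:
                if col == "gene_length" and (t[col] <= 0).any():
                    raise ValidationError("gene_length must be > 0")
                if col == "n_exons" and (t[col] < 1).any():
                    raise ValidationError("n_exons must be >= 1")
        if {"start", "end"} <= set(t.columns) and (t["start"] > t["end"]).any():
            raise ValidationError("start must be <= end")
        self.table = t

    @property
    def gene_ids(self):
        return self.table.index

    def lengths(self, gene_ids=None):
        t = self.table if gene_ids is None else self.table.loc[gene_ids]
        return t["gene_length"].to_numpy(dtype=float)

    def in_list(self, name, gene_ids):
        members = self.gene_lists.get(name, set())
        return np.array([g in members for g in gene_ids])


@dataclass
class SpliceCountTable:
    """Split-read junction counts plus per-site total/unsplit coverage.

    ``junctions`` rows: chromosome, donor, acceptor, strand, gene_id and one
    integer column per sample (split reads supporting the junction).
    ``sites`` rows: chromosome, position, strand, site_type (donor|acceptor),
    gene_id and two count blocks per sample: total split-read coverage
    (``split:<sample>``) and unsplit (exon-intron) coverage
    (``unsplit:<sample>``).
    """

    junctions: pd.DataFrame
    sites: pd.DataFrame
    sample_ids: list

    def __post_init__(self):
        jkey = ["chromosome", "donor", "acceptor", "strand"]
        _require_unique(pd.MultiIndex.from_frame(self.junctions[jkey]), "junction key")
        if (self.junctions["donor"] >= self.junctions["acceptor"]).any():
            bad = self.junctions.loc[self.junctions["donor"] >= self.junctions["acceptor"]]
            raise ValidationError(f"donor must be < acceptor (rows {list(bad.index[:5])})")
        for s in self.sample_ids:
            if (self.junctions[s] < 0).any():
                raise ValidationError(f"negative junction counts for sample {s}")
            if (self.sites[f"split:{s}"] < 0).any() or (self.sites[f"unsplit:{s}"] < 0).any():
                raise ValidationError(f"negative site counts for sample {s}")

    def junction_counts(self):
        """(n_junctions, n_samples) integer array of split reads."""
        return self.junctions[self.sample_ids].to_numpy()

    def site_split(self):
        return self.sites[[f"split:{s}" for s in self.sample_ids]].to_numpy()

    def site_unsplit(self):
        return self.sites[[f"unsplit:{s}" for s in self.sample_ids]].to_numpy()

    def copy(self):
        return SpliceCountTable(self.junctions.copy(), self.sites.copy(), list(self.sample_ids))


@dataclass
class AllelicCountTable:
    """Per-heterozygous-SNV allelic read counts, one row per (sample, variant)."""

    table: pd.DataFrame  # sample, chromosome, position, ref, alt, ref_count, alt_count, rare

    KEY = ["sample", "chromosome", "position", "ref", "alt"]

    def __post_init__(self):
        t = self.table
        missing = [c for c in self.KEY + ["ref_count", "alt_count"] if c not in t.columns]
        if missing:
            raise ValidationError(f"allelic count table missing columns: {missing}")
        if "rare" not in t.columns:
            t = t.assign(rare=False)
        _require_unique(pd.MultiIndex.from_frame(t[self.KEY]), "variant key per sample")
        if (t["ref_count"] < 0).any() or (t["alt_count"] < 0).any():
            raise ValidationError("allelic counts must be non-negative")
        self.table = t.reset_index(drop=True)

    @property
    def total(self):
        return (self.table["ref_count"] + self.table["alt_count"]).to_numpy()

    def copy(self):
        return AllelicCountTable(self.table.copy())


_VARIANT_MANDATORY = [
    "sample", "chromosome", "position", "ref", "alt", "genotype",
    "consequence", "maf_population", "maf_cohort", "qd", "fs", "alt_reads",
]


@dataclass
class VariantTable:
    """Annotated variants, one row per (sample, variant).

    Numeric annotation that is unavailable (e.g. QD/FS for WES-only calls) is
    carried as NaN, an explicit "unknown" that fails RNA-variant filters
    closed: an unknown-quality variant is never prioritized.
    """

    table: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _VARIANT_MANDATORY if c not in self.table.columns]
        if missing:
            raise ValidationError(f"variant table missing mandatory columns: {missing}")
        t = self.table.copy()
        if "in_repeat_mask" not in t.columns:
            t["in_repeat_mask"] = False
        if "gene_id" not in t.columns:
            t["gene_id"] = ""
        for col in ("maf_population", "maf_cohort", "qd", "fs"):
            t[col] = pd.to_numeric(t[col], errors="coerce")
        neg = (t[["qd", "fs"]] < 0).any(axis=None)
        if bool(neg):
            raise ValidationError("qd and fs must be >= 0 where known")
        self.table = t.reset_index(drop=True)

    def __len__(self):
        return len(self.table)

    def copy(self):
        return VariantTable(self.table.copy())


class RepeatMask:
    """Merged repeat intervals per chromosome, 1-based inclusive."""

    def __init__(self, intervals):
        # intervals: dict chrom -> list of (start, end), 1-based inclusive
        self._starts, self._ends = {}, {}
        for chrom, ivs in intervals.items():
            merged = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1] + 1:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._starts[chrom] = np.array([s for s, _ in merged])
            self._ends[chrom] = np.array([e for _, e in merged])

    def contains(self, chromosomes, positions):
        """Vectorised membership test for 1-based positions."""
        chromosomes = np.asarray(chromosomes)
        positions = np.asarray(positions)
        out = np.zeros(len(positions), dtype=bool)
        for chrom in np.unique(chromosomes):
            starts = self._starts.get(chrom)
            if starts is None or not len(starts):
                continue
            m = chromosomes == chrom
            pos = positions[m]
            idx = np.searchsorted(starts, pos, side="right") - 1
            hit = (idx >= 0) & (pos <= self._ends[chrom][np.clip(idx, 0, None)])
            out[m] = hit
        return out


# ---------------------------------------------------------------------------
# readers / writers


def read_count_matrix(path, strandedness="unstranded"):
    """Read a gene x sample count TSV (first column gene ids, header samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene_id"
    bad = df.columns[df.dtypes.apply(lambda d: not np.issubdtype(d, np.number))]
    if len(bad):
        raise ValidationError(f"non-numeric count columns: {list(bad)}")
    frac = df.to_numpy(dtype=float)
    if not np.allclose(frac, np.round(frac), atol=0):
        raise ValidationError("non-integer cell in count matrix")
    return GeneCountMatrix(df.astype(np.int64), strandedness=strandedness)


def write_count_matrix(matrix, path):
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_annotation(path, gene_lists=None):
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ANN_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"annotation missing columns: {missing}")
    return GeneAnnotation(df.set_index("gene_id"), gene_lists=gene_lists or {})


def write_annotation(annotation, path):
    annotation.table.to_csv(path, sep="\t", index_label="gene_id")


def read_splice_counts(junction_path, site_path):
    junctions = pd.read_csv(junction_path, sep="\t")
    sites = pd.read_csv(site_path, sep="\t")
    meta = {"chromosome", "donor", "acceptor", "strand", "gene_id"}
    sample_ids = [c for c in junctions.columns if c not in meta]
    return SpliceCountTable(junctions, sites, sample_ids)


def write_splice_counts(table, junction_path, site_path):
    table.junctions.to_csv(junction_path, sep="\t", index=False)
    table.sites.to_csv(site_path, sep="\t", index=False)


def read_allelic_counts(path):
    return AllelicCountTable(pd.read_csv(path, sep="\t"))


def write_allelic_counts(table, path):
    table.table.to_csv(path, sep="\t", index=False)


def read_variant_table(path, dialect="tsv"):
    """Read an annotated variant table.

    ``dialect="tsv"`` expects the package's own flat schema.  ``dialect=
    "vcf_like"`` accepts ``#CHROM/POS/REF/ALT``-style headers with the
    remaining annotation in identically named extra columns (a documented
    VCF-like subset; full VCF support is out of scope).
    """
    df = pd.read_csv(path, sep="\t")
    if dialect == "vcf_like":
        df = df.rename(columns={"#CHROM": "chromosome", "CHROM": "chromosome",
                                "POS": "position", "REF": "ref", "ALT": "alt"})
    missing = [c for c in _VARIANT_MANDATORY if c not in df.columns]
    if missing:
        raise ValidationError(f"variant table missing mandatory columns: {missing}")
    pos = pd.to_numeric(df["position"], errors="coerce")
    if pos.isna().any():
        rows = list(df.index[pos.isna()][:5])
        raise ValidationError(f"malformed position at rows {rows}")
    df["position"] = pos.astype(np.int64)
    return VariantTable(df)


def write_variant_table(table, path):
    table.table.to_csv(path, sep="\t", index=False)


def read_repeat_mask(path):
    """Read a BED file (0-based half-open) into 1-based inclusive intervals."""
    intervals = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            intervals.setdefault(chrom, []).append((int(start) + 1, int(end)))
    return RepeatMask(intervals)


def load_gene_lists(paths):
    """Load plain-text gene lists (one id per line) into name -> set.

    The list name is the file stem.  Unknown genes are retained: membership is
    independent of any annotation.  An empty file yields an empty set with a
    warning; a missing file is an explicit error.
    """
    lists = {}
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"gene list file not found: {path}")
        genes = {line.strip() for line in path.read_text().splitlines() if line.strip()}
        if not genes:
            warnings.warn(f"gene list {path.name} is empty")
        lists[path.stem] = genes
    return lists
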