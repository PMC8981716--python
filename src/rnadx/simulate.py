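"""Synthetic cohorts with the statistical structure the detectors assume.

The generator emulates a rare-disease fibroblast RNA-seq cohort: negative
binomial gene counts with per-gene dispersion and multiplicative low-rank
latent (batch-like) effects, beta-binomial junction usage around a reference
percent-spliced-in, allelic counts around a balanced ratio with mild
intra-class correlation, and annotated variant tables with consequence
categories and population/cohort allele frequencies.  Ground truth for every
injected aberration is recorded in a TruthTable so recall is measurable.

All generators are pure functions of (config, seed): reruns are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    AllelicCountTable,
    GeneAnnotation,
    GeneCountMatrix,
    SpliceCountTable,
    VariantTable,
)
from ._stats import betabinom_params

__all__ = [
    "CohortConfig",
    "TruthTable",
    "simulate_counts",
    "inject_expression_outliers",
    "simulate_splice_counts",
    "inject_splicing_outliers",
    "simulate_allelic_counts",
    "inject_mae",
    "simulate_variants",
]

#: consequence-category sampling frequencies, loosely matching the footprint of
#: an exome: mostly non-coding and missense/synonymous, few truncating events.
DEFAULT_CONSEQUENCE_FREQS = {
    "intron": 0.30,
    "upstream": 0.10,
    "downstream": 0.08,
    "intergenic": 0.05,
    "missense": 0.18,
    "synonymous": 0.15,
    "3 prime UTR": 0.05,
    "5 prime UTR": 0.03,
    "splice region": 0.03,
    "frameshift": 0.01,
    "stop gained": 0.005,
    "splice donor": 0.005,
    "splice acceptor": 0.005,
    "inframe deletion": 0.01,
}


@dataclass
class CohortConfig:
    """All simulation knobs in one place.  ``seed`` is mandatory.

    Expression: per-gene baseline means are log-normal; per-gene biological
    coefficient of variation (BCV = 1/sqrt(theta)) is log-normal around 0.2,
    the bulk of what fibroblast cohorts show; latent batch structure is a
    rank-``q_true`` multiplicative factor model on log-mean scale.
    """

    n_samples: int = 100
    n_genes: int = 2000
    seed: int = 0

    # gene count model
    log_mean_mu: float = 5.0      # ln scale; median baseline ~150 counts
    log_mean_sigma: float = 1.8
    bcv_log_mu: float = float(np.log(0.2))
    bcv_log_sigma: float = 0.35
    q_true: int = 2
    latent_scale: float = 0.15    # sd of the low-rank term on ln(mu)
    libsize_sigma: float = 0.25   # lognormal spread of size factors

    # splicing model
    junctions_per_gene: int = 2
    psi_ref_alpha: float = 8.0    # Beta(8, 2): reference psi concentrated high
    psi_ref_beta: float = 2.0
    site_coverage_mean: float = 30.0
    site_coverage_size: float = 3.0
    splice_rho: float = 0.01      # beta-binomial intra-class correlation
    splice_efficiency: float = 0.9

    # mono-allelic expression model
    snvs_per_sample: int = 200
    allelic_coverage_mean: float = 40.0
    allelic_coverage_size: float = 2.0
    allelic_null_ratio: float = 0.5
    mae_rho_null: float = 0.02    # calibrated so ~5-6% of null SNVs reach raw p < 0.05
    mae_rho_signal: float = 0.0   # injected events drawn binomially by default

    # variant tables
    variants_per_sample: int = 100
    consequence_freqs: dict = field(default_factory=lambda: dict(DEFAULT_CONSEQUENCE_FREQS))
    rare_fraction: float = 0.1

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_samples", "n_genes", "junctions_per_gene",
                     "snvs_per_sample", "variants_per_sample"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name, value in asdict(self).items():
            if isinstance(value, (int, float)) and not np.isfinite(value):
                raise ValueError(f"{name} must be finite")

    def rng(self, stream=0):
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class TruthTable:
    """One row per injected event: (sample, target id, event type, true effect)."""

    events: pd.DataFrame

    COLUMNS = ["sample", "target", "event_type", "true_effect", "batch"]

    @classmethod
    def empty(cls):
        return cls(pd.DataFrame(columns=cls.COLUMNS))

    def __len__(self):
        return len(self.events)

    def append(self, other):
        return TruthTable(pd.concat([self.events, other.events], ignore_index=True))


def _round_half_up(x):
    return np.floor(np.asarray(x, dtype=float) + 0.5).astype(np.int64)


# ---------------------------------------------------------------------------
# gene counts


def simulate_counts(config):
    """NB counts with latent low-rank structure.

    ``log mu_ij = ln(s_j m_i) + L_ij`` where ``L`` is a rank-``q_true`` factor
    term with independent standard-normal loadings, rescaled so its entries
    have standard deviation ``latent_scale``.  Counts ~ NB(mu_ij, theta_i).
    The per-gene true theta, BCV and baseline mean are recorded as side-car
    columns on the annotation.
    """
    rng = config.rng(stream=1)
    G, S = config.n_genes, config.n_samples
    gene_ids = [f"G{i:05d}" for i in range(G)]
    sample_ids = [f"S{j:04d}" for j in range(S)]

    m = rng.lognormal(config.log_mean_mu, config.log_mean_sigma, size=G)
    bcv = rng.lognormal(config.bcv_log_mu, config.bcv_log_sigma, size=G)
    theta = 1.0 / bcv**2
    s = rng.lognormal(0.0, config.libsize_sigma, size=S)
    s /= np.exp(np.mean(np.log(s)))  # geometric mean 1

    log_mu = np.log(m)[:, None] + np.log(s)[None, :]
    if config.q_true > 0 and config.latent_scale > 0:
        loadings = rng.standard_normal((G, config.q_true))
        factors = rng.standard_normal((config.q_true, S))
        latent = loadings @ factors
        latent *= config.latent_scale / np.sqrt(config.q_true)
        log_mu = log_mu + latent
    mu = np.exp(log_mu)
    p_nb = theta[:, None] / (theta[:, None] + mu)
    counts = rng.negative_binomial(theta[:, None], p_nb)

    matrix = GeneCountMatrix(
        pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)
    )
    ann = pd.DataFrame(
        {
            "chromosome": [f"chr{1 + i % 22}" for i in range(G)],
            "start": np.arange(G) * 100_000 + 1,
            "end": np.arange(G) * 100_000 + 50_000,
            "gene_length": rng.integers(500, 10_000, size=G),
            "n_exons": rng.integers(1, 30, size=G),
            "true_mean": m,
            "true_theta": theta,
            "true_bcv": bcv,
            "true_size_factor_applies": True,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    annotation = GeneAnnotation(ann)
    return matrix, annotation, TruthTable.empty()


def inject_expression_outliers(matrix, fold_changes, batch_size, seed, expected=None):
    """Replace one random sample's count per targeted gene by
    round(fc x expected count), half-up.

    Genes are processed in disjoint batches of ``batch_size`` (the batch index
    is recorded so detection can be run one batch at a time, keeping the
    injected fraction small enough not to distort cohort-wide FDR).  Fold
    changes cycle over batches so each fc covers the full expression range.
    """
    fold_changes = [float(fc) for fc in np.atleast_1d(fold_changes)]
    if any(fc <= 0 for fc in fold_changes):
        raise ValueError("fold changes must be > 0")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    G, S = matrix.shape
    if batch_size > G:
        raise ValueError(f"batch_size {batch_size} exceeds number of genes {G}")
    rng = np.random.default_rng([int(seed), 2])
    counts = matrix.counts.to_numpy().copy()
    if expected is None:
        libsize = counts.sum(axis=0).astype(float)
        rel = libsize / libsize.mean()
        expected = counts.mean(axis=1, keepdims=True) * rel[None, :]
    expected = np.asarray(expected, dtype=float)

    rows = []
    order = rng.permutation(G)
    n_batches = int(np.ceil(G / batch_size))
    for b in range(n_batches):
        genes = order[b * batch_size:(b + 1) * batch_size]
        fc = fold_changes[b % len(fold_changes)] if len(fold_changes) > 1 else fold_changes[0]
        samples = rng.integers(0, S, size=len(genes))
        counts[genes, samples] = _round_half_up(fc * expected[genes, samples])
        for g, j in zip(genes, samples):
            rows.append((matrix.sample_ids[j], matrix.gene_ids[g],
                         "underexpression" if fc < 1 else "overexpression", fc, b))
    out = GeneCountMatrix(
        pd.DataFrame(counts, index=matrix.gene_ids, columns=matrix.sample_ids),
        matrix.strandedness,
    )
    truth = TruthTable(pd.DataFrame(rows, columns=TruthTable.COLUMNS))
    return out, truth


# ---------------------------------------------------------------------------
# splicing


def _betabinom_rvs(rng, n, p, rho):
    """Beta-binomial draws; rho = 0 degenerates to binomial."""
    n = np.asarray(n)
    p = np.broadcast_to(np.asarray(p, dtype=float), n.shape)
    if rho <= 0:
        return rng.binomial(n, p)
    a, b = betabinom_params(p, rho)
    return rng.binomial(n, rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12)))


def simulate_splice_counts(config):
    """Per gene: one donor site carrying two competing junctions.

    Site total split-read coverage is NB; the annotated junction's split reads
    are beta-binomial(total, psi_ref, rho); the alternative junction takes the
    remainder, so psi5 of the competing junctions sums to one by construction.
    Unsplit (exon-intron) coverage at the donor site is generated around the
    configured splicing efficiency for theta-metric testing.
    """
    rng = config.rng(stream=3)
    G, S = config.n_genes, config.n_samples
    gene_ids = [f"G{i:05d}" for i in range(G)]
    sample_ids = [f"S{j:04d}" for j in range(S)]

    psi_ref = rng.beta(config.psi_ref_alpha, config.psi_ref_beta, size=G)
    p_cov = config.site_coverage_size / (config.site_coverage_size + config.site_coverage_mean)
    totals = rng.negative_binomial(config.site_coverage_size, p_cov, size=(G, S))
    k = _betabinom_rvs(rng, totals, psi_ref[:, None], config.splice_rho)

    eff = config.splice_efficiency
    unsplit = rng.negative_binomial(
        config.site_coverage_size,
        config.site_coverage_size / (config.site_coverage_size + config.site_coverage_mean * (1 - eff) / eff),
        size=(G, S),
    )

    jrows, srows = [], []
    for i, gid in enumerate(gene_ids):
        donor = 1_000 + i * 10_000
        jrows.append(("chr1", donor, donor + 500, "+", gid, "annotated", psi_ref[i], *k[i]))
        jrows.append(("chr1", donor, donor + 900, "+", gid, "alternative", 1 - psi_ref[i], *(totals[i] - k[i])))
        srows.append(("chr1", donor, "+", "donor", gid,
                      *totals[i], *unsplit[i]))
    jcols = ["chromosome", "donor", "acceptor", "strand", "gene_id", "role", "psi_ref"] + sample_ids
    scols = (["chromosome", "position", "strand", "site_type", "gene_id"]
             + [f"split:{s}" for s in sample_ids] + [f"unsplit:{s}" for s in sample_ids])
    table = SpliceCountTable(
        pd.DataFrame(jrows, columns=jcols),
        pd.DataFrame(srows, columns=scols),
        sample_ids,
    )
    return table, TruthTable.empty()


def inject_splicing_outliers(table, delta_psi, n_events, seed):
    """Redraw ``n_events`` (junction, sample) cells at psi_ref + delta_psi.

    The target psi is clipped to [0, 1]; the achieved (possibly clipped)
    effect is recorded in the truth table.  Only annotated junctions are
    targeted, and the competing alternative junction is adjusted so site
    totals are preserved.
    """
    rng = np.random.default_rng([int(seed), 4])
    out = table.copy()
    ann_idx = np.flatnonzero(out.junctions["role"].to_numpy() == "annotated")
    S = len(out.sample_ids)
    chosen = rng.choice(len(ann_idx) * S, size=min(n_events, len(ann_idx) * S), replace=False)
    rows = []
    counts = out.junctions[out.sample_ids].to_numpy().copy()
    for flat in chosen:
        ji = ann_idx[flat // S]
        sj = flat % S
        psi_ref = float(out.junctions["psi_ref"].iloc[ji])
        target = float(np.clip(psi_ref + delta_psi, 0.0, 1.0))
        achieved = target - psi_ref
        total = counts[ji, sj] + counts[ji + 1, sj]  # alternative junction is the next row
        k_new = _betabinom_rvs(rng, np.array([total]), target, 0.0)[0]
        counts[ji, sj] = k_new
        counts[ji + 1, sj] = total - k_new
        rows.append((out.sample_ids[sj], out.junctions["gene_id"].iloc[ji],
                     "delta_psi", achieved, 0))
    out.junctions[out.sample_ids] = counts
    return out, TruthTable(pd.DataFrame(rows, columns=TruthTable.COLUMNS))


# ---------------------------------------------------------------------------
# allelic counts


def simulate_allelic_counts(config):
    """Null heterozygous SNVs: alt ~ beta-binomial(n, 0.5, mae_rho_null)."""
    rng = config.rng(stream=5)
    S, V = config.n_samples, config.snvs_per_sample
    sample_ids = [f"S{j:04d}" for j in range(S)]
    p_cov = config.allelic_coverage_size / (config.allelic_coverage_size + config.allelic_coverage_mean)
    rows = []
    for s in sample_ids:
        n = rng.negative_binomial(config.allelic_coverage_size, p_cov, size=V) + 1
        alt = _betabinom_rvs(rng, n, config.allelic_null_ratio, config.mae_rho_null)
        for v in range(V):
            rows.append((s, f"chr{1 + v % 22}", 10_000 + v * 997, "A", "G",
                         int(n[v] - alt[v]), int(alt[v]), False))
    table = AllelicCountTable(pd.DataFrame(
        rows, columns=["sample", "chromosome", "position", "ref", "alt",
                       "ref_count", "alt_count", "rare"]))
    return table, TruthTable.empty()


def inject_mae(table, ratio, n_events, seed, rho=None):
    """Redraw ``n_events`` variants' alt counts at the given allelic ratio.

    ratio in [0.5, 1]: the alternative allele becomes dominant.  Coverage is
    untouched; only the allelic split is redrawn.
    """
    if not 0.5 <= ratio <= 1.0:
        raise ValueError("ratio must be in [0.5, 1]")
    rng = np.random.default_rng([int(seed), 6])
    out = table.copy()
    t = out.table
    idx = rng.choice(len(t), size=min(n_events, len(t)), replace=False)
    n = (t.loc[idx, "ref_count"] + t.loc[idx, "alt_count"]).to_numpy()
    alt = _betabinom_rvs(rng, n, ratio, 0.0 if rho is None else rho)
    t.loc[idx, "alt_count"] = alt
    t.loc[idx, "ref_count"] = n - alt
    truth = TruthTable(pd.DataFrame({
        "sample": t.loc[idx, "sample"].to_numpy(),
        "target": (t.loc[idx, "chromosome"].astype(str) + ":" + t.loc[idx, "position"].astype(str)).to_numpy(),
        "event_type": "MAE",
        "true_effect": ratio,
        "batch": 0,
    }))
    return out, truth


# ---------------------------------------------------------------------------
# variants


def simulate_variants(config, gene_ids=None):
    """Annotated variant tables with consequence categories and MAFs.

    A ``rare_fraction`` of variants is drawn rare (population MAF below 1e-3
    and cohort frequency below 1e-2); the rest get common frequencies.  QD and
    FS are drawn from well-behaved ranges so the hard filters pass unless a
    test perturbs them.
    """
    rng = config.rng(stream=7)
    S, V = config.n_samples, config.variants_per_sample
    sample_ids = [f"S{j:04d}" for j in range(S)]
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(config.n_genes)]
    terms = list(config.consequence_freqs)
    freqs = np.array([config.consequence_freqs[t] for t in terms], dtype=float)
    freqs /= freqs.sum()
    rows = []
    for s in sample_ids:
        cons = rng.choice(terms, p=freqs, size=V)
        rare = rng.random(V) < config.rare_fraction
        maf_pop = np.where(rare, rng.uniform(0, 1e-3, V), rng.uniform(2e-3, 0.5, V))
        maf_cohort = np.where(rare, rng.uniform(0, 1e-2, V), rng.uniform(2e-2, 0.5, V))
        genes = rng.choice(gene_ids, size=V)
        for v in range(V):
            rows.append((s, f"chr{1 + v % 22}", 5_000 + v * 1_003, "C", "T",
                         rng.choice(["het", "hom"], p=[0.8, 0.2]),
                         cons[v], maf_pop[v], maf_cohort[v],
                         rng.uniform(2.5, 30), rng.uniform(0, 20),
                         int(rng.integers(3, 40)), False, genes[v]))
    table = VariantTable(pd.DataFrame(
        rows, columns=_VARIANT_MANDATORY_WITH_EXTRAS))
    return table


_VARIANT_MANDATORY_WITH_EXTRAS = [
    "sample", "chromosome", "position", "ref", "alt", "genotype",
    "consequence", "maf_population", "maf_cohort", "qd", "fs", "alt_reads",
    "in_repeat_mask", "gene_id",
]
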