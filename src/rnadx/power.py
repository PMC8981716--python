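"""Power analyses: expression-outlier recall and MAE recall curves.

Two questions drive diagnostic interpretation: how strongly must a gene be
expressed (and how tightly regulated, i.e. how low its BCV) for a given fold
change to be detectable, and how much allelic coverage does an SNV need for
mono-allelic expression to be callable.  Both are answered by injecting
known events into synthetic cohorts and measuring recall with the production
detection settings.

Expression outliers are injected in batches (default 300 genes per batch) so
that the injected fraction never distorts the cohort-wide FDR estimate; each
batch is detected in a separate fit.

The MAE curve embeds ``n_signal`` events per coverage point in a balanced
(ratio-0.5) null background making up 95% of variants at that coverage, runs
the production test + BH + imbalance rule, and reports recall per coverage
and the minimal coverage whose recall exceeds one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import bh_adjust
from .expression import ExpressionOutlierModel
from .mae import MAEConfig, mae_pvalue_exact, mae_pvalue_wald
from .simulate import (
    CohortConfig,
    _betabinom_rvs,
    inject_expression_outliers,
    simulate_counts,
)

__all__ = [
    "expression_recall_curve",
    "bcv_recall_curve",
    "mae_coverage_curve",
    "MAECoverageResult",
]


def _detect_injected(matrix, truth, q, fdr_cutoff):
    """Fit the expression model and return the truth frame with a recalled
    flag and the per-gene mean expression of the clean matrix."""
    model = ExpressionOutlierModel(matrix, q=q)
    res = model.fit()
    sig = res.fdr <= fdr_cutoff
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    sample_pos = {s: j for j, s in enumerate(matrix.sample_ids)}
    recalled = [
        bool(sig[gene_pos[g], sample_pos[s]])
        for s, g in zip(truth.events["sample"], truth.events["target"])
    ]
    out = truth.events.copy()
    out["recalled"] = recalled
    return out


def expression_recall_curve(config=None, fold_changes=(0.1, 0.2, 0.5, 2.0),
                            batch_size=300, bin_width=50, q=None,
                            fdr_cutoff=0.05, min_events_per_bin=20):
    """Recall of injected expression outliers per (fold change, mean-count bin).

    One detection fit per (fold change, batch); genes are binned by their
    clean-cohort mean count, bins centred at ``bin_width/2 + k*bin_width``.
    """
    config = config or CohortConfig(n_samples=80, n_genes=1200, seed=0)
    matrix, annotation, _ = simulate_counts(config)
    if q is None:
        q = config.q_true
    gene_mean = matrix.values().mean(axis=1)
    mean_by_gene = dict(zip(matrix.gene_ids, gene_mean))

    frames = []
    for fc in fold_changes:
        injected, truth = inject_expression_outliers(
            matrix, [fc], batch_size, seed=config.seed)
        for b, batch_truth in truth.events.groupby("batch"):
            batch_matrix = matrix.copy()
            cols = {s: j for j, s in enumerate(matrix.sample_ids)}
            rows = {g: i for i, g in enumerate(matrix.gene_ids)}
            vals = batch_matrix.counts.to_numpy()
            inj_vals = injected.counts.to_numpy()
            for s, g in zip(batch_truth["sample"], batch_truth["target"]):
                vals[rows[g], cols[s]] = inj_vals[rows[g], cols[s]]
            scored = _detect_injected(
                batch_matrix, type(truth)(batch_truth), q, fdr_cutoff)
            scored["fold_change"] = fc
            frames.append(scored)
    events = pd.concat(frames, ignore_index=True)
    events["mean_count"] = events["target"].map(mean_by_gene)
    events["bin"] = (events["mean_count"] // bin_width) * bin_width + bin_width / 2

    curve = (events.groupby(["fold_change", "bin"])
             .agg(recall=("recalled", "mean"), n=("recalled", "size"))
             .reset_index())
    curve["low_confidence"] = curve["n"] < min_events_per_bin
    return curve


def bcv_recall_curve(bcv_grid=(0.02, 0.05, 0.1, 0.15, 0.2, 0.3), fold_change=0.5,
                     mean_count=2000.0, n_samples=150, n_genes_per_bcv=120,
                     seed=0, q=0, fdr_cutoff=0.05, batch_size=None):
    """Recall of fc-injected outliers as a function of BCV at high expression.

    All genes share a high mean so dispersion is the limiting factor; genes
    are assigned BCVs from the grid in equal blocks.
    """
    rng = np.random.default_rng([int(seed), 21])
    bcvs = np.repeat(np.asarray(bcv_grid, dtype=float), n_genes_per_bcv)
    G = bcvs.size
    theta = 1.0 / bcvs**2
    mu = np.full((G, n_samples), float(mean_count))
    counts = rng.negative_binomial(theta[:, None], theta[:, None] / (theta[:, None] + mu))

    from .io import GeneCountMatrix

    gene_ids = [f"G{i:05d}" for i in range(G)]
    sample_ids = [f"S{j:04d}" for j in range(n_samples)]
    matrix = GeneCountMatrix(pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                                          columns=sample_ids))
    batch = batch_size or min(300, G)
    injected, truth = inject_expression_outliers(matrix, [fold_change], batch, seed=seed,
                                                 expected=mu)
    frames = []
    for b, batch_truth in truth.events.groupby("batch"):
        bm = matrix.copy()
        vals = bm.counts.to_numpy()
        inj = injected.counts.to_numpy()
        rows = {g: i for i, g in enumerate(gene_ids)}
        cols = {s: j for j, s in enumerate(sample_ids)}
        for s, g in zip(batch_truth["sample"], batch_truth["target"]):
            vals[rows[g], cols[s]] = inj[rows[g], cols[s]]
        frames.append(_detect_injected(bm, type(truth)(batch_truth), q, fdr_cutoff))
    events = pd.concat(frames, ignore_index=True)
    events["bcv"] = events["target"].map(dict(zip(gene_ids, bcvs)))
    return (events.groupby("bcv").agg(recall=("recalled", "mean"),
                                      n=("recalled", "size")).reset_index())


@dataclass
class MAECoverageResult:
    curve: pd.DataFrame                  # ratio, coverage, recall, n
    thresholds: dict = field(default_factory=dict)  # ratio -> minimal coverage with recall > 0.5

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for ratio, g in self.curve.groupby("ratio"):
            ax.plot(g["coverage"], g["recall"], marker="o", ms=3, label=f"ratio {ratio}")
        ax.axhline(0.5, ls="--", c="grey", lw=0.8)
        ax.set_xlabel("RNA-seq coverage (reads)")
        ax.set_ylabel("recall of injected MAE events")
        ax.legend()
        return ax


def mae_coverage_curve(ratios=(0.85, 0.95), coverage_grid=None, n_signal=2000,
                       null_fraction=0.95, alpha=None, method=None,
                       rho_null=0.02, rho_signal=0.0, seed=0,
                       fdr_cutoff=0.05, imbalance_cutoff=0.8):
    """Recall of injected MAE events per (allelic ratio, coverage).

    At each coverage the tested set is ``n_signal`` events at the given
    allelic ratio embedded in a balanced beta-binomial null background
    (``null_fraction`` of all variants); BH runs across the whole set, as it
    would across a sample's tested SNVs.  The threshold per ratio is the
    smallest coverage whose recall exceeds 0.5.
    """
    cfg = MAEConfig()
    alpha = cfg.alpha if alpha is None else alpha
    method = cfg.method if method is None else method
    if coverage_grid is None:
        coverage_grid = range(5, 61)
    n_null = int(round(n_signal * null_fraction / (1.0 - null_fraction)))
    pfun = mae_pvalue_wald if method == "wald" else mae_pvalue_exact

    rows = []
    thresholds = {}
    for ratio in ratios:
        rng = np.random.default_rng([int(seed), 31, int(round(ratio * 1000))])
        for cov in coverage_grid:
            n = int(cov)
            alt_null = _betabinom_rvs(rng, np.full(n_null, n), 0.5, rho_null)
            alt_sig = _betabinom_rvs(rng, np.full(n_signal, n), ratio, rho_signal)
            alt = np.concatenate([alt_null, alt_sig])
            total = np.full(alt.size, n)
            p = pfun(alt, total, alpha)
            fdr = bh_adjust(p)
            imbalance = np.maximum(alt, total - alt) / total
            called = (fdr <= fdr_cutoff) & (imbalance > imbalance_cutoff)
            recall = called[n_null:].mean()
            rows.append((ratio, n, recall, n_signal))
            if ratio not in thresholds and recall > 0.5:
                thresholds[ratio] = n
        thresholds.setdefault(ratio, None)
    curve = pd.DataFrame(rows, columns=["ratio", "coverage", "recall", "n"])
    return MAECoverageResult(curve, thresholds)
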