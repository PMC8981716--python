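"""Aberrant expression calling with a negative-binomial outlier test.

The model follows the autoencoder-based callers in contract, not mechanism:
library-size factors by median-of-ratios, a deterministic rank-q fit
(truncated SVD of centred log counts) removing latent confounders, per-gene
NB dispersion by profile maximum likelihood with the fitted means held fixed,
and an exact two-sided NB p-value per (gene, sample) with Benjamini-Hochberg
correction across genes within each sample.  The rank q can be chosen
automatically by maximising recovery of self-injected outliers, the same
hyperparameter scheme the autoencoder callers use.

A gene's biological coefficient of variation is BCV = 1/sqrt(theta); genes
with BCV above roughly 0.12 are effectively blind to two-fold changes, which
the power module quantifies.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust_matrix, nb_pvalue_two_sided
from .qc import fpkm

__all__ = [
    "filter_expressed",
    "ExpressionOutlierModel",
    "ExpressionOutlierResults",
    "bcv",
]

_THETA_GRID = np.exp(np.linspace(np.log(1e-2), np.log(1e5), 120))


def filter_expressed(matrix, annotation, fpkm_cutoff=1.0, percentile=95):
    """Boolean gene mask: keep genes whose 95th-percentile FPKM >= 1.

    The percentile is nearest-rank (ceil(p/100 * n)-th order statistic), so a
    gene expressed at FPKM >= 1 in over 5% of samples survives.
    """
    f = fpkm(matrix, annotation)
    n = f.shape[1]
    rank = int(np.ceil(percentile / 100 * n))  # 1-based nearest-rank
    pctl = np.sort(f, axis=1)[:, rank - 1]
    return pctl >= fpkm_cutoff


def _size_factors(counts):
    """DESeq median-of-ratios; falls back to library-size ratios when no gene
    is expressed in every sample."""
    counts = counts.astype(float)
    with np.errstate(divide="ignore"):
        log_counts = np.log(counts)
    ok = np.isfinite(log_counts).all(axis=1)
    if ok.sum() >= 10:
        log_geo = log_counts[ok].mean(axis=1, keepdims=True)
        sf = np.exp(np.median(log_counts[ok] - log_geo, axis=0))
    else:
        lib = counts.sum(axis=0)
        sf = lib / np.exp(np.mean(np.log(lib)))
    return sf


def _fit_theta_grid(x, mu, grid=_THETA_GRID):
    """Per-gene profile-ML dispersion on a log-spaced grid with parabolic
    refinement.  Vectorised over genes; mu is held fixed."""
    G = x.shape[0]
    best_ll = np.full(G, -np.inf)
    best_idx = np.zeros(G, dtype=int)
    lls = np.empty((G, grid.size))
    for i, theta in enumerate(grid):
        p_nb = theta / (theta + mu)
        ll = stats.nbinom.logpmf(x, theta, p_nb).sum(axis=1)
        lls[:, i] = ll
        better = ll > best_ll
        best_ll[better] = ll[better]
        best_idx[better] = i
    # parabolic refinement in log-theta on the three grid points around the max
    log_grid = np.log(grid)
    theta_hat = grid[best_idx].astype(float)
    interior = (best_idx > 0) & (best_idx < grid.size - 1)
    ii = best_idx[interior]
    y0 = lls[interior, ii - 1]
    y1 = lls[interior, ii]
    y2 = lls[interior, ii + 1]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
    shift = np.clip(shift, -1.0, 1.0)
    step = log_grid[1] - log_grid[0]
    theta_hat[interior] = np.exp(log_grid[ii] + shift * step)
    return theta_hat


class ExpressionOutlierModel:
    """Negative-binomial expression-outlier model for a count matrix.

    Parameters
    ----------
    matrix : GeneCountMatrix
        Filtered counts (apply :func:`filter_expressed` first; all-zero genes
        are rejected).
    annotation : GeneAnnotation, optional
        Used only to attach gene metadata to calls.
    q : int or "auto"
        Rank of the latent-factor fit.  "auto" selects the rank by maximising
        average precision on self-injected corrupted counts.

    Examples
    --------
    >>> model = ExpressionOutlierModel(matrix, q=2)
    >>> res = model.fit()
    >>> calls = res.calls(fdr_cutoff=0.05)
    """

    def __init__(self, matrix, annotation=None, q="auto"):
        self.matrix = matrix
        self.annotation = annotation
        self.q = q
        x = matrix.values()
        if (x.sum(axis=1) == 0).any():
            raise ValueError("all-zero gene reached the fit; filter_expressed must precede")
        if x.shape[1] < 20:
            warnings.warn("fewer than 20 samples; dispersion estimates will be noisy")

    # -- fitting ----------------------------------------------------------

    def fit(self, auto_q_grid=(1, 2, 3, 5, 7, 10, 15, 20), seed=0):
        x = self.matrix.values()
        sf = _size_factors(x)
        q = self.q
        if q == "auto":
            q = self._select_q(x, sf, auto_q_grid, seed)
        mu = self._fit_mu(x, sf, q)
        theta = _fit_theta_grid(x, mu)
        return ExpressionOutlierResults(self, sf, mu, theta, q)

    @staticmethod
    def _fit_mu(x, sf, q):
        """Rank-q reconstruction of log size-normalised counts, rescaled per
        gene so fitted and observed totals agree."""
        l = np.log((x + 1.0) / sf[None, :])
        center = l.mean(axis=1, keepdims=True)
        if q > 0:
            resid = l - center
            u, s, vt = np.linalg.svd(resid, full_matrices=False)
            k = min(q, s.size)
            recon = (u[:, :k] * s[:k]) @ vt[:k]
        else:
            recon = 0.0
        mu = np.exp(center + recon) * sf[None, :]
        scale = x.sum(axis=1) / np.maximum(mu.sum(axis=1), 1e-12)
        mu *= scale[:, None]
        return np.maximum(mu, 1e-8)

    def _select_q(self, x, sf, grid, seed, inject_fraction=0.01, z=4.0):
        """Autoencoder-style hyperparameter search: corrupt a random subset of
        cells by +-z standard deviations on log scale, refit at each rank, and
        keep the rank with the best average precision at recovering them."""
        rng = np.random.default_rng([int(seed), 11])
        G, S = x.shape
        n_inject = max(200, int(inject_fraction * G * S))
        flat = rng.choice(G * S, size=min(n_inject, G * S), replace=False)
        gi, sj = np.unravel_index(flat, (G, S))
        l = np.log((x + 1.0) / sf[None, :])
        sd = l.std(axis=1)
        sign = rng.choice([-1.0, 1.0], size=flat.size)
        corrupted = x.copy()
        corrupted[gi, sj] = np.round(
            np.exp(l[gi, sj] + sign * z * sd[gi]) * sf[sj] - 1).clip(0).astype(np.int64)
        injected = np.zeros(G * S, dtype=bool)
        injected[flat] = True

        best_q, best_score = grid[0], -np.inf
        for q in grid:
            if q >= min(G, S):
                continue
            mu = self._fit_mu(corrupted, sf, q)
            theta = _fit_theta_grid(corrupted, mu, grid=_THETA_GRID[::4])
            p = nb_pvalue_two_sided(corrupted, mu, theta[:, None]).ravel()
            order = np.argsort(p)
            hits = injected[order]
            precision = np.cumsum(hits) / np.arange(1, hits.size + 1)
            score = (precision * hits).sum() / max(injected.sum(), 1)
            if score > best_score:
                best_q, best_score = q, score
        return int(best_q)


class ExpressionOutlierResults:
    """Fitted expression model: size factors, expected means, dispersions and
    outlier statistics."""

    def __init__(self, model, size_factors, mu, theta, q):
        self.model = model
        self.size_factors = size_factors
        self.mu = mu
        self.theta = theta
        self.q = q
        self._x = model.matrix.values()
        self.pvalues = nb_pvalue_two_sided(self._x, self.mu, self.theta[:, None])
        self.fdr = bh_adjust_matrix(self.pvalues, axis=0)  # across genes, per sample
        with np.errstate(divide="ignore", invalid="ignore"):
            log_resid = np.log2(self._x + 1.0) - np.log2(self.mu + 1.0)
        sd = log_resid.std(axis=1, ddof=1)
        self.zscores = log_resid / np.maximum(sd[:, None], 1e-12)

    @property
    def bcv(self):
        """Per-gene biological coefficient of variation, 1/sqrt(theta)."""
        return 1.0 / np.sqrt(self.theta)

    @property
    def fold_change(self):
        """Pseudocount-stabilised fold change (x+1)/(mu+1), reporting only."""
        return (self._x + 1.0) / (self.mu + 1.0)

    def calls(self, fdr_cutoff=0.05):
        """Significant outliers as a tidy OutlierCall frame, sorted by FDR."""
        gi, sj = np.nonzero(self.fdr <= fdr_cutoff)
        m = self.model.matrix
        fc = self.fold_change[gi, sj]
        calls = pd.DataFrame({
            "sample": np.asarray(m.sample_ids)[sj],
            "gene": np.asarray(m.gene_ids)[gi],
            "class": np.where(fc < 1, "underexpression", "overexpression"),
            "p_value": self.pvalues[gi, sj],
            "fdr": self.fdr[gi, sj],
            "effect_size": fc,
            "z_score": self.zscores[gi, sj],
        })
        return calls.sort_values("fdr", kind="stable").reset_index(drop=True)

    def outliers_per_sample(self, fdr_cutoff=0.05):
        counts = (self.fdr <= fdr_cutoff).sum(axis=0)
        return pd.Series(counts, index=self.model.matrix.sample_ids)

    def summary(self):
        m = self.model.matrix
        n_sig = int((self.fdr <= 0.05).sum())
        lines = [
            "Expression outlier model",
            "=" * 46,
            f"genes                 {m.shape[0]}",
            f"samples               {m.shape[1]}",
            f"latent rank q         {self.q}",
            f"median dispersion     {np.median(self.theta):.3g}",
            f"median BCV            {np.median(self.bcv):.3f}",
            f"calls at FDR<=0.05    {n_sig}",
            f"median calls/sample   {np.median((self.fdr <= 0.05).sum(axis=0)):.1f}",
        ]
        return "\n".join(lines)

    def plot_volcano(self, sample, ax=None):
        """-log10 p versus log2 fold change for one sample."""
        import matplotlib.pyplot as plt

        j = list(self.model.matrix.sample_ids).index(sample)
        if ax is None:
            _, ax = plt.subplots()
        lfc = np.log2(self.fold_change[:, j])
        ax.scatter(lfc, -np.log10(np.maximum(self.pvalues[:, j], 1e-300)),
                   s=6, c=np.where(self.fdr[:, j] <= 0.05, "crimson", "grey"))
        ax.set_xlabel("log2 fold change (obs/expected)")
        ax.set_ylabel("-log10 p")
        ax.set_title(f"expression outliers: {sample}")
        return ax


def bcv(results_or_theta):
    """Biological coefficient of variation 1/sqrt(theta)."""
    theta = getattr(results_or_theta, "theta", results_or_theta)
    return 1.0 / np.sqrt(np.asarray(theta, dtype=float))
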