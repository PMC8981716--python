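"""Shared statistical primitives: exact count-test p-values and multiple testing.

Conventions used throughout the package:

* Negative binomial parameterised by mean ``mu`` and size ``theta`` with
  ``Var(X) = mu + mu^2 / theta``; the biological coefficient of variation is
  ``1/sqrt(theta)``.
* Beta-binomial parameterised by ``(n, p, rho)`` where ``rho`` is the
  intra-class correlation; ``rho -> 0`` degenerates to the binomial.
* Two-sided p-values by tail doubling, ``p = min(1, 2 min(P(X<=x), P(X>=x)))``,
  which is monotone in the distance from the centre of the distribution.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "nb_pvalue_two_sided",
    "betabinom_params",
    "betabinom_pvalue_two_sided",
    "bh_adjust",
    "holm_adjust",
    "bh_adjust_matrix",
    "holm_adjust_matrix",
]


def nb_pvalue_two_sided(x, mu, theta):
    """Exact two-sided NB p-value by tail doubling.

    ``P(X <= x)`` and ``P(X >= x)`` are both computed under NB(mu, theta);
    the observation itself is included in both tails, so ``p`` can exceed 1
    before clipping (e.g. a draw at the mode).
    """
    x = np.asarray(x)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    p_nb = theta / (theta + mu)
    lower = stats.nbinom.cdf(x, theta, p_nb)
    upper = stats.nbinom.sf(x - 1, theta, p_nb)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def betabinom_params(p, rho):
    """Convert (mean fraction, intra-class correlation) to beta shape (a, b)."""
    p = np.asarray(p, dtype=float)
    rho = np.asarray(rho, dtype=float)
    scale = (1.0 - rho) / rho
    return p * scale, (1.0 - p) * scale


def betabinom_pvalue_two_sided(k, n, p, rho, min_rho=1e-8):
    """Two-sided beta-binomial p-value by tail doubling.

    For ``rho`` at or below ``min_rho`` the binomial distribution is used
    directly, avoiding numerically degenerate beta shapes.
    """
    k = np.asarray(k)
    n = np.asarray(n)
    p = np.asarray(p, dtype=float)
    rho = np.broadcast_to(np.asarray(rho, dtype=float), np.broadcast_shapes(np.shape(k), np.shape(rho))) \
        if np.ndim(rho) else np.full(np.shape(k) or (1,), float(rho))
    k, n, p, rho = np.broadcast_arrays(k, n, p, rho)
    out = np.ones(k.shape, dtype=float)
    binom_mask = rho <= min_rho
    if binom_mask.any():
        lower = stats.binom.cdf(k[binom_mask], n[binom_mask], p[binom_mask])
        upper = stats.binom.sf(k[binom_mask] - 1, n[binom_mask], p[binom_mask])
        out[binom_mask] = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    bb = ~binom_mask
    if bb.any():
        a, b = betabinom_params(p[bb], rho[bb])
        lower = stats.betabinom.cdf(k[bb], n[bb], a, b)
        upper = stats.betabinom.sf(k[bb] - 1, n[bb], a, b)
        out[bb] = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return out if out.shape else float(out)


def bh_adjust_matrix(pvalues, axis=0):
    """Benjamini-Hochberg adjusted p-values along ``axis``, NaN-tolerant.

    Each 1-D slice along the axis is an independent family; NaNs stay NaN and
    do not count toward the family size.
    """
    p = np.asarray(pvalues, dtype=float)
    p2 = np.moveaxis(np.atleast_2d(p), axis if p.ndim > 1 else -1, 0)
    shape = p2.shape
    p2 = p2.reshape(shape[0], -1)
    finite = np.isfinite(p2)
    m = finite.sum(axis=0)
    work = np.where(finite, p2, np.inf)
    order = np.argsort(work, axis=0, kind="stable")
    sorted_p = np.take_along_axis(work, order, axis=0)
    ranks = np.arange(1, shape[0] + 1)[:, None]
    adj = sorted_p * m[None, :] / ranks
    adj = np.minimum.accumulate(adj[::-1], axis=0)[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(work)
    np.put_along_axis(out, order, adj, axis=0)
    out[~finite] = np.nan
    out = out.reshape(shape)
    out = np.moveaxis(out, 0, axis if p.ndim > 1 else -1)
    return out.reshape(np.shape(pvalues))


def holm_adjust_matrix(pvalues, axis=0):
    """Holm step-down adjusted p-values along ``axis``, NaN-tolerant."""
    p = np.asarray(pvalues, dtype=float)
    p2 = np.moveaxis(np.atleast_2d(p), axis if p.ndim > 1 else -1, 0)
    shape = p2.shape
    p2 = p2.reshape(shape[0], -1)
    finite = np.isfinite(p2)
    m = finite.sum(axis=0)
    work = np.where(finite, p2, np.inf)
    order = np.argsort(work, axis=0, kind="stable")
    sorted_p = np.take_along_axis(work, order, axis=0)
    ranks = np.arange(shape[0])[:, None]
    mult = np.maximum(m[None, :] - ranks, 1)
    adj = np.maximum.accumulate(np.where(np.isfinite(sorted_p), mult * sorted_p, np.inf), axis=0)
    adj = np.minimum(adj, 1.0)
    out = np.empty_like(work)
    np.put_along_axis(out, order, adj, axis=0)
    out[~finite] = np.nan
    out = out.reshape(shape)
    out = np.moveaxis(out, 0, axis if p.ndim > 1 else -1)
    return out.reshape(np.shape(pvalues))


def bh_adjust(pvalues):
    """Benjamini-Hochberg adjusted p-values (1-D), NaN-tolerant."""
    return bh_adjust_matrix(np.asarray(pvalues, dtype=float).ravel()).reshape(np.shape(pvalues))


def holm_adjust(pvalues):
    """Holm step-down adjusted p-values (1-D), NaN-tolerant."""
    return holm_adjust_matrix(np.asarray(pvalues, dtype=float).ravel()).reshape(np.shape(pvalues))
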