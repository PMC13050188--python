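"""Genomic relatedness and the pairwise phenotypic-correlation curve.

The genomic relationship between two individuals is the average
cross-product of their standardized dosages, (X - 2q)/sqrt(2q(1-q)),
over loci.  Binning all pairs by relatedness and computing the Pearson
correlation of their phenotype pairs per bin yields a curve whose slope
in the unrelated region estimates the heritability; close relatives
(full sibs near 0.5) reveal extra resemblance from indirect parental
effects and assortment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "standardized_dosages",
    "grm",
    "RelatednessCurve",
    "correlation_curve",
    "full_sib_correlation",
]

logger = logging.getLogger(__name__)


def standardized_dosages(
    dosages: np.ndarray, allele_freqs: np.ndarray | None = None
) -> np.ndarray:
    """(X - 2q) / sqrt(2q(1-q)) per locus, monomorphic loci dropped.

    Frequencies default to the sample frequencies.  The number of
    excluded monomorphic loci is logged.
    """
    x = np.asarray(dosages, dtype=np.float32)
    if allele_freqs is None:
        q = x.mean(axis=0) / 2.0
    else:
        q = np.asarray(allele_freqs, dtype=np.float32)
    keep = (q > 0) & (q < 1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("excluding %d monomorphic loci from relatedness", n_dropped)
    x = x[:, keep]
    q = q[keep]
    return (x - 2.0 * q) / np.sqrt(2.0 * q * (1.0 - q))


def grm(dosages: np.ndarray, allele_freqs: np.ndarray | None = None) -> np.ndarray:
    """Full genomic relationship matrix Z Z^T / L (diagnostic scale)."""
    z = standardized_dosages(dosages, allele_freqs)
    return (z @ z.T) / z.shape[1]


@dataclass
class RelatednessCurve:
    """Binned relatedness vs pair phenotypic correlation with slope fits."""

    bin_mid: np.ndarray  # mean relatedness of pairs in each retained bin
    n_pairs: np.ndarray
    corr: np.ndarray  # Pearson correlation of phenotype pairs per bin
    se: np.ndarray  # large-sample standard error of each correlation
    slope: float  # weighted fit over the unrelated region
    intercept: float
    fit_range: tuple[float, float]

    def predict(self, pi: float | np.ndarray) -> np.ndarray:
        """Linear extrapolation of the unrelated-region fit."""
        return self.intercept + self.slope * np.asarray(pi)

    def close_relative_excess(self, pi_threshold: float = 0.4) -> float:
        """Mean (pair-weighted) observed minus extrapolated correlation
        over bins beyond ``pi_threshold`` — positive when close
        relatives resemble each other more than the unrelated-region
        slope predicts."""
        mask = self.bin_mid >= pi_threshold
        if not mask.any():
            raise ValueError("no bins beyond threshold")
        w = self.n_pairs[mask].astype(float)
        excess = self.corr[mask] - self.predict(self.bin_mid[mask])
        return float((w * excess).sum() / w.sum())


def _accumulate_pairs(
    z: np.ndarray,
    y: np.ndarray,
    edges: np.ndarray,
    rng: np.random.Generator,
    chunk: int,
) -> np.ndarray:
    """Per-bin accumulators (n, sum a, sum b, sum a^2, sum b^2, sum ab)
    over all unordered pairs, each entered once in randomized member
    order.  Row-chunked so the full pair matrix is never materialized."""
    n, n_loci = z.shape
    n_bins = len(edges) + 1
    acc = np.zeros((n_bins, 6))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = (z[start:stop] @ z.T) / n_loci  # (chunk, n)
        for i in range(start, stop):
            pi_row = block[i - start, i + 1 :]
            if pi_row.size == 0:
                continue
            bins = np.searchsorted(edges, pi_row)
            yj = y[i + 1 :]
            swap = rng.random(pi_row.size) < 0.5
            a = np.where(swap, yj, y[i])
            b = np.where(swap, y[i], yj)
            acc[:, 0] += np.bincount(bins, minlength=n_bins)
            acc[:, 1] += np.bincount(bins, weights=a, minlength=n_bins)
            acc[:, 2] += np.bincount(bins, weights=b, minlength=n_bins)
            acc[:, 3] += np.bincount(bins, weights=a * a, minlength=n_bins)
            acc[:, 4] += np.bincount(bins, weights=b * b, minlength=n_bins)
            acc[:, 5] += np.bincount(bins, weights=a * b, minlength=n_bins)
    return acc


def correlation_curve(
    dosages: np.ndarray,
    phenotypes: np.ndarray,
    allele_freqs: np.ndarray | None = None,
    bin_width: float = 0.01,
    min_pairs: int = 30,
    fit_range: tuple[float, float] = (-0.02, 0.02),
    pi_limits: tuple[float, float] = (-0.1, 0.7),
    chunk: int = 512,
    rng: np.random.Generator | int | None = None,
) -> RelatednessCurve:
    """Bin all pairs by genomic relatedness; Pearson correlation per bin.

    Phenotypes are standardized internally.  Each unordered pair enters
    once, in randomized member order (the randomization only affects
    which member is 'a' vs 'b'; with many pairs per bin the correlation
    is insensitive to it).  Bins with fewer than ``min_pairs`` pairs are
    dropped.  The slope is a pair-count-weighted least-squares fit of
    bin correlation on bin mean relatedness over ``fit_range``.
    """
    rng = np.random.default_rng(rng)
    y = np.asarray(phenotypes, dtype=float)
    y = (y - y.mean()) / y.std()
    z = standardized_dosages(dosages, allele_freqs)

    lo, hi = pi_limits
    edges = np.arange(lo, hi + bin_width, bin_width)
    acc = _accumulate_pairs(z, y, edges, rng, chunk)

    # also accumulate mean pi per bin for fit abscissa
    mids = np.concatenate([[lo - bin_width / 2], (edges[:-1] + edges[1:]) / 2, [hi + bin_width / 2]])

    n = acc[:, 0]
    keep = n >= max(min_pairs, 4)
    n_k = n[keep]
    sa, sb, saa, sbb, sab = (acc[keep, i] for i in range(1, 6))
    cov = sab / n_k - (sa / n_k) * (sb / n_k)
    va = saa / n_k - (sa / n_k) ** 2
    vb = sbb / n_k - (sb / n_k) ** 2
    corr = cov / np.sqrt(va * vb)
    se = (1.0 - corr**2) / np.sqrt(np.maximum(n_k - 1, 1))
    mid = mids[keep]

    in_fit = (mid >= fit_range[0]) & (mid <= fit_range[1])
    if in_fit.sum() < 2:
        raise ValueError("fewer than two bins inside the fit range")
    w = n_k[in_fit]
    xw = mid[in_fit]
    yw = corr[in_fit]
    wsum = w.sum()
    xbar = (w * xw).sum() / wsum
    ybar = (w * yw).sum() / wsum
    slope = ((w * (xw - xbar) * (yw - ybar)).sum()) / ((w * (xw - xbar) ** 2).sum())
    intercept = ybar - slope * xbar

    return RelatednessCurve(
        bin_mid=mid,
        n_pairs=n_k.astype(np.int64),
        corr=corr,
        se=se,
        slope=float(slope),
        intercept=float(intercept),
        fit_range=fit_range,
    )


def full_sib_correlation(phenotypes: np.ndarray, sib_pairs: np.ndarray) -> float:
    """Phenotypic correlation over full-sibling pairs (double entry).

    Each pair contributes both orderings, making the estimate symmetric
    in the siblings (the intraclass convention).  Pairs with a missing
    member (index < 0) are skipped.
    """
    sib_pairs = np.asarray(sib_pairs)
    ok = (sib_pairs >= 0).all(axis=1)
    if not ok.any():
        raise ValueError("no complete sibling pairs")
    a = np.asarray(phenotypes, dtype=float)[sib_pairs[ok, 0]]
    b = np.asarray(phenotypes, dtype=float)[sib_pairs[ok, 1]]
    x = np.concatenate([a, b])
    y = np.concatenate([b, a])
    return float(np.corrcoef(x, y)[0, 1])
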