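"""Synthetic founder haplotype panel.

Founders stand in for a reference panel of phased biallelic SNPs.  The
generator is a first-order Markov (latent Gaussian autoregressive)
copying model along loci: adjacent loci share latent correlation
``ld_decay`` per interval, so allele association decays geometrically
with locus distance, a coarse emulation of linkage-disequilibrium decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["HaplotypePanel", "generate_founders"]


@dataclass
class HaplotypePanel:
    """A phased panel: ``haplotypes`` is (2n, L) in {0, 1} copies of A2."""

    haplotypes: np.ndarray
    allele_freqs: np.ndarray  # realized A2 frequency per locus
    positions: np.ndarray  # abstract coordinates (locus index)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[1]


def generate_founders(
    n: int,
    n_loci: int,
    maf_bounds: tuple[float, float] = (0.05, 0.5),
    ld_decay: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> HaplotypePanel:
    """Generate ``2 n`` phased haplotypes over ``n_loci`` biallelic loci.

    Per-locus A2 frequencies are drawn uniformly from ``maf_bounds``.
    ``ld_decay`` in [0, 1) is the latent adjacent-locus correlation: 0
    gives independent loci, values near 1 long-range association.
    Monomorphic columns (possible at small n) are redrawn independently
    so every realized frequency is polymorphic.  Deterministic given the
    seed / generator.
    """
    if n < 1 or n_loci < 1:
        raise ValueError("n and n_loci must be >= 1")
    if not (0.0 <= ld_decay < 1.0):
        raise ValueError(f"ld_decay must be in [0, 1), got {ld_decay}")
    lo, hi = maf_bounds
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("maf_bounds must satisfy 0 < lo <= hi < 1")
    rng = np.random.default_rng(rng)

    q = rng.uniform(lo, hi, size=n_loci)
    thresh = stats.norm.ppf(q)

    n_hap = 2 * n
    latent = np.empty((n_hap, n_loci))
    latent[:, 0] = rng.standard_normal(n_hap)
    if n_loci > 1:
        innov = rng.standard_normal((n_hap, n_loci - 1))
        scale = np.sqrt(1.0 - ld_decay**2)
        for j in range(1, n_loci):
            latent[:, j] = ld_decay * latent[:, j - 1] + scale * innov[:, j - 1]
    hap = (latent < thresh).astype(np.uint8)

    # redraw monomorphic columns iid (breaks their LD, but keeps every
    # locus usable downstream; rare for n*q >> 1)
    freqs = hap.mean(axis=0)
    bad = np.flatnonzero((freqs == 0.0) | (freqs == 1.0))
    for j in bad:
        col = (rng.random(n_hap) < q[j]).astype(np.uint8)
        while col.min() == col.max():
            col = (rng.random(n_hap) < q[j]).astype(np.uint8)
        hap[:, j] = col
    freqs = hap.mean(axis=0)

    return HaplotypePanel(
        haplotypes=hap, allele_freqs=freqs, positions=np.arange(n_loci)
    )
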