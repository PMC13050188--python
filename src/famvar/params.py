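"""Domain parameter types shared across the package.

A biallelic locus carries five effect sizes acting on a child's phenotype:

* ``beta_c`` -- direct effect of the child's own allele dose,
* ``beta_m`` -- indirect effect of the mother's allele dose,
* ``beta_f`` -- indirect effect of the father's allele dose,
* ``beta_i`` -- parent-of-origin (imprinting) effect, positive for a
  maternally inherited A2 allele and negative for a paternally inherited
  one in heterozygotes,
* ``beta_s`` -- indirect effect of a sibling's allele dose.

Genotypes are dose-coded 0/1/2 copies of allele A2; the imprinting
covariate is coded +1 / -1 / 0 (maternal-A2 heterozygote / paternal-A2
heterozygote / homozygote).  This coding is fixed package-wide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["LocusParams", "AssortmentParams", "MultiLocusModel"]


@dataclass(frozen=True)
class LocusParams:
    """Allele frequency and effect sizes of one biallelic locus.

    Parameters
    ----------
    q2
        Frequency of allele A2, strictly inside (0, 1).
    beta_c, beta_m, beta_f, beta_i, beta_s
        Direct, indirect maternal, indirect paternal, parent-of-origin
        and indirect sibling effect sizes (trait units per A2 dose; the
        imprinting effect is per unit of the +1/-1 phase code).
    """

    q2: float
    beta_c: float = 0.0
    beta_m: float = 0.0
    beta_f: float = 0.0
    beta_i: float = 0.0
    beta_s: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.q2 < 1.0):
            raise ValueError(f"q2 must be in (0, 1), got {self.q2}")
        for name in ("beta_c", "beta_m", "beta_f", "beta_i", "beta_s"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def q1(self) -> float:
        """Frequency of allele A1 (= 1 - q2)."""
        return 1.0 - self.q2

    def relabelled(self) -> "LocusParams":
        """Return the locus under the allele relabelling A1 <-> A2.

        Swapping allele labels maps q2 -> q1 and flips the sign of every
        effect (including the imprinting effect, whose phase code also
        flips sign).  All variance formulas are invariant under this map.
        """
        return LocusParams(
            q2=self.q1,
            beta_c=-self.beta_c,
            beta_m=-self.beta_m,
            beta_f=-self.beta_f,
            beta_i=-self.beta_i,
            beta_s=-self.beta_s,
        )


@dataclass(frozen=True)
class AssortmentParams:
    """Correlation structure induced by assortative mating.

    Parameters
    ----------
    rho
        Correlation among the two alleles a child inherits at one causal
        locus (equivalently, the inbreeding coefficient F at that locus).
        Restricted to [0, 1]; disassortative mating is not modelled.
    rho_y
        Target phenotypic correlation among mates.  This is a simulator
        knob; the closed-form variances take ``rho`` at the allele level.
    f, k, s
        Allele-level correlations in a child: same locus across gametes
        (``f``, identical to ``rho``), different loci within one gamete
        (``k``), different loci across gametes (``s``).
    """

    rho: float = 0.0
    rho_y: float = 0.0
    f: float = 0.0
    k: float = 0.0
    s: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if not (0.0 <= self.rho_y <= 1.0):
            raise ValueError(f"rho_y must be in [0, 1], got {self.rho_y}")
        for name in ("f", "k", "s"):
            v = getattr(self, name)
            if not (-1.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [-1, 1], got {v}")


@dataclass
class MultiLocusModel:
    """An ordered collection of loci plus inter-locus genotype correlations.

    ``k_matrix[i, j]`` is the correlation between the per-locus genotypic
    values at loci i and j (zero diagonal, symmetric, entries in [-1, 1]).
    """

    loci: list[LocusParams]
    k_matrix: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.loci)
        if n < 1:
            raise ValueError("need at least one locus")
        if self.k_matrix is None:
            self.k_matrix = np.zeros((n, n))
        self.k_matrix = np.asarray(self.k_matrix, dtype=float)
        if self.k_matrix.shape != (n, n):
            raise ValueError("k_matrix shape must match number of loci")
        if not np.allclose(self.k_matrix, self.k_matrix.T):
            raise ValueError("k_matrix must be symmetric")
        if np.any(np.abs(self.k_matrix) > 1.0 + 1e-12):
            raise ValueError("|k_ij| must be <= 1")
        if np.any(np.abs(np.diag(self.k_matrix)) > 1e-12):
            raise ValueError("k_matrix diagonal must be zero")

    @property
    def n_loci(self) -> int:
        return len(self.loci)
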